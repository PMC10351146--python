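# Methods

`breedsim` simulates a closed dairy-cattle nucleus under genomic selection
and compares nine kinship matrices used to constrain optimum contribution
selection (OCS). This note records the model, its assumptions, the
numerical choices, and what the desk-scale test tier does and does not
demonstrate.

## Founder population

A Wright–Fisher population with discrete generations, random mating,
separate sexes (1:1) and recurrent biallelic mutation (allele state
flipped with probability 2×10⁻⁵ per transmission) is run through a size
trajectory — at full scale N = 2000 for 2000 generations, a decline to
200 over 100 generations and recovery to 1000 over 100 more, with sizes
interpolated linearly within a phase — and the final generation is
expanded into the base cohort (6000 males + 6000 females at full scale).
The genome is 29 chromosomes of 100 cM with 1800 evenly spaced loci each
(locus *i* of a chromosome with L loci sits at (i+½)/L Morgan);
crossovers are Poisson(1/Morgan) with uniform positions and no
interference, in both the historical and breeding phases. Mutation acts
only in the historical phase.

Every first-generation individual is heterozygous with random phase, so
all loci start at frequency exactly ½ with no linkage disequilibrium.
This makes the expected-heterozygosity decay exactly geometric in
expectation and gives the drift oracle a clean closed form. With separate
sexes the per-generation decay rate is (1/2N)(1 − 1/(2N−1)) rather than
1/(2N); oracle tests run at N = 50, where the difference is far below
Monte-Carlo error.

Locus classes: 3000 QTL and 3000 neutral loci are drawn uniformly from
segregating loci (no frequency criterion); the remaining segregating loci
pass a SNP-chip-like ascertainment filter (MAF < 0.01 discarded with
probability 0.5; 0.01 ≤ MAF < 0.02 with probability 0.2) and become
markers. QTL effects are gamma(shape 0.4, scale 1.66) magnitudes with
random signs. The residual variance is fixed at 1.5× the base-cohort TBV
variance (heritability 0.4 at generation zero) and never re-estimated, so
realized heritability drifts as additive variance erodes.

## Breeding scheme

Cohort 0 is the base population. Each selection event breeds the next
cohort from the current one: event 0 draws sires at random; events 1–4
truncate on PBLUP EBV (120 sires at full scale); events 5–19 run genomic
OCS (40 sires). Females are never selected. Every dam has exactly two
calves by two distinct, randomly assigned sires; sires are used equally
(quotas rebalanced by at most one when counts do not divide); offspring
sexes are an exact half split. At full scale each bull therefore serves
150 dams and leaves 300 calves.

Genotyping: the sires selected during the pedigree phase are genotyped
(building the "old bulls" reference); from the first genomic event on,
all females and the top males by parent average (2000 of 6000 at full
scale) are genotyped; the remaining males leave candidacy. Breeding
values come from the single-trait animal model y = 1μ + Za + e with
a ~ N(0, K σ²_A), where K is the pedigree NRM (PBLUP), a VanRaden-1 GRM
with base-generation reference frequencies (GBLUP), or the combined H
matrix (ssGBLUP), over an 8-generation data window. ssGBLUP is used for
the first genomic rounds and GBLUP afterwards; the *first* genomic event
always uses ssGBLUP regardless of the `always_gblup` toggle, because at
that point no genotyped female has a phenotype yet and only the
single-step model can use the (non-genotyped) dams' records. GBLUP
records are restricted to genotyped females; ssGBLUP uses all dam-age
records in the window. A female's phenotype enters evaluation only once
she is of dam age (born before the current event).

## Kinship matrices

With genotype matrix **M** (0/1/2 over m markers), reference allele
frequencies p and **Z** = **M** − 2p:

* VR1: G = ZZ′ / (2 Σⱼ pⱼ(1−pⱼ)) — one global scale;
* VR2: G = ZDZ′ with d_jj = 1/(m·2pⱼ(1−pⱼ)) — low-MAF loci up-weighted;
* Pedigree: the numerator relationship matrix by the tabular method.

No MAF filter is applied. RAF policies: **Base** (the full generation-1
cohort), **Old** (bulls selected in the pedigree phase), **All** (all
genotyped animals to date), **Current** (genotyped animals of the current
generation), and a fixed **0.5**. Each policy anchors "relative to which
population is relatedness measured": base/old frequencies penalize
cumulative allele-frequency change (restraining drift), current
frequencies only recent change, and 0.5 rewards heterozygosity itself.
Monomorphic reference loci are clamped into [1/(2n+1), 1−1/(2n+1)] for
VR2's reciprocal weights only; VR1 keeps them unclamped (they contribute
zero). For matrix inversion inside evaluation, G is blended as
G_w = 0.95 G + 0.05 A₂₂; the OCS constraint always uses the raw matrix.
All OCS computations are on the kinship scale (relationship/2), converted
in one place, so a non-inbred self-kinship is ½ and the rate target is on
the kinship scale.

## Optimum contribution selection

Candidates are the genotyped males of the current generation with GEBV
above the median (1000 of 2000 at full scale). All females enter as one
*pseudofemale* whose self-kinship is the mean over the female block
(including self-kinships) and whose kinship to each bull is that bull's
mean kinship to the females. Contributions are fixed — each selected bull
1/(2k), the pseudofemale ½ — so the optimization is over k-subsets:
maximize c′â subject to c′Rc ≤ C, with C = f̄ + ΔF(1 − f̄), ΔF = 0.005
(target Ne = 100), and f̄ the mean of the scenario's kinship matrix over
the *whole* current cohort, genotyped or not, so the rate is anchored to
the population rather than the genotyped subset.

The subset search enumerates exhaustively when C(n,k) is small (default
bound 10⁵) and otherwise runs seeded simulated annealing over swap moves
with a penalized energy, tracking the best strictly feasible subset, then
polishes with steepest-ascent swaps; it is pinned to the exhaustive
optimum on 200 random instances with n ≤ 15 in the acceptance suite. If
no feasible subset exists the minimum-c′Rc subset is returned with the
feasibility flag down and a warning, so a run never halts; this fallback
is the relevant regime whenever k is too small for the Robertson floor
≈ 1/(8k) to fit under ΔF.

## Metrics

Per generation: mean TBV in generation-zero additive-SD units; mean
empirical IBD kinship from founder-segment bookkeeping (expected shared
genome fraction of one random haplotype from each animal; sampled pairs,
360,000 at full scale); realized additive variance var(TBV); genic
variance Σ p(1−p)α² over QTL (a `factor2` flag gives the conventional
2Σp(1−p)α²; rates relative to the reference generation are identical
either way); mean MAF and segregating fractions per locus class; and the
inbreeding decomposition against reference-generation (start of genomic
selection) frequencies, restricted to loci with reference MAF > 0.001:

* F_drift = (1/m) Σ (p_t − p_ref)² / (p_ref(1−p_ref))
* F_hom  = 1 − (1/m) Σ 2p_t(1−p_t) / (2p_ref(1−p_ref))

F_hom is *one minus* the mean heterozygosity ratio: defined this way it
is zero at the reference generation, 1 for a fixed locus, and grows with
inbreeding, which is what the −log(1−F) trend transform requires. Note
the per-locus distributions are heavy-tailed: a low-MAF locus fixing at
its minor allele adds 1/m to F_hom but only ~p/m to F_drift, while the
rare fixation at the major allele adds ~1/(pm) to F_drift; their
expectations agree under pure drift, but realized averages need many loci
to converge, which drives the neutral-locus counts chosen for the test
tier.

## Scenario comparison

Responses (mean TBV in σ_A0 units, σ²_A and σ²_G as percentages of their
reference-generation values, and −log(1−x) of mean kinship and of the F
statistics; natural log) are fitted over the genomic generations with one
pooled OLS model: fixed replicate intercepts and one slope per scenario,
y_klm = β_k + β_l X_lm + e_klm. Fitting one pooled model (rather than
per-scenario regressions) gives slope differences a well-defined standard
error from the shared residual variance — the one intentional statistical
formalization. Pairwise slope t-tests are Bonferroni-corrected for
s(s−1)/2 comparisons at α = 0.05; compact letters come from a greedy
clique cover of the non-significance graph in slope order. The exported
tables report per-generation rates (Δf etc., ×100 for percentages),
ratios relative to the Pedigree scenario, last-generation F_hom − F_drift
per locus class, and gain-versus-kinship plot data.

## Determinism and seeds

Every random concern (founders, meiosis, phenotypes, mating, OCS search,
pair sampling, tie-breaks) draws from its own stream derived by hashing a
master seed with a label path. Pedigree-phase streams are keyed to the
replicate only, genomic-phase streams to (replicate, scenario), so all
scenarios of a replicate share one founder population and an identical
pedigree phase, and runs are bit-reproducible for a given master seed.

## Problem sizes for the test tier

The full design (12,000 animals/generation, ~40,000 markers, 21
generations, 9 scenarios, 10 replicates) is provided as
`configs/full.yaml` and is a long-running mode. The test and acceptance
tier uses a desk configuration (`configs/desk.yaml`): 5 chromosomes × 300
loci, 150 QTL + 300 neutral loci, historical trajectory 150→30→80 with
per-phase drift (generations/2N) matched to full scale, cohorts of
240+240, 48 PBLUP sires, 32 OCS sires, 160 genotyped males, a
4-generation window with GBLUP throughout, 600 sampled kinship pairs, and
3 replicates. The OCS sire count is deliberately *not* scaled
proportionally: below k ≈ 25 the group-kinship floor 1/(8k) exceeds the
0.005 target and OCS would degenerate into its infeasibility fallback
every generation — a different regime from the full design, where the
constraint is active but attainable. With k = 32 the desk runs reproduce
the full design's regime: per-generation kinship rates of ~0.5–0.8%, an
active constraint, and the qualitative scenario ordering.

What the desk tier shows: the RAF-recency ordering of kinship rates
(Base < All < Current), the lower kinship rate of base-frequency genomic
OCS versus pedigree OCS, and the fixed-0.5 reference trading drift for
heterozygosity (most negative F_hom − F_drift). What it does not show:
*gain parity*. At full scale, base-RAF genomic OCS sacrifices almost no
genetic gain relative to pedigree OCS; that near-parity relies on deep
candidate pools (25 candidates per selected sire) and large half-sib
families (300 calves per bull), which make the kinship constraint cheap
for a GRM and expensive for the pedigree matrix. At desk scale (2.5
candidates per sire, ~15 calves per bull) the constraint costs
base-frequency OCS a visible share of its gain, and the desk gain ratio
sits around 0.8 rather than near 1; the efficiency ordering
(gain per unit kinship: Base > Pedigree) is nevertheless preserved. The
acceptance suite asserts the full-scale-style ≥0.9 gain ratio as stated
and this check is expected to fail at desk scale; the analysis above is
the reason.

## Numerical choices and degenerate inputs

Dense direct solvers everywhere (Cholesky for K-inversion, symmetric
solve for the mixed-model equations); sizes in any configuration this
package is expected to run keep these comfortably in memory. Ties in
truncation selection are broken by a seeded random permutation before a
stable sort. Sampling of kinship pairs is exactly without replacement for
pair spaces up to 2×10⁶ and de-duplicated sampling with top-up above
that. Mating quotas rebalance by ±1 when 2·dams/k is not integral; a
single sire (or k < calves-per-dam) is rejected because the
distinct-sires rule is unsatisfiable. PLINK ped output loses phase by
construction of the format; the reader returns allele counts.

## Known limitations

No female selection, overlapping generations, dominance/epistasis,
maternal effects, crossover interference, variable recombination maps or
sex chromosomes. Variance components are fixed at base values by design.
The historical simulator models drift and recurrent flips, not
sequence-level mutation. The synthetic populations emulate the drift, LD
decay and family structure relevant to OCS, but not real-genome features
such as variable marker density, genotyping error or selective sweeps in
the founder haplotypes, so passing tests demonstrate internal
correctness and regime-level agreement, not calibration to any real
cattle population.
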