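"""Founder (base-population) simulation.

A historical population is simulated forward in time under random mating
with discrete generations, a 1:1 sex ratio, Poisson recombination and
recurrent biallelic mutation (allele state flipped with a fixed per-allele
per-transmission probability). Every locus starts at allele frequency
exactly one half: each first-generation individual is heterozygous with a
random phase, which also leaves the initial population free of linkage
disequilibrium. Population size follows a phase trajectory (sizes change
linearly per generation within a phase); the final generation is expanded
into the base cohort of the breeding program.

Loci are then partitioned into QTL and neutral loci (sampled uniformly from
segregating loci with no frequency criterion) and markers, which pass an
ascertainment filter shaped like a commercial SNP chip: loci with
MAF < 0.01 are discarded with probability 0.5, loci with 0.01 <= MAF < 0.02
with probability 0.2. QTL receive additive allele-substitution effects with
gamma-distributed magnitudes and random signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .genome import GenomeGrid, draw_crossovers, inheritance_mask
from .rng import seed_stream

__all__ = [
    "MARKER", "QTL", "NEUTRAL", "DISCARDED",
    "GenomeParams", "LocusMap", "TraitArchitecture", "FounderPopulation",
    "trajectory_sizes", "simulate_historical", "partition_loci",
    "assign_qtl_effects", "simulate_founders",
]

MARKER, QTL, NEUTRAL, DISCARDED = 0, 1, 2, 3
_CLASS_NAMES = {MARKER: "MARKER", QTL: "QTL", NEUTRAL: "NEUTRAL", DISCARDED: "DISCARDED"}


@dataclass(frozen=True)
class GenomeParams:
    """Genome architecture and historical-population settings."""

    n_chromosomes: int = 29
    loci_per_chromosome: int = 1800
    chromosome_length: float = 1.0  # Morgan
    mutation_rate: float = 2e-5
    historical_trajectory: tuple[tuple[int, int], ...] = ((2000, 2000), (200, 100), (1000, 100))
    base_males: int = 6000
    base_females: int = 6000
    n_qtl: int = 3000
    n_neutral: int = 3000

    def __post_init__(self):
        if min(self.n_chromosomes, self.loci_per_chromosome,
               self.base_males, self.base_females, self.n_qtl, self.n_neutral) <= 0:
            raise ValueError("all genome counts must be positive")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must lie in [0, 1)")
        if not self.historical_trajectory:
            raise ValueError("historical trajectory must have at least one phase")
        if any(size <= 1 or gens <= 0 for size, gens in self.historical_trajectory):
            raise ValueError("trajectory phases need size > 1 and generations > 0")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "GenomeParams":
        g = cfg.scaled().genome
        return cls(
            n_chromosomes=g.n_chromosomes,
            loci_per_chromosome=g.loci_per_chromosome,
            chromosome_length=g.chromosome_length,
            mutation_rate=g.mutation_rate,
            historical_trajectory=tuple((p.size, p.generations) for p in g.historical_trajectory),
            base_males=g.base_males,
            base_females=g.base_females,
            n_qtl=g.n_qtl,
            n_neutral=g.n_neutral,
        )

    def grid(self) -> GenomeGrid:
        return GenomeGrid.create(self.n_chromosomes, self.loci_per_chromosome,
                                 self.chromosome_length)


@dataclass
class LocusMap:
    """Per-locus chromosome, genetic position and class."""

    grid: GenomeGrid
    locus_class: np.ndarray  # uint8 codes MARKER/QTL/NEUTRAL/DISCARDED

    def __post_init__(self):
        if len(self.locus_class) != self.grid.n_loci:
            raise ValueError("locus_class length does not match grid")

    @property
    def chromosome(self) -> np.ndarray:
        return self.grid.chrom_of_locus

    @property
    def position(self) -> np.ndarray:
        """Genetic position within the chromosome (Morgan)."""
        return self.grid.pos_local

    def indices(self, cls: int) -> np.ndarray:
        return np.flatnonzero(self.locus_class == cls)

    @property
    def marker_indices(self) -> np.ndarray:
        return self.indices(MARKER)

    @property
    def qtl_indices(self) -> np.ndarray:
        return self.indices(QTL)

    @property
    def neutral_indices(self) -> np.ndarray:
        return self.indices(NEUTRAL)

    @property
    def m(self) -> int:
        """Number of marker loci (the GRM denominator count)."""
        return int((self.locus_class == MARKER).sum())

    def class_names(self) -> np.ndarray:
        return np.array([_CLASS_NAMES[c] for c in self.locus_class])


@dataclass
class TraitArchitecture:
    """Additive trait: QTL effects and base-generation variance components."""

    qtl_effects: np.ndarray
    base_additive_variance: float
    residual_variance: float
    base_heritability: float = 0.4

    @property
    def base_sd(self) -> float:
        return float(np.sqrt(self.base_additive_variance))

    @property
    def lambda_ratio(self) -> float:
        """Mixed-model shrinkage ratio sigma_e^2 / sigma_A^2 (fixed at base values)."""
        return self.residual_variance / self.base_additive_variance


@dataclass
class FounderPopulation:
    """Phased base-cohort haplotypes plus locus map and trait architecture."""

    haplotypes: np.ndarray  # (2n, L) uint8, rows 2i, 2i+1 belong to individual i
    sex: np.ndarray  # 0 = male, 1 = female
    locus_map: LocusMap
    trait: TraitArchitecture

    def __post_init__(self):
        if self.haplotypes.shape[0] != 2 * len(self.sex):
            raise ValueError("haplotype count must be twice the individual count")

    @property
    def n(self) -> int:
        return len(self.sex)

    @property
    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def trajectory_sizes(trajectory: tuple[tuple[int, int], ...]) -> np.ndarray:
    """Per-generation population sizes; linear interpolation within phases."""
    sizes = [trajectory[0][0]] * trajectory[0][1]
    prev = trajectory[0][0]
    for size, gens in trajectory[1:]:
        steps = np.linspace(prev, size, gens + 1)[1:]
        sizes.extend(int(round(x)) for x in steps)
        prev = size
    return np.asarray(sizes, dtype=np.int64)


def _wf_generation(rng: np.random.Generator, haplotypes: np.ndarray, n_offspring: int,
                   grid: GenomeGrid, mutation_rate: float) -> np.ndarray:
    """One generation of random mating with recombination and mutation."""
    n_parents = haplotypes.shape[0] // 2
    n_female = n_parents // 2
    n_male = n_parents - n_female
    if n_female < 1 or n_male < 1:
        raise ValueError("need at least one parent of each sex")
    dams = rng.integers(0, n_female, size=n_offspring)
    sires = n_female + rng.integers(0, n_male, size=n_offspring)
    out = np.empty((2 * n_offspring, grid.n_loci), dtype=np.uint8)
    for k, parent in enumerate((dams, sires)):
        xo = draw_crossovers(rng, n_offspring, grid)
        mask = inheritance_mask(xo, grid)
        out[k::2] = np.where(mask, haplotypes[2 * parent + 1], haplotypes[2 * parent])
    if mutation_rate > 0.0:
        n_mut = rng.binomial(out.size, mutation_rate)
        if n_mut:
            flat = rng.integers(0, out.size, size=n_mut)
            np.bitwise_xor.at(out.reshape(-1), flat, 1)
    return out


def simulate_historical(params: GenomeParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Run the historical population and expand it into the base cohort.

    Returns the phased haplotypes of the base cohort (males first, then
    females) and the per-locus base allele frequencies. Mutation acts on
    every historical transmission, including the final expansion; the
    breeding phase afterwards is mutation-free.
    """
    rng = np.random.default_rng(seed)
    grid = params.grid()
    sizes = trajectory_sizes(params.historical_trajectory)
    n0 = int(sizes[0])
    phase = rng.integers(0, 2, size=(n0, grid.n_loci), dtype=np.uint8)
    haps = np.empty((2 * n0, grid.n_loci), dtype=np.uint8)
    haps[0::2] = phase
    haps[1::2] = 1 - phase
    for n_next in sizes[1:]:
        haps = _wf_generation(rng, haps, int(n_next), grid, params.mutation_rate)
    haps = _wf_generation(rng, haps, params.base_males + params.base_females,
                          grid, params.mutation_rate)
    return haps, haps.mean(axis=0)


def partition_loci(freqs: np.ndarray, params: GenomeParams, seed: int) -> LocusMap:
    """Assign locus classes from base-cohort allele frequencies.

    QTL and neutral loci are sampled uniformly from segregating loci
    (0 < p < 1); the remaining segregating loci pass the MAF ascertainment
    filter and become markers; everything else is discarded.
    """
    rng = np.random.default_rng(seed)
    grid_n = len(freqs)
    maf = np.minimum(freqs, 1.0 - freqs)
    segregating = (freqs > 0.0) & (freqs < 1.0)
    n_special = params.n_qtl + params.n_neutral
    seg_idx = np.flatnonzero(segregating)
    if len(seg_idx) < n_special:
        raise ValueError(
            f"only {len(seg_idx)} segregating loci; need at least {n_special} "
            "for QTL and neutral classes")
    picked = rng.choice(seg_idx, size=n_special, replace=False)
    classes = np.full(grid_n, DISCARDED, dtype=np.uint8)
    classes[picked[:params.n_qtl]] = QTL
    classes[picked[params.n_qtl:]] = NEUTRAL
    remaining = segregating.copy()
    remaining[picked] = False
    discard_p = np.where(maf < 0.01, 0.5, np.where(maf < 0.02, 0.2, 0.0))
    survives = rng.random(grid_n) >= discard_p
    classes[remaining & survives] = MARKER
    return LocusMap(GenomeGrid.create(params.n_chromosomes, params.loci_per_chromosome,
                                      params.chromosome_length), classes)


def assign_qtl_effects(locus_map: LocusMap, base_haplotypes: np.ndarray, seed: int,
                       heritability: float = 0.4, gamma_shape: float = 0.4,
                       gamma_scale: float = 1.66) -> TraitArchitecture:
    """Draw QTL effects and anchor the variance components at the base cohort.

    Effect magnitudes are gamma(shape, scale) with the sign of each effect
    randomized to +-1; the residual variance is fixed from the base-cohort
    true-breeding-value variance at the base heritability and never changes,
    so realized heritability drifts as the additive variance erodes.
    """
    rng = np.random.default_rng(seed)
    qtl_idx = locus_map.qtl_indices
    if len(qtl_idx) == 0:
        raise ValueError("locus map has no QTL")
    magnitude = rng.gamma(gamma_shape, gamma_scale, size=len(qtl_idx))
    sign = rng.integers(0, 2, size=len(qtl_idx)) * 2 - 1
    effects = magnitude * sign
    counts = (base_haplotypes[0::2, qtl_idx].astype(np.int16)
              + base_haplotypes[1::2, qtl_idx])
    tbv = counts @ effects
    va0 = float(tbv.var())
    ve = va0 * (1.0 - heritability) / heritability
    return TraitArchitecture(effects, va0, ve, heritability)


def simulate_founders(params: GenomeParams, seed: int) -> FounderPopulation:
    """Full founder pipeline: historical simulation, partition, effects."""
    haps, freqs = simulate_historical(params, seed_stream(seed, "historical"))
    locus_map = partition_loci(freqs, params, seed_stream(seed, "partition"))
    trait = assign_qtl_effects(locus_map, haps, seed_stream(seed, "effects"))
    sex = np.concatenate([np.zeros(params.base_males, dtype=np.uint8),
                          np.ones(params.base_females, dtype=np.uint8)])
    return FounderPopulation(haps, sex, locus_map, trait)
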