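"""Meiosis, trait values, phenotypes and the mating design."""

import numpy as np
import pytest

from breedsim.founders import QTL, LocusMap, TraitArchitecture
from breedsim.genetics import (FEMALE, MALE, Cohort, assign_phenotypes,
                               base_cohort, mate_cohort, meiose, plan_matings,
                               true_breeding_value)
from breedsim.genome import GenomeGrid, draw_crossovers, reconstruct_alleles
from breedsim.kinship import pair_segment_kinship


def test_zero_crossovers_returns_parental_haplotype(rng):
    """With genetic length ~0, Poisson(L) draws no crossovers and the gamete
    is one parental haplotype verbatim."""
    short = GenomeGrid.create(1, 80, 1e-12)
    from breedsim.genome import founder_segments
    from breedsim.genetics import Individual
    haps = rng.integers(0, 2, size=(2, 80), dtype=np.uint8)
    ends, labels = founder_segments(2, short)
    parent = Individual(1, 0, 0, MALE, 0, haps, tuple(ends), tuple(labels),
                        0.0, np.nan, np.nan, False)
    gam = meiose(parent, short, np.random.default_rng(1))
    assert (np.array_equal(gam.alleles, haps[0])
            or np.array_equal(gam.alleles, haps[1]))


def test_homozygous_parent_gamete_invariant(grid_small, rng):
    haps = np.tile(rng.integers(0, 2, grid_small.n_loci, dtype=np.uint8), (2, 1))
    from breedsim.genome import founder_segments
    ends, labels = founder_segments(2, grid_small)
    from breedsim.genetics import Individual
    parent = Individual(1, 0, 0, MALE, 0, haps, tuple(ends), tuple(labels),
                        0.0, np.nan, np.nan, False)
    for seed in range(5):
        gam = meiose(parent, grid_small, np.random.default_rng(seed))
        np.testing.assert_array_equal(gam.alleles, haps[0])


def test_crossover_count_poisson_mean(rng):
    """Mean crossover count on a 1-Morgan chromosome is 1 within 3 SE."""
    grid = GenomeGrid.create(1, 10, 1.0)
    xo = draw_crossovers(rng, 10_000, grid)
    counts = np.diff(xo.offsets)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - 1.0) < 3 * se


def test_true_breeding_value_examples(grid_small):
    classes = np.full(grid_small.n_loci, 3, dtype=np.uint8)
    classes[[4, 10]] = QTL
    lm = LocusMap(grid_small, classes)
    trait = TraitArchitecture(np.array([2.0, -1.0]), 1.0, 1.5)
    haps = np.zeros((2, grid_small.n_loci), dtype=np.uint8)
    from breedsim.genetics import Individual
    ind = Individual(1, 0, 0, MALE, 0, haps, (None, None), (None, None),
                     0.0, np.nan, np.nan, False)
    assert true_breeding_value(ind, lm, trait) == 0.0
    haps[0, 4] = 1  # heterozygous at the first QTL
    assert true_breeding_value(ind, lm, trait) == 2.0
    # random genotype equals an independent dot product
    rng = np.random.default_rng(3)
    haps[:] = rng.integers(0, 2, haps.shape)
    counts = haps[:, [4, 10]].sum(axis=0)
    assert true_breeding_value(ind, lm, trait) == pytest.approx(
        counts @ np.array([2.0, -1.0]))


def test_phenotypes_female_only_with_base_h2(tiny_base, tiny_founders):
    cohort = tiny_base.copy()
    trait = tiny_founders.trait
    assign_phenotypes(cohort, trait, np.random.default_rng(2))
    assert np.all(np.isnan(cohort.phenotype[cohort.male_indices]))
    assert not np.any(np.isnan(cohort.phenotype[cohort.female_indices]))
    with pytest.raises(ValueError, match="male"):
        assign_phenotypes(cohort, trait, np.random.default_rng(0),
                          indices=cohort.male_indices[:1])


def test_phenotype_variance_matches_h2(tiny_founders):
    """var(y) ~ sigma_A^2 + 1.5 sigma_A^2, i.e. h2 ~ 0.4, on a large cohort."""
    trait = tiny_founders.trait
    rng = np.random.default_rng(8)
    n = 4000
    tbv = rng.normal(0.0, trait.base_sd, n)
    y = tbv + rng.normal(0.0, np.sqrt(trait.residual_variance), n)
    assert y.var() == pytest.approx(2.5 * trait.base_additive_variance, rel=0.1)


def test_zero_residual_phenotype_equals_tbv(tiny_base, tiny_founders):
    cohort = tiny_base.copy()
    trait = TraitArchitecture(tiny_founders.trait.qtl_effects,
                              tiny_founders.trait.base_additive_variance, 0.0)
    assign_phenotypes(cohort, trait, np.random.default_rng(0))
    f = cohort.female_indices
    np.testing.assert_allclose(cohort.phenotype[f], cohort.tbv[f])


def test_mating_counting_identities(tiny_base, tiny_founders, rng):
    """10 sires x 60 dams: each sire 12 calves, each dam 2, by distinct sires."""
    grid = tiny_founders.locus_map.grid
    sires = tiny_base.male_indices[:10]
    nxt = mate_cohort(tiny_base, sires, grid, rng, tiny_founders.locus_map,
                      tiny_founders.trait, id_start=1000)
    assert nxt.n == 2 * len(tiny_base.female_indices)
    sire_counts = np.unique(nxt.sire, return_counts=True)[1]
    assert np.all(sire_counts == nxt.n // len(sires))
    dam_counts = np.unique(nxt.dam, return_counts=True)[1]
    assert np.all(dam_counts == 2)
    pairs = nxt.sire.reshape(-1, 2)
    assert np.all(pairs[:, 0] != pairs[:, 1])  # distinct sires per dam
    assert (nxt.sex == MALE).sum() == nxt.n // 2  # exact sex balance


def test_single_sire_mating_rejected(rng):
    with pytest.raises(ValueError, match="distinct"):
        plan_matings(np.array([3]), n_dams=1, calves_per_dam=2, rng=rng)


def test_uneven_quota_rebalanced(rng):
    pairs = plan_matings(np.arange(3), n_dams=5, calves_per_dam=2, rng=rng)
    counts = np.bincount(pairs.reshape(-1), minlength=3)
    assert counts.sum() == 10 and counts.max() - counts.min() <= 1


def test_allele_conservation(tiny_base, tiny_founders, rng):
    """No breeding-phase mutation: a calf never carries an allele absent
    from both parents."""
    grid = tiny_founders.locus_map.grid
    nxt = mate_cohort(tiny_base, tiny_base.male_indices[:5], grid, rng,
                      tiny_founders.locus_map, tiny_founders.trait, id_start=1000)
    for calf in range(0, 10):
        s = int(nxt.sire[calf] - tiny_base.ids[0])
        d = int(nxt.dam[calf] - tiny_base.ids[0])
        parent_has = ((tiny_base.haplotypes[2 * s:2 * s + 2].any(axis=0))
                      | (tiny_base.haplotypes[2 * d:2 * d + 2].any(axis=0)))
        calf_has = nxt.haplotypes[2 * calf:2 * calf + 2].any(axis=0)
        assert not np.any(calf_has & ~parent_has)


def test_segments_reconstruct_alleles(tiny_base, tiny_founders, rng):
    """Founder-segment lists reproduce the allele arrays exactly."""
    grid = tiny_founders.locus_map.grid
    nxt = mate_cohort(tiny_base, tiny_base.male_indices[:5], grid, rng,
                      tiny_founders.locus_map, tiny_founders.trait, id_start=1000)
    for h in range(0, 12):
        rebuilt = reconstruct_alleles(nxt.seg_ends[h], nxt.seg_labels[h],
                                      tiny_base.haplotypes, grid)
        np.testing.assert_array_equal(rebuilt, nxt.haplotypes[h])


def test_pedigree_frame_round_trip(tmp_path, tiny_base):
    from breedsim.genetics import pedigree_frame
    from breedsim import plink_io
    frame = pedigree_frame([tiny_base])
    assert len(frame) == tiny_base.n
    plink_io.write_pedigree(tmp_path / "ped.csv", frame)
    back = plink_io.read_pedigree(tmp_path / "ped.csv")
    assert list(back.columns) == plink_io.PEDIGREE_COLUMNS
    np.testing.assert_array_equal(back["id"], tiny_base.ids)


def test_full_sib_kinship_quarter(tiny_base, tiny_founders):
    """Full sibs from unrelated, non-inbred parents average kinship 1/4."""
    grid = tiny_founders.locus_map.grid
    rng = np.random.default_rng(44)
    sire = tiny_base.individual(0)
    dam = tiny_base.individual(int(tiny_base.female_indices[0]))
    values = []
    for _ in range(150):
        sibs = []
        for _ in range(2):
            g1, g2 = meiose(dam, grid, rng), meiose(sire, grid, rng)
            sibs.append((g1, g2))
        cohort = Cohort(
            1, np.array([1, 2]), np.zeros(2, np.int64), np.zeros(2, np.int64),
            np.zeros(2, np.uint8),
            np.stack([sibs[0][0].alleles, sibs[0][1].alleles,
                      sibs[1][0].alleles, sibs[1][1].alleles]),
            [sibs[0][0].seg_ends, sibs[0][1].seg_ends,
             sibs[1][0].seg_ends, sibs[1][1].seg_ends],
            [sibs[0][0].seg_labels, sibs[0][1].seg_labels,
             sibs[1][0].seg_labels, sibs[1][1].seg_labels],
            np.zeros(2), np.full(2, np.nan), np.full(2, np.nan),
            np.zeros(2, bool))
        values.append(pair_segment_kinship(cohort, 0, cohort, 1, grid.total_length))
    values = np.asarray(values)
    se = values.std(ddof=1) / np.sqrt(len(values))
    assert abs(values.mean() - 0.25) < 3 * se
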