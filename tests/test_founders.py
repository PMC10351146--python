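"""Founder simulation: drift, ascertainment, trait architecture, PLINK I/O."""

import numpy as np
import pytest

from breedsim.founders import (DISCARDED, MARKER, NEUTRAL, QTL, GenomeParams,
                               LocusMap, assign_qtl_effects, partition_loci,
                               simulate_historical, trajectory_sizes)
from breedsim.genome import GenomeGrid
from breedsim import plink_io


def test_trajectory_sizes_interpolates_linearly():
    sizes = trajectory_sizes(((100, 3), (20, 4), (60, 2)))
    assert list(sizes[:3]) == [100, 100, 100]
    assert list(sizes[3:7]) == [80, 60, 40, 20]  # linear decline 100 -> 20
    assert list(sizes[7:]) == [40, 60]


def test_full_scale_locus_count():
    params = GenomeParams()
    assert params.grid().n_loci == 29 * 1800


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        GenomeParams(historical_trajectory=())
    with pytest.raises(ValueError):
        GenomeParams(mutation_rate=-1e-5)
    with pytest.raises(ValueError):
        GenomeParams(base_males=0)


def test_heterozygosity_decay_one_generation():
    """With N=2 and no mutation, E[H1]/H0 = 1 - 1/(2N) = 0.75.

    Every first-generation individual is heterozygous, so H0 = 0.5 exactly;
    the decay factor is checked by Monte Carlo against the closed form.
    """
    params = GenomeParams(
        n_chromosomes=1, loci_per_chromosome=300, mutation_rate=0.0,
        historical_trajectory=((2, 1),), base_males=1, base_females=1,
        n_qtl=1, n_neutral=1)
    ratios = []
    for seed in range(250):
        _, freqs = simulate_historical(params, seed)
        het = 2.0 * freqs * (1.0 - freqs)
        ratios.append(het.mean() / 0.5)
    ratios = np.asarray(ratios)
    se = ratios.std(ddof=1) / np.sqrt(len(ratios))
    assert abs(ratios.mean() - 0.75) < 3 * se


def test_frequency_spectrum_symmetric(tiny_founders):
    """Initial frequency 1/2 and symmetric mutation leave E[p] at 1/2."""
    freqs = tiny_founders.allele_frequencies
    assert abs(freqs.mean() - 0.5) < 0.06


def test_partition_high_maf_locus_always_marker(rng):
    params = GenomeParams(n_chromosomes=1, loci_per_chromosome=100,
                          base_males=2, base_females=2, n_qtl=2, n_neutral=2)
    freqs = np.full(100, 0.30)
    lm = partition_loci(freqs, params, seed=1)
    assert (lm.locus_class == QTL).sum() == 2
    assert (lm.locus_class == NEUTRAL).sum() == 2
    assert (lm.locus_class == MARKER).sum() == 96  # MAF 0.30: retained surely


def test_partition_low_maf_discard_rate():
    """MAF < 0.01 loci are discarded with probability one half."""
    params = GenomeParams(n_chromosomes=1, loci_per_chromosome=10_000,
                          base_males=2, base_females=2, n_qtl=2, n_neutral=2)
    freqs = np.full(10_000, 0.005)
    lm = partition_loci(freqs, params, seed=3)
    n_markers = (lm.locus_class == MARKER).sum()
    expected = (10_000 - 4) * 0.5
    assert abs(n_markers - expected) < 3 * np.sqrt(9996 * 0.25)


def test_partition_classes_disjoint_and_exhaustive(tiny_founders):
    lm = tiny_founders.locus_map
    counts = {c: (lm.locus_class == c).sum() for c in (MARKER, QTL, NEUTRAL, DISCARDED)}
    assert sum(counts.values()) == lm.grid.n_loci
    assert counts[QTL] == 40 and counts[NEUTRAL] == 40
    assert lm.m == counts[MARKER]


def test_partition_requires_enough_segregating_loci():
    params = GenomeParams(n_chromosomes=1, loci_per_chromosome=100,
                          base_males=2, base_females=2, n_qtl=60, n_neutral=60)
    freqs = np.zeros(100)
    with pytest.raises(ValueError, match="segregating"):
        partition_loci(freqs, params, seed=0)


def test_marker_ascertainment_flattens_maf(tiny_founders):
    """Markers have higher mean MAF than the unfiltered segregating pool."""
    lm = tiny_founders.locus_map
    freqs = tiny_founders.allele_frequencies
    maf = np.minimum(freqs, 1 - freqs)
    seg = (freqs > 0) & (freqs < 1)
    pool = seg & np.isin(lm.locus_class, (MARKER, DISCARDED))
    assert maf[lm.locus_class == MARKER].mean() > maf[pool].mean()


def test_qtl_effect_moments():
    """|alpha| has the gamma(0.4, 1.66) mean 0.664 and variance ~1.102."""
    grid = GenomeGrid.create(1, 50_000)
    lm = LocusMap(grid, np.full(grid.n_loci, QTL, dtype=np.uint8))
    haps = np.random.default_rng(5).integers(0, 2, size=(8, grid.n_loci)).astype(np.uint8)
    trait = assign_qtl_effects(lm, haps, seed=9)
    mag = np.abs(trait.qtl_effects)
    assert len(trait.qtl_effects) == 50_000
    assert abs(mag.mean() - 0.4 * 1.66) < 3 * mag.std() / np.sqrt(len(mag))
    assert abs(mag.var() - 0.4 * 1.66**2) < 0.05
    # signs are an even coin flip
    assert abs((trait.qtl_effects > 0).mean() - 0.5) < 0.02


def test_variance_components_anchored_at_h2(tiny_founders):
    trait = tiny_founders.trait
    assert trait.residual_variance == pytest.approx(
        trait.base_additive_variance * 1.5)
    assert trait.base_heritability == 0.4


def test_plink_round_trip(tmp_path, tiny_founders):
    """Unphased genotypes, animal count and locus count survive the round trip."""
    pop = tiny_founders
    prefix = tmp_path / "founders"
    plink_io.write_plink(prefix, pop.haplotypes[:40], pop.locus_map,
                         ids=np.arange(1, 21), sex=pop.sex[:20])
    data = plink_io.read_plink(prefix)
    expected = pop.haplotypes[:40:2].astype(np.int8) + pop.haplotypes[1:40:2]
    assert data.genotypes.shape == (20, pop.locus_map.grid.n_loci)
    np.testing.assert_array_equal(data.genotypes, expected)
    np.testing.assert_array_equal(data.ids, np.arange(1, 21))
    assert len(data.locus_map) == pop.locus_map.grid.n_loci


def test_plink_heterozygote_written_as_two_codes(tmp_path):
    grid = GenomeGrid.create(1, 2)
    lm = LocusMap(grid, np.array([MARKER, MARKER], dtype=np.uint8))
    haps = np.array([[0, 1], [1, 1]], dtype=np.uint8)  # one het, one hom locus
    plink_io.write_plink(tmp_path / "one", haps, lm)
    line = (tmp_path / "one.ped").read_text().split()
    assert line[6:8] == ["1", "2"]  # heterozygote: two different allele codes
    assert line[8:10] == ["2", "2"]


def test_plink_rejects_malformed_input(tmp_path):
    (tmp_path / "bad.map").write_text("1 c1_l0 0.5 1\n")
    (tmp_path / "bad.ped").write_text("1 1 0 0 1 -9 1\n")  # missing one allele
    with pytest.raises(ValueError, match="expected"):
        plink_io.read_plink(tmp_path / "bad")
    (tmp_path / "bad.ped").write_text("1 1 0 0 1 -9 1 3\n")  # bad allele code
    with pytest.raises(ValueError, match="allele codes"):
        plink_io.read_plink(tmp_path / "bad")
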