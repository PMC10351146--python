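"""Relationship matrices: VanRaden builders, NRM, H-inverse, IBD kinship."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breedsim.kinship import (RAF_ALL, RAF_HALF, RAFPolicy, allele_frequencies,
                              build_h_inverse, build_nrm, build_vr1, build_vr2,
                              compute_raf, kinship_scale, mean_segment_kinship,
                              pair_segment_kinship)


# ---------- reference allele frequencies ----------

def test_raf_fixed_half():
    p = compute_raf(RAFPolicy(RAF_HALF), None, m=7)
    np.testing.assert_array_equal(p, np.full(7, 0.5))


def test_raf_direct_count():
    geno = np.array([[0], [1], [2]])
    assert compute_raf(RAFPolicy(RAF_ALL), geno)[0] == 0.5


def test_raf_pooled_history_matches_tally(rng):
    """ALL-policy frequencies equal the per-animal allele tally."""
    chunks = [rng.integers(0, 3, size=(n, 12)) for n in (3, 5, 2)]
    pooled = np.concatenate(chunks)
    expected = pooled.sum(axis=0) / (2.0 * pooled.shape[0])
    np.testing.assert_allclose(compute_raf(RAFPolicy(RAF_ALL), pooled), expected)


def test_raf_empty_reference_rejected():
    with pytest.raises(ValueError, match="empty"):
        compute_raf(RAFPolicy(RAF_ALL), np.empty((0, 5)))


# ---------- VanRaden builders ----------

def test_vr1_single_locus_hand_example():
    """One locus, p=0.5, genotypes (0,1,2): Z=(-1,0,1), denominator 0.5."""
    G = build_vr1(np.array([[0], [1], [2]]), np.array([0.5]))
    np.testing.assert_allclose(G, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])


def test_vr1_centring_sum_zero(rng):
    M = rng.integers(0, 3, size=(8, 30))
    p = allele_frequencies(M)
    assert build_vr1(M, p).sum() == pytest.approx(0.0, abs=1e-9)


def test_vr1_matches_bruteforce(rng):
    M = rng.integers(0, 3, size=(10, 20)).astype(float)
    p = rng.uniform(0.05, 0.95, 20)
    G = build_vr1(M, p)
    denom = 2 * np.sum(p * (1 - p))
    for i in range(10):
        for k in range(10):
            zz = sum((M[i, j] - 2 * p[j]) * (M[k, j] - 2 * p[j]) for j in range(20))
            assert G[i, k] == pytest.approx(zz / denom, abs=1e-12)


def test_vr2_matches_bruteforce(rng):
    M = rng.integers(0, 3, size=(10, 20)).astype(float)
    p = rng.uniform(0.05, 0.95, 20)
    G = build_vr2(M, p)
    d = 1.0 / (20 * 2 * p * (1 - p))
    for i in range(10):
        for k in range(10):
            zz = sum(d[j] * (M[i, j] - 2 * p[j]) * (M[k, j] - 2 * p[j])
                     for j in range(20))
            assert G[i, k] == pytest.approx(zz, abs=1e-12)


def test_vr2_equals_vr1_single_locus():
    M = np.array([[0], [1], [2]], dtype=float)
    p = np.array([0.5])
    np.testing.assert_allclose(build_vr2(M, p), build_vr1(M, p))


def test_vr2_equals_vr1_at_uniform_half(rng):
    M = rng.integers(0, 3, size=(6, 15)).astype(float)
    p = np.full(15, 0.5)
    np.testing.assert_allclose(build_vr2(M, p), build_vr1(M, p), atol=1e-12)


def test_vr2_low_maf_weight_ratio():
    """A p=0.1 locus gets (2*0.5*0.5)/(2*0.1*0.9) ~ 2.78x the p=0.5 weight."""
    p = np.array([0.1, 0.5])
    d = 1.0 / (2 * 2 * p * (1 - p))
    assert d[0] / d[1] == pytest.approx(0.5 / 0.18)


def test_vr1_all_monomorphic_rejected():
    with pytest.raises(ValueError, match="monomorphic"):
        build_vr1(np.zeros((3, 4)), np.zeros(4))


def test_vr1_fixed_half_identity(rng):
    """With p=1/2 everywhere, VR1 reduces to ZZ'/(m/2)."""
    M = rng.integers(0, 3, size=(5, 12)).astype(float)
    Z = M - 1.0
    np.testing.assert_allclose(build_vr1(M, np.full(12, 0.5)), Z @ Z.T / 6.0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_builders_symmetric(seed):
    rng = np.random.default_rng(seed)
    M = rng.integers(0, 3, size=(6, 10)).astype(float)
    p = rng.uniform(0.01, 0.99, 10)
    for G in (build_vr1(M, p), build_vr2(M, p)):
        assert np.abs(G - G.T).max() < 1e-12 * max(1.0, np.abs(G).max())


# ---------- pedigree NRM ----------

def test_nrm_textbook_values():
    # founders 0,1 unrelated; 2 = 0x1; 3 = 0x1 (full sib of 2); 4 = 2x3
    sire = np.array([-1, -1, 0, 0, 2])
    dam = np.array([-1, -1, 1, 1, 3])
    A = build_nrm(sire, dam)
    assert A[0, 1] == 0.0
    assert A[0, 2] == 0.5  # parent-offspring
    assert A[2, 3] == 0.5  # full sibs
    assert A[4, 4] == 1.25  # offspring of full-sib mating
    np.testing.assert_allclose(build_nrm(np.full(4, -1), np.full(4, -1)), np.eye(4))


def test_nrm_matches_path_counting():
    """Tabular method equals the coancestry recursion on three pedigrees."""
    def coancestry(i, j, sire, dam, cache):
        if i > j:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        if i == j:
            s, d = sire[i], dam[i]
            val = 0.5 * (1 + (coancestry(s, d, sire, dam, cache)
                              if s >= 0 and d >= 0 else 0.0))
        else:
            s, d = sire[j], dam[j]  # j is the younger animal
            val = 0.0
            if s >= 0:
                val += 0.5 * coancestry(i, s, sire, dam, cache)
            if d >= 0:
                val += 0.5 * coancestry(i, d, sire, dam, cache)
        cache[(i, j)] = val
        return val

    pedigrees = [
        (np.array([-1, -1, 0, 0, 2]), np.array([-1, -1, 1, 1, 3])),
        (np.array([-1, -1, -1, 0, 0, 3]), np.array([-1, -1, -1, 1, 2, 4])),
        (np.array([-1, -1, 0, 2, 2]), np.array([-1, -1, 1, 1, 3])),
    ]
    for sire, dam in pedigrees:
        A = build_nrm(sire, dam)
        n = len(sire)
        expected = np.array([[2 * coancestry(i, j, sire, dam, {})
                              for j in range(n)] for i in range(n)])
        np.testing.assert_allclose(A, expected, atol=1e-12)


def test_nrm_positive_semidefinite():
    sire = np.array([-1, -1, 0, 0, 2, 2])
    dam = np.array([-1, -1, 1, 1, 3, 3])
    eig = np.linalg.eigvalsh(build_nrm(sire, dam))
    assert eig.min() > -1e-10


def test_nrm_requires_sorted_pedigree():
    with pytest.raises(ValueError, match="parents"):
        build_nrm(np.array([1, -1]), np.array([-1, -1]))


# ---------- H inverse ----------

def _toy_pedigree_A():
    sire = np.array([-1, -1, 0, 0, 2])
    dam = np.array([-1, -1, 1, 1, 3])
    return build_nrm(sire, dam)


def test_h_inverse_no_genotypes_is_a_inverse():
    A = _toy_pedigree_A()
    np.testing.assert_allclose(build_h_inverse(A, None, np.array([], dtype=int)),
                               np.linalg.inv(A))


def test_h_inverse_collapses_when_g_equals_a22():
    A = _toy_pedigree_A()
    g = np.arange(5)
    np.testing.assert_allclose(build_h_inverse(A, A, g, blend_weight=0.95),
                               np.linalg.inv(A), atol=1e-10)


def test_h_inverse_matches_block_formula():
    """H^-1 equals the inverse of the directly assembled H matrix."""
    A = _toy_pedigree_A()
    g = np.array([2, 3, 4])
    rng = np.random.default_rng(12)
    B = rng.normal(size=(3, 6))
    G = B @ B.T / 6 + A[np.ix_(g, g)]
    w = 0.95
    Gw = w * G + (1 - w) * A[np.ix_(g, g)]
    ng = np.array([0, 1])
    A11, A12, A22 = A[np.ix_(ng, ng)], A[np.ix_(ng, g)], A[np.ix_(g, g)]
    A22i = np.linalg.inv(A22)
    H = np.zeros_like(A)
    H[np.ix_(ng, ng)] = A11 + A12 @ A22i @ (Gw - A22) @ A22i @ A12.T
    H[np.ix_(ng, g)] = A12 @ A22i @ Gw
    H[np.ix_(g, ng)] = H[np.ix_(ng, g)].T
    H[np.ix_(g, g)] = Gw
    np.testing.assert_allclose(build_h_inverse(A, G, g, w), np.linalg.inv(H),
                               atol=1e-8)


# ---------- empirical IBD kinship ----------

def test_distinct_founders_zero_kinship(tiny_base, tiny_founders):
    L = tiny_founders.locus_map.grid.total_length
    assert pair_segment_kinship(tiny_base, 0, tiny_base, 1, L) == 0.0


def test_self_kinship_non_inbred_half(tiny_base, tiny_founders):
    L = tiny_founders.locus_map.grid.total_length
    assert pair_segment_kinship(tiny_base, 3, tiny_base, 3, L) == 0.5


def test_mean_kinship_of_founder_cohort_zero(tiny_base, tiny_founders, rng):
    L = tiny_founders.locus_map.grid.total_length
    assert mean_segment_kinship(tiny_base, 100, rng, L) == 0.0


def test_matrix_export_round_trip(tmp_path, rng):
    from breedsim.kinship import read_matrix, write_matrix
    M = rng.integers(0, 3, size=(4, 9)).astype(float)
    G = build_vr1(M, np.full(9, 0.5))
    ids = np.array([11, 12, 13, 14])
    write_matrix(tmp_path / "g", G, ids, "VR1", "BASE")
    K, meta = read_matrix(tmp_path / "g")
    np.testing.assert_allclose(K, G)
    assert meta["ids"] == [11, 12, 13, 14] and meta["raf_policy"] == "BASE"
    # the text lower triangle has n(n+1)/2 rows
    assert len((tmp_path / "g.txt").read_text().splitlines()) == 10


def test_kinship_scale_is_half_relationship(rng):
    M = rng.integers(0, 3, size=(4, 9)).astype(float)
    G = build_vr1(M, np.full(9, 0.5))
    np.testing.assert_allclose(kinship_scale(G), G / 2.0)
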