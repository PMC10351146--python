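"""Relationship and kinship matrices.

Two scales are used throughout. Builders return matrices on the
*relationship* (numerator-relationship-like) scale, where a non-inbred
animal has a self-relationship of 1; the *kinship* scale used by optimum
contribution selection is relationship / 2, so a non-inbred animal has
self-kinship 1/2. :func:`kinship_scale` is the single conversion point.

Genomic matrices follow VanRaden. With genotype matrix ``M`` (allele
counts 0/1/2 over ``m`` markers), reference allele frequencies ``p`` and
``Z = M - 2p``:

* method 1 (VR1):  G = Z Z' / (2 * sum_j p_j (1 - p_j))
* method 2 (VR2):  G = Z D Z',  d_jj = 1 / (m * 2 p_j (1 - p_j))

No MAF filter is applied. The choice of reference allele frequency (RAF)
is a policy: base-generation animals, old genotyped bulls, all genotyped
animals to date, the current generation, or a fixed 0.5 — each anchors
"identity by descent" to a different reference population.

The empirical IBD kinship uses the founder-segment bookkeeping: the
kinship of two animals is the expected fraction of genome shared
identical by descent by one haplotype drawn at random from each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .genetics import Cohort

__all__ = [
    "RAF_BASE", "RAF_OLD", "RAF_ALL", "RAF_CURRENT", "RAF_HALF", "RAFPolicy",
    "allele_frequencies", "compute_raf", "clamp_frequencies",
    "build_vr1", "build_vr2", "build_grm", "build_nrm", "build_h_inverse",
    "kinship_scale", "pair_segment_kinship", "mean_segment_kinship",
]

RAF_BASE = "BASE"
RAF_OLD = "OLD"
RAF_ALL = "ALL"
RAF_CURRENT = "CURRENT"
RAF_HALF = "HALF"
_RAF_KINDS = (RAF_BASE, RAF_OLD, RAF_ALL, RAF_CURRENT, RAF_HALF)


@dataclass(frozen=True)
class RAFPolicy:
    """Which animals' genotypes define the reference allele frequencies."""

    kind: str

    def __post_init__(self):
        if self.kind not in _RAF_KINDS:
            raise ValueError(f"unknown RAF policy {self.kind!r}; expected one of {_RAF_KINDS}")


def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Counted-allele frequencies from an (n, m) allele-count matrix."""
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2 or genotypes.shape[0] == 0:
        raise ValueError("need a non-empty (animals x markers) genotype matrix")
    return genotypes.mean(axis=0) / 2.0


def compute_raf(policy: RAFPolicy, reference_genotypes: np.ndarray | None,
                m: int | None = None) -> np.ndarray:
    """Resolve a RAF policy into a frequency vector.

    For the fixed-0.5 policy ``reference_genotypes`` may be None and ``m``
    gives the marker count; otherwise the reference cohort must be
    non-empty.
    """
    if policy.kind == RAF_HALF:
        if m is None:
            m = np.asarray(reference_genotypes).shape[1]
        return np.full(m, 0.5)
    if reference_genotypes is None or np.asarray(reference_genotypes).shape[0] == 0:
        raise ValueError(f"RAF policy {policy.kind} has an empty reference cohort")
    return allele_frequencies(reference_genotypes)


def clamp_frequencies(p: np.ndarray, n_reference: int) -> np.ndarray:
    """Clamp p into [1/(2n+1), 1 - 1/(2n+1)] so reciprocal weights stay finite."""
    lo = 1.0 / (2 * n_reference + 1)
    return np.clip(p, lo, 1.0 - lo)


def build_vr1(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """VanRaden method 1 relationship matrix G = ZZ' / (2 sum p(1-p)).

    Monomorphic loci are included as printed: they contribute zero to both
    Z and the denominator.
    """
    M = np.asarray(M, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all loci monomorphic at the reference frequencies; "
                         "VR1 denominator is zero")
    Z = M - 2.0 * p
    return (Z @ Z.T) / denom


def build_vr2(M: np.ndarray, p: np.ndarray, n_reference: int | None = None) -> np.ndarray:
    """VanRaden method 2 relationship matrix G = ZDZ', d_jj = 1/(m 2p_j(1-p_j)).

    Reference frequencies are clamped away from 0 and 1 before forming the
    reciprocal weights (centring still uses the unclamped p).
    """
    M = np.asarray(M, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    m = M.shape[1]
    if m < 1:
        raise ValueError("need at least one marker")
    if n_reference is None:
        n_reference = M.shape[0]
    pc = clamp_frequencies(p, n_reference)
    d = 1.0 / (m * 2.0 * pc * (1.0 - pc))
    Z = M - 2.0 * p
    return (Z * d) @ Z.T


def build_grm(method: str, M: np.ndarray, p: np.ndarray,
              n_reference: int | None = None) -> np.ndarray:
    if method == "VR1":
        return build_vr1(M, p)
    if method == "VR2":
        return build_vr2(M, p, n_reference)
    raise ValueError(f"unknown GRM method {method!r}")


def build_nrm(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``sire``/``dam`` hold parent *indices* into the same arrays, with -1
    for unknown; animals must be ordered so parents precede offspring.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = len(sire)
    if len(dam) != n:
        raise ValueError("sire and dam arrays differ in length")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= i or d >= i:
            raise ValueError(f"animal {i} appears before its parents; sort the pedigree")
        row = np.zeros(i)
        if s >= 0:
            row += A[s, :i]
        if d >= 0:
            row += A[d, :i]
        A[i, :i] = A[:i, i] = 0.5 * row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def build_h_inverse(A: np.ndarray, G: np.ndarray, genotyped: np.ndarray,
                    blend_weight: float = 0.95) -> np.ndarray:
    """Inverse of the combined pedigree-genomic relationship matrix.

    H^-1 = A^-1 + [0 0; 0 Gw^-1 - A22^-1] on the genotyped block, where
    Gw = w*G + (1-w)*A22 is the blended (invertible) genomic matrix.
    """
    A = np.asarray(A, dtype=np.float64)
    genotyped = np.asarray(genotyped)
    if genotyped.dtype == bool:
        genotyped = np.flatnonzero(genotyped)
    Hinv = np.linalg.inv(A)
    if len(genotyped) == 0:
        return Hinv
    A22 = A[np.ix_(genotyped, genotyped)]
    Gw = blend_weight * np.asarray(G, dtype=np.float64) + (1.0 - blend_weight) * A22
    try:
        Gw_inv = np.linalg.inv(Gw)
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular genotyped block in H-inverse construction") from exc
    Hinv[np.ix_(genotyped, genotyped)] += Gw_inv - A22_inv
    return Hinv


def write_matrix(prefix, K: np.ndarray, ids: np.ndarray, method: str,
                 raf_policy: str | None = None) -> None:
    """Export a kinship/relationship matrix.

    Writes a plain-text lower triangle (id_i, id_j, value), a dense ``.npy``
    and a JSON sidecar carrying ids, method and RAF policy.
    """
    import json
    from pathlib import Path

    prefix = Path(prefix)
    K = np.asarray(K)
    ids = np.asarray(ids)
    with prefix.with_suffix(".txt").open("w") as fh:
        for i in range(K.shape[0]):
            for j in range(i + 1):
                fh.write(f"{ids[i]} {ids[j]} {K[i, j]:.10g}\n")
    np.save(prefix.with_suffix(".npy"), K)
    prefix.with_suffix(".json").write_text(json.dumps({
        "ids": [int(x) for x in ids], "method": method,
        "raf_policy": raf_policy, "n": int(K.shape[0])}))


def read_matrix(prefix) -> tuple[np.ndarray, dict]:
    import json
    from pathlib import Path

    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return np.load(prefix.with_suffix(".npy")), meta


def kinship_scale(relationship: np.ndarray) -> np.ndarray:
    """Convert a relationship-scale matrix to the kinship scale (divide by 2)."""
    return np.asarray(relationship) / 2.0


def _shared_fraction(ends1: np.ndarray, labels1: np.ndarray,
                     ends2: np.ndarray, labels2: np.ndarray,
                     total_length: float) -> float:
    grid = np.union1d(ends1, ends2)
    lengths = np.diff(grid, prepend=0.0)
    l1 = labels1[np.searchsorted(ends1, grid, side="left")]
    l2 = labels2[np.searchsorted(ends2, grid, side="left")]
    return float(lengths[l1 == l2].sum()) / total_length


def pair_segment_kinship(cohort_i: Cohort, i: int, cohort_j: Cohort, j: int,
                         total_length: float) -> float:
    """Empirical IBD kinship of two animals from founder segments.

    One quarter of the summed IBD fractions over the four haplotype
    pairings; an animal with itself gives (1 + F)/2.
    """
    f = 0.0
    for a in range(2):
        for b in range(2):
            ha, hb = 2 * i + a, 2 * j + b
            if cohort_i is cohort_j and ha == hb:
                f += 1.0
                continue
            f += _shared_fraction(cohort_i.seg_ends[ha], cohort_i.seg_labels[ha],
                                  cohort_j.seg_ends[hb], cohort_j.seg_labels[hb],
                                  total_length)
    return f / 4.0


def _sample_pairs(n: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Sample distinct unordered pairs (i < j) without replacement.

    For large pair spaces the draw is made with replacement and
    de-duplicated (collisions are vanishingly rare), topping up until the
    requested count is reached.
    """
    total = n * (n - 1) // 2
    n_pairs = min(n_pairs, total)
    if total <= 2_000_000:
        flat = rng.choice(total, size=n_pairs, replace=False)
    else:
        flat = np.unique(rng.integers(0, total, size=int(1.05 * n_pairs) + 16))
        while len(flat) < n_pairs:
            flat = np.unique(np.concatenate([flat, rng.integers(0, total, size=n_pairs)]))
        flat = rng.permutation(flat)[:n_pairs]
    # decode the triangular index: pair (i, j), i < j
    i = (np.floor((np.sqrt(8.0 * flat + 1.0) - 1.0) / 2.0)).astype(np.int64)
    # guard floating-point rounding at block boundaries
    too_big = i * (i + 1) // 2 > flat
    i[too_big] -= 1
    j = (flat - i * (i + 1) // 2).astype(np.int64)
    return np.column_stack([j, i + 1])


def mean_segment_kinship(cohort: Cohort, n_pairs: int, rng: np.random.Generator,
                         total_length: float) -> float:
    """Mean empirical IBD kinship of a cohort from sampled pairs."""
    n = cohort.n
    if n < 2:
        raise ValueError("need at least two animals")
    total = n * (n - 1) // 2
    if n_pairs > total:
        n_pairs = total
    pairs = _sample_pairs(n, n_pairs, rng)
    acc = 0.0
    for i, j in pairs:
        acc += pair_segment_kinship(cohort, int(i), cohort, int(j), total_length)
    return acc / len(pairs)
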