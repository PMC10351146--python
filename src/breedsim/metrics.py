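"""Per-generation population statistics.

Inbreeding is decomposed against a reference generation (the start of
genomic selection) into:

* ``F_drift`` — mean squared allele-frequency change scaled by the
  reference heterozygosity, capturing drift plus selection-driven
  frequency change:  F_drift = (1/m) sum_k (p_tk - p_rk)^2 / (p_rk (1 - p_rk))
* ``F_hom``   — loss of expected heterozygosity relative to the reference:
  F_hom = 1 - (1/m) sum_k [2 p_tk (1 - p_tk)] / [2 p_rk (1 - p_rk)]

Both are computed separately for marker, QTL and neutral loci, restricted
to loci with reference-generation MAF above a small threshold so nearly
fixed loci do not dominate. The genic variance sum p(1-p)alpha^2 over QTL
assumes linkage equilibrium and Hardy-Weinberg proportions and is
insensitive to the Bulmer effect, unlike the realized additive variance
var(TBV).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .founders import LocusMap, TraitArchitecture, MARKER, QTL, NEUTRAL
from .genetics import Cohort
from .kinship import mean_segment_kinship

__all__ = ["MetricsPanel", "f_drift", "f_hom", "reference_mask",
           "genic_variance", "expected_het_deficit", "panel"]


@dataclass
class MetricsPanel:
    """All per-generation statistics reported for a cohort."""

    generation: int
    mean_tbv_sd0: float  # mean TBV in generation-zero additive-SD units
    mean_kinship: float  # empirical IBD kinship from sampled pairs
    var_a: float  # realized additive variance (variance of TBV)
    var_g: float  # genic variance sum p(1-p)alpha^2
    f_drift_marker: float
    f_drift_qtl: float
    f_drift_neutral: float
    f_hom_marker: float
    f_hom_qtl: float
    f_hom_neutral: float
    maf_qtl: float
    maf_neutral: float
    seg_marker: float  # fraction of loci of the class still segregating
    seg_qtl: float
    seg_neutral: float

    def to_row(self) -> dict:
        return asdict(self)


def f_drift(p_t: np.ndarray, p_ref: np.ndarray, mask: np.ndarray) -> float:
    """Drift inbreeding: mean squared frequency change over reference heterozygosity."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty locus mask")
    pt, pr = np.asarray(p_t)[mask], np.asarray(p_ref)[mask]
    return float(np.mean((pt - pr) ** 2 / (pr * (1.0 - pr))))


def f_hom(p_t: np.ndarray, p_ref: np.ndarray, mask: np.ndarray) -> float:
    """Homozygosity inbreeding: one minus the mean heterozygosity ratio.

    A locus fixed at generation t contributes 1 (its heterozygosity ratio
    is zero); p_t = p_ref gives 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty locus mask")
    pt, pr = np.asarray(p_t)[mask], np.asarray(p_ref)[mask]
    return float(1.0 - np.mean((2.0 * pt * (1.0 - pt)) / (2.0 * pr * (1.0 - pr))))


def reference_mask(p_ref: np.ndarray, maf_threshold: float = 0.001) -> np.ndarray:
    """Loci whose reference-generation MAF exceeds the threshold."""
    p_ref = np.asarray(p_ref)
    return np.minimum(p_ref, 1.0 - p_ref) > maf_threshold


def genic_variance(p_qtl: np.ndarray, effects: np.ndarray, factor2: bool = False) -> float:
    """Genic variance sum p(1-p)alpha^2 over QTL.

    ``factor2`` switches to the conventional 2*sum p(1-p)alpha^2; reported
    rates are relative to a reference generation, so the factor cancels
    there either way.
    """
    p = np.asarray(p_qtl, dtype=np.float64)
    a = np.asarray(effects, dtype=np.float64)
    s = float(np.sum(p * (1.0 - p) * a * a))
    return 2.0 * s if factor2 else s


def expected_het_deficit(n_males: int, n_females: int) -> float:
    """Robertson's heterozygote deficit 1/(8M) + 1/(8F) under random mating."""
    if n_males <= 0 or n_females <= 0:
        raise ValueError("sex counts must be positive")
    return 1.0 / (8.0 * n_males) + 1.0 / (8.0 * n_females)


def panel(cohort: Cohort, locus_map: LocusMap, trait: TraitArchitecture,
          rng: np.random.Generator, n_pairs: int,
          ref_freqs: Optional[np.ndarray] = None,
          maf_threshold: float = 0.001, genic_factor2: bool = False) -> MetricsPanel:
    """Assemble the full statistics panel for one cohort.

    ``ref_freqs`` are the reference-generation allele frequencies for the
    F statistics; when absent (generations before the reference exists)
    the F fields are NaN.
    """
    freqs = cohort.haplotypes.mean(axis=0)
    maf = np.minimum(freqs, 1.0 - freqs)
    seg = (freqs > 0.0) & (freqs < 1.0)

    stats: dict[str, float] = {}
    for name, code in (("marker", MARKER), ("qtl", QTL), ("neutral", NEUTRAL)):
        cls_mask = locus_map.locus_class == code
        stats[f"seg_{name}"] = float(seg[cls_mask].mean())
        if ref_freqs is None:
            stats[f"f_drift_{name}"] = np.nan
            stats[f"f_hom_{name}"] = np.nan
        else:
            use = cls_mask & reference_mask(ref_freqs, maf_threshold)
            stats[f"f_drift_{name}"] = f_drift(freqs, ref_freqs, use)
            stats[f"f_hom_{name}"] = f_hom(freqs, ref_freqs, use)

    qtl_idx = locus_map.qtl_indices
    return MetricsPanel(
        generation=cohort.generation,
        mean_tbv_sd0=float(cohort.tbv.mean()) / trait.base_sd,
        mean_kinship=mean_segment_kinship(cohort, n_pairs, rng,
                                          locus_map.grid.total_length),
        var_a=float(cohort.tbv.var()),
        var_g=genic_variance(freqs[qtl_idx], trait.qtl_effects, genic_factor2),
        maf_qtl=float(maf[qtl_idx].mean()),
        maf_neutral=float(maf[locus_map.neutral_indices].mean()),
        **stats,
    )
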