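"""Scenario comparison by trend regression.

Each response (genetic level in base-SD units, additive and genic
variance as percentages of their reference-generation values, and
-log(1 - x) transforms of mean kinship and the two inbreeding measures)
is regressed on generation over the genomic-selection window with fixed
replicate intercepts and one slope per scenario:

    y_klm = beta_k + beta_l * X_lm + e_klm

The per-scenario slope is the reported per-generation rate (Delta). All
nine scenarios share one model, so slope differences have well-defined
standard errors from the pooled residual variance; pairwise slope t-tests
are Bonferroni-corrected for the s(s-1)/2 comparisons, and compact letter
groups mark scenarios that are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["TrendModel", "SlopeComparison", "fit_trend", "pairwise_slope_tests",
           "letter_groups", "RESPONSES", "prepare_responses", "make_tables"]

#: response column -> whether it is computed as % of the reference generation
RESPONSES = {
    "mean_tbv_sd0": "level",
    "var_a_pct": "percent",
    "var_g_pct": "percent",
    "neglog_f": "neglog",
    "neglog_f_drift_neutral": "neglog",
    "neglog_f_drift_qtl": "neglog",
    "neglog_f_drift_marker": "neglog",
    "neglog_f_hom_neutral": "neglog",
    "neglog_f_hom_qtl": "neglog",
    "neglog_f_hom_marker": "neglog",
}


@dataclass
class TrendModel:
    response: str
    scenarios: list[str]
    replicates: list[int]
    slopes: dict[str, float]
    slope_se: dict[str, float]
    slope_cov: np.ndarray  # covariance of the scenario slopes
    intercepts: dict[int, float]
    sigma2: float
    df_resid: int
    nobs: int


@dataclass
class SlopeComparison:
    scenarios: list[str]
    t_matrix: np.ndarray
    p_matrix: np.ndarray
    significant: np.ndarray  # Bonferroni-corrected decisions
    n_comparisons: int
    letters: dict[str, str]


def fit_trend(frame: pd.DataFrame, response: str,
              gen_range: tuple[int, int] = (5, 20)) -> TrendModel:
    """OLS fit of the replicate-intercept, scenario-slope trend model."""
    df = frame[(frame["generation"] >= gen_range[0])
               & (frame["generation"] <= gen_range[1])].copy()
    if df.empty:
        raise ValueError("no rows in the requested generation range")
    reps = sorted(df["replicate"].unique())
    scens = list(dict.fromkeys(df["scenario"]))
    y = df[response].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite values in response {response!r}")
    n = len(df)
    r, s = len(reps), len(scens)
    X = np.zeros((n, r + s))
    for k, rep in enumerate(reps):
        X[(df["replicate"] == rep).to_numpy(), k] = 1.0
    gen = df["generation"].to_numpy(dtype=np.float64)
    for l, sc in enumerate(scens):
        m = (df["scenario"] == sc).to_numpy()
        X[m, r + l] = gen[m]
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < r + s:
        raise ValueError(
            f"rank-deficient trend design for {response!r} "
            f"(rank {rank} < {r + s}); need variation in generation per scenario")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df_resid = n - (r + s)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df_resid
    cov = sigma2 * np.linalg.inv(xtx)
    slope_cov = cov[r:, r:]
    return TrendModel(
        response=response, scenarios=scens, replicates=[int(x) for x in reps],
        slopes={sc: float(beta[r + l]) for l, sc in enumerate(scens)},
        slope_se={sc: float(np.sqrt(slope_cov[l, l])) for l, sc in enumerate(scens)},
        slope_cov=slope_cov,
        intercepts={int(rep): float(beta[k]) for k, rep in enumerate(reps)},
        sigma2=sigma2, df_resid=df_resid, nobs=n)


def letter_groups(scenarios: list[str], nonsig: np.ndarray) -> dict[str, str]:
    """Compact letter display: greedy clique cover of the non-significance graph.

    Scenarios must already be ordered (by slope); scenarios sharing a
    letter are not significantly different. Deterministic.
    """
    s = len(scenarios)
    groups: list[set[int]] = []
    for i in range(s):
        grp = {i}
        for j in range(i + 1, s):
            if all(nonsig[j, g] for g in grp):
                grp.add(j)
        if not any(grp <= g for g in groups):
            groups.append(grp)
    letters = {sc: "" for sc in scenarios}
    for gi, grp in enumerate(groups):
        ch = chr(ord("a") + gi) if gi < 26 else f"g{gi}"
        for i in sorted(grp):
            letters[scenarios[i]] += ch
    return letters


def pairwise_slope_tests(model: TrendModel, alpha: float = 0.05) -> SlopeComparison:
    """t-tests on all slope differences with Bonferroni correction."""
    if model.df_resid <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    scens = model.scenarios
    s = len(scens)
    n_comp = s * (s - 1) // 2
    tmat = np.zeros((s, s))
    pmat = np.ones((s, s))
    for i in range(s):
        for j in range(i + 1, s):
            var = (model.slope_cov[i, i] + model.slope_cov[j, j]
                   - 2.0 * model.slope_cov[i, j])
            diff = model.slopes[scens[i]] - model.slopes[scens[j]]
            t = diff / np.sqrt(var) if var > 0 else 0.0
            p = 2.0 * scipy.stats.t.sf(abs(t), model.df_resid)
            tmat[i, j] = tmat[j, i] = t
            pmat[i, j] = pmat[j, i] = p
    sig = pmat < (alpha / n_comp) if n_comp else np.zeros((s, s), dtype=bool)
    np.fill_diagonal(sig, False)
    order = np.argsort([model.slopes[sc] for sc in scens], kind="stable")
    ordered = [scens[i] for i in order]
    nonsig_ordered = ~sig[np.ix_(order, order)]
    letters = letter_groups(ordered, nonsig_ordered)
    return SlopeComparison(scens, tmat, pmat, sig, n_comp, letters)


def prepare_responses(metrics: pd.DataFrame,
                      ref_generation: int = 5) -> pd.DataFrame:
    """Add the transformed response columns to a long metrics table."""
    df = metrics.copy()
    for col in ("var_a", "var_g"):
        ref = df[df["generation"] == ref_generation].set_index(
            ["replicate", "scenario"])[col]
        key = pd.MultiIndex.from_frame(df[["replicate", "scenario"]])
        df[f"{col}_pct"] = 100.0 * df[col].to_numpy() / ref.reindex(key).to_numpy()
    df["neglog_f"] = -np.log(1.0 - df["mean_kinship"])
    for base in ("f_drift", "f_hom"):
        for cls in ("neutral", "qtl", "marker"):
            df[f"neglog_{base}_{cls}"] = -np.log(1.0 - df[f"{base}_{cls}"])
    return df


def make_tables(metrics: pd.DataFrame, alpha: float = 0.05,
                ref_generation: int = 5,
                gen_range: tuple[int, int] = (5, 20),
                out_dir: Optional[str | Path] = None) -> dict[str, pd.DataFrame]:
    """Rate tables, drift/homozygosity table, plot data and significance matrix.

    The first table reports per-generation rates (kinship and inbreeding
    rates in %, gain in base-SD units, variance losses in % of the
    reference-generation value) with ratios relative to the Pedigree
    scenario and letter groups; the second the drift/homozygosity rates
    per locus class and the final-generation F_hom - F_drift gap.
    """
    df = prepare_responses(metrics, ref_generation)
    scens = list(dict.fromkeys(df["scenario"]))
    models = {resp: fit_trend(df, resp, gen_range) for resp in RESPONSES}
    comps = {resp: pairwise_slope_tests(models[resp], alpha) for resp in RESPONSES}

    def col(resp: str, scale: float = 1.0) -> dict[str, float]:
        return {sc: models[resp].slopes[sc] * scale for sc in scens}

    t1 = pd.DataFrame(index=pd.Index(scens, name="scenario"))
    t1["delta_f_pct"] = pd.Series(col("neglog_f", 100.0))
    t1["delta_g_sd0"] = pd.Series(col("mean_tbv_sd0"))
    t1["delta_var_a_pct"] = pd.Series(col("var_a_pct"))
    t1["delta_var_g_pct"] = pd.Series(col("var_g_pct"))
    ped = "Pedigree"
    if ped in scens:
        for src, dst in (("delta_f_pct", "rel_delta_f"), ("delta_g_sd0", "rel_delta_g"),
                         ("delta_var_a_pct", "rel_delta_var_a"),
                         ("delta_var_g_pct", "rel_delta_var_g")):
            t1[dst] = t1[src] / t1.loc[ped, src]
    last_gen = df["generation"].max()
    final = df[df["generation"] == last_gen].groupby("scenario")
    t1["maf_qtl"] = final["maf_qtl"].mean()
    t1["maf_neutral"] = final["maf_neutral"].mean()
    for resp, name in (("neglog_f", "letters_delta_f"), ("mean_tbv_sd0", "letters_delta_g"),
                       ("var_a_pct", "letters_var_a"), ("var_g_pct", "letters_var_g")):
        t1[name] = pd.Series(comps[resp].letters)

    t2 = pd.DataFrame(index=pd.Index(scens, name="scenario"))
    for cls in ("neutral", "qtl", "marker"):
        t2[f"delta_f_drift_{cls}_pct"] = pd.Series(col(f"neglog_f_drift_{cls}", 100.0))
        t2[f"delta_f_hom_{cls}_pct"] = pd.Series(col(f"neglog_f_hom_{cls}", 100.0))
        gap = (final[f"f_hom_{cls}"].mean() - final[f"f_drift_{cls}"].mean()) * 100.0
        t2[f"fhom_minus_fdrift_{cls}_pct"] = gap
        t2[f"letters_drift_{cls}"] = pd.Series(comps[f"neglog_f_drift_{cls}"].letters)
        t2[f"letters_hom_{cls}"] = pd.Series(comps[f"neglog_f_hom_{cls}"].letters)

    fig1 = (df.groupby(["scenario", "generation"])
            [["mean_tbv_sd0", "mean_kinship", "f_drift_neutral", "f_hom_neutral"]]
            .mean().reset_index())

    sig_rows = []
    for resp, comp in comps.items():
        for i in range(len(comp.scenarios)):
            for j in range(i + 1, len(comp.scenarios)):
                sig_rows.append({
                    "response": resp, "a": comp.scenarios[i], "b": comp.scenarios[j],
                    "t": comp.t_matrix[i, j], "p": comp.p_matrix[i, j],
                    "significant": bool(comp.significant[i, j])})
    sig = pd.DataFrame(sig_rows)

    tables = {"table1": t1.reset_index(), "table2": t2.reset_index(),
              "fig1_data": fig1, "significance": sig}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out / f"{name}.csv", index=False)
    return tables
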