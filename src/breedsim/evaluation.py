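"""Breeding-value prediction by mixed-model equations, and parent averages.

The model is the single-trait animal model y = 1*mu + Z*a + e with
a ~ N(0, K * sigma_A^2) and e ~ N(0, I * sigma_e^2), where K is the
numerator relationship matrix (PBLUP), a genomic relationship matrix
(GBLUP) or the combined H matrix (ssGBLUP), all on the relationship
scale. Variance components are never re-estimated: sigma_A^2 is the
generation-zero true-breeding-value variance, so lambda = sigma_e^2 /
sigma_A^2 is constant while realized heritability drifts.

Animals without records obtain predictions through K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["BLUPResult", "solve_blup", "parent_average", "top_by_value"]


@dataclass
class BLUPResult:
    mu: float
    breeding_values: np.ndarray  # one entry per evaluated animal


def solve_blup(y: np.ndarray, record_animal: np.ndarray, n_animals: int,
               lam: float, K: np.ndarray | None = None,
               Kinv: np.ndarray | None = None) -> BLUPResult:
    """Solve the mixed-model equations for intercept and breeding values.

        [ 1'1   1'Z          ] [mu]   [1'y ]
        [ Z'1   Z'Z + K^-1 λ ] [a ] = [Z'y ]

    ``record_animal`` maps each record to the index of its animal among
    the ``n_animals`` evaluated; exactly one of ``K``/``Kinv`` must be
    given.
    """
    y = np.asarray(y, dtype=np.float64)
    record_animal = np.asarray(record_animal, dtype=np.int64)
    if len(y) == 0:
        raise ValueError("no records")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if (K is None) == (Kinv is None):
        raise ValueError("provide exactly one of K or Kinv")
    if Kinv is None:
        try:
            c, low = scipy.linalg.cho_factor(np.asarray(K, dtype=np.float64))
            Kinv = scipy.linalg.cho_solve((c, low), np.eye(n_animals))
        except np.linalg.LinAlgError as exc:
            raise ValueError("relationship matrix is not positive definite") from exc

    counts = np.bincount(record_animal, minlength=n_animals).astype(np.float64)
    zy = np.bincount(record_animal, weights=y, minlength=n_animals)
    C = np.empty((n_animals + 1, n_animals + 1))
    C[0, 0] = len(y)
    C[0, 1:] = counts
    C[1:, 0] = counts
    C[1:, 1:] = np.asarray(Kinv, dtype=np.float64) * lam
    C[np.arange(1, n_animals + 1), np.arange(1, n_animals + 1)] += counts
    rhs = np.concatenate(([y.sum()], zy))
    try:
        sol = scipy.linalg.solve(C, rhs, assume_a="sym")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:  # pragma: no cover
        raise ValueError("singular mixed-model coefficient matrix") from exc
    return BLUPResult(mu=float(sol[0]), breeding_values=sol[1:])


def parent_average(gebv_sire: np.ndarray, gebv_dam: np.ndarray) -> np.ndarray:
    """PA = (GEBV_sire + GEBV_dam) / 2; both parents must have a GEBV."""
    gebv_sire = np.asarray(gebv_sire, dtype=np.float64)
    gebv_dam = np.asarray(gebv_dam, dtype=np.float64)
    if np.any(np.isnan(gebv_sire)) or np.any(np.isnan(gebv_dam)):
        raise ValueError("missing parental GEBV")
    return 0.5 * (gebv_sire + gebv_dam)


def top_by_value(values: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of the n largest values; ties broken by a seeded random order."""
    values = np.asarray(values, dtype=np.float64)
    tiebreak = rng.permutation(len(values))
    order = np.lexsort((tiebreak, -values))
    return order[:n]
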