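"""Optimum contribution selection with a fixed number of sires.

The scheme selects exactly ``k`` sires per generation from the candidate
bulls, each selected bull contributing 1/(2k) and a single *pseudofemale*
— an aggregate of all dams, whose kinship entries are means over the
female side — contributing 1/2, so male and female contributions each sum
to one half. The objective is the contribution-weighted mean GEBV
c'a_hat, subject to the group-kinship constraint c'Rc <= C, where R is
the scenario's kinship-scale matrix and C allows a target rate of kinship
increase (C = f_t + dF (1 - f_t), dF = 0.005 for Ne = 100).

Because contributions are fixed, the optimization is a k-subset search:
exhaustive enumeration when the subset count is small, otherwise a seeded
simulated-annealing search with steepest-ascent polishing. Only a
strictly feasible subset is ever reported as feasible; if no subset
satisfies the constraint the minimum-kinship subset is returned with the
feasibility flag down, so a simulation never halts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["OCSProblem", "SelectionDecision", "build_pseudofemale",
           "kinship_target", "group_kinship", "contribution_vector",
           "brute_force_ocs", "optimize_contributions"]


@dataclass
class OCSProblem:
    """A fixed-contribution OCS instance over candidate bulls.

    ``R`` is the kinship-scale matrix among candidates; ``pf_cross`` the
    candidate-to-pseudofemale kinships and ``pf_self`` the pseudofemale
    self-kinship; ``k`` the number of sires; ``C`` the kinship bound.
    """

    gebv: np.ndarray
    R: np.ndarray
    pf_cross: np.ndarray
    pf_self: float
    k: int
    C: float

    @property
    def n(self) -> int:
        return len(self.gebv)

    def __post_init__(self):
        if self.R.shape != (self.n, self.n):
            raise ValueError("R must be square over the candidates")
        if len(self.pf_cross) != self.n:
            raise ValueError("pf_cross must have one entry per candidate")
        if not (0 < self.k <= self.n):
            raise ValueError(f"k={self.k} must be in 1..{self.n}")


@dataclass
class SelectionDecision:
    selected: np.ndarray  # sorted candidate indices, |selected| = k
    objective: float  # achieved c'a_hat
    group_kinship: float  # achieved c'Rc
    feasible: bool


def build_pseudofemale(R_bull_female: np.ndarray,
                       R_female: np.ndarray) -> tuple[np.ndarray, float]:
    """Aggregate all females into one pseudofemale.

    Self-kinship is the mean over all female-by-female entries including
    self-kinships; the entry to each bull is that bull's mean kinship to
    the females.
    """
    R_bull_female = np.atleast_2d(np.asarray(R_bull_female, dtype=np.float64))
    R_female = np.atleast_2d(np.asarray(R_female, dtype=np.float64))
    if R_female.shape[0] == 0:
        raise ValueError("no females to aggregate")
    return R_bull_female.mean(axis=1), float(R_female.mean())


def kinship_target(f_current: float, delta_f: float = 0.005) -> float:
    """Kinship bound C = f + dF (1 - f) for one generation at rate dF."""
    if not (0.0 <= f_current < 1.0):
        raise ValueError(f"current mean kinship {f_current} must lie in [0, 1)")
    return f_current + delta_f * (1.0 - f_current)


def contribution_vector(n: int, selected: np.ndarray, k: int) -> np.ndarray:
    """Contributions over candidates plus the trailing pseudofemale slot."""
    c = np.zeros(n + 1)
    c[np.asarray(selected)] = 1.0 / (2 * k)
    c[-1] = 0.5
    return c


def group_kinship(problem: OCSProblem, selected: np.ndarray) -> float:
    """c'Rc for equal male contributions 1/(2k) and pseudofemale 1/2."""
    S = np.asarray(selected)
    k = problem.k
    rr = float(problem.R[np.ix_(S, S)].sum())
    return (rr / (4.0 * k * k)
            + float(problem.pf_cross[S].sum()) / (2.0 * k)
            + 0.25 * problem.pf_self)


def _objective(problem: OCSProblem, selected: np.ndarray) -> float:
    return float(problem.gebv[np.asarray(selected)].sum()) / (2.0 * problem.k)


def brute_force_ocs(problem: OCSProblem, limit: int = 1_000_000) -> SelectionDecision:
    """Exhaustive enumeration of all k-subsets (testing oracle, exact)."""
    n, k = problem.n, problem.k
    if math.comb(n, k) > limit:
        raise ValueError(f"C({n},{k}) exceeds the enumeration guard of {limit}")
    best_feas = None
    best_infeas = None
    for combo in itertools.combinations(range(n), k):
        S = np.array(combo)
        q = group_kinship(problem, S)
        if q <= problem.C:
            obj = _objective(problem, S)
            if best_feas is None or obj > best_feas[0]:
                best_feas = (obj, q, S)
        elif best_feas is None:
            if best_infeas is None or q < best_infeas[1]:
                best_infeas = (_objective(problem, S), q, S)
    if best_feas is not None:
        obj, q, S = best_feas
        return SelectionDecision(S, obj, q, True)
    obj, q, S = best_infeas
    return SelectionDecision(S, obj, q, False)


class _SwapState:
    """Incremental bookkeeping for k-subset swap moves."""

    def __init__(self, problem: OCSProblem, selected: np.ndarray):
        self.p = problem
        self.sel = np.zeros(problem.n, dtype=bool)
        self.sel[selected] = True
        self.s = problem.R[:, selected].sum(axis=1)  # row sums over the subset
        self.rr = float(self.s[selected].sum())
        self.pf = float(problem.pf_cross[selected].sum())
        self.obj_sum = float(problem.gebv[selected].sum())

    def q(self) -> float:
        k = self.p.k
        return self.rr / (4 * k * k) + self.pf / (2 * k) + 0.25 * self.p.pf_self

    def objective(self) -> float:
        return self.obj_sum / (2 * self.p.k)

    def swap_delta(self, out: int, inn: int) -> tuple[float, float]:
        """(new rr, new pf sum) after swapping ``out`` for ``inn``."""
        R = self.p.R
        rr = self.rr - 2 * self.s[out] + R[out, out]
        rr += 2 * (self.s[inn] - R[inn, out]) + R[inn, inn]
        pf = self.pf - self.p.pf_cross[out] + self.p.pf_cross[inn]
        return rr, pf

    def apply(self, out: int, inn: int, rr: float, pf: float) -> None:
        self.sel[out] = False
        self.sel[inn] = True
        self.s += self.p.R[:, inn] - self.p.R[:, out]
        self.rr = rr
        self.pf = pf
        self.obj_sum += self.p.gebv[inn] - self.p.gebv[out]

    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.sel)


def _q_of(state: _SwapState, rr: float, pf: float) -> float:
    k = state.p.k
    return rr / (4 * k * k) + pf / (2 * k) + 0.25 * state.p.pf_self


def _steepest_ascent(problem: OCSProblem, state: _SwapState) -> None:
    """Greedy feasible swap improvement to a local optimum (in place)."""
    while True:
        sel = state.selected()
        unsel = np.flatnonzero(~state.sel)
        best = None
        for o in sel:
            for i in unsel:
                gain = problem.gebv[i] - problem.gebv[o]
                if best is not None and gain <= best[0]:
                    continue
                if gain <= 1e-15:
                    continue
                rr, pf = state.swap_delta(o, i)
                if _q_of(state, rr, pf) <= problem.C:
                    best = (gain, o, i, rr, pf)
        if best is None:
            return
        _, o, i, rr, pf = best
        state.apply(int(o), int(i), rr, pf)


def optimize_contributions(problem: OCSProblem, rng: np.random.Generator | None = None,
                           max_enumeration: int = 100_000, restarts: int = 4,
                           n_iter: int | None = None) -> SelectionDecision:
    """Select the k-subset maximizing c'a_hat subject to c'Rc <= C.

    Exact enumeration when the subset count is within ``max_enumeration``;
    otherwise seeded simulated annealing over swap moves with a penalized
    energy, tracking the best strictly feasible subset seen, followed by
    steepest-ascent polishing. Deterministic for a given ``rng`` seed.
    """
    n, k = problem.n, problem.k
    if math.comb(n, k) <= max_enumeration:
        return brute_force_ocs(problem, limit=max_enumeration)
    if rng is None:
        rng = np.random.default_rng(0)
    if n_iter is None:
        n_iter = max(3000, 250 * n)

    gebv = problem.gebv
    span = float(gebv.max() - gebv.min()) + 1e-9
    q_tol = max(1e-12, 1e-4 * max(abs(problem.C), 1e-3))
    penalty = span * k / q_tol  # any violation beyond q_tol dominates the objective

    def energy(obj_sum: float, q: float) -> float:
        return -obj_sum + penalty * max(0.0, q - problem.C)

    best_feas: tuple[float, np.ndarray] | None = None
    best_q: tuple[float, np.ndarray] | None = None

    for r in range(restarts):
        if r == 0:
            start = np.argsort(-gebv, kind="stable")[:k]
        else:
            start = rng.choice(n, size=k, replace=False)
        sel_idx = np.sort(start)
        state = _SwapState(problem, sel_idx)
        sel_idx = sel_idx.copy()
        e = energy(state.obj_sum, state.q())
        q0 = state.q()
        if q0 <= problem.C and (best_feas is None or state.obj_sum > best_feas[0]):
            best_feas = (state.obj_sum, np.sort(sel_idx))
        if best_q is None or q0 < best_q[0]:
            best_q = (q0, np.sort(sel_idx))
        t0, t_end = 0.5 * span, 1e-3 * span
        cool = (t_end / t0) ** (1.0 / n_iter)
        T = t0
        slots = rng.integers(0, k, size=n_iter)
        cands = rng.integers(0, n, size=n_iter)
        accept_u = rng.random(size=n_iter)
        for it in range(n_iter):
            o = int(sel_idx[slots[it]])
            i = int(cands[it])
            if state.sel[i]:
                T *= cool
                continue
            rr, pf = state.swap_delta(o, i)
            q_new = _q_of(state, rr, pf)
            obj_new = state.obj_sum + gebv[i] - gebv[o]
            e_new = energy(obj_new, q_new)
            if e_new <= e or accept_u[it] < np.exp(max(-700.0, (e - e_new) / T)):
                state.apply(o, i, rr, pf)
                sel_idx[slots[it]] = i
                e = e_new
                if q_new <= problem.C and (best_feas is None or obj_new > best_feas[0]):
                    best_feas = (obj_new, np.sort(sel_idx))
                if best_q is None or q_new < best_q[0]:
                    best_q = (q_new, np.sort(sel_idx))
            T *= cool

    if best_feas is not None:
        state = _SwapState(problem, best_feas[1])
        _steepest_ascent(problem, state)
        S = np.sort(state.selected())
        return SelectionDecision(S, state.objective(), state.q(), True)

    # infeasible everywhere we looked: descend on group kinship instead
    state = _SwapState(problem, best_q[1])
    improved = True
    while improved:
        improved = False
        for o in state.selected():
            for i in np.flatnonzero(~state.sel):
                rr, pf = state.swap_delta(int(o), int(i))
                if _q_of(state, rr, pf) < state.q() - 1e-15:
                    state.apply(int(o), int(i), rr, pf)
                    improved = True
                    break
            if improved:
                break
        if state.q() <= problem.C:
            break
    S = np.sort(state.selected())
    return SelectionDecision(S, state.objective(), state.q(), state.q() <= problem.C)
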