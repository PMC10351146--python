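"""The 21-generation breeding scheme under nine kinship-matrix scenarios.

Cohort 0 is the base population. Selection events breed cohort t+1 from
cohort t: event 0 picks sires at random, events 1..4 truncate on PBLUP
EBV (120 sires at full scale, used equally), and events 5..19 run genomic
optimum contribution selection with 40 sires. At each genomic event the
males of the current generation are pre-selected on parent average (top
2000 at full scale are genotyped, the rest drop out of candidacy), all
females are genotyped, breeding values are predicted by ssGBLUP for the
first genomic rounds and GBLUP afterwards using an 8-generation data
window, and OCS selects the sires under the scenario's kinship matrix.

Scenarios within a replicate share the founder population and the entire
pedigree phase: phase randomness is keyed to the replicate, scenario
randomness only enters with the first OCS event, so runs are identical
until the kinship matrices can first differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluation import parent_average, solve_blup, top_by_value
from .founders import FounderPopulation, GenomeParams, simulate_founders
from .genetics import FEMALE, MALE, Cohort, assign_phenotypes, base_cohort, mate_cohort
from .kinship import (RAF_ALL, RAF_BASE, RAF_CURRENT, RAF_HALF, RAF_OLD,
                      build_grm, build_h_inverse, build_vr1, kinship_scale)
from .metrics import MetricsPanel, panel
from .ocs import (OCSProblem, build_pseudofemale, kinship_target,
                  optimize_contributions)
from .rng import rng_for, seed_stream

__all__ = ["ScenarioSpec", "SCENARIOS", "GenerationRecord", "GenerationLog",
           "BreedingProgram", "run_scenario", "run_experiment"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the nine kinship-matrix scenarios used for OCS."""

    name: str
    method: str  # "VR1" | "VR2" | "PED"
    raf: Optional[str]  # RAF policy kind; None for the pedigree matrix


SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s for s in (
        ScenarioSpec("VR1 Base", "VR1", RAF_BASE),
        ScenarioSpec("VR1 Old", "VR1", RAF_OLD),
        ScenarioSpec("VR2 Base", "VR2", RAF_BASE),
        ScenarioSpec("VR1 All", "VR1", RAF_ALL),
        ScenarioSpec("VR2 All", "VR2", RAF_ALL),
        ScenarioSpec("VR1 0.5", "VR1", RAF_HALF),
        ScenarioSpec("VR1 Current", "VR1", RAF_CURRENT),
        ScenarioSpec("VR2 Current", "VR2", RAF_CURRENT),
        ScenarioSpec("Pedigree", "PED", None),
    )
}


@dataclass
class GenerationRecord:
    """Per-cohort log entry: how the cohort was bred, plus its metrics panel."""

    generation: int
    eval_mode: str  # "base" | "random" | "PBLUP" | "ssGBLUP" | "GBLUP"
    sire_ids: np.ndarray
    n_candidates: int
    kinship_bound: float
    group_kinship: float
    objective: float
    feasible: bool
    panel: MetricsPanel


@dataclass
class GenerationLog:
    scenario: str
    replicate: int
    records: list[GenerationRecord]
    final_state: Optional["ProgramState"] = field(default=None, repr=False)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"replicate": self.replicate, "scenario": self.scenario}
            row.update(rec.panel.to_row())
            rows.append(row)
        return pd.DataFrame(rows)

    def ocs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"replicate": self.replicate, "scenario": self.scenario,
             "generation": r.generation, "eval_mode": r.eval_mode,
             "n_sires": len(r.sire_ids), "n_candidates": r.n_candidates,
             "kinship_bound": r.kinship_bound, "group_kinship": r.group_kinship,
             "objective": r.objective, "feasible": r.feasible}
            for r in self.records])


class _NRMWindow:
    """Dense numerator relationship matrix over a sliding window of generations."""

    def __init__(self, n_base: int):
        self.gens: list[int] = [0]
        self.sizes: list[int] = [n_base]
        self.A = np.eye(n_base)

    def _offsets(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.sizes)))

    def gen_slice(self, gen: int) -> slice:
        i = self.gens.index(gen)
        off = self._offsets()
        return slice(int(off[i]), int(off[i + 1]))

    def extend(self, sire_pos: np.ndarray, dam_pos: np.ndarray) -> None:
        """Append the next generation; parents index into the latest generation."""
        prev = self.gen_slice(self.gens[-1])
        n_old = self.A.shape[0]
        n_new = len(sire_pos)
        As = self.A[:, prev][:, sire_pos]
        Ad = self.A[:, prev][:, dam_pos]
        cross = 0.5 * (As + Ad)
        App = self.A[prev, prev]
        new = 0.25 * (App[np.ix_(sire_pos, sire_pos)] + App[np.ix_(sire_pos, dam_pos)]
                      + App[np.ix_(dam_pos, sire_pos)] + App[np.ix_(dam_pos, dam_pos)])
        np.fill_diagonal(new, 1.0 + 0.5 * App[sire_pos, dam_pos])
        A = np.empty((n_old + n_new, n_old + n_new))
        A[:n_old, :n_old] = self.A
        A[:n_old, n_old:] = cross
        A[n_old:, :n_old] = cross.T
        A[n_old:, n_old:] = new
        self.A = A
        self.gens.append(self.gens[-1] + 1)
        self.sizes.append(n_new)

    def drop_before(self, gen: int) -> None:
        while self.gens and self.gens[0] < gen:
            n0 = self.sizes[0]
            self.A = self.A[n0:, n0:]
            self.gens.pop(0)
            self.sizes.pop(0)

    def block(self, members: list[tuple[int, np.ndarray]]) -> np.ndarray:
        """Submatrix for (generation, local indices) groups, in the given order."""
        parts = [self.gen_slice(g).start + np.asarray(li, dtype=np.int64)
                 for g, li in members]
        idx = np.concatenate(parts) if parts else np.array([], dtype=np.int64)
        return self.A[np.ix_(idx, idx)]

    def copy(self) -> "_NRMWindow":
        out = _NRMWindow.__new__(_NRMWindow)
        out.gens = list(self.gens)
        out.sizes = list(self.sizes)
        out.A = self.A.copy()
        return out


@dataclass
class ProgramState:
    """Mutable simulation state; cloned per scenario after the pedigree phase."""

    cohorts: list[Cohort]
    nrm: _NRMWindow
    next_id: int
    records: list[GenerationRecord]
    base_raf: Optional[np.ndarray] = None  # generation-one cohort frequencies
    old_raf: Optional[np.ndarray] = None  # bulls selected in the pedigree phase
    old_sum: Optional[np.ndarray] = None
    old_n: int = 0
    all_sum: Optional[np.ndarray] = None  # all genotyped animals to date
    all_n: int = 0
    ref_freqs: Optional[np.ndarray] = None  # reference-generation frequencies

    def copy(self) -> "ProgramState":
        return ProgramState(
            cohorts=[c.copy() for c in self.cohorts],
            nrm=self.nrm.copy(),
            next_id=self.next_id,
            records=list(self.records),
            base_raf=self.base_raf,
            old_raf=self.old_raf,
            old_sum=None if self.old_sum is None else self.old_sum.copy(),
            old_n=self.old_n,
            all_sum=None if self.all_sum is None else self.all_sum.copy(),
            all_n=self.all_n,
            ref_freqs=self.ref_freqs,
        )


class BreedingProgram:
    """Runs the breeding scheme for one replicate of one founder population."""

    def __init__(self, config: RunConfig, founders: FounderPopulation,
                 replicate: int, master_seed: int):
        self.cfg = config.scaled()
        self.founders = founders
        self.replicate = replicate
        self.master_seed = master_seed
        self.locus_map = founders.locus_map
        self.grid = founders.locus_map.grid
        self.trait = founders.trait
        self.marker_idx = founders.locus_map.marker_indices
        self.lam = founders.trait.lambda_ratio

    # ---------------- helpers ----------------

    def _rngs(self, *scope: str) -> dict[str, np.random.Generator]:
        return {name: rng_for(self.master_seed, "rep", self.replicate, *scope, name)
                for name in ("selection", "mating", "phenotype", "pairs",
                             "ocs", "preselect", "tiebreak")}

    def _marker_counts(self, cohort: Cohort, idx: np.ndarray | None = None) -> np.ndarray:
        g = cohort.genotype_counts(self.marker_idx)
        return g if idx is None else g[idx]

    def _panel(self, cohort: Cohort, state: ProgramState,
               rng: np.random.Generator) -> MetricsPanel:
        return panel(cohort, self.locus_map, self.trait, rng,
                     self.cfg.metrics.n_kinship_pairs,
                     ref_freqs=state.ref_freqs,
                     maf_threshold=self.cfg.metrics.maf_threshold,
                     genic_factor2=self.cfg.metrics.genic_variance_factor2)

    def _genotype(self, state: ProgramState, cohort: Cohort, idx: np.ndarray,
                  into_old: bool) -> None:
        """Mark animals genotyped and fold them into the RAF accumulators."""
        new = idx[~cohort.genotyped[idx]]
        if len(new) == 0:
            return
        cohort.genotyped[new] = True
        counts = self._marker_counts(cohort, new).sum(axis=0, dtype=np.int64)
        if state.all_sum is None:
            state.all_sum = np.zeros(len(self.marker_idx), dtype=np.int64)
            state.old_sum = np.zeros(len(self.marker_idx), dtype=np.int64)
        state.all_sum += counts
        state.all_n += len(new)
        if into_old:
            state.old_sum += counts
            state.old_n += len(new)

    def _window_gens(self, t: int) -> list[int]:
        w = self.cfg.evaluation.window_generations
        return list(range(max(0, t - w + 1), t + 1))

    def _collect_records(self, state: ProgramState, gens: list[int],
                         t: int, genotyped_only: bool,
                         animal_key: dict[tuple[int, int], int]) -> tuple[np.ndarray, np.ndarray]:
        """Phenotype records of dam-age females (born before event t) in the window."""
        ys, owner = [], []
        for g in gens:
            if g >= t:
                continue
            c = state.cohorts[g]
            sel = (c.sex == FEMALE) & ~np.isnan(c.phenotype)
            if genotyped_only:
                sel &= c.genotyped
            for i in np.flatnonzero(sel):
                key = (g, int(i))
                if key in animal_key:
                    ys.append(c.phenotype[i])
                    owner.append(animal_key[key])
        return np.asarray(ys), np.asarray(owner, dtype=np.int64)

    # ---------------- pedigree phase ----------------

    def run_pedigree_phase(self) -> ProgramState:
        cfg = self.cfg
        rngs = self._rngs("pedigree")
        cohort0 = base_cohort(self.founders)
        assign_phenotypes(cohort0, self.trait, rngs["phenotype"])
        state = ProgramState(cohorts=[cohort0], nrm=_NRMWindow(cohort0.n),
                             next_id=cohort0.n + 1, records=[])
        state.records.append(GenerationRecord(
            0, "base", np.array([], dtype=np.int64), 0, np.nan, np.nan, np.nan, True,
            self._panel(cohort0, state, rngs["pairs"])))

        for t in range(cfg.program.pedigree_generations):
            cohort = state.cohorts[t]
            males = cohort.male_indices
            if t == 0:
                mode = "random"
                sires = rngs["selection"].choice(males, size=cfg.program.n_sires_pblup,
                                                 replace=False)
            else:
                mode = "PBLUP"
                gens = self._window_gens(t)
                animal_key, n_animals = self._index_animals(state, gens, genotyped_only=False)
                A = state.nrm.block([(g, np.arange(state.cohorts[g].n)) for g in gens])
                y, owner = self._collect_records(state, gens, t, False, animal_key)
                res = solve_blup(y, owner, n_animals, self.lam, K=A)
                self._store_gebv(state, gens, animal_key, res.breeding_values,
                                 genotyped_only=False)
                sires = males[top_by_value(cohort.gebv[males], cfg.program.n_sires_pblup,
                                           rngs["tiebreak"])]
            self._genotype(state, cohort, np.sort(sires), into_old=(t <= 3))
            self._advance(state, t, cohort, np.sort(sires), mode,
                          np.nan, np.nan, np.nan, True, 0, rngs)
        return state

    # ---------------- genomic phase ----------------

    def run_genomic_phase(self, state: ProgramState, scenario: ScenarioSpec) -> GenerationLog:
        cfg = self.cfg
        rngs = self._rngs("scenario", scenario.name)
        first = cfg.program.pedigree_generations
        for t in range(first, cfg.program.generations):
            cohort = state.cohorts[t]
            # 1. parent-average pre-selection of males; genotype them and all females
            males = cohort.male_indices
            prev = state.cohorts[t - 1]
            pos_s = cohort.sire[males] - prev.ids[0]
            pos_d = cohort.dam[males] - prev.ids[0]
            pa = parent_average(prev.gebv[pos_s], prev.gebv[pos_d])
            n_g = min(cfg.evaluation.n_genotyped_males, len(males))
            keep = males[top_by_value(pa, n_g, rngs["preselect"])]
            self._genotype(state, cohort, np.sort(keep), into_old=False)
            self._genotype(state, cohort, cohort.female_indices, into_old=False)

            # 2. genomic evaluation; the first genomic event is always
            # single-step, since only ssGBLUP can see the (non-genotyped)
            # dams' phenotypes before any genotyped female has a record
            use_ss = t == first or (
                not cfg.evaluation.always_gblup
                and (t - first) < cfg.evaluation.ssgblup_rounds)
            mode = "ssGBLUP" if use_ss else "GBLUP"
            self._evaluate_genomic(state, t, use_ss)

            # 3. optimum contribution selection under the scenario matrix
            geno_males = males[cohort.genotyped[males]]
            n_cand = max(cfg.program.n_sires_ocs, len(geno_males) // 2)
            cand = geno_males[top_by_value(cohort.gebv[geno_males], n_cand,
                                           rngs["tiebreak"])]
            R_full = self._scenario_kinship(state, t, scenario)
            f_mean = float(R_full.mean())
            C = kinship_target(f_mean, cfg.ocs.delta_f)
            females = cohort.female_indices
            pf_cross, pf_self = build_pseudofemale(
                R_full[np.ix_(cand, females)], R_full[np.ix_(females, females)])
            problem = OCSProblem(gebv=cohort.gebv[cand].copy(),
                                 R=R_full[np.ix_(cand, cand)],
                                 pf_cross=pf_cross, pf_self=pf_self,
                                 k=cfg.program.n_sires_ocs, C=C)
            decision = optimize_contributions(problem, rngs["ocs"],
                                              max_enumeration=cfg.ocs.max_enumeration)
            if not decision.feasible:
                log.warning("OCS infeasible at generation %d (%s): c'Rc=%.5f > C=%.5f",
                            t, scenario.name, decision.group_kinship, C)
            sires = np.sort(cand[decision.selected])
            self._advance(state, t, cohort, sires, mode, C,
                          decision.group_kinship, decision.objective,
                          decision.feasible, len(cand), rngs)
            log.info("rep %d %s gen %d -> %d: %s, %d sires, c'Rc=%.5f (C=%.5f)",
                     self.replicate, scenario.name, t, t + 1, mode, len(sires),
                     decision.group_kinship, C)
        return GenerationLog(scenario.name, self.replicate, state.records, state)

    # ---------------- shared steps ----------------

    def _advance(self, state: ProgramState, t: int, cohort: Cohort,
                 sires: np.ndarray, mode: str, C: float, achieved: float,
                 objective: float, feasible: bool, n_candidates: int,
                 rngs: dict[str, np.random.Generator]) -> None:
        """Mate, bookkeep the NRM and snapshots, and record the new cohort."""
        cfg = self.cfg
        nxt = mate_cohort(cohort, sires, self.grid, rngs["mating"], self.locus_map,
                          self.trait, state.next_id, cfg.program.calves_per_dam)
        assign_phenotypes(nxt, self.trait, rngs["phenotype"])
        state.next_id += nxt.n
        state.cohorts.append(nxt)
        state.nrm.extend(nxt.sire - cohort.ids[0], nxt.dam - cohort.ids[0])
        state.nrm.drop_before(nxt.generation - cfg.evaluation.window_generations + 1)

        if nxt.generation == 1:
            state.base_raf = self._marker_counts(nxt).mean(axis=0) / 2.0
        if t == 3 and state.old_n > 0:
            state.old_raf = state.old_sum / (2.0 * state.old_n)
        if nxt.generation == cfg.program.pedigree_generations:
            state.ref_freqs = nxt.haplotypes.mean(axis=0)

        state.records.append(GenerationRecord(
            nxt.generation, mode, cohort.ids[sires], n_candidates, C,
            achieved, objective, feasible, self._panel(nxt, state, rngs["pairs"])))

    def _index_animals(self, state: ProgramState, gens: list[int],
                       genotyped_only: bool) -> tuple[dict[tuple[int, int], int], int]:
        key: dict[tuple[int, int], int] = {}
        n = 0
        for g in gens:
            c = state.cohorts[g]
            idx = np.flatnonzero(c.genotyped) if genotyped_only else np.arange(c.n)
            for i in idx:
                key[(g, int(i))] = n
                n += 1
        return key, n

    def _store_gebv(self, state: ProgramState, gens: list[int],
                    animal_key: dict[tuple[int, int], int], values: np.ndarray,
                    genotyped_only: bool) -> None:
        for (g, i), pos in animal_key.items():
            state.cohorts[g].gebv[i] = values[pos]

    def _evaluate_genomic(self, state: ProgramState, t: int, use_ss: bool) -> None:
        cfg = self.cfg
        gens = self._window_gens(t)
        geno_key, n_geno = self._index_animals(state, gens, genotyped_only=True)
        M = np.concatenate([
            self._marker_counts(state.cohorts[g], np.flatnonzero(state.cohorts[g].genotyped))
            for g in gens])
        G = build_vr1(M, state.base_raf)
        members_geno = [(g, np.flatnonzero(state.cohorts[g].genotyped)) for g in gens]
        A22 = state.nrm.block(members_geno)
        w = cfg.evaluation.blend_weight
        if use_ss:
            all_key, n_all = self._index_animals(state, gens, genotyped_only=False)
            A = state.nrm.block([(g, np.arange(state.cohorts[g].n)) for g in gens])
            geno_pos = np.array([all_key[k] for k in geno_key], dtype=np.int64)
            Hinv = build_h_inverse(A, G, geno_pos, w)
            # single-step uses every dam-age phenotype in the window;
            # non-genotyped females contribute through the pedigree part of H
            y, owner = self._collect_records(state, gens, t, False, all_key)
            res = solve_blup(y, owner, n_all, self.lam, Kinv=Hinv)
            self._store_gebv(state, gens, all_key, res.breeding_values, False)
        else:
            Gw = w * G + (1.0 - w) * A22
            y, owner = self._collect_records(state, gens, t, True, geno_key)
            res = solve_blup(y, owner, n_geno, self.lam, K=Gw)
            self._store_gebv(state, gens, geno_key, res.breeding_values, True)

    def _scenario_kinship(self, state: ProgramState, t: int,
                          scenario: ScenarioSpec) -> np.ndarray:
        """Kinship-scale matrix over the whole current cohort.

        The matrix covers genotyped and non-genotyped animals alike, so
        the kinship-rate target is anchored to the whole population rather
        than the genotyped subset.
        """
        cohort = state.cohorts[t]
        if scenario.method == "PED":
            A_tt = state.nrm.block([(t, np.arange(cohort.n))])
            return kinship_scale(A_tt)
        if scenario.raf == RAF_BASE:
            p, n_ref = state.base_raf, state.cohorts[1].n if len(state.cohorts) > 1 else 1
        elif scenario.raf == RAF_OLD:
            p, n_ref = state.old_raf, state.old_n
        elif scenario.raf == RAF_ALL:
            p, n_ref = state.all_sum / (2.0 * state.all_n), state.all_n
        elif scenario.raf == RAF_CURRENT:
            geno = np.flatnonzero(cohort.genotyped)
            p = self._marker_counts(cohort, geno).mean(axis=0) / 2.0
            n_ref = len(geno)
        elif scenario.raf == RAF_HALF:
            p, n_ref = np.full(len(self.marker_idx), 0.5), cohort.n
        else:  # pragma: no cover
            raise ValueError(f"unknown RAF policy {scenario.raf!r}")
        M = self._marker_counts(cohort)
        G = build_grm(scenario.method, M, p, n_reference=n_ref)
        return kinship_scale(G)


def run_scenario(config: RunConfig, founders: FounderPopulation,
                 scenario: ScenarioSpec | str, replicate: int = 0,
                 master_seed: int = 1,
                 pedigree_state: ProgramState | None = None) -> GenerationLog:
    """Run one scenario end to end for one replicate."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    prog = BreedingProgram(config, founders, replicate, master_seed)
    state = prog.run_pedigree_phase() if pedigree_state is None else pedigree_state.copy()
    return prog.run_genomic_phase(state, scenario)


def run_experiment(config: RunConfig, replicates: int,
                   scenarios: Optional[list[str]] = None,
                   master_seed: Optional[int] = None) -> tuple[list[GenerationLog], pd.DataFrame]:
    """Run replicates x scenarios; each replicate shares one founder population.

    Returns the generation logs and the combined long-format metrics table.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    cfg = config.scaled()
    seed = cfg.master_seed if master_seed is None else master_seed
    names = scenarios if scenarios is not None else list(SCENARIOS)
    specs = [SCENARIOS[n] if isinstance(n, str) else n for n in names]
    logs: list[GenerationLog] = []
    for rep in range(replicates):
        founders = simulate_founders(GenomeParams.from_config(cfg),
                                     seed_stream(seed, "rep", rep, "founders"))
        prog = BreedingProgram(cfg, founders, rep, seed)
        ped_state = prog.run_pedigree_phase()
        for spec in specs:
            log.info("replicate %d scenario %s", rep, spec.name)
            logs.append(prog.run_genomic_phase(ped_state.copy(), spec))
    metrics = pd.concat([lg.metrics_frame() for lg in logs], ignore_index=True)
    return logs, metrics
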