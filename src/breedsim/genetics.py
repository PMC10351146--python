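"""Individuals, cohorts, meiosis and the mating design.

A :class:`Cohort` stores a discrete generation column-wise: phased
haplotypes as a ``(2n, L)`` allele array (rows ``2i`` and ``2i+1`` belong
to individual ``i``), founder-segment lists per haplotype for
identity-by-descent bookkeeping, pedigree links, sex, true breeding value,
phenotype and (G)EBV. Meiosis draws Poisson crossovers per chromosome and
produces both the gamete allele array and its founder-segment list from
the same crossover realization; no mutation occurs in the breeding phase.

The mating design mirrors a fixed-size AI scheme: every dam has exactly
two calves by two distinct sires, every selected sire receives an equal
number of matings (rebalanced by at most one when counts do not divide),
and offspring sexes are an exact half/half split by random permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .founders import FounderPopulation, LocusMap, TraitArchitecture
from .genome import (GenomeGrid, draw_crossovers, founder_segments,
                     inheritance_mask, splice_segments)

__all__ = ["MALE", "FEMALE", "Individual", "Gamete", "Cohort",
           "base_cohort", "meiose", "true_breeding_value",
           "assign_phenotypes", "plan_matings", "mate_cohort"]

MALE, FEMALE = 0, 1


@dataclass
class Gamete:
    alleles: np.ndarray
    seg_ends: np.ndarray
    seg_labels: np.ndarray


@dataclass
class Individual:
    """Row view of one animal in a cohort."""

    id: int
    sire: int
    dam: int
    sex: int
    generation: int
    haplotypes: np.ndarray  # (2, L)
    seg_ends: tuple[np.ndarray, np.ndarray]
    seg_labels: tuple[np.ndarray, np.ndarray]
    tbv: float
    phenotype: float
    gebv: float
    genotyped: bool


@dataclass
class Cohort:
    """One discrete generation of animals (struct-of-arrays layout)."""

    generation: int
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    haplotypes: np.ndarray
    seg_ends: list[np.ndarray]
    seg_labels: list[np.ndarray]
    tbv: np.ndarray
    phenotype: np.ndarray
    gebv: np.ndarray
    genotyped: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def male_indices(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    @property
    def female_indices(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def genotype_counts(self, locus_indices: Optional[np.ndarray] = None) -> np.ndarray:
        g = self.haplotypes[0::2].astype(np.int16) + self.haplotypes[1::2]
        return g if locus_indices is None else g[:, locus_indices]

    def individual(self, i: int) -> Individual:
        return Individual(
            id=int(self.ids[i]), sire=int(self.sire[i]), dam=int(self.dam[i]),
            sex=int(self.sex[i]), generation=self.generation,
            haplotypes=self.haplotypes[2 * i:2 * i + 2],
            seg_ends=(self.seg_ends[2 * i], self.seg_ends[2 * i + 1]),
            seg_labels=(self.seg_labels[2 * i], self.seg_labels[2 * i + 1]),
            tbv=float(self.tbv[i]), phenotype=float(self.phenotype[i]),
            gebv=float(self.gebv[i]), genotyped=bool(self.genotyped[i]),
        )

    def copy(self) -> "Cohort":
        return Cohort(
            self.generation, self.ids.copy(), self.sire.copy(), self.dam.copy(),
            self.sex.copy(), self.haplotypes.copy(),
            list(self.seg_ends), list(self.seg_labels),
            self.tbv.copy(), self.phenotype.copy(), self.gebv.copy(),
            self.genotyped.copy(),
        )


def pedigree_frame(cohorts: list["Cohort"]):
    """Long-format pedigree table (one row per animal) across cohorts."""
    import pandas as pd

    frames = []
    for c in cohorts:
        frames.append(pd.DataFrame({
            "id": c.ids, "sire": c.sire, "dam": c.dam, "sex": c.sex,
            "generation": c.generation, "genotyped": c.genotyped,
            "tbv": c.tbv, "phenotype": c.phenotype, "gebv": c.gebv,
        }))
    return pd.concat(frames, ignore_index=True)


def base_cohort(founders: FounderPopulation) -> Cohort:
    """Generation-zero cohort; every haplotype is its own founder segment."""
    n = founders.n
    grid = founders.locus_map.grid
    ends, labels = founder_segments(2 * n, grid)
    tbv = true_breeding_value_cohort(founders.haplotypes, founders.locus_map, founders.trait)
    return Cohort(
        generation=0,
        ids=np.arange(1, n + 1, dtype=np.int64),
        sire=np.zeros(n, dtype=np.int64),
        dam=np.zeros(n, dtype=np.int64),
        sex=founders.sex.copy(),
        haplotypes=founders.haplotypes.copy(),
        seg_ends=ends, seg_labels=labels,
        tbv=tbv,
        phenotype=np.full(n, np.nan),
        gebv=np.full(n, np.nan),
        genotyped=np.zeros(n, dtype=bool),
    )


def meiose(parent: Individual, grid: GenomeGrid, rng: np.random.Generator) -> Gamete:
    """One gamete from one parent, with founder-segment provenance."""
    xo = draw_crossovers(rng, 1, grid)
    mask = inheritance_mask(xo, grid)[0]
    alleles = np.where(mask, parent.haplotypes[1], parent.haplotypes[0])
    ends, labels = splice_segments(
        parent.seg_ends[0], parent.seg_labels[0],
        parent.seg_ends[1], parent.seg_labels[1],
        xo.for_gamete(0), xo.starts[0], grid)
    return Gamete(alleles, ends, labels)


def true_breeding_value_cohort(haplotypes: np.ndarray, locus_map: LocusMap,
                               trait: TraitArchitecture) -> np.ndarray:
    counts = (haplotypes[0::2, locus_map.qtl_indices].astype(np.int16)
              + haplotypes[1::2, locus_map.qtl_indices])
    return counts @ trait.qtl_effects


def true_breeding_value(individual: Individual, locus_map: LocusMap,
                        trait: TraitArchitecture) -> float:
    """TBV = sum over QTL of allele count times substitution effect."""
    counts = individual.haplotypes[:, locus_map.qtl_indices].sum(axis=0)
    return float(counts @ trait.qtl_effects)


def assign_phenotypes(cohort: Cohort, trait: TraitArchitecture,
                      rng: np.random.Generator, mu: float = 0.0,
                      indices: Optional[np.ndarray] = None) -> None:
    """Record the female-only trait: y = mu + TBV + N(0, sigma_e^2).

    The residual variance is the constant fixed at generation zero.
    """
    if indices is None:
        indices = cohort.female_indices
    elif np.any(cohort.sex[np.asarray(indices)] == MALE):
        raise ValueError("phenotype requested for a male; the trait is female-only")
    e = rng.normal(0.0, np.sqrt(trait.residual_variance), size=len(indices))
    cohort.phenotype[indices] = mu + cohort.tbv[indices] + e


def plan_matings(sire_ids: np.ndarray, n_dams: int, calves_per_dam: int,
                 rng: np.random.Generator) -> np.ndarray:
    """(n_dams, calves_per_dam) sire assignment: equal usage, distinct sires per dam."""
    k = len(sire_ids)
    if k < calves_per_dam:
        raise ValueError(
            f"{k} sire(s) cannot give each dam {calves_per_dam} calves by distinct sires")
    total = n_dams * calves_per_dam
    quota, extra = divmod(total, k)
    quotas = np.full(k, quota, dtype=np.int64)
    if extra:  # documented +-1 rebalancing when counts do not divide
        quotas[rng.choice(k, size=extra, replace=False)] += 1
    slots = np.repeat(np.asarray(sire_ids), quotas)
    rng.shuffle(slots)
    pairs = slots.reshape(n_dams, calves_per_dam)
    for _ in range(10 * n_dams):
        if calves_per_dam == 2:
            bad = np.flatnonzero(pairs[:, 0] == pairs[:, 1])
        else:
            bad = np.flatnonzero([len(np.unique(row)) < calves_per_dam for row in pairs])
        if len(bad) == 0:
            break
        for i in bad:
            v = pairs[i, 1]
            # swap with a row that contains neither sire of the clashing pair
            for j in rng.permutation(n_dams):
                if j != i and v not in pairs[j] and pairs[i, 0] != pairs[j, 1]:
                    pairs[i, 1], pairs[j, 1] = pairs[j, 1], pairs[i, 1]
                    break
    else:
        raise RuntimeError("could not satisfy the distinct-sire rule")
    return pairs


def mate_cohort(cohort: Cohort, sire_indices: np.ndarray, grid: GenomeGrid,
                rng: np.random.Generator, locus_map: LocusMap,
                trait: TraitArchitecture, id_start: int,
                calves_per_dam: int = 2) -> Cohort:
    """Breed the next generation from selected sires and all dams of a cohort.

    Each dam is randomly mated to ``calves_per_dam`` distinct sires and has
    exactly that many calves; sires are used equally; offspring sexes are an
    exact half split.
    """
    sire_indices = np.asarray(sire_indices)
    dam_indices = cohort.female_indices
    n_dams = len(dam_indices)
    if n_dams == 0:
        raise ValueError("cohort has no dams")
    pairs = plan_matings(sire_indices, n_dams, calves_per_dam, rng)
    sire_of_calf = pairs.reshape(-1)
    dam_of_calf = np.repeat(dam_indices, calves_per_dam)
    n_off = len(sire_of_calf)

    haps = np.empty((2 * n_off, grid.n_loci), dtype=np.uint8)
    seg_ends: list[np.ndarray] = [None] * (2 * n_off)
    seg_labels: list[np.ndarray] = [None] * (2 * n_off)
    for k, parent in enumerate((dam_of_calf, sire_of_calf)):
        xo = draw_crossovers(rng, n_off, grid)
        mask = inheritance_mask(xo, grid)
        haps[k::2] = np.where(mask, cohort.haplotypes[2 * parent + 1],
                              cohort.haplotypes[2 * parent])
        for g in range(n_off):
            p = parent[g]
            ends, labels = splice_segments(
                cohort.seg_ends[2 * p], cohort.seg_labels[2 * p],
                cohort.seg_ends[2 * p + 1], cohort.seg_labels[2 * p + 1],
                xo.for_gamete(g), xo.starts[g], grid)
            seg_ends[2 * g + k] = ends
            seg_labels[2 * g + k] = labels

    n_male = n_off // 2
    sex = np.concatenate([np.zeros(n_male, dtype=np.uint8),
                          np.ones(n_off - n_male, dtype=np.uint8)])
    rng.shuffle(sex)
    return Cohort(
        generation=cohort.generation + 1,
        ids=np.arange(id_start, id_start + n_off, dtype=np.int64),
        sire=cohort.ids[sire_of_calf],
        dam=cohort.ids[dam_of_calf],
        sex=sex,
        haplotypes=haps,
        seg_ends=seg_ends, seg_labels=seg_labels,
        tbv=true_breeding_value_cohort(haps, locus_map, trait),
        phenotype=np.full(n_off, np.nan),
        gebv=np.full(n_off, np.nan),
        genotyped=np.zeros(n_off, dtype=bool),
    )
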