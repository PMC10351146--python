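"""Genome grid and meiosis primitives.

Loci are evenly spaced on equal-length chromosomes: locus ``i`` of a
chromosome with ``L`` loci sits at genetic position ``(i + 1/2) / L``
Morgan, so no locus lies exactly on a chromosome end. Crossover counts per
chromosome are Poisson with mean equal to the genetic length in Morgan
(no interference, no obligate chiasma), positions are uniform, and the
starting parental haplotype of each chromosome is chosen with probability
one half.

All positions are expressed in a single global coordinate with chromosome
``c`` occupying ``[c*length, (c+1)*length)``; founder-segment lists use the
same coordinate and always carry a breakpoint at every chromosome end, so
segments never span chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeGrid", "Crossovers", "draw_crossovers", "inheritance_mask",
           "splice_segments", "founder_segments", "reconstruct_alleles"]


@dataclass(frozen=True)
class GenomeGrid:
    """Locus coordinates of a genome with equal, evenly spaced chromosomes."""

    n_chromosomes: int
    loci_per_chromosome: int
    chromosome_length: float  # Morgan
    pos_global: np.ndarray = field(repr=False, default=None)
    chrom_of_locus: np.ndarray = field(repr=False, default=None)

    @classmethod
    def create(cls, n_chromosomes: int, loci_per_chromosome: int,
               chromosome_length: float = 1.0) -> "GenomeGrid":
        if n_chromosomes <= 0 or loci_per_chromosome <= 0 or chromosome_length <= 0:
            raise ValueError("genome dimensions must be positive")
        local = (np.arange(loci_per_chromosome) + 0.5) / loci_per_chromosome * chromosome_length
        offsets = np.arange(n_chromosomes) * chromosome_length
        pos = (offsets[:, None] + local[None, :]).ravel()
        chrom = np.repeat(np.arange(n_chromosomes, dtype=np.int16), loci_per_chromosome)
        return cls(n_chromosomes, loci_per_chromosome, chromosome_length, pos, chrom)

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.loci_per_chromosome

    @property
    def total_length(self) -> float:
        return self.n_chromosomes * self.chromosome_length

    @property
    def pos_local(self) -> np.ndarray:
        """Genetic position within the chromosome, in Morgan."""
        return self.pos_global - self.chrom_of_locus * self.chromosome_length

    def chrom_bounds(self, c: int) -> tuple[float, float]:
        return c * self.chromosome_length, (c + 1) * self.chromosome_length

    def chrom_ends(self) -> np.ndarray:
        return (np.arange(self.n_chromosomes, dtype=float) + 1.0) * self.chromosome_length

    def locus_slice(self, c: int) -> slice:
        return slice(c * self.loci_per_chromosome, (c + 1) * self.loci_per_chromosome)


@dataclass
class Crossovers:
    """Crossover realizations for a batch of gametes.

    ``gamete``/``pos`` are flat arrays sorted by (gamete, global position);
    ``offsets`` gives the slice of each gamete's crossovers; ``starts`` is
    the (n_gametes, n_chromosomes) array of starting-haplotype bits.
    """

    n_gametes: int
    gamete: np.ndarray
    pos: np.ndarray
    offsets: np.ndarray
    starts: np.ndarray

    def for_gamete(self, g: int) -> np.ndarray:
        return self.pos[self.offsets[g]:self.offsets[g + 1]]


def draw_crossovers(rng: np.random.Generator, n_gametes: int, grid: GenomeGrid) -> Crossovers:
    counts = rng.poisson(grid.chromosome_length, size=(n_gametes, grid.n_chromosomes))
    per_gamete = counts.sum(axis=1)
    total = int(per_gamete.sum())
    gam = np.repeat(np.arange(n_gametes), per_gamete)
    chrom = np.repeat(np.tile(np.arange(grid.n_chromosomes), n_gametes), counts.ravel())
    pos = chrom * grid.chromosome_length + rng.uniform(0.0, grid.chromosome_length, size=total)
    order = np.lexsort((pos, gam))
    gam, pos = gam[order], pos[order]
    offsets = np.zeros(n_gametes + 1, dtype=np.int64)
    np.cumsum(per_gamete, out=offsets[1:])
    starts = rng.integers(0, 2, size=(n_gametes, grid.n_chromosomes), dtype=np.int16)
    return Crossovers(n_gametes, gam, pos, offsets, starts)


def inheritance_mask(xo: Crossovers, grid: GenomeGrid) -> np.ndarray:
    """Boolean (n_gametes, n_loci) array: True = copy the second haplotype.

    A crossover at position x flips inheritance for all loci of its
    chromosome with position > x; parity restarts at every chromosome with
    the chromosome's start bit.
    """
    G, L = xo.n_gametes, grid.n_loci
    delta = np.zeros((G, L), dtype=np.int16)
    idx = np.searchsorted(grid.pos_global, xo.pos, side="left")
    # crossovers beyond the last locus of their chromosome flip nothing
    chrom = (xo.pos // grid.chromosome_length).astype(np.int64)
    valid = idx < (chrom + 1) * grid.loci_per_chromosome
    np.add.at(delta, (xo.gamete[valid], idx[valid]), 1)
    cc = np.cumsum(delta, axis=1)
    parity = np.empty((G, L), dtype=np.int16)
    for c in range(grid.n_chromosomes):
        sl = grid.locus_slice(c)
        base = cc[:, sl.start] - delta[:, sl.start]
        parity[:, sl] = cc[:, sl] - base[:, None] + xo.starts[:, c:c + 1]
    return (parity & 1).astype(bool)


def founder_segments(n_haplotypes: int, grid: GenomeGrid,
                     first_label: int = 0) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Whole-genome single-founder segments for base-population haplotypes."""
    ends_template = grid.chrom_ends()
    ends = [ends_template.copy() for _ in range(n_haplotypes)]
    labels = [np.full(grid.n_chromosomes, first_label + h, dtype=np.int64)
              for h in range(n_haplotypes)]
    return ends, labels


def splice_segments(ends_a: np.ndarray, labels_a: np.ndarray,
                    ends_b: np.ndarray, labels_b: np.ndarray,
                    xo_pos: np.ndarray, starts: np.ndarray,
                    grid: GenomeGrid) -> tuple[np.ndarray, np.ndarray]:
    """Founder segments of a gamete given parental segments and crossovers.

    ``xo_pos`` are the gamete's crossover positions (sorted, global
    coordinate); ``starts`` the per-chromosome starting-haplotype bits.
    """
    parents = ((ends_a, labels_a), (ends_b, labels_b))
    out_ends: list[np.ndarray] = []
    out_labels: list[np.ndarray] = []
    for c in range(grid.n_chromosomes):
        lo, hi = grid.chrom_bounds(c)
        xs = xo_pos[(xo_pos > lo) & (xo_pos < hi)]
        cuts = np.concatenate(([lo], xs, [hi]))
        src = int(starts[c])
        for a, b in zip(cuts[:-1], cuts[1:]):
            if a == b:
                src ^= 1
                continue
            ends_p, labels_p = parents[src]
            i0 = np.searchsorted(ends_p, a, side="right")
            i1 = np.searchsorted(ends_p, b, side="left")
            out_ends.append(ends_p[i0:i1])
            out_ends.append(np.array([b]))
            out_labels.append(labels_p[i0:i1 + 1])
            src ^= 1
    ends = np.concatenate(out_ends)
    labels = np.concatenate(out_labels)
    # merge adjacent segments with the same founder label (keeps lists short);
    # chromosome-end breakpoints are retained so segments never span chromosomes
    chrom_end = np.isin(ends, grid.chrom_ends())
    keep = np.ones(len(ends), dtype=bool)
    keep[:-1] = (labels[:-1] != labels[1:]) | chrom_end[:-1]
    return ends[keep], labels[keep]


def reconstruct_alleles(ends: np.ndarray, labels: np.ndarray,
                        founder_haplotypes: np.ndarray, grid: GenomeGrid) -> np.ndarray:
    """Rebuild an allele array by applying founder segments to founder haplotypes."""
    out = np.empty(grid.n_loci, dtype=founder_haplotypes.dtype)
    start_idx = 0
    for end, lab in zip(ends, labels):
        stop_idx = int(np.searchsorted(grid.pos_global, end, side="left"))
        out[start_idx:stop_idx] = founder_haplotypes[lab, start_idx:stop_idx]
        start_idx = stop_idx
    return out
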