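"""PLINK ped/map text I/O and the pedigree CSV.

The ped format stores two allele codes per locus per animal with no phase
semantics, so a write/read round trip preserves the unphased genotype
(allele counts) but not the haplotypes. Alleles are coded 1/2 (0 =
missing), columns are whitespace-separated:

    FID IID SIRE DAM SEX PHENOTYPE a1 a2 a1 a2 ...

The map file carries chromosome (1-based), locus id, genetic position in
centimorgan and a running base-pair surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .founders import LocusMap

__all__ = ["PlinkData", "write_plink", "read_plink",
           "write_pedigree", "read_pedigree", "write_locus_map"]

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation",
                    "genotyped", "tbv", "phenotype", "gebv"]


@dataclass
class PlinkData:
    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray  # 0 male, 1 female (converted from ped codes 1/2)
    genotypes: np.ndarray  # (n, L) allele counts, -1 = missing
    locus_map: pd.DataFrame  # chrom, id, pos_morgan


def write_plink(prefix: str | Path, haplotypes: np.ndarray, locus_map: LocusMap,
                ids: np.ndarray | None = None, sire=None, dam=None, sex=None,
                phenotype=None) -> tuple[Path, Path]:
    """Write a ped/map pair from phased haplotypes (phase is not preserved)."""
    prefix = Path(prefix)
    n = haplotypes.shape[0] // 2
    L = haplotypes.shape[1]
    ids = np.arange(1, n + 1) if ids is None else np.asarray(ids)
    sire = np.zeros(n, dtype=int) if sire is None else np.asarray(sire)
    dam = np.zeros(n, dtype=int) if dam is None else np.asarray(dam)
    sex = np.zeros(n, dtype=int) if sex is None else np.asarray(sex)
    phen = np.full(n, -9.0) if phenotype is None else np.asarray(phenotype, dtype=float)
    phen = np.where(np.isnan(phen), -9.0, phen)

    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    codes = (haplotypes + 1).astype("U1")  # allele 0 -> "1", allele 1 -> "2"
    with ped_path.open("w") as fh:
        for i in range(n):
            alleles = np.empty(2 * L, dtype="U1")
            alleles[0::2] = codes[2 * i]
            alleles[1::2] = codes[2 * i + 1]
            fh.write(f"1 {ids[i]} {sire[i]} {dam[i]} {1 if sex[i] == 0 else 2} "
                     f"{phen[i]:g} " + " ".join(alleles) + "\n")
    with map_path.open("w") as fh:
        for j in range(L):
            c = int(locus_map.chromosome[j])
            fh.write(f"{c + 1} c{c + 1}_l{j} {locus_map.position[j] * 100.0:.6f} {j + 1}\n")
    return ped_path, map_path


def read_plink(prefix: str | Path) -> PlinkData:
    """Read a ped/map pair into unphased allele counts."""
    prefix = Path(prefix)
    map_df = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                         names=["chrom", "id", "cm", "bp"])
    map_df["pos_morgan"] = map_df.pop("cm") / 100.0
    L = len(map_df)

    ids, sires, dams, sexes, rows = [], [], [], [], []
    with prefix.with_suffix(".ped").open() as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * L:
                raise ValueError(
                    f"ped line {lineno}: expected {6 + 2 * L} fields, got {len(fields)}")
            alleles = np.array(fields[6:], dtype="U1")
            if not np.isin(alleles, ("0", "1", "2")).all():
                bad = sorted(set(alleles) - {"0", "1", "2"})
                raise ValueError(f"ped line {lineno}: allele codes outside 0/1/2: {bad}")
            a = alleles.astype(np.int8)
            counts = (a[0::2] - 1) + (a[1::2] - 1)  # allele "2" counted
            counts[(a[0::2] == 0) | (a[1::2] == 0)] = -1
            ids.append(int(fields[1]))
            sires.append(int(fields[2]))
            dams.append(int(fields[3]))
            sexes.append(0 if fields[4] == "1" else 1)
            rows.append(counts)
    return PlinkData(np.array(ids), np.array(sires), np.array(dams),
                     np.array(sexes), np.array(rows, dtype=np.int8),
                     map_df[["chrom", "id", "pos_morgan"]])


def write_locus_map(path: str | Path, locus_map: LocusMap) -> None:
    pd.DataFrame({
        "chrom": locus_map.chromosome + 1,
        "id": [f"c{c + 1}_l{j}" for j, c in enumerate(locus_map.chromosome)],
        "pos_morgan": locus_map.position,
        "class": locus_map.class_names(),
    }).to_csv(path, index=False)


def write_pedigree(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, columns=PEDIGREE_COLUMNS)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
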