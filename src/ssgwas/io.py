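"""Readers and writers for the plain-text interchange formats.

Pedigree and phenotype tables travel as CSV with a header; genotypes as
PLINK-style .ped/.map pairs (two allele letters per SNP, "0 0" missing,
1-based bp positions) or as a dense tab-separated 0/1/2 matrix with NA for
missing. All writers emit fixed-precision text so re-runs are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .simulate import MISSING, PEDIGREE_COLUMNS, GenotypeData

PathLike = Union[str, Path]


def write_pedigree(ped: pd.DataFrame, path: PathLike) -> None:
    ped.to_csv(path, index=False)


def topological_sort(ped: pd.DataFrame) -> pd.DataFrame:
    """Reorder so every parent precedes its offspring (Kahn's algorithm);
    raises on cycles, listing the animals involved."""
    ids = list(ped["animal"])
    known = set(ids)
    parents = {r["animal"]: [p for p in (r["sire"], r["dam"]) if p in known and p != 0]
               for _, r in ped.iterrows()}
    placed: list = []
    placed_set: set = set()
    remaining = dict(parents)
    while remaining:
        ready = [a for a, ps in remaining.items() if all(p in placed_set for p in ps)]
        if not ready:
            raise ValueError(f"pedigree contains a cycle among animals {sorted(remaining)}")
        for a in ready:
            placed.append(a)
            placed_set.add(a)
            del remaining[a]
    order = {a: i for i, a in enumerate(placed)}
    return ped.sort_values("animal", key=lambda s: s.map(order)).reset_index(drop=True)


def read_pedigree(path: PathLike) -> pd.DataFrame:
    ped = pd.read_csv(path)
    missing_cols = set(["animal", "sire", "dam"]) - set(ped.columns)
    if missing_cols:
        raise ValueError(f"pedigree file lacks columns {sorted(missing_cols)}")
    ped["sire"] = ped["sire"].fillna(0).astype(int)
    ped["dam"] = ped["dam"].fillna(0).astype(int)
    return topological_sort(ped)


def write_phenotypes(pheno: pd.DataFrame, path: PathLike) -> None:
    pheno.to_csv(path, index=False, float_format="%.6f")


def read_phenotypes(path: PathLike, factors=("cg", "parity_class", "birth_month")
                    ) -> pd.DataFrame:
    df = pd.read_csv(path)
    before = len(df)
    df = df.dropna(subset=[f for f in factors if f in df.columns])
    if len(df) < before:
        import logging
        logging.getLogger(__name__).info(
            "excluded %d phenotype rows with missing factor levels", before - len(df))
    return df.reset_index(drop=True)


def write_dense_genotypes(geno: GenotypeData, prefix: PathLike) -> None:
    """Dense TSV dialect: <prefix>.tsv (animal x SNP, NA missing) and
    <prefix>.tsv.map (snp_id, chrom, pos_bp)."""
    prefix = str(prefix)
    d = pd.DataFrame(geno.calls, columns=geno.snp_map["snp_id"])
    d = d.replace(MISSING, pd.NA)
    d.insert(0, "animal", geno.animal_ids)
    d.to_csv(prefix + ".tsv", sep="\t", index=False, na_rep="NA")
    geno.snp_map.to_csv(prefix + ".tsv.map", sep="\t", index=False)


def read_dense_genotypes(prefix: PathLike) -> GenotypeData:
    prefix = str(prefix)
    d = pd.read_csv(prefix + ".tsv", sep="\t")
    snp_map = pd.read_csv(prefix + ".tsv.map", sep="\t")
    animals = d["animal"].values
    calls = d.drop(columns="animal").to_numpy(dtype=float)
    bad = ~(np.isnan(calls) | np.isin(calls, [0, 1, 2]))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"invalid genotype at data line {i + 1}, column {j + 1}")
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int16)
    return GenotypeData(calls=calls, animal_ids=animals, snp_map=snp_map)


def write_plink(geno: GenotypeData, prefix: PathLike, ped_frame=None) -> None:
    """PLINK-style .ped/.map with alleles A (ref) and B (alt), "0 0" missing."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for _, s in geno.snp_map.iterrows():
            fh.write(f"{s['chrom']}\t{s['snp_id']}\t0\t{s['pos_bp']}\n")
    sex_code = {}
    if ped_frame is not None:
        sex_code = {r["animal"]: (1 if r["sex"] == "M" else 2)
                    for _, r in ped_frame.iterrows()}
    allele_str = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(prefix + ".ped", "w") as fh:
        for i, animal in enumerate(geno.animal_ids):
            lead = [str(animal), str(animal), "0", "0",
                    str(sex_code.get(animal, 0)), "-9"]
            geno_cols = [allele_str[int(c)] for c in geno.calls[i]]
            fh.write(" ".join(lead + geno_cols) + "\n")


def read_plink(prefix: PathLike) -> GenotypeData:
    prefix = str(prefix)
    snp_map = pd.read_csv(prefix + ".map", sep="\t", header=None,
                          names=["chrom", "snp_id", "cm", "pos_bp"])
    snp_map = snp_map[["snp_id", "chrom", "pos_bp"]]
    animals, rows = [], []
    n_expected = None
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if n_expected is None:
                n_expected = len(parts)
            if len(parts) != n_expected:
                raise ValueError(f".ped line {ln}: ragged row "
                                 f"({len(parts)} fields, expected {n_expected})")
            animals.append(int(parts[1]) if parts[1].isdigit() else parts[1])
            alleles = parts[6:]
            calls = np.empty(len(alleles) // 2, dtype=np.int16)
            for j in range(0, len(alleles), 2):
                a, b = alleles[j], alleles[j + 1]
                if a == "0" or b == "0":
                    calls[j // 2] = MISSING
                elif {a, b} <= {"A", "B"}:
                    calls[j // 2] = (a == "B") + (b == "B")
                else:
                    raise ValueError(f".ped line {ln}: unknown allele {a!r}/{b!r}")
            rows.append(calls)
    calls = np.vstack(rows)
    if calls.shape[1] != len(snp_map):
        raise ValueError(".ped marker count does not match the .map file")
    return GenotypeData(calls=calls, animal_ids=np.asarray(animals), snp_map=snp_map)


def read_genotypes(path: PathLike, fmt: str = "dense") -> GenotypeData:
    if fmt == "dense":
        return read_dense_genotypes(path)
    if fmt == "plink":
        return read_plink(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_truth(truth, path: PathLike) -> None:
    pd.DataFrame({"qtl_id": truth.qtl_ids, "effect": truth.qtl_effects}
                 ).to_csv(path, sep="\t", index=False, float_format="%.8f")


def write_matrix_tsv(values: np.ndarray, ids, path: PathLike) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.8f")
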