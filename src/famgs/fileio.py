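"""Readers and writers for the text formats the pipeline touches.

PED/MAP follows the PLINK text dialect: PED rows are
``fid iid father mother sex phenotype`` followed by two allele symbols per
SNP ("0 0" = missing); MAP rows are ``chrom snp cM pos``.  All tabular
artifacts (QC reports, association results, scorecards, evidence and
annotation tables) are TSV with a header.  Coordinates are 1-based
inclusive; A1 is the first allele read for a SNP and genotype counts are
copies of A1 throughout.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import MISSING, FamilyCohort

VALID_ALLELES = set("ACGT12")

_STATUS_FROM_PED = {"2": 2, "1": 1, "0": 0, "-9": 0}


class PedFormatError(ValueError):
    """Malformed PED/MAP input; message carries the offending line number."""


def read_ped_map(ped_path, map_path) -> FamilyCohort:
    """Parse a PED/MAP pair into a :class:`FamilyCohort`.

    Phenotype 2 -> affected, 1 -> unaffected, 0/-9 -> unknown; sex 1 male /
    2 female; "0 0" genotypes are missing.  Ragged lines, duplicate
    individual ids and allele symbols outside {A,C,G,T,1,2,0} are rejected
    with the line number.
    """
    snps = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str, "snp": str},
    )
    m = len(snps)

    a1 = [None] * m
    a2 = [None] * m
    rows, dosages = [], []
    seen = set()
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise PedFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2x{m} SNPs), found {len(tok)}"
                )
            fid, iid, father, mother, sex, pheno = tok[:6]
            if iid in seen:
                raise PedFormatError(f"{ped_path}:{lineno}: duplicate individual id {iid!r}")
            seen.add(iid)
            if pheno not in _STATUS_FROM_PED:
                raise PedFormatError(f"{ped_path}:{lineno}: bad phenotype {pheno!r}")
            dos = np.empty(m, dtype=np.int8)
            for j in range(m):
                x, y = tok[6 + 2 * j], tok[7 + 2 * j]
                for al in (x, y):
                    if al != "0" and al not in VALID_ALLELES:
                        raise PedFormatError(
                            f"{ped_path}:{lineno}: invalid allele {al!r} at SNP {j + 1}"
                        )
                if x == "0" or y == "0":
                    dos[j] = MISSING
                    continue
                d = 0
                for al in (x, y):
                    if a1[j] is None:
                        a1[j] = al
                    if al == a1[j]:
                        d += 1
                    elif a2[j] is None:
                        a2[j] = al
                    elif al != a2[j]:
                        raise PedFormatError(
                            f"{ped_path}:{lineno}: third allele {al!r} at SNP {j + 1}"
                        )
                dos[j] = d
            rows.append((fid, iid, father, mother, int(sex), _STATUS_FROM_PED[pheno]))
            dosages.append(dos)
    individuals = pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "status"]
    )
    snp_table = pd.DataFrame(
        {
            "snp": snps["snp"],
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "a1": [x if x is not None else "0" for x in a1],
            "a2": [x if x is not None else "0" for x in a2],
        }
    )
    geno = np.array(dosages, dtype=np.int8) if dosages else np.empty((0, m), np.int8)
    return FamilyCohort(individuals, geno, snp_table)


def write_ped_map(cohort: FamilyCohort, ped_path, map_path) -> None:
    """Write a cohort back to PED/MAP (cM column written as 0)."""
    snps = cohort.snps
    with open(map_path, "w") as fh:
        for _, r in snps.iterrows():
            fh.write(f"{r['chrom']}\t{r['snp']}\t0\t{r['pos']}\n")
    a1 = snps["a1"].to_numpy().astype(object)
    a2 = snps["a2"].to_numpy().astype(object)
    # emit heterozygotes in the order a reader scanning the file would infer
    # (A1 = first allele read), so write(read(x)) is the identity on files
    het_first, het_second = a1.copy(), a2.copy()
    for j in range(len(snps)):
        col = cohort.genotypes[:, j]
        seen = col[col != MISSING]
        if len(seen) and seen[0] == 0:
            het_first[j], het_second[j] = a2[j], a1[j]
    pair = {
        2: lambda j: f"{a1[j]} {a1[j]}",
        1: lambda j: f"{het_first[j]} {het_second[j]}",
        0: lambda j: f"{a2[j]} {a2[j]}",
        MISSING: lambda j: "0 0",
    }
    status_out = {2: "2", 1: "1", 0: "0"}
    with open(ped_path, "w") as fh:
        for i, r in cohort.individuals.iterrows():
            lead = (
                f"{r['fid']} {r['iid']} {r['father']} {r['mother']} "
                f"{r['sex']} {status_out[int(r['status'])]}"
            )
            gts = " ".join(pair[int(g)](j) for j, g in enumerate(cohort.genotypes[i]))
            fh.write(lead + (" " + gts if gts else "") + "\n")


# ------------------------------------------------------------------ tables


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: gene, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    need = {"gene", "chrom", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"annotation table lacks columns {need - set(df.columns)}")
    if (df["start"] > df["end"]).any():
        raise ValueError("annotation has start > end")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene symbols in annotation")
    return df


def read_evidence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("is_eqtl", "cns_specific", "mouse_cns_model", "pathway_member"):
        if col in df:
            df[col] = df[col].astype(bool)
    if df.duplicated(["snp", "gene"]).any():
        raise ValueError("duplicate (snp, gene) keys in evidence table")
    for col, allowed in (
        ("prior_report", {"none", "related_disorder", "autism"}),
        ("expression_diff", {"none", "lymphoblastoid", "brain"}),
    ):
        bad = set(df[col]) - allowed
        if bad:
            raise ValueError(f"{col} contains non-enumerated values {bad}")
    return df


def write_results_table(records, path, header_comment: str | None = None) -> None:
    """Write homogeneous records (dataclasses, dicts, or a DataFrame) as TSV.

    Column order is stable (field order of the record type) and floats keep
    8 significant digits so a re-read reproduces values to well under 1e-6
    relative error.  An empty record list still yields a header-only file,
    which requires a record *type* — pass a DataFrame in that case.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and dataclasses.is_dataclass(records[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        else:
            df = pd.DataFrame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
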