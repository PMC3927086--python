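"""Family-based transmission tests (TDT/FBAT-style) per SNP.

For each SNP and genetic-model coding, the statistic sums the coded
genotypes of target-status offspring and compares the sum with its exact
Mendelian expectation conditional on parental genotypes:

    S = sum_children X_ij,   Z = (S - E[S]) / sqrt(Var[S]),

offspring within a family treated as independent transmissions and
between-family contributions summed.  Four analysis strata replicate the
discovery design: affected children of both sexes, affected males only,
affected females only, and transmissions to unaffected children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AFFECTED, FEMALE, MALE, MISSING, UNAFFECTED, FamilyCohort
from .models import CODINGS, MODELS

__all__ = ["AnalysisStratum", "AssocResult", "STRATA", "fbat_test", "run_family_gwas"]


@dataclass(frozen=True)
class AnalysisStratum:
    """Which offspring enter the test: target status and sex restriction."""

    target: str  # "affected" | "unaffected"
    sex: str  # "both" | "male" | "female"

    def __post_init__(self):
        if self.target not in ("affected", "unaffected"):
            raise ValueError(f"bad target {self.target!r}")
        if self.sex not in ("both", "male", "female"):
            raise ValueError(f"bad sex stratum {self.sex!r}")

    @property
    def label(self) -> str:
        return f"{self.target}_{self.sex}"


#: the four discovery-design runs
STRATA = (
    AnalysisStratum("affected", "both"),
    AnalysisStratum("affected", "male"),
    AnalysisStratum("affected", "female"),
    AnalysisStratum("unaffected", "both"),
)


@dataclass
class AssocResult:
    snp: str
    model: str
    stratum: str
    s: float
    e_s: float
    v_s: float
    z: float
    p: float
    n_informative_families: int
    direction: int  # sign of S - E[S] for the A1 allele


def _conditional_tables(model: str) -> tuple[np.ndarray, np.ndarray]:
    """E[X] and Var[X] of the coded child genotype given parental dosages,
    derived by enumerating the four equiprobable transmissions."""
    E = np.zeros((3, 3))
    V = np.zeros((3, 3))
    code = CODINGS[model]
    for gf in range(3):
        for gm in range(3):
            dist = np.zeros(3)
            for a in (0, 1):
                for b in (0, 1):
                    pa = gf / 2 if a else 1 - gf / 2
                    pb = gm / 2 if b else 1 - gm / 2
                    dist[a + b] += pa * pb
            m1 = dist @ code
            E[gf, gm] = m1
            V[gf, gm] = dist @ code**2 - m1 * m1
    return E, V


_TABLES = {m: _conditional_tables(m) for m in MODELS}


def _stratum_children(cohort: FamilyCohort, stratum: AnalysisStratum) -> np.ndarray:
    """Row positions (into child_rows) of offspring matching the stratum."""
    ind = cohort.individuals
    ch = cohort.child_rows
    status = ind["status"].to_numpy()[ch]
    sex = ind["sex"].to_numpy()[ch]
    want = AFFECTED if stratum.target == "affected" else UNAFFECTED
    keep = status == want
    if stratum.sex == "male":
        keep &= sex == MALE
    elif stratum.sex == "female":
        keep &= sex == FEMALE
    return np.flatnonzero(keep)


def fbat_test(
    cohort: FamilyCohort, snp_id: str, model: str, stratum: AnalysisStratum
) -> AssocResult:
    """Transmission test for one SNP under one coding and stratum.

    Families contribute only when both parents are genotyped; families whose
    summed transmission variance is zero (for example both parents
    homozygous) are excluded from ``n_informative_families``.  A SNP with no
    transmission variance anywhere returns Z = 0, p = 1 and zero informative
    families.
    """
    j = cohort.snp_index(snp_id)
    E, V = _TABLES[model]

    ch, fa, mo = cohort.child_rows, cohort.father_rows, cohort.mother_rows
    sel = _stratum_children(cohort, stratum)
    gc = cohort.genotypes[ch[sel], j]
    gf = cohort.genotypes[fa[sel], j]
    gm = cohort.genotypes[mo[sel], j]
    ok = (gc != MISSING) & (gf != MISSING) & (gm != MISSING)
    gc, gf, gm = gc[ok], gf[ok], gm[ok]
    fids = cohort.individuals["fid"].to_numpy()[ch[sel][ok]]

    code = CODINGS[model]
    s = float(code[gc].sum())
    e_s = float(E[gf, gm].sum())
    v_child = V[gf, gm]
    v_s = float(v_child.sum())

    if v_s <= 0:
        return AssocResult(snp_id, model, stratum.label, s, e_s, 0.0, 0.0, 1.0, 0, 0)

    fam_v = pd.Series(v_child).groupby(fids).sum()
    n_inf = int((fam_v > 0).sum())
    z = (s - e_s) / np.sqrt(v_s)
    p = float(2 * stats.norm.sf(abs(z)))
    return AssocResult(
        snp_id, model, stratum.label, s, e_s, v_s, float(z), max(p, 5e-324),
        n_inf, int(np.sign(s - e_s)),
    )


def run_family_gwas(
    cohort: FamilyCohort,
    models=MODELS,
    strata=STRATA,
    snp_ids=None,
) -> pd.DataFrame:
    """All (SNP, model, stratum) transmission tests as a tidy table.

    Adds per-SNP ``is_min_p`` marking the winning (model, stratum)
    combination (minimum p; first in evaluation order on exact ties) for
    downstream candidate selection.
    """
    if snp_ids is None:
        snp_ids = list(cohort.snps["snp"])
    rows = []
    for snp in snp_ids:
        for model in models:
            for stratum in strata:
                r = fbat_test(cohort, snp, model, stratum)
                rows.append(r.__dict__)
    df = pd.DataFrame(rows)
    df["is_min_p"] = False
    idx = df.groupby("snp")["p"].idxmin()
    df.loc[idx, "is_min_p"] = True
    return df
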