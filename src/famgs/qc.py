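"""SNP-level quality control: exact HWE test, call rate/MAF filters, and
family-wise Mendelian-error masking.

Order of operations in :func:`apply_qc` is Mendel masking first, then the
marker filters, since masking changes call rates.  HWE and MAF are computed
on founders only (the standard family-data convention, avoiding relatedness
distortion); call rate over all individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, FamilyCohort


@dataclass(frozen=True)
class QCThresholds:
    """Marker filters: exact-HWE p, call rate, and minor allele frequency."""

    hwe_p_min: float = 1e-3
    call_rate_min: float = 0.90
    maf_min: float = 0.05

    def __post_init__(self):
        for name in ("hwe_p_min", "call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0,1)")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    the observed one.  Monomorphic tables have a single attainable
    configuration, hence p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype table")
    n_a = n_Aa + 2 * n_aa  # minor-allele count (relabel below if needed)
    n_A = n_Aa + 2 * n_AA
    rare = min(n_a, n_A)

    # heterozygote count shares the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of each attainable het count
    from scipy.special import gammaln

    n_rare_hom = (rare - hets) // 2
    n_comm_hom = (2 * n - rare - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_comm_hom + 1)
        - gammaln(hets + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _snp_metrics(cohort: FamilyCohort) -> pd.DataFrame:
    g = cohort.genotypes
    founders = cohort.founder_rows
    call_rate = (g != MISSING).mean(axis=0) if len(g) else np.zeros(cohort.n_snps)

    gf = g[founders]
    obs = gf != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n_obs > 0, np.where(obs, gf, 0).sum(axis=0) / (2 * n_obs), np.nan)
    maf = np.minimum(p1, 1 - p1)

    hwe = np.ones(cohort.n_snps)
    for j in range(cohort.n_snps):
        col = gf[:, j]
        col = col[col != MISSING]
        if len(col) == 0:
            hwe[j] = np.nan
            continue
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        hwe[j] = hwe_exact_test(n2, n1, n0)
    return pd.DataFrame(
        {
            "snp": cohort.snps["snp"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe,
        }
    )


def snp_qc_filter(
    cohort: FamilyCohort, thresholds: QCThresholds = QCThresholds()
) -> tuple[FamilyCohort, pd.DataFrame]:
    """Remove SNPs failing HWE (founders), call rate (all), or MAF (founders).

    Returns the filtered cohort and a per-SNP report listing the three
    metrics, pass/fail, and comma-joined failure reasons.
    """
    if cohort.n_individuals == 0:
        raise ValueError("empty cohort")
    rep = _snp_metrics(cohort)
    reasons = []
    for _, r in rep.iterrows():
        why = []
        if not (r["hwe_p"] >= thresholds.hwe_p_min):
            why.append("hwe")
        if not (r["call_rate"] >= thresholds.call_rate_min):
            why.append("call_rate")
        if not (r["maf"] >= thresholds.maf_min):
            why.append("maf")
        reasons.append(",".join(why))
    rep["reasons"] = reasons
    rep["pass"] = rep["reasons"] == ""
    return cohort.subset_snps(rep["pass"].to_numpy()), rep


def mendel_mask(cohort: FamilyCohort) -> tuple[FamilyCohort, pd.DataFrame]:
    """Blank whole families at SNPs showing a Mendelian inconsistency.

    A child genotype is inconsistent when its A1-dosage falls outside the
    range attainable from its parents' genotypes (a homozygous parent must
    contribute its allele; a missing parent constrains nothing).  Any
    inconsistency sets the SNP to missing for *every* member of that family.
    Masking is idempotent: a second pass finds zero errors.
    """
    g = cohort.genotypes.copy()
    ch, fa, mo = cohort.child_rows, cohort.father_rows, cohort.mother_rows
    log_rows = []
    if len(ch):
        gc, gf, gm = g[ch], g[fa], g[mo]
        # per-parent min/max contribution of A1 alleles; missing -> (0, 1)
        def contrib(gp):
            cmin = np.where(gp == 2, 1, 0)
            cmax = np.where(gp == 0, 0, 1)
            return np.where(gp == MISSING, 0, cmin), np.where(gp == MISSING, 1, cmax)

        fmin, fmax = contrib(gf)
        mmin, mmax = contrib(gm)
        bad = (gc != MISSING) & ((gc < fmin + mmin) | (gc > fmax + mmax))
        fids = cohort.individuals["fid"].to_numpy()
        child_fids = fids[ch]
        for i, j in zip(*np.nonzero(bad)):
            log_rows.append(
                {
                    "fid": child_fids[i],
                    "snp": cohort.snps["snp"].iloc[j],
                    "child": cohort.individuals["iid"].iloc[ch[i]],
                    "child_gt": int(gc[i, j]),
                    "father_gt": int(gf[i, j]),
                    "mother_gt": int(gm[i, j]),
                }
            )
        if log_rows:
            for fid, snp_j in {(r["fid"], r["snp"]) for r in log_rows}:
                jcol = cohort.snp_index(snp_j)
                g[fids == fid, jcol] = MISSING
    log = pd.DataFrame(
        log_rows,
        columns=["fid", "snp", "child", "child_gt", "father_gt", "mother_gt"],
    )
    return FamilyCohort(cohort.individuals.copy(), g, cohort.snps.copy()), log


def apply_qc(
    cohort: FamilyCohort, thresholds: QCThresholds = QCThresholds()
) -> tuple[FamilyCohort, pd.DataFrame, pd.DataFrame]:
    """Mendel masking followed by marker filters; returns (cohort, qc report,
    mendel log)."""
    masked, log = mendel_mask(cohort)
    filtered, report = snp_qc_filter(masked, thresholds)
    return filtered, report, log
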