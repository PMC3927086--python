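"""Synthetic multiplex-family cohorts under a sex-specific liability model.

The generator emulates the design of autism multiplex-family collections:
nuclear families (two genotyped parents, two or more children) ascertained on
having at least two affected children.  Each child's latent liability is

    L = sum_c beta_c (X_c - E[X_c]) + s + e,

where ``X_c`` is the child's genotype at causal SNP c coded under that SNP's
genetic model, ``s`` is a sibling-shared Gaussian component (variance
``shared_sib_var``, identical for all sibs in a family) and ``e`` an
independent residual sized so the total liability variance is 1.  A child is
affected when L exceeds the sex-specific threshold Phi^-1(1 - K_sex); with
male prevalence 1/54 and female 1/252 the familiar ~4:1 affected male:female
ratio emerges from the thresholds alone.

Parents are drawn at Hardy-Weinberg proportions per SNP (no LD) and children
by independent Mendelian transmission, so cohorts are Mendel-consistent by
construction; missingness and genotype error can be injected to exercise QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import AFFECTED, FEMALE, MALE, MISSING, UNAFFECTED, UNKNOWN, FamilyCohort
from .models import CODINGS, MODELS

__all__ = [
    "CausalSNP",
    "SimulationParams",
    "simulate_families",
    "simulate_annotation",
    "simulate_evidence",
    "liability_effect_for_or",
    "coded_genotype_moments",
]

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass(frozen=True)
class CausalSNP:
    """A causal entry: SNP index, genetic model, liability effect per coded
    risk-genotype unit (standardized liability scale).  When ``maf`` is set
    the SNP's allele frequency is pinned to it instead of being drawn, so
    the liability variance the entry contributes is exact."""

    index: int
    model: str
    beta: float
    maf: float | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.maf is not None and not 0 < self.maf < 1:
            raise ValueError(f"maf={self.maf} outside (0,1)")


def causal_set_for_variance(
    n: int, total_variance: float, model: str = "additive", maf: float = 0.3,
    start_index: int = 0,
) -> tuple[CausalSNP, ...]:
    """``n`` equal-effect causal SNPs jointly explaining ``total_variance``
    of liability, each at allele frequency ``maf`` under ``model``."""
    _, var = coded_genotype_moments(maf, model)
    beta = np.sqrt(total_variance / n / var)
    return tuple(
        CausalSNP(start_index + i, model, float(beta), maf) for i in range(n)
    )


@dataclass
class SimulationParams:
    """Study-design knobs for :func:`simulate_families`.

    Defaults mirror a discovery-scale multiplex collection: 545 families of
    2-4 children ascertained on >= 2 affected, male prevalence 1/54, female
    1/252, and no causal SNPs (a null cohort) unless ``causal`` is given.
    """

    n_families: int = 545
    children_per_family: int | tuple[int, int] = (2, 4)
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal: tuple[CausalSNP, ...] = ()
    shared_sib_var: float = 0.0
    male_prevalence: float = 1.0 / 54
    female_prevalence: float = 1.0 / 252
    ascertainment_min_affected: int = 2
    missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.male_prevalence < 1 or not 0 < self.female_prevalence < 1:
            raise ValueError("prevalences must lie in (0,1)")
        if not 0 <= self.shared_sib_var < 1:
            raise ValueError("shared_sib_var must lie in [0,1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 1:
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if len(self.causal) > self.n_snps:
            raise ValueError("more causal entries than SNPs")
        for c in self.causal:
            if not 0 <= c.index < self.n_snps:
                raise ValueError(f"causal index {c.index} out of range")


def coded_genotype_moments(freq: float, model: str) -> tuple[float, float]:
    """(mean, variance) of the model-coded genotype at HWE with A1 freq."""
    p = freq
    probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])  # dosage 0,1,2
    code = CODINGS[model]
    m = float(probs @ code)
    v = float(probs @ code**2 - m * m)
    return m, v


def liability_effect_for_or(
    target_or: float, maf: float, K: float, model: str = "additive"
) -> float:
    """Liability effect per coded-genotype unit giving a target odds ratio.

    Under the liability model the penetrance of coded genotype x is
    ``1 - Phi((t - beta (x - mu)) / sqrt(1 - beta^2 var))``; the per-unit OR
    compares x = 1 against x = 0.  Solved numerically (exact under the
    model), which keeps the generator's variance bookkeeping on the
    standardized liability scale while letting scenarios be stated as ORs.
    """
    if target_or <= 0:
        raise ValueError("odds ratio must be positive")
    if target_or == 1.0:
        return 0.0
    t = stats.norm.isf(K)
    mu, var = coded_genotype_moments(maf, model)

    def or_at(beta):
        sd = np.sqrt(max(1e-12, 1.0 - beta * beta * var))
        k1 = stats.norm.sf((t - beta * (1.0 - mu)) / sd)
        k0 = stats.norm.sf((t - beta * (0.0 - mu)) / sd)
        return (k1 / (1 - k1)) / (k0 / (1 - k0))

    hi = min(2.5, 0.99 / np.sqrt(var))
    return float(optimize.brentq(lambda b: or_at(b) - target_or, 0.0 if target_or > 1 else -hi, hi if target_or > 1 else 0.0, xtol=1e-10))


def _children_counts(params: SimulationParams, n: int, rng) -> np.ndarray:
    c = params.children_per_family
    if isinstance(c, int):
        return np.full(n, c)
    lo, hi = c
    return rng.integers(lo, hi + 1, size=n)


def simulate_families(params: SimulationParams) -> FamilyCohort:
    """Generate an ascertained multiplex-family cohort.

    Families are simulated in vectorized batches and kept when at least
    ``ascertainment_min_affected`` children are affected, until
    ``n_families`` have been emitted.  Fully reproducible given
    ``params.seed``.

    Raises
    ------
    RuntimeError
        If the estimated ascertainment acceptance probability is below 1e-6
        (no family accepted after a large pilot), with a diagnostic.
    """
    rng = np.random.default_rng(params.seed)
    m = params.n_snps

    freq = rng.uniform(*params.maf_range, size=m)
    for c in params.causal:
        if c.maf is not None:
            freq[c.index] = c.maf
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    causal_var = 0.0
    causal_mean = {}
    for c in params.causal:
        mu, v = coded_genotype_moments(freq[c.index], c.model)
        causal_var += c.beta * c.beta * v
        causal_mean[c.index] = mu
    resid_var = 1.0 - causal_var - params.shared_sib_var
    if resid_var <= 0:
        raise ValueError(
            f"causal liability variance ({causal_var:.3f}) + shared_sib_var "
            f"({params.shared_sib_var:.3f}) must be < 1"
        )

    t_sex = {
        MALE: float(stats.norm.isf(params.male_prevalence)),
        FEMALE: float(stats.norm.isf(params.female_prevalence)),
    }

    kept_parents, kept_children, kept_counts = [], [], []
    kept_sex, kept_status = [], []
    n_kept = 0
    scanned = 0
    batch = 4000
    while n_kept < params.n_families:
        nb = batch
        counts = _children_counts(params, nb, rng)
        cmax = int(counts.max())
        par = rng.binomial(2, freq[None, None, :], size=(nb, 2, m)).astype(np.int8)
        # one transmitted allele per parent: A1 w.p. dosage/2
        pf = par[:, 0, None, :] / 2.0
        pm = par[:, 1, None, :] / 2.0
        u = rng.random(size=(nb, cmax, m))
        v_ = rng.random(size=(nb, cmax, m))
        child = (u < pf).astype(np.int8) + (v_ < pm).astype(np.int8)

        lia = np.zeros((nb, cmax))
        for c in params.causal:
            coded = CODINGS[c.model][child[:, :, c.index]]
            lia += c.beta * (coded - causal_mean[c.index])
        if params.shared_sib_var > 0:
            lia += rng.normal(0.0, np.sqrt(params.shared_sib_var), size=(nb, 1))
        lia += rng.normal(0.0, np.sqrt(resid_var), size=(nb, cmax))

        sex = np.where(rng.random(size=(nb, cmax)) < 0.5, MALE, FEMALE)
        thr = np.where(sex == MALE, t_sex[MALE], t_sex[FEMALE])
        affected = lia > thr
        valid = np.arange(cmax)[None, :] < counts[:, None]
        n_aff = (affected & valid).sum(axis=1)
        accept = n_aff >= params.ascertainment_min_affected

        scanned += nb
        for fi in np.flatnonzero(accept):
            if n_kept >= params.n_families:
                break
            k = counts[fi]
            kept_parents.append(par[fi])
            kept_children.append(child[fi, :k])
            kept_counts.append(k)
            kept_sex.append(sex[fi, :k])
            kept_status.append(affected[fi, :k])
            n_kept += 1
        if n_kept == 0 and scanned >= 400_000:
            raise RuntimeError(
                "ascertainment did not converge: 0 of "
                f"{scanned} simulated families had >= "
                f"{params.ascertainment_min_affected} affected children "
                "(estimated acceptance probability < 1e-6); "
                "lower the ascertainment bar or raise prevalence/sharing"
            )
        if scanned > 20_000_000:
            raise RuntimeError(
                f"ascertainment too slow: {n_kept}/{params.n_families} "
                f"families after {scanned} simulated"
            )

    rows = []
    geno = []
    for k, (par, chd, cnt, sx, st) in enumerate(
        zip(kept_parents, kept_children, kept_counts, kept_sex, kept_status)
    ):
        fid = f"F{k:05d}"
        fa, mo = f"{fid}_f", f"{fid}_m"
        rows.append((fid, fa, "0", "0", MALE, UNKNOWN))
        rows.append((fid, mo, "0", "0", FEMALE, UNKNOWN))
        geno.append(par[0])
        geno.append(par[1])
        for j in range(cnt):
            rows.append(
                (
                    fid,
                    f"{fid}_c{j + 1}",
                    fa,
                    mo,
                    int(sx[j]),
                    AFFECTED if st[j] else UNAFFECTED,
                )
            )
            geno.append(chd[j])
    individuals = pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "status"]
    )
    genotypes = (
        np.array(geno, dtype=np.int8) if geno else np.empty((0, m), dtype=np.int8)
    )

    if params.genotype_error_rate > 0:
        err = rng.random(genotypes.shape) < params.genotype_error_rate
        genotypes[err] = rng.integers(0, 3, size=int(err.sum()))
    if params.missing_rate > 0:
        genotypes[rng.random(genotypes.shape) < params.missing_rate] = MISSING

    snps = pd.DataFrame(
        {
            "snp": [f"rs{i + 1:06d}" for i in range(m)],
            "chrom": (np.arange(m) % 22 + 1).astype(str),
            "pos": (np.arange(m) // 22 + 1) * 100_000,
            "a1": a1,
            "a2": a2,
        }
    )
    return FamilyCohort(individuals, genotypes, snps)


def simulate_annotation(cohort: FamilyCohort, span: int = 2000) -> pd.DataFrame:
    """One synthetic gene per SNP, spanning ``pos +/- span`` so each SNP lies
    inside its gene.  Deterministic; columns ``gene, chrom, start, end``."""
    snps = cohort.snps
    return pd.DataFrame(
        {
            "gene": ["G_" + s for s in snps["snp"]],
            "chrom": snps["chrom"],
            "start": np.maximum(1, snps["pos"] - span),
            "end": snps["pos"] + span,
        }
    )


EVIDENCE_COLUMNS = [
    "snp",
    "gene",
    "is_eqtl",
    "prior_report",
    "expression_diff",
    "cns_specific",
    "mouse_cns_model",
    "pathway_member",
]


def simulate_evidence(
    cohort: FamilyCohort,
    causal_ids: set[str],
    p_true: float,
    p_false: float,
    seed: int,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Synthetic functional-genomics evidence for each SNP-gene pair.

    Stands in for curated inputs (eQTL lookups, prior association reports,
    expression and mouse-model review): each evidence field is favourable
    with probability ``p_true`` for genes of causal SNPs and ``p_false``
    otherwise.  Graded fields take their top category (autism prior, brain
    expression) with that probability and the intermediate category
    (related disorder, lymphoblastoid) with half of it.  Deterministic under
    ``seed``.
    """
    if not 0 <= p_false < p_true <= 1:
        raise ValueError("require 0 <= p_false < p_true <= 1")
    known = set(cohort.snps["snp"])
    bad = set(causal_ids) - known
    if bad:
        raise KeyError(f"unknown SNP ids in causal_ids: {sorted(bad)[:3]}")
    if annotation is None:
        annotation = simulate_annotation(cohort)

    rng = np.random.default_rng(seed)
    rows = []
    for snp, gene in zip(cohort.snps["snp"], annotation["gene"]):
        p = p_true if snp in causal_ids else p_false
        p_mid = min(p / 2, 1 - p)

        def graded(top, mid):
            u = rng.random()
            if u < p:
                return top
            if u < p + p_mid:
                return mid
            return "none"

        rows.append(
            {
                "snp": snp,
                "gene": gene,
                "is_eqtl": bool(rng.random() < p),
                "prior_report": graded("autism", "related_disorder"),
                "expression_diff": graded("brain", "lymphoblastoid"),
                "cns_specific": bool(rng.random() < p),
                "mouse_cns_model": bool(rng.random() < p),
                "pathway_member": bool(rng.random() < p),
            }
        )
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
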