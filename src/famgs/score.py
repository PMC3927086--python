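"""Sex-specific genetic scores and liability-scale variance explained.

A genetic score (GS) is the per-individual sum of risk-allele codings over
a fixed SNP panel, each SNP coded under its best-fitted genetic model.
Model fitting happens once, in the discovery cohort; the frozen model is
then evaluated in an independent validation cohort: genetic relative risk
(GRR, the odds ratio per GS unit from the cluster-robust logistic fit),
case/control AUC, the liability variance v the score explains, and
v / h2 — the proportion of *genetic* variance explained, with h2 the
Falconer estimate from prevalence and sibling recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AFFECTED, FEMALE, MALE, MISSING, UNAFFECTED, FamilyCohort
from .gee import gee_logistic, sibling_case_control
from .liability import (
    LiabilityParams,
    auc_to_liability_v,
    heritability_from_recurrence,
    liability_correlation_for_recurrence,
)
from .models import CODINGS, MODELS, code_genotypes

__all__ = [
    "GSEntry",
    "GSModel",
    "VarianceResult",
    "select_best_model",
    "compute_gs",
    "auc_of_score",
    "evaluate_gs",
]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class GSEntry:
    snp: str
    risk_is_a1: bool
    model: str


@dataclass
class GSModel:
    """Frozen per-SNP (risk allele, genetic model) choices for one sex."""

    sex: str  # "male" | "female" | "both"
    entries: tuple[GSEntry, ...]
    direction_filtered: bool = True
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.snp in seen:
                raise ValueError(f"duplicate SNP {e.snp} in GS model")
            seen.add(e.snp)
            if e.model not in MODELS:
                raise ValueError(f"unknown model {e.model!r}")


@dataclass
class VarianceResult:
    sex: str
    n_cases: int
    n_controls: int
    auc: float
    auc_flipped: bool
    v: float  # share of total liability variance (design-aware when corrected)
    v_uncorrected: float  # population (random-sample) AUC inversion
    h2: float
    genetic_variance_explained: float
    clamped: bool
    h2_above_one: bool
    grr: float
    p: float
    ascertainment_corrected: bool = True
    inversion_saturated: bool = False


def select_best_model(
    cohort: FamilyCohort,
    snp_entries,
    sex: str,
    direction_filter: bool = True,
) -> GSModel:
    """Choose each SNP's coding by its marginal discrimination in discovery.

    ``snp_entries`` is an iterable of (snp id, risk_is_a1) pairs — risk
    alleles fixed upstream by the family-based test.  Each of the three
    codings is fitted by the sibling case-control estimating equation in the
    given sex stratum; the coding with the largest |robust Wald z| wins
    (ties within 1e-12 break additive > dominant > recessive).  With
    ``direction_filter`` codings whose OR for the risk allele is <= 1 are
    excluded before maximization; SNPs with no admissible coding are
    dropped.
    """
    snp_entries = list(snp_entries)
    if not snp_entries:
        raise ValueError("empty SNP set")
    chosen = []
    for snp, risk_is_a1 in snp_entries:
        best = None  # (abs_z, order, model)
        for order, model in enumerate(MODELS):
            try:
                fit = sibling_case_control(cohort, snp, model, sex, risk_is_a1)
            except ValueError:
                continue
            if fit.non_estimable:
                continue
            if direction_filter and fit.odds_ratio <= 1.0:
                continue
            az = abs(float(fit.z[fit["genotype"]]))
            if best is None or az > best[0] + _TIE_EPS:
                best = (az, order, model)
        if best is not None:
            chosen.append(GSEntry(snp, bool(risk_is_a1), best[2]))
    return GSModel(sex, tuple(chosen), direction_filtered=direction_filter)


def compute_gs(
    cohort: FamilyCohort, gs_model: GSModel, rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic scores for the given individuals (default: all rows).

    Missing genotypes contribute the mean coding of that SNP over the scored
    individuals; individuals missing more than half the model SNPs are
    flagged low-confidence.  Returns ``(scores, low_confidence)``.
    """
    if not gs_model.entries:
        raise ValueError("GS model has no SNPs")
    if rows is None:
        rows = np.arange(cohort.n_individuals)
    scores = np.zeros(len(rows))
    n_missing = np.zeros(len(rows), dtype=int)
    for e in gs_model.entries:
        j = cohort.snp_index(e.snp)
        coded = code_genotypes(cohort.genotypes[rows, j], e.model, e.risk_is_a1)
        miss = np.isnan(coded)
        mean = np.nanmean(coded) if (~miss).any() else 0.0
        scores += np.where(miss, mean, coded)
        n_missing += miss
    low_conf = n_missing > len(gs_model.entries) / 2
    return scores, low_conf


def auc_of_score(case_scores, control_scores) -> tuple[float, bool]:
    """Mann-Whitney AUC with ties counted half, oriented to be >= 0.5.

    Returns ``(auc, flipped)`` where ``flipped`` records that the raw score
    discriminated in the protective direction.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[: len(cases)].sum() - len(cases) * (len(cases) + 1) / 2
    auc = u / (len(cases) * len(controls))
    if auc < 0.5:
        return 1.0 - float(auc), True
    return float(auc), False


def _sibling_design_auc_curve(
    v_grid: np.ndarray,
    rho: float,
    thresholds_by_sex: dict[int, float],
    sibship_sizes: np.ndarray,
    stratum_sex: str,
    min_affected: int,
    rng: np.random.Generator,
    snp_freqs: np.ndarray,
    snp_models: list[str],
    target_children: int = 30_000,
    max_scanned: int = 6_000_000,
) -> np.ndarray:
    """Expected affected-vs-unaffected-sibling AUC of the genetic score when
    it explains liability variance v, under multiplex ascertainment.

    The score is simulated from its actual composition: parental genotypes
    at the model SNPs' risk-allele frequencies, children by Mendelian
    transmission, each SNP coded under its selected model.  Liability is
    b (GS - mean) + family-shared Gaussian + residual, with b scaled so the
    score's liability variance equals v and the shared component sized so
    the total sibling liability correlation is rho.  Families replicate the
    observed sibship-size distribution with child sexes drawn 50:50 (the
    cohort's own sex mix is already a product of ascertainment), and a
    family is kept when at least ``min_affected`` children of either sex
    are affected.  Common random numbers across the v grid keep the curve
    smooth; chunks are simulated until roughly ``target_children`` stratum
    children from ascertained families accumulate per grid point, so a low
    acceptance probability costs time rather than precision.
    """
    sizes = np.asarray(sibship_sizes)
    sizes = sizes[sizes > 0]
    if len(sizes) == 0:
        raise ValueError("no children in the cohort to model")
    cmax = int(sizes.max())
    chunk_reps = max(1, 60_000 // len(sizes))
    nf = chunk_reps * len(sizes)
    size_rep = np.tile(sizes, chunk_reps)
    valid = np.arange(cmax)[None, :] < size_rep[:, None]
    t_male = thresholds_by_sex.get(MALE, np.inf)
    t_female = thresholds_by_sex.get(FEMALE, np.inf)

    m = len(snp_freqs)
    codes = [CODINGS[mod] for mod in snp_models]
    # population moments of the score under HWE and independent SNPs
    mu = var = 0.0
    for f, code in zip(snp_freqs, codes):
        pr = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
        m1 = pr @ code
        mu += m1
        var += pr @ code**2 - m1 * m1
    if var <= 0:
        raise ValueError("genetic score has no variance at these frequencies")

    cases = [[] for _ in v_grid]
    controls = [[] for _ in v_grid]
    cov_sib_acc = []
    scanned = 0
    while scanned < max_scanned:
        par = rng.binomial(2, snp_freqs[None, None, :], size=(nf, 2, m))
        pf = par[:, 0, None, :] / 2.0
        pm = par[:, 1, None, :] / 2.0
        dos = (rng.random((nf, cmax, m)) < pf).astype(np.int8) + (
            rng.random((nf, cmax, m)) < pm
        ).astype(np.int8)
        g = np.zeros((nf, cmax))
        for j, code in enumerate(codes):
            g += code[dos[:, :, j]]
        gc = g - mu

        # empirical sibling covariance of the score (first two children)
        cov_sib_acc.append(np.cov(gc[:, 0], gc[:, 1])[0, 1])
        cov_sib = float(np.mean(cov_sib_acc))

        S = np.where(rng.random((nf, cmax)) < 0.5, MALE, FEMALE)
        S[~valid] = 0
        thr = np.where(S == MALE, t_male, np.where(S == FEMALE, t_female, np.inf))
        want = valid if stratum_sex == "both" else (
            S == (MALE if stratum_sex == "male" else FEMALE)
        )
        zfam = rng.standard_normal(nf)[:, None]
        eps = rng.standard_normal((nf, cmax))

        for k, v in enumerate(v_grid):
            b = np.sqrt(v / var)
            c2 = max(0.0, rho - b * b * cov_sib)
            e2 = max(1e-12, 1.0 - b * b * var - c2)
            L = b * gc + np.sqrt(c2) * zfam + np.sqrt(e2) * eps
            aff = (L > thr) & valid
            keep = aff.sum(axis=1) >= min_affected
            cases[k].append(g[keep][aff[keep] & want[keep]])
            controls[k].append(g[keep][~aff[keep] & valid[keep] & want[keep]])
        scanned += nf
        mid = len(v_grid) // 2
        n_mid = sum(len(c) for c in cases[mid]) + sum(len(c) for c in controls[mid])
        if n_mid >= target_children:
            break

    aucs = np.empty(len(v_grid))
    for k in range(len(v_grid)):
        ca = np.concatenate(cases[k]) if cases[k] else np.empty(0)
        co = np.concatenate(controls[k]) if controls[k] else np.empty(0)
        if len(ca) == 0 or len(co) == 0:
            aucs[k] = np.nan
            continue
        aucs[k], _ = auc_of_score(ca, co)
    return aucs


def invert_sibling_auc(
    auc: float,
    sex: str,
    params: dict[str, LiabilityParams],
    sibship_sizes: np.ndarray,
    snp_freqs: np.ndarray,
    snp_models: list[str],
    min_affected: int = 2,
    seed: int = 0,
    n_grid: int = 13,
    target_children: int = 30_000,
) -> tuple[float, bool]:
    """Design-aware inverse of the sibling-case-control AUC.

    Builds the Monte-Carlo forward curve v -> E[AUC] for the ascertained
    sibling design — simulating the score from its actual SNP composition
    (risk-allele frequencies and codings) — and inverts the observed AUC by
    monotone interpolation.  The sibling liability correlation is the one
    implied by (K, K_R) of the evaluated sex.  Returns ``(v, saturated)``
    where ``saturated`` flags an observed AUC beyond the attainable curve
    (v clamped at the grid end).
    """
    pr = params[sex]
    rho = liability_correlation_for_recurrence(pr.K, pr.K_R)
    v_max = min(2 * rho, 2 * (1 - rho), 0.9)
    v_grid = np.linspace(0.0, v_max, n_grid)
    thresholds = {
        (MALE if s == "male" else FEMALE): stats.norm.isf(p.K)
        for s, p in params.items()
        if s in ("male", "female")
    }
    if not thresholds:  # unstratified evaluation: one prevalence for all
        thresholds = {MALE: stats.norm.isf(pr.K), FEMALE: stats.norm.isf(pr.K)}
    rng = np.random.default_rng(seed)
    curve = _sibling_design_auc_curve(
        v_grid, rho, thresholds, sibship_sizes, sex, min_affected, rng,
        np.asarray(snp_freqs, dtype=float), list(snp_models),
        target_children=target_children,
    )
    ok = np.isfinite(curve)
    v_grid, curve = v_grid[ok], curve[ok]
    curve = np.maximum.accumulate(curve)  # enforce monotone against MC noise
    if auc >= curve[-1]:
        return float(v_grid[-1]), True
    return float(np.interp(auc, curve, v_grid)), False


def evaluate_gs(
    cohort: FamilyCohort,
    gs_models: dict[str, GSModel],
    params: dict[str, LiabilityParams],
    reich: bool = False,
    correct_ascertainment: bool = True,
    min_affected: int = 2,
    mc_seed: int = 0,
    mc_target_children: int = 30_000,
) -> dict[str, VarianceResult]:
    """Evaluate frozen sex-specific GS models on an independent cohort.

    Per sex: scores for all children of that sex, GRR and association p
    from the cluster-robust logistic fit (GS the sole predictor), AUC of
    affected vs unaffected siblings, v from the AUC inversion, and
    genetic_variance_explained = v / h2 clamped to [0, 1] with the clamp
    flagged.  Model choices are never re-estimated here.

    With ``correct_ascertainment`` (default) v comes from the design-aware
    inversion (:func:`invert_sibling_auc`), which accounts for sibling
    controls in multiplex-ascertained families sharing risk alleles with
    the cases; the plain population inversion is always reported as
    ``v_uncorrected``.
    """
    out = {}
    ind = cohort.individuals
    ch = cohort.child_rows
    status = ind["status"].to_numpy()[ch]
    sexes = ind["sex"].to_numpy()[ch]
    sib_sizes = None
    if correct_ascertainment:
        fids = ind["fid"].to_numpy()[ch]
        sib_sizes = pd.Series(fids).value_counts().to_numpy()
    for sex, model in gs_models.items():
        want = {"male": sexes == MALE, "female": sexes == FEMALE}.get(
            sex, np.ones(len(ch), bool)
        )
        keep = want & np.isin(status, (AFFECTED, UNAFFECTED))
        rows = ch[keep]
        y = (status[keep] == AFFECTED).astype(float)
        if y.sum() == 0 or (1 - y).sum() == 0:
            raise ValueError(f"validation stratum {sex!r} lacks cases or controls")
        scores, _ = compute_gs(cohort, model, rows)
        X = np.column_stack([np.ones_like(scores), scores])
        fit = gee_logistic(y, X, ind["fid"].to_numpy()[rows], ["intercept", "score"])
        grr = np.nan if fit.non_estimable else fit.odds_ratio
        pval = np.nan if fit.non_estimable else fit.term_p("score")

        auc, flipped = auc_of_score(scores[y == 1], scores[y == 0])
        pr = params[sex]
        v_uncorr = auc_to_liability_v(min(auc, 1 - 1e-9), pr)
        saturated = False
        if correct_ascertainment:
            founders = cohort.founder_rows
            freqs, mods = [], []
            for e in model.entries:
                j = cohort.snp_index(e.snp)
                col = cohort.genotypes[founders, j]
                col = col[col != MISSING]
                f = col.mean() / 2.0 if len(col) else 0.5
                freqs.append(f if e.risk_is_a1 else 1.0 - f)
                mods.append(e.model)
            v, saturated = invert_sibling_auc(
                auc, sex, params, sib_sizes, np.array(freqs), mods,
                min_affected, mc_seed, target_children=mc_target_children,
            )
        else:
            v = v_uncorr
        h2 = heritability_from_recurrence(pr, reich=reich)
        gve = v / h2 if h2 > 0 else np.inf
        clamped = not 0 <= gve <= 1
        out[sex] = VarianceResult(
            sex=sex,
            n_cases=int(y.sum()),
            n_controls=int((1 - y).sum()),
            auc=auc,
            auc_flipped=flipped,
            v=v,
            v_uncorrected=v_uncorr,
            h2=h2,
            genetic_variance_explained=float(np.clip(gve, 0.0, 1.0)),
            clamped=clamped,
            h2_above_one=h2 > 1,
            grr=float(grr),
            p=float(pval),
            ascertainment_corrected=correct_ascertainment,
            inversion_saturated=saturated,
        )
    return out
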