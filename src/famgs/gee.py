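"""Logistic regression with cluster-robust (sandwich) inference.

Point estimates are the ordinary logistic maximum likelihood (the GEE
estimate under a working-independence correlation), obtained by IRLS with a
1e-8 coefficient tolerance; standard errors come from the sandwich
A^-1 B A^-1 with B accumulated from per-cluster summed score vectors, so
siblings from the same family are never treated as independent.  With every
cluster of size one the sandwich reduces exactly to HC0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AFFECTED, FEMALE, MALE, MISSING, UNAFFECTED, FamilyCohort
from .models import code_genotypes

__all__ = [
    "GEEFit",
    "NonEstimableError",
    "gee_logistic",
    "sibling_case_control",
    "run_sibling_tests",
    "select_candidates",
]

MAX_ABS_COEF = 15.0  # beyond this the fit is treated as separated


class NonEstimableError(RuntimeError):
    """Raised when a fit is flagged non-estimable and the caller demanded one."""


@dataclass
class GEEFit:
    names: list
    params: np.ndarray
    robust_se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    cov: np.ndarray = field(repr=False)
    n_clusters: int = 0
    n_observations: int = 0
    converged: bool = True
    non_estimable: bool = False

    def __getitem__(self, name: str) -> int:
        return self.names.index(name)

    @property
    def odds_ratio(self) -> float:
        """Exponentiated genotype (or score) coefficient."""
        for key in ("genotype", "score"):
            if key in self.names:
                return float(np.exp(self.params[self[key]]))
        raise KeyError("fit has no genotype/score term")

    def term_p(self, name: str) -> float:
        return float(self.p[self[name]])


def _irls_logistic(y, X, tol=1e-8, max_iter=100):
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        # working response regression
        zw = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ zw)
        except np.linalg.LinAlgError:
            return beta, mu, False, True
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > MAX_ABS_COEF:
            return beta, mu, False, True
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return beta, mu, converged, False


def gee_logistic(y, X, clusters, names=None) -> GEEFit:
    """Fit a binary-outcome estimating-equation model clustered by family.

    Parameters
    ----------
    y : (n,) 0/1 outcomes.
    X : (n, p) design matrix (include the intercept column yourself).
    clusters : (n,) cluster labels (family ids).
    names : column names; defaults to x0..x{p-1}.

    Separation (any |beta| > 15) and constant non-intercept columns are
    returned flagged ``non_estimable`` rather than raised; genuine rank
    deficiency among non-constant columns is rejected.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    clusters = np.asarray(clusters)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    n, p = X.shape
    uniq, inv = np.unique(clusters, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")

    # a constant predictor (beyond the intercept) is non-estimable, not an
    # error; the intercept is the column named so, else the first constant one
    const = [i for i in range(p) if np.ptp(X[:, i]) == 0]
    named = [i for i, nm in enumerate(names) if nm == "intercept"]
    intercept = (named or const)[:1]
    const_cols = [i for i in const if i not in intercept]
    if const_cols:
        nan = np.full(p, np.nan)
        return GEEFit(list(names), nan, nan, nan, nan, np.full((p, p), np.nan),
                      len(uniq), n, False, True)
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta, mu, converged, separated = _irls_logistic(y, X)
    if separated or not converged:
        nan = np.full(p, np.nan)
        return GEEFit(list(names), beta, nan, nan, nan, np.full((p, p), np.nan),
                      len(uniq), n, converged, True)

    w = np.maximum(mu * (1 - mu), 1e-12)
    A = (X.T * w) @ X
    resid = y - mu
    score = X * resid[:, None]
    # per-cluster summed score vectors
    S = np.zeros((len(uniq), p))
    np.add.at(S, inv, score)
    B = S.T @ S
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return GEEFit(list(names), beta, se, z, pvals, cov, len(uniq), n, True, False)


# ------------------------------------------------------- sibling case-control


def sibling_case_control(
    cohort: FamilyCohort,
    snp_id: str,
    model: str,
    sex: str = "both",
    risk_is_a1: bool = True,
) -> GEEFit:
    """Affected vs unaffected siblings, genotype coded under ``model`` for
    the designated risk allele, clustered by family.

    Parents are excluded; sex enters as an adjustment covariate only when it
    is not the stratification variable (``sex="both"``).
    """
    j = cohort.snp_index(snp_id)
    ind = cohort.individuals
    ch = cohort.child_rows
    status = ind["status"].to_numpy()[ch]
    sexes = ind["sex"].to_numpy()[ch]
    keep = np.isin(status, (AFFECTED, UNAFFECTED)) & (cohort.genotypes[ch, j] != MISSING)
    if sex == "male":
        keep &= sexes == MALE
    elif sex == "female":
        keep &= sexes == FEMALE
    rows = ch[keep]
    y = (status[keep] == AFFECTED).astype(float)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError(
            f"stratum {sex!r} lacks {'unaffected' if y.sum() else 'affected'} siblings"
        )
    x = code_genotypes(cohort.genotypes[rows, j], model, risk_is_a1)
    cols = [np.ones_like(x), x]
    names = ["intercept", "genotype"]
    if sex == "both":
        cols.append((sexes[keep] == FEMALE).astype(float))
        names.append("sex")
    X = np.column_stack(cols)
    fam = ind["fid"].to_numpy()[rows]
    return gee_logistic(y, X, fam, names)


def run_sibling_tests(
    cohort: FamilyCohort, family_results: pd.DataFrame, p_family_max: float = 1e-3
) -> pd.DataFrame:
    """Sibling case-control fits for every family-test row below threshold.

    The family test fixes the risk allele: the overtransmitted allele in
    affected strata, the *under*transmitted allele when the target is
    unaffected siblings (overtransmission to unaffected children marks the
    protective allele).  When the risk allele is A2 the coding model swaps
    dominant/recessive so the coded groups are preserved.
    """
    from .models import complementary_model

    rows = []
    hits = family_results[
        (family_results["p"] < p_family_max) & (family_results["direction"] != 0)
    ]
    for _, r in hits.iterrows():
        target, sex = r["stratum"].rsplit("_", 1)
        risk_is_a1 = (r["direction"] > 0) == (target == "affected")
        model = r["model"] if risk_is_a1 else complementary_model(r["model"])
        try:
            fit = sibling_case_control(cohort, r["snp"], model, sex, risk_is_a1)
        except ValueError:
            continue
        rows.append(
            {
                "snp": r["snp"],
                "model": r["model"],
                "stratum": r["stratum"],
                "risk_allele": "a1" if risk_is_a1 else "a2",
                "coded_model": model,
                "or": np.nan if fit.non_estimable else fit.odds_ratio,
                "p": np.nan if fit.non_estimable else fit.term_p("genotype"),
                "n_clusters": fit.n_clusters,
                "n_observations": fit.n_observations,
                "non_estimable": fit.non_estimable,
            }
        )
    cols = [
        "snp", "model", "stratum", "risk_allele", "coded_model",
        "or", "p", "n_clusters", "n_observations", "non_estimable",
    ]
    return pd.DataFrame(rows, columns=cols)


def select_candidates(
    family_results: pd.DataFrame,
    sibling_results: pd.DataFrame,
    p_family_max: float = 1e-3,
    p_sibling_max: float = 0.05,
) -> pd.DataFrame:
    """SNPs passing both funnels with concordant risk-allele direction.

    A SNP qualifies through a (model, stratum) combination when the family
    test gives p < ``p_family_max`` and the matching sibling case-control
    fit gives p < ``p_sibling_max`` with OR > 1 for the designated risk
    allele.  All qualifying combinations are returned; ``is_best`` marks the
    smallest family p per SNP.
    """
    fam = family_results[family_results["p"] < p_family_max]
    merged = fam.merge(
        sibling_results,
        on=["snp", "model", "stratum"],
        suffixes=("_family", "_sibling"),
    )
    ok = (
        (merged["p_sibling"] < p_sibling_max)
        & (merged["or"] > 1.0)
        & (~merged["non_estimable"].astype(bool))
    )
    out = merged.loc[
        ok,
        [
            "snp", "model", "stratum", "risk_allele", "coded_model",
            "p_family", "p_sibling", "or", "direction",
        ],
    ].reset_index(drop=True)
    out["is_best"] = False
    if len(out):
        out.loc[out.groupby("snp")["p_family"].idxmin(), "is_best"] = True
    return out
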