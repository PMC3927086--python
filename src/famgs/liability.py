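"""Liability-threshold machinery.

Disease is modelled as a standard-normal latent liability exceeding a
threshold t = Phi^-1(1-K) set by the prevalence K.  This module collects the
standard quantities derived from (K, K_R) — threshold, mean liability of
cases i = z/K and of controls i_ctrl = -iK/(1-K) — plus three conversions:

* Falconer heritability from sibling recurrence, h2 = 2 (t - t_R) / i,
  with an optional Reich-corrected variant;
* the mapping between the case/control AUC of a risk score and the
  proportion v of liability variance the score explains (the AUC-based
  relation of Wray and colleagues), with a monotone bisection inverse;
* exact sibling recurrence under a given sibling liability correlation
  (bivariate-normal orthant probability), used both to calibrate simulations
  and to sanity-check recurrence inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LiabilityParams",
    "auc_from_liability_v",
    "auc_to_liability_v",
    "heritability_from_recurrence",
    "sibling_recurrence",
    "liability_correlation_for_recurrence",
]


@dataclass(frozen=True)
class LiabilityParams:
    """Prevalence / sibling-recurrence pair and its derived thresholds.

    Attributes
    ----------
    K : float
        Population prevalence in (0, 1); sex-specific in practice.
    K_R : float
        Recurrence risk in full siblings of an affected individual.
    """

    K: float
    K_R: float

    def __post_init__(self):
        if not 0 < self.K < 1:
            raise ValueError(f"prevalence K={self.K} outside (0,1)")
        if not 0 < self.K_R < 1:
            raise ValueError(f"recurrence K_R={self.K_R} outside (0,1)")

    @property
    def t(self) -> float:
        """Liability threshold Phi^-1(1-K)."""
        return float(stats.norm.isf(self.K))

    @property
    def z(self) -> float:
        """Normal density at the threshold."""
        return float(stats.norm.pdf(self.t))

    @property
    def i(self) -> float:
        """Mean liability of cases (selection intensity) z/K."""
        return self.z / self.K

    @property
    def i_ctrl(self) -> float:
        """Mean liability of controls, -i K / (1-K)."""
        return -self.i * self.K / (1.0 - self.K)

    @property
    def t_R(self) -> float:
        """Threshold implied by the sibling recurrence risk."""
        return float(stats.norm.isf(self.K_R))


def auc_from_liability_v(v: float, params: LiabilityParams) -> float:
    """Expected case/control AUC of a score explaining liability variance v.

    The score is taken to be a normally distributed component of liability
    with variance v; conditioning on affection status shifts and shrinks it,
    giving

        AUC = Phi( v (i - i_ctrl) / sqrt( v(1 - v i (i - t))
                                          + v(1 - v i_ctrl (i_ctrl - t)) ) ).
    """
    if v < 0 or v >= 1:
        raise ValueError(f"v={v} outside [0,1)")
    if v == 0:
        return 0.5
    t, i, i2 = params.t, params.i, params.i_ctrl
    num = v * (i - i2)
    den = np.sqrt(v * (1 - v * i * (i - t)) + v * (1 - v * i2 * (i2 - t)))
    return float(stats.norm.cdf(num / den))


def auc_to_liability_v(auc: float, params: LiabilityParams, tol: float = 1e-8) -> float:
    """Invert :func:`auc_from_liability_v` by bisection on v in [0, 1).

    The forward map is strictly increasing in v, so bisection is exact to
    ``tol``.  AUC below 0.5 is rejected (orient the score first); AUC of 1
    corresponds to the v -> 1 boundary and is rejected with a diagnostic.
    """
    if auc < 0.5:
        raise ValueError(f"AUC={auc} < 0.5: orient the score before inverting")
    if auc >= 1.0:
        raise ValueError("AUC=1 implies v -> 1 (complete separation); not invertible")
    if auc == 0.5:
        return 0.0
    lo, hi = 0.0, 1.0 - 1e-12
    if auc_from_liability_v(hi, params) < auc:
        raise ValueError(f"AUC={auc} not attainable for these parameters")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if auc_from_liability_v(mid, params) < auc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def heritability_from_recurrence(params: LiabilityParams, reich: bool = False) -> float:
    """Liability-scale heritability from sibling recurrence.

    Falconer's estimate for full siblings (relatedness 1/2) is
    ``h2 = 2 (t - t_R) / i``.  With ``reich=True`` the threshold-shift
    correction of Reich and colleagues is applied instead:

        h2 = [t - t_R sqrt(1 - (t^2 - t_R^2)(1 - t/i))]
             / [a_R (i + t_R^2 (i - t))],     a_R = 1/2.

    Values above 1 (common for strongly familial, low-prevalence disorders)
    are returned as-is; callers are expected to flag them.  ``K_R < K``
    yields a negative estimate, likewise returned for the caller to flag.
    """
    t, t_r, i = params.t, params.t_R, params.i
    if reich:
        inner = 1.0 - (t * t - t_r * t_r) * (1.0 - t / i)
        if inner < 0:
            raise ValueError("Reich correction undefined for these parameters")
        return float((t - t_r * np.sqrt(inner)) / (0.5 * (i + t_r * t_r * (i - t))))
    return float(2.0 * (t - t_r) / i)


def sibling_recurrence(K: float, rho: float) -> float:
    """P(sib affected | proband affected) under liability correlation rho.

    Exact bivariate-normal orthant probability
    P(L1 > t, L2 > t) / K with both liabilities standard normal.
    """
    t = stats.norm.isf(K)
    if rho == 0:
        return K
    both = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    ).cdf([-t, -t])  # symmetry: P(X>t, Y>t) = P(X<-t, Y<-t)
    return float(both / K)


def liability_correlation_for_recurrence(K: float, K_R: float) -> float:
    """Sibling liability correlation that reproduces recurrence K_R at
    prevalence K (root of :func:`sibling_recurrence`)."""
    if not K < K_R:
        raise ValueError("expected K < K_R for a familial disorder")
    return float(
        optimize.brentq(
            lambda r: sibling_recurrence(K, r) - K_R, 1e-6, 1 - 1e-6, xtol=1e-10
        )
    )
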