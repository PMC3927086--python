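"""Family-bootstrap machinery: empirical CIs, selection-inflation audit,
and the genetic-model reproducibility index.

The resampling unit is always the family: each replicate draws families
with replacement up to the original family count.  Percentile 95% CIs use
the adjacent-rank convention (lower = ceil(0.025 B)-th, upper =
ceil(0.975 B)-th order statistic, 1-indexed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import FamilyCohort, resample_families
from .score import select_best_model

__all__ = [
    "BootstrapResult",
    "InflationSummary",
    "ReproducibilityIndex",
    "bootstrap_statistic",
    "inflation_check",
    "reproducibility_index",
]


@dataclass
class BootstrapResult:
    B: int
    observed: float
    replicates: np.ndarray = field(repr=False)
    ci_low: float = 0.0
    ci_high: float = 0.0
    mean: float = 0.0
    inflation: float = 0.0
    n_redrawn: int = 0
    seed: int | None = None


@dataclass
class InflationSummary:
    observed: float
    bootstrap_mean: float
    inflation: float
    relative_inflation: float


def percentile_ci(replicates: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Adjacent-rank percentile interval from a replicate vector."""
    rep = np.sort(np.asarray(replicates, dtype=float))
    B = len(rep)
    alpha = (1.0 - level) / 2.0
    # small epsilon guards against float fuzz in alpha*B at exact ranks
    lo = max(1, math.ceil(alpha * B - 1e-9))
    hi = min(B, math.ceil((1.0 - alpha) * B - 1e-9))
    return float(rep[lo - 1]), float(rep[hi - 1])


def bootstrap_statistic(
    cohort: FamilyCohort,
    statistic,
    B: int = 1000,
    seed: int = 0,
    max_redraw_frac: float = 0.2,
) -> BootstrapResult:
    """Family bootstrap of an arbitrary cohort statistic.

    ``statistic(cohort) -> float``; replicates where it raises or returns a
    non-finite value are redrawn (counted), aborting if more than
    ``max_redraw_frac * B`` redraws are needed.  Fully reproducible given
    ``seed``.
    """
    if cohort.n_families < 2:
        raise ValueError("need at least 2 families to bootstrap")
    observed = float(statistic(cohort))
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    n_redrawn = 0
    max_redraw = int(max_redraw_frac * B)
    i = 0
    while i < B:
        res = resample_families(cohort, rng)
        try:
            val = float(statistic(res))
        except (ValueError, RuntimeError):
            val = np.nan
        if not np.isfinite(val):
            n_redrawn += 1
            if n_redrawn > max_redraw:
                raise RuntimeError(
                    f"bootstrap aborted: {n_redrawn} non-estimable replicates "
                    f"(> {max_redraw_frac:.0%} of B={B})"
                )
            continue
        reps[i] = val
        i += 1
    lo, hi = percentile_ci(reps)
    mean = float(reps.mean())
    return BootstrapResult(
        B=B, observed=observed, replicates=reps, ci_low=lo, ci_high=hi,
        mean=mean, inflation=mean - observed, n_redrawn=n_redrawn, seed=seed,
    )


def inflation_check(observed: float, result: BootstrapResult) -> InflationSummary:
    """Compare the bootstrap mean of a statistic (typically the GRR) with
    its observed value; positive inflation flags optimistic selection."""
    mean = float(np.mean(result.replicates))
    diff = mean - observed
    rel = diff / observed if observed != 0 else np.nan
    return InflationSummary(observed, mean, diff, rel)


@dataclass
class ReproducibilityIndex:
    snp: str
    ri_cohort1: float
    ri_cohort2: float
    model_cohort1: str
    model_cohort2: str
    highly_reproducible: bool


def reproducibility_index(
    cohorts: tuple[FamilyCohort, FamilyCohort],
    snp_entries,
    sex: str = "both",
    B: int = 1000,
    seed: int = 0,
    direction_filter: bool = True,
    ri_threshold: float = 0.80,
) -> list[ReproducibilityIndex]:
    """Bootstrap reproducibility of each SNP's selected genetic model.

    Per cohort: select each SNP's model on the original sample, then on B
    family-bootstrap replicates; the RI is the fraction of replicates
    re-selecting the original model (replicates where the SNP is dropped or
    non-informative count as non-reproducing).  A SNP is flagged highly
    reproducible when RI exceeds ``ri_threshold`` in both cohorts.
    """
    snp_entries = list(snp_entries)
    rng = np.random.default_rng(seed)
    per_cohort = []
    for cohort in cohorts:
        original = {
            e.snp: e.model
            for e in select_best_model(cohort, snp_entries, sex, direction_filter).entries
        }
        counts = {snp: 0 for snp, _ in snp_entries}
        for _ in range(B):
            res = resample_families(cohort, rng)
            try:
                model = select_best_model(res, snp_entries, sex, direction_filter)
            except ValueError:
                continue
            picked = {e.snp: e.model for e in model.entries}
            for snp, _ in snp_entries:
                if snp in original and picked.get(snp) == original[snp]:
                    counts[snp] += 1
        per_cohort.append((original, {s: c / B for s, c in counts.items()}))

    out = []
    (orig1, ri1), (orig2, ri2) = per_cohort
    for snp, _ in snp_entries:
        r1, r2 = ri1[snp], ri2[snp]
        out.append(
            ReproducibilityIndex(
                snp=snp,
                ri_cohort1=r1,
                ri_cohort2=r2,
                model_cohort1=orig1.get(snp, "dropped"),
                model_cohort2=orig2.get(snp, "dropped"),
                highly_reproducible=(r1 > ri_threshold and r2 > ri_threshold),
            )
        )
    return out
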