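"""Genetic-model codings shared by the transmission and regression tests."""

from __future__ import annotations

import numpy as np

ADDITIVE = "additive"
DOMINANT = "dominant"
RECESSIVE = "recessive"

#: evaluation order doubles as the tie-break order for model selection
MODELS = (ADDITIVE, DOMINANT, RECESSIVE)

#: risk-allele copies {0,1,2} -> model score
CODINGS = {
    ADDITIVE: np.array([0.0, 1.0, 2.0]),
    DOMINANT: np.array([0.0, 1.0, 1.0]),
    RECESSIVE: np.array([0.0, 0.0, 1.0]),
}


def code_genotypes(dosage: np.ndarray, model: str, risk_is_a1: bool = True) -> np.ndarray:
    """Apply a model coding to A1-allele counts.

    ``dosage`` counts copies of A1 (missing < 0 propagates as NaN); when the
    risk allele is A2 the count is complemented before coding.
    """
    d = np.asarray(dosage, dtype=float)
    miss = d < 0
    d = np.where(miss, 0, d)
    if not risk_is_a1:
        d = 2 - d
    out = CODINGS[model][d.astype(int)]
    return np.where(miss, np.nan, out)


def complementary_model(model: str) -> str:
    """Model label seen from the other allele's perspective.

    Coding allele a2 dominantly groups the same genotypes as coding a1
    recessively (complemented), so dominant and recessive swap; additive is
    self-complementary.
    """
    return {ADDITIVE: ADDITIVE, DOMINANT: RECESSIVE, RECESSIVE: DOMINANT}[model]
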