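"""Shared builders for small hand-constructed cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from famgs.cohort import FamilyCohort

SNP1 = pd.DataFrame(
    {"snp": ["s1"], "chrom": ["1"], "pos": [100_000], "a1": ["A"], "a2": ["C"]}
)


def make_cohort(members, genotypes, snps=None) -> FamilyCohort:
    """members: (fid, iid, father, mother, sex, status) tuples;
    genotypes: one row of A1 dosages per member."""
    ind = pd.DataFrame(
        members, columns=["fid", "iid", "father", "mother", "sex", "status"]
    )
    g = np.asarray(genotypes, dtype=np.int8)
    if snps is None:
        m = g.shape[1]
        snps = pd.DataFrame(
            {
                "snp": [f"s{j + 1}" for j in range(m)],
                "chrom": ["1"] * m,
                "pos": [100_000 * (j + 1) for j in range(m)],
                "a1": ["A"] * m,
                "a2": ["C"] * m,
            }
        )
    return FamilyCohort(ind, g, snps)


def stack_trios(trios) -> FamilyCohort:
    """trios: list of (gf, gm, gc[, status[, sex]]) single-SNP trios."""
    members, geno = [], []
    for k, t in enumerate(trios):
        gf, gm, gc = t[:3]
        status = t[3] if len(t) > 3 else 2
        sex = t[4] if len(t) > 4 else 1
        fid = f"T{k}"
        members += [
            (fid, f"{fid}f", "0", "0", 1, 0),
            (fid, f"{fid}m", "0", "0", 2, 0),
            (fid, f"{fid}c", f"{fid}f", f"{fid}m", sex, status),
        ]
        geno += [[gf], [gm], [gc]]
    return make_cohort(members, geno, SNP1.copy())


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
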