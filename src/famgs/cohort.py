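"""Pedigree + genotype container shared by every analysis stage.

A :class:`FamilyCohort` holds nuclear-family pedigree records (family id,
individual id, parental ids, sex, affection status), a dense genotype matrix
counted as copies of the A1 allele, and the SNP map.  Genotypes are ``int8``
with ``-1`` for missing; sex and status follow the PLINK 1/2 conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

MALE = 1
FEMALE = 2

UNKNOWN = 0
UNAFFECTED = 1
AFFECTED = 2

#: individual-table columns, in canonical order
IND_COLUMNS = ["fid", "iid", "father", "mother", "sex", "status"]
#: SNP-map columns
SNP_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]


@dataclass
class FamilyCohort:
    """Nuclear-family cohort with diallelic genotypes.

    Parameters
    ----------
    individuals :
        One row per person with columns ``fid, iid, father, mother, sex,
        status``.  Parental ids of founders are ``"0"``.
    genotypes :
        ``(n_individuals, n_snps)`` array of A1-allele counts in ``{0,1,2}``,
        ``-1`` for missing.
    snps :
        One row per SNP with columns ``snp, chrom, pos, a1, a2``.
    """

    individuals: pd.DataFrame
    genotypes: np.ndarray
    snps: pd.DataFrame
    _ped_index: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.individuals = self.individuals.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        iids = self.individuals["iid"]
        if iids.duplicated().any():
            dup = iids[iids.duplicated()].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")
        # every non-founder parent id must resolve within the same family
        known = set(iids)
        for col in ("father", "mother"):
            parents = self.individuals[col]
            bad = parents[(parents != "0") & ~parents.isin(known)]
            if len(bad):
                raise ValueError(f"unresolved {col} id {bad.iloc[0]!r}")

    # ------------------------------------------------------------------ sizes
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_families(self) -> int:
        return self.individuals["fid"].nunique()

    # --------------------------------------------------------------- pedigree
    def _index(self):
        """(child_rows, father_rows, mother_rows) for children with both
        parents present in the cohort; cached."""
        if self._ped_index is None:
            pos = pd.Series(
                np.arange(self.n_individuals), index=self.individuals["iid"]
            )
            ind = self.individuals
            is_child = (ind["father"] != "0") & (ind["mother"] != "0")
            child_rows = np.flatnonzero(is_child.to_numpy())
            father_rows = pos[ind.loc[is_child, "father"]].to_numpy()
            mother_rows = pos[ind.loc[is_child, "mother"]].to_numpy()
            object.__setattr__(
                self, "_ped_index", (child_rows, father_rows, mother_rows)
            )
        return self._ped_index

    @property
    def child_rows(self) -> np.ndarray:
        return self._index()[0]

    @property
    def father_rows(self) -> np.ndarray:
        return self._index()[1]

    @property
    def mother_rows(self) -> np.ndarray:
        return self._index()[2]

    @property
    def founder_rows(self) -> np.ndarray:
        ind = self.individuals
        mask = (ind["father"] == "0") & (ind["mother"] == "0")
        return np.flatnonzero(mask.to_numpy())

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero((self.snps["snp"] == snp_id).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"SNP {snp_id!r} not in cohort")
        return int(hits[0])

    # ------------------------------------------------------------- subsetting
    def subset_snps(self, keep: np.ndarray) -> "FamilyCohort":
        """New cohort restricted to the SNP rows in ``keep`` (bool or index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return FamilyCohort(
            self.individuals.copy(),
            self.genotypes[:, keep].copy(),
            self.snps.iloc[keep].copy(),
        )

    def subset_families(self, fids) -> "FamilyCohort":
        mask = self.individuals["fid"].isin(set(fids)).to_numpy()
        return FamilyCohort(
            self.individuals.loc[mask].copy(),
            self.genotypes[mask].copy(),
            self.snps.copy(),
        )

    def copy(self) -> "FamilyCohort":
        return FamilyCohort(
            self.individuals.copy(), self.genotypes.copy(), self.snps.copy()
        )


def resample_families(cohort: FamilyCohort, rng: np.random.Generator) -> FamilyCohort:
    """Draw families with replacement to the original family count.

    The resampling unit is the family: every member of a drawn family is
    carried along, and repeated draws of the same family are relabelled
    (``fid.b<k>``, ids suffixed likewise) so clusters stay distinct.
    """
    ind = cohort.individuals
    fid_arr = ind["fid"].to_numpy()
    fids, inv = np.unique(fid_arr, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    counts = np.bincount(inv, minlength=len(fids))
    starts = np.concatenate([[0], np.cumsum(counts)])

    draws = rng.integers(0, len(fids), size=len(fids))
    rows = np.concatenate([order[starts[d] : starts[d + 1]] for d in draws])
    sizes = counts[draws]
    suffix = np.repeat(np.array([f".b{k}" for k in range(len(draws))]), sizes)

    base = {c: ind[c].to_numpy()[rows] for c in ind.columns}
    new = {
        "fid": np.char.add(base["fid"].astype(str), suffix),
        "iid": np.char.add(base["iid"].astype(str), suffix),
        "father": np.where(
            base["father"] == "0", "0", np.char.add(base["father"].astype(str), suffix)
        ),
        "mother": np.where(
            base["mother"] == "0", "0", np.char.add(base["mother"].astype(str), suffix)
        ),
        "sex": base["sex"],
        "status": base["status"],
    }
    new_ind = pd.DataFrame(new)
    return FamilyCohort(new_ind, cohort.genotypes[rows], cohort.snps)
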