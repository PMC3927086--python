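"""SNP-gene mapping and convergent functional-genomics scoring.

A SNP is related to the nearest gene within +/- 5 kb or, failing that, to
the closest upstream and downstream genes within 50 kb.  Each SNP-gene pair
is then scored on four capped evidence categories:

====================  ===  =========================================================
Statistical            2   GWAS p < 1e-8 (1) vs in [1e-8, 1e-5) (0.5);
                           sibling case-control OR >= 1.5 (1)
Genomic                2   SNP within the gene +/- 5 kb (1); SNP is an eQTL (1)
Previous reporting     1   prior autism association (1) vs related disorder (0.5)
Physiological          4   differential expression in brain (1) vs lymphoblastoid
                           lines (0.5); CNS-specific role (1); mouse CNS model (1);
                           member of an autism-implicated pathway (1)
====================  ===  =========================================================

The maximum total is 9; pairs scoring >= 4 are selected.  Score bands are
half-open with the stricter side winning: p exactly 1e-8 earns 0.5 and
exactly 1e-5 earns 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneMappingRules",
    "EvidenceProfile",
    "ScoreCard",
    "map_snp_to_genes",
    "score_pair",
    "prioritize",
]


@dataclass(frozen=True)
class GeneMappingRules:
    proximal_bp: int = 5_000
    extended_bp: int = 50_000

    def __post_init__(self):
        if not self.proximal_bp < self.extended_bp:
            raise ValueError("proximal window must be smaller than extended")


@dataclass(frozen=True)
class EvidenceProfile:
    """Evidence flags for one SNP-gene pair (inputs to :func:`score_pair`)."""

    gwas_p: float
    sibling_or: float
    within_gene: bool = False
    is_eqtl: bool = False
    prior_report: str = "none"  # none | related_disorder | autism
    expression_diff: str = "none"  # none | lymphoblastoid | brain
    cns_specific: bool = False
    mouse_cns_model: bool = False
    pathway_member: bool = False

    def __post_init__(self):
        if not 0 < self.gwas_p <= 1:
            raise ValueError(f"gwas_p={self.gwas_p} outside (0,1]")
        if self.sibling_or <= 0:
            raise ValueError("sibling_or must be positive")
        if self.prior_report not in ("none", "related_disorder", "autism"):
            raise ValueError(f"bad prior_report {self.prior_report!r}")
        if self.expression_diff not in ("none", "lymphoblastoid", "brain"):
            raise ValueError(f"bad expression_diff {self.expression_diff!r}")


@dataclass
class ScoreCard:
    snp: str
    gene: str
    statistical: float
    genomic: float
    previous: float
    physiological: float
    total: float
    selected: bool


def map_snp_to_genes(
    pos: int,
    chrom: str,
    annotation: pd.DataFrame,
    rules: GeneMappingRules = GeneMappingRules(),
) -> list[tuple[str, int]]:
    """Genes related to a SNP position, as (gene symbol, distance) pairs.

    Distance is 0 inside a gene span, else base pairs to the nearer edge.
    If any gene lies within the proximal window the single nearest such gene
    is returned (all of them on an exact tie); otherwise the closest
    upstream and closest downstream genes within the extended window (0, 1
    or 2 pairs).  No gene on the chromosome yields an empty list.
    """
    ann = annotation[annotation["chrom"].astype(str) == str(chrom)]
    if ann.empty:
        return []
    start = ann["start"].to_numpy()
    end = ann["end"].to_numpy()
    genes = ann["gene"].to_numpy()
    dist = np.where(
        (pos >= start) & (pos <= end),
        0,
        np.minimum(np.abs(pos - start), np.abs(pos - end)),
    )
    near = dist <= rules.proximal_bp
    if near.any():
        best = dist[near].min()
        tied = near & (dist == best)
        return [(g, int(d)) for g, d in zip(genes[tied], dist[tied])]
    out = []
    upstream = end < pos  # gene entirely before the SNP
    downstream = start > pos
    for side in (upstream, downstream):
        if side.any():
            k = np.flatnonzero(side)[dist[side].argmin()]
            if dist[k] <= rules.extended_bp:
                out.append((genes[k], int(dist[k])))
    return out


def score_pair(evidence: EvidenceProfile, snp: str = "", gene: str = "",
               cutoff: float = 4.0) -> ScoreCard:
    """Allocate points to a SNP-gene pair under the category caps above."""
    e = evidence
    statistical = 0.0
    if e.gwas_p < 1e-8:
        statistical += 1.0
    elif e.gwas_p < 1e-5:
        statistical += 0.5
    if e.sibling_or >= 1.5:
        statistical += 1.0

    genomic = (1.0 if e.within_gene else 0.0) + (1.0 if e.is_eqtl else 0.0)
    previous = {"none": 0.0, "related_disorder": 0.5, "autism": 1.0}[e.prior_report]
    physiological = {"none": 0.0, "lymphoblastoid": 0.5, "brain": 1.0}[e.expression_diff]
    physiological += sum(
        1.0 for f in (e.cns_specific, e.mouse_cns_model, e.pathway_member) if f
    )
    total = statistical + genomic + previous + physiological
    return ScoreCard(
        snp, gene, statistical, genomic, previous, physiological, total,
        total >= cutoff,
    )


def prioritize(
    candidates: pd.DataFrame,
    evidence: pd.DataFrame,
    annotation: pd.DataFrame,
    snp_map: pd.DataFrame,
    cutoff: float = 4.0,
    rules: GeneMappingRules = GeneMappingRules(),
) -> pd.DataFrame:
    """Score every candidate SNP's gene pairs; select SNPs with any pair
    scoring >= ``cutoff``.

    ``candidates`` comes from candidate selection (``is_best`` rows supply
    the winning family p and sibling OR); ``snp_map`` provides positions.
    Candidates absent from the evidence table are scored with all
    functional flags unfavourable.  Returns one row per SNP-gene pair with
    category subtotals, total, per-pair selection, and ``snp_selected``
    (best pair per SNP decides).
    """
    ev_idx = evidence.set_index(["snp", "gene"]) if len(evidence) else None
    pos_of = snp_map.set_index("snp")[["chrom", "pos"]]

    best = candidates[candidates["is_best"]] if "is_best" in candidates else candidates
    rows = []
    for _, cand in best.iterrows():
        snp = cand["snp"]
        chrom, pos = pos_of.loc[snp, "chrom"], int(pos_of.loc[snp, "pos"])
        pairs = map_snp_to_genes(pos, chrom, annotation, rules)
        for gene, dist in pairs:
            kwargs = dict(
                gwas_p=float(cand["p_family"]),
                sibling_or=float(cand["or"]),
                within_gene=dist <= rules.proximal_bp,
            )
            if ev_idx is not None and (snp, gene) in ev_idx.index:
                r = ev_idx.loc[(snp, gene)]
                kwargs.update(
                    is_eqtl=bool(r["is_eqtl"]),
                    prior_report=str(r["prior_report"]),
                    expression_diff=str(r["expression_diff"]),
                    cns_specific=bool(r["cns_specific"]),
                    mouse_cns_model=bool(r["mouse_cns_model"]),
                    pathway_member=bool(r["pathway_member"]),
                )
            card = score_pair(EvidenceProfile(**kwargs), snp, gene, cutoff)
            rows.append(card.__dict__)
    df = pd.DataFrame(
        rows,
        columns=[
            "snp", "gene", "statistical", "genomic", "previous",
            "physiological", "total", "selected",
        ],
    )
    if len(df):
        best_total = df.groupby("snp")["total"].transform("max")
        df["snp_selected"] = best_total >= cutoff
        df["is_best_pair"] = df["total"] == best_total
    else:
        df["snp_selected"] = pd.Series(dtype=bool)
        df["is_best_pair"] = pd.Series(dtype=bool)
    return df
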