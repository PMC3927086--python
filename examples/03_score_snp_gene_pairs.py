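"""Score SNP-gene pairs on the four evidence categories.

Points: statistical (GWAS p band + sibling OR, max 2), genomic (location +
eQTL, max 2), previous reporting (autism vs related disorder, max 1) and
physiological (expression, CNS role, mouse model, pathway, max 4).  The
maximum is 9; pairs scoring >= 4 are selected.
"""

from famgs import EvidenceProfile, score_pair

profiles = {
    "maximal evidence": EvidenceProfile(
        gwas_p=1e-9, sibling_or=1.6, within_gene=True, is_eqtl=True,
        prior_report="autism", expression_diff="brain", cns_specific=True,
        mouse_cns_model=True, pathway_member=True,
    ),
    "moderate evidence": EvidenceProfile(
        gwas_p=1e-6, sibling_or=1.6, within_gene=True,
        prior_report="related_disorder", expression_diff="brain", is_eqtl=True,
    ),
    "statistics only": EvidenceProfile(
        gwas_p=1e-9, sibling_or=2.0, within_gene=True,
    ),
    "no evidence": EvidenceProfile(gwas_p=0.01, sibling_or=1.1),
}

for name, prof in profiles.items():
    card = score_pair(prof, snp="rs0", gene="GENE")
    print(f"{name:20s} stat={card.statistical:3.1f} genomic={card.genomic:3.1f} "
          f"prior={card.previous:3.1f} physio={card.physiological:3.1f} "
          f"total={card.total:3.1f} selected={card.selected}")
# "statistics only" illustrates the design intent: even a genome-wide
# significant SNP is discarded when its gene carries no functional support.
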