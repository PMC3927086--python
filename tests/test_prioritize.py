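"""Gene mapping windows and the evidence-scoring algorithm."""

import itertools

import pandas as pd
import pytest

from famgs.prioritize import (
    EvidenceProfile,
    GeneMappingRules,
    map_snp_to_genes,
    prioritize,
    score_pair,
)

ANN = pd.DataFrame(
    {
        "gene": ["NEAR", "UP30", "DOWN20", "FAR"],
        "chrom": ["1", "1", "1", "1"],
        "start": [103_000, 50_000, 120_000, 300_000],
        "end": [110_000, 70_000, 130_000, 310_000],
    }
)


class TestMapping:
    def test_gene_within_proximal_window_wins_alone(self):
        pairs = map_snp_to_genes(100_000, "1", ANN)
        assert pairs == [("NEAR", 3_000)]

    def test_flanking_fallback_within_extended_window(self):
        ann = ANN[ANN["gene"] != "NEAR"]
        pairs = dict(map_snp_to_genes(100_000, "1", ann))
        assert pairs == {"UP30": 30_000, "DOWN20": 20_000}

    def test_everything_beyond_extended_window_drops_snp(self):
        ann = ANN[ANN["gene"] == "FAR"]
        assert map_snp_to_genes(100_000, "1", ann) == []

    def test_inside_span_is_distance_zero(self):
        assert map_snp_to_genes(105_000, "1", ANN)[0] == ("NEAR", 0)

    def test_chromosome_mismatch_gives_empty(self):
        assert map_snp_to_genes(100_000, "2", ANN) == []

    def test_windows_must_be_ordered(self):
        with pytest.raises(ValueError):
            GeneMappingRules(50_000, 5_000)


def maximal_profile():
    return EvidenceProfile(
        gwas_p=1e-9, sibling_or=1.5, within_gene=True, is_eqtl=True,
        prior_report="autism", expression_diff="brain", cns_specific=True,
        mouse_cns_model=True, pathway_member=True,
    )


class TestScorePair:
    def test_maximal_profile_scores_nine(self):
        card = score_pair(maximal_profile())
        assert card.total == 9.0
        assert (card.statistical, card.genomic, card.previous, card.physiological) == (
            2.0, 2.0, 1.0, 4.0,
        )
        assert card.selected

    def test_empty_profile_scores_zero(self):
        card = score_pair(EvidenceProfile(gwas_p=0.01, sibling_or=1.0))
        assert card.total == 0.0 and not card.selected

    def test_hand_summed_intermediate_profiles(self):
        lymph = EvidenceProfile(
            gwas_p=1e-6, sibling_or=1.6, within_gene=True,
            prior_report="related_disorder", expression_diff="lymphoblastoid",
        )
        assert score_pair(lymph).total == 3.5
        brain_eqtl = EvidenceProfile(
            gwas_p=1e-6, sibling_or=1.6, within_gene=True, is_eqtl=True,
            prior_report="related_disorder", expression_diff="brain",
        )
        card = score_pair(brain_eqtl)
        assert card.total == 5.0 and card.selected

    def test_p_value_band_boundaries_take_stricter_side(self):
        base = dict(sibling_or=1.0)
        assert score_pair(EvidenceProfile(gwas_p=1e-8, **base)).statistical == 0.5
        assert score_pair(EvidenceProfile(gwas_p=1e-5, **base)).statistical == 0.0
        assert score_pair(EvidenceProfile(gwas_p=9.99e-9, **base)).statistical == 1.0

    def test_or_threshold_is_closed(self):
        assert score_pair(EvidenceProfile(gwas_p=0.5, sibling_or=1.5)).statistical == 1.0
        assert score_pair(EvidenceProfile(gwas_p=0.5, sibling_or=1.49)).statistical == 0.0

    def test_cutoff_is_a_closed_bound(self):
        card = score_pair(
            EvidenceProfile(gwas_p=1e-6, sibling_or=1.6, within_gene=True,
                            is_eqtl=True, prior_report="related_disorder")
        )
        assert card.total == 4.0 and card.selected


P_LEVELS = [1e-4, 1e-6, 1e-9]
OR_LEVELS = [1.0, 1.6]
PRIORS = ["none", "related_disorder", "autism"]
EXPR = ["none", "lymphoblastoid", "brain"]


def all_profiles():
    for p, or_, wg, eq, pr, ex, cns, mouse, path in itertools.product(
        P_LEVELS, OR_LEVELS, [False, True], [False, True], PRIORS, EXPR,
        [False, True], [False, True], [False, True],
    ):
        yield EvidenceProfile(p, or_, wg, eq, pr, ex, cns, mouse, path)


class TestScoreProperties:
    def test_caps_and_half_point_lattice_over_all_profiles(self):
        for prof in all_profiles():
            c = score_pair(prof)
            assert c.statistical <= 2 and c.genomic <= 2
            assert c.previous <= 1 and c.physiological <= 4
            assert 0 <= c.total <= 9
            assert (c.total * 2) == int(c.total * 2)  # half-point steps
            assert c.total == c.statistical + c.genomic + c.previous + c.physiological

    def test_score_is_monotone_in_every_evidence_field(self):
        upgrades = {
            "gwas_p": lambda v: P_LEVELS[min(P_LEVELS.index(v) + 1, 2)],
            "sibling_or": lambda v: 1.6,
            "within_gene": lambda v: True,
            "is_eqtl": lambda v: True,
            "prior_report": lambda v: PRIORS[min(PRIORS.index(v) + 1, 2)],
            "expression_diff": lambda v: EXPR[min(EXPR.index(v) + 1, 2)],
            "cns_specific": lambda v: True,
            "mouse_cns_model": lambda v: True,
            "pathway_member": lambda v: True,
        }
        for prof in all_profiles():
            base = score_pair(prof).total
            for f, up in upgrades.items():
                d = prof.__dict__.copy()
                d[f] = up(d[f])
                assert score_pair(EvidenceProfile(**d)).total >= base

    def test_scoring_is_pure(self):
        p = maximal_profile()
        assert score_pair(p) == score_pair(p)


class TestPrioritize:
    def _inputs(self, totals_by_gene):
        cand = pd.DataFrame(
            [{"snp": "s1", "model": "additive", "stratum": "affected_both",
              "p_family": 1e-4, "or": 1.6, "risk_allele": "a1",
              "coded_model": "additive", "p_sibling": 0.01, "direction": 1,
              "is_best": True}]
        )
        snp_map = pd.DataFrame(
            {"snp": ["s1"], "chrom": ["1"], "pos": [100_000], "a1": ["A"], "a2": ["C"]}
        )
        ann = pd.DataFrame(
            {
                "gene": list(totals_by_gene),
                "chrom": "1",
                "start": [99_000 + 1_000 * i for i in range(len(totals_by_gene))],
                "end": [101_000 + 1_000 * i for i in range(len(totals_by_gene))],
            }
        )
        ev = pd.DataFrame(
            [
                {"snp": "s1", "gene": g, "is_eqtl": f.get("eqtl", False),
                 "prior_report": f.get("prior", "none"),
                 "expression_diff": f.get("expr", "none"),
                 "cns_specific": f.get("cns", False),
                 "mouse_cns_model": f.get("mouse", False),
                 "pathway_member": f.get("path", False)}
                for g, f in totals_by_gene.items()
            ]
        )
        return cand, ev, ann, snp_map

    def test_any_pair_reaching_cutoff_selects_the_snp(self):
        # pair 1: or(1) + within(1) = 2.0 ; pair 2 adds eqtl+cns -> 4.0
        cand, ev, ann, snp_map = self._inputs(
            {"G1": {}, "G2": {"eqtl": True, "cns": True}}
        )
        cards = prioritize(cand, ev, ann, snp_map)
        assert cards["snp_selected"].all()
        assert set(cards.loc[cards["selected"], "gene"]) == {"G2"}

    def test_missing_evidence_rows_score_flags_false(self):
        cand, ev, ann, snp_map = self._inputs({"G1": {}})
        cards = prioritize(cand, ev.iloc[0:0], ann, snp_map)
        # statistical or(1.6>=1.5)=1 + within_gene(1) only
        assert cards.loc[0, "total"] == 2.0
        assert not cards.loc[0, "snp_selected"]
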