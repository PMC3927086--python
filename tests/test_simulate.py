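"""Generator contracts: prevalence, ascertainment, Mendelian consistency,
recurrence calibration, evidence tables."""

import numpy as np
import pandas as pd
import pytest

from famgs.cohort import AFFECTED, MALE
from famgs.liability import liability_correlation_for_recurrence
from famgs.qc import mendel_mask
from famgs.simulate import (
    CausalSNP,
    SimulationParams,
    causal_set_for_variance,
    coded_genotype_moments,
    liability_effect_for_or,
    simulate_annotation,
    simulate_evidence,
    simulate_families,
)


def _children(cohort):
    return cohort.individuals[cohort.individuals["father"] != "0"]


class TestSimulateFamilies:
    def test_null_male_prevalence_matches_threshold(self):
        # no genetics, no sharing: affection is a pure threshold draw
        p = SimulationParams(
            n_families=25_000, children_per_family=2, n_snps=2,
            ascertainment_min_affected=0, male_prevalence=0.0185,
            seed=11,
        )
        kids = _children(simulate_families(p))
        males = kids[kids["sex"] == MALE]
        rate = (males["status"] == AFFECTED).mean()
        se = np.sqrt(0.0185 * (1 - 0.0185) / len(males))
        assert abs(rate - 0.0185) < 3 * se

    def test_ascertainment_bound_enforced(self):
        p = SimulationParams(n_families=50, n_snps=5, shared_sib_var=0.5, seed=3)
        c = simulate_families(p)
        n_aff = _children(c).groupby("fid")["status"].apply(lambda s: (s == AFFECTED).sum())
        assert (n_aff >= 2).all()

    def test_reproducible_under_seed(self):
        p = SimulationParams(n_families=30, n_snps=10, shared_sib_var=0.5, seed=42)
        c1, c2 = simulate_families(p), simulate_families(p)
        assert c1.individuals.equals(c2.individuals)
        assert np.array_equal(c1.genotypes, c2.genotypes)
        assert c1.snps.equals(c2.snps)

    def test_children_mendel_consistent_by_construction(self):
        p = SimulationParams(n_families=60, n_snps=30, shared_sib_var=0.5, seed=5)
        _, log = mendel_mask(simulate_families(p))
        assert len(log) == 0

    def test_pinned_causal_maf_reflected_in_parent_genotypes(self):
        p = SimulationParams(
            n_families=2_000, children_per_family=2, n_snps=3,
            causal=(CausalSNP(0, "additive", 0.1, maf=0.25),),
            ascertainment_min_affected=0, seed=7,
        )
        c = simulate_families(p)
        founders = c.genotypes[c.founder_rows, 0]
        freq = founders.mean() / 2
        se = np.sqrt(0.25 * 0.75 / (2 * len(founders)))
        assert abs(freq - 0.25) < 4 * se

    def test_shared_variance_calibration_hits_target_recurrence(self):
        # sibling correlation solved from (K, K_R); Monte-Carlo check on brothers
        K, K_R = 1 / 54, 0.259
        rho = liability_correlation_for_recurrence(K, K_R)
        p = SimulationParams(
            n_families=120_000, children_per_family=2, n_snps=2,
            shared_sib_var=rho, ascertainment_min_affected=0, seed=13,
        )
        kids = _children(simulate_families(p))
        males = kids[kids["sex"] == MALE]
        grp = males.assign(aff=(males["status"] == AFFECTED).astype(int)).groupby("fid")["aff"]
        size, n_aff = grp.size(), grp.sum()
        n_aff = n_aff[size == 2]  # all-male sibships of two
        # P(brother affected | proband affected), probands counted both ways
        recurrence = (n_aff == 2).sum() * 2 / (
            (n_aff == 1).sum() + 2 * (n_aff == 2).sum()
        )
        assert recurrence == pytest.approx(0.259, abs=0.02)

    def test_ascertained_cohort_inflates_sibling_recurrence(self):
        p = SimulationParams(
            n_families=300, n_snps=2, shared_sib_var=0.5,
            male_prevalence=0.05, female_prevalence=0.05, seed=17,
        )
        kids = _children(simulate_families(p))
        rate = (kids["status"] == AFFECTED).mean()
        assert rate > 0.05  # lambda_s > 1 by a wide margin under ascertainment

    def test_nonconvergent_ascertainment_aborts_with_diagnostic(self):
        p = SimulationParams(
            n_families=5, children_per_family=2, n_snps=1,
            male_prevalence=1e-5, female_prevalence=1e-5,
            ascertainment_min_affected=2, seed=1,
        )
        with pytest.raises(RuntimeError, match="ascertainment"):
            simulate_families(p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(shared_sib_var=1.2)
        with pytest.raises(ValueError):
            SimulationParams(male_prevalence=0.0)
        with pytest.raises(ValueError):
            SimulationParams(n_snps=2, causal=tuple(CausalSNP(i, "additive", 0.1) for i in range(3)))
        with pytest.raises(ValueError):
            simulate_families(
                SimulationParams(n_snps=2, causal=(CausalSNP(0, "additive", 2.0, maf=0.5),))
            )  # causal variance >= 1


class TestEffectHelpers:
    def test_causal_set_variance_bookkeeping(self):
        causal = causal_set_for_variance(4, 0.08, "additive", 0.3)
        total = sum(
            c.beta**2 * coded_genotype_moments(c.maf, c.model)[1] for c in causal
        )
        assert total == pytest.approx(0.08, abs=1e-12)

    def test_or_conversion_is_monotone_and_null_at_one(self):
        assert liability_effect_for_or(1.0, 0.3, 0.05) == 0.0
        b15 = liability_effect_for_or(1.5, 0.3, 0.05)
        b20 = liability_effect_for_or(2.0, 0.3, 0.05)
        assert 0 < b15 < b20
        assert liability_effect_for_or(0.7, 0.3, 0.05) < 0

    def test_or_conversion_round_trips_via_penetrance_simulation(self, rng):
        K, maf, target = 0.05, 0.3, 1.6
        beta = liability_effect_for_or(target, maf, K, "additive")
        mu, var = coded_genotype_moments(maf, "additive")
        n = 600_000
        x = rng.binomial(2, maf, size=n)
        lia = beta * (x - mu) + rng.standard_normal(n) * np.sqrt(1 - beta**2 * var)
        from scipy import stats as st

        t = st.norm.isf(K)
        d = lia > t
        k1 = d[x == 1].mean()
        k0 = d[x == 0].mean()
        or_hat = (k1 / (1 - k1)) / (k0 / (1 - k0))
        assert or_hat == pytest.approx(target, rel=0.06)


class TestEvidence:
    @pytest.fixture
    def cohort(self):
        return simulate_families(
            SimulationParams(n_families=10, n_snps=20, shared_sib_var=0.5, seed=2)
        )

    def test_extremes_give_deterministic_flags(self, cohort):
        causal = set(cohort.snps["snp"].iloc[:4])
        ev = simulate_evidence(cohort, causal, p_true=1.0, p_false=0.0, seed=1)
        is_causal = ev["snp"].isin(causal)
        assert ev.loc[is_causal, "is_eqtl"].all()
        assert (ev.loc[is_causal, "prior_report"] == "autism").all()
        assert (ev.loc[is_causal, "expression_diff"] == "brain").all()
        assert not ev.loc[~is_causal, ["is_eqtl", "cns_specific", "mouse_cns_model", "pathway_member"]].any().any()
        assert (ev.loc[~is_causal, "prior_report"] == "none").all()

    def test_causal_pairs_carry_more_evidence_on_average(self):
        cohort = simulate_families(
            SimulationParams(n_families=10, n_snps=200, shared_sib_var=0.5, seed=4)
        )
        causal = set(cohort.snps["snp"].iloc[:20])
        ev = simulate_evidence(cohort, causal, p_true=0.8, p_false=0.1, seed=9)
        points = (
            ev["is_eqtl"].astype(float)
            + ev["cns_specific"].astype(float)
            + ev["mouse_cns_model"].astype(float)
            + ev["pathway_member"].astype(float)
            + ev["prior_report"].map({"none": 0, "related_disorder": 0.5, "autism": 1.0})
            + ev["expression_diff"].map({"none": 0, "lymphoblastoid": 0.5, "brain": 1.0})
        )
        is_causal = ev["snp"].isin(causal)
        assert points[is_causal].mean() > points[~is_causal].mean() + 1.0

    def test_deterministic_under_seed(self, cohort):
        causal = set(cohort.snps["snp"].iloc[:2])
        e1 = simulate_evidence(cohort, causal, 0.9, 0.1, seed=5)
        e2 = simulate_evidence(cohort, causal, 0.9, 0.1, seed=5)
        assert e1.equals(e2)

    def test_unknown_snp_rejected(self, cohort):
        with pytest.raises(KeyError):
            simulate_evidence(cohort, {"rs_not_there"}, 0.9, 0.1, seed=1)

    def test_annotation_covers_each_snp(self, cohort):
        ann = simulate_annotation(cohort)
        assert len(ann) == cohort.n_snps
        assert (ann["start"] <= cohort.snps["pos"].to_numpy()).all()
        assert (ann["end"] >= cohort.snps["pos"].to_numpy()).all()
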