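"""Cluster-robust logistic fits: closed-form oracles, statsmodels
cross-check, selection funnel logic."""

import numpy as np
import pandas as pd
import pytest

from famgs.gee import (
    GEEFit,
    gee_logistic,
    select_candidates,
    sibling_case_control,
)

from conftest import make_cohort


def _two_by_two(exp_case, unexp_case, exp_ctrl, unexp_ctrl, pair_per_family=True):
    n = exp_case + unexp_case + exp_ctrl + unexp_ctrl
    y = np.r_[np.ones(exp_case + unexp_case), np.zeros(exp_ctrl + unexp_ctrl)]
    x = np.r_[
        np.ones(exp_case), np.zeros(unexp_case), np.ones(exp_ctrl), np.zeros(unexp_ctrl)
    ]
    clusters = np.arange(n) // 2 if pair_per_family else np.arange(n)
    X = np.column_stack([np.ones(n), x])
    return y, X, clusters


class TestGEELogistic:
    def test_or_equals_cross_product_ratio(self):
        y, X, cl = _two_by_two(30, 20, 10, 40)
        fit = gee_logistic(y, X, cl, ["intercept", "genotype"])
        assert fit.odds_ratio == pytest.approx(6.0, abs=1e-6)

    def test_constant_genotype_flagged_non_estimable(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        X = np.column_stack([np.ones(20), np.ones(20)])
        fit = gee_logistic(y, X, np.arange(20) // 2, ["intercept", "genotype"])
        assert fit.non_estimable

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = y.copy()
        X = np.column_stack([np.ones(40), x])
        fit = gee_logistic(y, X, np.arange(40) // 2, ["intercept", "genotype"])
        assert fit.non_estimable

    def test_rank_deficiency_rejected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.tile([0.0, 1.0], 10)
        X = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            gee_logistic(y, X, np.arange(20) // 2)

    def test_single_cluster_rejected(self):
        y = np.r_[1.0, 0.0]
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        with pytest.raises(ValueError, match="clusters"):
            gee_logistic(y, X, np.zeros(2))

    def test_point_estimates_invariant_to_cluster_labels(self, rng):
        n = 200
        x = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(0.5 - 0.4 * x))).astype(float)
        X = np.column_stack([np.ones(n), x])
        cl = np.repeat(np.arange(50), 4)
        perm = rng.permutation(50)
        fit1 = gee_logistic(y, X, cl)
        fit2 = gee_logistic(y, X, perm[cl])
        np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-12)
        np.testing.assert_allclose(fit1.robust_se, fit2.robust_se, atol=1e-12)

    def test_outcome_relabel_flips_genotype_sign(self, rng):
        n = 120
        x = rng.binomial(2, 0.4, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-0.3 * (x - 1)))).astype(float)
        X = np.column_stack([np.ones(n), x])
        cl = np.arange(n) // 3
        f1 = gee_logistic(y, X, cl)
        f2 = gee_logistic(1 - y, X, cl)
        assert f1.params[1] == pytest.approx(-f2.params[1], abs=1e-8)

    def test_singleton_clusters_reduce_to_hc0(self, rng):
        import statsmodels.api as sm

        n = 150
        x = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(0.2 - 0.5 * x))).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = gee_logistic(y, X, np.arange(n), ["intercept", "genotype"])
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        np.testing.assert_allclose(fit.params, glm.params, atol=1e-6)
        np.testing.assert_allclose(fit.robust_se, glm.bse, rtol=1e-5)

    def test_matches_statsmodels_gee_on_clustered_data(self, rng):
        import statsmodels.api as sm

        n_fam, size = 80, 3
        n = n_fam * size
        x = rng.binomial(2, 0.3, n).astype(float)
        shared = np.repeat(rng.normal(0, 0.8, n_fam), size)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.4 * x + shared)))).astype(float)
        cl = np.repeat(np.arange(n_fam), size)
        X = np.column_stack([np.ones(n), x])
        fit = gee_logistic(y, X, cl, ["intercept", "genotype"])
        ref = sm.GEE(
            y, X, groups=cl, family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Independence(),
        ).fit()
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.robust_se, ref.bse, rtol=1e-3)


class TestSiblingCaseControl:
    def _cohort(self, rng, n_fam=60, beta=0.0):
        members, geno = [], []
        for f in range(n_fam):
            fid = f"F{f}"
            members += [
                (fid, f"{fid}f", "0", "0", 1, 0),
                (fid, f"{fid}m", "0", "0", 2, 0),
            ]
            geno += [[rng.binomial(2, 0.4)], [rng.binomial(2, 0.4)]]
            for c, status_bias in ((0, 1), (1, 0)):
                x = rng.binomial(2, 0.4)
                p = 1 / (1 + np.exp(-(beta * x + (2 * status_bias - 1) * 0.2)))
                members.append(
                    (fid, f"{fid}c{c}", f"{fid}f", f"{fid}m",
                     1 + int(rng.random() < 0.5), 2 if rng.random() < p else 1)
                )
                geno.append([x])
        return make_cohort(members, geno)

    def test_sex_covariate_only_when_unstratified(self, rng):
        cohort = self._cohort(rng)
        both = sibling_case_control(cohort, "s1", "additive", "both")
        male = sibling_case_control(cohort, "s1", "additive", "male")
        assert "sex" in both.names
        assert "sex" not in male.names

    def test_perfect_discrimination_flags_separation(self):
        members, geno = [], []
        for f in range(20):
            fid = f"F{f}"
            members += [
                (fid, f"{fid}f", "0", "0", 1, 0),
                (fid, f"{fid}m", "0", "0", 2, 0),
                (fid, f"{fid}a", f"{fid}f", f"{fid}m", 1, 2),
                (fid, f"{fid}u", f"{fid}f", f"{fid}m", 1, 1),
            ]
            geno += [[1], [1], [2], [0]]
        fit = sibling_case_control(make_cohort(members, geno), "s1", "additive", "both")
        assert fit.non_estimable

    def test_missing_stratum_group_rejected(self, rng):
        cohort = self._cohort(rng)
        cohort.individuals.loc[
            cohort.individuals["status"] == 1, "status"
        ] = 2  # no unaffected children left
        with pytest.raises(ValueError, match="unaffected"):
            sibling_case_control(cohort, "s1", "additive", "both")


class TestSelectCandidates:
    def _frames(self, p_family, p_sibling, or_=1.4):
        fam = pd.DataFrame(
            [{"snp": "s1", "model": "additive", "stratum": "affected_both",
              "p": p_family, "direction": 1}]
        )
        sib = pd.DataFrame(
            [{"snp": "s1", "model": "additive", "stratum": "affected_both",
              "risk_allele": "a1", "coded_model": "additive",
              "or": or_, "p": p_sibling, "n_clusters": 100,
              "n_observations": 200, "non_estimable": False}]
        )
        return fam, sib

    def test_passing_both_funnels_selected(self):
        out = select_candidates(*self._frames(5e-4, 0.03))
        assert list(out["snp"]) == ["s1"]
        assert out.loc[0, "is_best"]

    def test_family_threshold_is_strict(self):
        assert len(select_candidates(*self._frames(2e-3, 0.001))) == 0

    def test_sibling_threshold_is_strict(self):
        assert len(select_candidates(*self._frames(1e-4, 0.06))) == 0

    def test_discordant_direction_excluded(self):
        fam, sib = self._frames(1e-4, 0.01, or_=0.8)
        assert len(select_candidates(fam, sib)) == 0
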