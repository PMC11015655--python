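"""The summary-data MR battery: Wald ratios, IVW, Egger, weighted median,
contamination mixture, PRESSO, and multivariable MR."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import menarchemr as m


def make_pair(bx, by, sx=None, sy=None):
    J = len(bx)
    sx = np.full(J, 0.01) if sx is None else np.asarray(sx, dtype=float)
    sy = np.full(J, 0.01) if sy is None else np.asarray(sy, dtype=float)
    base = pd.DataFrame({
        "snp": [f"s{i}" for i in range(J)], "chrom": 1,
        "pos": np.arange(J) * 10 ** 6, "effect_allele": "A",
        "other_allele": "G", "eaf": 0.3})
    exp = base.assign(beta=np.asarray(bx, dtype=float), se=sx, pval=1e-9,
                      n=100_000)
    out = base.assign(beta=np.asarray(by, dtype=float), se=sy, pval=0.5,
                      n=10_000)
    return m.SummaryPair(exp, out, 100_000, 10_000)


def ratios_df(r, se):
    return pd.DataFrame({"snp": [f"s{i}" for i in range(len(r))],
                         "ratio": r, "se": se})


class TestWaldRatios:
    def test_hand_example(self):
        pair = make_pair([0.1], [0.02], sy=[0.01])
        w = m.wald_ratios(pair)
        assert w["ratio"].iloc[0] == pytest.approx(0.2)
        assert w["se"].iloc[0] == pytest.approx(0.1)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        w = m.wald_ratios(make_pair([0.1], [0.0]))
        assert w["ratio"].iloc[0] == 0.0

    def test_zero_exposure_beta_dropped(self):
        w = m.wald_ratios(make_pair([0.1, 0.0], [0.02, 0.05]))
        assert len(w) == 1

    def test_elementwise_oracle(self, rng):
        bx = rng.normal(0.1, 0.02, 20)
        by = rng.normal(0.02, 0.01, 20)
        sy = rng.uniform(0.005, 0.02, 20)
        w = m.wald_ratios(make_pair(bx, by, sy=sy))
        for j in range(20):
            assert w["ratio"].iloc[j] == pytest.approx(by[j] / bx[j])
            assert w["se"].iloc[j] == pytest.approx(sy[j] / abs(bx[j]))


class TestIvw:
    def test_equal_weight_mean(self):
        res = m.ivw(ratios_df([0.5, 0.3], [0.1, 0.1]),
                    random_effects="fixed")
        assert res.estimate.theta_hat == pytest.approx(0.4)
        assert res.estimate.se == pytest.approx(0.1 / math.sqrt(2))

    def test_identical_ratios_zero_q(self):
        res = m.ivw(ratios_df([0.2] * 5, [0.05] * 5))
        assert res.q_stat["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_weighted_mean(self, rng):
        r = rng.normal(0.2, 0.1, 30)
        se = rng.uniform(0.02, 0.2, 30)
        res = m.ivw(ratios_df(r, se))
        w = 1 / se ** 2
        assert res.estimate.theta_hat == pytest.approx(
            float(np.sum(w * r) / np.sum(w)), abs=1e-12)

    def test_q_p_uniform_under_homogeneity(self):
        ps = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            se = rng.uniform(0.05, 0.15, 20)
            r = 0.2 + rng.normal(size=20) * se
            ps.append(m.ivw(ratios_df(r, se)).q_stat["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_ratio_rejected(self):
        with pytest.raises(ValueError, match="Wald"):
            m.ivw(ratios_df([0.1], [0.1]))


class TestEgger:
    def test_exact_fit_recovers_slope_and_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.01 + 0.3 * bx
        res = m.mr_egger(make_pair(bx, by))
        assert res.estimate.theta_hat == pytest.approx(0.3, abs=1e-10)
        assert res.egger_intercept.theta_hat == pytest.approx(0.01,
                                                              abs=1e-10)

    def test_directional_pleiotropy_positive_intercept(self):
        # positive gammas: effect alleles oriented exposure-increasing, so
        # the generator's directional pleiotropy stays directional
        params = m.SimParams(n_snps=100, n_individuals=2000,
                             gamma=np.full(100, 0.05),
                             invalid_fraction=1.0, alpha_pleio=0.02,
                             pleio_mode="directional",
                             n_gwas_outcome=50_000, seed=71)
        pair = m.generate_summary_pair(params)
        res = m.mr_egger(pair)
        assert res.egger_intercept.theta_hat > 0

    def test_slope_equals_ivw_when_intercept_constrained(self, rng):
        """Fitting the Egger design without intercept is exactly IVW."""
        bx = np.abs(rng.normal(0.1, 0.03, 25))
        by = rng.normal(0.02, 0.02, 25)
        sy = rng.uniform(0.005, 0.03, 25)
        pair = make_pair(bx, by, sy=sy)
        w = 1 / sy ** 2
        slope_c = float(np.sum(w * bx * by) / np.sum(w * bx ** 2))
        ivw_est = m.ivw(m.wald_ratios(pair)).estimate.theta_hat
        assert slope_c == pytest.approx(ivw_est, abs=1e-12)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            m.mr_egger(make_pair([0.1, 0.2], [0.01, 0.02]))


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        res = m.weighted_median(ratios_df([0.1, 0.2, 0.9], [0.1] * 3),
                                seed=0)
        assert res.estimate.theta_hat == pytest.approx(0.2)

    def test_dominant_weight_snp_wins(self):
        res = m.weighted_median(
            ratios_df([0.1, 0.2, 0.9], [1.0, 1.0, 0.01]), seed=0)
        assert res.estimate.theta_hat == pytest.approx(0.9, abs=0.05)

    def test_consistent_with_minority_invalid(self):
        rng = np.random.default_rng(5)
        J = 40
        se = np.full(J, 0.05)
        r = 0.2 + rng.normal(size=J) * se
        r[:12] += rng.uniform(0.5, 1.5, 12)  # 30% invalid, extreme
        res = m.weighted_median(ratios_df(r, se), seed=1)
        assert abs(res.estimate.theta_hat - 0.2) < 2 * res.estimate.se


class TestContaminationMixture:
    def test_degenerate_all_equal(self):
        res = m.contamination_mixture(
            ratios_df([0.2] * 5, [0.001] * 5), psi=0.5)
        assert res.estimate.theta_hat == pytest.approx(0.2, abs=0.001)

    def test_recovery_with_scattered_invalid(self):
        rng = np.random.default_rng(6)
        J = 50
        se = np.full(J, 0.04)
        r = 0.2 + rng.normal(size=J) * se
        r[:15] = rng.uniform(-1.0, 1.0, 15)  # 30% invalid
        res = m.contamination_mixture(ratios_df(r, se))
        assert abs(res.estimate.theta_hat - 0.2) < 2 * 0.04

    def test_ci_matches_dense_grid_scan(self):
        rng = np.random.default_rng(7)
        se = np.full(20, 0.05)
        r = 0.15 + rng.normal(size=20) * se
        rdf = ratios_df(r, se)
        res = m.contamination_mixture(rdf, psi=0.4, n_grid=2001)
        # brute-force scan at 10x the density over the same span
        grid = np.linspace(res.estimate.ci_low - 0.05,
                           res.estimate.ci_high + 0.05, 20001)
        res_dense = m.contamination_mixture(rdf, psi=0.4, grid=grid)
        assert res_dense.estimate.ci_low == pytest.approx(
            res.estimate.ci_low, abs=0.002)
        assert res_dense.estimate.ci_high == pytest.approx(
            res.estimate.ci_high, abs=0.002)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            m.contamination_mixture(ratios_df([0.1, 0.2, 0.3], [0.1] * 3),
                                    grid=np.array([0.1]))


class TestPresso:
    def test_minimal_smoke(self):
        pair = make_pair([0.1, 0.12, 0.09, 0.11],
                         [0.02, 0.025, 0.018, 0.022])
        res = m.mr_presso(pair, n_sim=200, seed=1)
        assert 0 < res.global_p <= 1

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(9)
        J = 30
        bx = np.abs(rng.normal(0.1, 0.02, J))
        sy = np.full(J, 0.005)
        by = 0.2 * bx + rng.normal(size=J) * sy
        by[3] += 0.2  # massive pleiotropic effect on one SNP
        # n_sim large enough that the smallest attainable per-SNP p-value,
        # 1/(n_sim+1), clears the Bonferroni threshold 0.05/J
        res = m.mr_presso(make_pair(bx, by, sy=sy), n_sim=1000, seed=2)
        assert "s3" in res.outliers
        assert res.global_p < 0.05

    def test_homogeneous_global_p_not_extreme(self):
        rng = np.random.default_rng(10)
        J = 30
        bx = np.abs(rng.normal(0.1, 0.02, J))
        sy = np.full(J, 0.01)
        by = 0.2 * bx + rng.normal(size=J) * sy
        res = m.mr_presso(make_pair(bx, by, sy=sy), n_sim=500, seed=3)
        assert res.global_p > 0.05
        assert res.outliers == []


class TestMvmr:
    def test_zero_second_exposure_reduces_to_ivw(self, rng):
        J = 20
        bx = np.abs(rng.normal(0.1, 0.02, J))
        sy = rng.uniform(0.005, 0.02, J)
        by = 0.25 * bx + rng.normal(size=J) * sy
        bexp = pd.DataFrame({"x1": bx, "x2": np.zeros(J)})
        bse = pd.DataFrame({"x1": np.full(J, 0.005),
                            "x2": np.full(J, 0.005)})
        with pytest.warns(UserWarning, match="all-zero"):
            res = m.mvmr(bexp, bse, by, sy)
        ivw_est = m.ivw(m.wald_ratios(make_pair(bx, by, sy=sy))).estimate
        assert res.estimate.theta_hat == pytest.approx(ivw_est.theta_hat,
                                                       abs=1e-10)

    def test_collinear_exposures_rejected(self, rng):
        J = 15
        bx = rng.normal(0.1, 0.02, J)
        bexp = pd.DataFrame({"x1": bx, "x2": 2 * bx})
        bse = pd.DataFrame({"x1": np.full(J, 0.01), "x2": np.full(J, 0.01)})
        with pytest.raises(ValueError, match="collinear"):
            m.mvmr(bexp, bse, rng.normal(size=J), np.full(J, 0.01))

    def test_attenuation_under_genetic_confounding(self):
        """With an overlapping body-size pathway, the univariable estimate
        absorbs the indirect effect; MVMR recovers the direct effect."""
        params = m.SimParams(n_snps=120, n_gwas_outcome=100_000, seed=73)
        bexp, bse, ostats, truth = m.generate_mvmr_tables(params)
        pair = m.generate_summary_pair(params)  # univariable, same seed
        res_mv = m.mvmr(bexp, bse, ostats["beta"].to_numpy(),
                        ostats["se"].to_numpy())
        direct = res_mv.estimates["menarche"]
        assert direct.theta_hat == pytest.approx(truth["menarche"],
                                                 abs=3 * direct.se)
        # univariable on the mvmr outcome absorbs the indirect pathway
        uni = m.ivw(ratios_df(
            ostats["beta"].to_numpy() / bexp["menarche"].to_numpy(),
            ostats["se"].to_numpy() / np.abs(bexp["menarche"].to_numpy())))
        assert abs(uni.estimate.theta_hat - truth["total_menarche"]) \
            < 3 * uni.estimate.se
        # attenuation direction: direct is closer to theta than total
        assert abs(direct.theta_hat - truth["menarche"]) < \
            abs(uni.estimate.theta_hat - truth["menarche"])

    def test_conditional_f_near_univariable_when_independent(self, rng):
        J = 80
        bx1 = rng.normal(0.0, 0.05, J)
        bx2 = rng.normal(0.0, 0.05, J)
        s1 = np.full(J, 0.01)
        bexp = pd.DataFrame({"x1": bx1, "x2": bx2})
        bse = pd.DataFrame({"x1": s1, "x2": s1})
        by = 0.1 * bx1 + rng.normal(size=J) * 0.02
        res = m.mvmr(bexp, bse, by, np.full(J, 0.02))
        f_uni = float(np.sum((bx1 / s1) ** 2)) / J
        assert res.conditional_f["x1"] == pytest.approx(f_uni, rel=0.15)


class TestInvariances:
    def test_relabel_and_sign_flip_invariance(self, rng):
        J = 25
        bx = rng.normal(0.1, 0.05, J)
        sy = rng.uniform(0.005, 0.02, J)
        by = 0.2 * bx + rng.normal(size=J) * sy
        pair = make_pair(bx, by, sy=sy)
        flip = rng.random(J) < 0.5
        bx2, by2 = bx.copy(), by.copy()
        bx2[flip] *= -1
        by2[flip] *= -1
        perm = rng.permutation(J)
        pair2 = make_pair(bx2[perm], by2[perm], sy=sy[perm])
        for fn in (lambda p: m.ivw(m.wald_ratios(p)).estimate.theta_hat,
                   lambda p: m.mr_egger(p).estimate.theta_hat,
                   lambda p: m.weighted_median(
                       m.wald_ratios(p), seed=0).estimate.theta_hat):
            assert fn(pair) == pytest.approx(fn(pair2), abs=1e-9)

    def test_ivw_consistent_with_tsls_same_generator(self):
        """Summary-level IVW and individual-level 2SLS estimate the same
        causal quantity from one parameter set."""
        params = m.SimParams(n_individuals=13_000, n_snps=80,
                             n_gwas_outcome=50_000, seed=74)
        c = m.generate_cohort(params)
        pair = m.generate_summary_pair(params)
        score = m.compute_grs(c.dosages, c.gamma)
        y = m.standardize(np.log1p(c.outcomes_cont["depression"].to_numpy()))
        iv1 = m.tsls(y, c.exposure_latent, score)
        iv2 = m.ivw(m.wald_ratios(pair)).estimate
        combined = math.hypot(iv1.se, iv2.se)
        assert abs(iv1.theta_hat - iv2.theta_hat) < 3 * combined
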