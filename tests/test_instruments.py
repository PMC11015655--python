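"""Clumping, allele-score construction, residualisation, the relevance
audit, and Steiger filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import menarchemr as m
from menarchemr.instruments import GwasSummaryRow


def _rows(snps, chroms, poss, pvals):
    return pd.DataFrame({
        "snp": snps, "chrom": chroms, "pos": poss,
        "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
        "beta": 0.1, "se": 0.01, "pval": pvals, "n": 1000})


def _ld(snps, mat):
    return pd.DataFrame(mat, index=snps, columns=snps)


class TestClump:
    def test_correlated_pair_within_window_keeps_best(self):
        rows = _rows(["a", "b"], [1, 1], [1_000_000, 6_000_000],
                     [1e-10, 1e-8])
        ld = _ld(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        kept = m.clump(rows, ld, r2_threshold=0.001, window_kb=10_000)
        assert kept["snp"].tolist() == ["a"]

    def test_same_pair_outside_window_keeps_both(self):
        rows = _rows(["a", "b"], [1, 1], [1_000_000, 21_000_000],
                     [1e-10, 1e-8])
        ld = _ld(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        kept = m.clump(rows, ld, r2_threshold=0.001, window_kb=10_000)
        assert sorted(kept["snp"]) == ["a", "b"]

    def test_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            n = 10
            snps = [f"s{i}" for i in range(n)]
            rows = _rows(snps, np.ones(n, dtype=int),
                         rng.integers(0, 30_000_000, n),
                         rng.uniform(1e-12, 1e-4, n))
            a = rng.uniform(0, 1, (n, n))
            mat = (a + a.T) / 2
            np.fill_diagonal(mat, 1.0)
            ld = _ld(snps, mat)
            kept = m.clump(rows, ld, r2_threshold=0.3, window_kb=10_000)
            # oracle: every retained pair within window must be below
            # threshold, and every dropped SNP must conflict with a
            # better-ranked retained SNP
            kept_set = set(kept["snp"])
            for i, r1 in rows.iterrows():
                for j, r2 in rows.iterrows():
                    if (r1["snp"] in kept_set and r2["snp"] in kept_set
                            and i < j
                            and abs(r1["pos"] - r2["pos"]) <= 1e7):
                        assert ld.loc[r1["snp"], r2["snp"]] < 0.3
            for _, r1 in rows[~rows["snp"].isin(kept_set)].iterrows():
                conflicts = [
                    k for _, k in kept.iterrows()
                    if abs(k["pos"] - r1["pos"]) <= 1e7
                    and ld.loc[r1["snp"], k["snp"]] >= 0.3
                    and k["pval"] <= r1["pval"]]
                assert conflicts

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        n = 8
        snps = [f"s{i}" for i in range(n)]
        rows = _rows(snps, np.ones(n, dtype=int),
                     rng.integers(0, 20_000_000, n),
                     rng.uniform(1e-10, 1e-5, n))
        a = rng.uniform(0, 1, (n, n))
        mat = (a + a.T) / 2
        np.fill_diagonal(mat, 1.0)
        ld = _ld(snps, mat)
        once = m.clump(rows, ld, 0.2, 10_000)
        twice = m.clump(once, ld, 0.2, 10_000)
        assert once["snp"].tolist() == twice["snp"].tolist()

    def test_snp_missing_from_ld_treated_independent(self):
        rows = _rows(["a", "b"], [1, 1], [1_000_000, 1_100_000],
                     [1e-10, 1e-8])
        ld = _ld(["a"], [[1.0]])
        kept = m.clump(rows, ld)
        assert sorted(kept["snp"]) == ["a", "b"]


class TestGrs:
    def test_hand_example(self):
        score = m.compute_grs(np.array([[2.0, 0.0, 1.0]]),
                              np.array([0.1, 0.2, 0.3]))
        assert score[0] == pytest.approx((0.2 + 0.0 + 0.3) / 3)

    def test_zero_weights_zero_score(self):
        d = np.random.default_rng(0).integers(0, 3, (5, 4)).astype(float)
        assert np.all(m.compute_grs(d, np.zeros(4)) == 0)

    def test_matches_naive_loop_oracle(self, rng):
        d = rng.integers(0, 3, (5, 4)).astype(float)
        w = rng.normal(size=4)
        expected = [sum(d[i, j] * w[j] for j in range(4)) / 4
                    for i in range(5)]
        assert np.allclose(m.compute_grs(d, w), expected)

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_linear_in_weights(self, a):
        d = np.random.default_rng(2).integers(0, 3, (6, 3)).astype(float)
        w = np.array([0.1, -0.4, 0.7])
        assert np.allclose(m.compute_grs(d, a * w),
                           a * m.compute_grs(d, w), atol=1e-12)

    def test_missing_dosage_requires_flag(self):
        d = np.array([[2.0, np.nan], [1.0, 0.0]])
        with pytest.raises(ValueError, match="missing"):
            m.compute_grs(d, np.ones(2))
        score = m.compute_grs(d, np.ones(2), eaf=np.array([0.3, 0.25]),
                              mean_impute=True)
        assert score[0] == pytest.approx((2.0 + 0.5) / 2)


class TestResidualize:
    def test_intercept_only_centres(self, rng):
        s = rng.normal(5, 1, 200)
        out = m.residualize(s, np.empty((200, 0)))
        assert abs(out.mean()) < 1e-10

    def test_exact_linear_function_of_pcs_vanishes(self, rng):
        pcs = rng.normal(size=(300, 4))
        s = pcs @ np.array([1.0, -2.0, 0.5, 3.0]) + 7.0
        out = m.residualize(s, pcs)
        assert np.max(np.abs(out)) < 1e-8

    def test_orthogonality_and_oracle(self, rng):
        pcs = rng.normal(size=(500, 5))
        s = rng.normal(size=500) + pcs[:, 0]
        out = m.residualize(s, pcs)
        X = np.column_stack([np.ones(500), pcs])
        beta = np.linalg.solve(X.T @ X, X.T @ s)
        assert np.allclose(out, s - X @ beta, atol=1e-8)
        for j in range(5):
            assert abs(np.corrcoef(out, pcs[:, j])[0, 1]) < 1e-10

    def test_collinear_column_dropped_with_warning(self, rng):
        pcs = rng.normal(size=(100, 2))
        nuis = np.column_stack([pcs, pcs[:, 0] * 2.0])
        with pytest.warns(UserWarning, match="collinear"):
            m.residualize(rng.normal(size=100), nuis)


class TestAudit:
    def test_f_closed_form_at_study_values(self):
        """R^2 = 0.069 at n = 13,446 implies first-stage F ~ 996."""
        r2, n = 0.069, 13_446
        f = (r2 / 1) / ((1 - r2) / (n - 2))
        assert f == pytest.approx(996.4, abs=0.5)
        # and the audit reproduces the same closed form on constructed data
        rng = np.random.default_rng(4)
        s = rng.normal(size=n)
        x = math.sqrt(r2) * s + math.sqrt(1 - r2) * rng.normal(size=n)
        audit = m.instrument_audit(s, x, pd.DataFrame({"c": rng.normal(size=n)}))
        f_expected = (audit["r2"] / 1) / ((1 - audit["r2"]) / (n - 2))
        assert audit["f_stat"] == pytest.approx(f_expected, rel=1e-12)
        assert audit["f_stat"] == pytest.approx(996.4, rel=0.1)

    def test_perfect_instrument_r2_one(self, rng):
        s = rng.normal(size=100)
        audit = m.instrument_audit(s, s, pd.DataFrame({"c": rng.normal(size=100)}))
        assert audit["r2"] == pytest.approx(1.0)

    def test_null_covariate_false_positive_rate(self, rng):
        n, k = 2000, 40
        s = rng.normal(size=n)
        covs = pd.DataFrame(rng.normal(size=(n, k)),
                            columns=[f"c{i}" for i in range(k)])
        audit = m.instrument_audit(s, rng.normal(size=n), covs)
        hits = (audit["associations"]["pval"] < 0.05).sum()
        assert hits <= 7  # binomial(40, 0.05) upper tail

    def test_zero_variance_covariate_skipped(self, rng):
        s = rng.normal(size=100)
        covs = pd.DataFrame({"flat": np.ones(100), "ok": rng.normal(size=100)})
        audit = m.instrument_audit(s, rng.normal(size=100), covs)
        assert audit["associations"]["covariate"].tolist() == ["ok"]


def _pair_from(bx, by, n_exp, n_out):
    base = pd.DataFrame({
        "snp": [f"s{i}" for i in range(len(bx))],
        "chrom": 1, "pos": np.arange(len(bx)) * 10**6,
        "effect_allele": "A", "other_allele": "G", "eaf": 0.3})
    exp = base.assign(beta=bx, se=0.01, pval=1e-8, n=n_exp)
    out = base.assign(beta=by, se=0.01, pval=0.5, n=n_out)
    return m.SummaryPair(exp, out, n_exp, n_out)


class TestSteiger:
    def test_direction_only_rules(self):
        # z chosen so r2 = z^2/(z^2+n) hits the stated values
        n = 10_000

        def beta_for(r2):
            z = math.sqrt(r2 * n / (1 - r2))
            return z * 0.01

        pair = _pair_from([beta_for(0.02), beta_for(0.001)],
                          [beta_for(0.001), beta_for(0.02)], n, n)
        filtered, log = m.steiger_filter(pair)
        assert log["removed"].tolist() == [False, True]
        assert filtered.n_snps == 1

    def test_tie_retains(self):
        pair = _pair_from([0.05, 0.02], [0.05, 0.01], 5000, 5000)
        _, log = m.steiger_filter(pair)
        assert not log["removed"].iloc[0]

    def test_preferentially_removes_reverse_causal_snps(self):
        """Simulated reverse-causal SNPs (larger outcome r2) are mostly
        removed; valid SNPs mostly retained."""
        rng = np.random.default_rng(17)
        n = 20_000
        J = 60
        reverse = np.arange(J) < 20
        # valid SNPs: strong exposure, weak outcome; reverse: converse
        r2_exp = np.where(reverse, 0.0004, 0.002)
        r2_out = np.where(reverse, 0.002, 0.0004)

        def noisy_beta(r2):
            z_true = np.sqrt(r2 * n / (1 - r2))
            return (z_true + rng.normal(size=J) * 0.35) * 0.01

        pair = _pair_from(noisy_beta(r2_exp), noisy_beta(r2_out), n, n)
        _, log = m.steiger_filter(pair)
        removed = log["removed"].to_numpy()
        assert removed[reverse].mean() > 0.5
        assert removed[~reverse].mean() < 0.10

    def test_missing_n_errors(self):
        pair = _pair_from([0.1], [0.05], 1000, 1000)
        pair.outcome_stats.loc[0, "n"] = np.nan
        with pytest.raises(ValueError, match="sample size"):
            m.steiger_filter(pair)


def test_summary_row_validation():
    with pytest.raises(ValueError):
        GwasSummaryRow("rs1", 1, 100, "A", "G", 0.3, 0.1, -0.01, 0.5, 100)
    with pytest.raises(ValueError):
        GwasSummaryRow("rs1", 1, 100, "A", "G", 1.5, 0.1, 0.01, 0.5, 100)
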