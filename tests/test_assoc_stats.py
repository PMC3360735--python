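"""Trend logistic regression, HWE, QC filtering and heterogeneity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adapt_bfdp.assoc_stats import (
    GenotypeCounts,
    StratumEstimate,
    cochran_q,
    fit_trend_many,
    genomic_inflation,
    hwe_test,
    qc_filter,
    trend_logistic,
)
from adapt_bfdp.bayes_rank import variance_from_summary


def newton_oracle(cases, controls, iters=60):
    """Independent per-subject Newton-Raphson fit of logit P = a + b*g."""
    g = np.concatenate(
        [np.repeat([0, 1, 2], cases), np.repeat([0, 1, 2], controls)]
    ).astype(float)
    y = np.concatenate(
        [np.ones(sum(cases)), np.zeros(sum(controls))]
    )
    X = np.column_stack([np.ones_like(g), g])
    beta = np.zeros(2)
    for _ in range(iters):
        p = 1 / (1 + np.exp(-X @ beta))
        grad = X.T @ (y - p)
        H = X.T @ (X * (p * (1 - p))[:, None])
        beta = beta + np.linalg.solve(H, grad)
    p = 1 / (1 + np.exp(-X @ beta))
    H = X.T @ (X * (p * (1 - p))[:, None])
    cov = np.linalg.inv(H)
    return beta[1], cov[1, 1]


class TestTrendLogistic:
    def test_balanced_table_gives_null(self):
        rec = trend_logistic(
            GenotypeCounts("rs1", cases=(50, 40, 10), controls=(50, 40, 10))
        )
        assert rec.theta_hat == pytest.approx(0.0, abs=1e-8)
        assert rec.or_point == pytest.approx(1.0, abs=1e-8)

    def test_matches_independent_newton_fit(self):
        cases, controls = (50, 40, 10), (40, 45, 15)
        rec = trend_logistic(GenotypeCounts("rs1", cases, controls))
        theta, var = newton_oracle(cases, controls)
        assert rec.theta_hat == pytest.approx(theta, rel=1e-6)
        assert rec.V == pytest.approx(var, rel=1e-6)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            cases = tuple(int(x) for x in rng.integers(5, 80, 3))
            controls = tuple(int(x) for x in rng.integers(5, 80, 3))
            rec = trend_logistic(GenotypeCounts("rs", cases, controls))
            theta, var = newton_oracle(cases, controls)
            assert rec.theta_hat == pytest.approx(theta, rel=1e-6, abs=1e-9)
            assert rec.V == pytest.approx(var, rel=1e-6)

    def test_dominant_collapse_matches_cross_product(self):
        """Coding carriers vs non-carriers (counts only in g=0 and g=1)
        reduces the trend model to a 2x2 table whose MLE is the
        cross-product odds ratio."""
        cases, controls = (30, 50, 0), (60, 25, 0)
        rec = trend_logistic(GenotypeCounts("rs", cases, controls))
        assert rec.or_point == pytest.approx((50 * 60) / (30 * 25), rel=1e-6)

    def test_absent_minor_allele_rejected(self):
        with pytest.raises(ValueError, match="minor allele"):
            trend_logistic(GenotypeCounts("rs", (50, 0, 0), (50, 0, 0)))

    def test_separation_flagged(self):
        with pytest.raises(ValueError):
            trend_logistic(GenotypeCounts("rs", (0, 0, 50), (50, 0, 0)))

    def test_stratified_fit_runs_and_shrinks_confounding(self):
        # same per-stratum odds, different baselines: stratified theta ~ 0
        s1 = GenotypeCounts("rs", (80, 15, 5), (80, 15, 5), stratum="A")
        s2 = GenotypeCounts("rs", (20, 40, 40), (20, 40, 40), stratum="B")
        rec = trend_logistic([s1, s2])
        assert rec.theta_hat == pytest.approx(0.0, abs=1e-6)

    def test_coverage_of_wald_interval(self):
        """Simulated tables with true OR 1.25: nominal 95% CI covers the
        truth between 93% and 97% of the time."""
        rng = np.random.default_rng(17)
        theta_true = math.log(1.25)
        f = 0.3
        hwe = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        tilt = hwe * np.exp(theta_true * np.arange(3))
        tilt /= tilt.sum()
        n = 500
        cases = rng.multinomial(800, tilt, size=n)
        controls = rng.multinomial(800, hwe, size=n)
        fit = fit_trend_many(cases, controls)
        lo = fit.theta_hat - 1.959964 * fit.se
        hi = fit.theta_hat + 1.959964 * fit.se
        cover = ((lo <= theta_true) & (theta_true <= hi)).mean()
        assert 0.93 <= cover <= 0.97


class TestFitTrendMany:
    def test_agrees_with_single_snp_fit(self):
        rng = np.random.default_rng(9)
        cases = rng.integers(5, 90, size=(20, 3))
        controls = rng.integers(5, 90, size=(20, 3))
        many = fit_trend_many(cases, controls)
        for i in range(20):
            rec = trend_logistic(
                GenotypeCounts(
                    "rs", tuple(int(x) for x in cases[i]),
                    tuple(int(x) for x in controls[i]),
                )
            )
            assert many.theta_hat[i] == pytest.approx(rec.theta_hat, rel=1e-6, abs=1e-8)
            assert many.se[i] == pytest.approx(math.sqrt(rec.V), rel=1e-6)

    def test_degenerate_rows_are_nan(self):
        cases = np.array([[50, 0, 0]])
        controls = np.array([[50, 0, 0]])
        out = fit_trend_many(cases, controls)
        assert np.isnan(out.theta_hat[0])


class TestHwe:
    def test_exact_proportions(self):
        chi2, p = hwe_test((25, 50, 25))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        chi2, p = hwe_test((30, 30, 40))
        assert chi2 == pytest.approx(15.52, abs=0.01)
        assert p == pytest.approx(8.2e-5, rel=0.02)

    def test_matches_three_cell_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            m = tuple(int(x) for x in rng.integers(1, 200, 3))
            chi2, _ = hwe_test(m)
            n = sum(m)
            q = (m[1] + 2 * m[2]) / (2 * n)
            exp = np.array(
                [n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2]
            )
            brute = (((np.array(m) - exp) ** 2) / exp).sum()
            assert chi2 == pytest.approx(brute, rel=1e-12)

    def test_monomorphic_warns(self):
        with pytest.warns(UserWarning):
            chi2, p = hwe_test((100, 0, 0))
        assert p == 1.0


class TestQcFilter:
    def _counts(self):
        return pd.DataFrame(
            {
                "rsid": ["rs1", "rs2", "rs3"],
                "case0": [40, 40, 40], "case1": [40, 40, 40], "case2": [20, 20, 20],
                "ctrl0": [45, 45, 80], "ctrl1": [40, 40, 0], "ctrl2": [15, 15, 20],
            }
        )

    def test_clean_dataset_untouched(self):
        counts = self._counts().iloc[:2]
        kept, report = qc_filter(counts)
        assert len(kept) == 2 and report.empty

    def test_call_rate_exclusion(self):
        rates = pd.Series({"rs1": 0.94, "rs2": 0.99, "rs3": 0.99})
        kept, report = qc_filter(self._counts(), snp_call_rate=rates)
        reasons = report.set_index("id")["reason"]
        assert reasons["rs1"] == "call_rate"

    def test_planted_hwe_violation_excluded(self):
        # rs3 controls (80, 0, 20): zero heterozygotes, p << 1e-7
        kept, report = qc_filter(self._counts())
        assert "rs3" not in set(kept["rsid"])
        assert (report.set_index("id").loc["rs3", "reason"]) == "hwe"

    def test_idempotent(self):
        kept, _ = qc_filter(self._counts())
        again, report = qc_filter(kept)
        assert report.empty and len(again) == len(kept)


class TestCochranQ:
    def test_identical_estimates(self):
        e = StratumEstimate("a", 0.2, 0.01)
        q, p = cochran_q([e, StratumEstimate("b", 0.2, 0.01)])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_published_two_phase_heterogeneity(self):
        """Discovery OR 0.81 (0.72-0.91) vs replication 0.84 (0.75-0.94)
        give Q ~ 0.19, p ~ 0.66."""
        v1 = variance_from_summary(ci_lo=0.72, ci_hi=0.91, route="ci")
        v2 = variance_from_summary(ci_lo=0.75, ci_hi=0.94, route="ci")
        q, p = cochran_q(
            [
                StratumEstimate("discovery", math.log(0.81), v1),
                StratumEstimate("replication", math.log(0.84), v2),
            ]
        )
        assert q == pytest.approx(0.19, abs=0.02)
        assert p == pytest.approx(0.66, abs=0.02)

    def test_equal_variance_reduces_to_scaled_sample_variance(self):
        rng = np.random.default_rng(8)
        theta = rng.normal(0, 0.2, 6)
        v = 0.01
        q, _ = cochran_q(
            [StratumEstimate(str(i), t, v) for i, t in enumerate(theta)]
        )
        brute = ((theta - theta.mean()) ** 2).sum() / v
        assert q == pytest.approx(brute, rel=1e-12)

    def test_permutation_invariant(self):
        ests = [
            StratumEstimate("a", 0.1, 0.01),
            StratumEstimate("b", -0.2, 0.02),
            StratumEstimate("c", 0.05, 0.015),
        ]
        assert cochran_q(ests) == cochran_q(ests[::-1])

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError):
            cochran_q([StratumEstimate("a", 0.1, 0.01)])


class TestLambda:
    def test_reference_median(self):
        stats_ = np.full(99, stats.chi2.ppf(0.5, 1))
        assert genomic_inflation(chi2_stats=stats_) == pytest.approx(1.0)

    def test_uniform_p_values(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 100_000)
        assert genomic_inflation(p_values=p) == pytest.approx(1.0, abs=0.02)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(13)
        x = stats.chi2.rvs(1, size=1001, random_state=rng)
        assert genomic_inflation(chi2_stats=2 * x) == pytest.approx(
            2 * genomic_inflation(chi2_stats=x)
        )
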