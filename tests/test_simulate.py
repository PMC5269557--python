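"""Synthetic-cohort generator: trajectories, hazards, event times, MNAR structure."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from engagejm import GeneratorConfig, generate_cohort, km_estimate, true_trajectory
from engagejm.simulate import cumulative_hazard, sample_event_time

TABLE_BETA_JOINT = (4.05, -0.14, 0.0021)
W0 = np.zeros(5)


class TestTrueTrajectory:
    def test_intercept_value(self):
        assert true_trajectory(TABLE_BETA_JOINT, (0.0, 0.0), 0.0) == pytest.approx(4.05)

    def test_six_month_value(self):
        # 4.05 - 0.14*26 + 0.0021*676
        assert true_trajectory(TABLE_BETA_JOINT, (0.0, 0.0), 26.0) == pytest.approx(1.8296)

    @pytest.mark.parametrize("shift", [-1.3, 0.7, 2.0])
    def test_intercept_shift(self, shift):
        base = true_trajectory(TABLE_BETA_JOINT, (0.0, 0.0), 0.0)
        assert true_trajectory(TABLE_BETA_JOINT, (shift, 0.0), 0.0) == pytest.approx(base + shift)


class TestCumulativeHazard:
    def test_reduces_to_lambda_t(self):
        cfg = GeneratorConfig(alpha=0.0, gamma=(0,) * 5, knots=(0.0, 100.0), rates=(0.1,))
        assert cumulative_hazard(cfg, W0, (0.0, 0.0), 10.0) == pytest.approx(1.0)

    def test_constant_trajectory_closed_form(self):
        # m(t) = 2 constant, alpha = 0.5 -> H(t) = 0.1 * e * t
        cfg = GeneratorConfig(
            beta=(0.0, 0.0, 0.0), alpha=0.5, gamma=(0,) * 5, knots=(0.0, 100.0), rates=(0.1,)
        )
        for t in (1.0, 7.5, 30.0):
            assert cumulative_hazard(cfg, W0, (2.0, 0.0), t) == pytest.approx(
                0.1 * math.e * t, rel=1e-10
            )

    def test_matches_dense_quadrature_oracle(self):
        cfg = GeneratorConfig()  # beta2 != 0: no elementary antiderivative
        b = (0.8, -0.03)
        w = np.array([2.0, 1.0, 1.0, 0.0, 0.0])

        def hazard(s):
            k = min(np.searchsorted(cfg.knots, s, side="right") - 1, len(cfg.rates) - 1)
            return cfg.rates[k] * math.exp(
                float(np.dot(cfg.gamma, w)) + cfg.alpha * true_trajectory(cfg.beta, b, s)
            )

        for t in (3.0, 13.7, 26.0):
            oracle, _ = integrate.quad(hazard, 0, t, limit=500,
                                       points=list(np.asarray(cfg.knots)[np.asarray(cfg.knots) < t]))
            mine = cumulative_hazard(cfg, w, b, t)
            assert mine == pytest.approx(oracle, rel=1e-8)

    def test_monotone_and_zero_at_origin(self):
        cfg = GeneratorConfig()
        vals = [cumulative_hazard(cfg, W0, (0.5, 0.01), t) for t in np.linspace(0, 30, 16)]
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) >= 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cumulative_hazard(GeneratorConfig(), W0, (0.0, 0.0), -1.0)


class TestSampleEventTime:
    def test_exponential_special_case(self):
        lam = 0.2
        cfg = GeneratorConfig(alpha=0.0, gamma=(0,) * 5, knots=(0.0, 1000.0), rates=(lam,))
        rng = np.random.default_rng(11)
        draws = np.array([sample_event_time(cfg, W0, (0.0, 0.0), rng) for _ in range(10_000)])
        se = (1 / lam) / math.sqrt(len(draws))
        assert abs(draws.mean() - 1 / lam) < 3 * se

    def test_higher_engagement_means_later_dropout(self):
        cfg = GeneratorConfig(alpha=-0.26)
        lo = np.array(
            [sample_event_time(cfg, W0, (-1.5, 0.0), np.random.default_rng(1000 + i))
             for i in range(3000)]
        )
        hi = np.array(
            [sample_event_time(cfg, W0, (1.5, 0.0), np.random.default_rng(5000 + i))
             for i in range(3000)]
        )
        # one-sided: high-engagement subject drops out stochastically later
        stat = stats.mannwhitneyu(hi, lo, alternative="greater")
        assert stat.pvalue < 1e-10

    def test_deterministic_under_seed(self):
        cfg = GeneratorConfig()
        a = [sample_event_time(cfg, W0, (0.3, 0.0), np.random.default_rng(5)) for _ in range(5)]
        b = [sample_event_time(cfg, W0, (0.3, 0.0), np.random.default_rng(5)) for _ in range(5)]
        assert a == b

    def test_matches_analytic_survival_function(self):
        # KS test of draws against S(t) = exp(-H(t)) for fixed (w, b); a
        # linearly declining trajectory makes dropout certain (no mass at inf)
        cfg = GeneratorConfig(beta=(4.05, -0.14, 0.0))
        b = (0.5, -0.02)
        rng = np.random.default_rng(77)
        draws = np.array([sample_event_time(cfg, W0, b, rng) for _ in range(10_000)])
        assert np.all(np.isfinite(draws))

        def cdf(ts):
            return np.array([1.0 - math.exp(-cumulative_hazard(cfg, W0, b, t)) for t in ts])

        res = stats.kstest(draws, cdf)
        assert res.pvalue > 0.01


class TestGenerateCohort:
    def test_contract_and_invariants(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_subjects=100), seed=0)
        assert cohort.n_subjects == 100
        assert len(truth.table) == 100
        # MNAR-by-construction: no records after event time (validated by
        # LinkedCohort, but assert explicitly)
        last = cohort.longitudinal.frame.groupby("subject_id")["time_weeks"].max()
        tev = cohort.survival.frame.set_index("subject_id")["event_time_weeks"]
        assert (last <= tev.loc[last.index]).all()

    def test_noiseless_limit_reproduces_trajectory(self):
        cfg = GeneratorConfig(
            n_subjects=20, sigma=1e-12, alpha=0.0, rates=(1e-8,) * 5,
            D=((1e-12, 0.0), (0.0, 1e-14)), staggered_fraction=0.0,
        )
        cohort, truth = generate_cohort(cfg, seed=2)
        lf = cohort.longitudinal.frame
        expect = true_trajectory(cfg.beta, (0.0, 0.0), lf["time_weeks"].to_numpy())
        assert np.allclose(lf["engagement_days"].to_numpy(), expect, atol=1e-5)

    def test_alpha_zero_event_times_independent_of_b(self):
        cfg = GeneratorConfig(n_subjects=1500, alpha=0.0, staggered_fraction=0.0)
        cohort, truth = generate_cohort(cfg, seed=9)
        tab = truth.table
        rho = stats.spearmanr(tab["b0"], np.minimum(tab["true_event_time"], 1e6)).statistic
        assert abs(rho) < 0.06

    def test_negative_alpha_links_engagement_and_duration(self):
        # early-week engagement (a window everyone contributes to) predicts
        # how long a subject keeps providing data
        cohort, truth = generate_cohort(GeneratorConfig(n_subjects=500), seed=4)
        lf = cohort.longitudinal.frame
        early = lf[lf["time_weeks"] <= 4].groupby("subject_id")["engagement_days"].mean()
        duration = cohort.survival.frame.set_index("subject_id")["event_time_weeks"]
        rho = stats.spearmanr(early, duration.loc[early.index]).statistic
        assert rho > 0.1

    def test_km_median_matches_study_scale(self):
        # study-condition calibration: median dropout near 22 weeks
        medians = []
        for seed in range(10):
            cohort, _ = generate_cohort(GeneratorConfig(), seed=seed)
            medians.append(km_estimate(cohort.survival).median)
        assert all(m is not None and 18.0 <= m <= 26.0 for m in medians)

    def test_counter_split_streams_stable_in_n(self):
        big, _ = generate_cohort(GeneratorConfig(n_subjects=60), seed=3)
        small, _ = generate_cohort(GeneratorConfig(n_subjects=30), seed=3)
        bf = big.survival.frame
        sf = small.survival.frame
        merged = sf.merge(bf, on="subject_id", suffixes=("_s", "_b"))
        assert len(merged) == 30
        assert np.allclose(merged["event_time_weeks_s"], merged["event_time_weeks_b"])
        assert np.allclose(merged["age_years_s"], merged["age_years_b"])

    def test_likert_clamping(self):
        cfg = GeneratorConfig(n_subjects=30, clamp_to_likert=True)
        cohort, _ = generate_cohort(cfg, seed=6)
        y = cohort.longitudinal.frame["engagement_days"].to_numpy()
        assert np.allclose(y, np.rint(y))
        assert y.min() >= 0 and y.max() <= 7

    def test_config_validation(self):
        with pytest.raises(ValueError, match="positive definite"):
            GeneratorConfig(D=((1.0, 2.0), (2.0, 1.0))).validate()
        with pytest.raises(ValueError, match="sigma"):
            GeneratorConfig(sigma=-1.0).validate()
        with pytest.raises(ValueError, match="rate"):
            GeneratorConfig(rates=(0.1,) * 4).validate()
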