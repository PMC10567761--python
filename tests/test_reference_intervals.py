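"""RI extraction, bootstrap errors and age-trend regressions."""

import numpy as np
import pytest

from labri import (
    GaussianComponent,
    RIConfig,
    annual_deterioration_rate,
    bootstrap_ri,
    estimate_ri_segment,
    fit_cubic_trend,
    fit_linear_trend,
    ri_from_component,
    ri_table,
)


def comp1d(mu, sd, w=1.0):
    return GaussianComponent(weight=w, mean=[mu], covariance=[[sd * sd]])


class TestRIFromComponent:
    def test_standard_normal_limits(self):
        low, high = ri_from_component(comp1d(0.0, 1.0))
        assert low == pytest.approx(-1.95996, abs=1e-5)
        assert high == pytest.approx(1.95996, abs=1e-5)

    def test_scaled_shifted_limits(self):
        low, high = ri_from_component(comp1d(0.9, 0.15))
        assert low == pytest.approx(0.60601, abs=1e-5)
        assert high == pytest.approx(1.19399, abs=1e-5)

    def test_matches_empirical_percentiles(self, rng):
        mu, sd, n = 0.9, 0.15, 10**6
        draws = rng.normal(mu, sd, n)
        low, high = ri_from_component(comp1d(mu, sd))
        # SE of the 2.5th empirical percentile
        se = np.sqrt(0.025 * 0.975 / n) / 0.0584 * sd
        assert np.percentile(draws, 2.5) == pytest.approx(low, abs=3 * se)
        assert np.percentile(draws, 97.5) == pytest.approx(high, abs=3 * se)

    def test_width_monotone_in_coverage(self):
        widths = [
            np.diff(ri_from_component(comp1d(1.0, 0.2), coverage=c))[0]
            for c in (0.5, 0.8, 0.95, 0.99)
        ]
        assert np.all(np.diff(widths) > 0)


class TestEstimateSegment:
    def test_pure_gaussian_segment(self, rng):
        """With no pathological mass at all, the estimate still reproduces
        the full healthy interval 1.0 -/+ 1.95996 * 0.15."""
        x = rng.normal(1.0, 0.15, 20_000)
        ri = estimate_ri_segment(x, RIConfig(seed=0))
        assert ri.reliable
        assert ri.low == pytest.approx(0.70601, abs=0.01)
        assert ri.high == pytest.approx(1.29399, abs=0.01)

    def test_contaminated_segment_recovers_healthy_interval(self, rng):
        """The method's central claim: the pathological tail does not drag
        the estimated healthy interval."""
        n = 20_000
        lab = rng.random(n) < 0.10
        x = np.where(lab, rng.normal(1.8, 0.5, n), rng.normal(1.0, 0.15, n))
        ri = estimate_ri_segment(x, RIConfig(seed=0))
        assert ri.low == pytest.approx(0.70601, abs=0.02)
        assert ri.high == pytest.approx(1.29399, abs=0.02)
        assert ri.outlier_fraction == pytest.approx(0.10, abs=0.02)

    def test_small_segment_flagged_without_estimate(self):
        ri = estimate_ri_segment(np.ones(50), RIConfig(min_n=120))
        assert not ri.reliable
        assert np.isnan(ri.low) and np.isnan(ri.high)

    def test_contamination_robustness(self, rng):
        """Limits move by < 5% of the healthy SD under 10% contamination
        placed 3+ SD away."""
        n = 20_000
        clean = rng.normal(10.0, 1.0, n)
        lab = rng.random(n) < 0.10
        contaminated = np.where(lab, rng.normal(14.0, 1.5, n), clean)
        ri1 = estimate_ri_segment(contaminated, RIConfig(seed=1))
        z = 1.959964
        assert abs(ri1.low - (10.0 - z)) < 0.05 * 1.0
        assert abs(ri1.high - (10.0 + z)) < 0.05 * 1.0

    def test_affine_equivariance(self, rng):
        x = np.concatenate([rng.normal(1.0, 0.15, 4500), rng.normal(1.8, 0.5, 500)])
        a = estimate_ri_segment(x, RIConfig(seed=2))
        b = estimate_ri_segment(10.0 * x, RIConfig(seed=2))
        assert b.low == pytest.approx(10.0 * a.low, rel=1e-3)
        assert b.high == pytest.approx(10.0 * a.high, rel=1e-3)


class TestRITable:
    def test_row_count_and_determinism(self, small_cohort):
        from labri import filter_plausible

        table, _ = small_cohort
        table, _ = filter_plausible(table)
        cfg = RIConfig(seed=5)
        t1 = ri_table(table, cfg)
        t2 = ri_table(table, cfg)
        # 2 analytes x 2 genders x 3 ages
        assert len(t1) == 12
        assert t1.equals(t2)

    def test_male_high_limits_exceed_female(self, small_cohort):
        from labri import filter_plausible

        table, _ = small_cohort
        table, _ = filter_plausible(table)
        t = ri_table(table, RIConfig(seed=5))
        t = t[t["reliable"]]
        wide = t.pivot_table(index=["analyte", "age"], columns="gender", values="high")
        assert (wide["male"] > wide["female"]).all()


class TestBootstrap:
    def test_degenerate_sample_has_zero_spread(self):
        bs = bootstrap_ri(np.full(400, 3.3), b=10, seed=0, config=RIConfig(min_n=10))
        assert bs.std_low == pytest.approx(0.0, abs=1e-9)
        assert bs.std_high == pytest.approx(0.0, abs=1e-9)
        assert bs.mean_low == pytest.approx(3.3, abs=1e-3)

    def test_mean_tracks_point_estimate(self, rng):
        x = rng.normal(5.0, 1.0, 4000)
        cfg = RIConfig(seed=3, n_init=1)
        point = estimate_ri_segment(x, cfg)
        bs = bootstrap_ri(x, b=40, frac=0.5, seed=3, config=cfg)
        # bootstrap-mean converges on the point estimate up to MC error
        assert bs.mean_high == pytest.approx(point.high, abs=4 * bs.std_high / np.sqrt(40))

    def test_error_shrinks_with_sample_size(self, rng):
        """Quadrupling n at fixed resample fraction shrinks the bootstrap SE
        of the high limit by about 1/2 (SE ~ 1/sqrt(n))."""
        cfg = RIConfig(seed=4, n_init=1, min_n=100)
        x1 = rng.normal(5.0, 1.0, 2000)
        x4 = rng.normal(5.0, 1.0, 8000)
        s1 = bootstrap_ri(x1, b=60, seed=4, config=cfg).std_high
        s4 = bootstrap_ri(x4, b=60, seed=4, config=cfg).std_high
        assert s4 / s1 == pytest.approx(0.5, rel=0.35)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="b must be"):
            bootstrap_ri(np.ones(100), b=1)


class TestAgeTrends:
    def test_exact_recovery_of_linear_coefficients(self):
        ages = np.arange(20, 61)
        limits = 0.00387 * ages + 1.108239
        tr = fit_linear_trend(ages, limits, age_range=(20, 60))
        assert tr.slope == pytest.approx(0.00387, abs=1e-10)
        assert tr.intercept == pytest.approx(1.108239, abs=1e-8)
        assert tr.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_degenerates_gracefully(self):
        tr = fit_linear_trend(np.arange(20, 40), np.full(20, 1.5))
        assert tr.slope == pytest.approx(0.0, abs=1e-12)
        assert tr.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        ages = np.arange(20, 61).astype(float)
        y = 0.004 * ages + 1.1 + rng.normal(0, 0.01, ages.size)
        tr = fit_linear_trend(ages, y, age_range=(20, 60))
        X = np.column_stack([np.ones_like(ages), ages])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(tr.coefficients, beta, atol=1e-10)

    def test_default_age_windows_applied_per_analyte(self):
        ages = np.arange(20, 91)
        y = 0.1 * ages + 14.0
        y[ages > 50] += 5.0  # kink outside the urea window
        tr = fit_linear_trend(ages, y, analyte="3094-0")
        assert tr.age_range == (20.0, 50.0)
        assert tr.slope == pytest.approx(0.1, abs=1e-10)

    def test_cubic_exact_recovery_and_nesting(self, rng):
        ages = np.arange(20, 91).astype(float)
        y = 1.0 + 0.01 * ages + 2e-4 * (ages - 60) ** 3 * (ages > 60)
        cub = fit_cubic_trend(ages, y)
        lin = fit_linear_trend(ages, y, age_range=(20, 90))
        assert cub.r_squared >= lin.r_squared
        exact = fit_cubic_trend(ages, 2.0 - 0.03 * ages + 1e-3 * ages**2 + 1e-5 * ages**3)
        pred = exact.predict(ages)
        np.testing.assert_allclose(
            pred, 2.0 - 0.03 * ages + 1e-3 * ages**2 + 1e-5 * ages**3, atol=1e-8
        )

    def test_cubic_beats_linear_on_accelerating_series(self, rng):
        ages = np.arange(20, 91).astype(float)
        y = 17.0 + 0.13 * ages + 2e-4 * np.maximum(ages - 60, 0) ** 3
        y += rng.normal(0, 0.05, ages.size)
        lin = fit_linear_trend(ages, y, age_range=(20, 90))
        cub = fit_cubic_trend(ages, y)
        rms = lambda t: np.sqrt(np.mean((t.predict(ages) - y) ** 2))  # noqa: E731
        assert rms(cub) < rms(lin)


class TestDeteriorationRate:
    def test_urea_male_printed_coefficients(self):
        ages = np.arange(20.0, 51.0)
        tr = fit_linear_trend(ages, 0.13385 * ages + 17.18661)
        assert annual_deterioration_rate(tr, ref_age=20) == pytest.approx(0.674, abs=5e-4)

    def test_creatinine_male_printed_coefficients(self):
        ages = np.arange(20.0, 61.0)
        tr = fit_linear_trend(ages, 0.00387 * ages + 1.108239)
        assert annual_deterioration_rate(tr, ref_age=20) == pytest.approx(0.326, abs=5e-4)

    def test_zero_slope_zero_rate(self):
        tr = fit_linear_trend(np.arange(10.0), np.full(10, 2.0))
        assert annual_deterioration_rate(tr) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_cubic_and_nonpositive_anchor(self):
        ages = np.arange(20, 30).astype(float)
        cub = fit_cubic_trend(ages, ages**3 * 1e-5)
        with pytest.raises(ValueError, match="linear"):
            annual_deterioration_rate(cub)
        falling = fit_linear_trend(ages, 1.0 - 0.2 * ages)
        with pytest.raises(ValueError, match="non-positive"):
            annual_deterioration_rate(falling, ref_age=20)
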