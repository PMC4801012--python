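"""Bayesian penalized-spline detector: basis algebra, sampler, summaries."""

import numpy as np
import pytest

from wolfallee.count_series import CountSeries, GrowthSeries, compute_growth
from wolfallee.spline_detector import (
    SplineConfig,
    build_basis,
    diagnose_convergence,
    sample_posterior,
    summarize_allee,
)

QUICK = dict(n_iter=4_000, n_burnin=1_000, thin=3)


def _growth(x, y):
    return GrowthSeries(years=np.arange(len(x)), ln_n=x, pgr=y)


class TestBasis:
    def test_dimensions(self, rng):
        x = rng.normal(4.0, 1.0, size=31)
        b = build_basis(x, 20)
        assert b.design_spline.shape == (31, 20)
        assert len(b.knots) == 20
        assert np.all(np.diff(b.knots) > 0)

    def test_observations_at_knots_identity(self):
        # evaluated exactly at the knots, R = Omega, so Z Z^T equals the
        # modulus |Omega| (the radial-cubic Gram is indefinite; the
        # construction takes the symmetric root of its modulus)
        x = np.linspace(0.0, 1.0, 9)
        b = build_basis(x, 7)
        z = b.evaluate(b.knots)
        omega = np.abs(np.subtract.outer(b.knots, b.knots)) ** 3
        evals, evecs = np.linalg.eigh(omega)
        modulus = (evecs * np.abs(evals)) @ evecs.T
        np.testing.assert_allclose(z @ z.T, modulus, atol=1e-8)

    def test_few_distinct_values_reduce_knots(self):
        x = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 4)
        with pytest.warns(UserWarning, match="reduced knot count"):
            b = build_basis(x, 20)
        assert b.n_knots <= 5

    def test_evaluate_matches_design(self, rng):
        x = rng.normal(size=25)
        b = build_basis(x, 10)
        np.testing.assert_allclose(
            b.evaluate(x), b.design_spline, atol=1e-12
        )


class TestSampler:
    def test_flat_series_recovered(self):
        # pgr identically c with no noise: fitted curve must sit at c
        x = np.linspace(3.0, 6.0, 20)
        g = _growth(x, np.full(20, 0.07))
        fit = sample_posterior(g, SplineConfig(seed=0, **QUICK))
        grid = fit.default_grid(64)
        curve = fit.posterior_mean_curve(grid)
        assert np.all(np.abs(curve - 0.07) < 0.02)
        summary = summarize_allee(fit, force=True)
        assert summary.shape == "flat"

    def test_prior_support_respected(self, rng):
        x = rng.normal(4, 1, size=15)
        y = rng.normal(0, 0.2, size=15)
        fit = sample_posterior(_growth(x, y), SplineConfig(seed=1, **QUICK))
        flat = fit.flat()
        sigma = flat[:, -2]
        nu = flat[:, -1]
        assert np.all((sigma > 0) & (sigma < 100))
        assert np.all((nu > 0) & (nu < 100))

    def test_curve_draws_reproducible_from_parameters(self, rng):
        x = rng.normal(4, 1, size=15)
        y = 0.1 * x + rng.normal(0, 0.1, size=15)
        fit = sample_posterior(_growth(x, y), SplineConfig(seed=2, **QUICK))
        grid = fit.default_grid(33)
        flat = fit.flat()
        k = fit.n_knots
        z = fit.basis.evaluate(grid)
        manual = (
            flat[:, 0][:, None]
            + np.outer(flat[:, 1], grid)
            + flat[:, 2 : 2 + k] @ z.T
        )
        np.testing.assert_allclose(fit.curve_draws(grid), manual, atol=1e-8)

    def test_linear_limit_matches_ols(self, rng):
        # nu pinned ~0 suppresses the spline: posterior means of the
        # intercept and slope must match ordinary least squares
        x = rng.uniform(3, 6, size=40)
        y = 0.5 - 0.08 * x + rng.normal(0, 0.05, size=40)
        fit = sample_posterior(
            _growth(x, y), SplineConfig(seed=3, fix_nu=1e-8, **QUICK)
        )
        flat = fit.flat()
        b0, b1 = flat[:, 0], flat[:, 1]
        ols = np.polyfit(x, y, 1)
        assert abs(b1.mean() - ols[0]) < 2 * b1.std()
        assert abs(b0.mean() - ols[1]) < 2 * b0.std()

    def test_seeded_reproducibility(self, rng):
        x = rng.uniform(3, 6, size=12)
        y = rng.normal(0, 0.1, size=12)
        cfg = SplineConfig(seed=11, **QUICK)
        f1 = sample_posterior(_growth(x, y), cfg)
        f2 = sample_posterior(_growth(x, y), cfg)
        np.testing.assert_array_equal(f1.draws, f2.draws)

    def test_nonfinite_data_rejected(self):
        x = np.array([1.0, 2.0, np.nan] + list(np.linspace(3, 4, 9)))
        y = np.zeros(12)
        with pytest.raises(ValueError):
            sample_posterior(_growth(x, y), SplineConfig(seed=0, **QUICK))


class TestConvergenceRule:
    def test_report_and_threshold(self, rng):
        x = rng.uniform(3, 6, size=15)
        y = rng.normal(0.1, 0.1, size=15)
        fit = sample_posterior(_growth(x, y), SplineConfig(seed=5, **QUICK))
        rep = diagnose_convergence(fit, threshold=1.1)
        assert rep.converged == bool(
            max(rep.psrf_upper.max(), rep.mpsrf) < 1.1
        )
        # an impossible threshold flips the verdict
        assert not diagnose_convergence(fit, threshold=1.0).converged


class TestAlleeSummary:
    def test_noiseless_hump_landmarks_exact(self):
        n = np.geomspace(12, 550, 34)
        g = 1.0 * (1 - n / 600) * (n - 30) / 600
        fit = sample_posterior(
            _growth(np.log(n), g), SplineConfig(seed=0, **QUICK)
        )
        s = summarize_allee(fit, force=True)
        assert s.shape == "hump"
        assert s.strength == "strong"
        assert s.allee_threshold.abundance == pytest.approx(30.0, rel=0.03)
        assert s.peak.abundance == pytest.approx(315.0, rel=0.10)
        assert s.allee_threshold.ci_low <= 30 <= s.allee_threshold.ci_high
        # threshold < peak, the structural ordering of a strong Allee curve
        assert s.allee_threshold.abundance < s.peak.abundance

    def test_carrying_capacity_from_downward_crossing(self):
        # extend the data beyond K so the curve crosses downward too
        n = np.geomspace(12, 750, 40)
        g = 1.0 * (1 - n / 600) * (n - 30) / 600
        fit = sample_posterior(
            _growth(np.log(n), g), SplineConfig(seed=1, **QUICK)
        )
        s = summarize_allee(fit, force=True)
        assert s.carrying_capacity is not None
        assert s.carrying_capacity.abundance == pytest.approx(600.0, rel=0.05)
        assert s.peak.abundance < s.carrying_capacity.abundance

    def test_monotone_decline_no_threshold(self):
        x = np.linspace(3, 6, 25)
        y = 0.5 - 0.15 * x  # declining growth, classical density dependence
        fit = sample_posterior(_growth(x, y), SplineConfig(seed=2, **QUICK))
        s = summarize_allee(fit, force=True)
        assert s.shape == "monotone_decreasing"
        assert s.strength == "none"
        assert s.allee_threshold is None

    def test_interpolated_crossing_arithmetic(self):
        # curve crossing upward between ln 2.9 and 3.1 with equal
        # magnitudes lands at e^3.0
        x = np.linspace(2.0, 4.0, 21)
        y = 0.3 * (x - 3.0)
        fit = sample_posterior(_growth(x, y), SplineConfig(seed=3, **QUICK))
        s = summarize_allee(fit, force=True)
        assert s.allee_threshold is not None
        assert s.allee_threshold.abundance == pytest.approx(
            np.exp(3.0), rel=0.03
        )

    def test_years_attached_from_series(self):
        years = np.arange(1980, 2000)
        counts = np.geomspace(15, 400, 20)
        series = CountSeries("sls", years, counts)
        g = compute_growth(series)
        hump = 1.0 * (1 - np.exp(g.ln_n) / 600) * (np.exp(g.ln_n) - 30) / 600
        fit = sample_posterior(
            GrowthSeries(g.years, g.ln_n, hump), SplineConfig(seed=4, **QUICK)
        )
        s = summarize_allee(fit, series, force=True)
        yrs = s.allee_threshold.years
        assert yrs is not None
        lo, hi = sorted(counts[np.isin(years, yrs)])
        assert lo <= s.allee_threshold.abundance <= hi
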