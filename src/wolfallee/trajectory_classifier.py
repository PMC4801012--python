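"""Per-repetition Allee classification of simulated trajectories.

Each repetition's SLS (Wisconsin + Michigan) census series is reduced to
one of four outcomes.  The growth window starts in the first year the
simulated SLS population reaches 15 wolves (the minimum ever observed in
the real population); a repetition that never gets there, or yields fewer
than 10 usable growth observations, is 'extinct'.  Otherwise a cubic
smoothing spline with six knots (smoothing level chosen by generalized
cross-validation) is fit to per-capita growth versus log abundance, and
the curve's behaviour at its low-abundance end decides the category:

* positive initial slope, negative initial value  -> strong Allee effect
* positive initial slope, positive initial value  -> weak Allee effect
* negative initial slope                          -> no evidence
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .count_series import GrowthSeries
from .ibse_simulator import Trajectory

__all__ = [
    "ClassificationRule",
    "ClassifiedOutcome",
    "SmoothCurve",
    "extract_growth_window",
    "fit_classifier_spline",
    "classify",
    "classify_trajectory",
]

CATEGORIES = ("extinct", "strong_allee", "weak_allee", "no_evidence")


@dataclass(frozen=True)
class ClassificationRule:
    min_population: int = 15
    min_points: int = 10
    spline_knots: int = 6
    #: "initial" reads 'negative values' as the fitted value at the left
    #: edge; "any" as any negative fitted value while the slope is positive
    negative_values_mode: str = "initial"

    def __post_init__(self) -> None:
        if min(self.min_population, self.min_points, self.spline_knots) <= 0:
            raise ValueError("rule constants must be positive")


@dataclass(frozen=True)
class ClassifiedOutcome:
    scenario: dict
    category: str
    initial_slope: float | None = None
    initial_value: float | None = None
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")


def extract_growth_window(
    trajectory: Trajectory, rule: ClassificationRule = ClassificationRule()
) -> GrowthSeries | None:
    """Growth observations from the first year with >= 15 SLS wolves.

    Returns None when the population never reaches the minimum or too few
    growth points follow (both read as 'extinct').  Counts of zero after
    the window opens truncate it (log growth is undefined beyond).
    """
    years = trajectory.years
    n = trajectory.n_sls.astype(float)
    at_least = np.flatnonzero(n >= rule.min_population)
    if len(at_least) == 0:
        return None
    start = at_least[0]
    n = n[start:]
    years = years[start:]
    positive = n > 0
    if not positive.all():
        stop = int(np.argmin(positive))  # first zero
        n = n[:stop]
        years = years[:stop]
    if len(n) < rule.min_points + 1:
        return None
    ln = np.log(n)
    return GrowthSeries(
        years=years[1:], ln_n=ln[1:], pgr=np.diff(ln), measure_id="sls_sim"
    )


class SmoothCurve:
    """A fitted penalized cubic spline, evaluable with analytic derivative."""

    def __init__(self, spline: BSpline | np.poly1d, gcv_lambda: float | None):
        self._s = spline
        self.gcv_lambda = gcv_lambda
        if isinstance(spline, BSpline):
            self._d = spline.derivative()
        else:
            self._d = spline.deriv()

    def __call__(self, x):
        return self._s(x)

    def derivative(self, x):
        return self._d(x)


def _penalty_matrix(t: np.ndarray, n_basis: int) -> np.ndarray:
    """Integrated squared second derivative of the cubic B-spline basis.

    Second derivatives of cubics are piecewise linear, so two-point
    Gauss-Legendre per knot span is exact.
    """
    p = np.zeros((n_basis, n_basis))
    spans = np.unique(t)
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for a, b in zip(spans[:-1], spans[1:]):
        if b <= a:
            continue
        half = (b - a) / 2.0
        pts = (a + b) / 2.0 + half * gauss
        d2 = np.empty((2, n_basis))
        for j in range(n_basis):
            c = np.zeros(n_basis)
            c[j] = 1.0
            d2[:, j] = BSpline(t, c, 3).derivative(2)(pts)
        p += half * (d2.T @ d2)
    return p


def fit_classifier_spline(
    growth: GrowthSeries, rule: ClassificationRule = ClassificationRule()
) -> SmoothCurve:
    """Penalized cubic spline of pgr on ln N, six quantile knots, GCV.

    Duplicate abscissae are collapsed to weighted means (a weighted fit).
    Fewer than four distinct abscissae trigger an ordinary least-squares
    line instead, with a warning.
    """
    order = np.argsort(growth.ln_n, kind="stable")
    x = np.asarray(growth.ln_n, float)[order]
    y = np.asarray(growth.pgr, float)[order]
    ux, inv, wts = np.unique(x, return_inverse=True, return_counts=True)
    if len(ux) < len(x):
        ym = np.zeros(len(ux))
        np.add.at(ym, inv, y)
        y = ym / wts
        x = ux
        w = wts.astype(float)
    else:
        w = np.ones(len(x))

    if len(x) < 4:
        warnings.warn("fewer than 4 distinct abscissae: falling back to OLS line")
        coef = np.polyfit(x, y, 1, w=np.sqrt(w))
        return SmoothCurve(np.poly1d(coef), None)

    k = rule.spline_knots
    knots = np.quantile(x, np.linspace(0.0, 1.0, k))
    knots = np.unique(knots)
    t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
    nb = len(t) - 4
    design = BSpline.design_matrix(x, t, 3).toarray()
    pen = _penalty_matrix(t, nb)
    bwb = design.T @ (design * w[:, None])
    bwy = design.T @ (w * y)
    n_eff = float(w.sum())

    scale = np.trace(bwb) / max(np.trace(pen), 1e-12)
    lambdas = scale * np.logspace(-8.0, 4.0, 49)
    best = None
    for lam in lambdas:
        try:
            m = np.linalg.solve(bwb + lam * pen, np.eye(nb))
        except np.linalg.LinAlgError:
            continue
        coef = m @ bwy
        fitted = design @ coef
        rss = float(w @ (y - fitted) ** 2)
        edf = float(np.trace(design.T @ (design * w[:, None]) @ m))
        denom = max(n_eff - edf, 1e-8)
        gcv = n_eff * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef)
    if best is None:
        raise RuntimeError("spline fit failed at every smoothing level")
    _, lam, coef = best
    return SmoothCurve(BSpline(t, coef, 3), lam)


def classify(
    curve: SmoothCurve,
    growth: GrowthSeries,
    rule: ClassificationRule = ClassificationRule(),
    scenario: dict | None = None,
) -> ClassifiedOutcome:
    """Category from the curve's behaviour at the smallest observed ln N."""
    x0 = float(np.min(growth.ln_n))
    slope = float(curve.derivative(x0))
    value = float(curve(x0))
    if slope > 0:
        if rule.negative_values_mode == "any":
            grid = np.linspace(x0, float(np.max(growth.ln_n)), 101)
            neg = bool(np.any(curve(grid) < 0))
        else:
            neg = value < 0
        category = "strong_allee" if neg else "weak_allee"
    else:
        category = "no_evidence"
    return ClassifiedOutcome(
        scenario=scenario or {},
        category=category,
        initial_slope=slope,
        initial_value=value,
        n_points=len(growth),
    )


def classify_trajectory(
    trajectory: Trajectory, rule: ClassificationRule = ClassificationRule()
) -> ClassifiedOutcome:
    """Full per-repetition pipeline: window, spline, category."""
    growth = extract_growth_window(trajectory, rule)
    if growth is None:
        return ClassifiedOutcome(scenario=trajectory.scenario, category="extinct")
    curve = fit_classifier_spline(growth, rule)
    return classify(curve, growth, rule, scenario=trajectory.scenario)
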