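"""Weighted straight-line fits with uncertainties in both coordinates.

Every exponential scaling relation in this package (death rate, recycling
yield, maintenance rate, cell volume versus growth rate) is a straight line
after a log transform of the ordinate,

    y = a + b * x,

where ``x`` is the growth rate (h^-1) and ``y`` the log-transformed
observable.  Both coordinates carry measurement error, so ordinary least
squares is biased; instead the chi-square is built with effective-variance
weights (Press et al., "fitting straight-line data with errors in both
coordinates"),

    chi2(a, b) = sum_i (y_i - a - b*x_i)^2 / (sy_i^2 + b^2 * sx_i^2).

Parameter uncertainties are profile errors: the half-width of the interval
over which the profiled chi-square rises by 1 from its minimum
(Delta-chi2 = 1).  Goodness of fit is the chi-square survival probability
Q = Gamma_reg(dof/2, chi2/2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, special


@dataclass(frozen=True)
class WeightedPoint:
    """One (x, y) datum with standard deviations in both coordinates.

    ``y`` is on the (log-transformed) fit scale; ``sy`` must already be on
    that scale (use :func:`log_transform_points` for native-scale data).
    """

    x: float
    y: float
    sx: float = 0.0
    sy: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("x and y must be finite")
        if self.sx < 0 or self.sy < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.sx == 0 and self.sy == 0:
            raise ValueError("at least one of sx, sy must be positive")


@dataclass(frozen=True)
class ScalingFit:
    """Result of a weighted log-linear fit y = a + b*x.

    ``prefactor`` = exp(a) is the fitted relation's prefactor on the
    observable's native scale; ``slope_b`` carries units of hours when x is
    a growth rate in h^-1.
    """

    intercept_a: float
    slope_b: float
    se_a: float
    se_b: float
    chi2: float
    dof: int
    Q: float

    @property
    def prefactor(self) -> float:
        return math.exp(self.intercept_a)

    def to_json(self) -> str:
        d = asdict(self)
        d["a"] = d.pop("intercept_a")
        d["b"] = d.pop("slope_b")
        d["prefactor"] = self.prefactor
        return json.dumps(d)


def log_transform_points(x, y, sx, sy):
    """Map native-scale observables to fit scale (delta method).

    The ordinate is log-transformed, ``sy`` becomes ``sy / y``; the abscissa
    (growth rate) stays linear.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = np.asarray(sx, float)
    sy = np.asarray(sy, float)
    if np.any(y <= 0):
        raise ValueError("log transform requires positive ordinates")
    return [
        WeightedPoint(float(xi), float(np.log(yi)), float(si), float(ti / yi))
        for xi, yi, si, ti in zip(x, y, sx, sy)
    ]


def _arrays(points):
    x = np.array([p.x for p in points], float)
    y = np.array([p.y for p in points], float)
    sx = np.array([p.sx for p in points], float)
    sy = np.array([p.sy for p in points], float)
    return x, y, sx, sy


def _chi2_profile_a(b, x, y, sx, sy):
    """min over a of chi2(a, b), and the minimizing a."""
    w = 1.0 / (sy**2 + b**2 * sx**2)
    a = np.sum(w * (y - b * x)) / np.sum(w)
    chi2 = float(np.sum(w * (y - a - b * x) ** 2))
    return chi2, float(a)


def chi_square(points, a, b) -> float:
    """Effective-variance chi-square at parameters (a, b)."""
    x, y, sx, sy = _arrays(points)
    w = 1.0 / (sy**2 + b**2 * sx**2)
    return float(np.sum(w * (y - a - b * x) ** 2))


def goodness_of_fit(chi2: float, dof: int) -> float:
    """Probability that a chi-square at least this poor arises by chance."""
    if dof < 1:
        raise ValueError("zero degrees of freedom")
    if chi2 < 0:
        raise ValueError("chi2 must be nonnegative")
    return float(special.gammaincc(dof / 2.0, chi2 / 2.0))


def _weighted_ols_slope(x, y, w):
    sw = np.sum(w)
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        raise ValueError("degenerate abscissa: all x identical")
    return float(np.sum(w * (x - xm) * (y - ym)) / sxx)


def fit_weighted_line(points, max_iter: int = 100, tol: float = 1e-9) -> ScalingFit:
    """Fit y = a + b*x minimizing the effective-variance chi-square.

    Iterated reweighting (fit -> recompute weights -> refit) provides the
    starting point; a 1-D Brent minimization of the a-profiled chi-square
    then refines b to the true minimum, since the reweighting fixed point
    neglects the b-dependence of the weights.
    """
    points = list(points)
    if len(points) < 3:
        raise ValueError("insufficient data: need at least 3 points")
    x, y, sx, sy = _arrays(points)
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all x identical")

    # iterated reweighting from the y-weighted OLS slope
    sy_eff = np.where(sy > 0, sy, np.min(sy[sy > 0]) if np.any(sy > 0) else 1.0)
    b = _weighted_ols_slope(x, y, 1.0 / sy_eff**2)
    for _ in range(max_iter):
        w = 1.0 / (sy**2 + b**2 * sx**2)
        b_new = _weighted_ols_slope(x, y, w)
        if abs(b_new - b) < tol:
            b = b_new
            break
        b = b_new

    if np.any(sx > 0):
        # refine: true minimum of the profiled chi-square
        f = lambda bb: _chi2_profile_a(bb, x, y, sx, sy)[0]
        span = max(1.0, abs(b))
        res = optimize.minimize_scalar(
            f, bracket=None, bounds=(b - 2 * span, b + 2 * span), method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun <= f(b):
            b = float(res.x)

    chi2, a = _chi2_profile_a(b, x, y, sx, sy)
    dof = len(points) - 2
    Q = goodness_of_fit(chi2, dof) if dof > 0 else 1.0
    se_a, se_b = profile_errors(points, a, b, chi2)
    return ScalingFit(a, b, se_a, se_b, chi2, dof, Q)


def _profile_halfwidths(f, center, chi2_min, step0):
    """Half-widths where profiled chi2 crosses chi2_min + 1, both sides."""
    target = chi2_min + 1.0
    widths = []
    for sign in (+1.0, -1.0):
        step = step0
        hi = center + sign * step
        for _ in range(200):
            if f(hi) >= target:
                break
            step *= 2.0
            hi = center + sign * step
        else:
            raise RuntimeError("profile failure: could not bracket Delta-chi2 = 1")
        sol = optimize.brentq(
            lambda v: f(v) - target, center, hi, xtol=1e-12, rtol=8.9e-16
        )
        widths.append(abs(sol - center))
    return widths


def profile_errors(points, a: float, b: float, chi2_min: float | None = None):
    """Delta-chi2 = 1 profile standard errors of (a, b).

    Each parameter is profiled with the other re-minimized; the two
    half-intervals are symmetrized by taking their maximum, matching the
    single +/- value convention of the fitted relations.
    """
    x, y, sx, sy = _arrays(points)
    if chi2_min is None:
        chi2_min = _chi2_profile_a(b, x, y, sx, sy)[0]

    fb = lambda bb: _chi2_profile_a(bb, x, y, sx, sy)[0]

    def fa(aa):
        # profile out b at fixed a (weights depend on b -> 1-D minimize)
        g = lambda bb: chi_square(points, aa, bb)
        span = max(1.0, abs(b))
        res = optimize.minimize_scalar(
            g, bounds=(b - 4 * span, b + 4 * span), method="bounded",
            options={"xatol": 1e-12},
        )
        return res.fun

    # curvature-based initial steps
    sw = np.sum(1.0 / (sy**2 + b**2 * sx**2))
    step_a = 1.0 / math.sqrt(sw)
    step_b = step_a / max(np.std(x), 1e-12)

    wb = _profile_halfwidths(fb, b, chi2_min, step_b)
    wa = _profile_halfwidths(fa, a, chi2_min, step_a)
    return max(wa), max(wb)


def fit_through_origin(x, y, sx, sy, max_iter: int = 100, tol: float = 1e-12):
    """Weighted through-origin fit y = m*x with errors in both coordinates.

    Returns (m, se_m) where se_m is the Delta-chi2 = 1 half-width.  Used for
    the recycling-yield and maintenance-lag slopes, whose defining models
    have no offset.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx = np.asarray(sx, float)
    sy = np.asarray(sy, float)
    if len(x) == 0:
        raise ValueError("insufficient data")

    def chi2(m):
        return float(np.sum((y - m * x) ** 2 / (sy**2 + m**2 * sx**2)))

    w0 = 1.0 / np.where(sy > 0, sy, 1.0) ** 2
    m = float(np.sum(w0 * x * y) / np.sum(w0 * x**2))
    for _ in range(max_iter):
        w = 1.0 / (sy**2 + m**2 * sx**2)
        m_new = float(np.sum(w * x * y) / np.sum(w * x**2))
        if abs(m_new - m) < tol:
            break
        m = m_new
    if np.any(sx > 0):
        span = max(1.0, abs(m))
        res = optimize.minimize_scalar(
            chi2, bounds=(m - 2 * span, m + 2 * span), method="bounded",
            options={"xatol": 1e-14},
        )
        if res.fun <= chi2(m):
            m = float(res.x)

    if len(x) == 1:
        # single point: slope error from the point's own relative errors
        m_se = abs(m) * math.sqrt(
            (sy[0] / y[0]) ** 2 + (sx[0] / x[0]) ** 2
        ) if y[0] != 0 else float("inf")
        return m, m_se

    c_min = chi2(m)
    w = 1.0 / (sy**2 + m**2 * sx**2)
    step = 1.0 / math.sqrt(np.sum(w * x**2))
    try:
        widths = _profile_halfwidths(chi2, m, c_min, step)
        se = max(widths)
    except RuntimeError:
        se = step
    return m, se
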