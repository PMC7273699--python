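"""Feast-famine fitness model under the growth-death trade-off.

Bacteria alternate between a feast period T+ (exponential growth at rate
mu) and a famine period T- (exponential death at rate gamma).  The measured
trade-off ties the death rate to the prior growth rate,

    gamma(mu) = a * exp(b * mu),

with defaults a = 0.21 day^-1 and b = 1.0 h.  The log fold change of viable
cells over one full cycle defines the fitness

    f(T+, T-, mu) = mu*T+ - gamma(mu)*T-,

which is strictly concave in mu, with interior optimum

    mu* = (1/b) * ln(T+ / (a*b*T-)),      gamma(mu*) = T+ / (b*T-),

clamped to mu* = 0 when famine dominates (argument of the log <= 1).  At
the default parameters 1/(a*b) = 114.3 h, so mu* = 1.0 h^-1 * ln(114 * T+/T-).

All internal arithmetic is in hours; the death-rate prefactor ``a`` is
supplied per day and converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import HOURS_PER_DAY


@dataclass(frozen=True)
class TradeoffRelation:
    """gamma(mu) = a * exp(b * mu); a in day^-1, b in hours."""

    a_per_day: float = 0.21
    b_h: float = 1.0

    def __post_init__(self):
        if self.a_per_day <= 0 or self.b_h <= 0:
            raise ValueError("trade-off parameters must be positive")

    @property
    def a_per_h(self) -> float:
        return self.a_per_day / HOURS_PER_DAY

    def gamma_per_day(self, mu: float) -> float:
        """Death rate (day^-1) after growth at mu (h^-1)."""
        return self.a_per_day * math.exp(self.b_h * mu)


@dataclass(frozen=True)
class FeastFamineScenario:
    """Feast duration T+ and famine duration T-, in hours."""

    T_plus_h: float
    T_minus_h: float

    def __post_init__(self):
        if self.T_plus_h <= 0 or self.T_minus_h <= 0:
            raise ValueError("feast and famine durations must be positive")

    @property
    def ratio(self) -> float:
        """T- / T+, the famine-to-feast ratio."""
        return self.T_minus_h / self.T_plus_h


def fitness(sc: FeastFamineScenario, mu: float,
            rel: TradeoffRelation = TradeoffRelation()) -> float:
    """Log fold change of viable cells over one feast-famine cycle."""
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    return mu * sc.T_plus_h - rel.a_per_h * math.exp(rel.b_h * mu) * sc.T_minus_h


def optimal_growth_rate(sc: FeastFamineScenario,
                        rel: TradeoffRelation = TradeoffRelation()):
    """Fitness-maximizing growth rate and its associated death rate.

    Returns (mu_star [h^-1], gamma_star [day^-1]).  When the famine-to-feast
    ratio exceeds 1/(a*b) the interior optimum vanishes and mu* clamps to 0.
    """
    arg = sc.T_plus_h / (rel.a_per_h * rel.b_h * sc.T_minus_h)
    if arg <= 1.0:
        mu_star = 0.0
    else:
        mu_star = math.log(arg) / rel.b_h
    return mu_star, rel.gamma_per_day(mu_star)


def log_constant(rel: TradeoffRelation = TradeoffRelation()) -> float:
    """The dimensionless constant 1/(a*b) inside the optimal-rate logarithm.

    At the defaults (a = 0.21 day^-1, b = 1.0 h) this is 114.29, so
    mu* = (1/b) ln(114 * T+/T-).
    """
    return 1.0 / (rel.a_per_h * rel.b_h)


def fitness_landscape(ratios, mus, T_plus_h: float = 3.0,
                      rel: TradeoffRelation = TradeoffRelation()):
    """Fitness matrix over a grid of famine-to-feast ratios and growth rates.

    Returns (F, mu_star) where F[i, j] = f at ratios[i], mus[j] and mu_star
    is the closed-form optimum per ratio.  Each row of F is concave in mu.
    """
    ratios = np.asarray(ratios, float)
    mus = np.asarray(mus, float)
    if np.any(ratios <= 0) or np.any(mus < 0):
        raise ValueError("grids must be positive (mu may include 0)")
    F = np.empty((ratios.size, mus.size))
    mu_star = np.empty(ratios.size)
    for i, r in enumerate(ratios):
        sc = FeastFamineScenario(T_plus_h, r * T_plus_h)
        F[i] = mus * sc.T_plus_h - rel.a_per_h * np.exp(rel.b_h * mus) * sc.T_minus_h
        mu_star[i] = optimal_growth_rate(sc, rel)[0]
    return F, mu_star
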