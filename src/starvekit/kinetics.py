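"""Exponential growth- and death-rate estimation from time courses.

Growth rates come from OD600 time courses during balanced growth; death
rates from colony-forming-unit (CFU) viability time courses during carbon
starvation, which decay as a single exponential N(t) = N0 * exp(-gamma*t).
Each replicate time course is fitted by unweighted least squares on the log
scale; replicates of a condition are then averaged, with the sample standard
deviation across replicates carrying the uncertainty.

Internal time unit is hours; death rates are conventionally reported per
day (1 day = 24 h, exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

HOURS_PER_DAY = 24.0


class Kind(str, Enum):
    viability = "viability"
    optical_density = "optical_density"


class Sign(str, Enum):
    growth = "growth"
    death = "death"


@dataclass(frozen=True)
class TimeCourse:
    """Timestamped positive measurements (CFU ml^-1 or OD600)."""

    times: tuple  # hours
    values: tuple  # CFU/ml or OD600
    kind: Kind = Kind.viability
    condition_label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("log of nonpositive measurement")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))


@dataclass(frozen=True)
class RateEstimate:
    """An exponential rate with standard error.

    ``rate`` is stored in h^-1; ``sign`` records whether it is a growth
    rate (+slope of log fit) or a death rate (-slope, so rate > 0 means
    decay).
    """

    rate: float  # h^-1
    se: float
    n_replicates: int = 1
    sign: Sign = Sign.death

    @property
    def per_day(self) -> float:
        return self.rate * HOURS_PER_DAY

    @property
    def se_per_day(self) -> float:
        return self.se * HOURS_PER_DAY


@dataclass(frozen=True)
class GrowthCondition:
    """A growth condition with its rate and uncertainty.

    Chemostat conditions carry a 5% relative growth-rate error from pump
    accuracy; batch conditions carry replicate scatter.
    """

    label: str
    mu: float  # h^-1
    mode: str = "batch"  # or "chemostat"
    sigma_mu: float | None = None

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.sigma_mu is None:
            s = 0.05 * self.mu if self.mode == "chemostat" else 0.0
            object.__setattr__(self, "sigma_mu", s)


def fit_exponential_rate(tc: TimeCourse) -> RateEstimate:
    """Unweighted log-linear least-squares rate of a time course.

    Viability courses return the death rate (rate > 0 for decay), OD
    courses the growth rate.
    """
    t = np.asarray(tc.times)
    v = np.log(np.asarray(tc.values))
    if len(t) < 3:
        raise ValueError("insufficient data: need at least 3 points")
    res = stats.linregress(t, v)
    slope, se = res.slope, res.stderr
    if not math.isfinite(se):
        se = 0.0
    if tc.kind == Kind.viability:
        return RateEstimate(-slope, se, 1, Sign.death)
    return RateEstimate(slope, se, 1, Sign.growth)


def aggregate_replicates(estimates: Sequence[RateEstimate]) -> RateEstimate:
    """Average replicate rate estimates of one condition.

    The reported uncertainty is one sample standard deviation across
    replicates (not the standard error of the mean).
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("need at least 2 replicate estimates")
    signs = {e.sign for e in estimates}
    if len(signs) != 1:
        raise ValueError("inconsistent replicate set: mixed growth/death signs")
    rates = np.array([e.rate for e in estimates])
    return RateEstimate(
        float(np.mean(rates)),
        float(np.std(rates, ddof=1)),
        len(estimates),
        estimates[0].sign,
    )


def read_timecourses_csv(path) -> list[TimeCourse]:
    """Load time courses from CSV (condition, replicate, time_h, value,
    kind); one TimeCourse per (condition, replicate, kind) group."""
    import pandas as pd

    df = pd.read_csv(path)
    courses = []
    for (cond, _rep, kind), grp in df.groupby(
            ["condition", "replicate", "kind"], sort=False):
        grp = grp.sort_values("time_h")
        courses.append(TimeCourse(tuple(grp["time_h"]), tuple(grp["value"]),
                                  Kind(kind), str(cond)))
    return courses


def rates_from_dataset(courses: Sequence[TimeCourse]) -> dict:
    """Fit each course and aggregate by condition label.

    Returns {label: RateEstimate}; conditions with a single replicate keep
    the within-fit standard error.
    """
    by_label: dict[str, list[RateEstimate]] = {}
    for tc in courses:
        by_label.setdefault(tc.condition_label, []).append(fit_exponential_rate(tc))
    out = {}
    for label, ests in by_label.items():
        out[label] = ests[0] if len(ests) == 1 else aggregate_replicates(ests)
    return out
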