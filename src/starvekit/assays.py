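"""Recycling-yield and maintenance-rate inference, and their consistency
with the measured death rate.

During carbon starvation the only resource available for maintenance is
biomass recycled from dead cells, so the death rate gamma is set by the
ratio of the maintenance rate beta (nutrient a viable cell must consume per
day to stay alive, fmol glycerol day^-1 CFU^-1) to the recycling yield
alpha (fraction of a dead cell's biomass that can be converted into new
viable cells):

    gamma = beta / alpha.

* alpha is measured by regrowing a 1% inoculum of starved cells on a
  UV-sterilized sample of the same culture: the absolute regrowth yield is
  proportional to the viability at extraction, with slope alpha.
* beta is measured by spiking starved cultures with small glycerol doses:
  the viability decay pauses for a lag T = s / beta, where s is the dose
  per viable cell, so beta is the inverse slope of lag versus dose.

Both slopes are fitted through the origin (the defining models have no
offset) with 10% relative plate-count errors on both coordinates; an
intercept-allowing variant is available for sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import TimeCourse, RateEstimate, GrowthCondition, HOURS_PER_DAY
from .regression import fit_through_origin, fit_weighted_line, WeightedPoint

#: default relative uncertainty of any CFU-derived quantity (plate counting)
PLATING_REL_ERR = 0.10


@dataclass(frozen=True)
class YieldAssayPoint:
    """One regrowth measurement of the recycling-yield assay."""

    viability_at_extraction: float  # CFU/ml of the starved control culture
    inoculum_viability: float  # CFU/ml, = min(N_G), the 1% inoculum
    max_regrowth: float  # CFU/ml, = max(N_G)

    def __post_init__(self):
        if min(self.viability_at_extraction, self.inoculum_viability,
               self.max_regrowth) <= 0:
            raise ValueError("assay viabilities must be positive")
        if self.max_regrowth < self.inoculum_viability:
            raise ValueError("max_regrowth must be >= inoculum_viability")


@dataclass(frozen=True)
class MaintenanceAssayPoint:
    """One glycerol-spike measurement of the maintenance assay."""

    glycerol_conc: float  # uM added
    viability_at_spike: float  # CFU/ml at the time of the spike
    lag_time: float  # days of delayed death

    def __post_init__(self):
        if self.glycerol_conc < 0 or self.viability_at_spike <= 0:
            raise ValueError("invalid maintenance assay point")

    @property
    def dose_per_cell(self) -> float:
        """Glycerol per viable cell, fmol CFU^-1."""
        return dose_per_cell(self.glycerol_conc, self.viability_at_spike)


@dataclass(frozen=True)
class PhysiologyRecord:
    """(gamma, alpha, beta) triplet of one growth condition."""

    condition: GrowthCondition
    gamma_per_day: float
    gamma_se: float
    alpha: float
    alpha_se: float
    beta: float  # fmol glycerol day^-1 CFU^-1
    beta_se: float


# ---------------------------------------------------------------- yield ----

def absolute_yield(p: YieldAssayPoint) -> float:
    """Absolute regrowth yield, max(N_G) - min(N_G), in CFU ml^-1."""
    y = p.max_regrowth - p.inoculum_viability
    if y <= 0:
        warnings.warn("non-positive yield: no net regrowth", stacklevel=2)
        return 0.0
    return y


def recycling_yield(points: Sequence[YieldAssayPoint],
                    rel_err: float = PLATING_REL_ERR,
                    through_origin: bool = True):
    """Recycling yield alpha as the slope of absolute yield vs extraction
    viability.

    Returns (alpha, se).  With a single point the ratio definition is used.
    Plating errors on both coordinates are relative (default 10%) and
    uncorrelated.
    """
    points = list(points)
    if not points:
        raise ValueError("no assay points")
    x = np.array([p.viability_at_extraction for p in points])
    y = np.array([absolute_yield(p) for p in points])
    if np.any(y <= 0):
        raise ValueError("non-positive yield point cannot be fitted")
    sx = rel_err * x
    sy = rel_err * y
    if len(points) == 1:
        alpha = float(y[0] / x[0])
        se = alpha * math.sqrt(2) * rel_err
    elif through_origin:
        alpha, se = fit_through_origin(x, y, sx, sy)
    else:
        pts = [WeightedPoint(float(a), float(b), float(c), float(d))
               for a, b, c, d in zip(x, y, sx, sy)]
        fit = fit_weighted_line(pts)
        alpha, se = fit.slope_b, fit.se_b
    if alpha > 1:
        warnings.warn("recycling exceeds unity", stacklevel=2)
    return alpha, se


# ---------------------------------------------------------- maintenance ----

def dose_per_cell(conc_uM: float, viability_cfu_per_ml: float) -> float:
    """Nutrient dose per viable cell in fmol CFU^-1.

    conc [uM] = 1e-9 mol ml^-1 = 1e6 fmol ml^-1; divide by the viable-cell
    density.
    """
    if conc_uM < 0 or viability_cfu_per_ml <= 0:
        raise ValueError("inputs must be positive (conc may be zero)")
    fmol_per_ml = conc_uM * 1e6
    return fmol_per_ml / viability_cfu_per_ml


def lag_time_from_ratios(ratios, gamma_per_day: float) -> float:
    """Lag time T = ln(<N_gly / N>) / gamma, in days.

    The brackets average the viability ratio itself (not its log) over the
    supplied window of time points.
    """
    if gamma_per_day <= 0:
        raise ValueError("gamma must be positive")
    r = np.asarray(ratios, float)
    if np.any(r <= 0):
        raise ValueError("ratios must be positive")
    return float(np.log(np.mean(r)) / gamma_per_day)


def lag_time(control: TimeCourse, spiked: TimeCourse, gamma: RateEstimate,
             slope_tol: float = 0.20) -> float:
    """Lag time (days) of a spiked culture relative to its control.

    The averaging window contains the time points after the initial lag,
    where the spiked culture has resumed exponential decay: points whose
    local log-slope is within ``slope_tol`` (relative) of the control's
    death rate.  Falls back to the second half of the course if no point
    qualifies.  A negative value (spiked below control) is returned signed,
    with a warning.
    """
    t_c = np.asarray(control.times)
    t_s = np.asarray(spiked.times)
    if t_c.shape != t_s.shape or np.any(t_c != t_s):
        raise ValueError("control and spiked must share sampling times")
    n = np.asarray(control.values)
    n_gly = np.asarray(spiked.values)
    gamma_h = gamma.rate  # h^-1, > 0 for death

    # local log-slope of the spiked course (centered differences)
    logs = np.log(n_gly)
    slope = np.gradient(logs, t_c)
    in_decay = np.abs(-slope - gamma_h) <= slope_tol * gamma_h
    # only points after the lag can be in the window
    idx = np.nonzero(in_decay)[0]
    if idx.size == 0:
        idx = np.arange(len(t_c) // 2, len(t_c))
    ratios = n_gly[idx] / n[idx]
    T = lag_time_from_ratios(ratios, gamma.per_day)
    if T < 0:
        warnings.warn("negative lag: spiked culture below control", stacklevel=2)
    return T


def maintenance_rate(points: Sequence[MaintenanceAssayPoint],
                     rel_err: float = PLATING_REL_ERR,
                     dose_rel_err: float = 0.0,
                     through_origin: bool = True):
    """Maintenance rate beta (fmol day^-1 CFU^-1) from lag-vs-dose points.

    beta is the inverse of the through-origin slope of lag time versus
    glycerol dose per cell; lag times carry 10% relative error by default.
    Returns (beta, se).
    """
    points = list(points)
    if len(points) < 2:
        raise ValueError("need at least 2 doses")
    x = np.array([p.dose_per_cell for p in points])  # fmol/CFU
    y = np.array([p.lag_time for p in points])  # day
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct doses")
    sy = rel_err * np.abs(y)
    sx = dose_rel_err * x
    if np.all(sy == 0) and np.all(sx == 0):
        sy = np.full_like(y, 1e-12)
    if through_origin:
        slope, slope_se = fit_through_origin(x, y, sx, sy)
    else:
        pts = [WeightedPoint(float(a), float(b), float(c), float(d))
               for a, b, c, d in zip(x, y, sx, sy)]
        fit = fit_weighted_line(pts)
        slope, slope_se = fit.slope_b, fit.se_b
    if slope <= 0:
        raise ValueError("maintenance inversion failure: non-positive slope")
    beta = 1.0 / slope
    se = slope_se / slope**2
    return beta, se


# ---------------------------------------------------------- consistency ----

def fold_change_consistency(records: Sequence[PhysiologyRecord],
                            reference_label: str):
    """Fold changes of gamma versus beta/alpha relative to a reference.

    Returns (table, score): ``table`` is a list of dicts with per-record
    FC(gamma) and FC(beta)/FC(alpha); ``score`` is the maximum relative
    deviation from the unity line FC(gamma) = FC(beta)/FC(alpha).
    """
    ref = next((r for r in records if r.condition.label == reference_label), None)
    if ref is None:
        raise ValueError(f"missing reference condition {reference_label!r}")
    rows = []
    devs = []
    for r in records:
        fc_gamma = r.gamma_per_day / ref.gamma_per_day
        fc_ba = (r.beta / ref.beta) / (r.alpha / ref.alpha)
        rows.append({
            "condition": r.condition.label,
            "FC_gamma": fc_gamma,
            "FC_beta_over_FC_alpha": fc_ba,
        })
        devs.append(abs(fc_ba / fc_gamma - 1.0))
    return rows, max(devs)


# ------------------------------------------------------------ unit maps ----

def glycerol_to_atp(beta: float, atp_per_glycerol: float = 15.0,
                    dry_mass_per_od_ug_per_ml: float = 509.0,
                    cfu_per_od_per_ml: float = 1e9) -> float:
    """Convert a maintenance rate to mmol ATP (g dry weight)^-1 h^-1.

    ``beta`` is in fmol glycerol day^-1 CFU^-1.  Conversion uses an ATP
    yield per glycerol molecule, a dry mass per OD600 (ug ml^-1 OD^-1) and
    a viable-cell density per OD600 (CFU ml^-1 OD^-1).
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    mol_per_cfu_h = beta * 1e-15 / HOURS_PER_DAY
    mol_per_ml_od_h = mol_per_cfu_h * cfu_per_od_per_ml
    g_dw_per_ml_od = dry_mass_per_od_ug_per_ml * 1e-6
    mol_atp_per_gdw_h = mol_per_ml_od_h * atp_per_glycerol / g_dw_per_ml_od
    return mol_atp_per_gdw_h * 1e3  # mmol


def dead_cells_per_new_cell(alpha: float) -> int:
    """Number of dead cells needed to produce one new viable cell."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return round(1.0 / alpha)
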