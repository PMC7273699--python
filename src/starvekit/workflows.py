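"""End-to-end analysis pipelines: simulate, fit rates, fit scalings,
run assays, normalize by volume, and evaluate the worked arithmetic.

These compose the library modules into the recovery experiments the
command-line interface exposes: generate a synthetic dataset from the
measured scaling relations, push it through the same inference machinery a
real dataset would use, and return the fitted relation next to the
generating truth.
"""

from __future__ import annotations

import math

import numpy as np

from . import assays, feast_famine, kinetics, morphology, synthetic_data
from .kinetics import GrowthCondition
from .regression import ScalingFit, fit_weighted_line, log_transform_points
from .synthetic_data import GeneratorConfig

#: growth rates of the chemostat assay series (h^-1)
CHEMOSTAT_PANEL = (0.1, 0.3, 0.5, 0.7, 0.9)


def _rng(cfg: GeneratorConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed, salt))


def recover_growth_death(cfg: GeneratorConfig, conditions=None,
                         mode: str = "batch"):
    """Simulate a growth/starvation panel and refit gamma(mu).

    Death rates come from replicate viability fits (mean +/- replicate SD);
    growth rates from OD fits (batch) or the chemostat dial with 5% pump
    error.  Returns (ScalingFit, dataset).
    """
    ds = synthetic_data.gen_growth_death_dataset(
        conditions, cfg, mode=mode, rng=_rng(cfg, 1))
    death = kinetics.rates_from_dataset(ds["viability_courses"])
    growth = kinetics.rates_from_dataset(ds["od_courses"])

    x, y, sx, sy = [], [], [], []
    for cond in ds["conditions"]:
        g = death[cond.label]
        if mode == "chemostat":
            mu, smu = cond.mu, cond.sigma_mu
        else:
            mu_est = growth[cond.label]
            mu, smu = mu_est.rate, mu_est.se
        x.append(mu)
        sx.append(smu)
        y.append(g.per_day)
        sy.append(g.se_per_day)
    fit = fit_weighted_line(log_transform_points(x, y, sx, sy))
    return fit, ds


def measure_yield_per_condition(cfg: GeneratorConfig, mus=CHEMOSTAT_PANEL):
    """(mu, alpha, se) per condition from simulated regrowth assays."""
    rng = _rng(cfg, 2)
    out = []
    for mu in mus:
        pts = synthetic_data.gen_yield_assay(mu, cfg, rng=rng)
        alpha, se = assays.recycling_yield(pts)
        out.append((mu, alpha, se))
    return out


def measure_maintenance_per_condition(cfg: GeneratorConfig,
                                      mus=CHEMOSTAT_PANEL):
    """(mu, beta, se) per condition from simulated glycerol-spike assays."""
    rng = _rng(cfg, 3)
    out = []
    for mu in mus:
        pts = synthetic_data.gen_maintenance_assay(mu, cfg, rng=rng)
        beta, se = assays.maintenance_rate(pts)
        out.append((mu, beta, se))
    return out


def measure_volume_per_condition(cfg: GeneratorConfig, mus=CHEMOSTAT_PANEL,
                                 n_cells: int = 300):
    """(mu, VolumeStat) per condition from simulated cell-size samples."""
    rng = _rng(cfg, 4)
    out = []
    for mu in mus:
        sample = synthetic_data.gen_cellsize_sample(mu, cfg, n=n_cells,
                                                    rng=rng)
        out.append((mu, morphology.sample_volume(sample)))
    return out


def _fit_scaling(rows, cfg: GeneratorConfig, chemostat: bool = True) -> ScalingFit:
    """Weighted log-linear fit of (mu, value, se) rows versus growth rate."""
    x = [r[0] for r in rows]
    y = [r[1] for r in rows]
    sy = [r[2] for r in rows]
    sx = [cfg.chemostat_mu_cv * m if chemostat else 0.0 for m in x]
    return fit_weighted_line(log_transform_points(x, y, sx, sy))


def recover_yield_relation(cfg: GeneratorConfig, mus=CHEMOSTAT_PANEL):
    rows = measure_yield_per_condition(cfg, mus)
    return _fit_scaling(rows, cfg), rows


def recover_maintenance_relation(cfg: GeneratorConfig, mus=CHEMOSTAT_PANEL):
    rows = measure_maintenance_per_condition(cfg, mus)
    return _fit_scaling(rows, cfg), rows


def recover_volume_relation(cfg: GeneratorConfig, mus=CHEMOSTAT_PANEL,
                            n_cells: int = 300):
    rows = measure_volume_per_condition(cfg, mus, n_cells)
    flat = [(mu, v.mean_volume, v.se) for mu, v in rows]
    return _fit_scaling(flat, cfg), rows


def recover_normalized_maintenance(cfg: GeneratorConfig, mus=CHEMOSTAT_PANEL):
    """Volume-normalized maintenance scaling: beta/V versus growth rate.

    Divides the per-condition maintenance rates by the per-condition mean
    volumes (same growth-rate panel, independent simulated experiments),
    propagates errors in quadrature, and refits.  The generating slope is
    the difference of the maintenance and volume slopes.
    """
    beta_rows = measure_maintenance_per_condition(cfg, mus)
    vol_rows = measure_volume_per_condition(cfg, mus)
    rows = []
    for (mu, beta, se), (_, vstat) in zip(beta_rows, vol_rows):
        val, val_se = morphology.normalize_by_volume(beta, se, vstat)
        rows.append((mu, val, val_se))
    return _fit_scaling(rows, cfg), rows


def recover_normalized_yield(cfg: GeneratorConfig, mus=CHEMOSTAT_PANEL):
    """Volume-normalized recycling yield versus growth rate."""
    a_rows = measure_yield_per_condition(cfg, mus)
    vol_rows = measure_volume_per_condition(cfg, mus)
    rows = []
    for (mu, alpha, se), (_, vstat) in zip(a_rows, vol_rows):
        val, val_se = morphology.normalize_by_volume(alpha, se, vstat)
        rows.append((mu, val, val_se))
    return _fit_scaling(rows, cfg), rows


def physiology_records(cfg: GeneratorConfig, mus=CHEMOSTAT_PANEL,
                       gamma_rel_err: float = 0.10):
    """Per-condition (gamma, alpha, beta) records for the consistency check.

    In coherent generator mode the underlying truth satisfies
    gamma = beta/alpha exactly; measured values scatter around it.
    """
    rng = _rng(cfg, 5)
    a_rows = measure_yield_per_condition(cfg, mus)
    b_rows = measure_maintenance_per_condition(cfg, mus)
    records = []
    for (mu, alpha, a_se), (_, beta, b_se) in zip(a_rows, b_rows):
        g_true = cfg.gamma_true(mu)
        g_obs = g_true * float(
            synthetic_data.lognormal_factors(rng, gamma_rel_err, 1)[0])
        cond = GrowthCondition(f"mu{mu:.3f}", mu, "chemostat")
        records.append(assays.PhysiologyRecord(
            cond, g_obs, gamma_rel_err * g_obs, alpha, a_se, beta, b_se))
    return records


# ------------------------------------------------------ worked examples ----

def worked_examples(rel_tol: float | None = None):
    """Recompute the study's printed arithmetic and compare to the printed
    values.

    The default tolerance is agreement at two significant digits (relative
    difference below 5%), which accommodates the rounding of the printed
    numbers; a tight ``rel_tol`` (e.g. 1e-6) makes the rounded entries fail
    while exact ones still pass.  Returns a list of dict rows
    (name, computed, printed, passed).
    """
    if rel_tol is None:
        rel_tol = 0.05
    rel = feast_famine.TradeoffRelation(0.21, 1.0)
    sc = feast_famine.FeastFamineScenario(3.0, 144.0)
    mu_star, gamma_star = feast_famine.optimal_growth_rate(sc, rel)
    rows = [
        ("atp_maintenance_mmol_per_gdw_h", assays.glycerol_to_atp(0.5), 0.61),
        ("glycerol_dose_fmol_per_cfu", assays.dose_per_cell(40.0, 1.21e8), 0.33),
        ("dead_cells_per_new_cell", float(assays.dead_cells_per_new_cell(0.12)), 8.0),
        ("optimal_growth_rate_per_h", mu_star, 0.86),
        ("optimal_death_rate_per_day", gamma_star, 0.5),
        ("tradeoff_log_constant", feast_famine.log_constant(rel), 114.0),
    ]
    out = []
    for name, computed, printed in rows:
        passed = abs(computed - printed) <= rel_tol * abs(printed)
        out.append({"name": name, "computed": computed, "printed": printed,
                    "passed": passed})
    return out
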