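"""Flux-controlled regulation (FCR) model of proteome remodeling during
nutrient depletion, and the death rate predicted from the final proteome
state.

The model tracks total protein mass M, ribosomal mass M_Rb and one
catabolic mass M_cat,j per nutrient.  Carbon influx is

    J(t) = sum_j k_j(c_j) * M_cat,j(t),      k(c) = k_max * c / (c + K_M),

and drives biomass growth dM/dt = J.  The translational activity
sigma = J / R (R = M_Rb) sets the regulation functions

    chi_R(sigma)   = phi_Rb0 / (1 - sigma/gamma_t)
    chi_Cat(sigma) = 1 - sigma * chi_R(sigma) / lambda_C   (clipped at 0),

which partition new protein synthesis: dM_Rb/dt = chi_R * J and
dM_cat,j/dt = h_j * chi_Cat * J.  Nutrients are measured in
biomass-equivalent units (yield 1, culture volume 1) so that
dc_j/dt = -k_j(c_j) * M_cat,j and biomass gained equals nutrient consumed.

Because proteome sectors vary linearly with steady-state growth rate,
phi_X = phi_X0 + mu * phi_X', the instantaneous "proteome adaptation"
(phi_X - phi_X0)/phi_X' (ribosomal sector, phi_X' = 1/gamma_t) equals the
steady-state growth rate whose proteome matches the current composition.
Mapping the adaptation state after depletion through the measured
growth-death trade-off predicts the starvation death rate,

    gamma = 0.21 day^-1 * exp(1.0 h * (phi_X - phi_X0)/phi_X').
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .feast_famine import TradeoffRelation


@dataclass(frozen=True)
class FCRParams:
    """FCR model constants.

    lambda_C is the C-line intercept (this system, 1.17 h^-1); gamma_t
    (maximal translation rate, h^-1) and phi_Rb0 (ribosomal fraction
    extrapolated to zero growth) come from the source FCR parameterization
    and are configurable.  death_* parameterize the growth-death trade-off.
    """

    lambda_C: float = 1.17
    gamma_t: float = 11.02
    phi_Rb0: float = 0.049
    death_a_per_day: float = 0.21
    death_b_h: float = 1.0
    allocation_h: tuple = (1.0,)

    def __post_init__(self):
        if not 0 < self.phi_Rb0 < 1:
            raise ValueError("phi_Rb0 must be in (0, 1)")
        if self.gamma_t <= self.lambda_C:
            raise ValueError("gamma_t must exceed lambda_C")
        h = np.asarray(self.allocation_h, float)
        if np.any(h < 0) or not math.isclose(h.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("allocation_h must be nonnegative and sum to 1")
        object.__setattr__(self, "allocation_h", tuple(float(v) for v in h))

    @property
    def tradeoff(self) -> TradeoffRelation:
        return TradeoffRelation(self.death_a_per_day, self.death_b_h)


@dataclass(frozen=True)
class NutrientPool:
    """Nutrient concentrations (biomass-equivalent units) and kinetics."""

    c: tuple  # current concentrations
    K_M: tuple  # Michaelis constants, same units
    k_max: tuple  # h^-1 per unit catabolic protein mass

    def __post_init__(self):
        c = np.asarray(self.c, float)
        km = np.asarray(self.K_M, float)
        km_ = np.asarray(self.k_max, float)
        if not (c.shape == km.shape == km_.shape):
            raise ValueError("pool arrays must have equal lengths")
        if np.any(c < 0) or np.any(km <= 0) or np.any(km_ <= 0):
            raise ValueError("invalid pool values")
        object.__setattr__(self, "c", tuple(float(v) for v in c))
        object.__setattr__(self, "K_M", tuple(float(v) for v in km))
        object.__setattr__(self, "k_max", tuple(float(v) for v in km_))

    @property
    def n(self) -> int:
        return len(self.c)


@dataclass(frozen=True)
class FCRState:
    """Protein masses at time t; other sectors fill M beyond Rb + cat."""

    M: float
    M_Rb: float
    M_cat: tuple
    t: float = 0.0


@dataclass(frozen=True)
class FCRTrajectory:
    """Time series of an FCR depletion simulation."""

    t: np.ndarray  # h
    M: np.ndarray
    phi_Rb: np.ndarray
    phi_cat: np.ndarray  # total catabolic fraction
    c: np.ndarray  # (n_nutrients, n_times)
    J: np.ndarray
    sigma: np.ndarray
    mu_inst: np.ndarray
    adaptation: np.ndarray  # h^-1
    gamma_pred: np.ndarray  # day^-1

    @property
    def final_adaptation(self) -> float:
        return float(self.adaptation[-1])

    @property
    def final_gamma(self) -> float:
        return float(self.gamma_pred[-1])


# ------------------------------------------------------------- kinetics ----

def uptake_rate(c, k_max, K_M):
    """Michaelis-Menten uptake rate k(c) = k_max * c / (c + K_M)."""
    c = np.asarray(c, float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    return k_max * c / (c + K_M)


def regulation_functions(sigma: float, params: FCRParams):
    """(chi_R, chi_Cat) at translational activity sigma.

    chi_Cat is clipped at 0; the remaining synthesis share goes implicitly
    to unmodeled sectors.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma >= params.gamma_t:
        raise ValueError("translation capacity exceeded: sigma >= gamma_t")
    chi_R = params.phi_Rb0 / (1.0 - sigma / params.gamma_t)
    chi_Cat = max(0.0, 1.0 - sigma * chi_R / params.lambda_C)
    return chi_R, chi_Cat


def steady_state_sigma(mu0: float, params: FCRParams) -> float:
    """Translational activity at steady-state growth mu0.

    Solves mu0 = sigma * chi_R(sigma) in closed form.
    """
    if mu0 <= 0:
        raise ValueError("mu0 must be positive")
    if mu0 >= params.lambda_C:
        raise ValueError(
            f"infeasible mu0: must be in (0, {params.lambda_C}) h^-1")
    return mu0 / (params.phi_Rb0 + mu0 / params.gamma_t)


def adaptation_state(phi_Rb: float, params: FCRParams) -> float:
    """Proteome adaptation (phi_X - phi_X0)/phi_X' of the ribosomal sector.

    Equals the steady-state growth rate whose proteome composition matches
    phi_Rb (phi_X' = 1/gamma_t).
    """
    return params.gamma_t * (phi_Rb - params.phi_Rb0)


def death_from_adaptation(state_value: float, params: FCRParams) -> float:
    """Predicted death rate (day^-1) from a proteome adaptation state."""
    return params.death_a_per_day * math.exp(params.death_b_h * state_value)


def init_steady_state(mu0: float, params: FCRParams, M0: float = 1.0) -> FCRState:
    """Steady-state proteome composition for balanced growth at mu0.

    Sector fractions are the regulation-function fixed point: with
    saturating nutrient and matched uptake rates, integrating leaves the
    fractions constant.
    """
    sigma0 = steady_state_sigma(mu0, params)
    chi_R, chi_Cat = regulation_functions(sigma0, params)
    h = np.asarray(params.allocation_h)
    return FCRState(
        M=M0,
        M_Rb=chi_R * M0,
        M_cat=tuple(float(v) for v in h * chi_Cat * M0),
        t=0.0,
    )


# ------------------------------------------------------------ simulator ----

def simulate_depletion(state0: FCRState, pool: NutrientPool,
                       params: FCRParams, t_end: float = 48.0,
                       rtol: float = 1e-8, n_out: int = 400) -> FCRTrajectory:
    """Integrate the FCR model until nutrients are exhausted.

    Terminates when every c_j < 1e-6 * max(K_M) or at t_end.  Mass
    conservation (biomass gained = nutrient consumed) holds to the
    integration tolerance.
    """
    n = pool.n
    h = np.asarray(params.allocation_h)
    if h.size != n:
        raise ValueError("allocation_h length must match pool size")
    k_max = np.asarray(pool.k_max)
    K_M = np.asarray(pool.K_M)
    c_floor = 1e-6 * float(np.max(K_M))

    def fluxes(y):
        M, M_Rb = y[0], y[1]
        M_cat = y[2:2 + n]
        c = np.maximum(y[2 + n:], 0.0)
        k = k_max * c / (c + K_M)
        per_nutrient = k * M_cat
        J = float(np.sum(per_nutrient))
        sigma = J / M_Rb
        return M, M_Rb, M_cat, c, per_nutrient, J, sigma

    def rhs(t, y):
        _, _, _, _, per_nutrient, J, sigma = fluxes(y)
        chi_R, chi_Cat = regulation_functions(sigma, params)
        dy = np.empty_like(y)
        dy[0] = J
        dy[1] = chi_R * J
        dy[2:2 + n] = h * chi_Cat * J
        dy[2 + n:] = -per_nutrient
        return dy

    def depleted(t, y):
        return float(np.max(y[2 + n:])) - c_floor

    depleted.terminal = True
    depleted.direction = -1

    y0 = np.concatenate(
        [[state0.M, state0.M_Rb], np.asarray(state0.M_cat), np.asarray(pool.c)]
    )
    sol = solve_ivp(
        rhs, (state0.t, state0.t + t_end), y0, method="LSODA",
        rtol=rtol, atol=1e-10 * max(1.0, float(np.max(y0))),
        events=depleted, dense_output=True, max_step=t_end,
    )
    if not sol.success:
        raise RuntimeError(f"integration failure: {sol.message}")

    t_stop = sol.t[-1]
    ts = np.linspace(state0.t, t_stop, n_out)
    Y = sol.sol(ts)

    M = Y[0]
    M_Rb = Y[1]
    M_cat = Y[2:2 + n]
    c = np.maximum(Y[2 + n:], 0.0)
    k = k_max[:, None] * c / (c + K_M[:, None])
    J = np.sum(k * M_cat, axis=0)
    sigma = J / M_Rb
    phi_Rb = M_Rb / M
    phi_cat = np.sum(M_cat, axis=0) / M
    adapt = params.gamma_t * (phi_Rb - params.phi_Rb0)
    gamma = params.death_a_per_day * np.exp(params.death_b_h * adapt)
    return FCRTrajectory(ts, M, phi_Rb, phi_cat, c, J, sigma, J / M,
                         adapt, gamma)


def mass_balance_error(traj: FCRTrajectory) -> float:
    """Relative violation of biomass gained == nutrient consumed."""
    gained = traj.M - traj.M[0]
    consumed = np.sum(traj.c[:, :1] - traj.c, axis=0)
    scale = max(float(traj.M[-1] - traj.M[0]), 1e-30)
    return float(np.max(np.abs(gained - consumed)) / scale)


# ------------------------------------------------------------ scenarios ----

def sequential_uptake_rates(N: int, lambda_max: float, params: FCRParams,
                            printed_indexing: bool = False):
    """Uptake rates for N sequentially depleted nutrients.

    Chosen so that the plateau growth rate on the remaining nutrients
    m..N decreases linearly: lambda_(m->N) = lambda_max * (N - m + 1)/N
    (so the final plateau is lambda_max/N).  Backward recursion:

        k_m = lambda_(m->N) / (1 - lambda_(m->N)/lambda_C) - sum_{j>m} k_j.

    ``printed_indexing`` selects the (N - m - 1)/N variant instead, which
    assigns a nonpositive rate to the last nutrient and is kept only for
    comparison.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if lambda_max >= params.lambda_C:
        raise ValueError("C-line violation: lambda_max must be < lambda_C")
    ks = np.zeros(N)
    tail = 0.0
    for m in range(N, 0, -1):
        if printed_indexing:
            lam = lambda_max * (N - m - 1) / N
        else:
            lam = lambda_max * (N - m + 1) / N
        if lam >= params.lambda_C:
            raise ValueError("C-line violation: plateau rate >= lambda_C")
        total = lam / (1.0 - lam / params.lambda_C) if lam != 0 else 0.0
        ks[m - 1] = total - tail
        tail = total
    return ks


def depletion_scenario(N: int, K_M_uM: float, c0_total_uM: float = 5000.0,
                       mu0: float = 0.9, params: FCRParams | None = None,
                       n_doublings: float = 3.0):
    """Assemble (state0, pool, params) for an entry-into-starvation run.

    Nutrients share the total supply equally and are measured in
    biomass-equivalent units: the initial biomass M0 = 1 is chosen so the
    full supply sustains ``n_doublings`` doublings.  Per-sector uptake
    rates are the sequential-recursion rates divided by the allocation
    fractions h_j (so plateau growth rates follow the linear ladder), with
    a Michaelis-Menten correction so the initial growth rate equals mu0
    exactly despite finite initial saturation.
    """
    if params is None:
        params = FCRParams()
    params = replace(params, allocation_h=tuple([1.0 / N] * N))
    M0 = 1.0
    supply = (2.0**n_doublings - 1.0) * M0  # biomass-equivalent units
    unit_per_uM = supply / c0_total_uM
    c0 = np.full(N, supply / N)
    K_M = np.full(N, K_M_uM * unit_per_uM)

    k_rec = sequential_uptake_rates(N, mu0, params)
    h = np.asarray(params.allocation_h)
    k_max = k_rec / h
    # initial-saturation correction: k(c0) recovers the recursion rate
    k_max = k_max * (c0 + K_M) / c0

    state0 = init_steady_state(mu0, params, M0=M0)
    pool = NutrientPool(tuple(c0), tuple(K_M), tuple(k_max))
    return state0, pool, params


def below_affinity_share(traj: FCRTrajectory, pool: NutrientPool,
                         nutrient: int = 0) -> float:
    """Fraction of a nutrient's supply consumed after c falls below K_M."""
    c = traj.c[nutrient]
    c0 = c[0]
    km = pool.K_M[nutrient]
    if c[-1] >= km:
        return 0.0
    # c is continuous and decreasing, so it crosses K_M exactly
    c_cross = min(c0, km)
    return float((c_cross - c[-1]) / c0)


def scenario_death_rates(single_K_M_uM=(10.0, 100.0, 1000.0),
                         multi_N=(1, 2, 10), multi_K_M_uM: float = 100.0,
                         mu0: float = 0.9, c0_total_uM: float = 5000.0,
                         params: FCRParams | None = None,
                         t_end: float = 200.0):
    """Predicted death rates for the single- and multi-nutrient scenarios.

    Returns a list of dict rows (scenario, K_M_uM, N, final_adaptation,
    gamma_pred_per_day).  Lower affinity (larger K_M) and more sequential
    nutrients both allow more proteome adaptation and lower death rates.
    """
    rows = []
    for km in single_K_M_uM:
        s0, pool, p = depletion_scenario(1, km, c0_total_uM, mu0, params)
        traj = simulate_depletion(s0, pool, p, t_end=t_end)
        rows.append({
            "scenario": "single", "K_M_uM": km, "N": 1,
            "final_adaptation": traj.final_adaptation,
            "gamma_pred_per_day": traj.final_gamma,
        })
    for N in multi_N:
        s0, pool, p = depletion_scenario(N, multi_K_M_uM, c0_total_uM,
                                         mu0, params)
        traj = simulate_depletion(s0, pool, p, t_end=t_end)
        rows.append({
            "scenario": "multi", "K_M_uM": multi_K_M_uM, "N": N,
            "final_adaptation": traj.final_adaptation,
            "gamma_pred_per_day": traj.final_gamma,
        })
    return rows
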