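# Methods

This note documents the models implemented in `starvekit`, their
assumptions, the defaults and why, and the numerical choices made where
the design was genuinely open.

## Scaling regressions with errors in both coordinates

All scaling relations (death rate, recycling yield, maintenance rate,
cell volume versus growth rate) are straight-line fits after a log
transform of the ordinate, y = a + bx. Because both the growth rate and
the observable carry measurement error, the fit minimizes the
effective-variance chi-square

    χ²(a, b) = Σᵢ (yᵢ − a − bxᵢ)² / (σ²_{y,i} + b² σ²_{x,i}),

the standard straight-line estimator for data with errors in both
coordinates (Press et al.). The b² factor in the denominator is required
for dimensional consistency. Native-scale standard deviations are mapped
to log space by the delta method, σ_log y = σ_y / y.

Numerics: because the weights depend on b, a plain weighted least-squares
iteration (fit → recompute weights → refit, converged at |Δb| < 10⁻⁹) is
used only as the starting point; it is a fixed point of the *reweighted*
normal equations, not of the full χ², so the profiled χ²(b) (a eliminated
analytically) is always refined by 1-D bounded Brent minimization. The
unit tests verify agreement with an exhaustive zooming grid search to
10⁻⁴.

Parameter uncertainties are Δχ² = 1 profile errors: the half-width of the
interval over which the profiled chi-square (the other parameter
re-minimized, not frozen) rises by 1; the two half-intervals are
symmetrized by taking the larger, matching the single ± convention of the
reported relations. Goodness of fit is Q = Γ_reg(dof/2, χ²/2), the
probability that a χ² at least this poor arises by chance; in the linear
Gaussian case (no x-errors) this is exact, with x-errors it is the usual
effective-variance approximation, which the test suite shows to be
uniformly calibrated at the study noise levels (10% relative on
observables, 5% on growth rates).

Degenerate inputs: fewer than 3 points and all-identical abscissae are
rejected; collinear points return χ² = 0, Q = 1 exactly.

## Rate estimation and aggregation

Growth (OD600) and death (CFU) time courses are fitted by unweighted
least squares on the log scale — no per-point weighting is justified for
plate counts with roughly constant coefficient of variation, and
replicate-to-replicate scatter dominates. Replicates are fitted
separately and averaged; the reported uncertainty is one *sample standard
deviation* across replicates (not the standard error of the mean),
matching how the per-condition rates are reported. Death decays are
modeled as single exponentials throughout; lag or shoulder behavior would
surface as a poor fit, not be silently removed. Internal time unit is
hours; death rates are reported per day (×24, exact).

## Assay inference

**Recycling yield α** is the slope of absolute regrowth yield
(max N_G − min N_G) versus viability at extraction. **Maintenance rate
β** is the inverse slope of glycerol-spike lag time versus dose per cell.
Both slopes are fitted *through the origin* with effective-variance
weights: the defining models (yield ∝ viability; T = s/β) have no offset.
An intercept-allowing variant is available behind a flag for sensitivity
analysis. All CFU-derived quantities default to 10% relative uncertainty
(plate-counting error), overridable per point; with a single assay point
the ratio definition is used and the two 10% errors combine in
quadrature.

Lag times are computed as T = ln⟨N_gly/N⟩/γ, where the brackets average
the viability *ratio* (not the log-ratio) over the window in which the
spiked culture has resumed exponential decay. The window is detected as
the points whose local log-slope (central differences) is within 20%
(configurable) of the control's death rate; if no point qualifies the
second half of the course is used as a fallback.

The consistency check compares fold changes FC(γ) against
FC(β)/FC(α) relative to a reference condition and scores the maximum
relative deviation from the unity line.

Unit conversions (dose per cell in fmol CFU⁻¹; maintenance rate to
mmol ATP (g dry weight)⁻¹ h⁻¹ via 15 ATP per glycerol, 509 μg dry mass
ml⁻¹ OD⁻¹ and 10⁹ CFU ml⁻¹ OD⁻¹) are centralized and exact.

## Cell volumes

Rods are modeled as spherocylinders, V = π(w/2)²(l − w) + (4/3)π(w/2)³.
The population volume is the mean of per-cell volumes — not the volume of
the mean cell, which differs for skewed samples — and its uncertainty
combines the sampling standard error with a 5% relative instrument error
in quadrature. Samples below 200 cells trigger a warning (not an error);
the generator default is 300 cells. Normalization of condition-level
quantities by mean volume divides the means and adds relative errors in
quadrature; no cell-by-cell pairing exists because volume and assay
measurements come from different experiments.

## Feast–famine fitness

Fitness per cycle is f = μT₊ − γ(μ)T₋ with γ(μ) = a·exp(bμ), defaults
a = 0.21 day⁻¹, b = 1.0 h. f is strictly concave in μ, with interior
optimum μ* = (1/b)·ln(T₊/(abT₋)) and γ(μ*) = T₊/(bT₋). At the defaults
1/(ab) = 114.29, so μ* = 1.0 h⁻¹ · ln(114·T₊/T₋) to printed precision.
When the famine-to-feast ratio exceeds 1/(ab) the argument of the
logarithm drops below 1 and the optimum clamps to μ* = 0 — a defined
regime, reported as such. All internal arithmetic is in hours; day-based
rates are converted at the boundary (death-rate prefactors are day⁻¹
throughout, consistent with the measured rates).

## FCR proteome-adaptation simulator

State: total protein M, ribosomal mass M_Rb, one catabolic mass M_cat,j
per nutrient, and nutrient concentrations c_j in biomass-equivalent units
(yield 1, culture volume 1), so dM/dt = J = Σ k_j(c_j)·M_cat,j exactly
and biomass gained equals nutrient consumed. Uptake is Michaelis–Menten,
k(c) = k_max·c/(c + K_M). The translational activity σ = J/R with
R ≡ M_Rb (total ribosome abundance) sets the regulation functions
χ_R(σ) = φ_Rb,0/(1 − σ/γ_t) and χ_Cat(σ) = 1 − σχ_R/λ_C, which partition
protein synthesis: dM_Rb/dt = χ_R·J, dM_cat,j/dt = h_j·χ_Cat·J. χ_Cat is
clipped at 0 (no negative synthesis); the remaining share implicitly
feeds unmodeled sectors, whose dynamics are irrelevant here.

Constants: λ_C = 1.17 h⁻¹ (C-line intercept, this system); γ_t =
11.02 h⁻¹ and φ_Rb,0 = 0.049 from the source parameterization of the FCR
model, both configurable. Allocation fractions h_j are uniform 1/N by
default (they are not constrained by the data).

The **adaptation state** is (φ_Rb − φ_Rb,0)/φ_Rb′ with φ_Rb′ = 1/γ_t: at
steady state it equals the growth rate, and after a downshift it is the
steady-state growth rate whose proteome matches the current composition.
One representative sector suffices because global regulation gives all
sectors near-identical adaptation dynamics. The predicted death rate is
γ = 0.21 day⁻¹·exp(1.0 h · adaptation), the measured trade-off evaluated
at the adaptation state.

Steady-state initialization solves μ₀ = σ·χ_R(σ) in closed form,
σ₀ = μ₀/(φ_Rb,0 + μ₀/γ_t), and sets φ_Rb = χ_R(σ₀), φ_cat,j = h_j·χ_Cat(σ₀);
feasible for μ₀ < λ_C.

**Sequential nutrients.** Uptake rates are chosen so the plateau growth
rate on the remaining nutrients m..N decreases linearly,
λ_(m→N) = λ_max·(N − m + 1)/N (final plateau λ_max/N), via the backward
recursion k_m = λ_(m→N)/(1 − λ_(m→N)/λ_C) − Σ_{j>m} k_j. The (N − m − 1)
index variant, which assigns a nonpositive rate to the last nutrient, is
kept behind a flag for comparison only. Because the recursion defines
*sector-level* rates (Σ_{j≥m} k_j = λ/(1 − λ/λ_C)) while synthesis is
split as h_j·χ_Cat, scenario assembly converts to per-unit-mass rates
k_max,j = k_j/h_j; this makes the initial steady state at λ_max
self-consistent and reproduces the plateau ladder. A Michaelis–Menten
correction factor (c₀ + K_M)/c₀ is applied so the *initial* growth rate
equals μ₀ exactly despite finite initial saturation, making scenarios
with different K_M start from identical states.

Scenario units: concentrations are configured in μM and rescaled to
biomass-equivalent units such that the total supply sustains 3 doublings
of the initial biomass (configurable); only the ratios c₀/K_M and
supply/M₀ matter.

Integration: `scipy.integrate.solve_ivp` (LSODA, rtol 10⁻⁸), terminated
by an event when every c_j < 10⁻⁶·max(K_M); c never crosses zero because
dc/dt ∝ −c near depletion. Mass conservation holds to ~10⁻¹⁵ relative in
practice (tolerance asserted: 10⁻⁶). The below-affinity nutrient share
uses the exact crossing value c = K_M (c is continuous and decreasing),
so for K_M = 1 mM and c₀ = 5 mM it equals K_M/c₀ = 1/5 up to the
depletion threshold.

## Synthetic data generator

The generator emulates the statistical structure of the study's
per-condition data; its defaults *are* the study conditions:

| quantity | generating relation / level |
| --- | --- |
| death rate (WT batch) | γ = 0.23 day⁻¹·exp(0.87 h·μ) |
| death slope (ΔrpoS variant) | 0.57 h |
| recycling yield | α = 0.11·exp(0.78 h·μ) |
| maintenance rate | β = 0.14 fmol day⁻¹ CFU⁻¹·exp(1.88 h·μ) |
| mean volume | V = 0.43 μm³·exp(0.88 h·μ) |
| length / width slopes | 0.23 h / 0.32 h |
| plating noise | 10% CV, lognormal multiplicative |
| chemostat pump error | 5% CV on the realized growth rate |
| single-cell size dispersion | lognormal, CV 0.2 (not constrained by data) |
| replicates | 3; viability sampled 8 points over 7 days |
| growth-rate panel | 13 values log-spaced in 0.15–1.9 h⁻¹ |

Noise is mean-preserving lognormal (μ_log = ln m − s²/2) so recovery
tests are unbiased; plate counts are positive with roughly constant CV,
which the lognormal captures. Chemostat conditions treat the dial value
as the known abscissa (5% uncertainty) and jitter the *realized* growth
rate — the causal structure of pump error. Cell-size samples anchor the
analytic mean spherocylinder volume exactly to the volume relation at
each growth rate via a common cube-root scale factor; base dimensions
(≈1.6 × 0.63 μm at μ → 0) are realistic for starved cells. The
independently measured yield/maintenance/death relations are only
approximately consistent with γ = β/α, so by default the generator uses
them as printed; a `coherent` flag derives the death relation from
β/α exactly (used by the unity-line consistency tests).

What the generator does **not** emulate: integer colony-count (Poisson)
statistics, biphasic decays, mutant takeover at long times, correlations
between assays of the same condition. Passing recovery tests therefore
demonstrate correctness of the inference chain under the stated noise
model, not robustness to those real-data features.

Problem sizes: recovery experiments (tests and the acceptance script)
use the default 13-condition panel with the default assay designs
(3 extractions; 4 glycerol doses; 300 cells), which makes every pipeline
run complete in seconds.

## Known limitations

* The regression engine profiles each parameter (re-minimizing the
  other) rather than using the joint Δχ² = 1 contour; both conventions
  exist, profiling matches the quoted single-parameter errors.
* Whether the yield/maintenance slope fits should allow an intercept is
  not decidable from the available description; through-origin is the
  model-consistent default, the flag covers the alternative.
* The FCR simulator omits cAMP/ppGpp signaling, protein degradation and
  stochastic single-cell effects; it addresses population-average
  proteome allocation only.
* "1/5 doubling" of growth below affinity is ambiguous between the
  nutrient-share and log₂-growth readings; the nutrient-share reading is
  exact and is what the simulator reports (log₂ growth is available from
  the trajectory).
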