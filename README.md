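# starvekit

Quantitative analysis of the growth–death trade-off of carbon-starved
bacteria. When an *Escherichia coli* culture is abruptly deprived of its
carbon source, the density of viable cells decays exponentially, and the
death rate γ depends on the growth rate μ the culture sustained *before*
starvation: slower growth leads to exponentially slower death,

    γ(μ) = a · exp(b · μ),        a ≈ 0.21–0.23 day⁻¹,  b ≈ 0.9–1.1 h.

Mechanistically the death rate is the ratio of two measurable quantities,

    γ = β / α,

where β is the **maintenance rate** (nutrient a viable cell must consume
per day to stay alive, fmol glycerol day⁻¹ CFU⁻¹) and α is the
**recycling yield** (fraction of a dead cell's biomass that viable cells
can scavenge into new cells). `starvekit` implements the full analysis
chain around these laws for quantitative microbial physiologists:

* **`regression`** — weighted straight-line fits of log-transformed data
  with uncertainties in *both* coordinates (effective-variance χ²,
  Δχ² = 1 profile errors, goodness of fit Q); the engine behind every
  exponential scaling relation here.
* **`kinetics`** — growth and death rates from OD600 / CFU time courses,
  replicate aggregation.
* **`assays`** — recycling yield from UV-kill regrowth assays, maintenance
  rate from glycerol-spike lag times (T = ln⟨N_gly/N⟩/γ), the
  FC(γ) = FC(β)/FC(α) consistency check, and ATP unit conversions.
* **`morphology`** — spherocylinder cell volumes from length/width samples
  and per-volume normalization with error propagation.
* **`feast_famine`** — fitness f = μT₊ − γ(μ)T₋ over feast–famine cycles
  and its closed-form optimal growth rate μ* = (1/b)·ln(T₊/(abT₋)).
* **`fcr_adaptation`** — flux-controlled-regulation (FCR) simulator of
  proteome remodeling during entry into starvation; predicts the death
  rate from the final proteome adaptation state.
* **`synthetic_data`** — seeded generators that emulate the study's
  datasets (exponential decays with 10% plating noise, 5% chemostat pump
  error, lognormal cell sizes) so every stage is testable end to end.
* **`workflows`** — simulate → infer → refit recovery pipelines.

## Worked example

```bash
starvekit report --seed 0 --out out/
```

recomputes the study's printed arithmetic:

```
atp_maintenance_mmol_per_gdw_h: 0.6139 (printed 0.61) pass
glycerol_dose_fmol_per_cfu: 0.3306 (printed 0.33) pass
dead_cells_per_new_cell: 8 (printed 8.0) pass
optimal_growth_rate_per_h: 0.8675 (printed 0.86) pass
optimal_death_rate_per_day: 0.5 (printed 0.5) pass
tradeoff_log_constant: 114.3 (printed 114.0) pass
```

A maintenance rate of 0.5 fmol glycerol day⁻¹ CFU⁻¹ corresponds to
0.61 mmol ATP (g dry weight)⁻¹ h⁻¹; 40 μM glycerol added to a culture of
1.21·10⁸ CFU ml⁻¹ is 0.33 fmol per cell; a recycling yield of 12% means
about eight dead cells feed one new cell; and with feast/famine durations
in ratio T₋/T₊ = 48 the fitness-optimal strategy is to grow at
0.86 h⁻¹ and die at 0.5 day⁻¹ — far below the ~2.2 h⁻¹ *E. coli* can
reach in rich medium.

End-to-end parameter recovery from a synthetic 13-condition panel:

```bash
starvekit fit --seed 1 --out out/
# gamma(mu) = 0.233/day * exp(0.862 h * mu)  (generating: 0.23 / 0.87)
```

and the proteome-adaptation scenarios (`starvekit fcr`): depleting one
nutrient with low affinity (K_M = 1 mM) lets cells adapt to a proteome
state of 0.73 h⁻¹ (predicted γ = 0.44 day⁻¹ instead of 0.51 day⁻¹ at
K_M = 10 μM), while ten sequentially depleted nutrients allow adaptation
down to 0.53 h⁻¹ (γ = 0.36 day⁻¹) — gradual entry into starvation
noticeably improves survival.

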