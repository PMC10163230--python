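# befcausal

Causal panel-data designs for estimating the effect of plant species
richness on grassland productivity from longitudinal observational data.

## The problem

Grassland plots observed over many years show correlated changes in plant
species richness *R* and aboveground live biomass *P* (g/m²/yr). Reading
that correlation causally is hard: confounders — soil, topography, land-use
history at the plot or site level, weather and herbivory shocks that vary by
site and year — push richness and productivity together, and productivity
itself can feed back on richness (e.g. through shading). `befcausal`
implements the estimation designs that econometrics and biostatistics use to
attack exactly this structure, for ecologists working with plot × site ×
year panels such as unmanipulated Nutrient Network plots.

## The designs

All headline models are ln–ln, so the coefficient of interest is an
elasticity (% change in productivity per % change in richness):

* **Bivariate**: `ln P_pst = β ln R_pst + ε_pst` — no controls.
* **Common Design** (conditioning on observables):
  `ln P_pst = β ln R_pst + X_p + X_s + X_st + ε_pst` with measured
  covariates entered directly.
* **Main Design** (two-way fixed effects):
  `ln P_pst = β ln R_pst + δ_p + μ_st + ε_pst`, where plot intercepts δ_p
  absorb *all* time-invariant plot and site attributes and site-by-year
  intercepts μ_st absorb *all* site-level shocks. Estimated by alternating
  within-group demeaning; standard errors are CR1 cluster-robust at the plot
  (or site) level with t(G−1) confidence intervals.
* **Robustness designs**: just-identified two-stage least squares with a
  richness-shifting instrument (weak-instrument diagnosis via the effective
  F statistic), mechanism blocking (adding the shading covariate to cut the
  productivity → shading → richness path), a lagged-dependent-variable
  design `ln P_pst = β ln R_pst + θ ln P_ps(t−1) + μ_st + ε_pst` that
  brackets the true effect together with the Main Design, and
  Oster/Altonji proportional-selection sensitivity bounds (both the
  first-order approximation and the exact cubic root).
* **Heterogeneity**: species are classified per site into rare/non-rare ×
  native/non-native types from relative cover; the Main Design is re-fit on
  the four per-type richness counts (inverse-hyperbolic-sine scale, so zero
  counts are fine) and a Wald test asks whether the four effects are equal.

Every estimator is validated against a synthetic-panel generator
(`simulate_panel`) whose data-generating process encodes the causal diagram
— correlated confounder loadings at plot, site-year and plot-year level, an
excluded instrument, a lagged shading feedback, and a geometric
rank-abundance community where the marginal species at high richness is
increasingly rare and non-native — so recovery of known ground truth, not
agreement with itself, is the test.

## Worked example

```python
import befcausal as bc

panel, truth = bc.simulate_panel(bc.scenario("confounded", seed=42))
main = bc.estimate_main_design(panel)
print(main.elasticity_report())
```

prints (240 plot-years, 40 plots, true elasticity −0.24):

```
{'beta': -0.3683, 'se': 0.0694,
 'pct_per_10pct_linear': -3.6829, 'pct_per_10pct_exact': -3.4493,
 'ci_lower': -0.5086, 'ci_upper': -0.2280}
```

i.e. this realization estimates that a 10% increase in richness lowers
productivity by ≈3.7% (the 95% CI comfortably covers the true −2.4% per
10%). On the same draw the bivariate regression gives β = −0.074 — pulled
toward zero by positively correlated confounding — and 2SLS gives
β = −0.365 with an effective F of 68 (a strong instrument). Averaged over
200 replicates (`bc.monte_carlo`) the Main Design is unbiased with 95% CI
coverage ≈ 0.95 while the bivariate and Common designs stay biased upward.

The same battery is available from the shell:

```bash
befcausal all --scenario paper_like --seed 1 --out results/run1
befcausal montecarlo --scenario confounded --n-reps 200 --designs main
```

## Layout

| module | contents |
| --- | --- |
| `befcausal.panel` | panel container/validation, diversity metrics, IHS, FE absorption |
| `befcausal.lsq` | OLS with deterministic collinearity handling, CR1 sandwich |
| `befcausal.estimators` | bivariate / Common / Main designs, moderation |
| `befcausal.robustness` | 2SLS + effective F, mechanism block, LDV, bracketing, Oster |
| `befcausal.heterogeneity` | species typing, per-type richness, equality test |
| `befcausal.simulate` / `befcausal.config` | the synthetic-panel generator and scenarios |
| `befcausal.pipeline` / `befcausal.cli` | orchestration, Monte Carlo, CLI |

See `docs/methods.md` for the model, the generator's assumptions, numerical
choices and known limitations.
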