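# Methods

## Estimands and designs

The quantity of interest is the elasticity β of plot-level aboveground live
biomass with respect to plot species richness, identified from ln–ln
regressions on a plot × site × year panel. The package implements a ladder
of designs whose assumptions weaken step by step:

1. **Bivariate** — credible only if no confounding exists at all.
2. **Common Design** — covariate conditioning; credible only if the measured
   covariates capture every confounder, without error.
3. **Main Design** — two-way fixed effects: plot intercepts δ_p absorb every
   time-invariant plot- and site-level attribute (plots are nested in sites,
   so site effects are subsumed), and site-by-year intercepts μ_st absorb
   every site-level shock. The remaining identifying variation is
   within-plot, over-time deviation of richness; the design assumes no
   time-varying *plot-level* confounder.
4. **Robustness designs** that each drop one Main-Design assumption:
   instrumental variables (2SLS), mechanism blocking via shading, a
   lagged-dependent-variable (LDV) model, and Oster-style
   proportional-selection bounds.
5. **Heterogeneity** — the treatment "add one species" is compound; the
   per-type design splits richness into rare/non-rare × native/non-native
   counts and estimates one coefficient per type on the
   inverse-hyperbolic-sine scale (defined at zero, log-like above ~2, so
   absent types are admissible).

Inference everywhere is CR1 cluster-robust — the sandwich
(X'X)⁻¹[Σ_g X_g'u_g u_g'X_g](X'X)⁻¹ scaled by G/(G−1)·(n−1)/(n−k) — with
clusters at the plot level by default (site level optionally), allowing
arbitrary serial correlation within plots and heteroskedasticity across
them. Confidence intervals use t critical values with G−1 degrees of
freedom (conservative cluster df). The k in the small-sample factor counts
absorbed fixed-effect dimensions: levels(plot) + levels(site-year) minus the
number of connected components of the plot/site-year bipartite graph
(computed by union-find; for plots nested in sites this is the number of
sites).

## The synthetic data-generating process

`simulate_panel` draws, for plot p in site s at year t:

    lnR_pt = r0 + α_p + ν_st + a_pt + γ Z_pt + λ shade_{p,t−1} + u_pt
    R_pt   = clip(round(exp(lnR_pt)), 1, pool_size)
    lnP_pt = p0 + β ln R_pt + δ_p + μ_st + b_pt + ε_pt
    shade_pt = logistic((lnP_pt − 5.7) / 0.8)

(α_p, δ_p), (ν_st, μ_st) and (a_pt, b_pt) are mean-zero bivariate Gaussian
loading pairs with common standard deviation and correlation ρ — the
confounders that strike richness and productivity together. Z is a standard
normal excluded instrument entering richness only; u_pt is
richness-specific noise; ε_pt is productivity-only noise, optionally AR(1)
with stationary variance sd_noise². A burn-in year initializes the shading
lag and the AR(1) state and is discarded.

Key choices:

* **Observed-richness construction.** Productivity responds to the *logged
  observed integer richness*, so a configuration with all noise and
  confounding switched off recovers β exactly — the generator's most basic
  contract, and the anchor for the noiseless oracle tests. Rounding makes
  the regressor distribution realistic (integer richness 1–37) without
  introducing errors-in-variables bias.
* **Reverse causality with a one-year lag.** Richness responds to last
  year's shading, keeping the system recursive and simulable. For this
  channel to bias the within estimator at all, the productivity error must
  be serially correlated — with iid errors, last year's shading is
  independent of this year's shock — hence the `ar1_noise` parameter. The
  mechanism-blocking design therefore controls the *lagged* shading measure
  by default (the covariate actually on the causal path); contemporaneous
  shade is available via `shade_col`.
* **Shading is logistic in ln productivity**, mapping to a light-interception
  fraction in [0,1]; midpoint 5.7 and scale 0.8 place typical panels on the
  responsive part of the curve.
* **Community structure.** Each site has a geometric rank-abundance pool
  (relative abundance ∝ decay^rank, decay 0.85, pool 37). A plot-year with
  richness R contains R species drawn by abundance-weighted sampling without
  replacement (Gumbel top-k), so dominants enter first and the marginal
  species at higher richness is increasingly from the rare tail. A species
  is *truly* rare when its pool relative abundance falls below the rarity
  cutoff (default 0.05); non-native labels are drawn with probability rising
  linearly in rank, averaging `frac_nonnative` (0.3), so the rare tail is
  disproportionately non-native. Relative covers are the pool abundances of
  the drawn species renormalized to one.
* **Observed covariate proxies.** `cov_plot` and `cov_siteyear` are the
  productivity-side confounder loadings plus independent noise
  (`covariate_noise`); handing only `cov_plot` to the Common Design mimics a
  study that measures plot attributes but cannot measure site-year shocks.
* **Two random streams** are spawned from the seed — one for the panel, one
  for composition — so the panel realization does not depend on whether
  cover is simulated. Identical config + seed reproduces every frame bit for
  bit.

Default scale parameters (r0 = 2.35, p0 = 6.3) give richness averaging ≈ 11
with median ≈ 10 across 1–37 and biomass of a few hundred g/m², matching
typical temperate-grassland panels.

### Scenarios

Named scenarios fix the study conditions used by the tests and the
acceptance script; all are 10 sites × 4 plots × 6 years unless noted.

| scenario | purpose | departures from defaults |
| --- | --- | --- |
| `ideal` | unbiasedness/no-confounding baselines | all confounder sds and correlations zero |
| `confounded` | default validation (Main assumptions hold) | plot ρ=0.5 sd=0.3; site-year ρ=0.6 sd=0.25 |
| `sign_flip` | Common>0 vs Main<0 qualitative twin | site-year ρ=0.9 sd=0.5 |
| `iv` | plot-year confounding + valid instrument | plot-year ρ=0.7 sd=0.3, γ=0.4 |
| `reverse_causality` | shading feedback / LDV bracketing | λ=1.0, AR(1)=0.5, no plot confounding |
| `heterogeneous` | per-type effects | β by type (−0.15, +0.15, −0.15, −0.15), 20 sites |
| `null_equality` | equality-test calibration | all four type effects −0.1, 30 sites |
| `paper_like` | study-scale battery | 43 sites, 4/3-plot cycle (151 plots), 11 years with 5–11-year windows; site-year ρ=0.8 sd=0.45; mild plot-year confounding, λ=0.4, AR(1)=0.3 |

The true elasticity defaults to β = −0.24 throughout. In `paper_like` the
positive plot- and site-year-level confounding makes the bivariate and
Common estimates positive while the Main Design recovers ≈ −2.4% per 10%
richness, the IV/LDV/blocking designs stay negative, and the Oster upper
bound at π = −0.10, Rmax = 1 stays ≈ −2% per 10% — the full qualitative
design-comparison pattern.

The null-equality calibration uses 30 sites × 4 plots × 6 years (120 plot
clusters) so that the chi-square(3) reference for the cluster-robust Wald
statistic is accurate; with few clusters the robust Wald over-rejects and a
calibration claim would conflate the test with small-G distortion.

### What the generator does not emulate

Real NutNet-style panels have spatially structured weather, observer and
measurement error in cover, species turnover with colonization/extinction
dynamics, non-Gaussian confounders, and an instrument built from actual
neighboring-plot richness rather than an abstract shifter (a leave-one-out
group-mean helper, `block_mean_instrument`, is provided for real data).
Passing tests therefore demonstrate that the estimators do what they claim
under the stated causal structure — not that any particular field dataset
satisfies that structure.

## Estimator internals and numerical choices

* **Collinearity** is resolved by a left-to-right modified Gram–Schmidt rank
  screen (tolerance 1e−9 relative) with a second orthogonalization pass;
  callers order the variable of interest first, so drops are deterministic
  and reported.
* **Fixed-effect absorption** alternates within-group demeaning over the
  factors to tolerance 1e−10 (max 1000 sweeps; non-convergence raises).
  Tests verify exact agreement with explicit-dummy least squares and the
  Frisch–Waugh–Lovell property on random instances.
* **2SLS** absorbs the fixed effects from outcome, regressor and instrument,
  and in the just-identified case computes β as reduced-form / first-stage.
  Second-stage residuals use the observed (not fitted) regressor; the
  variance is the IV sandwich (z'x)⁻¹[Σ_g (z u)_g²](x'z)⁻¹ with the CR1
  factor. With a single instrument the effective F equals the first stage's
  cluster-robust Wald statistic γ̂²/var_rob(γ̂); a perfect first stage
  (instrument ≡ regressor) reports an infinite effective F rather than
  failing. The classical F uses the homoskedastic variance s²/(z'z). Note
  the two differ systematically *after* within demeaning even with iid
  errors, because demeaning induces negative within-cluster correlation;
  their equivalence holds in the singleton-cluster, no-FE setting, which is
  how the tests state it.
* **LDV** drops each plot's first usable year and any non-consecutive year
  pairs, absorbs site-by-year effects only (combining the lag with plot
  fixed effects would induce Nickell bias), and reports both β and the
  persistence coefficient θ.
* **Oster bounds.** The approximation is
  β* = β̃ − π(β̇ − β̃)(Rmax − R̃)/(R̃ − Ṙ). The exact method derives the
  proportional-selection moment system of the model y = βx + w₁ + W₂ + e
  (observable index w₁, unobservable index W₂ ⊥ controls):

      s2x(b) = (β̃ − b)·τx
      s1x(b) = (β̇ − b)·σx² − s2x
      s11(b) = (R̃ − Ṙ)·σy² − s2x²/τx + (β̇ − b)²·σx²
      s22(b) = (Rmax − R̃)·σy² + s2x²/τx
      f(b)   = s2x·s11 − π·s1x·s22 = 0

  f is exactly cubic in b; its coefficients are recovered by interpolation
  at four nodes (no hand-expanded algebra to get wrong) and solved with the
  companion-matrix root finder. Among real roots the one closest to β̃ is
  selected. The derivation is validated two ways in the tests: the real
  roots must match a brute-force sign-change grid search, and on a large
  simulated dataset where the selection model holds exactly (with Rmax set
  to the full-model R²) the selected root must recover the true β. Both
  π = −0.10 (spurious-negative confounder) and π = +0.10 (masking
  confounder) are default report rows. The exact method needs σy², σx² and
  τx, which `oster_inputs_from_designs` computes from the panel; the
  controlled regression is the Main Design, whose total R² counts the
  absorbed fixed effects as controls.
* **Bracketing.** The LDV and within estimates are ordered into an interval
  with a sign-agreement flag. When one design's assumptions hold exactly,
  the truth sits *at* one endpoint in expectation, so Monte-Carlo
  containment approaches one half times the probability that the other,
  biased estimate falls on its far side; the containment test threshold
  (≥ 0.25) reflects that, rather than a naive 95% reading.
* **Moderation.** Site-level moderators interact with ln richness; the
  moderator main effect is refused (it is collinear with the plot fixed
  effects). A joint Wald test on the interaction block is reported.
* **Equality test.** Pairwise-difference contrast C (3×4) against a base
  type; W = (Cβ)'(CΣC')⁻¹(Cβ) ~ χ²(3). The statistic is base-invariant
  (verified over all four bases).
* **Degenerate inputs.** Duplicate plot-years, plots under two sites,
  all-zero cover, single clusters, rank-zero designs, constant instruments
  after absorption, missing shade/instrument columns, r2_tilde = r2_dot in
  the Oster formula, and richness above the pool all raise typed errors;
  non-positive biomass and sub-minimum plot histories are dropped with a
  reconciling drop-log (`rows_in = rows_used + Σ dropped`).

## Transforms and diversity metrics

ln is used for biomass and total richness (both strictly positive after
validation); IHS = arcsinh for per-type counts. Inverse Simpson
(1/Σ p_i²) is the implemented Simpson's form, and Pielou J
(−Σ p_i ln p_i / ln R) the evenness metric; richness-1 plot-years have
*missing* (not zero) evenness and are excluded only from evenness-controlled
variants. Both the diversity variable (ln richness, ln Simpson,
untransformed, quadratic) and the rarity metric (relative cover vs relative
frequency) and cutoff are configurable, since reasonable alternatives exist
for each.

## Problem sizes

Test and acceptance problem sizes are chosen to make Monte-Carlo claims
sharp at desk scale: 200 replicates of the 10 × 4 × 6 scenario for recovery,
coverage, sign-flip and IV validity (Monte-Carlo SE of the mean ≈ 0.004–0.01
on β, an order of magnitude below the biases being detected); 500 replicates
of the 30-site scenario for the equality-test null; and the 43-site,
151-plot, 5–11-year scenario for the single-panel design battery
(≈ 1200 plot-years, matching the study scale).

## Known limitations

* The Common Design is covariate-adjusted least squares; a random-intercept
  (mixed-model) variant is not implemented.
* Single-instrument 2SLS only: no overidentification tests, no
  Anderson–Rubin confidence sets, no small-sample IV refinements.
* The equality test relies on the chi-square reference; with few clusters
  (≲ 50 plots) it will over-reject, as the calibration scenario choice
  acknowledges.
* No spatial structure: dispersal, spatial error correlation and
  site-location covariates are out of scope, as are species traits,
  taxonomy resolution and cover-to-biomass allometry.
* Richness discretization means ln R_obs is a step function of the latent
  log-richness; at very low richness (R = 1–2) the step noise is largest.
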