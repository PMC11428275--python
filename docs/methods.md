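# Methods

This note records the models implemented in `herbwue`, the constants and
defaults they use, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## Anatomical maximum stomatal conductance

`stomatal_morphology` evaluates the diffusion ceiling

g_smax = (d_w/v) · D · a_max / (p + (π/2)·√(a_max/π))

entirely in SI units internally (the interface speaks mm⁻² and µm, the
units stomatal data are published in). d_w = 2.49×10⁻⁵ m² s⁻¹ and
v = 2.24×10⁻² m³ mol⁻¹ are the diffusivity of water vapour and the molar
volume of air at 25 °C. The pore is modelled as an ellipse, a_max = πL²/8;
pore depth equals guard-cell width (guard cells inflated to a circular
cross-section). Because mean-of-squares ≠ square-of-mean, a_max computed
from raw per-stoma pore lengths (areas averaged, as measured under the
microscope) differs from a_max computed from a pre-averaged leaf-mean
length; both paths are supported and the result records which one was
used (`from_leaf_mean_length`).

## Isotope chain

`isotope_iwue` implements the simple two-fractionation discrimination
model: Δ = (δ¹³C_air − δ¹³C_plant)/(1 + δ¹³C_plant/1000), c_i/c_a =
(Δ − a)/(b − a) with a = 4.4‰ (diffusion in air) and b = 27‰ (net
biochemical fractionation appropriate to bulk leaf material; `b` is
exposed as a parameter), and iWUE = c_a(1 − c_i/c_a)/1.6. Boundary-layer,
mesophyll, photorespiration, day-respiration and ternary terms are
deliberately absent — the target quantity is a leaf-lifetime-integrated
c_i/c_a from dried matter, for which this reduced model is the standard
compromise. c_i/c_a values outside [0, 1], which real isotope noise
produces, are returned with an `out_of_range` flag rather than clamped or
dropped, so regressions see the same scatter the data carry.

The bundled atmosphere table (`data/atmosphere_1927_2015.csv`) is an
editable CSV of annual c_a and δ¹³C_air assembled by monotone (PCHIP)
interpolation of anchor points from the public ice-core and
direct-measurement records (c_a 305.2 → 400.8 ppm, δ¹³C_air −6.70 →
−8.44‰ over 1927–2015). Any stage accepts a user-supplied table instead.
Year lookups never extrapolate.

## Empirical–biochemical engine

`photosynthesis_eb` chains four steps per specimen.

**Trait model for V_cmax,25.** `ln V_cmax,25 ~ recN + lnSLA +
recN:lnSLA + (1|species)` with recN = 1/N_area (m² g⁻¹ N reciprocal
scale) and lnSLA the natural log of SLA in m² g⁻¹ (SLA = 1/LMA). Fitting
is REML through statsmodels MixedLM; an AIC comparison between the fixed
and mixed forms (both refit by full ML) is available via
`selection="aic"`. Reported diagnostics: pseudo-R² (squared correlation
of observed and conditional fitted values) and a Shapiro residual-
normality p-value. Degenerate designs — one species, or zero residual
variance — fall back to ordinary least squares with a warning. Species
seen in training are predicted with their random intercept; unseen
species get the fixed part only.

**Temperature responses.** V_cmax, K_C, K_O and Γ* scale from 25 °C by
Arrhenius factors exp(Ha(T − 25)/(298.15·R·T_K)). Reference values and
activation energies are the standard Bernacchi-type set: K_C,25 = 404.9
µmol mol⁻¹ (Ha 79.43 kJ mol⁻¹), K_O,25 = 278.4 mmol mol⁻¹ (36.38),
Γ*₂₅ = 42.75 µmol mol⁻¹ (37.83), Ha(V_cmax) = 65.33 kJ mol⁻¹; ambient
O₂ = 210 mmol mol⁻¹. All constants live in one `EBConfig` dataclass and
are swappable. Day respiration is R_d = 0.015·V_cmax at leaf
temperature; the default operating temperature is 29 °C, the
present-day mean leaf temperature of the study region. The reciprocal
of the same Arrhenius factor is the exact inverse used to move a
measured V_cmax to 25 °C (one-point method).

**Conductances.** Operational g_s = 0.51·g_smax (the measured mean
ratio of light-saturated field conductance to the anatomical maximum for
these species; configurable). g_c = g_s/1.6 (H₂O:CO₂ diffusivity ratio);
total CO₂ conductance combines g_c with a boundary-layer conductance
g_cb = 2 mol m⁻² s⁻¹ in series. Mesophyll conductance is treated as
non-limiting; ternary effects on c_i (~2%) are documented here, not
corrected.

**Coupled solution.** Substituting c_i = c_a − A/g_t into the
Rubisco-limited rate A_c = V_cmax(c_i − Γ*)/(c_i + K_m) − R_d gives

(1/g_t)A² − (c_a + K_m + (V_cmax − R_d)/g_t)A + V_cmax(c_a − Γ*) − R_d(c_a + K_m) = 0.

The physical solution is the smaller root, evaluated in the
cancellation-free form 2c/(−b + √(b² − 4ac)) (the naive (−b − √)/2a form
loses ~6 digits at small g_t); it is validated to give 0 < c_i ≤ c_a and
agrees with an independent bisection on the supply–demand balance to
~1e-12 µmol m⁻² s⁻¹ in the tests. Rubisco limitation is assumed
throughout, valid under saturating light at c_a ≤ 400 ppm; the
RuBP-regeneration-limited rate A_j is provided for completeness but is
not on the default path (no J_max estimation is attempted). The engine
only runs on specimens with complete g_smax, SLA and N_area; incomplete
specimens are counted, never silently zero-filled.

## Monte-Carlo propagation of g_smax uncertainty

`mc_uncertainty` treats the species-level regression g_smax = β₁ + β₂c_a
(specimen-level OLS — specimens are the empirical unit) as uncertain and
propagates that uncertainty through the process model: 10,000 coefficient
pairs drawn from N(β̂, Σ̂) (SVD-based sampling so a zero covariance
degenerates cleanly), one annual g_smax trajectory per draw, the EB
engine run per draw-year with species-mean trait parameterisation, and
per-draw OLS slopes of annual iWUE, A and g_s against c_a. Confidence
intervals are equal-tailed 2.5/97.5 percentiles across draws. Draws whose
trajectory would go nonpositive are floored at 1 mmol m⁻² s⁻¹ and
counted, keeping the ensemble size fixed without rejection bias; draws
with any inadmissible solver year are excluded from the quantiles and
counted. Everything is reproducible bit-for-bit under a fixed seed.

The process model here is the package's own EB engine at annual
resolution. The statistical extension itself is model-agnostic — it only
needs a deterministic simulator parameterised by an annual g_smax series —
and could wrap a daily biogeochemical model instead; daily meteorology,
canopy light partitioning and soil/C/N state are out of scope for this
package, so annual aggregation is vacuous here by construction.

## Trend statistics

OLS throughout (`statsmodels`), with t-based 95% CIs. Relative
sensitivity is 100·slope·100ppm/(fitted value at 300 ppm), making traits
with different units comparable; it is invariant to positive rescaling of
the trait. The g_smax variability ANOVA uses the four bins 300–325,
326–350, 351–375 and 376–400 ppm. The iWUE ~ c_a + MAP variance
partition averages each predictor's incremental r² over both entry
orders (the two-predictor case of dominance averaging) and normalises the
shares to the model r² — the decomposition is symmetric and well-defined,
but it is one choice among several. RMSE between simulated and empirical
per-species slope sets matches species by name.

## Phenotypic space

Communities are compared in (log₁₀ a_max, log₁₀ D). Each specimen cloud
becomes a probability distribution on a shared 100×100 grid via a
product-Gaussian KDE with per-axis normal-reference bandwidths
(1.06·min(s, IQR/1.34)·n^(−1/5), the classical kde2d convention),
cell-normalised to sum to one; bandwidths are floored at half a grid cell
so degenerate clouds concentrate instead of vanishing. The shared grid
spans the joint range of both communities padded by 10% of the span per
axis, limiting edge mass leakage (points outside a declared grid warn,
they do not error). Overlap is the standard Jensen–Shannon divergence
JSD = ½KL(p‖m) + ½KL(q‖m), m = (p+q)/2, base-2 logs, so 0 = identical
and 1 = disjoint; 0·log 0 terms contribute zero and cells empty in one
distribution stay finite through the mixture. (A variant of the formula
sometimes printed with the mixture term lacking the factor 2 evaluates
to −1 for identical distributions and cannot satisfy the stated [0, 1]
bounds; the standard form is implemented.) Iso-g_smax contours come in
closed form from the conductance equation's linearity in D:
D(a_max) = g·(p + (π/2)√(a_max/π))/((d_w/v)·a_max).

## Synthetic data generator

The generator emulates the statistical anatomy of a five-species,
246-specimen tropical herbarium series over 1927–2015 (c_a ~305→400
ppm): collection years drawn with weights that thin the early decades
(collection effort), traits following baseline + trend·(c_a − 300) with
mean-one multiplicative lognormal scatter, and leaf δ¹³C back-computed
from a target c_i/c_a trajectory by inverting the discrimination chain,
plus 0.8‰ additive noise.

The five default archetypes encode the observed response taxonomy and
its published effect sizes: two responders whose stomatal density
declines at 3.52 and 0.76 mm⁻² ppm⁻¹ (emergent g_smax declines ≈ −6.2
and −1.7 mmol m⁻² s⁻¹ ppm⁻¹) with constant c_i/c_a targets giving iWUE
slopes of 0.17 and 0.14 µmol mol⁻¹ ppm⁻¹; two iWUE-only responders
(flat anatomy, constant c_i/c_a, slopes 0.13–0.135); and one
non-responder whose c_i/c_a drifts upward just enough to hold iWUE flat,
with a slight pore-area increase. Anatomy baselines place the species in
the three observed phenotypic-space clusters (the strong responder at
1000–2000 mmol m⁻² s⁻¹ g_smax, the rest at 500–1000), and each species'
LMA and N_area are set so the trait model yields a V_cmax,25 whose
simulated light-saturated A matches the species' measured field rates
(15, 14, 13, 9 and 9 µmol m⁻² s⁻¹) — the non-responder has the lowest
photosynthetic capacity. Default trait noise (relative SD 0.125–0.15
for density, ~0.04–0.06 for pore dimensions) keeps residuals around the
fitted trends inside the ±25–50% band reported for real herbarium
material.

What the generator does *not* emulate: climate covariates beyond an
optional white-noise MAP column (no drought signal, no El Niño
structure), measurement error structure beyond lognormal/Gaussian
scatter, phylogenetic covariance among species, and any real collection
metadata. Passing tests therefore demonstrate that the estimators
recover known generative structure at realistic noise — not that real
herbarium data satisfy that structure.

A note on stochastic end-to-end checks: with ~50 specimens per species
and the prescribed noise band, a flat species' 95% CI on Δg_s/Δc_a
excludes zero in ~5% of community realisations by construction, the
moderate responder's decline is detected with ~90% power, and the
ensemble-mean ΔiWUE/Δc_a spacing among the three flat species is
comparable to its realisation-to-realisation spread. The taxonomy test
is therefore run at a fixed canonical seed; across random seeds the full
conjunction holds in roughly 60% of realisations. This is a property of
the study conditions themselves, not of the estimators.

## Data conventions and degenerate inputs

CSV with header row, UTF-8, "." decimal; fixed units per column (mm⁻²,
µm, ‰, g m⁻²), never auto-detected. An empty cell means "not measured";
zero is a measured (and rejected) value, never a sentinel. Validation is
report-only and idempotent; rejected rows are itemised as JSON lines.
Atmosphere series must be gapless and strictly year-increasing.
Degenerate statistical inputs raise (single distinct c_a in a
regression, empty ANOVA bin, collinear partition predictors) or degrade
explicitly (constant response → r² = 0; no between-group variance →
F = 0, p = 1).

## Problem sizes

Defaults used by the test suite and the acceptance script: 246
specimens across five species; 10,000 Monte-Carlo draws per species
(smaller ensembles in unit tests); 100 community realisations for
slope-recovery coverage; 1,000 random parameterisations for the
solver–oracle comparison; 100×100 density grids. A full acceptance run
completes in well under a minute on one CPU.
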