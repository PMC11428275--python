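# herbwue

Long-term CO₂ responses of tropical trees, inferred from herbarium leaves.

Herbaria hold decades of leaves collected while atmospheric CO₂ (c_a) rose
from ~305 to ~400 ppm. Two leaf-level quantities can be read off a dried
specimen and tracked through that rise:

- **Anatomical maximum stomatal conductance.** From stomatal density *D*
  (mm⁻²), maximum pore area *a*_max = πL²/8 (from pore length *L*) and pore
  depth *p* (≈ guard-cell width), the diffusion ceiling on water-vapour
  conductance is

  g_smax = (d_w/v) · D · a_max / (p + (π/2)·√(a_max/π)),

  with d_w = 2.49×10⁻⁵ m² s⁻¹ and v = 2.24×10⁻² m³ mol⁻¹ at 25 °C.

- **Intrinsic water-use efficiency (iWUE = A/g_s).** Leaf δ¹³C gives the
  photosynthetic discrimination Δ = (δ¹³C_air − δ¹³C_plant)/(1 + δ¹³C_plant/1000),
  which maps to the CO₂ drawdown ratio via Δ = a + (b − a)·c_i/c_a
  (a = 4.4‰, b = 27‰), and iWUE = c_a(1 − c_i/c_a)/1.6.

Around these two observables the package builds the full analysis a
herbarium CO₂-response study needs:

- an **empirical–biochemical (EB) engine**: per specimen, V_cmax,25 is
  predicted from leaf nitrogen per area and specific leaf area through a
  mixed model (`ln V ~ 1/N_area * ln SLA + (1|species)`), scaled to leaf
  temperature with Arrhenius kinetics, combined with g_s = 0.51·g_smax and a
  boundary-layer conductance, and the Rubisco-limited Farquhar–von
  Caemmerer–Berry rate coupled to Fick's law is solved in closed form for
  (A, c_i) and hence simulated iWUE;
- a **Monte-Carlo uncertainty extension**: per species, the OLS fit of
  specimen g_smax on c_a is resampled (10,000 multivariate-normal
  coefficient draws), every draw's annual g_smax trajectory is pushed
  through the EB engine, and the per-draw slopes ΔiWUE/Δc_a, ΔA/Δc_a and
  Δg_s/Δc_a yield quantile confidence intervals that carry the
  intraspecific trait variation into the simulated responses;
- **trend statistics**: OLS trait-vs-c_a slopes with t-based CIs, relative
  sensitivities (% per 100 ppm against the fitted value at 300 ppm), binned
  ANOVA, a two-predictor variance partition, and RMSE between simulated and
  empirical slope sets;
- a **phenotypic-space module**: 2-D kernel densities on a 100×100
  (log a_max, log D) grid, Jensen–Shannon divergence between communities,
  and closed-form iso-g_smax contour lines;
- a **synthetic-data generator** that emulates the statistical structure of
  a five-species, 246-specimen herbarium dataset (species-specific linear
  trait trends, ±25–50% intraspecific scatter, collection-effort-weighted
  years), so every stage is testable against known ground truth.

## Worked example

```python
import herbwue as h

atm = h.read_atmosphere_series()          # bundled 1927-2015 table
rec = h.SpecimenRecord("TCD-2015-041", "Dillenia biflora", 2015,
                       stomatal_density=310.0, pore_length=7.2,
                       guard_cell_width=5.5, delta13c=-29.4,
                       lma=135.0, n_area=2.1)

morpho = h.leaf_gsmax(rec)
print(f"a_max = {morpho.amax:.2f} um^2, "
      f"g_smax = {morpho.gsmax_mmol:.0f} mmol m-2 s-1")

iso = h.specimen_iwue(rec, atm)
print(f"Delta = {iso.delta_plant:.2f} permil, ci/ca = {iso.ci_over_ca:.3f}, "
      f"iWUE = {iso.iwue:.1f} umol mol-1")

model = h.fit_vcmax_model(h.generate_vcmax_training(seed=0))
(eb,), _ = h.eb_simulate([rec], atm, model)
print(f"Vcmax25 = {eb.vcmax25:.1f}, A = {eb.a_net:.1f} umol m-2 s-1, "
      f"simulated iWUE = {eb.iwue:.1f} umol mol-1")
```

prints

```
a_max = 20.36 um^2, g_smax = 739 mmol m-2 s-1
Delta = 21.59 permil, ci/ca = 0.761, iWUE = 59.9 umol mol-1
Vcmax25 = 56.2, A = 15.3 umol m-2 s-1, simulated iWUE = 40.7 umol mol-1
```

Reading: this 2015 leaf's anatomy allows at most 739 mmol m⁻² s⁻¹ of
water-vapour conductance; its isotopes say it operated at c_i/c_a ≈ 0.76,
an integrated water-use efficiency of ~60 µmol CO₂ per mol H₂O; the EB
engine, given its traits, simulates a light-saturated assimilation of
~15 µmol m⁻² s⁻¹ at an operational g_s of 0.51·g_smax.

The same stages are available as a CLI over CSV artifacts:

```bash
herbwue all --out-dir run/ --seed 0
```

writes `specimens.csv`, `gsmax.csv`, `iwue.csv`, `eb_results.csv`,
`mc_responses.csv`, `trends.csv`, density grids and a `manifest.json` with
content hashes, the resolved configuration and the seed.

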