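# Methods

`brutia-flux` simulates daily stand-level carbon fluxes — gross primary
productivity (GPP), net primary productivity (NPP), soil heterotrophic
respiration (R_het) and net ecosystem productivity (NEP) — for
Mediterranean *Pinus brutia* stands of known, static structure. This note
documents the model equations as implemented, the parameter choices, the
synthetic-data generators, and the numerical and design decisions.

## Model structure

Each simulated day, for one plot (constant leaf area index, fixed soil
column):

1. **Forcing correction.** Air temperatures from the forcing source are
   corrected to the plot elevation with a linear lapse rate, default
   0.638 °C per 100 m (locally fitted for the study island; configurable).
   The same coefficient is applied to mean, minimum and maximum
   temperature.
2. **Atmospheric demand.** Extraterrestrial radiation R_ex follows the
   FAO-56 daily equation (solar constant 0.0820 MJ m⁻² min⁻¹). Potential
   evapotranspiration uses an empirical radiation–temperature equation
   fitted for Greece: PET = 0.06257·R_ex/(1 − 0.0234·T_mean) mm day⁻¹.
3. **Soil water bucket.** Plant-available water AW (mm) evolves as
   AW(d) = min(max(AW(d−1) + P(d) − REW(d−1)·PET(d−1), AW_r), AW_fc):
   today's precipitation enters, the previous day's REW-limited PET is
   withdrawn, and the store is clamped between residual and
   field-capacity bounds. Volumetric moisture is
   θ = AW·ρ_w/(ρ_soil·SD) over the column depth SD; the Campbell
   retention curve Ψ = −Ψ_e·(θ/θ_s)^(−b) interconverts moisture and
   potential; relative extractable water is
   REW = (θ − θ_Spmin)/(θ_fc − θ_Spmin) clamped to [0, 1], where θ_Spmin
   is the moisture at the species minimum water potential (default
   magnitude 3.3 MPa for the study pine, stored internally as a negative
   potential).
4. **GPP.** An optimality-based light-use-efficiency formulation:
   GPP = φ₀(T)·I_abs·REW·m′·M_c (g C m⁻² day⁻¹). φ₀(T) is the standard
   temperature quadratic (0.352 + 0.022·T − 3.4·10⁻⁴·T², clamped at zero)
   scaled by a reference yield of 0.081785 mol CO₂ mol photons⁻¹.
   I_abs converts shortwave radiation to absorbed photosynthetic photon
   flux with a PAR fraction of 0.50, a photon conversion of
   4.57 mol MJ⁻¹, and Beer–Lambert absorption 1 − e^(−k·LAI) with
   k = 0.5. m′ is the CO₂ limitation factor for light-limited
   assimilation: the optimal ci:ca ratio χ minimises the combined
   transpiration and carboxylation cost per unit assimilation,
   χ = Γ*/c_a + (1 − Γ*/c_a)·ξ/(ξ + √D) with
   ξ = √(β(K + Γ*)/(1.6η*)), β = 146; then
   m = (c_i − Γ*)/(c_i + 2Γ*) and the Jmax-limitation correction
   m′ = m·√(1 − (c*/m)^(2/3)) with c* = 0.41. Γ* and the effective
   Michaelis–Menten coefficient K use standard Arrhenius kinetics
   (Γ*₂₅ = 4.332 Pa, Kc₂₅ = 39.97 Pa, Ko₂₅ = 27480 Pa) at the elevation's
   barometric pressure. The water-viscosity ratio η* uses the Korson
   temperature dependence relative to 25 °C; its pressure dependence is
   negligible at stand elevations and is omitted. Vapour pressure deficit
   comes from mean temperature and relative humidity via the Magnus
   saturation-vapour-pressure formula (the forcing records RH, not VPD).
5. **Allocation.** NPP = 0.53·GPP + 66.05/365, i.e. a fixed autotrophic
   respiration fraction of GPP plus a small annual term expressed per
   day. No process-based autotrophic respiration is modelled.
6. **Soil respiration.** Soil temperature is a linear function of air
   temperature; the default (intercept 1.311 °C, slope 0.889) is the
   least-squares fit to the annual-mean air/soil temperature pairs of the
   five monitored plots with soil sensors, and can be overridden per
   plot. Heterotrophic respiration is the fitted empirical equation
   R_het = exp(−4.31 + 0.25·T_s − 0.004·T_s² + 5.36·θ − 6.37·θ² +
   0.69·ln LAI) in µmol CO₂ m⁻² s⁻¹ (natural log), converted to
   g C m⁻² day⁻¹ by 86400·12.011·10⁻⁶ ≈ 1.03775. The temperature response
   peaks at T_s = 31.25 °C and the moisture response at θ = 0.42, so both
   heat and saturation eventually suppress the flux; LAI acts as a proxy
   for substrate (soil organic carbon) supply.
7. **NEP.** NEP = NPP − R_het, daily; annual values are calendar-year
   sums. Positive NEP is a carbon sink.

The bucket starts at field capacity and the first simulated year is
discarded as spin-up (default 365 days). The model carries no
demography: LAI is constant per run, so simulations are snapshots of
fluxes for a prescribed stand structure.

## Parameters that matter

| Parameter | Default | Units | Notes |
|---|---|---|---|
| lapse rate | 0.638 | °C / 100 m | locally fitted; configurable |
| Ψ_min | 3.3 | MPa (magnitude) | species water-extraction limit |
| PET temperature cap | 40 | °C | guard against the PET pole at ≈42.7 °C |
| φ₀ reference | 0.081785 | mol CO₂ mol photons⁻¹ | scales the quantum-yield quadratic |
| k (extinction) | 0.5 | – | Beer–Lambert canopy absorption |
| β | 146 | – | unit-cost ratio in the optimal-χ criterion |
| c* | 0.41 | – | Jmax-limitation constant |
| PAR fraction / photon conversion | 0.50 / 4.57 | – / mol MJ⁻¹ | shortwave → PPFD |
| NPP allocation | 0.53, 66.05 | –, g C m⁻² yr⁻¹ | slope and annual intercept |
| spin-up | 365 | days | discarded before reporting |

Soil texture classes (Coarse … Very Fine) ship with class-level Campbell
parameters assembled from published European pedotransfer compilations;
the shipped per-plot soil depths and texture assignments are synthetic
defaults consistent with the reported 20–40 cm depths on shallow
ophiolitic soils (the per-plot measurements are not published) and are
meant to be overridden where better data exist.

## Empirical respiration fitting

The respiration equation is the fixed-effect part of a linear
mixed-effects model of log flux with a random intercept per plot.
The fitting machinery mirrors that workflow: REML estimates are
reported; model comparison across the twelve shipped candidate
fixed-effect structures uses AIC from maximum-likelihood refits
(REML likelihoods are not comparable across fixed-effect structures),
with ties broken by parsimony and then registry order. Marginal and
conditional R² follow the Nakagawa–Schielzeth variance-ratio
definitions: fixed-effect prediction variance over (fixed + plot +
residual) variance, with the plot variance added to the numerator for
the conditional version. Observations with non-positive flux are
dropped (with a logged count) before the log transform. AIC selection
is not consistent — it admits a spurious extra term with ≈16%
probability per superset competitor — so the self-selection tests
assert a majority win over replicates rather than per-dataset
certainty.

The synthetic observation generator emulates a chamber campaign: one LAI
per plot (LAI varies between, not within, plots), soil temperature and
moisture drawn uniformly over field-plausible ranges (5–30 °C,
0.05–0.45 m³ m⁻³), Gaussian plot intercepts and residual noise on the
log scale (defaults 0.15 and 0.30). It does not emulate seasonal
confounding between temperature and moisture, autocorrelation within
measurement days, or instrument error structure — so coefficient
recovery here demonstrates the fitter, not robustness to real
campaign designs.

## Synthetic weather generator

The generator reproduces the island normals used to calibrate it: mean
annual temperature 18.0 °C with a sinusoidal cycle peaking in mid-July
(amplitude 8.2 °C) plus AR(1) daily noise (σ = 1.5 °C, ρ = 0.7); 645 mm
annual precipitation distributed over monthly totals concentrated from
November to March, with a two-state Markov occurrence chain per month
(persistence 0.3) and gamma-distributed amounts (shape 0.75); relative
humidity from monthly normals with noise, moister on wet days; and
shortwave radiation as FAO extraterrestrial radiation times a stochastic
transmissivity (≈0.68 clear, ≈0.35 wet). A single integer seed drives
all streams. The generator does not produce heat waves, multi-year
droughts, autocorrelated storm tracks or trends, so simulator behaviour
under such regimes is untested; climate-change sensitivity runs are
built by uniform perturbations (ΔT, precipitation scaling, ΔCO₂) or by
substituting scenario CO₂ trajectories from the shipped decadal lookup
(linearly interpolated; baseline holds 368 ppm).

## Factorials, scenarios, evaluation

The three factorial setups separate stand structure from elevation:
`conLAIvarT` fixes LAI at the across-plot mean (1.96 m² m⁻² on the
shipped elevation gradient, computed at run time from the plot set, not
hard-coded) while temperature varies with elevation; `varLAIconT` keeps
measured LAIs but imposes the reference plot's elevation (hence
temperature and pressure) on all plots; `varLAIvarT` is the plain
simulation. Scenario runs compare ten-year windows (baseline 1996–2005,
mid-term 2051–2060, long-term 2091–2100) and report mean percent
differences per flux, computed per plot first and then averaged
(a pooled variant is available by flag). Model output can be evaluated
against an annual tree-ring width index by Pearson correlation on
overlapping years; a convenience negative-exponential detrender is
included but labelled as such — dedicated dendrochronology software
should be preferred.

## Numerical choices and degenerate inputs

- The PET denominator crosses zero at T ≈ 42.7 °C; temperature is capped
  at 40 °C inside the PET evaluation only.
- The bucket clamp guarantees AW ∈ [AW_r, AW_fc] for any forcing; REW is
  clamped to [0, 1]; the retention curve rejects θ ≤ 0 and the inverse
  rejects Ψ ≥ 0.
- Bucket bounds AW_r/AW_fc are derived from θ_r/θ_fc by the same
  moisture conversion used at run time, so conversions and bounds cannot
  drift apart.
- The moisture conversion is implemented exactly as stated, including
  the ρ_w/ρ_soil ratio with ρ_w = 1 g cm⁻³; users should note that this
  scales θ by bulk density (a gravimetric flavour) even though it is
  used as volumetric throughout.
- χ is evaluated in closed form; a guard floor on √D avoids division
  issues at exactly zero VPD. m′ is clamped to 0 when m ≤ c*.
- Candidate-model ranking is a stable sort on (AIC, term count, registry
  order), so exact AIC ties resolve deterministically.
- Leap days are simulated like any other day (proleptic Gregorian
  calendar); a 365-day spin-up in a leap year leaves one residual day,
  which the aggregation helpers trim via complete-calendar-year
  filtering.

## Problem sizes

The shipped tests and the reproduction script run entirely on synthetic
data at desk scale: weather series of 3–50 years, bucket checks over
~1000 random days, mixed-model designs of 30 plots × 60 observations
(coefficient recovery) and 100 replicates of 10 plots × 50 (confidence
interval calibration), and scenario windows of ten years over three to
five plots. These sizes were chosen as the smallest at which the
statistical properties under test are stable.

## Known limitations

- No demography (growth, regeneration, mortality), no inter-tree
  competition: not a dynamic vegetation model.
- One homogeneous big-leaf canopy with generic (not species-specific)
  photosynthetic parameters; no sun/shade partitioning.
- Single-layer bucket: no drainage routing, runoff, interception or
  snow.
- The aboveground heterotrophic flux is assumed negligible relative to
  soil R_het.
- The respiration equation is site-calibrated; transferring it to other
  regions re-uses coefficients outside their fitted domain.
- Annual NEP magnitudes depend on the synthetic soil assignments where
  measured soil columns are unavailable.
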