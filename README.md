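# brutia-flux

Process-based simulation of daily stand-level carbon fluxes — gross
primary productivity (GPP), net primary productivity (NPP), soil
heterotrophic respiration (R_het) and net ecosystem productivity
(NEP) — for Mediterranean *Pinus brutia* forests.

The package is aimed at forest-ecosystem modellers who want to ask
whether pine stands of known structure remain carbon sinks under
warming, drying Mediterranean climates, and how much of the flux
variation across a landscape is driven by stand structure (leaf area
index, LAI) versus elevation (temperature).

## Model core

For each day *d* of a forcing series (temperature, humidity,
precipitation, shortwave radiation, CO₂), corrected to the plot
elevation with a local lapse rate (0.638 °C / 100 m):

- **Soil water bucket.** Available water
  AW(d) = min(max(AW(d−1) + P(d) − REW(d−1)·PET(d−1), AW_r), AW_fc),
  with PET = 0.06257·R_ex/(1 − 0.0234·T) (R_ex from FAO-56), the
  Campbell retention curve Ψ = −Ψ_e(θ/θ_s)^(−b) linking moisture and
  potential, and relative extractable water
  REW = (θ − θ_Spmin)/(θ_fc − θ_Spmin) ∈ [0, 1] normalised between field
  capacity and the moisture at the species' minimum water potential
  (3.3 MPa).
- **GPP** (optimality-based light-use efficiency):
  GPP = φ₀(T)·I_abs·REW·m′·M_c, with a temperature-dependent quantum
  yield φ₀, Beer–Lambert canopy absorption I_abs = PPFD·(1 − e^(−k·LAI)),
  and the CO₂ limitation factor m′ built from the least-cost optimal
  ci:ca ratio with a Jmax-limitation correction.
- **Allocation:** NPP = 0.53·GPP + 66.05/365.
- **Soil respiration** (empirical, fitted as a linear mixed model of log
  flux with plot random intercepts):
  R_het = exp(−4.31 + 0.25·T_s − 0.004·T_s² + 5.36·θ − 6.37·θ² + 0.69·ln LAI)
  µmol CO₂ m⁻² s⁻¹, with soil temperature T_s a linear function of air
  temperature.
- **NEP = NPP − R_het.**

The nine monitoring plots of the study region (four along a post-fire
chronosequence, five along an elevation gradient) ship as a fixture, and
a stochastic weather generator calibrated to the island normals
(18.0 °C mean annual temperature, 645 mm winter-concentrated annual
precipitation) provides reproducible synthetic forcing. See
`docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Simulate the densest elevation-gradient plot (OLY1, LAI 4.26, 350 m asl)
under three years of synthetic island weather, then apply a uniform
+3 °C / −20% precipitation perturbation:

```python
import brutia_flux as bf
from brutia_flux.experiments import complete_years

forcing = bf.synth_weather(bf.WeatherGenParams(seed=42), n_years=4, start_year=2000)
plot = next(p for p in bf.load_plots(group="elevation") if p.plot_id == "OLY1")

daily = complete_years(bf.simulate_plot(plot, forcing))   # first year = spin-up
annual = bf.annual_aggregate(daily, plot_id=plot.plot_id)
print(annual.round(1).to_string(index=False))

warmer = forcing.perturb(dt=3.0, precip_factor=0.8)
warm = bf.annual_aggregate(complete_years(bf.simulate_plot(plot, warmer)),
                           plot_id=plot.plot_id)
print(bf.percent_change(warm, annual).round(1).to_string())
```

which prints

```
plot_id  year    gpp   npp  rhet   nep
   OLY1  2001 1214.7 709.9 588.3 121.5
   OLY1  2002 1190.9 697.2 595.5 101.8
   OLY1  2003 1240.6 723.6 601.9 121.7
gpp     -11.2
npp     -10.2
rhet     27.8
nep    -206.8
```

Annual fluxes are g C m⁻² yr⁻¹: the stand assimilates ≈1200 g C of GPP
and stores ≈100–120 g C (a carbon sink). Under the warmer, drier
forcing, water limitation cuts GPP by ~11% while warmer soils raise
heterotrophic respiration by ~28%; the NEP change below −100% means the
stand flips from sink to source. (Adding CO₂ fertilization via
`co2_delta=200.0` roughly offsets the GPP loss but not the respiration
rise.)

A command-line interface covers the same workflows:

```sh
brutia-flux synth-weather --years 10 --seed 42 --out met.csv
brutia-flux simulate --plot-id OLY1 --forcing met.csv --out daily.csv
brutia-flux experiment --mode conLAIvarT --forcing met.csv --out annual.csv
brutia-flux fit-rhet --observations obs.csv --out fit.json
brutia-flux show-config
```

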