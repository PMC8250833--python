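# sandflux

Denitrification rates, substrate kinetics and solute penetration dynamics
from microsensor depth profiles in permeable (sandy) sediments — plus a
forward 1-D reaction-transport simulator that validates every inference
stage by parameter recovery.

## The problem

In intertidal sand flats, porewater advection during tidal inundation —
rather than diffusion — delivers nitrate and oxygen centimeters deep into
the sediment, fueling denitrification well below the photic surface layer
inhabited by the microphytobenthos (MPB). Quantifying this requires turning
raw microsensor time series into derived quantities:

* **Volumetric potential denitrification rates** from repeated N₂O
  microprofiles measured under acetylene block (acetylene stops N₂O
  reduction, so N₂O accumulation tracks denitrification). For each depth,
  the budget

  R = dC/dt + (J_out − J_in)/Δz,  J = −φ^(4/3) · D_w · dC/dz

  combines the regression slope of N₂O versus time with the divergence of
  the Fickian fluxes through the layer boundaries (porosity φ, free-solution
  diffusivity D_w). Rates are reported per mole of N (2 × the N₂O rate) in
  mmol N m⁻³ sediment h⁻¹.

* **Denitrification kinetics**: instantaneous rates (central differences of
  the N₂O accumulation curves plus the same transport correction) are paired
  with the apparent porewater NOₓ remaining,
  NOₓ(app) = NOₓ(init) − 2·N₂O·f, where f corrects for NOₓ consumed by
  processes other than denitrification. The rate–substrate cloud is fitted
  with the Hill equation

  R(C) = V_max · Cⁿ / (K_Mⁿ + Cⁿ)

  and compared against Michaelis–Menten (n = 1) by AIC.

* **Penetration dynamics**: during downward percolation the O₂ and NOₓ
  fronts deepen and approach a maximum; each penetration-versus-time series
  is summarised by the asymptotic fit d(t) = a − b·cᵗ.

* **Advection budgets**: infiltration rates, imposed solute fluxes,
  plug-flow displacement depths and areal MPB-uptake mass balances that put
  the microsensor numbers in context.

Because raw microprofiles of this kind are rarely published as tables, the
`simulate` module generates synthetic acetylene-block and percolation
experiments with known ground truth (Hill kinetics with a depth ramp,
oxygen inhibition, non-denitrification NOₓ sinks, observation noise), so the
whole chain can be checked by recovering what was put in.

## Worked example

Simulate an acetylene-block incubation at the plateau-zone truth
(V_max = 6.8 mmol N m⁻³ h⁻¹, K_M = 3.1 µmol L⁻¹, n = 2.4) and recover the
kinetics from the synthetic profiles:

```python
from sandflux import (ScenarioConfig, simulate, SedimentCore, Analyte,
                      instantaneous_rate_cloud, fit_kinetics, FitModel,
                      saturating_concentration)

result = simulate(ScenarioConfig(noise_sd=0.0))
cloud = instantaneous_rate_cloud(result.series[Analyte.N2O], SedimentCore(),
                                 depth_range=(0.014, 0.020), nox_init=20.0)
fit = fit_kinetics(cloud, FitModel.HILL)
print(f"V_max = {fit.v_max:.2f} mmol N m-3 h-1")
print(f"K_M   = {fit.k_m:.2f} umol/L")
print(f"n     = {fit.hill_n:.2f}")
print(f"C(90% V_max) = {saturating_concentration(fit, 0.9):.2f} umol/L")
```

prints

```
V_max = 6.89 mmol N m-3 h-1
K_M   = 2.81 umol/L
n     = 2.01
C(90% V_max) = 8.38 umol/L
```

i.e. the maximum rate is recovered within ~1% and the half-saturation
constant within ~10% of the simulated truth; the concentration needed to
drive 90% of V_max (the threshold behind "saturation depths") comes out
near 8 µmol L⁻¹. The flow arithmetic is available from the shell:

```bash
$ sandflux budget --solute-conc 15
flow_mL_min  infiltration_L_m2_h  imposed_umol_m2_h  plug_flow_cm
       0.11                  1.2                 18           2.6
       0.36                  4.0                 60           8.4
        1.3                 14.4                216          30.3
N2O ceiling from 20 umol/L NOx: 10 umol/L
```

Other subcommands: `sandflux rates`, `sandflux kinetics`,
`sandflux penetration`, `sandflux simulate`, `sandflux fixtures`, and
`sandflux run --config run.yaml` for the whole pipeline.

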