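# Methods

This note documents the models, conventions, parameter choices and
numerical details behind `sandflux`, in the order the pipeline runs.

## Units and conventions

Depth is in m, positive downward, 0 at the sediment–water interface;
concentration in µmol L⁻¹ (numerically mmol m⁻³ of porewater); time in h;
volumetric rates in mmol N m⁻³ sediment h⁻¹; areal fluxes in
µmol m⁻² h⁻¹. Penetration depths are reported in cm at the API boundary
only. Overlying-water rows (depth < 0) are accepted in profile tables and
ignored by sediment computations. Negative concentrations (sensor baseline
noise) are clipped to zero at read time by default (`clip_negatives=False`
keeps them).

## Rate-profile budget

For repeated N₂O profiles under acetylene block, the volumetric rate at an
interior depth i is

    R_N2O = dC/dt + (J_below − J_above) / Δz

with `dC/dt` the ordinary-least-squares slope of concentration versus time
and `J = −φ^(4/3) D_w ΔC/Δz` the Fickian flux through each layer boundary
(positive downward). The boundary-flux difference divided by Δz is a
discrete −D_eff ∂²C/∂z², so summed over interior layers it telescopes to
the domain-boundary fluxes. Reported rates are 2 × R_N2O (per mole N).
Defaults: φ = 0.38, D_w = 6.58 × 10⁻⁶ m² h⁻¹ (N₂O at 20 °C), Δz = 0.001 m.

Choices a user should know about:

* **Tortuosity**: the φ-exponent (default 4/3) is configurable; other
  porosity–tortuosity relations can be swapped in via
  `tortuosity_exponent`.
* **Storage term**: `dC/dt` is used without a porosity multiplier, matching
  the conventional bookkeeping in which porewater concentration change is
  equated directly with the volumetric rate; `porosity_on_storage=True`
  enables the stricter variant. The simulator uses the same bookkeeping, so
  recovery tests are consistent whichever is chosen.
* **Linear window**: accumulation curves flatten as substrate exhausts, so
  the per-depth regression uses profiles up to the first one reaching 80%
  of that depth's maximum (≥ 3 profiles always retained; fraction
  configurable, `None` uses all profiles).
* **Edges**: the surface-most and bottom-most depths get no rate; one-sided
  fluxes would bias them.
* Stop-flow point rates are −slope of an OLS fit over the measurement
  window, with a QC flag requiring r² > 0.95 and p < 0.01.

## Kinetics

Instantaneous rates use the two-sided (central) difference of N₂O versus
time at each depth — exact for linear accumulation, O(Δt²) truncation
otherwise — plus the same per-profile flux-divergence correction, times 2
for the N basis. Apparent substrate is reconstructed as

    NOx(app) = NOx(init) − 2 · N2O · f,   f = 1 + (1 − 2·N2O_max / NOx(init))

where `N2O_max` is the per-depth maximum. The additive form of f is the
default; it assumes near-total consumption of the initial pool and leaves a
residual of init·(1 − 2·N2O_max/init)², negligible when ≥ ~90% of the pool
was consumed. The exact normalisation f = init/(2·N2O_max), which zeroes
the residual identically, is available via `exact=True`; the two differ by
< 1% at realistic ceiling approaches.

Fitting minimises squared residuals of R(C) = V_max Cⁿ/(K_Mⁿ + Cⁿ) with
positive-parameter bounds, from a small multi-start grid (V_max₀ ∈ {max
rate, 1.5 × max rate}; K_M₀ ∈ {25%, 50% concentration quantiles};
n₀ ∈ {1, 2, 4}); the best RSS wins. Michaelis–Menten fixes n = 1. Model
comparison uses the least-squares AIC, N·ln(RSS/N) + 2k (k = 3 Hill, 2 MM),
with no small-sample correction. Two numerical safeguards:

* when both models are compared, the Hill fit is additionally polished from
  the MM optimum, guaranteeing RSS(Hill) ≤ RSS(MM) (nesting) up to solver
  tolerance;
* RSS is floored at N·(10⁻⁸ × data scale)² inside the AIC so that
  numerically perfect fits yield the +2 parameter penalty rather than
  ln(0) noise.

Points on the flat tail of the accumulation curve (N₂O above 95% of the
per-depth maximum) are excluded from fitting by default — central
differences there are pure noise at near-zero apparent substrate. Negative
instantaneous rates are kept, preserving noise symmetry so V_max is not
biased upward.

## Penetration depths and the asymptote

Penetration depth is the shallowest sediment depth with concentration at or
below a threshold; the default threshold is 1.0 µmol L⁻¹ rather than a
literal zero because sensor baselines make exact zero ill-defined, and
interpolation between bracketing samples is off by default to match the
"first depth at which" reading convention (both configurable). Saturation
depth is the same operation with the threshold set to the concentration
driving a given fraction (default 90%) of V_max,
C = K_M·(q/(1−q))^(1/n). Since it only changes the threshold, saturation
depth ≤ penetration depth holds for any profile.

The deepening series d(t) is fitted with d = a − b·cᵗ by bounded
least squares (lmfit), c constrained to (0, 1) so the approach to the
asymptote is monotone; initialisation a₀ = max depth, b₀ = a₀ − d(first),
c₀ = 0.5. The asymptote a is reported with its standard error. Constant
series degenerate cleanly to a = d, b ≈ 0. Time translation changes b and
c but not a.

## Advection budgets

Plug-flow arithmetic on a cylindrical core: infiltration = flow/area;
imposed flux = infiltration × concentration; theoretical penetration =
volume/(area × porosity); porewater velocity = infiltration/porosity. The
stoichiometric N₂O ceiling is half the initial NOₓ pool. Areal uptake =
volumetric rate × zone thickness. Full precision is kept internally;
`display_round` reproduces conventional display rounding (1 decimal for
infiltration, integers for fluxes and percentages).

## Forward simulator

Explicit finite differences on a uniform grid (default 0–4 cm at 1 mm):
FTCS diffusion with D_eff = φ^(4/3)·D_w, first-order upwind advection,
Euler reaction steps with per-step clamping so no pool goes negative.
Stability is enforced at configuration time: dt ≤ 0.4·Δz²/D_eff and
Courant number v·dt/Δz ≤ 0.5; the snapshot cadence must be a multiple of
dt. Refinement tests show < 1% change in snapshots when Δz and dt are
halved, and a diffused concentration step matches the half-space erfc
solution within 1% of the step height.

**Acetylene-block scenario** (closed boundaries, v = 0): uniform initial
NOₓ (20 µmol L⁻¹), denitrification R_den = capacity(z) × Hill(NOₓ) with
truth (V_max, K_M, n) = (6.8, 3.1, 2.4) by default; each mole N denitrified
yields ½ mole N₂O. A non-denitrification sink consumes an additional
s/(1−s) of R_den (s = `other_sink_fraction`, default 0.09), so the N₂O
ceiling approach is 2·N₂O_max/NOₓ(init) ≈ 1 − s ≈ 0.91 and total N
(NOₓ + 2·N₂O + cumulative other sink) is conserved exactly in the closed
domain. `kinetics_true` is therefore the denitrification (N₂O-producing)
law, and the pipeline's recovered V_max is directly comparable to it.
Capacity ramps linearly from 15% of the plateau value at 0.4 cm to 100% at
1.4 cm, reproducing the observed rise of denitrification potential to a
deep plateau.

**Percolation scenario**: constant downward porewater velocity
(infiltration/φ), Dirichlet surface concentrations (O₂ 250, NOₓ 15 or 1.5
µmol L⁻¹ by season), zero-gradient bottom. Oxygen is consumed by Monod
kinetics (V = 150 mmol m⁻³ h⁻¹, K = 10 µmol L⁻¹ — chosen to reproduce the
~1 cm steady oxygen penetration observed at the low pump rate);
denitrification is suppressed by oxygen via the factor k_i/(k_i + O₂) with
k_i = 40 µmol L⁻¹, giving the observed ~6–7× anoxic/oxic rate contrast at
air-saturated porewater. The resulting NOₓ fronts deepen monotonically and
stall where consumption balances supply; at quasi-steady state the front
width approaches the pure-advection quadrature v·∫dC/R(C), broadened by
(physical plus numerical) diffusion. Note that with the default Hill
parameters this front model predicts a penetration-to-saturation gap of
~0.8 cm at the low flow rate — wider than is typical of field profiles,
where additional low-concentration sinks (assimilation) sharpen the tail;
the ordering saturation ≤ penetration is unconditional.

Observation noise is Gaussian, added to output snapshots only (the
internal state stays exact and is returned as ground truth), reproducible
from the scenario seed. `make_fixture_suite` writes a deterministic
fixture set: the acetylene run, percolation at the three laboratory pump
rates (0.11, 0.36 mL min⁻¹ spring; 1.3 mL min⁻¹ summer), and zero-reaction
controls, with a YAML manifest of ground-truth parameters.

### What the synthetic data do and do not emulate

Emulated: uniform substrate spiking, depth-ramped Hill kinetics,
stoichiometric N₂O accumulation toward a ceiling, non-denitrification NOₓ
losses, diffusive smearing, advective fronts with oxygen shading, sensor
noise, the ~18-min profiling cadence. Not emulated: 2-D/3-D ripple-driven
flow fields, incomplete acetylene inhibition, N₂O sensor
cross-sensitivities, DNRA/ammonium cycling, light-dependent MPB dynamics,
or drift in sensor calibration. Passing recovery tests therefore show that
the inference chain is consistent and unbiased under its own transport
assumptions at realistic noise — not that those assumptions hold in any
particular field data set.

## Problem sizes

Defaults keep everything desk-scale: acetylene runs are 6 h of simulated
time at 0.3-h cadence on 41 grid nodes (~600 time steps); percolation runs
8–12 h at 0.005-h steps; Monte-Carlo checks use 200 replicates for AIC
model selection, 500 for asymptote recovery and 1000 for stop-flow slope
coverage. The full test suite runs in well under a minute.

## Known limitations

* The explicit scheme is first-order in time; the convergence test bounds
  the discretisation error at the default resolution (< 1%) but stiff
  custom kinetics may need smaller dt.
* The additive correction factor f biases apparent NOₓ slightly high when
  incubations stop far short of exhaustion; use the exact form or longer
  simulated incubations in that regime.
* Hill-fit standard errors come from the Gauss–Newton covariance and are
  approximate for strongly correlated (V_max, K_M, n) triples.
* `stopflow_rate` assumes a linear window; it does not detect curvature
  beyond the QC flag.
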