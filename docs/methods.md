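# Methods

## The model

`leafenergy` computes the equilibrium temperature of a horizontal leaf by
balancing its energy budget,

```
0 = R_abs − (S_r + H + L),
```

where (all in W m⁻²)

* **R_abs** — absorbed radiation: direct shortwave on the upper surface,
  ground-reflected shortwave `r·S_sw` on the lower surface (same shortwave
  absorptivity `abs_s` on both), plus long-wave absorbed with `abs_l`:
  `R_abs = abs_s (1 + r) S_sw + abs_l S_lw`.  The incident long-wave load
  `S_lw = σT_sky⁴ + σT_air⁴` distinguishes the radiative environments above
  (cold clear sky) and below (surroundings at air temperature) the leaf.
* **S_r** — thermal infrared emission from both surfaces,
  `2·abs_l·σ·T_leaf⁴` (emissivity = absorptivity, Kirchhoff).
* **H** — sensible heat, `P_a c_p g_h (T_leaf − T_air)` with `g_h` the
  two-surface (parallel) boundary-layer conductance to heat.
* **L** — latent heat, `h_vap·E` with `E = g_tw·d_wv` the transpiration
  rate driven by the saturated leaf interior versus the ambient vapour
  concentration.  Negative `d_wv` (dew) is an energy gain.

Every temperature-dependent quantity — emission, the leaf-interior
saturation vapour pressure, the latent heat, and the buoyancy term through
the virtual temperature of saturated air at the leaf surface — is
re-evaluated at each candidate `T_leaf`.  This is what distinguishes the
model from isothermal-net-radiation approximations, which freeze the
radiative and humidity terms at air temperature for speed.

## Boundary-layer transport

Forced convection is indexed by the Reynolds number `Re = u·d/D_m` and free
convection by the Grashof number
`Gr = G·d³·|T_v,leaf − T_v,air| / (T_v,air·D_m²)`, computed from **virtual**
temperatures `T_v = T/(1 − (1 − ε)p/P)` so that humidity differences drive
buoyancy even at equal kinetic temperatures.  Flat-plate correlations give
the Nusselt number: forced `Nu = a·Re^b` with laminar coefficients
(0.6, 0.5) up to `Re_crit = 4000` and turbulent (0.032, 0.8) beyond —
a genuine jump discontinuity representing the laminar→turbulent
transition — and free `Nu = c·Gr^d` with (c, d) = (0.5, 0.25).  Mixed
convection combines them as `Nu = (Nu_forced^m + Nu_free^m)^(1/m)` with
`m = 3.5`, which collapses exactly to either pure regime when the other
driver vanishes.  The Sherwood number (mass transfer) shares the same
coefficient table.  All coefficients, `Re_crit`, `m` and the asymmetry
factor below live in `PhysicalConstants`, so alternative correlations are a
constructor argument, not a code change.

Each surface gets its own conductances `g = D·Nu/d`.  Free convection is
damped by the factor `free_asymmetry = 0.5` on the stably-stratified side —
below a leaf warmer than the air, above a leaf cooler than it — because
buoyant plumes cannot develop against a stable density gradient.  The
stomatal ratio SR (stored on the logit scale) assigns `SR·g_sw` to the
upper surface and `(1 − SR)·g_sw` to the lower; cuticular conductance
`g_uw` is split equally, since cuticle covers both surfaces.  Per surface,
the (stomatal + cuticular) conductance — converted from molar
(µmol m⁻² s⁻¹ Pa⁻¹) to velocity units via the ideal gas law,
`g_vel = g·10⁻⁶·R·T` — acts in series with that surface's boundary-layer
conductance; a sealed path (zero conductance) carries no flux.  The two
surfaces add in parallel into `g_tw`.  With equal boundary layers `g_tw`
is maximal and symmetric about SR = 0.5, which is why amphistomatous
leaves transpire more than hypo- or hyperstomatous ones, especially in
still air.

The Archimedes number `Ar = Gr/Re²` classifies the regime: forced
(Ar < 0.1), mixed (0.1 ≤ Ar ≤ 10), free (Ar > 10); still air (Re = 0) is
free convection by definition.

## Empirical parameterizations

These closures are isolated each behind a single function so they can be
swapped without touching anything else:

* **Saturation vapour pressure** — Goff–Gratch over liquid water, within
  1 % of steam-table values over 273–320 K; validity restricted to
  (240, 340) K.
* **Latent heat of vaporization** — linear in T, calibrated to
  45.06 kJ mol⁻¹ at 0 °C and 43.99 kJ mol⁻¹ at 25 °C.
* **Clear-sky temperature** — `T_sky = T_air − 20 K × S_sw/(1000 W m⁻²)`:
  the sky equals air temperature in the dark and is 20 K colder at full
  sun.  The solver accepts any `(T_air, S_sw) → T_sky` callable in its
  place (e.g. a cloudy-sky model).
* **Diffusivity scaling** — `D(T, P) = D₀ (T/273.15)^1.75 (101.3246/P)`.

Evaluation temperatures where a choice had to be made: air density, the
diffusivities and the molar→velocity conductance conversion use `T_air`
(keeping the `T_leaf` dependence of the net flux confined to the physics
terms); the latent heat uses `T_leaf`, where the evaporation happens.  The
leaf intercellular air space is assumed saturated (RH = 1 inside).

## Solving

The net flux is strictly decreasing in `T_leaf` (emission is quartic,
sensible and latent losses increase monotonically), so the equilibrium is
the unique root.  It is found with Brent's bracketed method over
`[T_air − 30 K, T_air + 30 K]`, widened by doubling to at most 120 K if the
flux does not change sign, and clipped to [241, 339] K so candidate
temperatures stay inside the vapour-pressure validity range.  Tolerances:
absolute temperature 1e-10 K, which leaves the residual comfortably below
the 1e-6 W m⁻² convergence bound even at net-flux slopes of order
10² W m⁻² K⁻¹.  A solution reports `value` (the residual) and
`convergence` (0/1).  In batch mode failures are data: a grid row that
cannot be solved — e.g. an extreme scenario whose equilibrium lies outside
the admissible range — is returned flagged with `convergence = 1`, never
dropped and never an exception.  Grid execution is serial, so identical
inputs give bit-identical tables.

## Units

Calculations run in two modes that agree to better than 1e-10 relative:
a fast unitless mode in which floats are interpreted in each function's
canonical unit, and a unit-tagged mode (`units=True`, the CLI default) in
which every value crossing a function boundary carries explicit dimensions
and is checked and converted on entry (`Quantity(10, "cm")` for a leaf is
stored as 0.1 m; a pressure passed where a temperature belongs raises
`DimensionalityError`).  The layer is deliberately small: five SI base
dimensions, the units this model needs, no offset units (temperatures are
kelvin throughout).

## Validation ranges and the test conditions

Hard bounds (errors) are physical: fractions in [0, 1], positive lengths,
temperatures and pressures, non-negative conductances, fluxes and wind.
Soft bounds (warnings) flag implausible but not impossible values:
d ∈ [0.001, 1] m, abs_s ∈ [0.2, 0.9], abs_l ∈ [0.9, 1], g_sw ≤ 20 and
g_uw ≤ 1 µmol m⁻² s⁻¹ Pa⁻¹, P ∈ [50, 110] kPa, RH ≥ 0.05,
S_sw ≤ 1500 W m⁻², T_air ∈ [265, 320] K, u ≤ 15 m s⁻¹ — values spanning
field conditions from alpine to desert vegetation.

Property tests and the acceptance script draw random parameter sets inside
these ranges (leaf size log-uniform over 0.004–0.4 m, the rest uniform over
the sub-ranges listed in `tests/conftest.py`).  Those draws exercise the
model across regimes (forced through free convection, dew through strong
transpiration) but they are synthetic scenarios, not field data: passing
them shows the solver is correct and the physics internally consistent, not
that the closures (clear-sky model, flat-plate correlations) match any
particular canopy.  The brute-force oracle used to check the solver scans
the net flux at 0.1 K resolution over the full bracket (verifying the
single sign change) and refines the crossing interval at 0.001 K; it shares
the flux function but is independent of the root-finding path it checks.
Problem sizes — 100 draws for energy closure, 20 for the oracle comparison,
50 for dual-path agreement — keep the whole suite and the acceptance script
in a few seconds at desk scale while giving the maxima being reported
stable orders of magnitude.

## Known limitations

Equilibrium only (no transient approach to it); horizontal homogeneous
leaves (no leaf angle, no within-leaf temperature gradients); simple
clear-sky and direct-beam radiation treatment; no coupling to
photosynthesis or stomatal-optimization models — the stomatal conductance
is an input, not a response.  The flat-plate correlation coefficients are
engineering standards for smooth plates; real fluttering, rough leaves can
depart from them, which is why they are exposed as constants.
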