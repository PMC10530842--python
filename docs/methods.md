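# Methods

## The process being modelled

A hot agarose solution (2% w/w, poured at 85 °C) freezes inside an
aluminum mold standing in a glycol chiller bath. Growing ice crystals
template the pore network of the resulting cryogel, so the local freezing
rate controls the local pore size: slow freezing grows large crystals,
fast freezing near the cooled walls leaves fine pores. The package
simulates the thermal history of the sample, converts late-stage cooling
rates into crystal-size estimates, extracts freezing times from
thermocouple-style traces, and measures sample geometry and stress in
unconfined compression tests from silhouette photographs.

## Freezing model

### Domains and boundaries

The solver treats the solid parts of the setup in 2-D axisymmetric (r–z)
coordinates: the gel (10 × 10 mm r×z) on a 5 mm aluminum mold base,
surrounded by a 5 mm aluminum wall out to r = 15 mm, closed from above by
a PLA cap plate (the cap is 17 mm tall in hardware; only its 5 mm plate
participates thermally, the rest stands in ambient air), optionally
resting on a Pyrex beaker bottom. The bath and air are not simulated as
fluids. Instead:

* surfaces below the immersion level exchange heat with an ambient equal
  to the chiller set point + 2 °C (the measured contact offset) through a
  convective coefficient `h_bath`;
* air-exposed surfaces see 10 °C through `h_air` (default 10 W/m²K);
* the still-liquid gel gets an effective conductivity multiplier
  `kappa_liquid_factor` (default 8) representing natural convection in
  the solution before it gels and freezes. Without it, a conduction-only
  liquid develops tens of kelvin of internal spread and the sample cannot
  supercool nearly uniformly to the nucleation temperature, contrary to
  the simultaneous recalescence all probes actually record. The factor is
  sized so the pre-nucleation radial spread stays below the ~8 K
  supercooling depth at the coldest bath; once a cell has nucleated its
  conductivity reverts to the solid/liquid mixture.

`h_bath` is the single calibration constant of the thermal model. It was
set once, to 150 W/m²K, so that the simulated freezing-time scale matches
the measured one (freezing time ≈ 0.94 min at the probe 6.7 mm from the
axis in the −25 °C run; wall freezing under a minute; full solidification
within the 20-minute protocol at −12 °C). No pore-size information was
used in that calibration.

### Phase change

Freezing is handled with a conservative enthalpy formulation. Every cell
carries a volumetric enthalpy H and reads its temperature off a
precomputed monotone H(T) curve. The gel has two branches:

* **liquid branch** — pure (super)cooled liquid; latent heat still
  stored. Liquid water properties are treated as constant below 0 °C.
* **nucleated branch** — the apparent-heat-capacity mixture: sensible
  heat of the θ-weighted solid/liquid mixture plus the latent heat of
  fusion distributed over a transition interval `[T_f − 2·dT_trans, T_f]`
  (default half-width `dT_trans` = 0.5 K) as a truncated-Gaussian pulse
  with width parameter `a = dT_trans/2`, the standard apparent-heat-
  capacity form. The solid fraction label θph1(T) is a cubic smoothstep
  over the same interval (a linear ramp is available).

A gel cell switches branch when it first reaches the crystallization
onset `Tc` (−8 °C, the experimentally observed average), **or** — once
ice exists in contact with it — as soon as it is below `T_f`: deep
supercooling is required only for the first nucleation event; growth then
propagates into any subcooled liquid. At the switch the cell's enthalpy
corresponds to a point well up the nucleated branch, so its temperature
relaxes upward (recalescence) at the rate set by the nucleation source
`Qn = λ·k_i·(T_f − T*)` with `k_i` = 430 kg/(m³ K s), and then freezes
along the plateau under conduction control. Because sensible and latent
heat live in one enthalpy variable, the nucleation burst and the plateau
share a single latent budget; nothing can be released twice.

### Discretization and conservation

Finite volumes on a structured axisymmetric grid (default spacing 1 mm,
faces aligned with every material interface), harmonic-mean face
conductivities, implicit backward-Euler steps (default dt = 0.5 s) with
capacities lagged one step, followed by an exact enthalpy update and a
curve-consistent temperature read-back. The energy ledger (stored
enthalpy vs boundary-flux integral) closes to machine precision by
construction; the `energy_residual` on every result makes that checkable.
Probes are bilinearly interpolated between the four surrounding gel cell
centers, so probe readings refine smoothly with the grid.

Halving the grid spacing and the time step moves plateau-entry, local
freezing-completion and global solidification times by under 2%. The
plateau *duration* tc = tcf − tci at a probe is a small difference of two
such times and can shift by up to ~8% between refinement levels. The
volume-averaged pore diameter is tied to how sharply the grid resolves
the freezing front; all reported numbers use the default 1 mm / 0.5 s
discretization.

### Verification against the Stefan problem

With supercooling disabled (`Tc = T_f`), a 1-D slab configuration, a
constant-property equal-density water/ice registry (the idealization the
Neumann similarity solution assumes; shipped as
`synthetic.constant_property_registry`), a tightened transition
(`dT_trans` = 0.2 K), 0.25 mm cells and dt = 0.1 s, the simulated frozen
front tracks the analytic solution within 2% for times at which the front
spans at least ~8 cells (t ≥ 200 s under the test conditions); earlier
the smeared transition is under-resolved and the error transiently
reaches ~2.5%.

## Pore-size estimation

The empirical correlation `d_p [μm] = 50·v_c^(−0.25)` converts the local
freezing rate to a solvent-crystal (pore) diameter, with `v_c` defined as
the mean |dT/dt| while the local solid fraction crosses 0.96–0.99
(near-complete freezing). Where that window spans two or more stored
samples, `v_c` is the trapezoid-weighted mean of centered finite
differences. Cells near the cooled wall cross the whole window within a
single 0.5 s step; a raw one-step slope there would mix the in-window
rate with the much faster post-plateau crash and bias the estimate. For
such degenerate windows `v_c` is recovered from the energy balance
instead: the volumetric heat-extraction rate across the crossing step
(enthalpy drop read off the gel's H(T) curve) divided by the window's
mean apparent heat capacity — exactly the |dT/dt| the window would show
if it were resolved. An endpoint-slope variant is exposed as an option.

The correlation is applied per cell and only then averaged; sample-level
summaries use the axisymmetric volume average (2πr weighting). Crystal
coalescence into channels, which microscopy shows at the warmer set
points, is outside the correlation's scope.

## Freezing-window detection

Traces are lightly smoothed (centered 3-point median) for detection; raw
samples are used for reported temperatures. The plateau entry `t_ci` is
the first sample that jumps up into `T_f ± band` (band default 0.5 K)
after a supercooling nadir; the exit `t_cf` is the first sample that
falls below `T_f − band` permanently *and* keeps decreasing, which is
operationalized as a sustained drop of ≥ 2 K within 30 s (a slower
collapse falls back to the permanent band exit). Entry requires either a
3-sample dwell in the band or a continuous residence until a permanent
downward exit, so near-instant wall freezes are still windowed. The
onset temperature is the raw value at the first sub-zero local minimum
followed by a ≥ 1 K rise within 3 samples.

## Compression-test image metrology

The camera model is a pinhole calibrated at the sample's vertical
symmetry plane: conversion factor `base_scale` (px/mm) at the plane and
`scale_at(d) = base_scale·W/(W − d)` for points `d` mm closer to the lens
(`W` = working distance). For an image column at lateral offset `R_c`
from the cylinder axis, the visible surface lies `d_i = sqrt(R² − R_c²)`
in front of the symmetry plane, so column heights are converted at
`scale_at(d_i)`; diameters are measured from row widths at the base
scale. Frames are segmented by Otsu threshold (fixed override available),
closed with a 3×3 element, and the largest connected component is taken
as the sample; rows/columns within 5% of the silhouette's extremes are
excluded from the averages. Frames whose height drops more than 3 MAD
below a rolling median are flagged (water expelled during compression
can shadow the sample's lower edge) but never deleted; the MAD is floored
at 0.5% of the median height so dropouts are caught even in otherwise
constant sequences. Engineering stress is force over the initial
cross-section, `σ = F/(π d0²/4)`, with `d0` from the first (pre-contact)
frame.

## Synthetic data

The generators exist so each stage is testable without laboratory data;
all are seed-deterministic.

* `synth_probe_trace` emulates the measured trace morphology: exponential
  cooling ramp to a supercooling nadir, recalescence jump, exact plateau
  at 0 °C between `t_ci` and `t_cf` (snapped to the 1.5 s sampling grid so
  the ground truth is actually sampled), then exponential decay toward the
  bath with a 25 s time constant — a decisive one-sample exit from the
  detection band, matching the sharp measured collapse. It does not
  emulate sensor quantization, drift, or the slow within-plateau slide a
  wide numerical transition produces.
* `render_cylinder_sequence` rasterizes the cylinder silhouette under the
  same pinhole projection the metrology inverts (every surface point
  scaled at its own depth), with optional seeded pixel noise. It renders
  ideal high-contrast silhouettes: no blur, glare, meniscus, or the
  water-film artifacts of real footage — so passing recovery tests shows
  the geometry pipeline is unbiased, not that segmentation is robust to
  arbitrary lighting.
* `stefan_oracle` is the two-phase Neumann similarity solution (front
  `s = 2Λ√(α_s t)`, Λ from the interface energy balance solved by
  bracketed root finding to 1e-12) used purely as the solver's analytic
  oracle.
* `relaxation_force` is a shape fixture (ramp + exponential relaxation)
  for exercising the stress pipeline; it implements no constitutive
  model.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `bath_setpoint_C` | −19 °C | chiller set point (−25/−19/−12 studied) |
| `bath_contact_offset_K` | +2 K | measured bath-contact temperature offset |
| `Tc_C` | −8 °C | crystallization onset (equal to `T_f` disables supercooling) |
| `T_f_C` | 0 °C | freezing front temperature |
| `dT_trans_K` | 0.5 K | transition half-width of the apparent-Cp pulse |
| `k_i` | 430 kg/(m³ K s) | nucleation-rate constant in Qn |
| `h_bath` | 150 W/m²K | bath convection (the calibrated constant) |
| `h_air` | 10 W/m²K | air-side natural convection |
| `kappa_liquid_factor` | 8 | effective liquid-gel conductivity multiplier |
| `grid_size` / `dt` | 1 mm / 0.5 s | discretization |
| `trace_interval` | 1.5 s | probe sampling interval |
| probe points | r = 0, 6.7, 9.6 mm at z = 1.5 mm | thermocouple locations |

## Known limitations

* The fluid dynamics of bath and air are reduced to two constants plus
  the liquid-conductivity factor; transient bath stratification and the
  air gap under the cap are not represented.
* The numerical transition width (1 K by default) makes the simulated
  plateau drift from ≈ −0.1 to −1 °C instead of sitting at exactly 0 °C,
  so band-based window durations are interpreted on that smeared shape.
* At −12 °C the onset margin over the bath contact temperature (−10 °C)
  is only 2 K; nucleation timing there is sensitive to `h_bath` and
  `kappa_liquid_factor`.
* Pore-size estimates inherit the front-resolution dependence described
  above and the correlation's own scatter; they are first estimates, not
  pore-size-distribution predictions, and crystal fusion into channels is
  not modelled.
* Mechanical results are validated on synthetic silhouettes only;
  measured peak stresses of real cryogels are not reproducible from this
  model and are out of scope.
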