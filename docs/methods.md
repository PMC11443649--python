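# Methods

## The physical problem

A focused Ga⁺ beam dwelling on one scan point delivers ions at the mean rate
*I*/*e* (114 ps apart at 1.4 nA). Each ion thermalizes within nanometers,
depositing most of its kinetic energy as heat (phonon + ionization losses) in
a track comparable to its projected range. In a good conductor this heat is
carried away between impacts; in collagen (k = 0.29 W·m⁻¹·K⁻¹) it
accumulates, and sustained nanoampere irradiation can exceed the ~65 °C
collagen→gelatin denaturation threshold. Lowering the acceleration voltage
from 30 to 5 keV cuts the per-ion heat loss ~6× (28.9 → 4.7 keV) while the
sputter yield only halves (2.9 → 1.4), so milling at low energy is ~3× faster
per unit heat — the quantitative case this package makes computable.

## Steady-state spot model

The closed-form estimate treats the irradiated spot as a disc of effective
diameter d_eff = max(native diameter, blur diameter) conducting the full beam
heat flux P = ΔE_heat[eV]·I[A] through a slab of thickness R_proj:

    ΔT = P · R_proj / (k · π (d_eff/2)²).

Assumptions: one-dimensional conduction across the range depth only (no
lateral spreading resistance), steady state, constant properties. The model
is deliberately simple and is exact bookkeeping otherwise: heat flux equals
heat loss per ion times arrival rate; dose rate and dose are the arrival rate
divided by the spot area, per µs and per dwell respectively. Scan-point
overlap is carried as metadata only — no per-spot quantity depends on it.

Because it ignores lateral spreading, this model *underestimates* the true
quasi-steady spot temperature whenever R_proj ≪ d_eff (the 5 keV regime:
15.4 nm vs 50–246 nm); the transient simulator shows the difference
(see "Known discrepancies").

## Transient FTCS simulator

The heat equation ∂T/∂t = α∇²T is integrated on a uniform voxel grid with
the explicit 7-point forward-time centered-space stencil. Defaults copy the
reference configuration: 600 × 600 × 400 nm domain, Δx = 5 nm
(120 × 120 × 80 voxels), ambient 298.15 K (25 °C, chosen so a 35 K rise
reads "approximately 60 °C"), four lateral faces and the bottom clamped to
ambient, top face insulated via a mirror ghost layer (no dissipation into
vacuum).

* **Stability.** Δt ≤ Δx²/(8α) = 23 ps for collagen — stricter than the
  classic 3D von Neumann limit Δx²/(6α) ≈ 31 ps. The default step is the
  largest value within the bound that divides the 0.1 ns snapshot cadence
  evenly (20 ps), so snapshots land exactly on steps.
* **Source model.** Ions arrive at exactly e/I intervals (first at t = 0; the
  equal-interval schedule is the modelled quantity, shot noise is not
  included), positioned uniformly on the experimental spot disc by default, or
  from an isotropic Gaussian (FWHM = stated diameter, σ = FWHM/2.355; the
  reference figure caption mentions a "50 nm Gaussian profile" without
  defining it, so the parameterization is configurable). Each impact raises a
  10 × 10 × 20 nm track cuboid (top face at the surface, laterally snapped to
  the nearest voxel block, ties toward the negative axis; arrival snapped to
  the nearest step, ties down) uniformly by
  ΔT = 0.9·E / (ρ c_p V_track) ≈ 94.4 K for 5 keV — energy closes exactly on
  the grid. The heat fraction 0.9 follows the stated source model (the
  stopping table itself implies 4.7/5 = 0.94; both are available via
  `heat_fraction`). For 30 keV cross-checks a 20 × 20 × 45 nm track (range
  467 Å) is used.
* **Diffusivity inconsistency.** The tabulated collagen constants are
  internally inconsistent: stated α = 1.36 × 10⁻⁷ m²/s ≠ k/(ρc_p) =
  7.6 × 10⁻⁸. The stated α drives the diffusion stencil (it reproduces the
  23 ps bound); ρc_p converts deposited energy to temperature. `Material`
  stores both and logs the mismatch.
* **Storage.** Scalar global- and surface-maximum traces are recorded every
  step; stored arrays (optional surface planes per snapshot, the final 3D
  field) are quantized to mK, mirroring the reference storage precision.
  Full 3D fields at every 0.1 ns snapshot would be ~10 GB for the headline
  run and are not kept by default.
* **RNG.** numpy's counter-based Philox generator, seed recorded in every
  trace; identical seeds give bit-identical runs.

### Validation

* Single-voxel deposits diffused ≥10 steps agree with the instantaneous
  point-source Green's function (image source across the insulated surface)
  to 1–3 % at the peak voxel.
* With all-Neumann test boundaries, total excess thermal energy
  Σ ρc_p (T − T_room) Δx³ is conserved to 10⁻¹⁰ relative over hundreds of
  steps, and increases by exactly 0.9·E per deposit.
* Maximum principle holds without sources; the numba kernel and the pure-numpy
  fallback agree to 10⁻¹² K.
* Fitted single-impact cooling constants: 251 ps for the 5 keV track and
  988 ps for the 30 keV-parameterized track (reference finite-element values:
  ~170 ps and ~1 ns — order agreement; the source models differ).

## Synthetic data

`generate_stream` emulates exactly what the solver assumes: equal-interval
arrivals and per-impact independent positions (uniform-disc radial CDF ∝ r²,
χ²-tested on equal-area annuli; truncated Gaussian available). It does not
emulate raster scanning within the spot, beam tails, current fluctuation or
Poisson arrival statistics — a green simulation test therefore establishes
correctness of the stated source model, not realism of a physical beam.
`analytic_fixture` evaluates the free-space/image Green's kernel on the grid
as the solver oracle; its voxel quadrature recovers the deposited energy to
≤1 % once 4αt ≥ (3Δx)².

## Known discrepancies with the reference values

* **Steady-state table.** From the printed inputs the model gives 7.35, 3.69
  and 4.41 K where the published table prints 7.5, 3.8 and 4.5 — consistently
  one unit low in the last printed digit (all other cells match exactly after
  rounding). Comparisons therefore use printed-precision rounding (half away
  from zero) with a one-last-digit tolerance.
* **Headline transient run.** For 5 keV / 1.4 nA / 246 nm / 990 ns the
  published claim is a surface rise below 35 K. The faithful simulation of
  the stated parameters yields a final-snapshot surface maximum of 62–67 K
  across seeds (quasi-steady background ~46 K). This is not a solver artifact:
  the steady disc-source-on-half-space limit gives
  ΔT_center = P/(π a k) ≈ 56 K for these parameters, minus ~10 K for the
  Dirichlet box — consistent with the simulation, and the stepper is pinned
  to the analytic kernel by the oracle tests. The published number cannot be
  regenerated from the stated inputs; the corresponding acceptance check is
  intentionally left failing and reports the computed value. The 29 pA
  companion claim ("well below 10 K") is reproduced (quasi-steady ≈ 1.5 K).
* **Snapshot-phase sensitivity.** At 1.4 nA the impact interval (114 ps)
  exceeds the 0.1 ns snapshot cadence, so nearly every snapshot contains a
  freshly deposited, still-hot track: the surface maximum oscillates between
  ~46 and ~100 K depending on phase. Traces report the (min, max) over the
  final 100 snapshots alongside the final-snapshot value and the median;
  none of the three statistics reaches 35 K or below.
* **30 keV table row.** The printed dose and ΔT imply an effective spot
  diameter ≈ 230 nm that no stated input produces (native 30 keV diameter
  unstated); the row is emitted flagged "not reproducible from printed
  inputs" rather than silently recomputed.

## Other choices and limitations

* ice_cryo preset: conductivity 2.5 W·m⁻¹·K⁻¹ (midpoint of the 2–3 range);
  density 917 kg/m³ and c_p 2100 J·kg⁻¹·K⁻¹ are standard ice values with α
  derived, since only k is given in the source discussion.
* Impacts whose track cuboid would cross a lateral Dirichlet face are
  rejected (the spot is always far smaller than the domain; the guard exists
  for misconfiguration, with an opt-in clip-and-warn mode).
* Out of scope: per-path electronic-stopping deposition (particle tracing),
  implicit/adaptive stepping, temperature-dependent properties, denaturation
  kinetics (threshold comparison only), glancing incidence and anisotropic
  interaction volumes.
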