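# Methods

## Mechanical model

The monofilament is modelled as an ideal slender elastic column. The
critical buckling force is Euler's closed form F_c = π² E I / L_e² with
the circular-section second moment I = π d⁴/64 and effective length
L_e = k L. Two contact regimes are supported as named presets: firm
clamped–pinned contact (k = 0.7) and clamped with a pinned-and-sliding
free end (k = 2.0); any other k is available as a `custom` boundary
condition. The model assumes linear elasticity, a perfectly straight
prismatic column, static loading and no imperfections; it predicts the
onset of buckling only, not the post-buckling shape (no elastica,
no finite-element analysis, no viscoelastic or creep behaviour).

Euler theory is a slender-column theory. The package computes the
effective slenderness L_e/(d/4) and emits a warning — without refusing to
compute — when it falls below 30. The threshold is this package's own
convention: clinical monofilaments sit far above it (the 0.61 mm × 38 mm
device has slenderness ≈ 174), so the warning only fires for geometries
well outside the intended regime.

The inverse operation E = F_c L_e²/(π² I) estimates Young's modulus for a
device of unknown material from a measured critical force. It is the
exact algebraic inverse of the forward formula, and the round trip is
property-tested to relative error below 1e-12.

### Self-weight deflection

Held horizontally the filament is a cantilever under its own distributed
weight w = (π d²/4) L ρ g. The tip deflection uses the classical
uniformly-distributed-load solution δ = w L³/(8 E I) ≡ q L⁴/(8 E I) with
line load q = w/L, valid for small deflections (δ < L/10); results carry
a validity flag instead of raising when the bound is exceeded. The
relative deflection δ/d is reported because it governs whether a device
shows an overshoot in its compression curve.

### Units and constants

Internally everything is SI (m, N, Pa, kg·m⁻³). Interfaces accept the
units monofilaments are actually specified in — mm, gf, GPa — and convert
on entry/exit, because device labels, bench instruments and data sheets
mix these freely. Standard gravity is fixed at 9.80665 m·s⁻² and is the
single constant behind all gf↔N conversions; it is deliberately not
configurable.

The default density is 1140 kg·m⁻³ for extruded Nylon 6.6. The
literature quotes values from 1100 to 1150 for this material; 1140 is
adopted here because it makes the deflection predictions internally
consistent with the published per-device values this package reproduces
(the reference device's 81.81 µm and the short/thick device's 55 µm),
which 1100 does not (it gives 78.9 µm). Any density can be passed
explicitly wherever the default is used.

### Environmental corrections

Nylon's modulus drifts with temperature and humidity; to first order
E(T) = E₀(1 − α(T − T₀)) and E(H) = E₀(1 − β(H − H₀)). The coefficients
α, β are manufacturer-specific and have **no defaults**: operations that
need them fail loudly (`ConfigurationError`) when unset, rather than
silently assuming a material. When both corrections apply they compose
multiplicatively, E₀(1 − αΔT)(1 − βΔH) — a convention of this package,
chosen because it is order-independent, reduces exactly to either single
correction when the other coefficient is zero, and agrees with the
additive composition to first order. A correction that would drive E ≤ 0
is outside the linear model's validity and raises.

## Sensitivity sweeps

`critical_force_grid` evaluates F_c (reported in gf) on a linearly spaced
(L, d) grid; linear sampling is this package's choice, and plotting is
left to downstream tooling. `deflection_tolerance_table` evaluates δ on
the 3×3 grid of {−v, 0, +v} fractional variations of d and L (default
v = 0.10, the usual manufacturing-tolerance scenario). Each cell reports
the absolute deflection (µm), the change relative to the reference cell
(δ%), and the deflection as a fraction of that cell's own diameter (δ%d).
Because δ ∝ ρ L⁴/(E d²), the δ% cells equal (1+ΔL)⁴/(1+Δd)² − 1
identically — independent of E and ρ — which serves as a closed-form
oracle in the tests. The printed table rounds µm to two decimals and
percentages to integers (half away from zero), matching how such tables
are conventionally reported; unrounded values remain available.

`boundary_condition_comparison` takes per-device (geometry, measured
force at k = 0.7) pairs, estimates each device's modulus, recomputes the
force for the sliding regime (k = 2.0; identically 0.1225× the measured
force), and reports the mean modulus across devices.

## Curve and fatigue metrology

A measured compression cycle shows a linear ramp followed by a buckling
plateau, sometimes after a transient overshoot. `extract_features`
reduces a sampled cycle to:

- **critical force** — the global maximum of the trace. The choice of
  maximum (rather than, say, the breakpoint force) is this package's
  explicit convention; it matches the observation that first-cycle peaks
  dominate fatigue series.
- **plateau force** — mean over the final 20 % (configurable) of the
  displacement span.
- **initial stiffness** — least-squares slope over the first
  max(5 samples, 10 % of the trace).
- **breakpoint displacement** — first point where the centred-difference
  local slope falls below 20 % (configurable) of the initial stiffness.
  Points inside the stiffness-fit window are excluded so a flat start
  cannot masquerade as buckling. A trace whose slope never drops is
  flagged "no buckling detected" (warning + flag, not an error).
- **overshoot index** — (critical − plateau)/plateau.

No smoothing beyond the slope window is applied; heavily noisy traces
should be averaged upstream rather than filtered here.

`analyze_fatigue` summarises a per-cycle critical-force series by its
first-cycle force, the mean ± SD over cycles ≥ 3 (configurable), the
total decay percentage 100·(F₁ − plateau)/F₁, and a monotone-decay flag
that tolerates cycle-to-cycle increases up to 0.03 gf — the instrument's
stated precision below 100 gf.

`verify_monofilament` compares a measured summary (curve plateau or peak,
fatigue plateau or first cycle, or a bare number) against the nominal
force, defaulting to 10 gf. The default ±10 % acceptance band is this
package's convention — no standard prescribes one — and every report
carries the band used; the verdict is band-edge inclusive.

`display_round` reproduces the bench display: one decimal below 100 gf,
nearest unit from 100 to 500 gf, with range classification applied after
rounding (99.96 → 100) and a hard `OverloadError` above the 500 gf
admissible load. Rounding is half-away-from-zero, the behaviour of
everyday instrument displays; only the resolution, not the rounding mode,
is dictated by the instrument specification.

## Agreement statistics

`bland_altman` fixes the difference direction as candidate − reference
(stated in every output), uses the sample SD (n−1) and the conventional
1.96 multiplier for the limits of agreement with no small-sample
t-correction. `reference_point_summary` gives per-group mean ± sample SD
in input order; `mean_relative_error` averages 100·|candidate −
reference|/reference. No proportional-bias regression extension is
provided.

## Synthetic bench data

The generators emulate the three data shapes the physical bench produces,
with exactly known ground truth:

- **Curves**: linear ramp at the specified stiffness up to the critical
  force, then exponential relaxation onto the plateau with displacement
  constant λ = 10 % of the span (configurable; the decay shape of real
  devices is not standardised, so it is exposed as a spec field). The
  relaxation is anchored to the first sample grid point at or after the
  ramp peak so the sampled trace attains the critical force exactly.
  Defaults: 10 mm span (the stroke that produces the recommended buckling
  curvature) sampled at 0.08 mm (the bench's displacement resolution).
- **Fatigue series**: F(n) = plateau + (first − plateau)·exp(−r(n−1)),
  n = 1..20 cycles by default, mirroring the bench stress-test protocol
  of 20 compressions at 3 s intervals.
- **Pairs**: reference = truth + N(0, σ_ref²), candidate = truth + bias +
  N(0, σ_cand²), with an optional uniform [1, 1.25] jitter of the truths
  emulating the validation protocol's randomised reference increase.

Noise is additive Gaussian, clipped at zero; the default σ = 0.03 gf is
the instrument's stated precision in the sub-100 gf range. Every
generator is a pure function of its spec including the seed
(`numpy.random.default_rng`), so identical specs give bit-identical
output.

What the generators do **not** emulate: transducer drift, contact
detection transients, viscoelastic speed dependence (the speed field is
metadata only), temperature/humidity drift during a run, and the bimodal
manufacturing clusters seen across real device fleets (mixtures can be
composed from multiple specs). Passing round-trip tests therefore
demonstrates correctness of the analysis pipeline on idealised traces
with the documented morphology, not robustness to every artefact of
physical hardware. Bench-measured quantities themselves — per-point force
tables, the instrument's ~0.28 % mean relative error, measured force
contours and their averages — are inputs from physical hardware, not
outputs this package can recompute.

## Numerical choices and problem sizes

Feature extraction uses `numpy.polyfit` for the stiffness line and
`numpy.gradient` (centred differences) for local slopes; no other fitting
or optimisation is involved, and all mechanics are closed-form, so every
headline quantity is exact to machine precision. Statistical tests run at
modest sizes chosen so estimator error bounds (3σ/√n) are meaningful:
curve traces of ~125 samples, 20-cycle fatigue series, and up to 10⁴
measurement pairs for bias-recovery checks. Property tests draw from
realistic monofilament ranges (d ∈ [0.1, 2] mm, L ∈ [10, 100] mm,
E ∈ [0.5, 10] GPa, ρ ∈ [900, 1500] kg·m⁻³) with derandomised hypothesis
profiles so runs are reproducible.

## Known limitations

- The Euler model ignores imperfections, pre-curvature and plastic
  damage, all of which lower real buckling loads; predictions are upper
  bounds for worn devices.
- The deflection formula is the linearised small-deflection solution;
  for δ ≥ L/10 the validity flag trips and the value should be treated
  as indicative only.
- The environmental corrections are first-order and uncalibrated here:
  α and β must come from the material manufacturer.
- Breakpoint detection is a heuristic on sampled slopes; traces with
  extremely slow post-buckling decay relative to the noise floor can
  evade it.
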