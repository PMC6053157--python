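# Methods

This note documents the models, numerical choices and limitations of
`hemorheo`, in the order data flow through the package.

## Two-fluid stratified duct flow

**Model.** Steady, fully developed, incompressible Stokes flow of two
immiscible-in-practice fluids side by side in a rectangular channel
(width *w* across the streams, depth *h*, aspect ratio β = h/w ≈ 0.545
for the 110 × 60 μm default). The interface is assumed flat and
vertical at y = Y·w (centerline origin); fluid 1 (reference) occupies
y > Y·w. Diffusion and interface curvature are neglected — appropriate
at the Re ≪ 1, Pe-limited conditions of the bench device — and so is
any unsteadiness.

**Series solution.** The axial velocity is expanded in sin(nπz/h)
modes; each odd mode solves a 1-D Helmholtz equation across the width
with no-slip side walls and continuity of velocity and shear stress
μ ∂u/∂y at the interface. The resulting modal interface velocity is

    U_n = p_n (tanh(kL₁/2) + tanh(kL₂/2)) / (μ₁ coth(kL₁) + μ₂ coth(kL₂)),

with k = nπ/h, L₁, L₂ the stream widths and p_n the modal pressure
forcing. The O(1/n⁴) part of the flow-rate sum telescopes exactly to
the plane-Poiseuille base flow G h³ L_i/(12 μ_i) per stream and is
summed in closed form; the remaining correction decays like 1/n⁵. All
hyperbolic ratios are tanh/coth of positive arguments, so the series is
overflow-safe at any aspect ratio and interface position.

**Truncation.** Defaults: 2000 odd modes, relative tolerance 1e-10 on
the last term of both stream sums. Convergence slows when one stream is
very thin (terms only begin their asymptotic decay once k·min(L₁,L₂) ≳
1), which sets the generous default mode count; a violation raises a
convergence error carrying the last two partial values. Cost is a few
vectorized array operations — microseconds per evaluation.

**Inversions.** Viscosity ratio from flow ratio: bracketed root search
in log r over [1e-3, 1e3] with Brent's method (xtol 1e-14), after a
numerical monotonicity check of the forward map across the bracket.
Interface position from (flow ratio, viscosity ratio): Brent over
Y ∈ [−0.4995, 0.4995]. Both solve the forward model to ~1e-10 relative.

**Finite-difference oracle.** ∇·(μ∇u) = −G is discretized in
conservative (flux) form on a grid built from two uniform blocks
sharing the interface grid line; face viscosities are taken from the
fluid each face lies in, which enforces shear-stress continuity
naturally, and the interface node uses the mean viscosity for its
depth-direction fluxes. Direct sparse solve. Against the classical
single-fluid duct series the 201×201 solution is accurate to ~9e-5
relative in flow rate; against the two-fluid series solution it agrees
to better than 0.1% across viscosity ratios 0.2–20 and |Y| ≤ 0.3. The
FD solver is the independent check on the series (and vice versa) and
the field generator for synthetic experiments; the two are never
collapsed into one code path.

**Units.** SI internally (Pa·s, m, m³/s); μm, cP and μL/hr at the
interfaces, converted once (`hemorheo.units`).

## Micro-PIV

* **Background removal**: per-pixel temporal minimum (default; robust
  for sparse bright tracers on a static background) or temporal mean.
  The estimate needs a handful of frames with independent particle
  positions to converge; the default measurement uses 100 pairs.
* **Correlation**: two passes, 64 px then 32 px windows at 50% overlap.
  The coarse pass supplies an integer predictor that shifts the
  second-pass windows in frame B, keeping the residual displacement
  small. Windows are mean-subtracted and weighted by an anisotropic
  Gaussian elongated 4:1 in the streamwise direction — the elongated
  weighting matches unidirectional microchannel flow, concentrating
  correlation energy along x.
* **Subpixel peak**: three-point Gaussian interpolation per axis, with
  a parabolic fallback when a neighbor is non-positive.
* **Validation**: normalized median test (threshold 2.0, ε = 0.1 px,
  3×3 neighborhood); outliers are replaced by the local median and
  *marked*, never silently overwritten. Flat windows are flagged
  invalid, not raised.
* **Accuracy**: uniform shifts of 2–10 px at ≥ 0.02 particles/px²
  recover to < 0.02 px RMS (tested bound 0.1 px). Window centers on the
  frame border see a truncated particle field and are biased; profile
  fits use interior windows.
* **Averaging**: temporal mean and RMS (the exact sample standard
  deviation, computed in the N·Σu² − (Σu)² form) per grid point over
  the N fields, then a streamwise mean along the visualization window.
* **Shear rate**: ordinary least squares on u(y) over the central 80%
  (configurable) of the blood layer, slope converted (mm/s)/μm → 1/s.
  The layer itself is the maximal contiguous interval where the
  transverse tracer-density profile exceeds half its maximum, with
  subpixel edges by linear interpolation. dt defaults to the value
  placing the fastest tracer at 8 px/frame (6–10 px working range).

The measurement plane is treated as the channel mid-depth plane;
depth-of-correlation effects are out of scope.

## Aggregate imaging

* **Flat-fielding**: divide by a background estimated with a triple box
  filter (≈ Gaussian) at a scale of a quarter of the frame height —
  far above the ~8 μm cell scale — using odd-reflection padding so a
  linear illumination ramp is reproduced exactly; renormalized to the
  original median.
* **Threshold**: Otsu on the corrected frame (objects are the dark
  class), or a fixed threshold by configuration. Because Otsu always
  splits *something*, a frame is declared object-free unless the
  inter-class contrast exceeds 4 background standard deviations —
  Gaussian noise alone separates its halves by only ~1.6 σ.
* **Cleanup**: binary hole filling; removal of components below
  20 μm² (≈ one RBC projected area; configurable) as debris;
  8-connected labeling. Border-touching objects are kept by default.
* **Sizing**: area = pixel count × (pixel scale)², exactly quadratic in
  the scale (0.2 μm/px default for the high-speed camera).
* **Statistics**: per-frame mean area, then mean and standard error of
  the per-frame means over the recording; frames with no detections are
  excluded from the mean-of-means and counted separately. Size classes
  use half-open bins with default edges {0, 100, 500, 1500, 3500, ∞}
  μm², chosen to bracket the ranges reported for 5–15% H suspensions;
  fully configurable. No frame-to-frame tracking is attempted — sizes
  are re-measured per frame, matching the frame-averaging procedure.
* No distinction is made between 1-D rouleaux and 3-D clusters.

## Rheology fits

* **Power law**: OLS of log μ on log γ̇; slope = n − 1, intercept =
  log K. Exact for noiseless model data; K is reported in the curve's
  viscosity unit × s^(n−1) (for cP-scale curves, cP·sⁿ⁻¹) and the unit
  recorded with the fit, with no silent conversion.
* **Carreau** (shape a = 2, Carreau–Yasuda available by overriding a):
  Levenberg–Marquardt on residuals in linear viscosity, with μ₀, μ∞, λ
  optimized as logarithms so positivity is structural. Data-driven
  initialization μ₀ ← max μ, μ∞ ← min μ, λ ← 1 s, n ← 0.5. λ may be
  held fixed; the RMSE degrees of freedom adjust (p = 4 − #fixed).
* **Goodness of fit**: R² on the linear viscosity scale (reported for
  familiarity even though it is a weak diagnostic for nonlinear fits)
  together with RMSE = sqrt(Σ(μ_exp − μ_fit)²/(m − p)).
* **Identifiability**: λ trades off against μ₀ around the knee of the
  curve; with 2% multiplicative noise on 60 points its recovery error
  is typically ~12% while μ₀ and n recover within a few percent. This
  is why pinning λ is supported — published low-hematocrit tables show
  λ nearly constant (≈ 3.31 s) across all conditions, consistent with a
  pinned or initialization-dominated value. Negative fitted n is
  accepted with a warning (one published 37 °C row prints n = −0.152).
* The Casson yield-stress law is deliberately not implemented.

## Synthetic data: what it emulates — and what it does not

The generators are seeded (`numpy.random.default_rng`) and fully
deterministic; every artifact carries a machine-readable truth record.

* **Co-flow experiments** honor the bench logic: the pumps fix Q₁/Q₂
  (default 4:1, reference faster), the physics then fixes Y, and the FD
  field is scaled to the requested blood flow rate (default 10 μL/hr;
  the bench range 5–35 μL/hr maps to mid-plane blood-layer shear rates
  of roughly 1–50 s⁻¹ for plausible viscosity ratios — the range where
  RBC aggregation lives). The recorded truth shear rate is the OLS
  slope of the mid-plane FD profile over the same central-layer window
  the velocimetry stage fits, so truth and estimate share a definition.
* **Tracer pairs**: Gaussian spots (σ ≈ 1.2 px, mimicking a 0.79 μm
  particle imaged at 0.27 μm/px) seeded uniformly in the blood stream
  only — as in the sample preparation — advected by the mid-plane
  velocity, with additive Gaussian noise and an optional static
  illumination ramp. Out-of-plane motion, Brownian wander and
  depth-of-correlation blur are *not* modeled, so PIV error bounds on
  synthetic data are optimistic relative to bench data.
* **Bright-field frames**: dark objects on a bright background
  (default 70 vs 200 counts, SNR ≈ 10 after σ = 5 noise), blurred by a
  1 px PSF, under a multiplicative linear ramp (default 20%).
  Rouleaux are chains of 3–25 overlapping ellipses (8 × 2.4 μm coins
  with orientation jitter), clusters are unions of 5–60 disks (largest
  connected piece kept), disks span 3–18 μm radius. Objects keep a
  ≥ 3 px clearance by default so counting is well-posed; allowing
  overlap emulates the crowded higher-hematocrit regime where the
  detector visibly undercounts. Coverage above 45% of the frame raises
  rather than producing meaningless truth. The truth area is the
  rasterized pixel count — what an ideal detector would measure; for
  disks it matches πr² to rasterization error. The log-uniform-ish
  size mix is a modeling choice, not a claim about real aggregate-size
  distributions.
* **Viscosity curves**: log-spaced shear rates, exact model values,
  optional multiplicative Gaussian noise.

Passing tests on these data demonstrate that the *measurement chain* is
correct and self-consistent; they do not validate biological claims
about aggregation, nor instrument effects the generators omit.

## Problem sizes used in tests

Fixtures are sized for a single-CPU desk run: 8 tracer pairs per
synthetic PIV measurement (bench: 100), 60–200 bright-field frames per
recording (bench: 1200), FD grids of 101²–401², and 40–60-point
viscosity curves (matching the fitting procedure's sample counts).
Accuracy at these sizes bounds the per-pair/per-frame error; averaging
over the full bench counts only tightens it.

## Known limitations

* The interface is flat and vertical; curved interfaces (strong
  viscosity contrast with low interfacial tension) bias Y and hence μ₂.
* The blood stream is treated as a homogeneous Newtonian fluid at each
  operating point (that is what "apparent viscosity" means here);
  cell-free layers and local hematocrit gradients are not modeled.
* The PBS reference viscosity is a required user input — no value is
  assumed.
* Aggregate sizing is 2-D projected area; overlapping or out-of-focus
  aggregates merge, which is why per-recording means, not per-object
  counts, are the robust statistic at higher area fractions.
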