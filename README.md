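# hemorheo

Microfluidic blood microrheology at low hematocrit: a tested Python
implementation of the full measurement chain used to quantify red blood
cell (RBC) aggregation and the non-Newtonian viscosity of dilute blood
suspensions in a two-fluid Y-microchannel.

**Who it is for.** Experimentalists running co-flow ("optical
viscometer") microchannels with μPIV and bright-field imaging, and
modelers who need power-law / Carreau parameters for blood at
microcirculation-like hematocrits (5–15% H), where classical 45% H
rheometer data do not apply.

## What it computes

**Optical viscometry.** Two streams — a reference fluid of viscosity
μ₁ (e.g. PBS) and the blood suspension of unknown apparent viscosity
μ₂ — co-flow in a rectangular channel of width *w* and depth *h*
(aspect ratio β = h/w). For fully developed Stokes flow the flow-rate
ratio is an analytic series in the viscosity ratio and the dimensionless
interface position Y (Y = ½ − w₁/w):

    Q₁/Q₂ = F(μ₂/μ₁, Y, β)

`hemorheo.coflow` evaluates F as an exact modal series (sine expansion
across the depth, velocity and shear-stress continuity at the
interface), inverts it for μ₂/μ₁ or Y with bracketing root finders, and
cross-checks everything against an independent second-order
finite-difference solver of the same piecewise-viscosity duct problem.

**Velocimetry.** `hemorheo.velocimetry` estimates velocities from
fluorescent tracer image pairs by multi-pass cross-correlation
(64×64 → 32×32 px windows, 50% overlap, 4:1 streamwise window
weighting, three-point Gaussian subpixel peaks, normalized-median
validation), averages N repeated fields in time and then streamwise
into one transverse profile with its RMS fluctuation

    RMS = sqrt[(N·Σuᵢ² − (Σuᵢ)²) / (N(N−1))],

locates the blood layer from the tracer-density profile, and reports
the shear rate γ̇ as the slope of the profile over the central part of
the layer.

**Aggregate sizing.** `hemorheo.aggregates` flat-fields bright-field
frames, thresholds dark aggregates (Otsu), fills holes, removes
sub-cellular debris, labels 8-connected components, converts pixel
counts to μm², and averages per frame then per recording.

**Rheology.** `hemorheo.rheology` provides the two shear-thinning laws
as scikit-learn estimators:

* power law (Ostwald–de Waele): μ(γ̇) = K·γ̇ⁿ⁻¹, fitted by ordinary
  least squares on log–log axes (slope = n − 1, intercept = log K);
* Carreau: μ(γ̇) = μ∞ + (μ₀ − μ∞)(1 + (λγ̇)²)^((n−1)/2), fitted by
  Levenberg–Marquardt with positivity enforced through log-parameters.

Both report R² and the degrees-of-freedom-corrected
RMSE = sqrt(Σ(μ_exp − μ_fit)²/(m − p)).

**Synthetic data.** `hemorheo.synthetic` generates every input with
ground truth: consistent co-flow experiments (pump ratio → interface
position → FD velocity field), tracer image pairs advected by the
mid-plane profile, bright-field frames with rouleau-chain / cluster /
disk objects under non-uniform illumination, and viscosity curves drawn
from published parameter rows (`hemorheo.reference`).

## Worked example

```python
import numpy as np
from hemorheo import coflow
from hemorheo.synthetic import gen_viscosity_samples
from hemorheo.rheology import fit_carreau
from hemorheo.reference import CARREAU_23C

# optical viscometry: pumps at 4:1, interface observed at Y = -0.060
ratio = coflow.solve_viscosity_ratio(4.0, -0.060, 60/110)
print(f"viscosity ratio mu2/mu1 = {ratio:.3f}")

# noisy Carreau curve for 10% hematocrit blood, then refit
curve = gen_viscosity_samples("carreau", CARREAU_23C[10],
                              gamma_range=(0.5, 100), m=60,
                              noise_sigma=0.02, seed=1)
fit = fit_carreau(curve)
print(f"mu_0 = {fit.mu_zero:.1f} cP   mu_inf = {fit.mu_inf:.2f} cP")
print(f"lambda = {fit.relaxation_lambda:.2f} s   n = {fit.index_n:.3f}")
print(f"R^2 = {fit.r_squared:.4f}   RMSE = {fit.rmse:.3f} cP")
```

prints

```
viscosity ratio mu2/mu1 = 5.007
mu_0 = 92.8 cP   mu_inf = 1.63 cP
lambda = 3.48 s   n = 0.367
R^2 = 0.9995   RMSE = 0.370 cP
```

The first line says a 4:1 pump ratio with the interface just below the
centerline implies the test stream is 5.0× as viscous as the reference
— exactly how apparent blood viscosity is read off the channel. The
refit recovers the generating 10% H parameters (μ₀ = 89.9 cP,
μ∞ = 1.6 cP, λ = 3.31 s, n = 0.369) to within the scatter injected by
the 2% noise; λ and μ₀ trade off against each other and carry most of
the uncertainty.

## Command line

```
hemorheo viscometry --q-ref 40 --q-test 10 --interface-y -0.06 --mu-ref-cp 1.0
hemorheo piv --frames pairs.tif --dt-ms 2.0 --pixel-scale-um 0.27 --out out/
hemorheo aggregates --frames frames.tif --pixel-scale-um 0.2 --out out/
hemorheo fit-rheology --curve curve.csv --model carreau --out fit.json
hemorheo simulate {coflow|particles|aggregates|viscosity} --seed 1 --out dir/
hemorheo pipeline --config experiment.yaml --out run/
```

The pipeline config is YAML with the keys of
`hemorheo.pipeline.ExperimentConfig` (channel geometry, the two pump
flow rates in μL/hr, reference and plasma viscosities in cP, pixel
scales, dt, labels, seed); every run writes the resolved config and a
provenance sidecar next to its outputs.

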