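# Methods

## Contact model and state-space formulation

The Hunt–Crossley law `F = K dⁿ + B dⁿ ḋᵖ` describes tool–tissue contact
with a force that vanishes continuously at zero indentation, unlike linear
spring–damper (Kelvin–Voigt / Maxwell / Kelvin–Boltzmann) models, which jump
at contact on/offset.  For online estimation the contact is written as a
discrete 7-state system

```
x_k = [d, ḋ, F, K, B, n, p]_k ,   y_k = [d, F]_k + r_k ,  r ~ N(0, R)
```

with transition `d ← d + ḋ·Δt`, `F ← K dⁿ + B dⁿ ḋᵖ` evaluated at the
*previous* step's depth and velocity, and the four material parameters held
constant up to process noise.  Units follow the robotic-indentation
convention: mm for depth, mm/s for velocity, mN for force; one filter step is
Δt = 0.1 s in the bundled studies.  Writing the force from the previous
step's kinematics makes the prediction lag the measurement by one step; the
estimated parameters absorb a compensation of relative size ≈ n·Δd/d, which
bounds how far force-reconstruction error can fall below the per-step depth
increment times the force slope.  The measurement map is the linear selection
`H = [e_d; e_F]`, so `H` is its own exact Jacobian and `P_y − R = H P̄ Hᵀ`
holds identically.

## Unscented Kalman filter conventions

The scaled unscented transform uses the standard 2N+1 point set (center plus
symmetric pairs from the Cholesky factor of `(N+λ)P`), with α = 1, β = 2,
κ = 0 by default (λ = 0 for N = 7).  Two conventions matter:

* **Measurement update from re-drawn sigma points.**  The update draws fresh
  sigma points from the predicted belief N(x̄, P̄) instead of reusing the
  propagated points.  For the linear measurement map this makes
  `P_y = H P̄ Hᵀ + R` exact — the identity the strong-tracking scaling factor
  is derived from — and it makes "repeat the measurement update with an
  inflated P̄" a well-defined operation.  (The propagated points' weighted
  spread equals `P̄ − Q`, which would break both.)
* **Joseph-style posterior covariance.**  The posterior covariance is
  computed as the completed square
  `P̄ − K P_xyᵀ − P_xy Kᵀ + K P_y Kᵀ`, algebraically equal to the textbook
  `P̄ − K P_y Kᵀ` but positive semi-definite for any gain, which survives the
  ill-conditioning that large covariance inflations can cause.

Covariances are symmetrized each step; Cholesky failures are repaired first
by scaled jitter (three retries starting at `1e-9·(1 + tr/N)`), then by
eigenvalue clipping onto the PSD cone.

## Adaptive layer (RWSTUKF)

Contact-model error is detected from the Mahalanobis distance of the
innovation, `θ = Zᵀ P_y⁻¹ Z`.  Under a correct model `θ` is asymptotically
χ²-distributed with 2 degrees of freedom (the measurement is a 2-vector), so
the default threshold is the χ²₂ quantile at 0.99, `θ_T ≈ 9.21`; the boundary
case `θ = θ_T` counts as "no error".  Detection is disabled on the very first
step, before any innovation history exists.

On detection, the innovation covariance is estimated over the window of the
`M` most recent *completed-step* innovations (the current innovation is
excluded; including it was tried and makes the correction over-react to a
single outlier at fault onset) with random convex weights drawn from a flat
Dirichlet distribution — non-negative, summing to one, component mean `1/M`,
so the estimate is unbiased for the equal-weight window average while
down- or up-weighting individual innovations.  The scaling factor

```
γ = ( tr(B₀) − tr(R) ) / tr(H P̄ Hᵀ)
```

uses `H P̄ Hᵀ = P_y − R`.  γ is clamped below at 1 (the correction only
inflates; sampling noise in B₀ must not deflate the covariance) and above at
`γ_max = 5`.  The upper bound is a *bounded fading factor*: consecutive
detections still compound geometrically, so total inflation over a burst is
unbounded, but a single step can no longer kick the estimate through a bad
region of the parameter space — without the bound a few percent of
badly-initialized runs transit through (K, n) combinations whose
reconstruction error briefly exceeds the unadapted filter's.  After
inflation, only the measurement update is repeated (a single pass; detection
is not re-tested within the step), and the final innovation enters the
window.

With detection disabled (`θ_T = ∞`) the adaptive filter is bitwise identical
to the standard UKF; this is asserted in the tests.

## Constraint box

Joint estimation of a power law from one force channel is only partially
identifiable (at constant indentation velocity, only `n` and the lumped
coefficient `K + B ḋᵖ` are determined), and the likelihood has a spurious
basin where a large exponent with a small stiffness shadow-fits the data at
one depth while being wildly wrong elsewhere.  Two safeguards keep the
estimator in the physical regime:

* inside the filter dynamics, exponents are evaluated clipped to
  `[10⁻³, 3]` (soft-tissue exponents sit near 1–2; Hertzian contact gives
  n = 1.5) and the force component is capped at ±10⁶ mN;
* after each update the posterior mean's parameter components are projected
  onto the same box, with `K, B ≥ 10⁻⁶`.

The caps never bind on physically plausible trajectories; they only exclude
the degenerate basin and keep `dⁿ` representable in float64 when the
covariance is temporarily large.

## Simulated studies

Truth trajectories are deterministic constant-velocity indentations
(`d_k = k·ḋ·Δt`) through the H-C law with K = 10, B = 1, n = 2, p = 1.05;
measurements add i.i.d. Gaussian noise with covariance R.  Truth carries no
process noise — Q is purely the filter's tuning — and estimation quality is
scored by reconstructing force from the per-step parameter estimates along
the *true* depth/velocity series and comparing with the noise-free input
force (mean, max and RMS of the absolute error).  Three presets:

| study | filter defect | velocity | steps | q | r |
|---|---|---|---|---|---|
| `init_error` | starts at K=150, B=2, n=1, p=1 | 0.1 mm/s | 300 | 0.01 | 0.01 |
| `simplified` | transition uses velocity exponent 1 | 0.01 mm/s | 500 | 0.1 | 0.1 |
| `local_error` | `[0,0,0,0.8,0.8,0,0]` added to the predicted mean on steps 200–220 | 0.1 mm/s | 300 | 0.01 | 0.01 |

The nominal noise intensity `q` (mN²) enters the **force state only**:
`Q = diag(ε, ε, q, ε, ε, ε, ε)` with ε = 10⁻⁸.  The kinematic states follow
the commanded indentation almost exactly and the material parameters are
physically constant, so both carry only a tiny regularization noise.  This
structure is what makes the detector work: a uniform `q` on all seven states
inflates the predicted measurement covariance with depth (through ∂F/∂d and
∂F/∂n), hiding genuine faults inside an ever-growing `P_y`, and
simultaneously lets the parameter estimates random-walk without bound.

The initial covariance is `P₀ = diag(1, 1, 1, 200, 1, 1, 1)`: prior standard
deviation ≈ 14 for stiffness (tissue stiffness spans the tens through low
hundreds in these units) and 1 elsewhere.  The filter's `d`, `ḋ`, `F`
components are initialized from the first measurement and the commanded
velocity; metrics cover the subsequently filtered steps.  The local-fault
interval is indexed on trajectory steps (0-based).  Window size M = 4.

Monte-Carlo batches re-run a study over consecutive seeds; for each seed the
measurement noise and the Dirichlet weights come from independent child
streams, so both filters see identical measurements.

## What the generator does and does not emulate

The generator reproduces the statistical structure the filters are designed
for — a deterministic nonlinear force trajectory with additive white Gaussian
sensor noise and three canonical model-error mechanisms.  It does not emulate
a real master–slave indentation rig: no servo jitter or varying velocity
(hence the velocity exponent `p` is structurally unidentifiable in the
bundled studies), no force-sensor drift or quantization, no contact
make/break transients, no tissue relaxation or heterogeneity.  Passing the
bundled studies therefore demonstrates the adaptation mechanism under
controlled model error, not performance on hardware data; recorded
indentations can be fed through `palpkf fit` / `read_indentation_csv`.

## Numerical and design choices

* UT constants α = 1, β = 2, κ = 0; overridable per scenario config.
* θ_T = χ²₂(0.99); M = 4; γ ∈ [1, 5]; all configurable.
* Scalar (trace-resolved) scaling factor, not a diagonal per-state matrix.
* Degenerate inputs: exactly-zero covariance yields coincident sigma points;
  an empty innovation window disables detection; negative depths clamp to 0
  and negative velocities use the sign-preserving power.
* Monte-Carlo sizes: the bundled studies use 20–60 repetitions of 300–500
  steps, enough for the heavy-tailed max-error statistic to stabilize while
  keeping a full re-run in tens of seconds.

## Known limitations

* At constant indentation velocity, `B` and `p` are confounded
  (`B ḋᵖ` is one lumped coefficient); their individual estimates carry prior
  information and should not be over-interpreted.  Identifying `p` requires
  velocity variation.
* The one-step force lag in the transition biases the parameter estimates by
  the lag-compensation factor; with fast indentation this floor exceeds the
  sensor-noise scale.
* The detector's power degrades if the filter's own predicted measurement
  covariance is inflated by mis-tuned process noise; the structured-Q
  convention above is a modelling commitment, not an estimated quantity.
* Force reconstruction uses the full H-C law with estimated exponents even
  when the filter ran the simplified transition; the residual difference
  between the full and simplified damping terms is then part of the reported
  error.
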