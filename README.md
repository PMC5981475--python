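# palpkf — online soft-tissue contact characterization from robotic palpation

Robotic-assisted minimally invasive surgery needs live estimates of soft-tissue
mechanical properties: stiffness and damping change between organs, tissue
layers and patients, and haptic feedback or contact-force control built on a
stale model is unsafe.  `palpkf` estimates the parameters of the
**Hunt–Crossley (H-C) viscoelastic contact law**

```
F = K·dⁿ + B·dⁿ·ḋᵖ
```

(`F` contact force, `d` indentation depth, `ḋ` indentation velocity, stiffness
`K`, damping `B`, exponents `n`, `p`) online, from streaming depth/force
measurements, by joint state–parameter filtering of the 7-state system
`x = [d, ḋ, F, K, B, n, p]` with measurements `y = [d, F]`.

Two filters are provided:

* a standard **unscented Kalman filter** (UKF) — exact to third order for the
  nonlinear force law, no Jacobians;
* the **random-weighting strong-tracking UKF** (RWSTUKF), which makes the UKF
  robust to *contact-model error* (wrong initialization, a simplified force
  law inside the filter, transient modelling faults).  Each step it computes
  the Mahalanobis distance of the innovation, `θ = Zᵀ P_y⁻¹ Z`, compares it
  with a χ²(2) threshold, and on detection estimates the innovation covariance
  over a sliding window of `M` past innovations with **random convex weights**
  (flat Dirichlet, unbiased for the window average), forms the scaling factor

  ```
  γ = ( tr(Σⱼ vⱼ Z₋ⱼ Z₋ⱼᵀ) − tr(R) ) / tr(H P̄ Hᵀ),   clamped to [1, γmax],
  ```

  inflates the predicted covariance `P̄ ← γ·P̄`, and repeats only the
  measurement update.  `H P̄ Hᵀ` is obtained as `P_y − R` (the measurement map
  is a linear selection), so no Jacobian is ever formed.

A simulator reproduces three contact-model-error studies (bad initial
parameters; a filter that drops the velocity exponent; a constant offset
injected into the predicted state over steps 200–220) and scores both filters
by reconstructing force from the parameter estimates along the true
trajectory.

## Worked example

```python
import numpy as np
from palpkf import scenario_preset, monte_carlo

cfg = scenario_preset("init_error")        # truth K=10,B=1,n=2,p=1.05; filter starts at K=150,B=2,n=1,p=1
for kind in ("ukf", "rwstukf"):
    mc = monte_carlo(cfg, kind, n_runs=20, base_seed=0)
    s = mc.summary()
    print(f"{kind:8s} mean={s['mean_error']:.3f}  max={s['max_error']:.3f}  rmse={s['rmse']:.3f}  (mN)")
```

prints

```
ukf      mean=37.142  max=79.194  rmse=44.134  (mN)
rwstukf  mean=5.211  max=14.662  rmse=6.257  (mN)
```

Under a badly wrong initialization the standard UKF, trusting its prior,
accumulates a large force-reconstruction error during its slow convergence
(maximum ≈ 79 mN here), while the adaptive filter detects the inconsistency,
inflates its predicted covariance and converges several times faster
(maximum ≈ 15 mN, RMSE seven times smaller).  The same comparison from the
shell:

```
palpkf simulate --scenario init_error --filter both --runs 20 --seed 0 --out out/
palpkf report --in out/
```

A recorded indentation (CSV with columns `time, displacement, [velocity,]
force`) can be fitted with `palpkf fit --input record.csv --filter rwstukf
--out fit/`.

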