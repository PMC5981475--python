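"""Hunt-Crossley viscoelastic contact dynamics.

The Hunt-Crossley (H-C) law relates indentation depth ``d`` and indentation
velocity ``d_dot`` to the contact force

    F = K * d**n + B * d**n * d_dot**p

with stiffness ``K``, damping ``B`` and the two dimensionless exponents
``n`` (displacement) and ``p`` (velocity).  Unlike linear spring-damper
models (Kelvin-Voigt, Maxwell, Kelvin-Boltzmann) the force vanishes
continuously at zero indentation, which matches tool-tissue contact.

For joint state/parameter estimation the contact is written as a 7-state
discrete-time system

    x = [d, d_dot, F, K, B, n, p]

where the parameters follow random walks and the force component is
recomputed from the previous step's depth and velocity.  Only depth and
force are measured: y = [d, F].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STATE_DIM = 7
MEAS_DIM = 2

# state vector layout
IDX_D, IDX_DDOT, IDX_F, IDX_K, IDX_B, IDX_N, IDX_P = range(STATE_DIM)

# positivity floors applied to parameter estimates after each filter update
PARAM_FLOOR_KB = 1e-6
PARAM_FLOOR_NP = 1e-3

# Constraint box used when evaluating the force law inside the *filter*
# dynamics and when clamping posterior estimates: soft-tissue contact
# exponents sit near 1-2 (Hertzian contact gives n = 1.5), so values
# beyond EXPONENT_CAP are unphysical, and d**n at large n destroys both
# the conditioning of the state covariance and the identifiability basin
# (an inflated exponent with a tiny stiffness can shadow-fit the data at
# one depth while being wildly wrong everywhere else).  The force
# component is capped at +/- FORCE_CAP (1 kN -- far beyond any palpation
# force).
EXPONENT_CAP = 3.0
FORCE_CAP = 1e6


@dataclass(frozen=True)
class HCParameters:
    """The four Hunt-Crossley material parameters.

    Units follow the mN/mm convention of robotic indentation rigs:
    ``K`` in mN*mm^-n, ``B`` in mN*mm^-n*(mm/step)^-p, ``n`` and ``p``
    dimensionless.  Negative values are physically meaningless and are
    clamped to small positive floors on construction.
    """

    K: float
    B: float
    n: float
    p: float

    def __post_init__(self) -> None:
        vals = (self.K, self.B, self.n, self.p)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite H-C parameters: {vals}")
        object.__setattr__(self, "K", max(float(self.K), 0.0))
        object.__setattr__(self, "B", max(float(self.B), 0.0))
        object.__setattr__(self, "n", max(float(self.n), PARAM_FLOOR_NP))
        object.__setattr__(self, "p", max(float(self.p), PARAM_FLOOR_NP))

    def as_array(self) -> np.ndarray:
        return np.array([self.K, self.B, self.n, self.p], dtype=float)


# Numerical cap on each power term.  Sigma points explore large exponents
# when the covariance is inflated; capping keeps d**n representable in
# float64 without inf - inf producing NaNs, while leaving every physically
# plausible force (<< 1e12 mN) untouched.
_POWER_CAP = 1e12


def _signed_power(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """sign(x)*|x|**p -- keeps fractional powers real for negative velocity."""
    with np.errstate(over="ignore"):
        mag = np.abs(x) ** p
    return np.sign(x) * np.minimum(mag, _POWER_CAP)


def _depth_power(d: np.ndarray, n: np.ndarray) -> np.ndarray:
    """d**n with d clamped to >= 0 and 0**n defined as 0 (also for n <= 0)."""
    d = np.maximum(d, 0.0)
    safe = np.where(d > 0.0, d, 1.0)
    with np.errstate(over="ignore"):
        dn = safe ** n
    return np.where(d > 0.0, np.minimum(dn, _POWER_CAP), 0.0)


def hc_force(params, d, d_dot):
    """Contact force of the Hunt-Crossley law, F = K d^n + B d^n d_dot^p.

    Parameters
    ----------
    params : HCParameters or array-like
        Either an :class:`HCParameters` instance or an array whose last
        axis is ``[K, B, n, p]`` (broadcast against ``d`` / ``d_dot``).
    d, d_dot : float or ndarray
        Indentation depth (mm) and velocity (mm/step).  Negative depths are
        clamped to zero; negative velocities use the sign-preserving power.
    """
    if isinstance(params, HCParameters):
        K, B, n, p = params.K, params.B, params.n, params.p
    else:
        arr = np.asarray(params, dtype=float)
        K, B, n, p = (arr[..., i] for i in range(4))
    d = np.asarray(d, dtype=float)
    d_dot = np.asarray(d_dot, dtype=float)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(d_dot))):
        raise ValueError("non-finite displacement or velocity")
    dn = _depth_power(d, np.asarray(n, dtype=float))
    out = K * dn + B * dn * _signed_power(d_dot, np.asarray(p, dtype=float))
    return out if out.ndim else float(out)


def state_transition(x: np.ndarray, dt: float = 1.0, simplified: bool = False) -> np.ndarray:
    """One step of the contact state equation.

    ``d`` advances by ``d_dot * dt``; the force component is re-evaluated
    from the *previous* step's depth and velocity (the state equation is
    written that way); velocity and the four parameters are constant apart
    from process noise, which the filter adds through Q.

    With ``simplified=True`` the velocity exponent is forced to 1
    (F = K d^n + B d^n d_dot), the linear-damping simplification used as a
    deliberately wrong filter model in the model-simplification scenario.
    Vectorized over any leading axes of ``x`` (last axis = 7 states).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != STATE_DIM:
        raise ValueError(f"state must have last axis {STATE_DIM}, got {x.shape}")
    out = x.copy()
    d, d_dot = x[..., IDX_D], x[..., IDX_DDOT]
    K, B = x[..., IDX_K], x[..., IDX_B]
    # sigma points are evaluated on the constrained parameter box (see above)
    n = np.clip(x[..., IDX_N], PARAM_FLOOR_NP, EXPONENT_CAP)
    if simplified:
        p = np.ones_like(x[..., IDX_P])
    else:
        p = np.clip(x[..., IDX_P], PARAM_FLOOR_NP, EXPONENT_CAP)
    dn = _depth_power(d, n)
    out[..., IDX_D] = d + d_dot * dt
    F = K * dn + B * dn * _signed_power(d_dot, p)
    out[..., IDX_F] = np.clip(F, -FORCE_CAP, FORCE_CAP)
    return out


def measurement_fn(x: np.ndarray) -> np.ndarray:
    """Measured quantities y = [d, F]: depth from the encoder, force from the sensor."""
    x = np.asarray(x, dtype=float)
    return x[..., [IDX_D, IDX_F]]


def measurement_matrix() -> np.ndarray:
    """The constant 2x7 selection matrix H with H @ x == measurement_fn(x).

    Because the measurement function is linear, H is also its exact Jacobian.
    """
    H = np.zeros((MEAS_DIM, STATE_DIM))
    H[0, IDX_D] = 1.0
    H[1, IDX_F] = 1.0
    return H


def clamp_parameter_states(mean: np.ndarray) -> np.ndarray:
    """Clamp the parameter components of a state mean to their positivity floors.

    Applied after each filter update so fractional powers stay real and sigma
    points cannot drive NaNs through the dynamics.
    """
    out = np.asarray(mean, dtype=float).copy()
    out[IDX_K] = max(out[IDX_K], PARAM_FLOOR_KB)
    out[IDX_B] = max(out[IDX_B], PARAM_FLOOR_KB)
    out[IDX_N] = min(max(out[IDX_N], PARAM_FLOOR_NP), EXPONENT_CAP)
    out[IDX_P] = min(max(out[IDX_P], PARAM_FLOOR_NP), EXPONENT_CAP)
    return out
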