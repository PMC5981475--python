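"""Random-weighting strong-tracking UKF (RWSTUKF).

The standard UKF assumes the contact model is correct; an initial-state
error, a simplified force law in the filter, or a transient modelling
fault all bias the predicted state covariance and degrade the gain.  This
layer wraps one UKF step with:

1. *Detection* -- the Mahalanobis distance of the innovation,
   theta = Z^T P_y^{-1} Z, compared against a chi-square threshold
   (the innovation is a 2-vector, so theta ~ chi2(2) under a correct model).

2. *Innovation-covariance estimation* -- a sliding window of the last M
   innovations combined with random convex weights (flat Dirichlet, so the
   estimate is unbiased relative to the equal-weight window average).

3. *Strong-tracking correction* -- a scalar scaling factor
   gamma = (tr(B0) - tr(R)) / tr(H P_bar H^T), clamped to >= 1, derived
   from the innovation-orthogonality principle; the predicted covariance
   is inflated to gamma * P_bar and the measurement update alone is redone,
   so the filter re-trusts fresh measurements while the model is wrong.

H P_bar H^T is obtained as P_y - R (exact because the measurement map is a
linear selection), so no Jacobian is ever formed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Deque, Optional

import numpy as np
from scipy import stats

from .ukf import (
    GaussianBelief,
    NoiseSpec,
    NumericalError,
    Prediction,
    UpdateResult,
    UTWeights,
    predict,
    update,
)

Array = np.ndarray


class InsufficientHistoryError(RuntimeError):
    """Windowed innovation covariance requested before any innovation exists."""


def default_threshold(chi2_level: float = 0.99, dof: int = 2) -> float:
    """Chi-square quantile used as the model-error detection threshold."""
    return float(stats.chi2.ppf(chi2_level, df=dof))


@dataclass
class InnovationWindow:
    """The last up-to-M innovation vectors, oldest first."""

    M: int
    buffer: Deque[Array] = field(default_factory=deque)

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("window size M must be >= 1")
        self.buffer = deque(self.buffer, maxlen=self.M)

    def append(self, innovation: Array) -> None:
        self.buffer.append(np.asarray(innovation, dtype=float))

    def __len__(self) -> int:
        return len(self.buffer)

    def as_array(self) -> Array:
        return np.asarray(self.buffer, dtype=float)


@dataclass
class DetectionConfig:
    """Model-error detection and random-weighting settings.

    theta_T defaults to the chi-square(2) quantile at ``chi2_level``
    (about 9.21 at 0.99); M is the innovation-window length in steps.
    """

    M: int = 4
    chi2_level: float = 0.99
    theta_T: Optional[float] = None
    gamma_max: float = 5.0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not 0.0 < self.chi2_level < 1.0:
            raise ValueError("chi2_level must lie in (0, 1)")
        if self.theta_T is None:
            self.theta_T = default_threshold(self.chi2_level)
        if self.theta_T <= 0:
            raise ValueError("theta_T must be positive")
        if self.gamma_max < 1.0:
            raise ValueError("gamma_max must be >= 1")


@dataclass
class StepDiagnostics:
    """Per-step adaptation record: distance, scaling factor, and the weights used."""

    theta: float
    gamma: float
    corrected: bool
    weights: Optional[Array] = None


def mahalanobis(innovation: Array, innov_cov: Array) -> float:
    """Squared Mahalanobis length Z^T P_y^{-1} Z of an innovation."""
    z = np.asarray(innovation, dtype=float)
    S = np.asarray(innov_cov, dtype=float)
    try:
        sol = np.linalg.solve(S, z)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("innovation covariance is singular") from exc
    return float(z @ sol)


def detect(theta: float, theta_T: float) -> bool:
    """Model error is flagged strictly above the threshold (theta <= theta_T passes)."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return theta > theta_T


def draw_random_weights(m: int, rng: np.random.Generator) -> Array:
    """Random convex weights over ``m`` window slots: flat Dirichlet draw.

    Non-negative, sum to one, component mean 1/m -- so the random-weighted
    innovation covariance is unbiased for the equal-weight window average.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return np.array([1.0])
    return rng.dirichlet(np.ones(m))


def rw_innovation_cov(window: InnovationWindow, v: Array) -> Array:
    """Weighted innovation covariance  B0 = sum_j v_j Z_j Z_j^T  over the window."""
    if len(window) == 0:
        raise InsufficientHistoryError("no innovations stored yet")
    v = np.asarray(v, dtype=float)
    Z = window.as_array()
    if v.shape[0] != Z.shape[0]:
        raise ValueError(f"{v.shape[0]} weights for {Z.shape[0]} innovations")
    return (Z.T * v) @ Z


def scaling_factor(B0: Array, R: Array, HPH: Array, gamma_max: float = np.inf) -> float:
    """Strong-tracking scaling factor gamma = (tr(B0) - tr(R)) / tr(H P H^T).

    Clamped below at 1 -- the correction only ever inflates the predicted
    covariance; sampling noise in B0 must not deflate it -- and above at
    ``gamma_max``: a bounded fading factor keeps the sigma-point spread
    within the range where the contact nonlinearity is still well
    approximated (an unbounded inflation after a burst of large
    innovations can push exponent sigma points far outside the physical
    regime and destabilize the filter).
    """
    denom = float(np.trace(np.atleast_2d(HPH)))
    if denom <= 0:
        raise NumericalError(f"tr(H P H^T) must be positive, got {denom}")
    raw = (float(np.trace(np.atleast_2d(B0))) - float(np.trace(np.atleast_2d(R)))) / denom
    return float(min(max(raw, 1.0), gamma_max))


def corrected_covariance(pred_cov: Array, gamma: float) -> Array:
    """Inflated predicted state covariance gamma * P_bar."""
    if gamma < 1.0:
        raise ValueError("gamma must be >= 1 after clamping")
    return gamma * np.asarray(pred_cov, dtype=float)


def rwstukf_step(
    belief: GaussianBelief,
    y: Array,
    window: InnovationWindow,
    config: DetectionConfig,
    noise: NoiseSpec,
    weights: UTWeights,
    transition: Callable[[Array], Array],
    measurement: Callable[[Array], Array],
    rng: np.random.Generator,
    predicted_mean_offset: Optional[Array] = None,
) -> tuple[UpdateResult, StepDiagnostics, InnovationWindow]:
    """One adaptive filter step.

    Runs the standard predict + update, tests the innovation's Mahalanobis
    distance against theta_T, and on detection (possible only once the
    window holds at least one past innovation) inflates the predicted
    covariance by the random-weighted scaling factor and repeats the
    measurement update only.  The final innovation is appended to the
    window afterwards, so the window always holds completed-step
    innovations and never the current one.

    ``predicted_mean_offset`` is an optional vector added to the predicted
    state mean before the measurement update; the simulator uses it to
    inject a transient modelling fault.
    """
    pred = predict(belief, transition, noise.Q, weights)
    if predicted_mean_offset is not None:
        pred = Prediction(
            mean=pred.mean + np.asarray(predicted_mean_offset, dtype=float),
            cov=pred.cov,
            sigma=pred.sigma,
        )
    result = update(pred, y, measurement, noise.R, weights)
    theta = mahalanobis(result.innovation, result.innov_cov)

    gamma = 1.0
    v: Optional[Array] = None
    corrected = False
    if len(window) > 0 and detect(theta, config.theta_T):
        v = draw_random_weights(len(window), rng)
        B0 = rw_innovation_cov(window, v)
        HPH = result.innov_cov - noise.R  # exact H P_bar H^T: h is linear
        gamma = scaling_factor(B0, noise.R, HPH, gamma_max=config.gamma_max)
        inflated = Prediction(
            mean=pred.mean,
            cov=corrected_covariance(pred.cov, gamma),
            sigma=pred.sigma,
        )
        result = update(inflated, y, measurement, noise.R, weights)
        corrected = True

    window.append(result.innovation)
    diag = StepDiagnostics(theta=theta, gamma=gamma, corrected=corrected, weights=v)
    return result, diag, window
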