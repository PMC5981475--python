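"""Standard unscented Kalman filter (UKF).

Generic sigma-point filter over an N-dimensional state with nonlinear
dynamics f and measurement h.  The scaled unscented transform with the
usual 2N+1 point set (center point plus symmetric pairs drawn from the
Cholesky factor of (N+lambda)P) propagates mean and covariance to
third-order accuracy without Jacobians.

One convention matters downstream: the measurement update re-draws sigma
points from the *predicted* belief N(x_bar, P_bar) rather than reusing the
points propagated through f.  For a linear measurement h(x) = Hx this makes
the predicted measurement covariance exactly H P_bar H^T + R, the identity
the strong-tracking scaling factor relies on, and it makes "repeat the
measurement update with an inflated P_bar" a well-defined operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

Array = np.ndarray


class NumericalError(RuntimeError):
    """Covariance could not be factorized / innovation covariance singular."""


@dataclass
class GaussianBelief:
    """State estimate: mean x_hat (N,) and covariance P_hat (N, N)."""

    mean: Array
    cov: Array

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError(f"covariance shape {self.cov.shape} != ({n}, {n})")


@dataclass(frozen=True)
class UTWeights:
    """Unscented-transform constants and the derived point weights."""

    alpha: float
    beta: float
    kappa: float
    n_dim: int
    lam: float
    wm: Array  # (2N+1,) mean weights, center first
    wc: Array  # (2N+1,) covariance weights


@dataclass
class NoiseSpec:
    """Process covariance Q (N, N) and measurement covariance R (m, m)."""

    Q: Array
    R: Array

    def __post_init__(self) -> None:
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        for name, m in (("Q", self.Q), ("R", self.R)):
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} must be symmetric")


@dataclass
class Prediction:
    """Time-update output: predicted mean/covariance and the propagated points."""

    mean: Array
    cov: Array
    sigma: Array  # (2N+1, N) sigma points pushed through the dynamics


@dataclass
class UpdateResult:
    """Measurement-update output plus the intermediate filter quantities."""

    posterior: GaussianBelief
    innovation: Array  # y - y_bar
    innov_cov: Array  # predicted measurement covariance P_y
    gain: Array  # Kalman gain (N, m)
    cross_cov: Array  # P_xy (N, m)


def _symmetrize(a: Array) -> Array:
    return 0.5 * (a + a.T)


def ut_weights(n_dim: int, alpha: float = 1.0, beta: float = 2.0, kappa: float = 0.0) -> UTWeights:
    """Scaled unscented-transform weights for an ``n_dim``-state filter.

    lambda = alpha^2 (N + kappa) - N; the center mean weight is
    lambda/(N+lambda), the center covariance weight adds (1 - alpha^2 + beta),
    and the 2N symmetric points share weight 1/(2(N+lambda)).
    """
    if n_dim < 1:
        raise ValueError("n_dim must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    lam = alpha**2 * (n_dim + kappa) - n_dim
    if n_dim + lam <= 0:
        raise ValueError(f"N + lambda must be positive, got {n_dim + lam}")
    wm = np.full(2 * n_dim + 1, 1.0 / (2.0 * (n_dim + lam)))
    wc = wm.copy()
    wm[0] = lam / (n_dim + lam)
    wc[0] = lam / (n_dim + lam) + (1.0 - alpha**2 + beta)
    return UTWeights(alpha, beta, kappa, n_dim, lam, wm, wc)


def _cholesky_with_jitter(cov: Array) -> Array:
    """Lower Cholesky factor, with jitter retries and an eigenvalue-clipping
    fallback (nearest-PSD projection) for indefinite input."""
    n = cov.shape[0]
    sym = _symmetrize(cov)
    if not np.all(np.isfinite(sym)):
        raise NumericalError("covariance contains non-finite entries")
    jitter = 1e-9 * (1.0 + np.trace(sym) / n)
    for _ in range(3):
        try:
            return np.linalg.cholesky(sym)
        except np.linalg.LinAlgError:
            sym = sym + jitter * np.eye(n)
            jitter *= 10.0
    # project onto the PSD cone: clip negative eigenvalues
    evals, evecs = np.linalg.eigh(_symmetrize(cov))
    floor = 1e-12 * (1.0 + float(evals.max(initial=0.0)))
    repaired = (evecs * np.maximum(evals, floor)) @ evecs.T
    try:
        return np.linalg.cholesky(_symmetrize(repaired))
    except np.linalg.LinAlgError as exc:
        raise NumericalError("covariance not repairable to positive definite") from exc


def sigma_points(belief: GaussianBelief, weights: UTWeights) -> Array:
    """The 2N+1 scaled sigma points: mean, then mean +/- columns of chol((N+lam)P)."""
    n = weights.n_dim
    if belief.mean.shape[0] != n:
        raise ValueError("belief dimension does not match weights")
    scaled = (n + weights.lam) * belief.cov
    if not scaled.any():  # exactly degenerate covariance
        offsets = np.zeros((n, n))
    else:
        offsets = _cholesky_with_jitter(scaled).T  # rows are the offset vectors
    pts = np.empty((2 * n + 1, n))
    pts[0] = belief.mean
    pts[1 : n + 1] = belief.mean + offsets
    pts[n + 1 :] = belief.mean - offsets
    return pts


def predict(
    belief: GaussianBelief,
    transition: Callable[[Array], Array],
    Q: Array,
    weights: UTWeights,
) -> Prediction:
    """Time update: push sigma points through the dynamics, add Q."""
    pts = sigma_points(belief, weights)
    prop = np.asarray(transition(pts), dtype=float)
    if not np.all(np.isfinite(prop)):
        bad = int(np.argwhere(~np.isfinite(prop).all(axis=1))[0, 0])
        raise NumericalError(f"state transition produced non-finite sigma point #{bad}")
    mean = weights.wm @ prop
    dev = prop - mean
    cov = _symmetrize(dev.T @ (weights.wc[:, None] * dev) + np.atleast_2d(Q))
    return Prediction(mean=mean, cov=cov, sigma=prop)


def update(
    pred: Prediction,
    y: Array,
    measurement: Callable[[Array], Array],
    R: Array,
    weights: UTWeights,
) -> UpdateResult:
    """Measurement update from the predicted belief.

    Sigma points are re-drawn from N(pred.mean, pred.cov) -- see the module
    docstring -- then mapped through h to form the predicted measurement,
    its covariance P_y (plus R) and the state-measurement cross covariance.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    pts = sigma_points(GaussianBelief(pred.mean, pred.cov), weights)
    ypts = np.atleast_2d(np.asarray(measurement(pts), dtype=float))
    y_bar = weights.wm @ ypts
    dy = ypts - y_bar
    dx = pts - pred.mean
    innov_cov = _symmetrize(dy.T @ (weights.wc[:, None] * dy) + np.atleast_2d(R))
    cross_cov = dx.T @ (weights.wc[:, None] * dy)
    try:
        gain = np.linalg.solve(innov_cov, cross_cov.T).T
    except np.linalg.LinAlgError as exc:
        raise NumericalError("innovation covariance is singular") from exc
    innovation = y - y_bar
    mean = pred.mean + gain @ innovation
    # Joseph-style completed square: algebraically equal to
    # P_bar - K P_y K^T for K = P_xy P_y^{-1}, but positive semi-definite
    # for *any* gain, which survives ill-conditioned P_y.
    cov = _symmetrize(
        pred.cov - gain @ cross_cov.T - cross_cov @ gain.T + gain @ innov_cov @ gain.T
    )
    return UpdateResult(
        posterior=GaussianBelief(mean, cov),
        innovation=innovation,
        innov_cov=innov_cov,
        gain=gain,
        cross_cov=cross_cov,
    )


def ukf_step(
    belief: GaussianBelief,
    y: Array,
    transition: Callable[[Array], Array],
    measurement: Callable[[Array], Array],
    noise: NoiseSpec,
    weights: UTWeights,
) -> UpdateResult:
    """One predict + update cycle of the standard UKF."""
    pred = predict(belief, transition, noise.Q, weights)
    return update(pred, y, measurement, noise.R, weights)
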