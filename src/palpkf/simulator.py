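"""Synthetic indentation trajectories and the three contact-model-error studies.

A constant-velocity indentation is simulated from the Hunt-Crossley law
with fixed true parameters (K=10, B=1, n=2, p=1.05 in the mN/mm unit
convention); depth and force measurements are the noise-free truth plus
zero-mean Gaussian noise.  Three preset scenarios each break the filter's
model in a different way:

``init_error``
    The filter starts from badly wrong parameters (K0=150, B0=2, n0=1,
    p0=1) while the data come from the true model.
``simplified``
    The filter's state equation drops the velocity exponent (p-term forced
    to 1) while the truth uses the full law -- a deliberate model
    simplification whose force discrepancy grows with depth.
``local_error``
    The filter is correct except that a constant offset [0,0,0,0.8,0.8,0,0]
    is injected into its predicted state mean over steps 200-220,
    emulating a transient modelling fault.

Truth trajectories are noise-free and deterministic: Q is purely the
filter's tuning, and the reconstruction error is scored against the
noise-free input force.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import partial
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .evaluation import ErrorReport, error_metrics, reconstruct_force
from .hc_model import (
    HCParameters,
    STATE_DIM,
    clamp_parameter_states,
    hc_force,
    measurement_fn,
    state_transition,
)
from .rwstukf import DetectionConfig, InnovationWindow, default_threshold, rwstukf_step
from .ukf import GaussianBelief, NoiseSpec, Prediction, predict, ut_weights, update

Array = np.ndarray

TRUE_PARAMS = HCParameters(K=10.0, B=1.0, n=2.0, p=1.05)

FILTER_KINDS = ("ukf", "rwstukf")
SCENARIO_NAMES = ("init_error", "simplified", "local_error")


@dataclass
class ScenarioConfig:
    """Full configuration of one simulated indentation + filtering study."""

    name: str
    true_params: HCParameters = TRUE_PARAMS
    init_params: HCParameters = TRUE_PARAMS
    d_dot: float = 0.1  # commanded indentation velocity, mm per step
    dt: float = 1.0  # one filter step
    n_steps: int = 300
    q_diag: float = 0.01  # process covariance Q = q_diag * I_7
    r_diag: float = 0.01  # measurement covariance R = r_diag * I_2
    M: int = 4  # innovation-window length
    theta_T: Optional[float] = None  # None -> chi2(2) quantile at 0.99
    gamma_max: float = 5.0  # bounded per-step fading factor
    p0_diag: float = 1.0  # initial state covariance P0 = p0_diag * I_7
    alpha: float = 1.0
    beta: float = 2.0
    kappa: float = 0.0
    simplified_filter: bool = False
    local_error_offset: Optional[Array] = None  # 7-vector added to predicted mean
    local_error_window: tuple[int, int] = (200, 220)  # inclusive step indices
    seed: Optional[int] = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.local_error_offset is not None:
            self.local_error_offset = np.asarray(self.local_error_offset, dtype=float)
            if self.local_error_offset.shape != (STATE_DIM,):
                raise ValueError("local_error_offset must be a 7-vector")
            lo, hi = self.local_error_window
            if not 1 <= lo <= hi <= self.n_steps:
                raise ValueError("local_error_window must lie within [1, n_steps]")
        if self.theta_T is None:
            self.theta_T = default_threshold()

    @property
    def Q(self) -> Array:
        return np.diag(np.broadcast_to(np.asarray(self.q_diag, dtype=float), (STATE_DIM,)))

    @property
    def R(self) -> Array:
        return np.diag(np.broadcast_to(np.asarray(self.r_diag, dtype=float), (2,)))

    @property
    def P0(self) -> Array:
        return np.diag(np.broadcast_to(np.asarray(self.p0_diag, dtype=float), (STATE_DIM,)))

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "true_params": vars(self.true_params).copy(),
            "init_params": vars(self.init_params).copy(),
            "d_dot": self.d_dot,
            "dt": self.dt,
            "n_steps": self.n_steps,
            "q_diag": self.q_diag,
            "r_diag": self.r_diag,
            "M": self.M,
            "theta_T": float(self.theta_T),
            "gamma_max": self.gamma_max,
            "p0_diag": self.p0_diag,
            "alpha": self.alpha,
            "beta": self.beta,
            "kappa": self.kappa,
            "simplified_filter": self.simplified_filter,
            "local_error_offset": (
                None if self.local_error_offset is None else [float(v) for v in self.local_error_offset]
            ),
            "local_error_window": list(self.local_error_window),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["true_params"] = HCParameters(**d["true_params"])
        d["init_params"] = HCParameters(**d["init_params"])
        if d.get("local_error_window") is not None:
            d["local_error_window"] = tuple(d["local_error_window"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Trajectory:
    """Time-indexed truth (and optionally noisy measurements) of one indentation."""

    t: Array  # step index, 0-based
    d_true: Array
    d_dot_true: Array
    F_true: Array
    y: Optional[Array] = None  # (n, 2) noisy [d, F] measurements

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.t,
                "displacement": self.d_true,
                "velocity": self.d_dot_true,
                "force_true": self.F_true,
            }
        )
        if self.y is not None:
            df["d_meas"] = self.y[:, 0]
            df["F_meas"] = self.y[:, 1]
        return df


def simulate_truth(config: ScenarioConfig) -> Trajectory:
    """Noise-free constant-velocity indentation: d_k = (k+1) * d_dot * dt."""
    k = np.arange(config.n_steps)
    d = (k + 1) * config.d_dot * config.dt
    d_dot = np.full(config.n_steps, config.d_dot)
    F = hc_force(config.true_params, d, d_dot)
    return Trajectory(t=k, d_true=d, d_dot_true=d_dot, F_true=np.atleast_1d(F))


def add_measurement_noise(traj: Trajectory, R: Array, rng: np.random.Generator) -> Trajectory:
    """Attach y_k = [d_k, F_k] + r_k with r_k ~ N(0, R), i.i.d. across steps."""
    R = np.atleast_2d(np.asarray(R, dtype=float))
    truth = np.column_stack([traj.d_true, traj.F_true])
    if not R.any():
        y = truth.copy()
    else:
        y = truth + rng.multivariate_normal(np.zeros(2), R, size=len(traj), method="cholesky")
    return replace(traj, y=y)


# Structure of the filter tuning shared by all presets.
#
# The nominal process-noise intensity q of a study enters the *force*
# state only: the force component is the one recomputed from the contact
# law each step, so it is where contact-model error lives.  The kinematic
# states follow the commanded indentation almost exactly, and the material
# parameters are physically constant, so both carry only a tiny
# regularization noise.  (A uniform q on all seven states makes the
# predicted measurement covariance balloon with ``d`` through the force
# slope and the exponent sensitivity, which both blinds the Mahalanobis
# detector and lets the parameter estimates random-walk without bound.)
_Q_EPS = 1e-8

# Prior standard deviations of the parameter states span physiological
# variability: tissue stiffness K varies over an order of magnitude
# across organs and conditions (sigma ~ 14 in mN/mm^n covers the tens
# through low hundreds), while damping and the two exponents sit near 1
# for soft tissue (sigma ~ 1).
_P0_DIAG = (1.0, 1.0, 1.0, 200.0, 1.0, 1.0, 1.0)


def _structured_q(q: float) -> list[float]:
    return [_Q_EPS, _Q_EPS, q, _Q_EPS, _Q_EPS, _Q_EPS, _Q_EPS]


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    """One of the three study presets (see the module docstring), or ``custom``."""
    if name == "init_error":
        cfg = ScenarioConfig(
            name=name,
            init_params=HCParameters(K=150.0, B=2.0, n=1.0, p=1.0),
            d_dot=0.1,
            dt=0.1,
            n_steps=300,
            q_diag=_structured_q(0.01),
            r_diag=0.01,
            p0_diag=list(_P0_DIAG),
        )
    elif name == "simplified":
        cfg = ScenarioConfig(
            name=name,
            init_params=HCParameters(K=10.0, B=1.0, n=2.0, p=1.05),
            d_dot=0.01,
            dt=0.1,
            n_steps=500,
            q_diag=_structured_q(0.1),
            r_diag=0.1,
            p0_diag=list(_P0_DIAG),
            simplified_filter=True,
        )
    elif name == "local_error":
        cfg = ScenarioConfig(
            name=name,
            init_params=TRUE_PARAMS,
            d_dot=0.1,
            dt=0.1,
            n_steps=300,
            q_diag=_structured_q(0.01),
            r_diag=0.01,
            p0_diag=list(_P0_DIAG),
            local_error_offset=np.array([0, 0, 0, 0.8, 0.8, 0, 0], dtype=float),
            local_error_window=(200, 220),
        )
    elif name == "custom":
        cfg = ScenarioConfig(name=name)
    else:
        raise ValueError(f"unknown scenario '{name}'; choose from {SCENARIO_NAMES + ('custom',)}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


@dataclass
class FilterRun:
    """Per-step output of one filter over one noisy trajectory.

    Estimates cover steps 1..n-1 (step 0 initializes the filter from the
    first measurement and the commanded velocity).
    """

    config: ScenarioConfig
    kind: str
    trajectory: Trajectory
    estimates: Array  # (n-1, 7) posterior state means
    theta: Array  # (n-1,) Mahalanobis distances (NaN where not computed)
    gamma: Array  # (n-1,) scaling factors (1 where no correction)
    corrected: Array  # (n-1,) bool

    @property
    def steps(self) -> Array:
        return self.trajectory.t[1:]

    def reconstructed_force(self) -> Array:
        return reconstruct_force(
            self.estimates, self.trajectory.d_true[1:], self.trajectory.d_dot_true[1:]
        )

    def metrics(self) -> ErrorReport:
        return error_metrics(self.reconstructed_force(), self.trajectory.F_true[1:])


def _initial_belief(config: ScenarioConfig, y0: Array) -> GaussianBelief:
    p = config.init_params
    mean = np.array([y0[0], config.d_dot, y0[1], p.K, p.B, p.n, p.p], dtype=float)
    return GaussianBelief(mean, config.P0)


def run_filter_on_scenario(
    config: ScenarioConfig,
    kind: str,
    seed: Optional[int] = None,
    trajectory: Optional[Trajectory] = None,
) -> FilterRun:
    """Simulate (or reuse) a noisy trajectory and run one filter over it.

    ``seed`` overrides ``config.seed`` and drives both the measurement
    noise and the random-weight draws through independent child streams,
    so the measurement stream is identical across filter kinds for a
    given seed.
    """
    if kind not in FILTER_KINDS:
        raise ValueError(f"unknown filter kind '{kind}'; choose from {FILTER_KINDS}")
    seed = config.seed if seed is None else seed
    noise_ss, weight_ss = np.random.SeedSequence(seed).spawn(2)
    if trajectory is None:
        trajectory = add_measurement_noise(
            simulate_truth(config), config.R, np.random.default_rng(noise_ss)
        )
    if trajectory.y is None:
        raise ValueError("trajectory has no measurements")

    weights = ut_weights(STATE_DIM, config.alpha, config.beta, config.kappa)
    noise = NoiseSpec(config.Q, config.R)
    transition = partial(state_transition, dt=config.dt, simplified=config.simplified_filter)
    belief = _initial_belief(config, trajectory.y[0])
    det = DetectionConfig(M=config.M, theta_T=config.theta_T, gamma_max=config.gamma_max)
    window = InnovationWindow(M=config.M)
    weight_rng = np.random.default_rng(weight_ss)

    n = len(trajectory)
    est = np.empty((n - 1, STATE_DIM))
    theta = np.full(n - 1, np.nan)
    gamma = np.ones(n - 1)
    corrected = np.zeros(n - 1, dtype=bool)

    lo, hi = config.local_error_window
    for i, k in enumerate(range(1, n)):
        offset = None
        if config.local_error_offset is not None and lo <= k <= hi:
            offset = config.local_error_offset
        y = trajectory.y[k]
        if kind == "ukf":
            pred = predict(belief, transition, noise.Q, weights)
            if offset is not None:
                pred = Prediction(pred.mean + offset, pred.cov, pred.sigma)
            res = update(pred, y, measurement_fn, noise.R, weights)
        else:
            res, diag, window = rwstukf_step(
                belief,
                y,
                window,
                det,
                noise,
                weights,
                transition,
                measurement_fn,
                weight_rng,
                predicted_mean_offset=offset,
            )
            theta[i] = diag.theta
            gamma[i] = diag.gamma
            corrected[i] = diag.corrected
        mean = clamp_parameter_states(res.posterior.mean)
        belief = GaussianBelief(mean, res.posterior.cov)
        est[i] = mean

    return FilterRun(
        config=config,
        kind=kind,
        trajectory=trajectory,
        estimates=est,
        theta=theta,
        gamma=gamma,
        corrected=corrected,
    )


@dataclass
class MonteCarloResult:
    """Per-run force-error metrics and their Monte-Carlo averages."""

    config: ScenarioConfig
    kind: str
    seeds: Array
    mean_error: Array  # (n_runs,)
    max_error: Array
    rmse: Array

    def summary(self) -> dict:
        return {
            "mean_error": float(self.mean_error.mean()),
            "max_error": float(self.max_error.mean()),
            "rmse": float(self.rmse.mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seed": self.seeds,
                "mean_error": self.mean_error,
                "max_error": self.max_error,
                "rmse": self.rmse,
            }
        )


def monte_carlo(
    config: ScenarioConfig, kind: str, n_runs: int, base_seed: int = 0
) -> MonteCarloResult:
    """Repeat run_filter_on_scenario with seeds base_seed .. base_seed+n_runs-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = base_seed + np.arange(n_runs)
    reports = [run_filter_on_scenario(config, kind, seed=int(s)).metrics() for s in seeds]
    return MonteCarloResult(
        config=config,
        kind=kind,
        seeds=seeds,
        mean_error=np.array([r.mean_error for r in reports]),
        max_error=np.array([r.max_error for r in reports]),
        rmse=np.array([r.rmse for r in reports]),
    )
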