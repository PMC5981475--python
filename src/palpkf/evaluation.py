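"""Force reconstruction, error metrics, and indentation-record I/O.

Estimation quality is scored in *force* space: the per-step parameter
estimates (K, B, n, p) are pushed back through the Hunt-Crossley law along
the reference depth/velocity trajectory and compared with the noise-free
input force.  Parameter-space errors are secondary diagnostics only --
several parameter combinations can produce near-identical forces over a
short indentation, so force error is the quantity a surgeon-facing system
actually cares about.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hc_model import IDX_B, IDX_K, IDX_N, IDX_P, hc_force

log = logging.getLogger(__name__)

Array = np.ndarray


@dataclass
class ErrorReport:
    """Absolute force-reconstruction error statistics over a run."""

    mean_error: float
    max_error: float
    rmse: float
    per_step_error: Array

    def as_dict(self) -> dict:
        return {
            "mean_error": self.mean_error,
            "max_error": self.max_error,
            "rmse": self.rmse,
        }


def reconstruct_force(param_estimates: Array, d: Array, d_dot: Array) -> Array:
    """Per-step force from estimated H-C parameters along the reference trajectory.

    ``param_estimates`` is (n, 4) columns [K, B, n, p] (or a full (n, 7)
    state-estimate array, from which the parameter columns are taken);
    ``d`` and ``d_dot`` are the *true* depth and velocity series.
    """
    est = np.asarray(param_estimates, dtype=float)
    if est.ndim != 2:
        raise ValueError("param_estimates must be 2-D")
    if est.shape[1] == 7:
        est = est[:, [IDX_K, IDX_B, IDX_N, IDX_P]]
    elif est.shape[1] != 4:
        raise ValueError(f"expected 4 or 7 columns, got {est.shape[1]}")
    d = np.asarray(d, dtype=float)
    d_dot = np.asarray(d_dot, dtype=float)
    if not (len(est) == len(d) == len(d_dot)):
        raise ValueError("estimates, d and d_dot must have equal length")
    return hc_force(est, d, d_dot)


def error_metrics(F_hat: Array, F_ref: Array) -> ErrorReport:
    """Mean, max and RMSE of the absolute force-reconstruction error."""
    F_hat = np.asarray(F_hat, dtype=float)
    F_ref = np.asarray(F_ref, dtype=float)
    if F_hat.shape != F_ref.shape or F_hat.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    err = np.abs(F_hat - F_ref)
    return ErrorReport(
        mean_error=float(err.mean()),
        max_error=float(err.max()),
        rmse=float(np.sqrt(np.mean(err**2))),
        per_step_error=err,
    )


def read_indentation_csv(path) -> pd.DataFrame:
    """Read a recorded indentation as CSV with columns time, displacement,
    [velocity,] force.

    Velocity is optional: when absent it is recovered by central differences
    of displacement over time (one-sided at the endpoints).  Returns a
    DataFrame with all four columns, validated numeric and finite.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["time", "displacement", "force"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0]) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric value in column '{col}' at line {row}")
        df[col] = coerced.astype(float)
    if "velocity" not in df.columns:
        if len(df) < 2:
            raise ValueError(f"{path}: need >= 2 rows to differentiate displacement")
        df["velocity"] = np.gradient(df["displacement"].to_numpy(), df["time"].to_numpy())
        log.info("velocity column absent; recovered by finite differences")
    df = df[["time", "displacement", "velocity", "force"]]
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{path}: non-finite values in record")
    log.info("read %d indentation samples from %s (units assumed mm / mN)", len(df), path)
    return df
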