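"""Independent reference filters used as test oracles.

Deliberately naive, loop-based implementations written separately from the
package: a closed-form Kalman filter for linear-Gaussian systems and a
plain scaled-sigma-point UKF.  They share only the mathematical
conventions (2N+1 scaled sigma set; measurement update from sigma points
re-drawn out of the predicted belief), not any code.
"""

from __future__ import annotations

import numpy as np


def kalman_filter(x0, P0, A, H, Q, R, ys):
    """Textbook linear Kalman filter; returns lists of posterior means/covs."""
    x, P = np.array(x0, dtype=float), np.array(P0, dtype=float)
    means, covs = [], []
    for y in ys:
        x = A @ x
        P = A @ P @ A.T + Q
        S = H @ P @ H.T + R
        K = P @ H.T @ np.linalg.inv(S)
        x = x + K @ (np.atleast_1d(y) - H @ x)
        P = P - K @ S @ K.T
        means.append(x.copy())
        covs.append(P.copy())
    return means, covs


def _sigma_set(mean, cov, lam):
    n = len(mean)
    L = np.linalg.cholesky((n + lam) * cov)
    pts = [np.array(mean, dtype=float)]
    for i in range(n):
        pts.append(mean + L[:, i])
    for i in range(n):
        pts.append(mean - L[:, i])
    return pts


def _weights(n, alpha, beta, kappa):
    lam = alpha**2 * (n + kappa) - n
    wm = [lam / (n + lam)] + [1.0 / (2 * (n + lam))] * (2 * n)
    wc = list(wm)
    wc[0] += 1.0 - alpha**2 + beta
    return lam, wm, wc


def ukf_step(mean, cov, y, f, h, Q, R, alpha=1.0, beta=2.0, kappa=0.0):
    """One naive UKF step; returns (posterior mean, posterior covariance)."""
    mean = np.asarray(mean, dtype=float)
    n = len(mean)
    lam, wm, wc = _weights(n, alpha, beta, kappa)

    pts = _sigma_set(mean, cov, lam)
    prop = [np.atleast_1d(np.asarray(f(p), dtype=float)) for p in pts]
    x_bar = sum(w * p for w, p in zip(wm, prop))
    P_bar = np.zeros((n, n))
    for w, p in zip(wc, prop):
        d = (p - x_bar)[:, None]
        P_bar += w * (d @ d.T)
    P_bar += Q
    P_bar = 0.5 * (P_bar + P_bar.T)

    pts2 = _sigma_set(x_bar, P_bar, lam)
    ypts = [np.atleast_1d(np.asarray(h(p), dtype=float)) for p in pts2]
    y_bar = sum(w * p for w, p in zip(wm, ypts))
    m = len(y_bar)
    Py = np.zeros((m, m))
    Pxy = np.zeros((n, m))
    for w, p, xp in zip(wc, ypts, pts2):
        dy = (p - y_bar)[:, None]
        dx = (xp - x_bar)[:, None]
        Py += w * (dy @ dy.T)
        Pxy += w * (dx @ dy.T)
    Py += R
    K = Pxy @ np.linalg.inv(Py)
    x_hat = x_bar + K @ (np.atleast_1d(y) - y_bar)
    P_hat = P_bar - K @ Py @ K.T
    return x_hat, 0.5 * (P_hat + P_hat.T)
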