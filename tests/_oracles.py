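"""Independent oracles used by the test suite.

Each oracle is a deliberately naive reference implementation (brute force,
dense-grid integration, closed form) kept free of the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def criterion_oracle(outcomes) -> int | None:
    """Brute-force sliding-window scan for 13-of-the-last-15 correct."""
    y = list(outcomes)
    for t in range(len(y)):
        if t + 1 < 13:
            continue
        window = y[max(0, t + 1 - 15):t + 1]
        if sum(window) >= 13:
            return t
    return None


def count_spikes_interval(times, t0, t1) -> int:
    """Brute-force half-open interval count."""
    return sum(1 for t in times if t0 <= t < t1)


def grid_smoother(outcomes, mu, x0, s2, n_grid=2001, span=10.0):
    """Dense-grid forward-backward smoother for the Bernoulli random walk.

    Exact (up to discretisation) posterior over the latent state on a grid
    of ``n_grid`` points; returns the per-trial posterior mean of the
    latent state mapped through the logistic (the statistic the smoother
    estimates).  Transition N(0, s2) applied by direct convolution.
    """
    y = np.asarray(outcomes, float)
    T = len(y)
    x = np.linspace(x0 - span, x0 + span, n_grid)
    h = x[1] - x[0]
    half = min((n_grid - 1) // 2, max(3, int(np.ceil(6.0 * np.sqrt(s2) / h))))
    kx = np.arange(-half, half + 1) * h
    kernel = np.exp(-0.5 * kx ** 2 / s2)
    kernel /= kernel.sum()

    p_of_x = 1.0 / (1.0 + np.exp(-(x + mu)))
    lik = np.where(y[:, None] == 1.0, p_of_x, 1.0 - p_of_x)

    def prop(v):
        out = np.convolve(v, kernel, mode="same")
        return out

    alpha = np.empty((T, n_grid))
    prior1 = np.exp(-0.5 * (x - x0) ** 2 / s2)
    prior1 /= prior1.sum()
    a = prior1 * lik[0]
    alpha[0] = a / a.sum()
    for t in range(1, T):
        a = prop(alpha[t - 1]) * lik[t]
        alpha[t] = a / a.sum()

    beta = np.empty((T, n_grid))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = prop(beta[t + 1] * lik[t + 1])
        beta[t] = b / b.max()

    p_mean = np.empty(T)
    for t in range(T):
        post = alpha[t] * beta[t]
        post /= post.sum()
        xm = float((post * x).sum())
        p_mean[t] = 1.0 / (1.0 + np.exp(-(xm + mu)))
    return p_mean


def mahalanobis_solve_oracle(t, centre, S_reg):
    """Explicit linear-solve Mahalanobis distance on a given matrix."""
    diff = np.asarray(t, float) - np.asarray(centre, float)
    return float(np.sqrt(diff @ np.linalg.solve(S_reg, diff)))


def partial_spearman_residual_oracle(x, y, z):
    """Partial rank correlation via OLS residuals of the ranks."""
    from scipy.stats import rankdata
    rx, ry, rz = (rankdata(v) for v in (x, y, z))
    Z = np.column_stack([np.ones(len(rz)), rz])
    res_x = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    res_y = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    return float(np.corrcoef(res_x, res_y)[0, 1])


def ols_normal_equations(X, y):
    """Closed-form least squares via the normal equations."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)
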