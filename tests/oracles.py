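"""Independent numerical oracles used by the tests.

Everything here is deliberately written from first principles (explicit
RK4 stepping, brute-force enumeration, normal equations) and never calls
the package code paths it is used to check.
"""

from __future__ import annotations

import numpy as np


def rk4_logistic_substrate(
    x0, xmax, mu, y_xs, alpha, y_ps, ke, s0, t_end=264.0, step=0.01, record_every=100
):
    """Jointly integrate dX/dt = mu X (1 - X/xmax) and the substrate balance
    -dS/dt = (1/y_xs + alpha/y_ps) dX/dt + ke X with classical RK4.

    Parameters may be scalars or equal-length arrays (vectorized over
    parameter sets).  Returns (t_grid, X, S) sampled every
    ``record_every`` steps (including t = 0).
    """
    x0, xmax, mu, y_xs, alpha, y_ps, ke, s0 = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, float)) for v in (x0, xmax, mu, y_xs, alpha, y_ps, ke, s0))
    )
    coeff = 1.0 / y_xs + alpha / y_ps

    def deriv(x):
        dx = mu * x * (1.0 - x / xmax)
        ds = -(coeff * dx + ke * x)
        return dx, ds

    n_steps = int(round(t_end / step))
    x = x0.copy()
    s = s0.copy()
    ts, xs, ss = [0.0], [x.copy()], [s.copy()]
    for i in range(1, n_steps + 1):
        k1x, k1s = deriv(x)
        k2x, k2s = deriv(x + 0.5 * step * k1x)
        k3x, k3s = deriv(x + 0.5 * step * k2x)
        k4x, k4s = deriv(x + step * k3x)
        x = x + (step / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x)
        s = s + (step / 6.0) * (k1s + 2 * k2s + 2 * k3s + k4s)
        if i % record_every == 0:
            ts.append(i * step)
            xs.append(x.copy())
            ss.append(s.copy())
    return np.array(ts), np.array(xs), np.array(ss)


def bh_stepup_brute(p):
    """Benjamini-Hochberg adjusted p-values by direct enumeration of the
    step-up definition: q_i = min(1, min_{j: p_j >= p_i} m * p_j / rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        adj[i] = min(1.0, min(candidates))
    return adj


def ols_normal_equations(x, y):
    """Simple-regression slope/intercept from covariance formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean()


def two_pass_mean_sd(values):
    """Textbook two-pass mean and sample SD."""
    values = list(map(float, values))
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var**0.5
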