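"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's adaptive Runge-Kutta code path:
the trajectory oracle is a fixed-step explicit Euler scheme, and the
initial-slope oracle is the closed-form rate law evaluated at S = 1.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def euler_single(V, K, n, beta, alpha, t_end, dt):
    """Fixed-step explicit Euler solution of the single-pair rate law."""
    s = 1.0
    steps = int(round(t_end / dt))
    for _ in range(steps):
        d = s - beta
        if d > 0.0:
            dn = d**n
            s += dt * (-alpha * V * dn / (dn + K**n))
        if s < beta:
            s = beta
    return s


def mixture_initial_slope(km, alphas):
    """Closed-form d[S_i]/dt at t = 0 (S_i = 1) for every substrate."""
    alphas = np.asarray(alphas, dtype=float)
    d = 1.0 - km.beta
    dn = d**km.n
    rates = alphas[None, :] * km.V * dn / (dn + km.K**km.n)
    return -rates.sum(axis=1)


def rmse_by_hand(true, est):
    """Textbook per-column RMSE, written independently of the package."""
    true = np.atleast_2d(np.asarray(true, dtype=float))
    est = np.atleast_2d(np.asarray(est, dtype=float))
    out = []
    for j in range(true.shape[1]):
        sq = [(est[k, j] - true[k, j]) ** 2 for k in range(true.shape[0])]
        out.append((sum(sq) / len(sq)) ** 0.5)
    return np.array(out)
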