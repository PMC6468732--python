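"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: a fixed-step
classical Runge-Kutta integrator (vs the adaptive LSODA route) and a
brute-force rank enumeration for the MSSS decile score.
"""

import numpy as np

from opncircuit.model import _rhs


def rk4_trajectory(params, init_vec, schedule, t_end, dt):
    """Classical fixed-step RK4 from t=0 to t_end; returns (times, states)."""
    n = int(round(t_end / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    out = np.empty((n + 1, len(init_vec)))
    y = np.asarray(init_vec, dtype=float).copy()
    out[0] = y
    for k in range(n):
        t = times[k]
        k1 = _rhs(t, y, params, schedule)
        k2 = _rhs(t + dt / 2, y + dt / 2 * k1, params, schedule)
        k3 = _rhs(t + dt / 2, y + dt / 2 * k2, params, schedule)
        k4 = _rhs(t + dt, y + dt * k3, params, schedule)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k + 1] = y
    return times, out


def msss_brute_force(bin_values, edss):
    """Rank enumeration: sort the augmented bin, average the ranks of the
    query value, divide by (augmented size + 1), times 10."""
    aug = sorted(list(bin_values) + [edss])
    ranks = [i + 1 for i, v in enumerate(aug) if v == edss]
    mid = (min(ranks) + max(ranks)) / 2.0
    return 10.0 * mid / (len(aug) + 1)
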