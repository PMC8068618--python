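"""Reference dynamical systems for validating the nonlinear-dynamics stack.

These generate trajectories with known Lyapunov structure (the r = 4
logistic map has an exact exponent of ln 2; the classic Lorenz system a
largest exponent near 0.9 nats per time unit) and serve as benchmark
inputs for the embedding and divergence machinery.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logistic_map_series", "lorenz_series", "LOGISTIC_LLE", "LORENZ_PARAMS"]

LOGISTIC_LLE = float(np.log(2.0))  # exact largest exponent at r = 4
LORENZ_PARAMS = (10.0, 28.0, 8.0 / 3.0)  # sigma, rho, beta


def logistic_map_series(n: int, x0: float = 0.2, r: float = 4.0) -> np.ndarray:
    """Iterates of the logistic map x <- r x (1 - x)."""
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x


def _lorenz_rhs(state: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x, y, z = state
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def lorenz_series(
    n: int,
    dt: float = 0.01,
    transient: int = 2000,
    initial: tuple[float, float, float] = (1.0, 1.0, 1.0),
    params: tuple[float, float, float] = LORENZ_PARAMS,
) -> np.ndarray:
    """(n, 3) Lorenz trajectory, RK4-integrated, after a discarded transient."""
    sigma, rho, beta = params
    state = np.array(initial, dtype=float)
    out = np.empty((n, 3))
    for i in range(-transient, n):
        k1 = _lorenz_rhs(state, sigma, rho, beta)
        k2 = _lorenz_rhs(state + 0.5 * dt * k1, sigma, rho, beta)
        k3 = _lorenz_rhs(state + 0.5 * dt * k2, sigma, rho, beta)
        k4 = _lorenz_rhs(state + dt * k3, sigma, rho, beta)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= 0:
            out[i] = state
    return out
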