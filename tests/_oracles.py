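"""Independent oracles used by the tests.

The convex oracle solves the l1/l2-constrained linear maximization as a smooth
nonlinear program via SLSQP with omega = w+ - w- variable splitting (both parts
nonnegative, so the l1 constraint becomes linear). It shares no code with the
closed-form solver it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def convex_oracle(v: np.ndarray, s: float) -> np.ndarray:
    """Maximize <v, omega> s.t. ||omega||_2 <= 1, ||omega||_1 <= sqrt(s)."""
    v = np.asarray(v, dtype=float)
    p = v.size

    def neg_obj(z):
        return -(v @ (z[:p] - z[p:]))

    def grad(_z):
        return np.concatenate([-v, v])

    cons = [
        {
            "type": "ineq",
            "fun": lambda z: np.sqrt(s) - z.sum(),
            "jac": lambda z: -np.ones(2 * p),
        },
        {
            "type": "ineq",
            "fun": lambda z: 1.0 - ((z[:p] - z[p:]) ** 2).sum(),
            "jac": lambda z: np.concatenate(
                [-2 * (z[:p] - z[p:]), 2 * (z[:p] - z[p:])]
            ),
        },
    ]
    x0 = np.zeros(2 * p)
    top = int(np.argmax(np.abs(v)))
    if v[top] >= 0:
        x0[top] = 0.5
    else:
        x0[p + top] = 0.5
    res = minimize(
        neg_obj,
        x0,
        jac=grad,
        constraints=cons,
        bounds=[(0.0, None)] * (2 * p),
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    z = res.x
    return z[:p] - z[p:]


def beta_grid_search(v: np.ndarray, s: float, n_grid: int = 200_001) -> float:
    """Dense grid search for the threshold where the l1/l2 ratio hits sqrt(s)."""
    v = np.asarray(v, dtype=float)
    a = np.abs(v)
    grid = np.linspace(0.0, a.max() * (1 - 1e-9), n_grid)
    best_beta, best_gap = 0.0, np.inf
    for b in grid:
        t = np.sign(v) * np.maximum(a - b, 0.0)
        n2 = np.linalg.norm(t)
        if n2 == 0:
            break
        gap = abs(np.abs(t).sum() / n2 - np.sqrt(s))
        if gap < best_gap:
            best_gap, best_beta = gap, b
    return best_beta


def random_feasible(rng: np.random.Generator, p: int, s: float, n: int) -> np.ndarray:
    """n random points inside {||w||_2 <= 1, ||w||_1 <= sqrt(s)}."""
    W = rng.normal(size=(n, p))
    W /= np.maximum(np.linalg.norm(W, axis=1, keepdims=True), 1e-12)
    W *= rng.uniform(0, 1, size=(n, 1)) ** (1.0 / p)
    l1 = np.abs(W).sum(axis=1, keepdims=True)
    shrink = np.minimum(1.0, np.sqrt(s) / np.maximum(l1, 1e-12))
    return W * shrink
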