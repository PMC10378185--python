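"""Independent oracles used by the test suite.

These re-derive expected values by brute force or closed form, without
touching the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import scipy.stats


def rk4(f, y0, t_end: float, dt: float) -> np.ndarray:
    """Fixed-step classical Runge-Kutta integration of y' = f(t, y)."""
    y = np.array(y0, dtype=float)
    t = 0.0
    n_steps = max(1, int(round(t_end / dt)))
    dt = t_end / n_steps
    for _ in range(n_steps):
        k1 = f(t, y)
        k2 = f(t + dt / 2, y + dt / 2 * k1)
        k3 = f(t + dt / 2, y + dt / 2 * k2)
        k4 = f(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


def recovery_curve_auc(expression: np.ndarray, member_mask: np.ndarray, top: int) -> float:
    """Brute-force rank-AUC: sort genes by decreasing expression (assumes no
    ties), count set members among the top x for x = 1..top, sum the step
    curve and normalize by the ideal curve for the same set size."""
    order = np.argsort(-expression, kind="stable")
    hits = member_mask[order[:top]]
    area = 0
    running = 0
    for x in range(top):
        running += int(hits[x])
        area += running
    m = int(member_mask.sum())
    if m == 0:
        return 0.0
    max_area = sum(min(x, m) for x in range(1, top + 1))
    return area / max_area


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept from the explicit (X^T X)^-1 X^T y solution."""
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[0]), float(beta[1])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by direct tail minimum: q_i = min_{j: p_j >= p_i}
    (m * p_j / rank_j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    tail_min = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(tail_min, 1.0)
    return out


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided equal-variance two-sample t-test from the textbook formula."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * scipy.stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)
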