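"""Growth laws for cultured cell populations and multi-clone competition.

The single-population laws are the generalized logistic (Richards) family

    dN/dt = r * N * (1 - (N/K)^v),

its ``v = 1`` special case (Verhulst, the classic logistic), and the Gompertz
law ``dN/dt = r * N * ln(K/N)``.  ``r`` is the maximum per-capita growth rate
(1/day), ``K`` the carrying capacity set by spatial limitation, and ``v`` the
loss-of-contact-inhibition exponent shaping how growth slows near confluence.

Co-existing clones of the same cell line compete through a shared capacity
constraint: every clone's growth is throttled by the summed occupancy of all
clones,

    dN_i/dt = N_i * r_i * (1 - (sum_j N_j/K_j)^v),

with ``v`` identical for all clones of a line.  When the culture is seeded
below the capacity surface (``sum_j N_j(0)/K_j < 1``) every clone's derivative
stays nonnegative along the trajectory, so populations never shrink; this is
exercised numerically by the test suite.

Internal state is absolute cell count.  Densities in cells/cm^2 are converted
at the I/O boundary using a configurable culture surface area (default 25 cm^2,
a T25 flask).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidParameterError

MODELS = ("verhulst", "richards", "gompertz")

#: Tolerances of the adaptive Dormand-Prince integrator (scipy ``RK45``).
RTOL = 1e-8
ATOL = 1e-6

#: Culture surface of a T25 flask, used to convert densities to counts.
DEFAULT_AREA_CM2 = 25.0


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one population's growth law.

    Attributes
    ----------
    r : maximum per-capita growth rate (1/day), ``r >= 0``.
    K : carrying capacity (cells), ``K > 0``.
    n0 : initial population size (cells), ``n0 > 0``.
    v : loss-of-contact-inhibition exponent, ``v > 0``; ignored by Gompertz,
        must equal 1 for Verhulst.
    """

    r: float
    K: float
    n0: float
    v: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.r, self.K, self.n0, self.v)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite growth parameters: {vals}")
        if self.r < 0:
            raise InvalidParameterError(f"r must be >= 0, got {self.r}")
        if self.K <= 0:
            raise InvalidParameterError(f"K must be > 0, got {self.K}")
        if self.n0 <= 0:
            raise InvalidParameterError(f"n0 must be > 0, got {self.n0}")
        if self.v <= 0:
            raise InvalidParameterError(f"v must be > 0, got {self.v}")


@dataclass
class GrowthCurve:
    """Timestamped cell counts for one cell line or one simulation."""

    times: np.ndarray
    counts: np.ndarray
    population_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise InvalidParameterError("times and counts must be 1-D and equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if len(self.times) and self.times[0] < 0:
            raise InvalidParameterError("times must be non-negative")
        if not np.all(np.isfinite(self.counts)):
            raise InvalidParameterError("counts must be finite")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "count": self.counts,
                "population_id": self.population_id,
            }
        )


def verhulst_solution(params: GrowthParams, t) -> np.ndarray:
    """Exact logistic trajectory ``K / (1 + ((K-n0)/n0) e^{-rt})``.

    Requires ``params.v == 1``; no integration is performed.
    """
    if params.v != 1:
        raise InvalidParameterError("verhulst_solution requires v = 1")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    b = (params.K - params.n0) / params.n0
    return params.K / (1.0 + b * np.exp(-params.r * t))


def richards_solution(params: GrowthParams, t) -> np.ndarray:
    """Exact Richards trajectory ``K (1 + ((K/n0)^v - 1) e^{-rvt})^{-1/v}``.

    Evaluated in log space so that extreme ``v`` or ``K/n0`` (as visited by
    likelihood profiling) do not overflow.
    """
    t = np.asarray(t, dtype=float)
    r, K, n0, v = params.r, params.K, params.n0, params.v
    q = v * np.log(K / n0)
    if q > 0:
        # A = expm1(q) > 0: use log1p(exp(.)) = logaddexp(0, .) for stability
        log_a = q + np.log1p(-np.exp(-q)) if q > 1e-10 else np.log(np.expm1(q))
        log_term = np.logaddexp(0.0, log_a - r * v * t)
    else:
        # n0 >= K: A in (-1, 0], direct evaluation is safe
        log_term = np.log1p(np.expm1(q) * np.exp(-r * v * t))
    return K * np.exp(-log_term / v)


def gompertz_solution(params: GrowthParams, t) -> np.ndarray:
    """Exact Gompertz trajectory ``K exp(ln(n0/K) e^{-rt})``."""
    t = np.asarray(t, dtype=float)
    return params.K * np.exp(np.log(params.n0 / params.K) * np.exp(-params.r * t))


_SOLUTIONS = {
    "verhulst": verhulst_solution,
    "richards": richards_solution,
    "gompertz": gompertz_solution,
}


def model_solution(model: str, params: GrowthParams, t) -> np.ndarray:
    """Closed-form trajectory of ``model`` evaluated at times ``t``."""
    if model not in MODELS:
        raise InvalidParameterError(f"unknown model {model!r}; choose from {MODELS}")
    return _SOLUTIONS[model](params, t)


def growth_rhs(model: str, params: GrowthParams, n) -> np.ndarray:
    """Right-hand side dN/dt of the chosen growth law at population size ``n``.

    Gompertz at ``n = 0`` is defined as 0 (the limit of ``r n ln(K/n)``).
    """
    if model not in MODELS:
        raise InvalidParameterError(f"unknown model {model!r}; choose from {MODELS}")
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise InvalidParameterError("population size must be >= 0")
    r, K, v = params.r, params.K, params.v
    if model == "gompertz":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(n_arr > 0, r * n_arr * np.log(K / np.maximum(n_arr, 1e-300)), 0.0)
    else:
        vv = 1.0 if model == "verhulst" else v
        out = n_arr * r * (1.0 - (n_arr / K) ** vv)
    return out if np.ndim(n) else float(out)


def simulate_growth(
    model: str,
    params: GrowthParams,
    t_grid,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> GrowthCurve:
    """Integrate the chosen growth law over ``t_grid`` (days, starting at 0).

    Verhulst trajectories agree with :func:`verhulst_solution` to the solver
    tolerance (relative error below ~1e-6 of K over tens of days).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise InvalidParameterError("t_grid must contain at least two times")
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError("t_grid must be strictly increasing from 0")

    def rhs(_t, y):
        return [growth_rhs(model, params, max(y[0], 0.0))]

    sol = solve_ivp(
        rhs,
        (0.0, t_grid[-1]),
        [params.n0],
        t_eval=t_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"growth integration failed: {sol.message}")
    return GrowthCurve(times=t_grid, counts=sol.y[0], population_id=model)


@dataclass
class CloneSystem:
    """Clones of one cell line competing under a shared capacity constraint.

    ``clone_ids``, ``r`` and ``K`` are parallel sequences; ``v`` is the shared
    loss-of-contact-inhibition exponent; ``state`` holds current clone sizes.
    """

    clone_ids: Sequence[str]
    r: np.ndarray
    K: np.ndarray
    v: float = 1.0
    state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.clone_ids = tuple(str(c) for c in self.clone_ids)
        self.r = np.asarray(self.r, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.clone_ids)
        if len(set(self.clone_ids)) != n:
            raise InvalidParameterError("clone IDs must be unique")
        if self.r.shape != (n,) or self.K.shape != (n,):
            raise InvalidParameterError("r and K must match the number of clones")
        if np.any(self.r < 0) or np.any(~np.isfinite(self.r)):
            raise InvalidParameterError("clone growth rates must be finite and >= 0")
        if np.any(self.K <= 0) or np.any(~np.isfinite(self.K)):
            raise InvalidParameterError("clone capacities must be finite and > 0")
        if self.v <= 0 or not np.isfinite(self.v):
            raise InvalidParameterError("v must be finite and > 0")
        if self.state is not None:
            self.state = np.asarray(self.state, dtype=float)
            if self.state.shape != (n,):
                raise InvalidParameterError("state length must match the number of clones")
            if np.any(self.state < 0):
                raise InvalidParameterError("clone sizes must be >= 0")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def with_state(self, state) -> "CloneSystem":
        return dataclasses.replace(self, state=np.asarray(state, dtype=float))


def competition_rhs(system: CloneSystem, n_vec) -> np.ndarray:
    """dN_i/dt for every clone at clone sizes ``n_vec``."""
    n_vec = np.asarray(n_vec, dtype=float)
    if n_vec.shape != (system.n_clones,):
        raise InvalidParameterError("state length must match the number of clones")
    occupancy = float(np.sum(np.maximum(n_vec, 0.0) / system.K))
    return n_vec * system.r * (1.0 - occupancy**system.v)


@dataclass
class CloneTrajectories:
    """Per-clone population trajectories from a competition simulation."""

    clone_ids: tuple
    times: np.ndarray
    sizes: np.ndarray  # shape (n_times, n_clones)

    @property
    def totals(self) -> np.ndarray:
        return self.sizes.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.totals
        return self.sizes / tot[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sizes, index=self.times, columns=list(self.clone_ids))


def simulate_clonal_competition(
    system: CloneSystem,
    t_grid,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> CloneTrajectories:
    """Integrate the shared-capacity competition system over ``t_grid``.

    Clones seeded at 0 stay at 0.  Under the precondition
    ``sum_i N_i(0)/K_i < 1`` all trajectories are non-decreasing.  Clone sizes
    are never truncated at an extinction floor: the model is continuous and
    arbitrarily small frequencies are reported exactly.
    """
    if system.state is None:
        raise InvalidParameterError("CloneSystem.state must be set before simulation")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise InvalidParameterError("t_grid must contain at least two times")
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError("t_grid must be strictly increasing from 0")

    sol = solve_ivp(
        lambda _t, y: competition_rhs(system, y),
        (0.0, t_grid[-1]),
        system.state,
        t_eval=t_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"competition integration failed: {sol.message}")
    return CloneTrajectories(
        clone_ids=tuple(system.clone_ids), times=t_grid, sizes=sol.y.T.copy()
    )
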