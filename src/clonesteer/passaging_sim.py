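"""Serial-passage simulation of clonal competition and evolutionary steering.

A passage seeds ``seeding_density * area`` cells at given clone frequencies,
lets the shared-capacity competition system grow for ``interval_days``, then
harvests; harvest frequencies set the seeding frequencies of the next passage
(deterministic dilution, no bottleneck sampling).  Because every clone's
per-capita growth is throttled by the same occupancy factor (1 - sum N_j/K_j),
the faster-growing clone gains frequency whenever the culture grows at all;
what the schedule controls is the number of doublings per passage.  Low
seeding densities and long intervals let the r-selected clone sweep quickly;
high densities and short intervals keep the culture near confluence so an
initially dominant K-selected clone holds its advantage for many passages.
The schedule thus steers how fast clonal composition shifts.

The steering heatmap scans (density, interval) grids and summarizes each
schedule with the signed winner metric

    sgn(CloneK - Cloner) * log10(max(Cloner, CloneK)),

positive when the designated K-clone ends larger (K selection), negative when
the r-clone does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, SeedingError
from .growth_models import DEFAULT_AREA_CM2, CloneSystem, simulate_clonal_competition


@dataclass(frozen=True)
class PassageSchedule:
    """A culture schedule: how densely to seed and how often to split."""

    seeding_density: float  # cells/cm^2
    interval_days: float
    n_passages: int
    area_cm2: float = DEFAULT_AREA_CM2

    def __post_init__(self):
        if self.seeding_density <= 0 or self.area_cm2 <= 0:
            raise InvalidParameterError("seeding density and area must be > 0")
        if self.interval_days <= 0:
            raise InvalidParameterError("splitting interval must be > 0")
        if self.n_passages < 0:
            raise InvalidParameterError("number of passages must be >= 0")

    @property
    def seed_total(self) -> float:
        return self.seeding_density * self.area_cm2


@dataclass
class PassageOutcome:
    """Per-passage clone sizes under one schedule.

    ``sizes`` has shape (n_passages + 1, n_clones): row 0 is the seeded state
    (passage 0), row p the harvest of passage p.
    """

    clone_ids: tuple
    sizes: np.ndarray
    schedule: PassageSchedule

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.sizes.sum(axis=1)
        return self.sizes / tot[:, None]

    @property
    def final_sizes(self) -> dict:
        return dict(zip(self.clone_ids, self.sizes[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.sizes, columns=list(self.clone_ids))
        df.index.name = "passage"
        return df


def _check_seeding(seeded: np.ndarray, K: np.ndarray) -> None:
    occ = float(np.sum(seeded / K))
    if occ >= 1.0:
        raise SeedingError(
            f"seeded occupancy sum(N0/K) = {occ:.3f} >= 1 violates the "
            "nonnegative-growth precondition"
        )


def run_passage_series(
    clones: CloneSystem,
    schedule: PassageSchedule,
    initial_frequencies,
) -> PassageOutcome:
    """Simulate ``schedule.n_passages`` passages of clonal competition.

    Every passage integrates the shared-capacity system for the splitting
    interval from the seeded state; harvest frequencies set the next seeding.
    The seeded total always equals density x area exactly, and reseeding
    preserves clone ratios (deterministic dilution).
    """
    f = np.asarray(initial_frequencies, dtype=float)
    if f.shape != (clones.n_clones,):
        raise InvalidParameterError("initial frequencies must match the number of clones")
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
        raise InvalidParameterError("initial frequencies must be >= 0 and sum to 1")

    state = schedule.seed_total * f
    _check_seeding(state, clones.K)
    sizes = [state]
    for _ in range(schedule.n_passages):
        traj = simulate_clonal_competition(
            clones.with_state(state), np.array([0.0, schedule.interval_days])
        )
        harvest = np.maximum(traj.sizes[-1], 0.0)
        sizes.append(harvest)
        state = schedule.seed_total * harvest / harvest.sum()
        _check_seeding(state, clones.K)
    return PassageOutcome(
        clone_ids=tuple(clones.clone_ids), sizes=np.array(sizes), schedule=schedule
    )


def outcome_metric(clone_r_size: float, clone_k_size: float) -> float:
    """Signed winner metric ``sgn(CloneK - Cloner) * log10(max(Cloner, CloneK))``.

    Positive entries mean K selection (the K-clone wins), negative entries r
    selection; the magnitude is the log size of the winning clone.
    """
    if clone_r_size < 0 or clone_k_size < 0:
        raise InvalidParameterError("clone sizes must be >= 0")
    if clone_r_size == 0 and clone_k_size == 0:
        warnings.warn("both clone sizes are 0; metric set to 0", stacklevel=2)
        return 0.0
    return float(np.sign(clone_k_size - clone_r_size) * np.log10(max(clone_r_size, clone_k_size)))


def steering_heatmap(
    clones: CloneSystem,
    density_grid,
    interval_grid,
    r_clone: str,
    k_clone: str,
    n_passages: int = 30,
    initial_frequencies=None,
    area_cm2: float = DEFAULT_AREA_CM2,
) -> pd.DataFrame:
    """Outcome metric of the designated clone pair across a schedule grid.

    Rows are splitting intervals (days), columns seeding densities
    (cells/cm^2).  Any clones beyond the focal pair stay in the system during
    simulation; the metric is computed on the pair only.  Schedules seeding at
    or above the capacity surface are marked missing (NaN), not fatal.
    """
    density_grid = np.asarray(density_grid, dtype=float)
    interval_grid = np.asarray(interval_grid, dtype=float)
    if density_grid.size == 0 or interval_grid.size == 0:
        raise InvalidParameterError("density and interval grids must be non-empty")
    ids = list(clones.clone_ids)
    for c in (r_clone, k_clone):
        if c not in ids:
            raise InvalidParameterError(f"clone {c!r} not in system {ids}")
    if initial_frequencies is None:
        initial_frequencies = np.full(clones.n_clones, 1.0 / clones.n_clones)
    ir, ik = ids.index(r_clone), ids.index(k_clone)

    mat = np.full((len(interval_grid), len(density_grid)), np.nan)
    for i, interval in enumerate(interval_grid):
        for j, density in enumerate(density_grid):
            schedule = PassageSchedule(
                seeding_density=float(density),
                interval_days=float(interval),
                n_passages=n_passages,
                area_cm2=area_cm2,
            )
            try:
                outcome = run_passage_series(clones, schedule, initial_frequencies)
            except SeedingError:
                continue
            final = outcome.sizes[-1]
            mat[i, j] = outcome_metric(final[ir], final[ik])
    df = pd.DataFrame(mat, index=interval_grid, columns=density_grid)
    df.index.name = "interval_days"
    df.columns.name = "seeding_density"
    return df


def crossing_passage(outcome: PassageOutcome, clone_a: str, clone_b: str):
    """Smallest passage index at which frequency(a) strictly exceeds
    frequency(b), or ``None`` if it never does.

    Passage 0 is the seeded state; passages 1..n are harvests.
    """
    ids = list(outcome.clone_ids)
    for c in (clone_a, clone_b):
        if c not in ids:
            raise InvalidParameterError(f"clone {c!r} not in outcome {ids}")
    ia, ib = ids.index(clone_a), ids.index(clone_b)
    freq = outcome.frequencies
    above = np.nonzero(freq[:, ia] > freq[:, ib])[0]
    return int(above[0]) if len(above) else None
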