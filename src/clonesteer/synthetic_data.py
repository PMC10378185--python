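"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates the three inputs of the pipeline without any downloads:

1. **Growth curves** — daily cell counts from a chosen growth law with
   multiplicative log-normal observation noise of a given coefficient of
   variation, emulating live-cell-imaging counts.  Default parameter ranges
   follow the in-vitro regime the pipeline is designed for: seeding densities
   of 4.98-38.64e3 cells/cm^2, carrying capacities of 1.92-15.32e5
   cells/cm^2 on a 25 cm^2 flask, growth until plateau within 6-21 days.

2. **Clone-structured expression matrices** — negative-binomial counts for
   cells labeled by cell line, clone and cell-cycle phase.  One driver gene
   set carries the growth-rate signal and another the carrying-capacity
   signal: each driver gene's expected expression scales as
   ``effect_fold ** z``, where ``z`` in [0, 1] is the clone's parameter
   normalized across the cohort.  Rank-based activity of the driver set is
   therefore monotone (approximately linear) in the clone's true parameter,
   which is what the biomarker regression assumes.  Background genes are
   i.i.d. across cells.

3. **Ground truth** — the generating parameters per line and clone, the
   driver set names, and the planted trade-off pair, for recovery tests.

Everything is deterministic given the scenario seed; changing only the seed
changes noise realizations, not structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .errors import ConfoundedDesignError, InvalidParameterError
from .growth_models import DEFAULT_AREA_CM2, GrowthCurve, GrowthParams, model_solution
from .pathway_activity import PHASES, GeneSet

#: In-vitro regime (cells/cm^2) the defaults emulate.
SEEDING_DENSITY_RANGE = (4.98e3, 38.64e3)
CAPACITY_DENSITY_RANGE = (1.92e5, 15.32e5)
#: Growth-rate range (1/day) consistent with reaching confluence in 6-21 days.
GROWTH_RATE_RANGE = (0.4, 1.3)


@dataclass(frozen=True)
class CloneSpec:
    clone_id: str
    r: float
    K: float
    n_cells: int = 200


@dataclass(frozen=True)
class CellLineSpec:
    name: str
    params: GrowthParams
    clones: tuple = ()


@dataclass
class SyntheticScenario:
    """Full specification of a synthetic cohort."""

    cell_lines: list
    seed: int = 0
    n_genes: int = 2000
    n_gene_sets: int = 25
    genes_per_set: int = 20
    driver_r_set: str = "PW01"
    driver_k_set: str = "PW02"
    effect_fold: float = 4.0  # driver-gene fold change across the cohort range
    background_mean: float = 1.0
    nb_dispersion: float | None = 2.0  # None = noise-free expression
    library_sigma: float = 0.15  # log-sd of per-cell library size factors
    phase_probs: tuple = (0.6, 0.2, 0.2)
    count_noise_cv: float = 0.05
    sampling_days: int = 21
    area_cm2: float = DEFAULT_AREA_CM2

    def __post_init__(self):
        if self.driver_r_set == self.driver_k_set:
            raise ConfoundedDesignError("r and K driver gene sets must differ")
        if self.n_gene_sets * self.genes_per_set > self.n_genes:
            raise InvalidParameterError("gene sets do not fit into the gene universe")
        if abs(sum(self.phase_probs) - 1.0) > 1e-9:
            raise InvalidParameterError("phase probabilities must sum to 1")

    def gene_sets(self) -> list[GeneSet]:
        """Disjoint gene sets PW01..PWnn over the gene universe."""
        names = [f"PW{i + 1:02d}" for i in range(self.n_gene_sets)]
        out = []
        for s, name in enumerate(names):
            lo = s * self.genes_per_set
            out.append(
                GeneSet(name, tuple(f"G{g:04d}" for g in range(lo, lo + self.genes_per_set)))
            )
        return out

    def all_clones(self) -> list[CloneSpec]:
        return [c for line in self.cell_lines for c in line.clones]


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """An 8-cell-line cohort mirroring the pipeline's target regime.

    Line CL1 carries the planted r/K trade-off (clone c1A grows faster, c1B
    saturates higher); its third clone and every clone pair of the other
    lines differ concordantly (higher r together with higher K), which can
    never satisfy the opposing-ratio rule.  Line CL2 carries no trade-off by
    construction.  Line-level (r, K) values span the regime's printed ranges
    with no strong r-K correlation across lines.
    """
    area = DEFAULT_AREA_CM2
    # densities (cells/cm^2) -> absolute counts on a T25 flask
    # (r, K) pairing chosen so line-level r and K are nearly uncorrelated
    # (Pearson ~ 0.1), as in cohorts where the two traits vary independently.
    line_defs = [
        # name,   r,    K density, N0 density
        ("CL1", 1.30, 6.0e5, 1.0e4),
        ("CL2", 0.50, 4.8e5, 2.5e4),
        ("CL3", 0.90, 12.0e5, 0.8e4),
        ("CL4", 0.70, 4.0e5, 3.0e4),
        ("CL5", 1.10, 10.0e5, 1.5e4),
        ("CL6", 0.60, 7.2e5, 3.6e4),
        ("CL7", 1.00, 3.2e5, 0.6e4),
        ("CL8", 0.80, 14.0e5, 2.0e4),
    ]
    lines = []
    for name, r, k_dens, n0_dens in line_defs:
        K, n0 = k_dens * area, n0_dens * area
        if name == "CL1":
            # median clone r equals the line r so the line's median activity
            # stays on the cohort-level linear trend; the K-selected clone is
            # the most abundant, so schedules can either preserve or erode
            # its dominance over the r-selected clone
            clones = (
                CloneSpec("c1A", r=1.30, K=0.65 * K, n_cells=200),  # r-selected
                CloneSpec("c1B", r=0.90, K=1.30 * K, n_cells=280),  # K-selected
                CloneSpec("c1C", r=1.50, K=1.45 * K, n_cells=120),  # concordant
            )
        else:
            clones = (
                CloneSpec(f"{name.lower()}a", r=r + 0.15, K=1.25 * K),
                CloneSpec(f"{name.lower()}b", r=r - 0.15, K=0.80 * K),
            )
        lines.append(CellLineSpec(name, GrowthParams(r=r, K=K, n0=n0), clones))
    return SyntheticScenario(cell_lines=lines, seed=seed)


def generate_growth_curve(
    params: GrowthParams,
    schedule,
    noise_cv: float,
    seed: int,
    model: str = "verhulst",
    population_id: str = "",
) -> GrowthCurve:
    """Noisy daily counts from a growth trajectory.

    Observation noise is multiplicative log-normal with coefficient of
    variation ``noise_cv`` and unit mean, so the expected count equals the
    model trajectory; ``noise_cv = 0`` returns the exact trajectory.
    Deterministic per seed.
    """
    if noise_cv < 0:
        raise InvalidParameterError("noise_cv must be >= 0")
    t = np.asarray(schedule, dtype=float)
    traj = model_solution(model, params, t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        traj = traj * rng.lognormal(-(sigma**2) / 2.0, sigma, size=len(t))
    return GrowthCurve(times=t, counts=traj, population_id=population_id)


def saturation_window(params: GrowthParams, lo: float = 6.0, hi: float = 21.0) -> int:
    """Observation duration (days): time to reach 98% of K, clipped to
    [lo, hi], emulating a run-until-plateau protocol."""
    b = max((params.K - params.n0) / params.n0, 1e-9)
    t98 = np.log(b * 0.98 / 0.02) / max(params.r, 1e-9)
    return int(np.clip(np.ceil(t98), lo, hi))


def generate_growth_curves(scenario: SyntheticScenario) -> dict[str, GrowthCurve]:
    """One noisy curve per cell line, sampled daily until plateau."""
    out = {}
    for i, line in enumerate(scenario.cell_lines):
        days = saturation_window(line.params, hi=scenario.sampling_days)
        out[line.name] = generate_growth_curve(
            line.params,
            np.arange(days + 1, dtype=float),
            scenario.count_noise_cv,
            seed=scenario.seed * 10_000 + i,
            population_id=line.name,
        )
    return out


def _nb_sample(rng, mean: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return np.round(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def generate_population(scenario: SyntheticScenario):
    """Generate the expression matrix, annotations and ground truth.

    Returns ``(adata, annotations, gene_sets, truth)`` where ``adata`` is an
    AnnData of cells x genes NB counts, ``annotations`` a DataFrame with
    columns cell_id / cell_line / clone_id / phase, ``gene_sets`` the GMT-able
    list of :class:`GeneSet`, and ``truth`` a dict holding per-line and
    per-clone generating parameters plus the driver set names.
    """
    rng = np.random.default_rng(scenario.seed)
    sets = scenario.gene_sets()
    set_names = [s.name for s in sets]
    for drv in (scenario.driver_r_set, scenario.driver_k_set):
        if drv not in set_names:
            raise InvalidParameterError(f"driver set {drv!r} not among generated sets")
    genes = [f"G{g:04d}" for g in range(scenario.n_genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    r_idx = [gene_pos[g] for g in sets[set_names.index(scenario.driver_r_set)].genes]
    k_idx = [gene_pos[g] for g in sets[set_names.index(scenario.driver_k_set)].genes]
    if set(r_idx) & set(k_idx):
        raise ConfoundedDesignError("driver gene sets overlap")

    clones = scenario.all_clones()
    r_vals = np.array([c.r for c in clones])
    k_vals = np.array([c.K for c in clones])
    r_lo, r_hi = r_vals.min(), r_vals.max()
    k_lo, k_hi = k_vals.min(), k_vals.max()

    blocks, rows = [], []
    log_fold = np.log(scenario.effect_fold)
    for line in scenario.cell_lines:
        for clone in line.clones:
            z_r = (clone.r - r_lo) / max(r_hi - r_lo, 1e-12)
            z_k = (clone.K - k_lo) / max(k_hi - k_lo, 1e-12)
            mu = np.full(scenario.n_genes, scenario.background_mean)
            mu[r_idx] *= np.exp(log_fold * z_r)
            mu[k_idx] *= np.exp(log_fold * z_k)
            n = clone.n_cells
            if scenario.nb_dispersion is None or scenario.library_sigma == 0:
                lib = np.ones(n)
            else:
                lib = rng.lognormal(0.0, scenario.library_sigma, size=n)
            cell_mu = lib[:, None] * mu[None, :]
            blocks.append(_nb_sample(rng, cell_mu, scenario.nb_dispersion))
            phases = rng.choice(PHASES, size=n, p=scenario.phase_probs)
            for j in range(n):
                rows.append(
                    {
                        "cell_id": f"{line.name}.{clone.clone_id}.{j:03d}",
                        "cell_line": line.name,
                        "clone_id": clone.clone_id,
                        "phase": phases[j],
                    }
                )

    annotations = pd.DataFrame(rows)
    X = np.vstack(blocks)
    adata = AnnData(
        X=X,
        obs=annotations.set_index("cell_id")[["cell_line", "clone_id", "phase"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    truth = {
        "driver_r_set": scenario.driver_r_set,
        "driver_k_set": scenario.driver_k_set,
        "cell_lines": {
            line.name: {"r": line.params.r, "K": line.params.K, "n0": line.params.n0}
            for line in scenario.cell_lines
        },
        "clones": {
            line.name: {c.clone_id: {"r": c.r, "K": c.K} for c in line.clones}
            for line in scenario.cell_lines
        },
    }
    return adata, annotations, sets, truth


def planted_tradeoff_pair(scenario: SyntheticScenario):
    """The (cell line, clone_x, clone_y) pair with opposing (r, K) ordering,
    or None if the scenario plants none."""
    for line in scenario.cell_lines:
        for i, a in enumerate(line.clones):
            for b in line.clones[i + 1:]:
                if (a.r - b.r) * (a.K - b.K) < 0:
                    return line.name, a.clone_id, b.clone_id
    return None
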