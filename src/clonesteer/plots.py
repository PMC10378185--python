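"""Small matplotlib helpers for fit diagnostics and steering figures."""

from __future__ import annotations

import numpy as np

from .growth_fitting import FitResult
from .growth_models import GrowthCurve, model_solution
from .passaging_sim import PassageOutcome


def _axis(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_growth_fit(curve: GrowthCurve, fit: FitResult, ax=None):
    """Observed counts with the fitted trajectory overlaid."""
    ax = _axis(ax)
    ax.plot(curve.times, curve.counts, "o", label="observed", color="0.3")
    if fit.converged and fit.params is not None:
        t = np.linspace(curve.times[0], curve.times[-1], 200)
        ax.plot(t, model_solution(fit.model, fit.params, t), "-",
                label=f"{fit.model} (adj R2={fit.adj_r_squared:.3f})")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("cell count")
    ax.set_title(curve.population_id)
    ax.legend()
    return ax


def plot_steering_heatmap(heatmap, ax=None):
    """Signed winner metric across (seeding density, splitting interval)."""
    ax = _axis(ax)
    vmax = np.nanmax(np.abs(heatmap.to_numpy()))
    im = ax.imshow(
        heatmap.to_numpy(), origin="lower", aspect="auto",
        cmap="RdBu", vmin=-vmax, vmax=vmax,
        extent=(0, heatmap.shape[1], 0, heatmap.shape[0]),
    )
    ax.set_xticks(np.arange(heatmap.shape[1]) + 0.5)
    ax.set_xticklabels([f"{d:.0f}" for d in heatmap.columns], rotation=90, fontsize=7)
    ax.set_yticks(np.arange(heatmap.shape[0]) + 0.5)
    ax.set_yticklabels([f"{i:g}" for i in heatmap.index], fontsize=7)
    ax.set_xlabel("seeding density (cells/cm$^2$)")
    ax.set_ylabel("splitting interval (days)")
    ax.figure.colorbar(im, ax=ax, label="sgn(K-r) log10 winner size")
    return ax


def plot_frequency_trajectories(outcome: PassageOutcome, ax=None):
    """Clone frequencies across passages under one schedule."""
    ax = _axis(ax)
    freq = outcome.frequencies
    for j, cid in enumerate(outcome.clone_ids):
        ax.plot(range(freq.shape[0]), freq[:, j], marker="o", label=cid)
    ax.set_xlabel("passage")
    ax.set_ylabel("clone frequency")
    ax.set_yscale("log")
    ax.legend()
    return ax
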