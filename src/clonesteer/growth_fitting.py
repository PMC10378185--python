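"""Nonlinear least-squares fitting of growth models to cell-count series.

Fits the Verhulst, Richards and Gompertz laws to a :class:`GrowthCurve` by
minimizing the residual sum of squares between observed counts and the exact
model trajectory, with multi-start initialization (logistic fits are sensitive
to starting values).  The error model is i.i.d. Gaussian noise on counts, so
the log-likelihood, AIC and likelihood profiles all derive from the RSS.

Also implements:

* model ranking by AIC (ties broken toward fewer parameters),
* practical-identifiability assessment by likelihood profiling — a parameter
  is identifiable when the 95% profile confidence region is bounded within the
  searched grid,
* the experiment stopping rule: stop once the inferred carrying capacity is
  stable (fold change < 4%) under truncation of any tail portion of the last
  20% of time points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2

from .errors import InvalidParameterError
from .growth_models import MODELS, GrowthCurve, GrowthParams, model_solution

#: Minimum number of observations required for a fit.
MIN_OBSERVATIONS = 5

#: Guard for log(RSS) when a fit is exact; AIC/log-likelihood use
#: max(RSS, RSS_FLOOR) so a perfect fit yields a very negative, finite AIC.
RSS_FLOOR = 1e-24

_FREE_PARAMS = {
    "verhulst": ("r", "K", "n0"),
    "richards": ("r", "K", "n0", "v"),
    "gompertz": ("r", "K", "n0"),
}


@dataclass
class FitResult:
    """Outcome of fitting one growth model to one curve."""

    model: str
    params: GrowthParams | None
    rss: float = np.nan
    r_squared: float = np.nan
    adj_r_squared: float = np.nan
    loglik: float = np.nan
    aic: float = np.nan
    n_obs: int = 0
    n_params: int = 0
    converged: bool = False
    degenerate: bool = False
    message: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.params is not None:
            d["params"] = dataclasses.asdict(self.params)
        return d


@dataclass
class ProfileResult:
    """Profile likelihood of one parameter over a grid of fixed values."""

    param_name: str
    grid: np.ndarray
    loglik: np.ndarray
    estimate: float
    max_loglik: float
    ci_low: float
    ci_high: float
    lower_bounded: bool
    upper_bounded: bool
    identifiable: bool
    confidence: float = 0.95


@dataclass
class StoppingDecision:
    """Result of the carrying-capacity stability stopping rule."""

    stop: bool
    max_fold_change: float
    k_full: float
    k_truncated: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.stop


def adjusted_r2(r_squared: float, n: int, k: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1)."""
    if n <= k + 1:
        raise InvalidParameterError(f"need n > k + 1 (got n={n}, k={k})")
    return 1.0 - (1.0 - r_squared) * (n - 1) / (n - k - 1)


def aic_value(rss: float, n_obs: int, n_growth_params: int) -> float:
    """Gaussian-error AIC, ``n ln(RSS/n) + 2k`` with k counting the growth
    parameters plus the noise variance.  RSS is floored at :data:`RSS_FLOOR`."""
    k = n_growth_params + 1
    return n_obs * np.log(max(rss, RSS_FLOOR) / n_obs) + 2 * k


def _gaussian_loglik(rss: float, n: int) -> float:
    sigma2 = max(rss, RSS_FLOOR) / n
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def _initial_r(times: np.ndarray, counts: np.ndarray) -> float:
    """Heuristic growth rate from a log-linear fit of the early points."""
    m = max(3, len(times) // 3)
    t, y = times[:m], np.maximum(counts[:m], 1e-12)
    slope = np.polyfit(t, np.log(y), 1)[0]
    return float(np.clip(slope, 0.05, 5.0))


def _start_grid(times, counts, model, init: GrowthParams | None):
    ymax = counts.max()
    r0 = _initial_r(times, counts)
    n00 = max(counts[0], 1e-6 * ymax)
    starts = []
    if init is not None:
        starts.append((init.r, init.K, init.n0, init.v))
    v_grid = (0.5, 1.0, 2.0) if model == "richards" else (1.0,)
    for kmul in (1.0, 2.0, 5.0):
        for v0 in v_grid:
            starts.append((r0, kmul * ymax, n00, v0))
    return starts


def _bounds(counts, model):
    ymax = counts.max()
    lo = {"r": 1e-6, "K": 0.2 * ymax, "n0": 1e-6 * ymax, "v": 1e-2}
    hi = {"r": 50.0, "K": 1e6 * ymax, "n0": 2.0 * ymax, "v": 1e2}
    names = _FREE_PARAMS[model]
    return (
        np.log([lo[p] for p in names]),
        np.log([hi[p] for p in names]),
        names,
    )


def _theta_to_params(theta, names, fixed: dict | None = None) -> GrowthParams:
    d = {"v": 1.0}
    d.update(fixed or {})
    for name, val in zip(names, theta):
        d[name] = float(np.exp(val))
    return GrowthParams(r=d["r"], K=d["K"], n0=d["n0"], v=d["v"])


def _minimize(times, counts, model, starts, names, lo, hi, fixed=None):
    """Run least squares from each start; return (best_theta, best_rss)."""
    best = (None, np.inf)
    for start in starts:
        full = dict(zip(("r", "K", "n0", "v"), start))
        theta0 = np.log([full[p] for p in names])
        theta0 = np.clip(theta0, lo, hi)

        def resid(theta):
            params = _theta_to_params(theta, names, fixed)
            with np.errstate(over="ignore", invalid="ignore"):
                pred = model_solution(model, params, times)
            pred = np.where(np.isfinite(pred), pred, 1e12)
            return pred - counts

        try:
            res = least_squares(resid, theta0, bounds=(lo, hi), max_nfev=2000)
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        rss = float(2.0 * res.cost)
        if np.isfinite(rss) and rss < best[1]:
            best = (res.x, rss)
    return best


def fit_growth_model(
    curve: GrowthCurve,
    model: str = "verhulst",
    init: GrowthParams | None = None,
) -> FitResult:
    """Fit one growth model to a cell-count curve by multi-start least squares.

    Non-convergence from every start yields a ``FitResult`` with
    ``converged=False``, never an exception.  A curve whose counts carry no
    variance (flat data) produces a fit flagged ``degenerate``.
    """
    if model not in MODELS:
        raise InvalidParameterError(f"unknown model {model!r}; choose from {MODELS}")
    times, counts = curve.times, curve.counts
    n = len(times)
    if n < MIN_OBSERVATIONS:
        raise InvalidParameterError(f"need >= {MIN_OBSERVATIONS} observations, got {n}")
    if np.any(counts <= 0):
        raise InvalidParameterError("counts must be > 0 for fitting")

    lo, hi, names = _bounds(counts, model)
    starts = _start_grid(times, counts, model, init)
    theta, rss = _minimize(times, counts, model, starts, names, lo, hi)
    if theta is None:
        return FitResult(model=model, params=None, n_obs=n, message="no start converged")

    params = _theta_to_params(theta, names)
    k = len(names)
    tss = float(np.sum((counts - counts.mean()) ** 2))
    degenerate = tss == 0.0
    r2 = np.nan if degenerate else 1.0 - rss / tss
    adj = np.nan if degenerate else adjusted_r2(r2, n, k)
    return FitResult(
        model=model,
        params=params,
        rss=rss,
        r_squared=r2,
        adj_r_squared=adj,
        loglik=_gaussian_loglik(rss, n),
        aic=aic_value(rss, n, k),
        n_obs=n,
        n_params=k,
        converged=True,
        degenerate=degenerate,
        message="zero total sum of squares" if degenerate else "",
    )


def rank_models(fits: list[FitResult]) -> list[FitResult]:
    """Order fits of the same curve by AIC (lower first); ties go to the
    model with fewer parameters."""
    ok = [f for f in fits if f.converged]
    return sorted(ok, key=lambda f: (f.aic, f.n_params, f.model))


def profile_likelihood(
    curve: GrowthCurve,
    model: str,
    param_name: str,
    grid=None,
    n_grid: int = 41,
    confidence: float = 0.95,
    full_fit: FitResult | None = None,
) -> ProfileResult:
    """Profile the likelihood of one parameter of a fitted growth model.

    For each grid value the remaining parameters are re-optimized.  The
    confidence region is the contiguous grid stretch around the maximum where
    the profile log-likelihood stays within chi2(1, confidence)/2 (~1.92 for
    95%) of its peak; the parameter is practically identifiable when that
    region is bounded strictly inside the searched grid.

    Default grids span [estimate/100, estimate*100]: log-spaced for ``K``,
    ``n0`` and ``v``, linear for ``r``.
    """
    if full_fit is None:
        full_fit = fit_growth_model(curve, model)
    if not full_fit.converged or full_fit.params is None:
        raise InvalidParameterError("profiling requires a successful full fit")
    names = _FREE_PARAMS[model]
    if param_name not in names:
        raise InvalidParameterError(f"{param_name!r} is not a free parameter of {model}")
    est = float(getattr(full_fit.params, param_name))

    if grid is None:
        if param_name == "r":
            grid = np.linspace(est / 100.0, est * 100.0, n_grid)
        else:
            grid = np.geomspace(est / 100.0, est * 100.0, n_grid)
    grid = np.unique(np.concatenate([np.asarray(grid, dtype=float), [est]]))

    times, counts = curve.times, curve.counts
    n = len(times)
    free = tuple(p for p in names if p != param_name)
    lo_all, hi_all, _ = _bounds(counts, model)
    idx = [names.index(p) for p in free]
    lo, hi = lo_all[idx], hi_all[idx]

    p_full = full_fit.params
    start_full = (p_full.r, p_full.K, p_full.n0, p_full.v)
    heuristic = _start_grid(times, counts, model, None)[1]

    loglik = np.empty(len(grid))
    for i, g in enumerate(grid):
        fixed = {param_name: float(g)}
        _, rss = _minimize(
            times, counts, model, [start_full, heuristic], free, lo, hi, fixed=fixed
        )
        loglik[i] = _gaussian_loglik(rss, n) if np.isfinite(rss) else -np.inf

    imax = int(np.argmax(loglik))
    delta = chi2.ppf(confidence, df=1) / 2.0
    above = loglik >= loglik[imax] - delta - 1e-9
    j_lo = imax
    while j_lo > 0 and above[j_lo - 1]:
        j_lo -= 1
    j_hi = imax
    while j_hi < len(grid) - 1 and above[j_hi + 1]:
        j_hi += 1
    lower_bounded = j_lo > 0
    upper_bounded = j_hi < len(grid) - 1
    return ProfileResult(
        param_name=param_name,
        grid=grid,
        loglik=loglik,
        estimate=est,
        max_loglik=float(loglik[imax]),
        ci_low=float(grid[j_lo]) if lower_bounded else -np.inf,
        ci_high=float(grid[j_hi]) if upper_bounded else np.inf,
        lower_bounded=lower_bounded,
        upper_bounded=upper_bounded,
        identifiable=lower_bounded and upper_bounded,
        confidence=confidence,
    )


def stopping_criterion(
    curve: GrowthCurve,
    tail_fraction: float = 0.2,
    threshold: float = 0.04,
    model: str = "verhulst",
) -> StoppingDecision:
    """Decide whether the growth experiment can stop.

    Refits the curve with each contiguous truncation of the last
    ``tail_fraction`` of time points removed (drop last 1, 2, ..., m points)
    and stops when the fold change of the inferred carrying capacity relative
    to the full fit stays below ``threshold`` (default 4%) for every
    truncation.  Any failed truncated fit vetoes stopping.
    """
    n = len(curve)
    m = max(1, int(np.floor(tail_fraction * n)))
    if n - m < MIN_OBSERVATIONS:
        raise InvalidParameterError(
            f"curve too short: dropping {m} of {n} points leaves < {MIN_OBSERVATIONS}"
        )
    full = fit_growth_model(curve, model)
    if not full.converged or full.params is None:
        return StoppingDecision(stop=False, max_fold_change=np.inf, k_full=np.nan)
    k_full = full.params.K
    k_trunc: list[float] = []
    worst = 0.0
    for j in range(1, m + 1):
        sub = GrowthCurve(
            times=curve.times[:-j],
            counts=curve.counts[:-j],
            population_id=curve.population_id,
        )
        fit = fit_growth_model(sub, model, init=full.params)
        if not fit.converged or fit.params is None:
            return StoppingDecision(
                stop=False, max_fold_change=np.inf, k_full=k_full, k_truncated=k_trunc
            )
        k_trunc.append(fit.params.K)
        worst = max(worst, abs(fit.params.K - k_full) / k_full)
    return StoppingDecision(
        stop=worst < threshold,
        max_fold_change=worst,
        k_full=k_full,
        k_truncated=k_trunc,
    )
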