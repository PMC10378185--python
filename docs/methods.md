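# Methods

This note documents the models, numerical choices and design decisions
behind `clonesteer`, and what the synthetic cohorts used by the test suite
do and do not emulate.

## Growth laws and fitting

Single populations follow the generalized logistic (Richards) family
`dN/dt = r N (1 - (N/K)^v)` with maximum per-capita growth rate `r` (1/day),
carrying capacity `K` (cells) and loss-of-contact-inhibition exponent `v`
(dimensionless; `v = 1` gives the Verhulst logistic). The Gompertz law is
taken in its standard (r, K)-parameterized form `dN/dt = r N ln(K/N)`, so
all three models share the same parameter interpretation. All three have
exact closed-form trajectories, which are what the fitter evaluates —
numerical integration is used only for the multi-clone system. The Richards
closed form is evaluated in log space so likelihood profiling can visit
extreme `v` or `K/N0` without overflow.

Internally all state is absolute cell count; densities in cells/cm² are
converted at the I/O boundary with a configurable culture surface (default
25 cm², a T25 flask).

Fitting minimizes the residual sum of squares between observed counts and
the model trajectory, i.e. an i.i.d. Gaussian error model on counts. This is
the conventional least-squares contract for growth-curve packages and makes
the log-likelihood, AIC and profiles simple functions of the RSS; no
count-dependent variance model is attempted. Parameters are optimized in log
space (enforcing positivity) with `scipy.optimize.least_squares` under
generous bounds, from a multi-start grid: `K0 ∈ {1, 2, 5}·max(count)`, `r0`
from a log-linear fit of the early points, `N0₀` = first count, and for
Richards `v0 ∈ {0.5, 1, 2}`. The best RSS over starts wins; failure of every
start yields a flagged non-converged result rather than an exception.

AIC is the Gaussian form `n·ln(RSS/n) + 2k` with `k` counting growth
parameters plus the noise variance (4 for Verhulst/Gompertz, 5 for
Richards). RSS is floored at 1e-24 so a numerically perfect fit produces a
very negative but finite AIC. Ties in model ranking go to the model with
fewer parameters.

### Identifiability by likelihood profiling

For one parameter at a time, the profile re-optimizes all remaining
parameters over a grid of fixed values (41 points spanning
[estimate/100, estimate·100]; log-spaced for `K`, `n0`, `v`, linear for
`r`; the point estimate is always inserted into the grid). The 95%
confidence region is the contiguous grid stretch around the maximum within
χ²(1, 0.95)/2 ≈ 1.92 log-likelihood units of the peak; the parameter counts
as practically identifiable when that region is bounded strictly inside the
searched grid. Note the reported CI endpoints are grid points: with the
default coarse grid they locate non-identifiability reliably, but a fine
local grid should be passed when the CI width itself is of interest.

### Stopping rule

The experiment-ending rule refits the curve with the last 1, 2, …, m points
removed, where m is 20% of the series (contiguous tail truncations — the
intent of the rule is stability of K̂ as the experiment ends, so the
exponential power set of tail subsets is not enumerated), and stops when
every truncated K̂ is within 4% of the full-fit K̂. Any failed truncated fit
vetoes stopping.

## Multi-clone competition and passaging

Clones of one line share a capacity constraint:

    dN_i/dt = N_i r_i (1 - (Σ_j N_j/K_j)^v),   v shared, default 1.

The system is integrated with scipy's adaptive Dormand–Prince RK45 at
rtol 1e-8 / atol 1e-6. Seeded below the capacity surface
(Σ N_i(0)/K_i < 1), every clone's derivative remains nonnegative; the test
suite verifies this numerically in per-capita form — the trajectory
occupancy Σ N_i/K_i never overshoots 1 by more than 1e-9 (checked at
rtol 1e-11, measured overshoot ~1e-11). An absolute bound of 1e-9 cells/day
would demand occupancy accuracy near 1e-16, below float resolution at
realistic counts, which is why the invariant is stated per capita.

A consequence worth making explicit: because the occupancy factor is common
to all clones, per-capita growth is `r_i (1 - occ)` and the fastest clone
gains frequency whenever the culture grows at all. "K selection" in this
model therefore means *slowing the sweep*: a schedule that keeps the culture
near confluence (dense seeding, short intervals) freezes composition and
preserves an initially dominant K-selected clone, while sparse seeding with
long intervals maximizes doublings per passage and lets the r-selected clone
take over quickly.

Serial passaging integrates the system for the splitting interval, harvests,
and reseeds `density × area` cells at the harvest frequencies (deterministic
dilution — no stochastic bottleneck sampling, so rare-clone extinction by
drift is not modeled). Clone sizes are never truncated at an extinction
floor; arbitrarily small frequencies are propagated exactly. The steering
heatmap reports, per (density, interval) schedule, the signed winner metric
`sgn(CloneK − Cloner)·log10(max(Cloner, CloneK))` on the focal pair at the
final harvest, with any additional clones retained in the system during
simulation. Two caveats follow from keeping the formula exact: (i) schedules
seeding at or above the capacity surface are reported as missing values, and
(ii) if a third clone sweeps the system so hard that both focal clones fall
below one "cell", log10 of the winner turns negative and the sign convention
inverts; consumers should read |entry| < 0 magnitudes with that in mind.

The pipeline seeds its passaging simulations from the observed clonal
composition (cells per clone), since harvest frequencies set the next
seeding in the experimental protocol being emulated. Its two narrative
schedules are "sparse/long" (the low end of the experimental seeding range,
7-day splits) and "dense/short" (daily reseeding at 95% of the focal
system's capacity surface). The dense schedule is defined through occupancy
rather than a fixed density because inferred clone capacities can sit an
order of magnitude above the experimental seeding range, where no in-range
density approaches confluence.

## Pathway activity (rank-AUC)

For each cell, genes are ranked by decreasing expression; ties are broken by
a random permutation drawn once per cell from a fixed-seed generator
(default seed 42), making results deterministic while leaving tie handling
unbiased. With G genes and threshold T = ⌈0.05·G⌉ ("top 5% of the ranking"),
the recovery curve counts gene-set members among the top x ranks for
x = 1…T; the score is its area divided by the area of the ideal curve for
the same set size, so scores lie in [0, 1] exactly and a perfectly
top-ranked set scores 1. The 5% threshold is taken over all genes in the
matrix (not per-cell detected genes); this is configurable. Cells with fewer
than 200 detected features are removed first. All cell lines are scored
jointly in one matrix with no further batch correction.

## Biomarkers, validation, trade-offs

Biomarker candidates are simple OLS fits (`scipy.stats.linregress`) of a
cell line's fitted growth parameter on its median pathway activity within
one cell-cycle grouping; adjusted R² uses k = 1 predictor. Gene sets with
zero activity variance are flagged degenerate and excluded from ranking.
Candidates are ranked within each (target, grouping) family — descending
adjusted R², ties to smaller p then name — and the top five per family go to
validation. Validation refits each candidate on the full cohort and applies
Benjamini–Hochberg FDR (`statsmodels.multipletests`) per target parameter
across the tested models (the narrowest defensible family); confirmed means
adjusted p < 0.05. The training/validation split is a configuration input
(default: first five lines train, remaining three validate). When no
candidate is confirmed for a target, the pipeline falls back to the best
validated model and records the situation rather than stopping.

Per-cell predictions use only cells in the phase grouping of the chosen
biomarker ("all" uses every cell); clones with fewer than two usable cells
are excluded. Trade-off testing uses the classic equal-variance two-sample
Student's t-test (two-sided; Welch is available as an option), α = 0.1 on
both parameters, and the opposing-ratio rule on arithmetic clone means. All
unordered clone pairs of a line are tested once, with no multiple-testing
correction across pairs — two independent tests at α plus an opposing
direction requirement already hold the null flag rate near α²/2.

## Synthetic cohorts

The generator produces the three pipeline inputs with known ground truth.

*Growth curves*: daily counts from the chosen law with multiplicative
log-normal noise of a given CV (default 5%) and unit mean. The observation
window runs until the trajectory reaches 98% of K, clipped to [6, 21] days,
emulating a grow-until-plateau protocol. Default parameter ranges mirror the
target in-vitro regime: seeding densities 4.98–38.64·10³ cells/cm²,
capacities 1.92–15.32·10⁵ cells/cm² on 25 cm². Growth rates default to
0.4–1.3/day, the range consistent with reaching confluence inside that
window at those density ratios.

*Expression*: negative-binomial counts (dispersion θ = 2, the standard
single-cell count emulation; per-cell library factors log-normal with
σ = 0.15) over 2000 genes, with 25 disjoint 20-gene sets. One set drives r
and one drives K: driver-gene means scale as `fold^z` with fold = 4 and z
the clone's parameter normalized to [0, 1] across the cohort, making
rank-AUC activity monotone (approximately linear) in the true parameter.
Setting the dispersion to `None` disables sampling noise for noise-free
checks. Phase labels are multinomial with default proportions
(0.6, 0.2, 0.2).

*Default cohort*: eight cell lines whose (r, K) pairing is nearly
uncorrelated across lines (Pearson ≈ 0.1), as in cohorts where the two
traits vary independently. Line CL1 carries the planted r/K trade-off
(c1A fast/low-K vs c1B slow/high-K, with the K-clone most abundant so
steering has something to preserve) plus a third clone dominating both —
concordant pairs can never satisfy the opposing-ratio rule, so exactly one
trade-off exists by construction. CL1's median clone growth rate equals the
line-level rate so the line's median activity stays on the cohort-level
linear trend. Everything is deterministic given the scenario seed; changing
the seed changes noise realizations only.

What the generator does **not** emulate: real copy-number-driven expression
programs (driver sets are disjoint and background genes are i.i.d., so there
is no gene–gene correlation structure or compositional ambient RNA),
cell-cycle-dependent expression (phases are labels only), doublets, batch
effects, or stochastic clone dynamics. Passing tests therefore demonstrate
that the statistical machinery recovers planted structure under the stated
noise model — not that biomarkers discovered on real data are causal.

## Problem sizes used in tests

The test suite and the reproduction script use 200 fit replicates for the
fit-quality property, 50 replicates per generator for model selection, 50
seeds (20 in the script) for end-to-end recovery on the default cohort
(~3,400 cells × 2,000 genes each), and 100 random clone systems for the
nonnegativity invariant. These sizes put the binomial uncertainty of the
measured rates well below the margins being asserted while keeping a full
run in the minutes range on one CPU.

## Known limitations

- The Gaussian/RSS likelihood treats all counts as equally noisy;
  multiplicative observation noise makes plateau residuals larger, which
  mildly overweights the plateau in fits (the recovery-bias test bounds the
  practical effect at <2%).
- Profile CI endpoints are grid points; widths are grid-resolution limited.
- The shared-capacity model has no clone-specific density response beyond
  (r_i, K_i) — v is shared — and no death, migration or nutrient terms.
- Deterministic dilution ignores sampling noise at splitting, so predicted
  sub-cell frequencies (e.g. 10⁻³⁰) mean "extinct in any real culture".
- Biomarker models are univariate; correlated pathways can substitute for
  one another, and confirmation on eight lines cannot distinguish a causal
  pathway from a correlated passenger.
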