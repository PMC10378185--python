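"""Run the whole analysis end to end on a synthetic cohort.

Generates growth curves and a clone-structured expression matrix for 8 cell
lines, then runs fit -> score -> biomarkers -> trade-off scan -> passaging
simulation in one call and prints the summary.
"""

import warnings

from clonesteer import (
    AnalysisSettings,
    default_scenario,
    generate_growth_curves,
    generate_population,
    run_analysis,
)

scenario = default_scenario(seed=3)
curves = generate_growth_curves(scenario)
adata, annotations, gene_sets, truth = generate_population(scenario)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_analysis(curves, adata, annotations, gene_sets, AnalysisSettings())

print("growth fits (per cell line):")
for name, fit in report["growth_fits"].items():
    print(f"  {name}: r={fit['r']:.2f}/day K={fit['K']:.2e} adjR2={fit['adj_r_squared']:.3f}")

print(f"\nconfirmed biomarkers: {report['confirmed_biomarkers']}")
print(f"flagged trade-off pairs: {report['flagged_pairs']}")
print(f"planted trade-off: CL1 c1A (r-selected) vs c1B (K-selected)")

steering = report["steering"]
print(
    f"\nsteering for {steering['cell_line']} "
    f"({steering['r_clone']} vs {steering['k_clone']}):"
)
print(f"  heatmap metric range: [{steering['metric_min']:.2f}, {steering['metric_max']:.2f}]")
print(f"  r-clone overtakes at passage: {steering['crossing_passage']}")
print(
    "\nsparse_long seeds at the low end of the experimental density range with"
    "\n7-day splits (r-clone sweeps early); dense_short reseeds daily at 95%"
    "\noccupancy, delaying the takeover by many passages."
)
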