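"""The full prognostic pipeline: selection, budding grade, survival report.

Runs repeated-CV stability selection on a synthetic cohort with planted
effects, fits the selected-feature Cox model, splits its linear predictor
into low/high budding grades, compares their survival and runs the final
stepwise multivariable model against the clinicopathological covariates.
"""

import warnings

from morphome import SimulationConfig, run_matrix_pipeline, simulate_cohort

warnings.simplefilter("ignore")

cohort = simulate_cohort(SimulationConfig(), seed=5, expand_cells=False)
res = run_matrix_pipeline(cohort.features, cohort.clinical, seed=5, R=10, V=10)

print("stability-selected features (frequency > 0.8 over 10 repeats):")
freq = res.stability.selection_frequency
print(freq[freq > 0].sort_values(ascending=False).round(2).to_string())
print("\nselected-feature Cox model (hazard ratios):")
print(res.selected_fit.summary().round(3).to_string())

print("\nbudding-grade survival:")
print(res.grade_report.table.round(1).to_string())
print(f"log-rank chi2 = {res.grade_report.chi2:.1f}, p = {res.grade_report.p:.2e}")

print("\nstepwise multivariable model retained:", ", ".join(res.stepwise.retained_blocks))
if res.stepwise.fit is not None:
    print(res.stepwise.fit.summary().round(3).to_string())
# A high budding grade marks the half of the cohort whose morphome-based
# risk score is elevated; its shorter median OS and the retained
# budding_grade block in the stepwise model mirror the prognostic claim.
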