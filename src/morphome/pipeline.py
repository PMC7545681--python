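"""End-to-end morphome analysis: census -> features -> selection -> grade.

One call chains the whole analysis on a cells table plus clinical data, the
way the individual modules would be used by hand, and returns every
intermediate product.  The pipeline is deterministic given the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import CensusSummary, build_cluster_census, summarize_census
from .features import build_morphome_matrix
from .grading import (
    GradeSurvivalReport,
    StepwiseResult,
    assign_budding_grade,
    build_clinical_design,
    fit_selected_cox,
    grade_survival_report,
    linear_predictor,
    stepwise_cox,
)
from .stability import StabilityReport, stability_select
from .survival import CoxFit


@dataclass
class PipelineResult:
    census: pd.DataFrame
    census_summary: CensusSummary
    features: pd.DataFrame
    stability: StabilityReport
    selected_fit: CoxFit
    grades: pd.DataFrame
    grade_report: GradeSurvivalReport
    stepwise: StepwiseResult | None
    stepwise_subgroup: StepwiseResult | None


def run_pipeline(
    cells: pd.DataFrame,
    clinical: pd.DataFrame,
    seed: int,
    R: int = 10,
    V: int = 10,
    alpha: float = 1.0,
    threshold: float = 0.8,
    max_cluster_size: int = 50,
    n_lambda: int = 100,
    run_stepwise: bool = True,
    subgroup: tuple[str, str] | None = ("location", "PDAC"),
) -> PipelineResult:
    """Run the full analysis on a per-cell table and a clinical table.

    ``clinical`` must carry ``patient_id``, the clinicopathological
    covariates, ``time_months`` and ``event``.  The subgroup stepwise model
    (default: PDAC-only) reuses the grade labels fitted on the full cohort.
    """
    census, _ = build_cluster_census(cells, max_size=max_cluster_size)
    return run_matrix_pipeline(
        build_morphome_matrix(
            census, patients=clinical["patient_id"].astype(str).tolist()
        ),
        clinical, seed, R=R, V=V, alpha=alpha, threshold=threshold,
        n_lambda=n_lambda, run_stepwise=run_stepwise, subgroup=subgroup,
        census=census,
    )


def run_matrix_pipeline(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    seed: int,
    R: int = 10,
    V: int = 10,
    alpha: float = 1.0,
    threshold: float = 0.8,
    n_lambda: int = 100,
    run_stepwise: bool = True,
    subgroup: tuple[str, str] | None = ("location", "PDAC"),
    census: pd.DataFrame | None = None,
) -> PipelineResult:
    """Pipeline from a prebuilt morphome matrix (see :func:`run_pipeline`)."""
    clinical = clinical.reset_index(drop=True)
    features = features.loc[clinical["patient_id"].astype(str)]
    time = clinical["time_months"].to_numpy(float)
    event = clinical["event"].to_numpy(bool)

    stability = stability_select(
        features, time, event, R=R, V=V, alpha=alpha,
        threshold=threshold, seed=seed, n_lambda=n_lambda,
    )
    fit = fit_selected_cox(features, time, event, selected=stability.selected)
    grades = assign_budding_grade(linear_predictor(fit, features))
    report = grade_survival_report(grades, time, event)

    step = step_sub = None
    if run_stepwise:
        design, blocks = build_clinical_design(clinical, grades)
        step = stepwise_cox(design, blocks, time, event)
        if subgroup is not None:
            var, level = subgroup
            mask = (clinical[var].astype(str) == level).to_numpy()
            if mask.sum() >= 10 and event[mask].sum() >= 2:
                sub_design, sub_blocks = build_clinical_design(
                    clinical[mask].reset_index(drop=True),
                    grades[mask].reset_index(drop=True),
                )
                sub_blocks.pop(var, None)  # constant within the subgroup
                step_sub = stepwise_cox(
                    sub_design, sub_blocks, time[mask], event[mask]
                )
    summary = summarize_census(census) if census is not None and len(census) else None
    return PipelineResult(
        census=census if census is not None else pd.DataFrame(),
        census_summary=summary,
        features=features,
        stability=stability,
        selected_fit=fit,
        grades=grades,
        grade_report=report,
        stepwise=step,
        stepwise_subgroup=step_sub,
    )
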