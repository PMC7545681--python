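"""From selected morphome features to a dichotomous budding grade.

The stability-selected features are fitted in an ordinary multivariable Cox
model; each patient's linear predictor (log relative hazard) from that model
is split at the median into two equally sized groups, the *low* and *high*
budding grade.  The grade then competes with the standard clinicopathological
covariates in a stepwise multivariable Cox model, and the two grade groups
are compared by Kaplan-Meier medians and the log-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, FormatError
from .survival import (
    CoxFit,
    KMEstimate,
    cox_fit,
    cox_loglik,
    kaplan_meier,
    logrank_test,
)

#: Closed category sets of the clinical table, with the reference level first.
CLINICAL_LEVELS = {
    "sex": ("female", "male"),
    "pN": ("N0", "N+"),
    "M": ("M0", "M+"),
    "lymphovascular": ("absent", "present"),
    "vascular": ("absent", "present"),
    "perineural": ("absent", "present"),
    "margin": ("R0", "R+"),
    "location": ("PDAC", "DBDAC", "AMPAC", "DUOAC"),
    "histology": ("PB", "MIX", "INT", "UNDIFF", "OTH"),
}
CLINICAL_COLUMNS = (
    "patient_id", "age", "sex", "pT", "pN", "M", "grade",
    "lymphovascular", "vascular", "perineural", "margin",
    "location", "histology",
)


def read_clinical(path) -> pd.DataFrame:
    """Read the tab-separated clinical table (plus time_months / event)."""
    clin = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS + ("time_months", "event") if c not in clin.columns]
    if missing:
        raise FormatError(f"clinical file {path} is missing column(s) {missing}")
    for var, levels in CLINICAL_LEVELS.items():
        bad = set(clin[var].astype(str).unique()) - set(levels)
        if bad:
            raise FormatError(f"column {var}: unknown level(s) {sorted(bad)}")
    return clin


def fit_selected_cox(X, time, event, selected=None, ties: str = "breslow") -> CoxFit:
    """Multivariable Cox model on exactly the selected feature columns."""
    if selected is not None:
        if len(selected) == 0:
            raise FitError(
                "no features were selected — review the stability threshold"
            )
        X = X[list(selected)]
    elif hasattr(X, "shape") and X.shape[1] == 0:
        raise FitError("no features were selected — review the stability threshold")
    names = list(X.columns) if hasattr(X, "columns") else None
    return cox_fit(np.asarray(X, float), time, event, ties=ties, feature_names=names)


def linear_predictor(fit: CoxFit, X) -> pd.Series:
    """Per-patient risk score eta = x . beta_hat on the fitted features."""
    if fit.feature_names:
        X = X[fit.feature_names]
    eta = np.asarray(X, float) @ fit.coefficients
    index = X.index if hasattr(X, "index") else pd.RangeIndex(len(eta))
    return pd.Series(eta, index=index, name="linear_predictor")


def assign_budding_grade(eta: pd.Series) -> pd.DataFrame:
    """Median-split the linear predictor into low / high budding grade.

    Patients are ranked by eta ascending with ties broken by patient id
    (lexicographic); the first ceil(n/2) patients are *low*, the rest
    *high*, so with odd n the low group holds the extra patient.  The split
    depends only on ranks, hence is invariant to any strictly increasing
    transform of eta.
    """
    if len(eta) < 2:
        raise ValueError("need at least 2 patients to form two grade groups")
    df = pd.DataFrame(
        {"patient_id": eta.index.astype(str), "linear_predictor": eta.values}
    )
    df = df.sort_values(["linear_predictor", "patient_id"], kind="stable")
    n_low = math.ceil(len(df) / 2)
    df["grade"] = ["low"] * n_low + ["high"] * (len(df) - n_low)
    out = df.set_index("patient_id").loc[eta.index.astype(str)]
    out.index.name = "patient_id"
    return out.reset_index()


# ---------------------------------------------------------------------------
# clinical design encoding
# ---------------------------------------------------------------------------

def build_clinical_design(
    clinical: pd.DataFrame, grades: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-code the clinical table against its reference levels.

    Multi-level factors (tumor location vs PDAC, histologic subtype vs PB)
    become dummy blocks that stepwise selection moves in and out as a unit;
    pT stage and histologic grade enter as ordinal scores.  When a grade
    table is supplied, a ``budding_high`` indicator block is added.

    Returns the design matrix (indexed by patient) and a mapping
    block name -> design columns.
    """
    idx = pd.Index(clinical["patient_id"].astype(str), name="patient_id")
    design = pd.DataFrame(index=idx)
    blocks: dict[str, list[str]] = {}

    design["age"] = clinical["age"].to_numpy(float)
    blocks["age"] = ["age"]
    design["pT"] = clinical["pT"].to_numpy(float)
    blocks["pT"] = ["pT"]
    design["histologic_grade"] = clinical["grade"].to_numpy(float)
    blocks["histologic_grade"] = ["histologic_grade"]
    for var, levels in CLINICAL_LEVELS.items():
        vals = clinical[var].astype(str).to_numpy()
        cols = []
        for lev in levels[1:]:
            col = f"{var}_{lev}".replace("+", "pos")
            design[col] = (vals == lev).astype(float)
            cols.append(col)
        blocks[var] = cols
    if grades is not None:
        g = grades.set_index(grades["patient_id"].astype(str))["grade"]
        design["budding_high"] = (g.reindex(idx) == "high").astype(float)
        blocks["budding_grade"] = ["budding_high"]
    return design, blocks


# ---------------------------------------------------------------------------
# stepwise multivariable Cox
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    """Final stepwise model with its move log."""

    fit: CoxFit | None  # None when the empty model wins
    retained_blocks: list[str]
    columns: list[str]
    criterion: str
    criterion_value: float
    move_log: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        if self.fit is None:
            return pd.DataFrame()
        return self.fit.summary()


def _model_aic(design, cols, time, event, ties):
    if not cols:
        n = len(time)
        ll0 = cox_loglik(np.zeros(0), np.empty((n, 0)), time, event, ties)
        return -2.0 * ll0, None
    fit = cox_fit(design[cols].to_numpy(float), time, event,
                  ties=ties, feature_names=cols)
    if not fit.converged:
        raise FitError("non-converged candidate model")
    return -2.0 * fit.log_partial_likelihood + 2 * len(cols), fit


def stepwise_cox(
    design: pd.DataFrame,
    blocks: dict[str, list[str]],
    time,
    event,
    criterion: str = "aic",
    start: str = "empty",
    force_in: tuple[str, ...] = (),
    ties: str = "breslow",
    max_steps: int = 100,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Bidirectional stepwise Cox model over covariate blocks.

    With the default AIC criterion, each step (from the empty or full
    model) evaluates every single block addition and removal and takes the
    move that most improves the AIC, stopping when no move improves.  With
    ``criterion="pvalue"`` the classic entry/removal scheme is used
    instead: add the block with the smallest likelihood-ratio p-value if it
    is below ``p_enter``, then drop the block with the largest p-value
    above ``p_remove``, until neither applies.  Multi-level factors enter
    and leave as whole blocks.  Candidate moves whose fit fails
    (separation / monotone likelihood, singular information, constant
    column — e.g. a level absent from a subgroup) are skipped with a
    logged warning.  ``force_in`` blocks are always kept in the model.
    """
    if criterion not in ("aic", "pvalue"):
        raise ValueError("criterion must be 'aic' or 'pvalue'")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if start not in ("empty", "full"):
        raise ValueError("start must be 'empty' or 'full'")
    current: list[str] = list(blocks) if start == "full" else list(force_in)
    log: list[dict] = []

    def try_model(blist):
        cols = [c for b in blist for c in blocks[b]]
        return _model_aic(design, cols, time, event, ties)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            aic, fit = try_model(current)
        except (FitError, np.linalg.LinAlgError):
            if start == "full":  # fall back to empty start
                current = list(force_in)
                aic, fit = try_model(current)
            else:
                raise
        if criterion == "aic":
            for _ in range(max_steps):
                best = None
                for b in blocks:
                    if b in current:
                        if b in force_in:
                            continue
                        cand = [x for x in current if x != b]
                        move = ("drop", b)
                    else:
                        cand = current + [b]
                        move = ("add", b)
                    try:
                        cand_aic, cand_fit = try_model(cand)
                    except (FitError, np.linalg.LinAlgError) as exc:
                        log.append({"move": move, "skipped": str(exc)})
                        continue
                    if best is None or cand_aic < best[0]:
                        best = (cand_aic, cand_fit, cand, move)
                if best is None or best[0] >= aic - 1e-8:
                    break
                aic, fit, current, move = best
                log.append({"move": move, "aic": aic, "model": tuple(current)})
        else:
            # LRT p-value of a move: chi2 on the block's dof, comparing the
            # candidate against the current model
            def move_p(df_diff, ll_small, ll_big):
                return float(stats.chi2.sf(2.0 * (ll_big - ll_small), df_diff))

            for _ in range(max_steps):
                changed = False
                # entry step
                best = None
                for b in blocks:
                    if b in current:
                        continue
                    try:
                        cand_aic, cand_fit = try_model(current + [b])
                    except (FitError, np.linalg.LinAlgError) as exc:
                        log.append({"move": ("add", b), "skipped": str(exc)})
                        continue
                    ll_big = cand_fit.log_partial_likelihood
                    ll_small = (fit.log_partial_likelihood if fit is not None
                                else -0.5 * aic)
                    p = move_p(len(blocks[b]), ll_small, ll_big)
                    if p < p_enter and (best is None or p < best[0]):
                        best = (p, cand_aic, cand_fit, b)
                if best is not None:
                    p, aic, fit, b = best
                    current = current + [b]
                    log.append({"move": ("add", b), "p": p, "model": tuple(current)})
                    changed = True
                # removal step
                worst = None
                for b in current:
                    if b in force_in:
                        continue
                    try:
                        cand_aic, cand_fit = try_model([x for x in current if x != b])
                    except (FitError, np.linalg.LinAlgError) as exc:
                        log.append({"move": ("drop", b), "skipped": str(exc)})
                        continue
                    ll_small = (cand_fit.log_partial_likelihood if cand_fit is not None
                                else -0.5 * cand_aic)
                    p = move_p(len(blocks[b]), ll_small,
                               fit.log_partial_likelihood)
                    if p > p_remove and (worst is None or p > worst[0]):
                        worst = (p, cand_aic, cand_fit, b)
                if worst is not None:
                    p, aic, fit, b = worst
                    current = [x for x in current if x != b]
                    log.append({"move": ("drop", b), "p": p, "model": tuple(current)})
                    changed = True
                if not changed:
                    break
    cols = [c for b in current for c in blocks[b]]
    return StepwiseResult(
        fit=fit,
        retained_blocks=current,
        columns=cols,
        criterion=criterion,
        criterion_value=float(aic),
        move_log=log,
    )


# ---------------------------------------------------------------------------
# grade-level survival report
# ---------------------------------------------------------------------------

@dataclass
class GradeSurvivalReport:
    """Kaplan-Meier comparison of the low and high budding grades."""

    km: dict[str, KMEstimate]
    table: pd.DataFrame  # per grade: n, n_events, median_os
    chi2: float
    p: float

    @property
    def median_os(self) -> dict[str, float]:
        return self.table["median_os"].to_dict()


def grade_survival_report(grades: pd.DataFrame, time, event) -> GradeSurvivalReport:
    """Per-grade KM estimates, median overall survival and the log-rank test.

    ``grades`` rows must align with ``time`` / ``event`` order.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = grades["grade"].to_numpy()
    for g in ("low", "high"):
        if not (labels == g).any():
            raise ValueError(f"grade group {g!r} is empty")
    km, rows = {}, []
    for g in ("low", "high"):
        m = labels == g
        est = kaplan_meier(time[m], event[m])
        km[g] = est
        rows.append(
            {"grade": g, "n": int(m.sum()), "n_events": int(event[m].sum()),
             "median_os": est.median_survival}
        )
    lo, hi = labels == "low", labels == "high"
    chi2, p = logrank_test(time[lo], event[lo], time[hi], event[hi])
    return GradeSurvivalReport(
        km=km, table=pd.DataFrame(rows).set_index("grade"), chi2=chi2, p=p
    )
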