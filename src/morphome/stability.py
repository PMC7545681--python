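"""Repeated-CV stability selection of prognostic morphome features.

A single CV-tuned lasso Cox fit is unstable in which borderline features it
keeps: the tuned penalty moves with the fold assignment.  The selection is
therefore repeated R times (default 10), each repetition re-drawing the
cross-validation folds on the same cohort, and only features with a nonzero
coefficient at that repetition's deviance-optimal penalty in strictly more
than ``threshold`` (default 0.8) of repetitions are retained — with R = 10
and threshold 0.8 a feature must appear in at least 9 of 10 repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxnet import CVResult, cv_coxnet


def derive_seed(master_seed: int, r: int) -> int:
    """Deterministic per-repetition seed from the master seed (stable hash)."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(r)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RepeatResult:
    seed: int
    lambda_opt: float
    nonzero: tuple[str, ...]


@dataclass
class StabilityReport:
    """Per-feature selection frequencies over repeated CV-tuned lasso fits."""

    n_repeats: int
    threshold: float
    selection_frequency: pd.Series  # feature -> proportion of repetitions
    selected: list[str]  # frequency strictly above threshold, matrix order
    per_repeat: list[RepeatResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency": self.selection_frequency,
                "selected": [
                    f in self.selected for f in self.selection_frequency.index
                ],
            }
        ).rename_axis("feature")

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def stability_select(
    X,
    time,
    event,
    R: int = 10,
    V: int = 10,
    alpha: float = 1.0,
    threshold: float = 0.8,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    bootstrap: bool = False,
    feature_names=None,
) -> StabilityReport:
    """Run R repetitions of CV-tuned lasso Cox and threshold the frequencies.

    Parameters
    ----------
    X
        Feature matrix (DataFrame or array), e.g. the 40-column morphome.
    R, V
        Number of repetitions and CV folds.
    threshold
        Selection requires frequency strictly greater than this.
    bootstrap
        When True each repetition additionally resamples patients with
        replacement (off by default: the repetitions re-draw CV folds only).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if feature_names is None:
        feature_names = (
            list(X.columns) if hasattr(X, "columns")
            else [f"x{j}" for j in range(np.asarray(X).shape[1])]
        )
    Xa = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = len(time)
    counts = pd.Series(0, index=pd.Index(feature_names, name="feature"), dtype=int)
    per_repeat: list[RepeatResult] = []
    for r in range(R):
        rep_seed = derive_seed(seed, r)
        if bootstrap:
            rs = np.random.default_rng(rep_seed).integers(0, n, size=n)
            Xr, tr, er = Xa[rs], time[rs], event[rs]
        else:
            Xr, tr, er = Xa, time, event
        cv: CVResult = cv_coxnet(
            Xr, tr, er, V=V, alpha=alpha, seed=rep_seed,
            n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
            feature_names=feature_names,
        )
        nonzero = tuple(cv.nonzero_at_opt())
        counts[list(nonzero)] += 1
        per_repeat.append(RepeatResult(rep_seed, cv.lambda_opt, nonzero))
    freq = counts / R
    selected = [f for f in feature_names if freq[f] > threshold]
    return StabilityReport(
        n_repeats=R,
        threshold=threshold,
        selection_frequency=freq,
        selected=selected,
        per_repeat=per_repeat,
    )
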