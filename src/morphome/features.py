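"""The 40-feature morphome matrix and cluster-size relationships.

Cluster sizes 1..50 are divided into ten 5-cell bins (1-5, 6-10, ..., 46-50).
Per patient the morphome records, for each bin, the absolute cluster count
(``buds.<u>`` where ``u`` is the bin's upper bound) and the fraction of cells
in that bin's clusters whose ECad staining is cytoplasmic / mixed /
membranous (``cyto.<u>``, ``mix.<u>``, ``memb.<u>``).  Cohort-level
cluster-count decay with size is summarized by an inverse regression
(count ~ 1/size).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, IntegrityError

N_BINS = 10
BIN_WIDTH = 5
MAX_SIZE = N_BINS * BIN_WIDTH


@dataclass(frozen=True)
class SizeBin:
    """One 5-cell-wide cluster size category."""

    index: int  # 1..10
    lower: int
    upper: int

    @property
    def label(self) -> str:
        return f"buds.{self.upper}"


SIZE_BINS: tuple[SizeBin, ...] = tuple(
    SizeBin(i, BIN_WIDTH * (i - 1) + 1, BIN_WIDTH * i) for i in range(1, N_BINS + 1)
)

BUD_COLUMNS = tuple(b.label for b in SIZE_BINS)
#: Full fixed column order: the ten count columns, then for each bin the
#: (cyto, mix, memb) fraction triple.
FEATURE_COLUMNS: tuple[str, ...] = BUD_COLUMNS + tuple(
    f"{pat}.{b.upper}" for b in SIZE_BINS for pat in ("cyto", "mix", "memb")
)


def assign_bin(size: int) -> SizeBin:
    """Map a cluster size (1..50) to its size category: bin ceil(size/5)."""
    if not 1 <= size <= MAX_SIZE:
        raise ValueError(f"cluster size must be in 1..{MAX_SIZE}, got {size}")
    return SIZE_BINS[(int(size) - 1) // BIN_WIDTH]


def build_morphome_matrix(
    census: pd.DataFrame,
    patients: Sequence[str] | None = None,
    empty_bin_fraction: float = 0.0,
) -> pd.DataFrame:
    """Convert a cluster census into the per-patient morphome matrix.

    Parameters
    ----------
    census
        Cluster table with columns ``patient_id, size, n_membranous,
        n_mixed, n_cytoplasmic`` (the output of
        :func:`morphome.census.build_cluster_census`).
    patients
        Row order of the output.  Every patient present in the census must
        appear here; patients without clusters get all-zero count rows.
        Defaults to the sorted census patients.
    empty_bin_fraction
        Value imputed for all three pattern fractions of a bin in which the
        patient has no clusters (the paired count column is 0 and carries
        the absence signal).

    Returns
    -------
    pandas.DataFrame
        One row per patient, 40 columns in :data:`FEATURE_COLUMNS` order.
    """
    if patients is None:
        patients = sorted(census["patient_id"].unique())
    else:
        patients = list(patients)
        missing = set(census["patient_id"].unique()) - set(patients)
        if missing:
            raise IntegrityError(
                f"census patients {sorted(missing)} absent from the patient list"
            )
    mat = pd.DataFrame(0.0, index=pd.Index(patients, name="patient_id"),
                       columns=list(FEATURE_COLUMNS))
    if len(census):
        c = census.copy()
        c["bin_upper"] = ((c["size"].astype(int) - 1) // BIN_WIDTH + 1) * BIN_WIDTH
        if (c["size"] < 1).any() or (c["size"] > MAX_SIZE).any():
            raise IntegrityError(f"census contains cluster sizes outside 1..{MAX_SIZE}")
        g = c.groupby(["patient_id", "bin_upper"])
        counts = g.size()
        cells = g[["n_cytoplasmic", "n_mixed", "n_membranous", "size"]].sum()
        for (pid, u), n_clusters in counts.items():
            mat.loc[pid, f"buds.{u}"] = float(n_clusters)
        tot = cells["size"].astype(float)
        for pat, col in (("cyto", "n_cytoplasmic"), ("mix", "n_mixed"), ("memb", "n_membranous")):
            frac = cells[col].astype(float) / tot
            for (pid, u), v in frac.items():
                mat.loc[pid, f"{pat}.{u}"] = v
    if empty_bin_fraction != 0.0:
        for b in SIZE_BINS:
            empty = mat[b.label] == 0
            for pat in ("cyto", "mix", "memb"):
                mat.loc[empty, f"{pat}.{b.upper}"] = empty_bin_fraction
    return mat


@dataclass
class InverseFit:
    """OLS fit of count on 1/size (decay of cluster count with size)."""

    intercept: float
    slope: float
    p_slope: float
    r_squared: float


def inverse_regression(sizes: Sequence[float], counts: Sequence[float]) -> InverseFit:
    """Ordinary least squares of ``count ~ 1/size``.

    The two-sided p-value is the t-test on the slope of the transformed
    predictor.  Points are pooled across patients when called at cohort
    level (a between-subjects relationship).
    """
    sizes = np.asarray(sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if sizes.size < 3:
        raise ValueError("inverse regression needs at least 3 points")
    if np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    x = 1.0 / sizes
    if np.ptp(x) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(x, counts)
    return InverseFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        p_slope=float(res.pvalue),
        r_squared=float(res.rvalue**2),
    )


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="patient_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col="patient_id")
    missing = [c for c in FEATURE_COLUMNS if c not in mat.columns]
    if missing:
        raise FormatError(f"matrix file {path} is missing feature column(s) {missing}")
    return mat[list(FEATURE_COLUMNS)]
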