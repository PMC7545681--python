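"""Per-cell annotation I/O and the per-patient cluster census.

The unit of observation is a single tumor cell at the invasion front,
annotated with the cohesive cluster it belongs to and the subcellular
localization of its E-cadherin (ECad) staining: purely membranous, purely
cytoplasmic, or mixed.  Clusters of up to ``max_size`` (default 50) cohesive
cells enter the analysis; larger aggregates belong to the main tumor mass and
are excluded — but always logged, never silently dropped.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

#: The three admissible ECad localization patterns.  Fully ECad-negative tumor
#: cells do not occur in this assay (the stain doubles as the epithelial
#: marker that identifies tumor cells in the first place).
ECAD_PATTERNS = ("membranous", "mixed", "cytoplasmic")

CELL_COLUMNS = ("patient_id", "field_id", "cluster_id", "cell_id", "ecad_pattern")
CENSUS_COLUMNS = (
    "patient_id",
    "cluster_id",
    "size",
    "n_membranous",
    "n_mixed",
    "n_cytoplasmic",
)


@dataclass(frozen=True)
class CellRecord:
    """One annotated tumor cell."""

    patient_id: str
    field_id: str
    cluster_id: str
    cell_id: str
    ecad_pattern: str

    def __post_init__(self) -> None:
        if self.ecad_pattern not in ECAD_PATTERNS:
            raise IntegrityError(
                f"unknown ecad_pattern {self.ecad_pattern!r}; "
                f"expected one of {ECAD_PATTERNS}"
            )


@dataclass(frozen=True)
class ClusterRecord:
    """A cohesive tumor cell cluster with its per-pattern cell tally."""

    patient_id: str
    cluster_id: str
    size: int
    pattern_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise IntegrityError(f"cluster size must be >= 1, got {self.size}")
        if sum(self.pattern_counts.values()) != self.size:
            raise IntegrityError(
                "pattern_counts must sum to cluster size "
                f"({dict(self.pattern_counts)} vs size {self.size})"
            )


@dataclass
class CensusSummary:
    """Cohort-level accounting of cells, patterns and cluster sizes."""

    total_cells: int
    pattern_totals: dict[str, int]
    pattern_fractions: dict[str, float]
    clusters_per_patient: dict[str, int]
    median_cluster_size_per_patient: dict[str, float]
    overall_median_cluster_size: float

    def pattern_percents(self) -> dict[str, int]:
        """Pattern shares as half-up-rounded integer percents."""
        return {
            k: int(round_half_up(100 * Fraction(v, self.total_cells), 0))
            for k, v in self.pattern_totals.items()
        }


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check column layout, pattern enum values and key uniqueness."""
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"cells table is missing column(s) {missing}")
    bad = set(cells["ecad_pattern"].unique()) - set(ECAD_PATTERNS)
    if bad:
        raise IntegrityError(
            f"unknown ecad_pattern value(s) {sorted(bad)}; "
            f"expected one of {ECAD_PATTERNS}"
        )
    key = ["patient_id", "field_id", "cluster_id", "cell_id"]
    if cells.duplicated(subset=key).any():
        dup = cells[cells.duplicated(subset=key, keep=False)].iloc[0]
        raise IntegrityError(
            "duplicate cell key "
            f"({dup.patient_id}, {dup.field_id}, {dup.cluster_id}, {dup.cell_id})"
        )
    return cells


def read_cells(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated per-cell annotation table.

    Expected header: ``patient_id  field_id  cluster_id  cell_id
    ecad_pattern``.  Every row is validated; unknown patterns and duplicate
    cell keys raise :class:`~morphome.errors.IntegrityError`.
    """
    cells = pd.read_csv(path, sep="\t", dtype=str)
    if cells.empty and not set(CELL_COLUMNS) <= set(cells.columns):
        raise FormatError(
            f"cells file {path} lacks the expected header {CELL_COLUMNS}"
        )
    return validate_cells(cells)


def cells_to_records(cells: pd.DataFrame) -> list[CellRecord]:
    """Materialize a validated cells table as typed records."""
    return [CellRecord(*row) for row in cells[list(CELL_COLUMNS)].itertuples(index=False)]


@dataclass
class ExclusionLog:
    """Clusters dropped from the census because they exceed ``max_size``."""

    max_size: int
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_clusters(self) -> int:
        return len(self.excluded)

    @property
    def n_cells(self) -> int:
        return int(self.excluded["size"].sum()) if self.n_clusters else 0


def build_cluster_census(
    cells: pd.DataFrame, max_size: int = 50
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Tally cells into clusters and apply the size cut-off.

    Clusters are keyed by (patient, field, cluster); the same cluster_id in
    two different fields names two distinct clusters.  Clusters larger than
    ``max_size`` cells are excluded from the census and recorded in the
    returned :class:`ExclusionLog`.

    Returns a census frame with columns ``patient_id, cluster_id, size,
    n_membranous, n_mixed, n_cytoplasmic`` where ``cluster_id`` is the
    field-qualified identifier ``<field_id>:<cluster_id>``.
    """
    cells = validate_cells(cells)
    if cells.empty:
        return pd.DataFrame(columns=CENSUS_COLUMNS), ExclusionLog(max_size)
    tally = (
        cells.groupby(["patient_id", "field_id", "cluster_id"], sort=True)["ecad_pattern"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=ECAD_PATTERNS, fill_value=0)
        .reset_index()
    )
    census = pd.DataFrame(
        {
            "patient_id": tally["patient_id"],
            "cluster_id": tally["field_id"].astype(str)
            + ":"
            + tally["cluster_id"].astype(str),
            "size": tally[list(ECAD_PATTERNS)].sum(axis=1).astype(int),
            "n_membranous": tally["membranous"].astype(int),
            "n_mixed": tally["mixed"].astype(int),
            "n_cytoplasmic": tally["cytoplasmic"].astype(int),
        }
    )
    census = census.sort_values(["patient_id", "cluster_id"], kind="stable")
    too_big = census["size"] > max_size
    log = ExclusionLog(max_size, census[too_big].reset_index(drop=True))
    return census[~too_big].reset_index(drop=True), log


def census_to_records(census: pd.DataFrame) -> list[ClusterRecord]:
    return [
        ClusterRecord(
            row.patient_id,
            row.cluster_id,
            int(row.size),
            {
                "membranous": int(row.n_membranous),
                "mixed": int(row.n_mixed),
                "cytoplasmic": int(row.n_cytoplasmic),
            },
        )
        for row in census.itertuples(index=False)
    ]


def summarize_census(census: pd.DataFrame) -> CensusSummary:
    """Cohort summary: pattern totals/fractions and per-patient cluster medians.

    Pattern fractions are computed with rational arithmetic on the integer
    counts (so they sum to exactly 1) before the final float conversion.
    The overall median cluster size is the median, across patients, of each
    patient's own median cluster size.
    """
    if census.empty:
        raise IntegrityError("cannot summarize an empty census")
    totals = {
        "membranous": int(census["n_membranous"].sum()),
        "mixed": int(census["n_mixed"].sum()),
        "cytoplasmic": int(census["n_cytoplasmic"].sum()),
    }
    total_cells = sum(totals.values())
    fracs_exact = {k: Fraction(v, total_cells) for k, v in totals.items()}
    assert sum(fracs_exact.values()) == 1
    per_patient = census.groupby("patient_id")["size"]
    medians = per_patient.median().to_dict()
    return CensusSummary(
        total_cells=total_cells,
        pattern_totals=totals,
        pattern_fractions={k: float(v) for k, v in fracs_exact.items()},
        clusters_per_patient=per_patient.size().to_dict(),
        median_cluster_size_per_patient=medians,
        overall_median_cluster_size=float(np.median(list(medians.values()))),
    )


def round_half_up(x: float | Fraction, decimals: int) -> float:
    """Round half away from zero at ``decimals`` places (report convention)."""
    if isinstance(x, Fraction):
        d = decimal.Decimal(x.numerator) / decimal.Decimal(x.denominator)
    else:
        d = decimal.Decimal(repr(float(x)))
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=decimal.ROUND_HALF_UP))


def field_area_mm2(area_um2: float, decimals: int = 3) -> float:
    """Convert a field area from square micrometres to square millimetres.

    Rounded half-up to ``decimals`` places; e.g. the 516788.1 µm² field of a
    200x-magnification digital slide view is reported as 0.517 mm².
    """
    if area_um2 < 0:
        raise ValueError(f"area must be nonnegative, got {area_um2}")
    return round_half_up(area_um2 / 1e6, decimals)


def write_census(census: pd.DataFrame, path: str | Path) -> None:
    """Write the census as a tab-separated file, ordered by (patient, cluster)."""
    out = census.sort_values(["patient_id", "cluster_id"], kind="stable")
    out.to_csv(path, sep="\t", index=False)


def read_census(path: str | Path) -> pd.DataFrame:
    census = pd.read_csv(
        path,
        sep="\t",
        dtype={c: (str if c in ("patient_id", "cluster_id") else int) for c in CENSUS_COLUMNS},
    )
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise FormatError(f"census file {path} is missing column(s) {missing}")
    sizes = census[["n_membranous", "n_mixed", "n_cytoplasmic"]].sum(axis=1)
    if (sizes != census["size"]).any():
        raise IntegrityError("pattern counts do not sum to cluster size")
    return census
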