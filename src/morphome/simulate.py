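"""Synthetic periampullary-carcinoma cohorts with planted morphome effects.

The generator reproduces the statistical structure the analysis pipeline
assumes, so that every stage can be exercised and scored without patient
data:

* cluster counts per patient fall off inversely with cluster size
  (expected count of size-s clusters = c/s, drawn Poisson);
* the per-cell ECad pattern follows a size-dependent categorical model —
  two logistic curves give P(cytoplasmic) (falling with size) and
  P(membranous) (rising with size), mixed takes the remainder;
* overall survival is exponential with rate
  ``baseline_hazard * exp(x . beta)`` on the *realized* morphome features,
  censored by an independent uniform follow-up window;
* clinicopathological covariates are independent categorical draws with
  marginals matching a typical resected periampullary cohort.

Default planted log-hazards sit on buds.10 (+, small clusters harmful),
buds.35 (-, larger clusters protective), cyto.15 and cyto.30 (+, cytoplasmic
ECad shift harmful) — the four prognostic morphome features, with their
observed effect directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import build_morphome_matrix

#: Clinicopathological category probabilities (cohort-analog marginals).
DEFAULT_CLINICAL_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"male": 88 / 171, "female": 83 / 171},
    "pT": {"1": 13 / 171, "2": 27 / 171, "3": 113 / 171, "4": 18 / 171},
    "pN": {"N0": 57 / 171, "N+": 114 / 171},
    "M": {"M0": 164 / 171, "M+": 7 / 171},
    "grade": {"1": 3 / 171, "2": 108 / 171, "3": 59 / 171, "4": 1 / 171},
    "lymphovascular": {"present": 74 / 171, "absent": 97 / 171},
    "vascular": {"present": 26 / 171, "absent": 145 / 171},
    "perineural": {"present": 101 / 171, "absent": 70 / 171},
    "margin": {"R0": 126 / 171, "R+": 45 / 171},
    "location": {"PDAC": 110 / 171, "DBDAC": 18 / 171, "AMPAC": 36 / 171,
                 "DUOAC": 7 / 171},
    "histology": {"PB": 104 / 171, "MIX": 11 / 171, "INT": 34 / 171,
                  "UNDIFF": 17 / 171, "OTH": 5 / 171},
}

#: Planted log-hazard ratios on morphome features (effect directions and
#: magnitudes of the prognostic quartet).
DEFAULT_BETA: dict[str, float] = {
    "buds.10": 0.08,
    "buds.35": -0.35,
    "cyto.15": 2.5,
    "cyto.30": 1.8,
}


@dataclass
class PatternModel:
    """Size-dependent ECad pattern probabilities.

    ``P(cytoplasmic | size s) = expit(a_cyto + b_cyto * s)`` and likewise
    for membranous; mixed takes the remainder.  The defaults make the
    cytoplasmic fraction fall from ~0.42 in isolated cells to ~0.09 in
    50-cell clusters while the membranous fraction rises ~0.15 -> 0.43,
    giving cohort-level cell fractions near 21/26/54 percent
    (cytoplasmic / membranous / mixed).
    """

    a_cyto: float = -0.3
    b_cyto: float = -0.04
    a_memb: float = -1.8
    b_memb: float = 0.03

    def probs(self, size, emt_shift: float = 0.0) -> np.ndarray:
        """(P_cyto, P_mix, P_memb) for the given size(s); columns sum to 1.

        ``emt_shift`` is a per-patient EMT-axis displacement: it raises the
        cytoplasmic logit and lowers the membranous logit by the same
        amount, modelling tumors whose cells have shifted ECad from the
        membrane to the cytoplasm more (or less) than the cohort average.
        """
        size = np.asarray(size, dtype=float)
        p_c = expit(self.a_cyto + self.b_cyto * size + emt_shift)
        p_m = expit(self.a_memb + self.b_memb * size - emt_shift)
        p_x = 1.0 - p_c - p_m
        if np.any(p_x < 0):
            raise ValueError("pattern model gives negative mixed probability")
        return np.stack([p_c, p_x, p_m], axis=-1)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator."""

    n_patients: int = 171
    # Expected clusters of size s per patient = scale/s.  With the gamma
    # intensity multiplier below (median < mean), 11.8 puts the *median*
    # total cluster count per field at ~42; under the strict 1/s law the
    # median total cell count then lands near ~490 (the inverse law cannot
    # match a cohort's cluster count and cell count simultaneously; we pin
    # the cluster count).
    cluster_count_scale: float = 11.8
    max_cluster_size: int = 50
    # Heterogeneity.  Real cohorts are strongly overdispersed relative to
    # Poisson/binomial sampling: per-field cluster counts span 3-283 around
    # a median of 42, and per-patient cytoplasmic fractions span most of the
    # unit interval.  A gamma budding-intensity multiplier (mean 1, shape
    # below) drawn independently per patient x size-bin makes each bin's
    # count negative binomial with the printed spread while keeping the ten
    # count features independent of one another — matching the planted-null
    # design in which only the four causal features carry signal.  EMT
    # displacement of the pattern logits acts at the *cluster* level (each
    # bud carries its own EMT state, giving the wide per-bin scatter without
    # coupling fractions across bins); an optional patient-level shift is
    # available for sensitivity analyses.  shape = inf / SDs = 0 recover the
    # homogeneous model.
    cluster_dispersion_shape: float = 1.5
    emt_cluster_sd: float = 0.9  # cluster-level SD of the EMT logit shift
    emt_shift_sd: float = 0.0  # optional patient-level SD (couples bins)
    pattern_model: PatternModel = field(default_factory=PatternModel)
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    baseline_hazard: float = 0.006  # per month; targets ~50% observed deaths
    censoring_window: tuple[float, float] = (1.0, 116.0)  # months, uniform
    clinical_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL_MARGINALS.items()}
    )
    age_mean: float = 66.0
    age_sd: float = 12.0
    age_range: tuple[int, int] = (30, 89)

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.cluster_dispersion_shape <= 0:
            raise ValueError("cluster_dispersion_shape must be positive (inf = none)")
        if self.emt_shift_sd < 0 or self.emt_cluster_sd < 0:
            raise ValueError("EMT shift SDs must be nonnegative")
        for var, marg in self.clinical_marginals.items():
            tot = sum(marg.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"marginals for {var} sum to {tot}, not 1")
        sizes = np.arange(1, self.max_cluster_size + 1)
        for shift in (-3.0, 0.0, 3.0):  # truncation bounds of the EMT shift
            self.pattern_model.probs(sizes, shift)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["censoring_window"] = list(self.censoring_window)
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "pattern_model" in d and isinstance(d["pattern_model"], Mapping):
            d["pattern_model"] = PatternModel(**d["pattern_model"])
        for key in ("censoring_window", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:04d}" for i in range(n)]


def simulate_clusters(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str]]:
    """Draw the per-patient cluster census.

    For each patient and each size s in 1..max the number of clusters is
    Poisson(m * c/s), where the budding-intensity multiplier m is gamma
    with mean 1 (shape ``cluster_dispersion_shape``) drawn independently
    per patient and 5-cell size bin, making each bin's count negative
    binomial across patients while keeping the expected count c/s and the
    ten count features mutually independent.  Per-cluster pattern counts
    are multinomial with the size-dependent probabilities displaced by the
    cluster's (and optionally the patient's) EMT shift.  A patient who
    draws zero clusters gets a single size-1 cluster injected (every
    patient must contribute at least one cluster); the returned list names
    the repaired patients.
    """
    n, smax = cfg.n_patients, cfg.max_cluster_size
    sizes = np.arange(1, smax + 1)
    lam = cfg.cluster_count_scale / sizes
    shape = cfg.cluster_dispersion_shape
    n_bins = (smax + 4) // 5
    mult = (np.ones((n, n_bins)) if np.isinf(shape)
            else rng.gamma(shape, 1.0 / shape, size=(n, n_bins)))
    emt = (np.zeros(n) if cfg.emt_shift_sd == 0
           else rng.normal(0.0, cfg.emt_shift_sd, size=n))
    counts = rng.poisson(mult[:, (sizes - 1) // 5] * lam[None, :])
    injected = []
    pids = _patient_ids(n)
    for i in range(n):
        if counts[i].sum() == 0:
            counts[i, 0] = 1
            injected.append(pids[i])
    rows = []
    for i, pid in enumerate(pids):
        k_cluster = 0
        for s in sizes:
            k = int(counts[i, s - 1])
            if k == 0:
                continue
            shifts = emt[i] + (
                rng.normal(0.0, cfg.emt_cluster_sd, size=k)
                if cfg.emt_cluster_sd > 0 else np.zeros(k)
            )
            shifts = np.clip(shifts, -3.0, 3.0)
            probs = cfg.pattern_model.probs(float(s), shifts)  # (k, 3)
            block = rng.multinomial(int(s), probs)
            for c, x, m in block:
                k_cluster += 1
                rows.append((pid, f"F1:C{k_cluster:04d}", int(s),
                             int(m), int(x), int(c)))
    census = pd.DataFrame(
        rows,
        columns=["patient_id", "cluster_id", "size",
                 "n_membranous", "n_mixed", "n_cytoplasmic"],
    )
    return census, injected


def clusters_to_cells(census: pd.DataFrame) -> pd.DataFrame:
    """Expand a cluster census into the per-cell annotation table."""
    pats, fields, clusters, cells, patterns = [], [], [], [], []
    for row in census.itertuples(index=False):
        fid, cid = str(row.cluster_id).split(":", 1)
        labels = (
            ["membranous"] * int(row.n_membranous)
            + ["mixed"] * int(row.n_mixed)
            + ["cytoplasmic"] * int(row.n_cytoplasmic)
        )
        for j, lab in enumerate(labels):
            pats.append(row.patient_id)
            fields.append(fid)
            clusters.append(cid)
            cells.append(f"{cid}c{j + 1:03d}")
            patterns.append(lab)
    return pd.DataFrame(
        {"patient_id": pats, "field_id": fields, "cluster_id": clusters,
         "cell_id": cells, "ecad_pattern": patterns}
    )


def simulate_census(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Convenience wrapper: draw clusters and expand them to cells."""
    census, _ = simulate_clusters(cfg, np.random.default_rng(seed))
    return clusters_to_cells(census)


def simulate_survival(
    features: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential survival under the planted proportional-hazards model.

    ``T ~ Exp(baseline_hazard * exp(x . beta))`` censored at an independent
    Uniform(censoring window) time; the event flag marks observed deaths.
    """
    unknown = set(cfg.beta) - set(features.columns)
    if unknown:
        raise ValueError(f"beta names {sorted(unknown)} not in the feature matrix")
    eta = np.zeros(len(features))
    for f, b in cfg.beta.items():
        eta += b * features[f].to_numpy(float)
    rate = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    lo, hi = cfg.censoring_window
    t_cens = rng.uniform(lo, hi, size=len(features))
    time = np.minimum(t_event, t_cens)
    return pd.DataFrame(
        {
            "patient_id": features.index.astype(str),
            "time_months": time,
            "event": t_event <= t_cens,
            "linear_predictor_true": eta,
        }
    )


def simulate_clinical(
    cfg: SimulationConfig, rng: np.random.Generator, n: int | None = None
) -> pd.DataFrame:
    """Independent categorical draws of the clinicopathological covariates."""
    n = cfg.n_patients if n is None else n
    out = pd.DataFrame({"patient_id": _patient_ids(n)})
    age = np.rint(rng.normal(cfg.age_mean, cfg.age_sd, size=n))
    out["age"] = np.clip(age, *cfg.age_range).astype(int)
    for var, marg in cfg.clinical_marginals.items():
        cats = list(marg)
        p = np.array([marg[c] for c in cats], dtype=float)
        out[var] = rng.choice(cats, p=p / p.sum(), size=n)
    return out


@dataclass
class SyntheticCohort:
    """A complete generated dataset plus the ground truth that made it."""

    cells: pd.DataFrame
    clusters: pd.DataFrame
    features: pd.DataFrame  # the 40-column morphome matrix
    clinical: pd.DataFrame  # covariates + time_months + event + true eta
    injected_patients: list[str]
    truth: SimulationConfig
    seed: int


def simulate_cohort(
    cfg: SimulationConfig, seed: int, expand_cells: bool = True
) -> SyntheticCohort:
    """Generate a full cohort: census, morphome matrix, survival, clinical.

    Survival is driven by the realized (not expected) morphome features.
    Pure function of (cfg, seed).  ``expand_cells=False`` skips the per-cell
    table for speed when only the matrix-level pipeline is exercised.
    """
    rng = np.random.default_rng(seed)
    clusters, injected = simulate_clusters(cfg, rng)
    features = build_morphome_matrix(clusters, patients=_patient_ids(cfg.n_patients))
    outcome = simulate_survival(features, cfg, rng)
    clinical = simulate_clinical(cfg, rng)
    clinical = clinical.merge(outcome, on="patient_id")
    cells = clusters_to_cells(clusters) if expand_cells else pd.DataFrame()
    return SyntheticCohort(
        cells=cells,
        clusters=clusters,
        features=features,
        clinical=clinical,
        injected_patients=injected,
        truth=cfg,
        seed=seed,
    )
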