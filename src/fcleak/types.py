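"""Core data containers shared across the pipeline.

A cohort is represented by a plain :class:`pandas.DataFrame` ("cohort
table") with one row per scan and columns ``subject_id``, ``scan_id``,
``phenotype_cont`` (continuous phenotype, identical across scans of a
subject) and ``phenotype_bin`` (0/1 label derived from the continuous
one).  Connectivity features travel either as lists of
:class:`ConnectivityVector` or as a flat "FC table" DataFrame produced by
:func:`vectors_to_frame`.

Throughout the package a *unit* is the atom of train/test assignment: a
``(subject_id, scan_id, window_index)`` triple, with ``window_index = -1``
denoting a whole-scan (static) FC vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: window_index value marking a whole-scan (non-windowed) FC vector.
STATIC_WINDOW = -1

COHORT_COLUMNS = ["subject_id", "scan_id", "phenotype_cont", "phenotype_bin"]
UNIT_COLUMNS = ["subject_id", "scan_id", "window_index"]


@dataclass
class RoiTimeseries:
    """One scan's BOLD-like ROI timeseries, shape (T timepoints, P regions)."""

    subject_id: str
    scan_id: str
    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RoiTimeseries.values must be a T x P matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RoiTimeseries contains non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityVector:
    """Vectorized strict upper triangle of a P x P correlation matrix.

    Entry order is row-major over the strict upper triangle (the
    ``numpy.triu_indices(P, k=1)`` order); every module in the package
    shares this single convention.
    """

    subject_id: str
    scan_id: str
    values: np.ndarray
    n_rois: int
    window_index: int = STATIC_WINDOW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        expected = self.n_rois * (self.n_rois - 1) // 2
        if self.values.size != expected:
            raise ValueError(
                f"FC vector length {self.values.size} does not match "
                f"P(P-1)/2 = {expected} for P = {self.n_rois}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ConnectivityVector contains non-finite entries")
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def unit(self) -> tuple:
        return (self.subject_id, self.scan_id, int(self.window_index))


@dataclass
class SimilarityMatrix:
    """Pairwise scan similarity with its scan index.

    For ``metric='euclidean'`` values are *negated* distances so that
    "higher = more similar" holds uniformly; the unit-diagonal invariant
    is then waived (``unit_diagonal`` records which convention applies).
    """

    scan_index: list
    values: np.ndarray
    metric: str = "cosine"
    unit_diagonal: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.scan_index)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match index")

    def to_frame(self) -> pd.DataFrame:
        labels = ["|".join(map(str, u)) for u in self.scan_index]
        return pd.DataFrame(self.values, index=labels, columns=labels)


@dataclass
class SplitSpec:
    """Train/test assignment of units, tagged with the leakage mode.

    ``leakage_mode`` is one of ``subject_disjoint``, ``scan_double_dip``,
    ``window_double_dip``, ``scan_shuffled`` (random scan-level
    assignment) or ``cross_cohort``.
    """

    train_units: list
    test_units: list
    leakage_mode: str
    seed: Optional[int] = None

    VALID_MODES = (
        "subject_disjoint",
        "scan_double_dip",
        "window_double_dip",
        "scan_shuffled",
        "cross_cohort",
    )

    def __post_init__(self) -> None:
        if self.leakage_mode not in self.VALID_MODES:
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")
        self.train_units = [tuple(u) for u in self.train_units]
        self.test_units = [tuple(u) for u in self.test_units]
        if not self.train_units or not self.test_units:
            raise ValueError("both split sides must be non-empty")
        overlap = set(self.train_units) & set(self.test_units)
        if overlap:
            raise ValueError(f"train and test unit sets overlap: {sorted(overlap)[:3]}")
        train_subjects = {u[0] for u in self.train_units}
        test_subjects = {u[0] for u in self.test_units}
        if self.leakage_mode == "subject_disjoint" and train_subjects & test_subjects:
            raise ValueError("subject_disjoint split has subjects on both sides")
        if self.leakage_mode == "scan_double_dip":
            if not test_subjects <= train_subjects:
                raise ValueError("scan_double_dip: every test subject needs a train scan")


@dataclass
class ExperimentResult:
    """Per-iteration and aggregated metrics for one experimental arm."""

    task: str  # 'classification' or 'regression'
    arm: str  # 'null', 'legitimate' or 'double_dip'
    per_iteration_metric: list = field(default_factory=list)
    metric_mean: float = float("nan")
    metric_sd: float = float("nan")
    n_train: int = 0
    n_test: int = 0
    chosen_hyperparameter: list = field(default_factory=list)

    @classmethod
    def from_iterations(
        cls,
        task: str,
        arm: str,
        metrics: Sequence[float],
        n_train: int,
        n_test: int,
        hyperparameters: Sequence[float] = (),
    ) -> "ExperimentResult":
        metrics = [float(m) for m in metrics]
        return cls(
            task=task,
            arm=arm,
            per_iteration_metric=metrics,
            metric_mean=float(np.mean(metrics)),
            metric_sd=float(np.std(metrics, ddof=1)) if len(metrics) > 1 else 0.0,
            n_train=n_train,
            n_test=n_test,
            chosen_hyperparameter=[float(h) for h in hyperparameters],
        )


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check cohort-table invariants; returns the (unmodified) table."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if cohort.duplicated(["subject_id", "scan_id"]).any():
        raise ValueError("(subject_id, scan_id) pairs must be unique")
    for col in ("phenotype_cont", "phenotype_bin"):
        if cohort.groupby("subject_id")[col].nunique().gt(1).any():
            raise ValueError(f"{col} varies across scans of one subject")
    if not set(cohort["phenotype_bin"].unique()) <= {0, 1}:
        raise ValueError("phenotype_bin must be 0/1")
    return cohort


def vectors_to_frame(vectors: Sequence[ConnectivityVector]) -> pd.DataFrame:
    """Flatten ConnectivityVectors into an FC table.

    Columns: subject_id, scan_id, window_index, then one column per edge
    named ``ROI{i}_ROI{j}`` in the shared row-major upper-triangle order.
    """
    if not vectors:
        raise ValueError("no vectors given")
    p = vectors[0].n_rois
    if any(v.n_rois != p for v in vectors):
        raise ValueError("mixed ROI counts in vector list")
    iu, ju = np.triu_indices(p, k=1)
    edge_cols = [f"ROI{i}_ROI{j}" for i, j in zip(iu, ju)]
    meta = pd.DataFrame(
        {
            "subject_id": [v.subject_id for v in vectors],
            "scan_id": [v.scan_id for v in vectors],
            "window_index": [int(v.window_index) for v in vectors],
        }
    )
    feats = pd.DataFrame(np.vstack([v.values for v in vectors]), columns=edge_cols)
    return pd.concat([meta, feats], axis=1)


def frame_to_vectors(fc_table: pd.DataFrame) -> list:
    """Inverse of :func:`vectors_to_frame`."""
    edge_cols = [c for c in fc_table.columns if c not in UNIT_COLUMNS]
    n_edges = len(edge_cols)
    # invert E = P(P-1)/2
    p = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if p * (p - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} edge columns is not P(P-1)/2 for integer P")
    out = []
    for _, row in fc_table.iterrows():
        out.append(
            ConnectivityVector(
                subject_id=str(row["subject_id"]),
                scan_id=str(row["scan_id"]),
                window_index=int(row.get("window_index", STATIC_WINDOW)),
                values=row[edge_cols].to_numpy(dtype=float),
                n_rois=p,
            )
        )
    return out


def units_of(fc_table: pd.DataFrame) -> list:
    """Unit triples of an FC table, in row order."""
    return [
        (str(s), str(c), int(w))
        for s, c, w in zip(
            fc_table["subject_id"], fc_table["scan_id"], fc_table["window_index"]
        )
    ]
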