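"""Synthetic multi-scan FC cohorts with controllable fingerprint strength.

The generator builds, for every scan *s* of subject *i*, a target
correlation matrix in Fisher-z space::

    Z_is = Z_base + alpha * F_i + beta * y_i * W + sigma * E_is

where ``Z_base`` is a cohort-common backbone, ``F_i`` a subject-stable
low-rank symmetric pattern (what makes scans of one person identifiable),
``W`` a fixed symmetric phenotype-loading pattern shared by the cohort,
``y_i`` the subject's standardized continuous phenotype and ``E_is``
symmetric session noise redrawn per scan.  Every rank-1 term of ``F_i``
and ``W`` has unit Frobenius norm (so a rank-k fingerprint has norm
~ sqrt(k)) and ``E_is`` is normalized to unit Frobenius norm, which makes
``alpha``, ``beta`` and ``sigma`` comparable component magnitudes
independent of the ROI count.  The z-space sum is mapped back through
tanh, projected to
the nearest valid correlation matrix, and either returned directly as an
FC vector (:func:`generate_fc_cohort`) or used as the covariance of a
zero-mean multivariate normal from which ``T`` timepoints are sampled
(:func:`generate_cohort`).

The binary phenotype is the continuous one thresholded at zero, so one
generative path serves both the ridge (regression) and logistic
(classification) arms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .types import ConnectivityVector, RoiTimeseries, STATIC_WINDOW

__all__ = ["SynthConfig", "generate_cohort", "generate_fc_cohort", "nearest_correlation"]

#: default generation settings used by fixtures and the pipeline
DEFAULTS = dict(
    n_subjects=50,
    scans_per_subject=2,
    n_rois=30,
    n_timepoints=200,
    tr_seconds=2.0,
    alpha_fingerprint=1.0,
    beta_phenotype=0.5,
    sigma_session=0.5,
    fingerprint_rank=3,
    seed=0,
)


@dataclass(frozen=True)
class SynthConfig:
    """Cohort generation settings.

    alpha_fingerprint, beta_phenotype and sigma_session are the Fisher-z
    magnitudes (Frobenius norms) of the subject, phenotype and session
    components.  ``structure_seed`` controls the cohort-common backbone
    and phenotype pattern; leave it at None (= ``seed``) except when two
    cohorts must share structure, e.g. for cross-cohort experiments.
    """

    n_subjects: int = DEFAULTS["n_subjects"]
    scans_per_subject: int = DEFAULTS["scans_per_subject"]
    n_rois: int = DEFAULTS["n_rois"]
    n_timepoints: int = DEFAULTS["n_timepoints"]
    tr_seconds: float = DEFAULTS["tr_seconds"]
    alpha_fingerprint: float = DEFAULTS["alpha_fingerprint"]
    beta_phenotype: float = DEFAULTS["beta_phenotype"]
    sigma_session: float = DEFAULTS["sigma_session"]
    fingerprint_rank: int = DEFAULTS["fingerprint_rank"]
    seed: int = DEFAULTS["seed"]
    structure_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.scans_per_subject < 1:
            raise ValueError("scans_per_subject must be >= 1")
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name in ("alpha_fingerprint", "beta_phenotype", "sigma_session"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fingerprint_rank < 1:
            raise ValueError("fingerprint_rank must be >= 1")

    def validate_for_timeseries(self) -> None:
        # sample correlation from T points in P dims needs T comfortably
        # above P to be well conditioned at desk scale
        if self.n_timepoints < 2 * self.n_rois:
            raise ValueError(
                f"n_timepoints = {self.n_timepoints} < 2 * n_rois = "
                f"{2 * self.n_rois}; too short for stable sample correlations"
            )

    @property
    def effective_structure_seed(self) -> int:
        return self.seed if self.structure_seed is None else self.structure_seed

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Symmetrize, clip eigenvalues at ``eig_floor``, reconstruct, and
    renormalize to unit diagonal.  Deterministic and cheap at desk scale.
    """
    m = np.asarray(mat, dtype=float)
    m = (m + m.T) / 2.0
    w, v = np.linalg.eigh(m)
    w = np.clip(w, eig_floor, None)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise np.linalg.LinAlgError(
            "correlation projection failed (component scales too extreme)"
        )
    r = r / np.outer(d, d)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def _lowrank_pattern(rng: np.random.Generator, p: int, rank: int) -> np.ndarray:
    """Sum of rank-1 outer products of unit-norm vectors, hollowed.

    Each term u_k u_k^T has unit Frobenius norm, so the component scale
    is comparable across ROI counts; a rank-k pattern has Frobenius norm
    ~ sqrt(k).
    """
    m = np.zeros((p, p))
    for _ in range(rank):
        u = rng.standard_normal(p)
        u /= np.linalg.norm(u)
        m += np.outer(u, u)
    np.fill_diagonal(m, 0.0)
    return m


def _unit_frobenius_noise(rng: np.random.Generator, p: int) -> np.ndarray:
    """Hollow symmetric matrix with i.i.d. normal upper triangle, unit Frobenius."""
    iu = np.triu_indices(p, k=1)
    e = np.zeros((p, p))
    e[iu] = rng.standard_normal(iu[0].size)
    e = e + e.T
    return e / np.linalg.norm(e)


def _backbone(rng: np.random.Generator, p: int) -> np.ndarray:
    """Cohort-common connectivity backbone in Fisher-z space.

    Mildly positive edges (z ~ N(0.25, 0.15)) mimic the positive-mean FC
    distribution typical of resting-state cohorts.
    """
    iu = np.triu_indices(p, k=1)
    z = np.zeros((p, p))
    z[iu] = rng.normal(0.25, 0.15, size=iu[0].size)
    return z + z.T


def _cohort_targets(config: SynthConfig):
    """Draw phenotypes and per-scan target correlation matrices.

    Returns (records, matrices) where records is the cohort-table content
    and matrices maps (subject_id, scan_id) -> projected correlation
    matrix.  Both :func:`generate_cohort` and :func:`generate_fc_cohort`
    use this single draw, so the two paths share identical generative
    parameters for a given config.
    """
    p = config.n_rois
    struct_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.effective_structure_seed), 17])
    )
    z_base = _backbone(struct_rng, p)
    w_pattern = _lowrank_pattern(struct_rng, p, rank=1)

    cohort_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 29]))
    y = cohort_rng.standard_normal(config.n_subjects)

    records = []
    matrices = {}
    for i in range(config.n_subjects):
        subject_id = f"sub{i:04d}"
        f_i = _lowrank_pattern(cohort_rng, p, config.fingerprint_rank)
        for s in range(config.scans_per_subject):
            scan_id = f"scan{s:02d}"
            e_is = _unit_frobenius_noise(cohort_rng, p)
            z = (
                z_base
                + config.alpha_fingerprint * f_i
                + config.beta_phenotype * y[i] * w_pattern
                + config.sigma_session * e_is
            )
            r = np.tanh(z)
            np.fill_diagonal(r, 1.0)
            matrices[(subject_id, scan_id)] = nearest_correlation(r)
            records.append(
                {
                    "subject_id": subject_id,
                    "scan_id": scan_id,
                    "phenotype_cont": float(y[i]),
                    "phenotype_bin": int(y[i] > 0),
                }
            )
    cohort = pd.DataFrame.from_records(records)
    return cohort, matrices


def generate_cohort(config: SynthConfig):
    """Generate ROI timeseries for every (subject, scan) plus the cohort table.

    Each scan's T x P matrix is drawn from a zero-mean multivariate
    normal whose covariance is that scan's target correlation matrix.
    Deterministic given the config (including seed).

    Returns
    -------
    (list of RoiTimeseries, pandas.DataFrame)
    """
    config.validate_for_timeseries()
    cohort, matrices = _cohort_targets(config)
    ts_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 43]))
    scans = []
    for (subject_id, scan_id), corr in matrices.items():
        w, v = np.linalg.eigh(corr)
        if np.any(w < -1e-10) or not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError(
                f"target correlation for {subject_id}/{scan_id} is not "
                "positive semidefinite after projection"
            )
        factor = v * np.sqrt(np.clip(w, 0.0, None))
        data = ts_rng.standard_normal((config.n_timepoints, config.n_rois)) @ factor.T
        scans.append(
            RoiTimeseries(
                subject_id=subject_id,
                scan_id=scan_id,
                values=data,
                tr_seconds=config.tr_seconds,
            )
        )
    return scans, cohort


def generate_fc_cohort(config: SynthConfig):
    """Fast path: return the target FC matrices directly as vectors.

    Skips timeseries sampling (``n_timepoints`` is ignored); vectors are
    the upper triangle of the projected per-scan correlation matrices, in
    the shared row-major order.

    Returns
    -------
    (list of ConnectivityVector, pandas.DataFrame)
    """
    cohort, matrices = _cohort_targets(config)
    iu = np.triu_indices(config.n_rois, k=1)
    vectors = [
        ConnectivityVector(
            subject_id=subject_id,
            scan_id=scan_id,
            values=corr[iu],
            n_rois=config.n_rois,
            window_index=STATIC_WINDOW,
        )
        for (subject_id, scan_id), corr in matrices.items()
    ]
    return vectors, cohort
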