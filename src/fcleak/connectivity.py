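"""Static and windowed (dynamic) functional connectivity from ROI timeseries.

Pipeline convention: bandpass filter the *full* timeseries first (an
order-4 zero-phase Butterworth over 0.01-0.15 Hz by default), then
correlate — either over the whole scan (:func:`compute_fc`) or over
non-overlapping windows anchored at TR 0 (:func:`compute_dfc`).  FC is
the plain Pearson correlation matrix reduced to its strict upper
triangle in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import signal

from .types import ConnectivityVector, RoiTimeseries, STATIC_WINDOW

__all__ = [
    "BandpassSpec",
    "bandpass_filter",
    "compute_fc",
    "compute_dfc",
    "vectorize_matrix",
    "unvectorize",
]

#: default physiological band for resting-state BOLD, in Hz
DEFAULT_LOW_HZ = 0.01
DEFAULT_HIGH_HZ = 0.15
#: default non-overlapping window length for dFC, in TRs
DEFAULT_WINDOW_TRS = 50

_FILTER_ORDER = 4


@dataclass(frozen=True)
class BandpassSpec:
    """Passband edges in Hz and the sampling interval they apply to."""

    low_hz: float = DEFAULT_LOW_HZ
    high_hz: float = DEFAULT_HIGH_HZ
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        nyquist = 0.5 / self.tr_seconds
        if not (0.0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"need 0 < low_hz < high_hz < Nyquist ({nyquist:g} Hz); "
                f"got low_hz={self.low_hz}, high_hz={self.high_hz}"
            )

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds


def _sos(spec: BandpassSpec):
    return signal.butter(
        _FILTER_ORDER,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=1.0 / spec.tr_seconds,
        output="sos",
    )


def bandpass_filter(ts: RoiTimeseries, spec: BandpassSpec | None = None) -> RoiTimeseries:
    """Zero-phase bandpass filter, each ROI column independently.

    Applies the Butterworth filter forward and backward (sosfiltfilt), so
    the output has no phase shift and the same shape as the input.
    """
    if spec is None:
        spec = BandpassSpec(tr_seconds=ts.tr_seconds)
    if abs(spec.tr_seconds - ts.tr_seconds) > 1e-12:
        raise ValueError(
            f"BandpassSpec tr_seconds={spec.tr_seconds} does not match "
            f"timeseries tr_seconds={ts.tr_seconds}"
        )
    sos = _sos(spec)
    # sosfiltfilt default padlen; reject series too short to pad stably
    padlen = 3 * (2 * sos.shape[0] + 1)
    if ts.n_timepoints <= padlen:
        raise ValueError(
            f"T={ts.n_timepoints} too short for stable zero-phase filtering "
            f"(need > {padlen} timepoints)"
        )
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return RoiTimeseries(
        subject_id=ts.subject_id,
        scan_id=ts.scan_id,
        values=np.ascontiguousarray(filtered),
        tr_seconds=ts.tr_seconds,
    )


def vectorize_matrix(corr: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a square matrix, row-major order."""
    corr = np.asarray(corr)
    p = corr.shape[0]
    if corr.shape != (p, p):
        raise ValueError("expected a square matrix")
    return corr[np.triu_indices(p, k=1)]


def unvectorize(vec: np.ndarray, n_rois: int) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from an edge vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n_rois * (n_rois - 1) // 2:
        raise ValueError("vector length does not match n_rois")
    m = np.eye(n_rois)
    iu = np.triu_indices(n_rois, k=1)
    m[iu] = vec
    m[(iu[1], iu[0])] = vec
    return m


def _pearson_vector(values: np.ndarray, context: str) -> np.ndarray:
    if values.shape[0] < 3:
        raise ValueError(f"{context}: need at least 3 timepoints for correlation")
    # ptp catches exactly-constant columns that float std can miss
    zero_var = np.flatnonzero(
        (values.std(axis=0) == 0) | (np.ptp(values, axis=0) == 0)
    )
    if zero_var.size:
        raise ValueError(f"{context}: zero-variance ROI column(s) {zero_var.tolist()}")
    corr = np.corrcoef(values, rowvar=False)
    return np.clip(vectorize_matrix(corr), -1.0, 1.0)


def compute_fc(ts: RoiTimeseries) -> ConnectivityVector:
    """Whole-scan Pearson FC, vectorized."""
    vec = _pearson_vector(ts.values, f"{ts.subject_id}/{ts.scan_id}")
    return ConnectivityVector(
        subject_id=ts.subject_id,
        scan_id=ts.scan_id,
        values=vec,
        n_rois=ts.n_rois,
        window_index=STATIC_WINDOW,
    )


def compute_dfc(ts: RoiTimeseries, window_trs: int = DEFAULT_WINDOW_TRS) -> List[ConnectivityVector]:
    """Non-overlapping-window dFC.

    Windows are ``[0, w), [w, 2w), ...`` in TR units; the trailing
    partial window is discarded, so exactly ``floor(T / window_trs)``
    vectors come back, with ``window_index = 0, 1, ...``.
    """
    if window_trs < 3:
        raise ValueError("window_trs must be >= 3")
    t = ts.n_timepoints
    if t < window_trs:
        raise ValueError(f"T={t} shorter than window_trs={window_trs}")
    n_windows = t // window_trs
    out = []
    for k in range(n_windows):
        chunk = ts.values[k * window_trs : (k + 1) * window_trs]
        vec = _pearson_vector(chunk, f"{ts.subject_id}/{ts.scan_id} window {k}")
        out.append(
            ConnectivityVector(
                subject_id=ts.subject_id,
                scan_id=ts.scan_id,
                values=vec,
                n_rois=ts.n_rois,
                window_index=k,
            )
        )
    return out
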