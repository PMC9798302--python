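"""Motion quality control, cosine band-limiting and eigenvariate extraction.

Only the analysis-side preprocessing is implemented here: spatial
realignment, normalization, smoothing and ICA denoising happen upstream in
image space and are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["QCReport", "motion_qc", "cosine_detrend", "principal_eigenvariate"]

F_HIGHPASS = 0.0078  # Hz, drift cut-off


@dataclass
class QCReport:
    """Outcome of the motion-based exclusion rules for one subject."""

    subject: str
    mean_fd: float
    max_fd: float
    outlier_fraction: float
    included: bool
    reasons: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def motion_qc(fd: np.ndarray, subject: str = "", *,
              mean_threshold: float = 0.3, spike_threshold: float = 5.0,
              outlier_fd: float = 0.5, outlier_fraction_threshold: float = 0.30,
              ) -> QCReport:
    """Apply the stringent motion exclusion rules to a framewise-displacement series.

    A subject is excluded if (i) mean FD exceeds 0.3 mm, (ii) any single
    FD exceeds 5 mm, or (iii) more than 30% of volumes are outliers.  An
    outlier volume is one with FD > 0.5 mm (a convention; the threshold is
    configurable).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty framewise-displacement series")
    if np.any(fd < 0):
        raise ValueError("framewise displacement must be nonnegative")
    mean_fd = float(fd.mean())
    max_fd = float(fd.max())
    outlier_fraction = float(np.mean(fd > outlier_fd))
    reasons = []
    if mean_fd > mean_threshold:
        reasons.append(f"mean FD {mean_fd:.3f} mm > {mean_threshold} mm")
    if max_fd > spike_threshold:
        reasons.append(f"max FD {max_fd:.3f} mm > {spike_threshold} mm")
    if outlier_fraction > outlier_fraction_threshold:
        reasons.append(
            f"outlier volumes {100 * outlier_fraction:.1f}% > "
            f"{100 * outlier_fraction_threshold:.0f}% (FD > {outlier_fd} mm)")
    return QCReport(subject, mean_fd, max_fd, outlier_fraction,
                    included=not reasons, reasons=reasons)


def _drift_basis(n: int, dt: float, f_cut: float) -> np.ndarray:
    """Mean plus discrete-cosine regressors with frequency below f_cut.

    The k-th DCT-II basis function over n volumes has frequency
    k / (2 n dt) Hz.
    """
    k_max = int(np.floor(2 * n * dt * f_cut))
    t = np.arange(n)
    cols = [np.ones(n)]
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * (2 * t + 1) / (2 * n)))
    return np.column_stack(cols)


def cosine_detrend(ts: np.ndarray, dt: float, f_cut: float = F_HIGHPASS) -> np.ndarray:
    """Remove the mean and slow cosine drifts (< 0.0078 Hz) by regression.

    ``ts`` is regions x volumes; the residual series is returned.  The
    operation is a projection, hence idempotent.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n = ts.shape[1]
    if n < 16:
        raise ValueError("need at least 16 volumes to detrend")
    X = _drift_basis(n, dt, f_cut)
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def principal_eigenvariate(voxels: np.ndarray) -> np.ndarray:
    """Summary time series of an ROI: scaled first right singular vector.

    The voxels x volumes matrix is centered in time, and the first right
    singular vector is scaled by its singular value over sqrt(n_voxels)
    (so a homogeneous ROI returns the common centered series).  The sign
    is fixed so the output correlates nonnegatively with the mean voxel
    signal.
    """
    voxels = np.atleast_2d(np.asarray(voxels, dtype=float))
    if voxels.shape[0] < 1:
        raise ValueError("need at least one voxel")
    centered = voxels - voxels.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("all-zero (constant) ROI signal")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0] * s[0] / np.sqrt(voxels.shape[0])
    if v @ centered.mean(axis=0) < 0:
        v = -v
    return v
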