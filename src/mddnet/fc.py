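"""Quality-controlled Fisher-z functional connectivity from ROI time series.

The resting-state pipeline implemented here starts at parcellated BOLD
signals: a ``volumes x regions`` matrix per participant plus six rigid-body
motion parameters per volume.  It covers temporal band-pass filtering,
framewise-displacement (FD) scrubbing, motion-based participant exclusion,
optional nuisance regression, and the Fisher-z transformed Pearson
correlation vector over the lower triangle of the region-by-region
correlation matrix.  With the 379-region whole-brain parcellation used in
multi-site depression studies this vector has 379*378/2 = 71,631 entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "RoiTimeSeries",
    "MotionParams",
    "ConnectivityVector",
    "lower_triangle_size",
    "pair_to_index",
    "index_to_pair",
    "bandpass_filter",
    "framewise_displacement",
    "scrub",
    "exclude_high_motion_participants",
    "regress_nuisance",
    "compute_connectivity",
    "vector_to_matrix",
    "matrix_to_vector",
]

#: Pair-index convention: row-major over (i, j) with i > j, 0-based.
PAIR_CONVENTION = "row-major (i, j), i > j, 0-based"


@dataclass
class RoiTimeSeries:
    """Parcellated BOLD time series for one scan.

    Parameters
    ----------
    values
        ``volumes x regions`` array in arbitrary BOLD units.
    sampling_interval
        Repetition time in seconds per volume.
    subject_id, site_id
        Identifiers carried through the pipeline.
    """

    values: np.ndarray
    sampling_interval: float
    subject_id: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D volumes x regions array")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise ValueError("need at least 2 volumes and 2 regions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionParams:
    """Rigid-body motion parameters: translations (mm) and rotations (radians)."""

    translations: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape[1] != 3 or self.rotations.shape[1] != 3:
            raise ValueError("translations and rotations must each have 3 columns")
        if self.translations.shape[0] != self.rotations.shape[0]:
            raise ValueError("translations and rotations must have equal volume counts")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]


@dataclass
class ConnectivityVector:
    """Lower-triangle Fisher-z connectivity values with a fixed pair index.

    ``values[k]`` is atanh(r) for the region pair ``index_to_pair(k)`` under
    the row-major ``(i, j), i > j`` 0-based convention.
    """

    values: np.ndarray
    n_regions: int
    pair_index_convention: str = field(default=PAIR_CONVENTION)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        expected = lower_triangle_size(self.n_regions)
        if self.values.size != expected:
            raise ValueError(
                f"connectivity vector has {self.values.size} entries; "
                f"{self.n_regions} regions require {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity vector contains non-finite values")


def lower_triangle_size(n_regions: int) -> int:
    """Number of unordered region pairs, ``R(R-1)/2``."""
    if not float(n_regions).is_integer() or n_regions < 1:
        raise ValueError("n_regions must be a positive integer")
    n_regions = int(n_regions)
    return n_regions * (n_regions - 1) // 2


def pair_to_index(i: int, j: int) -> int:
    """Map region pair (i, j), i > j >= 0, to its lower-triangle index."""
    if not (i > j >= 0):
        raise ValueError("require i > j >= 0")
    return i * (i - 1) // 2 + j


def index_to_pair(k: int) -> tuple[int, int]:
    """Inverse of :func:`pair_to_index`."""
    if k < 0:
        raise ValueError("index must be non-negative")
    i = int((1 + np.sqrt(1 + 8 * k)) // 2)
    j = k - i * (i - 1) // 2
    return i, j


def bandpass_filter(ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> RoiTimeSeries:
    """Zero-phase first-order Butterworth band-pass, per region.

    The conventional resting-state pass band of 0.01-0.08 Hz is the default.
    Forward-backward application (``filtfilt``) avoids phase lag, so each
    edge of the band is effectively applied twice.
    """
    nyquist = 0.5 / ts.sampling_interval
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"pass band ({low_hz}, {high_hz}) Hz must lie strictly inside (0, {nyquist}) Hz"
        )
    b, a = signal.butter(1, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.sampling_interval)
    filtered = signal.filtfilt(b, a, ts.values, axis=0)
    return replace(ts, values=filtered)


def framewise_displacement(motion: MotionParams, rotation_radius_mm: float = 50.0) -> np.ndarray:
    """Per-volume framewise displacement in millimetres.

    FD[t] sums the absolute backward differences of the three translations
    plus the rotation differences converted to arc length on a sphere of
    ``rotation_radius_mm`` (Power-style, 50 mm default).  FD of the first
    volume is defined as 0.
    """
    if rotation_radius_mm <= 0:
        raise ValueError("rotation_radius_mm must be positive")
    fd = np.zeros(motion.n_volumes)
    if motion.n_volumes > 1:
        dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
        dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
        fd[1:] = dt + rotation_radius_mm * dr
    return fd


def scrub(ts: RoiTimeSeries, fd: np.ndarray, fd_threshold: float = 0.5) -> tuple[RoiTimeSeries, float]:
    """Remove volumes with FD strictly above the threshold.

    Returns the censored series and the fraction of volumes removed.
    Raises if scrubbing would remove every volume.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (ts.n_volumes,):
        raise ValueError("FD length must equal the volume count")
    keep = fd <= fd_threshold
    excluded_fraction = float((~keep).sum()) / ts.n_volumes
    if not keep.any():
        raise ValueError("scrubbing removed every volume")
    return replace(ts, values=ts.values[keep]), excluded_fraction


def exclude_high_motion_participants(excluded_fractions: np.ndarray) -> np.ndarray:
    """Inclusion mask: drop participants whose scrubbed fraction exceeds mean + 3 SD.

    The mean and (population) SD are computed over all participants before
    any exclusion; a participant is excluded iff strictly above the cut.
    """
    fr = np.asarray(excluded_fractions, dtype=float)
    if fr.size < 2:
        raise ValueError("need at least 2 participants")
    cut = fr.mean() + 3.0 * fr.std()
    return fr <= cut


def regress_nuisance(ts: RoiTimeSeries, regressors: np.ndarray) -> RoiTimeSeries:
    """Project a pre-supplied nuisance regressor matrix out of each region.

    ``regressors`` is ``volumes x k`` (e.g. 6 motion parameters + aCompCor
    components); an intercept column is always appended.  Residuals are
    returned as a new time series.
    """
    reg = np.atleast_2d(np.asarray(regressors, dtype=float))
    if reg.shape[0] != ts.n_volumes:
        raise ValueError("regressor rows must equal the volume count")
    design = np.column_stack([reg, np.ones(ts.n_volumes)])
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return replace(ts, values=ts.values - design @ beta)


def compute_connectivity(ts: RoiTimeSeries, clip_eps: float = 1e-7) -> ConnectivityVector:
    """Fisher-z transformed Pearson correlations over the lower triangle.

    Correlations of exactly +/-1 are clipped to +/-(1 - clip_eps) before
    atanh so the output stays finite.  A region with zero variance is a
    hard error (its correlations are undefined).
    """
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes to estimate correlations")
    sd = ts.values.std(axis=0)
    scale = np.maximum(np.abs(ts.values).max(axis=0), 1.0)
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(r, -1.0 + clip_eps, 1.0 - clip_eps)
    z = np.arctanh(r)
    return ConnectivityVector(values=matrix_to_vector(z), n_regions=ts.n_regions)


def matrix_to_vector(mat: np.ndarray) -> np.ndarray:
    """Extract the strict lower triangle row-major: (1,0),(2,0),(2,1),..."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j].copy()


def vector_to_matrix(vec: np.ndarray, n_regions: int, diagonal: float = 0.0) -> np.ndarray:
    """Rebuild the symmetric matrix from a lower-triangle vector."""
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != lower_triangle_size(n_regions):
        raise ValueError("vector length inconsistent with n_regions")
    mat = np.full((n_regions, n_regions), float(diagonal))
    i, j = np.tril_indices(n_regions, k=-1)
    mat[i, j] = vec
    mat[j, i] = vec
    return mat
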