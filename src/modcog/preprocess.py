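"""Frame censoring, filtering and nuisance regression on node time series.

Implements the motion-scrubbing convention in which per-frame head motion is
summarized as framewise displacement (FD: sum of absolute backward differences
of the six rigid-body parameters, rotations converted to arc length on a
50 mm sphere) and per-frame signal change as DVARS (root-mean-square of the
temporal derivative, as percent of the mode-1000 rescaled grand mean).
Frames exceeding either threshold are flagged, flags are dilated one frame
back and two forward, and the two dilated masks are intersected to give the
final set of censored frames.

All operators are deterministic and frames are 0-based throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = [
    "NodeTimeSeries",
    "MotionParams",
    "TemporalMask",
    "compute_fd",
    "compute_dvars",
    "build_temporal_mask",
    "bandpass",
    "bandpass_array",
    "nuisance_regress",
    "censor",
]


@dataclass
class NodeTimeSeries:
    """A frames x nodes signal matrix with its sampling interval.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_nodes)
        Node-level signal, one column per parcel.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    node_ids : sequence of str, optional
        Ordered node labels; defaults to ``n000 .. n<k>``.
    """

    values: np.ndarray
    tr_seconds: float
    node_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise FormatError("time series must be a 2-D frames x nodes array")
        if self.values.shape[0] < 2:
            raise FormatError("time series needs at least 2 frames")
        if not np.isfinite(self.values).all():
            raise FormatError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        if self.node_ids is None:
            self.node_ids = [f"n{i:03d}" for i in range(self.values.shape[1])]
        else:
            self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) != self.values.shape[1]:
            raise FormatError("node_ids length does not match number of columns")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise FormatError("node_ids must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "NodeTimeSeries":
        return NodeTimeSeries(values, self.tr_seconds, list(self.node_ids))


@dataclass
class MotionParams:
    """Frames x 6 rigid-body motion trace.

    Columns are three translations in mm followed by three rotations in
    radians: (trans_x, trans_y, trans_z, rot_x, rot_y, rot_z).
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise FormatError(
                "motion parameters must be a frames x 6 array "
                f"(got shape {self.values.shape})"
            )
        if not np.isfinite(self.values).all():
            raise FormatError("motion parameters contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class TemporalMask:
    """Per-frame keep/censor decision with the criterion masks that led to it.

    ``kept`` is the boolean complement of ``flagged_final``; the three flag
    sets record 0-based frame indices.
    """

    kept: np.ndarray
    flagged_fd: frozenset
    flagged_dvars: frozenset
    flagged_final: frozenset

    def __post_init__(self):
        self.kept = np.asarray(self.kept, dtype=bool)
        n = self.kept.size
        expected = np.ones(n, dtype=bool)
        expected[sorted(self.flagged_final)] = False
        if not np.array_equal(self.kept, expected):
            raise FormatError("kept must be the complement of flagged_final")

    @property
    def n_frames(self) -> int:
        return self.kept.size

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept)


def compute_fd(motion: MotionParams, sphere_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement in mm.

    FD(0) = 0 and FD(t) is the sum of absolute backward differences of the
    three translations plus ``sphere_radius_mm`` times the sum of absolute
    backward differences of the three rotations (radians converted to arc
    length). The later frame of each frame pair carries the flag.
    """
    if motion.n_frames < 2:
        raise FormatError("need at least 2 frames to compute FD")
    if sphere_radius_mm <= 0:
        raise ParameterError("sphere_radius_mm must be positive")
    d = np.diff(motion.values, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + sphere_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_dvars(ts: NodeTimeSeries, scale_to_mode: float = 1000.0) -> np.ndarray:
    """DVARS as percent signal change after mode-1000-style rescaling.

    The series is rescaled so its grand mean equals ``scale_to_mode``;
    DVARS(t) is the root-mean-square over nodes of the frame-to-frame
    difference, expressed as percent of ``scale_to_mode`` (so the statistic
    is invariant to rescaling the raw signal). DVARS(0) = 0.
    """
    if scale_to_mode <= 0:
        raise ParameterError("scale_to_mode must be positive")
    x = ts.values
    grand_mean = x.mean()
    scale = np.abs(grand_mean)
    if scale <= 1e-12 * max(1.0, np.abs(x).max(initial=0.0)):
        raise DegenerateInputError(
            "grand mean of the series is (near) zero; DVARS rescaling undefined "
            "— compute DVARS before mean removal"
        )
    d = np.diff(x, axis=0)
    rms = np.sqrt((d**2).mean(axis=1))
    dvars = 100.0 * rms / scale
    return np.concatenate([[0.0], dvars])


def _augment(flags: np.ndarray, n: int, back: int, fwd: int) -> set:
    out: set = set()
    for t in np.flatnonzero(flags):
        lo = max(0, t - back)
        hi = min(n - 1, t + fwd)
        out.update(range(lo, hi + 1))
    return out


def build_temporal_mask(
    fd: np.ndarray,
    dvars: np.ndarray,
    fd_thresh_mm: float = 0.5,
    dvars_thresh_pct: float = 0.5,
    augment_back: int = 1,
    augment_fwd: int = 2,
    combine: str = "intersection",
    augment_before_combine: bool = True,
) -> TemporalMask:
    """Combine FD and DVARS exceedances into a final censoring mask.

    Each criterion flags frames above its threshold; flags are dilated
    ``augment_back`` frames back and ``augment_fwd`` forward (clipped to the
    valid range), then the two dilated masks are intersected (default) or
    unioned. ``augment_before_combine=False`` combines the raw masks first
    and dilates the result, for sensitivity analysis.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape or fd.ndim != 1:
        raise FormatError("fd and dvars must be 1-D arrays of equal length")
    if fd_thresh_mm <= 0 or dvars_thresh_pct <= 0:
        raise ParameterError("censoring thresholds must be positive")
    if combine not in ("intersection", "union"):
        raise ParameterError("combine must be 'intersection' or 'union'")
    n = fd.size
    raw_fd = fd > fd_thresh_mm
    raw_dv = dvars > dvars_thresh_pct
    if augment_before_combine:
        set_fd = _augment(raw_fd, n, augment_back, augment_fwd)
        set_dv = _augment(raw_dv, n, augment_back, augment_fwd)
        final = set_fd & set_dv if combine == "intersection" else set_fd | set_dv
    else:
        set_fd = set(np.flatnonzero(raw_fd))
        set_dv = set(np.flatnonzero(raw_dv))
        raw = set_fd & set_dv if combine == "intersection" else set_fd | set_dv
        ind = np.zeros(n, dtype=bool)
        ind[sorted(raw)] = True
        final = _augment(ind, n, augment_back, augment_fwd)
        set_fd = _augment(raw_fd, n, augment_back, augment_fwd)
        set_dv = _augment(raw_dv, n, augment_back, augment_fwd)
    kept = np.ones(n, dtype=bool)
    kept[sorted(final)] = False
    return TemporalMask(
        kept=kept,
        flagged_fd=frozenset(set_fd),
        flagged_dvars=frozenset(set_dv),
        flagged_final=frozenset(final),
    )


def bandpass_array(
    values: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
    transition_hz: float = 0.002,
) -> np.ndarray:
    """Zero-phase frequency-domain bandpass of a frames x k array.

    The frequency response is 1 inside [low_hz, high_hz], falls to 0 over a
    raised-cosine transition of width ``transition_hz`` outside each edge,
    and the DC (0 Hz) component is removed exactly.
    """
    values = np.asarray(values, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not (0 <= low_hz < high_hz):
        raise ParameterError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ParameterError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    n = values.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    resp = np.zeros_like(freqs)
    w = transition_hz
    lo_start = max(low_hz - w, 0.0)
    # rising edge
    rising = (freqs >= lo_start) & (freqs < low_hz)
    if low_hz > lo_start:
        resp[rising] = 0.5 * (1 - np.cos(np.pi * (freqs[rising] - lo_start) / (low_hz - lo_start)))
    resp[(freqs >= low_hz) & (freqs <= high_hz)] = 1.0
    falling = (freqs > high_hz) & (freqs <= high_hz + w)
    resp[falling] = 0.5 * (1 + np.cos(np.pi * (freqs[falling] - high_hz) / w))
    resp[0] = 0.0  # exact mean removal
    spec = np.fft.rfft(values, axis=0)
    return np.fft.irfft(spec * resp[:, None], n=n, axis=0)


def bandpass(
    ts: NodeTimeSeries,
    low_hz: float = 0.008,
    high_hz: float = 0.1,
    transition_hz: float = 0.002,
) -> NodeTimeSeries:
    """Bandpass-filter a node time series (see :func:`bandpass_array`)."""
    return ts.with_values(
        bandpass_array(ts.values, ts.tr_seconds, low_hz, high_hz, transition_hz)
    )


def nuisance_regress(ts: NodeTimeSeries, regressors: np.ndarray) -> NodeTimeSeries:
    """Residualize every node signal on a set of nuisance regressors.

    An intercept column is always included, so residuals are orthogonal to
    each regressor and mean-free. Collinear columns are dropped (with a
    warning) before solving the least-squares problem.
    """
    R = np.asarray(regressors, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if R.shape[0] != ts.n_frames:
        raise FormatError("regressors must have one row per frame")
    if R.shape[1] >= ts.n_frames:
        raise ParameterError("need fewer regressors than frames")
    X = np.column_stack([np.ones(ts.n_frames), R])
    # drop collinear columns via pivoted QR on the scaled design
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    from scipy.linalg import qr

    _, r, piv = qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    keep = np.sort(piv[: int((diag > tol).sum())])
    if keep.size < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(keep.tolist()))
        warnings.warn(
            f"nuisance design is rank deficient; dropping columns {dropped} "
            "(0 = intercept)",
            stacklevel=2,
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    resid = ts.values - X @ beta
    return ts.with_values(resid)


def censor(ts: NodeTimeSeries, mask: TemporalMask) -> NodeTimeSeries:
    """Remove censored frames. Frames are dropped in place, never interpolated."""
    if mask.n_frames != ts.n_frames:
        raise FormatError("mask and time series frame counts differ")
    if mask.n_kept < 2:
        raise DegenerateInputError("fewer than 2 frames survive censoring")
    return ts.with_values(ts.values[mask.kept])
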