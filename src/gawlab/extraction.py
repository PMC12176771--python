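"""Glottis mask stacks to glottal area waveforms (GAWs) and phonation cycles.

The processing chain mirrors the standard high-speed videoendoscopy (HSV)
workflow: per-frame glottis segmentation, a static PCA midline splitting the
glottal area into left and right vocal-fold contributions, per-frame area
summation into total/partial GAWs, trimming to a fixed analysis duration, and
minimum-to-minimum phonation-cycle segmentation driven by a global
fundamental-frequency estimate.

Coordinates are the row-major pixel grid with origin at the top-left corner;
areas are in px^2 (no physical calibration — downstream features are
calibration-free ratios or reported in arbitrary units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from skimage import measure as _measure

__all__ = [
    "MaskStack",
    "GAWRecord",
    "Midline",
    "CycleSegmentation",
    "DegenerateMidlineError",
    "InsufficientPhonationError",
    "NoPeriodicityError",
    "segment_frame",
    "compute_midline",
    "split_areas",
    "assemble_gaws",
    "trim_recording",
    "detect_cycles",
]


class DegenerateMidlineError(ValueError):
    """Raised when PCA cannot define a glottal midline (too few pixels or
    isotropic pixel cloud)."""


class InsufficientPhonationError(ValueError):
    """Raised when a recording is shorter than the requested analysis window."""


class NoPeriodicityError(ValueError):
    """Raised when no autocorrelation peak exists in the F0 search range."""


@dataclass
class MaskStack:
    """Ordered stack of binary glottis masks at a fixed frame rate.

    Parameters
    ----------
    frames : ndarray of bool, shape (N, height, width)
        One binary glottis mask per video frame.
    fs : float
        Frame rate in Hz (nominally 4000 for HSV).
    """

    frames: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (N, height, width) stack with N >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class GAWRecord:
    """Total and partial (left/right) glottal area waveforms.

    ``total[n]`` is the glottal area of frame ``n`` in px^2; ``left`` and
    ``right`` are the areas on either side of the glottal midline and sum to
    the total up to pixel rounding.
    """

    total: np.ndarray
    left: np.ndarray
    right: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if not (len(self.total) == len(self.left) == len(self.right)):
            raise ValueError("total/left/right must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.total)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Midline:
    """Static glottal midline: an anchor point and a unit direction vector,
    both in (row, col) pixel coordinates."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValueError("direction must be a nonzero vector")
        self.direction = self.direction / nrm


@dataclass
class CycleSegmentation:
    """Phonation cycles delimited minimum-to-minimum.

    ``boundaries`` are sample indices into the GAW (strictly increasing,
    ``n_cycles + 1`` of them); ``periods`` are in seconds and
    ``peak_amplitudes`` are per-cycle (max - min) areas in px^2.
    """

    boundaries: np.ndarray
    fs: float
    periods: np.ndarray = field(default=None)  # type: ignore[assignment]
    peak_amplitudes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if len(self.boundaries) < 2 or np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing with >= 2 entries")
        if self.periods is None:
            self.periods = np.diff(self.boundaries) / self.fs
        else:
            self.periods = np.asarray(self.periods, dtype=float)
        if self.peak_amplitudes is not None:
            self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    def slices(self):
        """Iterate ``slice`` objects, one per cycle."""
        for i in range(self.n_cycles):
            yield slice(self.boundaries[i], self.boundaries[i + 1])


def segment_frame(frame: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a grayscale frame and keep the largest connected component.

    Stands in for a learned glottis segmenter on synthetic frames: pixels above
    ``threshold * max(frame)`` are marked glottal.  An empty frame yields an
    empty mask (not an error).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    frame = np.asarray(frame)
    peak = frame.max() if frame.size else 0
    if peak <= 0:
        return np.zeros(frame.shape, dtype=bool)
    mask = frame > threshold * peak
    labels = _measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros(frame.shape, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def compute_midline(stack: MaskStack) -> Midline:
    """PCA midline of the pooled glottal pixels across all frames.

    The anchor is the centroid and the direction the first principal axis of
    the pooled (row, col) coordinates.  Degenerate clouds (fewer than three
    pixels, or an isotropic covariance where no principal axis is defined)
    raise :class:`DegenerateMidlineError`.
    """
    coords = np.argwhere(stack.frames)[:, 1:]  # (row, col) pooled over frames
    if len(coords) == 0:
        raise DegenerateMidlineError("no glottal area detected")
    if len(coords) <= 2:
        raise DegenerateMidlineError("too few glottal pixels for PCA midline")
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending eigenvalues; principal axis is the last column
    if evals[1] <= 0 or (evals[1] - evals[0]) / evals[1] < 1e-9:
        raise DegenerateMidlineError("isotropic pixel cloud: midline undefined")
    direction = evecs[:, 1]
    # canonical sign: first nonzero component positive
    lead = direction[np.nonzero(direction)[0][0]]
    if lead < 0:
        direction = -direction
    return Midline(point=centroid, direction=direction)


def split_areas(mask: np.ndarray, midline: Midline) -> tuple[int, int]:
    """Split a binary mask's pixel count into (left, right) of the midline.

    Each glottal pixel is assigned by the sign of its signed perpendicular
    distance to the midline; pixels exactly on the line alternate sides by
    parity of their scan order, which keeps ``left + right`` equal to the
    total pixel count exactly.  Flipping the midline direction swaps the two
    outputs exactly.
    """
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    if len(coords) == 0:
        return 0, 0
    d = midline.direction
    normal = np.array([d[1], -d[0]])
    offset = (coords - midline.point) @ normal
    tol = 1e-9
    left = int(np.sum(offset > tol))
    right = int(np.sum(offset < -tol))
    n_on = len(coords) - left - right
    # alternate on-line pixels: even scan positions left, odd right
    left += (n_on + 1) // 2
    right += n_on // 2
    return left, right


def assemble_gaws(stack: MaskStack) -> GAWRecord:
    """Per-frame total/left/right areas concatenated into a GAWRecord.

    The midline is static (pooled over frames): a single anatomical axis that
    stabilizes the partial GAWs.  Empty frames contribute zeros.
    """
    midline = compute_midline(stack)
    n = stack.n_frames
    total = np.zeros(n)
    left = np.zeros(n)
    right = np.zeros(n)
    for i in range(n):
        frame = stack.frames[i]
        total[i] = frame.sum()
        left[i], right[i] = split_areas(frame, midline)
    return GAWRecord(total=total, left=left, right=right, fs=stack.fs)


def trim_recording(
    gaw: GAWRecord, duration_s: float = 0.25, onset_skip_s: float = 0.1
) -> GAWRecord:
    """Trim a GAW to a fixed duration of sustained phonation.

    The analysis window is 250 ms by default (1,000 frames at 4 kHz), the
    clinical minimum for >= 20 phonation cycles at habitual pitch.  The first
    ``onset_skip_s`` of phonation onset is skipped when the recording is long
    enough, otherwise trimming starts at sample 0.
    """
    n = int(round(duration_s * gaw.fs))
    if gaw.n_samples < n:
        raise InsufficientPhonationError(
            f"insufficient phonation: {gaw.n_samples} samples < {n} required"
        )
    skip = int(round(onset_skip_s * gaw.fs))
    start = skip if gaw.n_samples >= n + skip else 0
    sl = slice(start, start + n)
    return GAWRecord(
        total=gaw.total[sl], left=gaw.left[sl], right=gaw.right[sl], fs=gaw.fs
    )


def _first_min_index(seg: np.ndarray) -> int:
    """First index attaining the segment minimum (start of a closure plateau)."""
    m = seg.min()
    eps = 1e-12 * max(1.0, float(np.ptp(seg)))
    return int(np.flatnonzero(seg <= m + eps)[0])


def detect_cycles(
    gaw: GAWRecord, f0_range: tuple[float, float] = (50.0, 500.0)
) -> CycleSegmentation:
    """Segment a GAW into phonation cycles via fundamental-frequency analysis.

    A global F0 is estimated from the autocorrelation peak of the mean-removed
    total GAW within ``f0_range``; cycle boundaries are then located at signal
    minima between successive oscillation peaks (minimum-to-minimum
    convention — closure instants are the sharpest landmarks of a GAW), with
    edge minima before the first and after the last peak included so the
    leading and trailing cycles are kept.
    """
    x = gaw.total - gaw.total.mean()
    n = len(x)
    if np.allclose(x, 0):
        raise NoPeriodicityError("constant signal: no periodicity detected")
    f_lo, f_hi = f0_range
    if not 0 < f_lo < f_hi or f_hi > gaw.fs / 2:
        raise ValueError("f0_range must satisfy 0 < lo < hi <= fs/2")
    lag_min = max(2, int(np.ceil(gaw.fs / f_hi)))
    lag_max = min(n - 2, int(np.floor(gaw.fs / f_lo)))
    if lag_min >= lag_max:
        raise NoPeriodicityError("signal too short for the F0 search range")
    ac = _sig.correlate(x, x, mode="full")[n - 1 :]
    band = ac[lag_min : lag_max + 1]
    peaks, _ = _sig.find_peaks(band)
    if len(peaks) == 0 or band.max() <= 0:
        raise NoPeriodicityError("no periodicity detected in the F0 search range")
    t0 = lag_min + peaks[np.argmax(band[peaks])]  # period in samples

    # oscillation peaks: located on a lightly smoothed copy, at least 0.6
    # periods apart (tolerates +-40% boundary drift) and above mid-range so
    # noise bumps on the closed-phase plateau are not mistaken for cycles
    w = max(1, int(t0 // 8))
    smooth = np.convolve(gaw.total, np.ones(w) / w, mode="same") if w > 1 else gaw.total
    height = smooth.min() + 0.4 * np.ptp(smooth)
    pk, _ = _sig.find_peaks(smooth, distance=max(1, int(0.6 * t0)), height=height)
    if len(pk) < 2:
        raise NoPeriodicityError("fewer than two oscillation peaks detected")

    boundaries = []
    lead = gaw.total[: pk[0] + 1]
    if len(lead) > 1:
        boundaries.append(_first_min_index(lead))
    for a, b in zip(pk[:-1], pk[1:]):
        boundaries.append(a + _first_min_index(gaw.total[a : b + 1]))
    tail = gaw.total[pk[-1] :]
    if len(tail) > 1:
        m = tail.min()
        eps = 1e-12 * max(1.0, float(np.ptp(tail)))
        idx_last = int(np.flatnonzero(tail <= m + eps)[-1])
        if idx_last == len(tail) - 1:
            # still falling at the record end: the closure instant is the
            # (exclusive) end of the signal, keeping the last cycle complete
            boundaries.append(n)
        else:
            boundaries.append(pk[-1] + idx_last)
    boundaries = np.unique(np.asarray(boundaries, dtype=int))
    if len(boundaries) < 2:
        raise NoPeriodicityError("could not place cycle boundaries")

    periods = np.diff(boundaries) / gaw.fs
    amps = np.array(
        [
            gaw.total[boundaries[i] : boundaries[i + 1]].max()
            - gaw.total[boundaries[i] : boundaries[i + 1]].min()
            for i in range(len(boundaries) - 1)
        ]
    )
    return CycleSegmentation(
        boundaries=boundaries, fs=gaw.fs, periods=periods, peak_amplitudes=amps
    )
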