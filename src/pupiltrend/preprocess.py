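"""Blink handling for continuous pupil recordings.

Raw eye-tracker output contains stretches where the pupil is partially or
fully occluded by the eyelid.  During a blink the measured diameter drops
to zero (or is flagged invalid by the tracker), and the samples immediately
flanking the closure are contaminated by the lid sweeping across the pupil.
This module finds those stretches, pads them with a safety margin, and
replaces them by linear interpolation so that downstream window averages
and wavelet transforms see a gap-free series.

The blink detector is deliberately simple and noise-robust: the core of a
blink is any run of invalid / non-positive / missing samples; the run is
then grown outwards while the sample-to-sample difference is implausibly
large compared with the robust (MAD-based) noise level of the whole trace,
which captures the fast partial-occlusion flanks.  A fixed margin
(default 200 ms) is added on both sides before merging overlapping
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PupilRecording",
    "BlinkSegment",
    "CleanSeries",
    "EyeUnusableError",
    "detect_blinks",
    "interpolate_blinks",
    "interpolated_fraction",
    "read_samples",
    "write_samples",
]

#: Default margin (ms) excluded before and after each detected blink.
DEFAULT_MARGIN_MS = 200.0

#: Default multiplier on the MAD of first differences used to grow blink
#: runs into their high-noise flanks.
DEFAULT_FLANK_K = 5.0


class EyeUnusableError(ValueError):
    """Raised when one eye has no valid samples at all (e.g. a participant
    whose eyelid covered the pupil throughout the task)."""


@dataclass
class PupilRecording:
    """One session of binocular pupil-diameter samples.

    Timestamps are in milliseconds, strictly increasing with a constant
    step of ``1000 / sample_rate``.  Diameters are in the tracker's
    arbitrary pixel units; invalid samples are never used directly in any
    downstream statistic.
    """

    participant_id: str
    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.valid_left = np.asarray(self.valid_left, dtype=bool)
        self.valid_right = np.asarray(self.valid_right, dtype=bool)
        n = self.t.size
        for name in ("left", "right", "valid_left", "valid_right"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} != t length {n}")
        if n >= 2:
            steps = np.diff(self.t)
            expected = 1000.0 / self.sample_rate
            if not np.allclose(steps, expected, rtol=0, atol=1e-6 * expected + 1e-9):
                raise ValueError("timestamps are not uniformly spaced at the stated sample rate")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0])

    def eye(self, eye: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(diameter, valid)`` for ``eye`` in {'left', 'right'}."""
        if eye == "left":
            return self.left, self.valid_left
        if eye == "right":
            return self.right, self.valid_right
        raise ValueError(f"unknown eye label {eye!r}; expected 'left' or 'right'")


@dataclass(frozen=True)
class BlinkSegment:
    """Closed interval [t_start, t_end] (ms) of samples excluded around a blink.

    Margins are already applied; segments for one eye are non-overlapping
    after merging.
    """

    t_start: float
    t_end: float
    eye: str

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ValueError("t_start must not exceed t_end")


@dataclass
class CleanSeries:
    """A gap-free single-eye diameter series after blink interpolation.

    ``value`` equals the raw sample exactly wherever ``interpolated`` is
    False; inside each interpolated gap the values lie on the straight line
    between the flanking valid samples (constant at the recording edges).
    """

    t: np.ndarray
    value: np.ndarray
    interpolated: np.ndarray
    sample_rate: float = 1000.0
    eye: str = "left"
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if not (self.t.size == self.value.size == self.interpolated.size):
            raise ValueError("t, value and interpolated must have equal length")
        if np.any(~np.isfinite(self.value)):
            raise ValueError("CleanSeries must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.t.size


def _invalid_mask(diam: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Samples that form the core of a blink: flagged invalid, non-positive,
    or missing diameter."""
    return (~valid) | ~np.isfinite(diam) | (diam <= 0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of True runs in a boolean mask."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2] - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_blinks(
    recording: PupilRecording,
    eye: str,
    margin_ms: float = DEFAULT_MARGIN_MS,
    flank_k: float = DEFAULT_FLANK_K,
) -> list[BlinkSegment]:
    """Detect blink segments for one eye.

    Core blinks are runs of invalid / non-positive / missing samples; each
    run is extended outwards while the absolute first difference of the
    trace exceeds ``flank_k`` times the MAD of first differences over the
    whole eye trace (the "noise-robust" flank rule).  A margin of
    ``margin_ms`` is then applied on both sides, segments are clamped to
    the recording bounds, and overlapping segments are merged.

    Returns an empty list for a fully valid trace.
    """
    diam, valid = recording.eye(eye)
    core = _invalid_mask(diam, valid)
    runs = _runs(core)
    if not runs:
        return []

    # Robust noise scale of sample-to-sample changes, over valid stretches.
    diffs = np.abs(np.diff(diam))
    ok = np.isfinite(diffs) & ~core[:-1] & ~core[1:]
    mad = float(np.median(np.abs(diffs[ok] - np.median(diffs[ok])))) if ok.any() else 0.0
    thresh = flank_k * mad if mad > 0 else np.inf

    n = recording.n_samples
    extended: list[tuple[int, int]] = []
    for a, b in runs:
        # Grow outwards over the partial-occlusion flanks: absorb the next
        # sample outside the run while its step from *its* outer neighbour
        # is implausibly large.  Steps into the invalid run itself are not
        # informative (the run is zeros/NaNs) and are never tested.
        while a >= 2 and abs(diam[a - 1] - diam[a - 2]) > thresh:
            a -= 1
        while b <= n - 3 and abs(diam[b + 2] - diam[b + 1]) > thresh:
            b += 1
        extended.append((a, b))

    t0, t_end = recording.t[0], recording.t[-1]
    intervals = [
        (max(t0, recording.t[a] - margin_ms), min(t_end, recording.t[b] + margin_ms))
        for a, b in extended
    ]
    intervals.sort()
    merged: list[list[float]] = []
    for lo, hi in intervals:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [BlinkSegment(lo, hi, eye) for lo, hi in merged]


def interpolate_blinks(
    recording: PupilRecording,
    segments: list[BlinkSegment],
    eye: str,
) -> CleanSeries:
    """Replace samples inside blink segments by linear interpolation.

    Interpolation anchors are the nearest samples outside any segment;
    gaps touching a recording edge are filled with the nearest retained
    value (constant extension).  Samples outside segments are untouched.

    Raises
    ------
    EyeUnusableError
        If no sample of this eye survives outside the blink segments.
    """
    diam, valid = recording.eye(eye)
    t = recording.t
    bad = np.zeros(recording.n_samples, dtype=bool)
    for seg in segments:
        if seg.eye not in (eye, "both"):
            raise ValueError(f"segment for eye {seg.eye!r} passed to interpolation of {eye!r}")
        bad |= (t >= seg.t_start) & (t <= seg.t_end)
    # Any residual invalid sample not covered by a segment is also replaced:
    # downstream statistics must never touch invalid raw values.
    bad |= _invalid_mask(diam, valid)

    good = ~bad
    if not good.any():
        raise EyeUnusableError(
            f"eye {eye!r} of participant {recording.participant_id!r} has no valid samples"
        )
    value = diam.astype(float).copy()
    value[bad] = np.interp(t[bad], t[good], diam[good])
    return CleanSeries(
        t=t.copy(),
        value=value,
        interpolated=bad,
        sample_rate=recording.sample_rate,
        eye=eye,
        participant_id=recording.participant_id,
    )


def interpolated_fraction(
    series: CleanSeries, t_center: float, half_span_ms: float
) -> tuple[float, bool]:
    """Share of samples flagged interpolated in [t_center - half_span, t_center + half_span].

    Returns ``(fraction, complete)`` where ``complete`` is False when the
    window had to be truncated at a recording edge.

    Raises
    ------
    ValueError
        If the window lies entirely outside the recording.
    """
    lo, hi = t_center - half_span_ms, t_center + half_span_ms
    if hi < series.t[0] or lo > series.t[-1]:
        raise ValueError("window entirely outside recording: no data")
    inside = (series.t >= lo) & (series.t <= hi)
    complete = bool(lo >= series.t[0] and hi <= series.t[-1])
    frac = float(series.interpolated[inside].mean())
    return frac, complete


# ---------------------------------------------------------------------------
# Samples file I/O: delimited text with columns
# t_ms, left_px, right_px, valid_left, valid_right
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["t_ms", "left_px", "right_px", "valid_left", "valid_right"]


def read_samples(path, participant_id: str | None = None, sample_rate: float | None = None) -> PupilRecording:
    """Read a delimited samples table into a :class:`PupilRecording`.

    Missing diameters may be empty fields or 0; both are treated as invalid
    by the blink detector.  The sample rate is inferred from the timestamp
    step when not given.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"samples file {path} missing columns {missing}")
    t = df["t_ms"].to_numpy(dtype=float)
    if sample_rate is None:
        if t.size < 2:
            raise ValueError("cannot infer sample rate from fewer than 2 samples")
        sample_rate = 1000.0 / float(np.median(np.diff(t)))
    return PupilRecording(
        participant_id=participant_id or str(path),
        t=t,
        left=df["left_px"].to_numpy(dtype=float),
        right=df["right_px"].to_numpy(dtype=float),
        valid_left=df["valid_left"].to_numpy().astype(bool),
        valid_right=df["valid_right"].to_numpy().astype(bool),
        sample_rate=sample_rate,
    )


def write_samples(recording: PupilRecording, path) -> None:
    df = pd.DataFrame(
        {
            "t_ms": recording.t,
            "left_px": recording.left,
            "right_px": recording.right,
            "valid_left": recording.valid_left.astype(int),
            "valid_right": recording.valid_right.astype(int),
        }
    )
    df.to_csv(path, index=False)
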