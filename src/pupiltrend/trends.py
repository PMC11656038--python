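"""Pupil trend indices: smoothed, conservative, and wavelet-decomposed.

A "pupil trend" is the signed change in pupil diameter over a window
centered on a task event, computed from a blink-interpolated series.
Because every index is a *difference* of slowly varying summaries, the
trends are insensitive to the absolute pupil size and to fast
luminance-driven transients, which makes them usable as tonic-alertness
markers in tasks whose stimuli themselves move the pupil.

Three families are provided:

``smoothed``
    Difference of the centered moving average evaluated half a window
    after vs half a window before the event; equivalently, the mean
    diameter over [t0, t0+w] minus the mean over [t0-w, t0]
    (w = 5, 10 or 15 s by default).

``conservative``
    A 14 s-span variant using 10 s windows: mean over [t0+2 s, t0+12 s]
    minus mean over [t0-12 s, t0-2 s].  By construction it is exactly
    immune to any signal confined to +/-2 s of the event, i.e. to the
    phasic, event-locked response.

``decomposed``
    Two-point difference (+/- scale/2) read from one dyadic-scale
    component of a shift-invariant Symlet-4 multiresolution analysis.
    A decimated DWT is not translation invariant, which would corrupt
    per-event readouts, so the stationary (maximal-overlap) transform is
    used; any backend must satisfy the additive reconstruction invariant
    checked by the test suite.

Sample-index convention: a time t maps to index round((t - t[0]) * rate);
window means use inclusive index ranges on both ends.  The oracle tests
use the identical convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import CleanSeries

__all__ = [
    "TrendValue",
    "MRAComponents",
    "moving_average",
    "smoothed_trend",
    "conservative_trend",
    "mra_decompose",
    "decomposed_trend",
    "binocular_trend",
    "px_to_mm",
    "TrendExtractor",
    "DEFAULT_WINDOWS_S",
    "DEFAULT_SCALES_MS",
]

DEFAULT_WINDOWS_S = (5.0, 10.0, 15.0)
DEFAULT_SCALES_MS = (4096, 8192, 16384, 32768)
DEFAULT_WAVELET = "sym4"
#: A trend is rejected when more than this share of either flanking
#: window had to be blink-interpolated.
DEFAULT_MAX_INTERP_FRAC = 0.5

QUALITY_COMPLETE = "complete"
QUALITY_INCOMPLETE = "incomplete"
QUALITY_REJECTED = "rejected"


@dataclass
class TrendValue:
    """One trend index for one trial, eye and method/scale.

    ``value_px`` is the signed diameter change in pixels (positive =
    dilation across the event-centered window); it is finite whenever
    ``quality == "complete"``.  ``monocular`` marks binocular values that
    could be computed from only one eye.
    """

    trial_id: object
    method: str
    scale_ms: float
    value_px: float
    eye: str
    quality: str
    monocular: bool = False


@dataclass
class MRAComponents:
    """Additive multiresolution decomposition of one clean series.

    ``approximation`` holds the coarsest-scale component at absolute
    diameter level; ``details`` maps a dyadic scale label (ms) to the
    zero-centred detail series at that scale.  The label 2^j * dt (dt =
    sample period in ms) denotes the level-j detail, whose passband spans
    fluctuation periods of roughly one to two scale lengths.  The sum of
    the approximation and all details reconstructs the input to within
    1e-6 relative error.
    """

    t: np.ndarray
    approximation: np.ndarray
    details: dict[float, np.ndarray]
    sample_rate: float

    def reconstruct(self) -> np.ndarray:
        out = self.approximation.copy()
        for d in self.details.values():
            out = out + d
        return out


# ---------------------------------------------------------------------------
# index helpers
# ---------------------------------------------------------------------------


def _index_of(series: CleanSeries, t_ms: float) -> int:
    return int(round((t_ms - series.t[0]) * series.sample_rate / 1000.0))


def _window_mean(cumsum: np.ndarray, i: int, j: int) -> float:
    """Mean over inclusive index range [i, j] using a 0-prepended cumsum."""
    return float((cumsum[j + 1] - cumsum[i]) / (j + 1 - i))


def _cumsum(x: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(x, dtype=float)])


def _series_cumsums(series: CleanSeries) -> np.ndarray:
    """Cached 0-prepended cumulative sum of the interpolation mask
    (interpolated-sample counts per window are then O(1) and exact,
    being integer-valued floats)."""
    cache = getattr(series, "_cumsum_cache", None)
    if cache is None or cache[0] is not series.value:
        cache = (series.value, _cumsum(series.interpolated.astype(float)))
        series._cumsum_cache = cache
    return cache[1]


# ---------------------------------------------------------------------------
# smoothed / conservative trends
# ---------------------------------------------------------------------------


def moving_average(series: CleanSeries, window_s: float) -> np.ndarray:
    """Centered moving average with an inclusive-symmetric sample window.

    The value at sample j is the mean over samples [j-h, j+h] with
    h = round(window_s * rate / 2).  Positions whose window would exceed
    the recording are NaN (unavailable) rather than partially averaged.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    h = int(round(window_s * series.sample_rate / 2.0))
    n = series.n_samples
    if 2 * h + 1 > n:
        raise ValueError("window too long: exceeds the recording")
    cs = _cumsum(series.value)
    out = np.full(n, np.nan)
    j = np.arange(h, n - h)
    out[j] = (cs[j + h + 1] - cs[j - h]) / (2 * h + 1)
    return out


def _two_window_trend(
    series: CleanSeries,
    t0_ms: float,
    pre: tuple[float, float],
    post: tuple[float, float],
    method: str,
    scale_ms: float,
    trial_id: object,
    max_interp_frac: float,
) -> TrendValue:
    """Common machinery: mean over ``post`` minus mean over ``pre``,
    both windows given as (offset_lo_ms, offset_hi_ms) around t0."""
    if t0_ms < series.t[0] or t0_ms > series.t[-1]:
        raise ValueError("event outside recording")
    rate = series.sample_rate / 1000.0  # samples per ms
    i0 = _index_of(series, t0_ms)
    n = series.n_samples
    idx = {}
    for name, (lo, hi) in (("pre", pre), ("post", post)):
        idx[name] = (i0 + int(round(lo * rate)), i0 + int(round(hi * rate)))
    lo_all = min(idx["pre"][0], idx["post"][0])
    hi_all = max(idx["pre"][1], idx["post"][1])
    if lo_all < 0 or hi_all > n - 1:
        return TrendValue(trial_id, method, scale_ms, np.nan, series.eye, QUALITY_INCOMPLETE)
    cs_int = _series_cumsums(series)
    for a, b in idx.values():
        if _window_mean(cs_int, a, b) > max_interp_frac:
            return TrendValue(trial_id, method, scale_ms, np.nan, series.eye, QUALITY_REJECTED)
    # Direct slice means (not cumulative-sum differences): samples outside
    # the two windows then cannot perturb the value even at round-off level,
    # which keeps the conservative trend *exactly* zero for transients
    # confined to the guard interval.
    v = series.value
    (a0, b0), (a1, b1) = idx["pre"], idx["post"]
    value = float(v[a1 : b1 + 1].mean() - v[a0 : b0 + 1].mean())
    return TrendValue(trial_id, method, scale_ms, value, series.eye, QUALITY_COMPLETE)


def smoothed_trend(
    series: CleanSeries,
    t0_ms: float,
    window_s: float,
    trial_id: object = None,
    max_interp_frac: float = DEFAULT_MAX_INTERP_FRAC,
) -> TrendValue:
    """Smoothed trend: mean over [t0, t0+w] minus mean over [t0-w, t0].

    Identical to evaluating the centered moving average at t0 + w/2 and
    subtracting its value at t0 - w/2.  Positive values indicate dilation
    across the window centered on the event.
    """
    w = window_s * 1000.0
    return _two_window_trend(
        series, t0_ms, (-w, 0.0), (0.0, w), "smoothed", w, trial_id, max_interp_frac
    )


def conservative_trend(
    series: CleanSeries,
    t0_ms: float,
    trial_id: object = None,
    window_s: float = 10.0,
    span_s: float = 14.0,
    max_interp_frac: float = DEFAULT_MAX_INTERP_FRAC,
) -> TrendValue:
    """Conservative trend over a ``span_s`` interval with ``window_s`` windows.

    With the defaults (10 s window, 14 s span): mean over [t0+2 s, t0+12 s]
    minus mean over [t0-12 s, t0-2 s].  The +/-2 s guard interval makes the
    index exactly immune to event-locked transients confined within it.
    """
    gap = (span_s - window_s) / 2.0 * 1000.0  # ms from t0 to the inner window edge
    w = window_s * 1000.0
    return _two_window_trend(
        series,
        t0_ms,
        (-(gap + w), -gap),
        (gap, gap + w),
        "conservative",
        w,
        trial_id,
        max_interp_frac,
    )


# ---------------------------------------------------------------------------
# multiresolution decomposition
# ---------------------------------------------------------------------------


def mra_decompose(
    series: CleanSeries,
    max_scale_ms: float = 32768.0,
    wavelet: str = DEFAULT_WAVELET,
) -> MRAComponents:
    """Shift-invariant additive multiresolution analysis of a clean series.

    Uses the stationary wavelet transform with the given filter pair
    (Symlet-4 by default) and per-level time-aligned reconstruction, so
    that approximation + sum(details) equals the input to within 1e-6
    relative error.  Scales are dyadic in samples and labelled in ms:
    level j is 2^j * dt ms for sample period dt.  At 1,000 Hz the labels
    run 2, 4, ..., ``max_scale_ms`` with the approximation at twice the
    coarsest detail scale (65,536 ms by default).

    The input is mirror-padded to a multiple of 2^J before the transform
    and trimmed afterwards; values within one coarsest-scale length of the
    series edge are boundary-affected and event readouts there are
    flagged incomplete by :func:`decomposed_trend`.
    """
    dt_ms = 1000.0 / series.sample_rate
    ratio = max_scale_ms / dt_ms
    n_levels = int(round(np.log2(ratio)))
    if not np.isclose(2.0**n_levels, ratio):
        raise ValueError(
            f"max_scale_ms={max_scale_ms} is not a dyadic multiple of the "
            f"sample period {dt_ms} ms"
        )
    n = series.n_samples
    coarse_samples = 2**n_levels
    if n < 2 * coarse_samples:
        raise ValueError(
            f"series too short for scale: need >= {2 * coarse_samples} samples "
            f"(twice the coarsest scale), got {n}"
        )
    block = 2**n_levels
    pad = (-n) % block
    x = np.pad(series.value, (0, pad), mode="symmetric") if pad else series.value
    comps = pywt.mra(x, wavelet, level=n_levels, transform="swt")
    # comps = [A_J, D_J, D_{J-1}, ..., D_1]
    approx = comps[0][:n]
    details: dict[float, np.ndarray] = {}
    for k, d in enumerate(comps[1:]):
        level = n_levels - k
        details[float(2**level * dt_ms)] = d[:n]
    return MRAComponents(
        t=series.t.copy(),
        approximation=approx,
        details=details,
        sample_rate=series.sample_rate,
    )


def decomposed_trend(
    components: MRAComponents,
    t0_ms: float,
    scale_ms: float,
    trial_id: object = None,
    interpolated: np.ndarray | None = None,
    max_interp_frac: float = DEFAULT_MAX_INTERP_FRAC,
    eye: str = "",
) -> TrendValue:
    """Two-point trend read from one detail component.

    value = detail(t0 + scale/2) - detail(t0 - scale/2).  Readouts whose
    points fall within one scale length of a series boundary are flagged
    incomplete (boundary-affected reconstruction).  When the blink-
    interpolation mask of the source series is supplied, readouts whose
    flanking half-scale windows are mostly interpolated are rejected.
    """
    if float(scale_ms) not in components.details:
        supported = sorted(components.details)
        raise ValueError(f"unsupported scale {scale_ms}; supported scales: {supported}")
    d = components.details[float(scale_ms)]
    rate = components.sample_rate / 1000.0
    i0 = int(round((t0_ms - components.t[0]) * rate))
    half = int(round(scale_ms / 2.0 * rate))
    scale_samp = int(round(scale_ms * rate))
    n = d.size
    lo, hi = i0 - half, i0 + half
    if lo < 0 or hi > n - 1:
        return TrendValue(trial_id, "decomposed", scale_ms, np.nan, eye, QUALITY_INCOMPLETE)
    if lo - scale_samp < 0 or hi + scale_samp > n - 1:
        return TrendValue(trial_id, "decomposed", scale_ms, np.nan, eye, QUALITY_INCOMPLETE)
    if interpolated is not None:
        cache = getattr(components, "_int_cumsum", None)
        if cache is None or cache[0] is not interpolated:
            cache = (interpolated, _cumsum(np.asarray(interpolated, dtype=float)))
            components._int_cumsum = cache
        cs_int = cache[1]
        for a, b in ((lo, i0), (i0, hi)):
            if _window_mean(cs_int, a, b) > max_interp_frac:
                return TrendValue(trial_id, "decomposed", scale_ms, np.nan, eye, QUALITY_REJECTED)
    value = float(d[hi] - d[lo])
    return TrendValue(trial_id, "decomposed", scale_ms, value, eye, QUALITY_COMPLETE)


# ---------------------------------------------------------------------------
# binocular combination and calibration
# ---------------------------------------------------------------------------


def binocular_trend(left: TrendValue, right: TrendValue) -> TrendValue:
    """Average the per-eye indices into a binocular trend.

    Both complete -> arithmetic mean; exactly one complete -> that eye's
    value flagged monocular; neither -> rejected.
    """
    if (left.trial_id, left.method, left.scale_ms) != (right.trial_id, right.method, right.scale_ms):
        raise ValueError("mismatched trial/method/scale between eyes")
    lc = left.quality == QUALITY_COMPLETE
    rc = right.quality == QUALITY_COMPLETE
    if lc and rc:
        value = (left.value_px + right.value_px) / 2.0
        return TrendValue(left.trial_id, left.method, left.scale_ms, value, "binocular", QUALITY_COMPLETE)
    if lc or rc:
        src = left if lc else right
        return TrendValue(
            left.trial_id, left.method, left.scale_ms, src.value_px, "binocular",
            QUALITY_COMPLETE, monocular=True,
        )
    return TrendValue(left.trial_id, left.method, left.scale_ms, np.nan, "binocular", QUALITY_REJECTED)


def px_to_mm(value_px: float, calib_px: float = 3300.0, calib_mm: float = 4.5) -> float:
    """Linear pixel-to-millimetre calibration.

    The default correspondence (3,300 px ~ 4.5 mm) is the conventional
    dark-background pupil size used to express trend differences in
    physical units.
    """
    if calib_px <= 0 or calib_mm <= 0:
        raise ValueError("calibration values must be positive")
    return value_px * calib_mm / calib_px


# ---------------------------------------------------------------------------
# batch extraction
# ---------------------------------------------------------------------------


class TrendExtractor:
    """Compute the full trend grid for one clean series efficiently.

    Precomputes cumulative sums and the multiresolution decomposition
    once, then evaluates every (method, scale) index per event.
    """

    def __init__(
        self,
        series: CleanSeries,
        windows_s: tuple[float, ...] = DEFAULT_WINDOWS_S,
        conservative_window_s: float = 10.0,
        conservative_span_s: float = 14.0,
        scales_ms: tuple[float, ...] = DEFAULT_SCALES_MS,
        wavelet: str = DEFAULT_WAVELET,
        max_interp_frac: float = DEFAULT_MAX_INTERP_FRAC,
        include_decomposed: bool = True,
    ):
        self.series = series
        self.windows_s = tuple(windows_s)
        self.conservative_window_s = conservative_window_s
        self.conservative_span_s = conservative_span_s
        self.scales_ms = tuple(scales_ms)
        self.max_interp_frac = max_interp_frac
        self.components = None
        if include_decomposed and scales_ms:
            self.components = mra_decompose(series, max(scales_ms), wavelet)

    def trends_at(self, t0_ms: float, trial_id: object = None) -> list[TrendValue]:
        out = []
        for w in self.windows_s:
            out.append(
                smoothed_trend(self.series, t0_ms, w, trial_id, self.max_interp_frac)
            )
        out.append(
            conservative_trend(
                self.series, t0_ms, trial_id,
                self.conservative_window_s, self.conservative_span_s,
                self.max_interp_frac,
            )
        )
        if self.components is not None:
            for s in self.scales_ms:
                out.append(
                    decomposed_trend(
                        self.components, t0_ms, s, trial_id,
                        self.series.interpolated, self.max_interp_frac,
                        eye=self.series.eye,
                    )
                )
        return out
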