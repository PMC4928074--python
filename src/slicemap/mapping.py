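"""Per-beat feature extraction and per-pixel activation/duration maps.

Activation time is the first upward crossing of 50% of the beat's
upstroke amplitude; action-potential / calcium-transient duration (APD80 /
CaTD80) runs from activation to the first downward crossing of 80%
repolarization after the peak.  Both crossings are linearly interpolated
between samples for sub-frame resolution, and the amplitude is defined per
beat window (robust to beat-to-beat amplitude change).

Traces must be conditioned (depolarization-positive) before mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .conditioning import FrameStack, TissueMask, Trace, extract_trace

__all__ = [
    "BeatWindow",
    "ActivationMap",
    "DurationMap",
    "segment_beats",
    "activation_time",
    "duration80",
    "upstroke_metrics",
    "build_maps",
    "map_to_frame",
]


@dataclass
class BeatWindow:
    """One beat's time window; ``stim_time_ms`` is None for spontaneous beats."""

    start_ms: float
    end_ms: float
    stim_time_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("window start must precede end")

    @property
    def is_paced(self) -> bool:
        return self.stim_time_ms is not None


@dataclass
class ActivationMap:
    """Per-pixel activation times (ms); NaN outside the mask / undefined."""

    times_ms: np.ndarray
    pixel_size_mm: float
    reference_ms: float | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.times_ms)


@dataclass
class DurationMap:
    """Per-pixel AP/CaT durations at 80% repolarization (ms)."""

    durations_ms: np.ndarray
    modality: str = "Vm"
    level: float = 0.8

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.durations_ms)


# ---------------------------------------------------------------------------
# Beat segmentation
# ---------------------------------------------------------------------------


def segment_beats(trace: Trace, stim_times_ms=None,
                  capture_tolerance_ms: float = 50.0,
                  min_interval_ms: float = 150.0,
                  lead_ms: float = 60.0,
                  derivative_fraction: float = 0.25) -> list[BeatWindow]:
    """Detect beats from derivative peaks and window each one.

    An upstroke is a peak of the first difference exceeding
    ``derivative_fraction`` of the largest derivative, with peaks closer
    than ``min_interval_ms`` merged.  Each window starts ``lead_ms`` before
    its upstroke and ends ``lead_ms`` before the next one (or at the end of
    the record).  A beat is tagged to a stimulus when its upstroke falls
    within ``capture_tolerance_ms`` after that stimulus; otherwise it is
    spontaneous.
    """
    stim_times_ms = list(stim_times_ms or [])
    y = trace.samples
    dt_ms = 1000.0 / trace.fps_hz
    dy = np.diff(y)
    if dy.size == 0 or dy.max() <= 0 or np.ptp(y) == 0:
        warnings.warn("no beats detected (flat or monotone-decreasing trace)",
                      stacklevel=2)
        return []
    height = derivative_fraction * dy.max()
    distance = max(1, int(round(min_interval_ms / dt_ms)))
    peaks, _ = find_peaks(dy, height=height, distance=distance)
    if peaks.size == 0:
        warnings.warn("no beats detected (no derivative peak above threshold)",
                      stacklevel=2)
        return []
    peak_times = (peaks + 0.5) * dt_ms
    total_ms = y.size * dt_ms
    windows: list[BeatWindow] = []
    for i, pt in enumerate(peak_times):
        start = max(0.0, pt - lead_ms)
        end = peak_times[i + 1] - lead_ms if i + 1 < peak_times.size else total_ms
        if end <= start:
            continue
        stim = None
        for s in stim_times_ms:
            if 0.0 <= pt - s <= capture_tolerance_ms:
                stim = s
                break
        windows.append(BeatWindow(start_ms=start, end_ms=end, stim_time_ms=stim))
    return windows


def _window_slice(trace: Trace, window: BeatWindow) -> tuple[np.ndarray, int]:
    dt_ms = 1000.0 / trace.fps_hz
    i0 = max(0, int(np.ceil(window.start_ms / dt_ms)))
    i1 = min(trace.samples.size, int(np.floor(window.end_ms / dt_ms)) + 1)
    return trace.samples[i0:i1], i0


def _cross_up(y: np.ndarray, level: float, start: int = 0) -> float | None:
    """Index (fractional) of first upward crossing of ``level`` at/after start."""
    a, b = y[start:-1], y[start + 1:]
    hits = np.nonzero((a < level) & (b >= level))[0]
    if hits.size == 0:
        return None
    i = int(hits[0]) + start
    return i + (level - y[i]) / (y[i + 1] - y[i])


def _cross_down(y: np.ndarray, level: float, start: int) -> float | None:
    a, b = y[start:-1], y[start + 1:]
    hits = np.nonzero((a >= level) & (b < level))[0]
    if hits.size == 0:
        return None
    i = int(hits[0]) + start
    return i + (y[i] - level) / (y[i] - y[i + 1])


def activation_time(trace: Trace, window: BeatWindow) -> float:
    """Activation time: first upward crossing of 50% upstroke amplitude (ms).

    Amplitude is max - min within the window; the crossing is linearly
    interpolated.  Returns NaN (with a warning) when the window holds no
    upstroke.
    """
    y, i0 = _window_slice(trace, window)
    if y.size < 2:
        warnings.warn("window too short for activation detection", stacklevel=2)
        return np.nan
    lo, hi = y.min(), y.max()
    if hi <= lo:
        warnings.warn("zero amplitude in beat window", stacklevel=2)
        return np.nan
    level = lo + 0.5 * (hi - lo)
    idx = _cross_up(y, level)
    if idx is None:
        warnings.warn("no 50%-upstroke crossing in beat window", stacklevel=2)
        return np.nan
    return (i0 + idx) * 1000.0 / trace.fps_hz


def duration80(trace: Trace, window: BeatWindow, level: float = 0.8) -> float:
    """APD80/CaTD80: activation to first downward crossing of 80%
    repolarization after the peak (ms).  NaN when the beat is truncated.
    """
    y, i0 = _window_slice(trace, window)
    act_ms = activation_time(trace, window)
    if not np.isfinite(act_ms):
        return np.nan
    lo, hi = y.min(), y.max()
    rep_level = lo + (1.0 - level) * (hi - lo)
    peak = int(np.argmax(y))
    idx = _cross_down(y, rep_level, peak)
    if idx is None:
        warnings.warn("beat truncated before 80% repolarization", stacklevel=2)
        return np.nan
    return (i0 + idx) * 1000.0 / trace.fps_hz - act_ms


def upstroke_metrics(trace: Trace, window: BeatWindow) -> dict[str, float]:
    """10-90% rise time (ms) and maximum upstroke rate (amplitude per ms)."""
    y, i0 = _window_slice(trace, window)
    if y.size < 2 or np.ptp(y) == 0:
        return {"rise_time_10_90_ms": np.nan, "max_derivative_per_ms": np.nan}
    lo, hi = y.min(), y.max()
    amp = hi - lo
    i10 = _cross_up(y, lo + 0.1 * amp)
    i90 = _cross_up(y, lo + 0.9 * amp)
    dt_ms = 1000.0 / trace.fps_hz
    rise = (i90 - i10) * dt_ms if (i10 is not None and i90 is not None) else np.nan
    max_deriv = np.diff(y).max() / dt_ms
    return {"rise_time_10_90_ms": rise, "max_derivative_per_ms": max_deriv}


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------


def build_maps(stack: FrameStack, mask: TissueMask, beat_index: int = 0,
               windows: list[BeatWindow] | None = None,
               max_undefined_fraction: float = 0.5,
               **segment_kwargs) -> tuple[ActivationMap, DurationMap]:
    """Per-pixel activation and duration maps for one beat.

    Beat windows are segmented on the in-mask mean trace (so all pixels
    share a window even though local activation differs), then
    :func:`activation_time` and :func:`duration80` run per pixel.  Pixels
    without a valid crossing are NaN; if more than
    ``max_undefined_fraction`` of the mask is undefined the beat is
    considered absent and an error is raised.
    """
    if mask.mask.shape != stack.shape:
        raise ValueError("mask shape does not match stack")
    if windows is None:
        mean_trace = extract_trace(stack, mask)
        windows = segment_beats(mean_trace, stack.stim_times_ms, **segment_kwargs)
    if not windows:
        raise ValueError("no beats detected in the masked mean trace")
    if not 0 <= beat_index < len(windows):
        raise ValueError(f"beat_index {beat_index} out of range "
                         f"(detected {len(windows)} beats)")
    window = windows[beat_index]
    h, w = stack.shape
    act = np.full((h, w), np.nan)
    dur = np.full((h, w), np.nan)
    rows, cols = np.nonzero(mask.mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r, c in zip(rows, cols):
            tr = Trace(stack.frames[:, r, c], stack.fps_hz, (int(r), int(c)))
            a = activation_time(tr, window)
            act[r, c] = a
            if np.isfinite(a):
                dur[r, c] = duration80(tr, window)
    n_mask = rows.size
    n_undef = int(np.isnan(act[mask.mask]).sum())
    if n_undef > max_undefined_fraction * n_mask:
        raise ValueError(
            f"beat {beat_index} absent in {n_undef}/{n_mask} masked pixels"
        )
    return (
        ActivationMap(times_ms=act, pixel_size_mm=stack.pixel_size_mm,
                      reference_ms=window.stim_time_ms),
        DurationMap(durations_ms=dur, modality=stack.modality),
    )


def map_to_frame(map_obj: ActivationMap | DurationMap) -> pd.DataFrame:
    """Long-format (row, col, value) table of the defined pixels."""
    arr = map_obj.times_ms if isinstance(map_obj, ActivationMap) else map_obj.durations_ms
    rows, cols = np.nonzero(np.isfinite(arr))
    return pd.DataFrame({"row": rows, "col": cols, "value": arr[rows, cols]})
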