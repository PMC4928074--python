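"""Movie I/O and fluorescence signal conditioning.

Optical-mapping movies arrive as 16-bit TIFF stacks with a JSON sidecar
carrying the acquisition metadata (frame rate, pixel size, modality,
stimulus times).  Raw optical signals are small modulations on a large
background and are conditioned before any feature extraction:

1. tissue masking by signal-to-noise ratio,
2. 3x3 spatial averaging restricted to in-mask pixels,
3. zero-phase low-pass filtering (default 100 Hz cutoff),
4. first-order (linear) drift removal,
5. per-pixel 0-to-1 normalization,
6. polarity orientation so depolarization is positive (voltage dyes such
   as di-4-ANEPPS fluoresce *less* on depolarization).

All operations are deterministic; none of them enlarges the tissue mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage, signal, stats

__all__ = [
    "FrameStack",
    "TissueMask",
    "Trace",
    "read_stack",
    "write_stack",
    "make_mask",
    "spatial_bin",
    "lowpass",
    "remove_drift",
    "normalize",
    "orient_polarity",
    "condition",
    "extract_trace",
]

_REQUIRED_SIDECAR = ("fps_hz", "pixel_size_mm", "modality")


@dataclass
class FrameStack:
    """A T x H x W fluorescence movie with acquisition metadata.

    Attributes
    ----------
    frames : (T, H, W) float array of pixel intensities.
    fps_hz : acquisition frame rate.
    pixel_size_mm : physical size of one pixel edge.
    modality : ``"Vm"`` (transmembrane voltage dye) or ``"Ca"`` (calcium dye).
    stim_times_ms : sorted pacing stimulus times, all inside the record.
    """

    frames: np.ndarray
    fps_hz: float
    pixel_size_mm: float
    modality: str = "Vm"
    stim_times_ms: list[float] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not self.fps_hz > 0:
            raise ValueError("fps_hz must be positive")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.modality not in ("Vm", "Ca"):
            raise ValueError(f"modality must be 'Vm' or 'Ca', got {self.modality!r}")
        st = list(self.stim_times_ms)
        if st != sorted(st):
            raise ValueError("stim_times_ms must be sorted ascending")
        if st and (st[0] < 0 or st[-1] >= self.duration_ms):
            raise ValueError("stimulus times must lie inside the record")
        self.stim_times_ms = st

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_ms(self) -> float:
        return self.n_frames / self.fps_hz * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        """Timestamp of frame i is i/fps (0-based)."""
        return np.arange(self.n_frames) / self.fps_hz * 1000.0


@dataclass
class TissueMask:
    """Boolean H x W map of pixels with usable signal."""

    mask: np.ndarray
    snr_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Trace:
    """A single time series: one pixel or a regional mean."""

    samples: np.ndarray
    fps_hz: float
    pixel: tuple[int, int] | str = "regional mean"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be 1-D")
        if not self.fps_hz > 0:
            raise ValueError("fps_hz must be positive")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fps_hz * 1000.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_stack(stack: FrameStack, tiff_path, sidecar_path) -> None:
    """Write a 16-bit TIFF stack plus a JSON metadata sidecar.

    Frame values are rounded to the nearest integer; values outside the
    16-bit range [0, 65535] are rejected rather than clipped.
    """
    rounded = np.round(stack.frames)
    if rounded.min() < 0 or rounded.max() > 65535:
        raise ValueError(
            "frame values out of 16-bit range after rounding: "
            f"[{rounded.min():.1f}, {rounded.max():.1f}] not within [0, 65535]"
        )
    tifffile.imwrite(str(tiff_path), rounded.astype(np.uint16),
                     photometric="minisblack")
    meta = {
        "fps_hz": stack.fps_hz,
        "pixel_size_mm": stack.pixel_size_mm,
        "modality": stack.modality,
        "stim_times_ms": list(stack.stim_times_ms),
        "provenance": stack.provenance,
        "n_frames": stack.n_frames,
        "shape": list(stack.shape),
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_stack(tiff_path, sidecar_path) -> FrameStack:
    """Read a TIFF movie and its JSON sidecar into a :class:`FrameStack`."""
    meta = json.loads(Path(sidecar_path).read_text())
    missing = [k for k in _REQUIRED_SIDECAR if k not in meta]
    if missing:
        raise ValueError(f"sidecar is missing required field(s): {', '.join(missing)}")
    frames = np.asarray(tifffile.imread(str(tiff_path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if "n_frames" in meta and frames.shape[0] != meta["n_frames"]:
        raise ValueError(
            f"TIFF has {frames.shape[0]} frames but sidecar states {meta['n_frames']}"
        )
    if "shape" in meta and list(frames.shape[1:]) != list(meta["shape"]):
        raise ValueError(
            f"TIFF frame shape {frames.shape[1:]} does not match sidecar {meta['shape']}"
        )
    return FrameStack(
        frames=frames,
        fps_hz=meta["fps_hz"],
        pixel_size_mm=meta["pixel_size_mm"],
        modality=meta["modality"],
        stim_times_ms=meta.get("stim_times_ms", []),
        provenance=meta.get("provenance", ""),
    )


def extract_trace(stack: FrameStack, pixels) -> Trace:
    """Mean trace over a pixel selection.

    ``pixels`` may be a single (row, col), a boolean H x W array, or a
    :class:`TissueMask`.
    """
    if isinstance(pixels, TissueMask):
        pixels = pixels.mask
    pixels_arr = np.asarray(pixels)
    if pixels_arr.dtype == bool:
        if not pixels_arr.any():
            raise ValueError("empty pixel selection")
        samples = stack.frames[:, pixels_arr].mean(axis=1)
        return Trace(samples, stack.fps_hz, "regional mean")
    r, c = int(pixels_arr[0]), int(pixels_arr[1])
    return Trace(stack.frames[:, r, c], stack.fps_hz, (r, c))


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


def _snr_map(frames: np.ndarray) -> np.ndarray:
    """Per-pixel beat amplitude over diastolic noise SD.

    Amplitude is a robust peak-to-peak range; noise is estimated from the
    samples in the lower half of each pixel's range (the diastolic segment),
    after removing the local mean.  Noiseless signal pixels get +inf,
    constant pixels get 0.
    """
    lo = np.percentile(frames, 0.5, axis=0)
    hi = np.percentile(frames, 99.5, axis=0)
    amplitude = hi - lo
    # diastolic segment: samples below mid-range
    mid = lo + 0.5 * amplitude
    diastolic = np.where(frames <= mid[None], frames, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        noise = np.nanstd(diastolic, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = amplitude / noise
    snr[(amplitude > 0) & (noise == 0)] = np.inf
    snr[amplitude == 0] = 0.0
    return snr


def make_mask(stack: FrameStack, snr_threshold: float = 3.0) -> TissueMask:
    """Tissue mask: keep pixels whose beat SNR reaches ``snr_threshold``."""
    if snr_threshold < 0:
        raise ValueError("snr_threshold must be non-negative")
    snr = _snr_map(stack.frames)
    mask = snr >= snr_threshold
    if not mask.any():
        raise ValueError(
            "no pixel reaches the SNR threshold "
            f"({snr_threshold:g}); max observed SNR is {np.nanmax(snr):.2f} — "
            "lower the threshold"
        )
    return TissueMask(mask=mask, snr_threshold=snr_threshold)


# ---------------------------------------------------------------------------
# Conditioning operations
# ---------------------------------------------------------------------------


def spatial_bin(stack: FrameStack, mask: TissueMask | None = None) -> FrameStack:
    """3x3 spatial averaging over in-mask pixels.

    Each in-mask pixel becomes the mean of the in-mask pixels in its 3x3
    neighborhood (neighborhoods shrink at edges and at mask borders, no
    zero padding).  Out-of-mask pixels are left untouched.
    """
    frames = stack.frames
    if mask is None:
        m = np.ones(stack.shape, dtype=bool)
    else:
        if mask.mask.shape != stack.shape:
            raise ValueError("mask shape does not match stack")
        m = mask.mask
    kernel = np.ones((1, 3, 3))
    weighted = ndimage.convolve(frames * m[None], kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(
        np.broadcast_to(m[None].astype(float), (1,) + m.shape).copy(),
        kernel,
        mode="constant",
        cval=0.0,
    )[0]
    out = frames.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        averaged = weighted / counts[None]
    out[:, m] = averaged[:, m]
    return replace(stack, frames=out)


def _lowpass_array(arr: np.ndarray, fps_hz: float, cutoff_hz: float, order: int) -> np.ndarray:
    nyquist = fps_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz:g} Hz must be below the Nyquist frequency {nyquist:g} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fps_hz, output="sos")
    return signal.sosfiltfilt(sos, arr, axis=0)


def lowpass(obj: FrameStack | Trace, cutoff_hz: float = 100.0, order: int = 4):
    """Zero-phase Butterworth low-pass along time (default 100 Hz, order 4).

    Zero-phase filtering (forward-backward) leaves activation times
    unbiased; DC is preserved exactly.
    """
    if isinstance(obj, FrameStack):
        return replace(obj, frames=_lowpass_array(obj.frames, obj.fps_hz, cutoff_hz, order))
    return replace(obj, samples=_lowpass_array(obj.samples, obj.fps_hz, cutoff_hz, order))


def _detrend_array(arr: np.ndarray, diastolic_only: bool) -> np.ndarray:
    t = np.arange(arr.shape[0], dtype=float)
    flat = arr.reshape(arr.shape[0], -1)
    out = np.empty_like(flat)
    if not diastolic_only:
        # single shared design matrix -> one lstsq for all pixels
        design = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
        out = flat - design @ coef
        # keep the mean level; only the linear trend is removed
        out += coef[0][None, :]
    else:
        for j in range(flat.shape[1]):
            y = flat[:, j]
            thresh = np.percentile(y, 30)
            sel = y <= thresh
            if sel.sum() < 2:
                sel = np.ones_like(sel)
            slope, intercept = np.polyfit(t[sel], y[sel], 1)
            out[:, j] = y - slope * t
    return out.reshape(arr.shape)


def remove_drift(obj: FrameStack | Trace, diastolic_only: bool = False):
    """Remove fluorescent drift with a first-order (linear) fitted curve.

    The least-squares line over the full trace is subtracted (the constant
    term is retained so the signal level is unchanged).  With
    ``diastolic_only=True`` the line is fitted on the lowest 30% of samples
    only, which is more robust when long plateaus dominate the record.
    """
    if isinstance(obj, FrameStack):
        return replace(obj, frames=_detrend_array(obj.frames, diastolic_only))
    if obj.samples.size < 2:
        raise ValueError("need at least 2 samples to fit a drift line")
    return replace(obj, samples=_detrend_array(obj.samples, diastolic_only))


def normalize(obj: FrameStack | Trace, window: slice | None = None,
              mask: TissueMask | None = None):
    """Affine rescale to the [0, 1] range within ``window`` (default: all).

    For stacks the rescale is per pixel; out-of-mask pixels are set to 0.
    A constant trace (zero dynamic range) is rejected.
    """
    window = window if window is not None else slice(None)
    if isinstance(obj, Trace):
        seg = obj.samples[window]
        if seg.size == 0:
            raise ValueError("empty normalization window")
        lo, hi = seg.min(), seg.max()
        if hi <= lo:
            raise ValueError("cannot normalize a constant trace (zero dynamic range)")
        return replace(obj, samples=(obj.samples - lo) / (hi - lo))
    frames = obj.frames
    m = mask.mask if mask is not None else np.ones(obj.shape, dtype=bool)
    seg = frames[window]
    lo = seg.min(axis=0)
    hi = seg.max(axis=0)
    span = hi - lo
    if np.any(span[m] <= 0):
        n_bad = int((span[m] <= 0).sum())
        raise ValueError(f"{n_bad} in-mask pixel(s) are constant; cannot normalize")
    out = np.zeros_like(frames)
    out[:, m] = (frames[:, m] - lo[m]) / span[m]
    return replace(obj, frames=out)


def orient_polarity(obj: FrameStack | Trace, mask: TissueMask | None = None,
                    skew_tolerance: float = 0.05, override: int | None = None):
    """Standardize sign so depolarization transients point upward.

    Voltage-sensitive dyes emit decreasing fluorescence on depolarization,
    so raw Vm movies are upside down.  The transient direction is read from
    the skewness of the signal (a trace dominated by upward transients is
    right-skewed); a negative skew flips the signal about its baseline
    (median).  Idempotent.  Near-zero skewness is ambiguous: a warning is
    issued and ``override`` (+1 keep, -1 flip) is honored, defaulting to
    keep.
    """
    if isinstance(obj, Trace):
        ref = obj.samples
    else:
        m = mask.mask if mask is not None else np.ones(obj.shape, dtype=bool)
        ref = obj.frames[:, m].mean(axis=1)
    if np.ptp(ref) == 0:
        raise ValueError("cannot orient a constant signal")
    skew = stats.skew(ref)
    if abs(skew) < skew_tolerance:
        warnings.warn(
            f"polarity is ambiguous (skewness {skew:+.3f}); "
            f"using override={'+1' if (override or 1) > 0 else '-1'}",
            stacklevel=2,
        )
        flip = (override is not None and override < 0)
    else:
        flip = skew < 0
    if not flip:
        return obj
    if isinstance(obj, Trace):
        baseline = np.median(obj.samples)
        return replace(obj, samples=2 * baseline - obj.samples)
    baseline = np.median(obj.frames, axis=0)
    return replace(obj, frames=2 * baseline[None] - obj.frames)


def condition(stack: FrameStack, mask: TissueMask | None = None,
              cutoff_hz: float = 100.0, detrend: bool = True,
              diastolic_only: bool = False) -> FrameStack:
    """Full conditioning chain: bin -> low-pass -> drift -> orient -> normalize.

    Polarity is oriented before normalization so the [0, 1] range maps
    diastole to 0 and the action-potential peak to 1.  Returns a new stack;
    the mask is never modified.
    """
    out = spatial_bin(stack, mask)
    out = lowpass(out, cutoff_hz)
    if detrend:
        out = remove_drift(out, diastolic_only=diastolic_only)
    out = orient_polarity(out, mask)
    out = normalize(out, mask=mask)
    return out
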