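"""Conduction velocity from activation maps.

The activation surface t(x, y) is fitted with a local least-squares plane
in a (2r+1) x (2r+1) window around each pixel; the gradient g (ms/mm) of
that plane points along propagation, and speed = 1/|g| (mm/ms = m/s).
Implausibly fast pixels (near-flat local activation, e.g. at the pacing
edge or across wave collisions) are gated by a maximum speed and a fit
quality (R^2) threshold.  Summary CV is the median over defined pixels,
which is robust to the remaining fit outliers.

For point stimulation, transverse CV is the slope of distance-from-source
versus activation time along a chosen ray (the study could only resolve
the transverse component on small tissue, and chose the direction
manually).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conditioning import TissueMask
from .mapping import ActivationMap

__all__ = [
    "VelocityField",
    "CvSummary",
    "local_velocity_field",
    "summary_cv",
    "transverse_cv",
    "field_to_frame",
]


@dataclass
class VelocityField:
    """Per-pixel conduction speed (m/s) and propagation direction (rad)."""

    speed_m_per_s: np.ndarray
    direction_rad: np.ndarray
    fit_quality: np.ndarray
    window_radius_px: int
    max_speed_m_per_s: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.speed_m_per_s)


@dataclass
class CvSummary:
    """Scalar CV summary with dispersion over the contributing pixels."""

    central_value_m_per_s: float
    dispersion: float
    n_pixels: int
    method: str


def local_velocity_field(act: ActivationMap, pixel_size_mm: float | None = None,
                         window_radius_px: int = 2,
                         max_speed_m_per_s: float = 2.0,
                         quality_threshold: float = 0.8,
                         min_fraction: float = 0.5) -> VelocityField:
    """Least-squares plane fit of local activation time at every pixel.

    A pixel is fitted when at least ``min_fraction`` of its window holds
    defined activation times; it stays undefined when the local fit is
    degenerate (constant times), slower than ``1/max_speed`` in gradient
    terms, or has R^2 below ``quality_threshold``.
    """
    px_mm = pixel_size_mm if pixel_size_mm is not None else act.pixel_size_mm
    if not px_mm > 0:
        raise ValueError("pixel size must be positive")
    t = act.times_ms
    h, w = t.shape
    r = window_radius_px
    n_win = (2 * r + 1) ** 2
    min_pts = max(3, int(np.ceil(min_fraction * n_win)))

    offs = np.arange(-r, r + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    dy = dy.ravel() * px_mm
    dx = dx.ravel() * px_mm

    speed = np.full((h, w), np.nan)
    direction = np.full((h, w), np.nan)
    quality = np.full((h, w), np.nan)
    for i in range(h):
        for j in range(w):
            if not np.isfinite(t[i, j]):
                continue
            i0, i1 = max(0, i - r), min(h, i + r + 1)
            j0, j1 = max(0, j - r), min(w, j + r + 1)
            block = t[i0:i1, j0:j1]
            by, bx = np.meshgrid(np.arange(i0, i1) - i, np.arange(j0, j1) - j,
                                 indexing="ij")
            vals = block.ravel()
            ok = np.isfinite(vals)
            if ok.sum() < min_pts:
                continue
            yv = by.ravel()[ok] * px_mm
            xv = bx.ravel()[ok] * px_mm
            tv = vals[ok]
            design = np.column_stack([np.ones_like(xv), xv, yv])
            coef, res, rank, _ = np.linalg.lstsq(design, tv, rcond=None)
            if rank < 3:
                continue
            gx, gy = coef[1], coef[2]
            gnorm = np.hypot(gx, gy)
            if gnorm == 0:
                continue
            fitted = design @ coef
            ss_tot = np.sum((tv - tv.mean()) ** 2)
            if ss_tot == 0:
                continue
            r2 = 1.0 - np.sum((tv - fitted) ** 2) / ss_tot
            s = 1.0 / gnorm
            if s > max_speed_m_per_s or r2 < quality_threshold:
                continue
            speed[i, j] = s
            direction[i, j] = np.arctan2(gy, gx)
            quality[i, j] = r2
    return VelocityField(
        speed_m_per_s=speed,
        direction_rad=direction,
        fit_quality=quality,
        window_radius_px=r,
        max_speed_m_per_s=max_speed_m_per_s,
    )


def summary_cv(field: VelocityField, mask: TissueMask | None = None,
               method: str = "median", min_pixels: int = 25) -> CvSummary:
    """Summarize a velocity field: median with IQR (default) or mean with SD."""
    sel = field.defined
    if mask is not None:
        if not mask.mask.any():
            raise ValueError("empty mask")
        sel = sel & mask.mask
    speeds = field.speed_m_per_s[sel]
    if speeds.size < min_pixels:
        raise ValueError(
            f"only {speeds.size} defined velocity pixels (minimum {min_pixels})"
        )
    if method == "median":
        q1, q3 = np.percentile(speeds, [25, 75])
        return CvSummary(float(np.median(speeds)), float(q3 - q1),
                         int(speeds.size), "median/IQR")
    if method == "mean":
        return CvSummary(float(speeds.mean()), float(speeds.std(ddof=1)),
                         int(speeds.size), "mean/SD")
    raise ValueError("method must be 'median' or 'mean'")


def transverse_cv(act: ActivationMap, source_px: tuple[int, int],
                  ray_angle_rad: float, pixel_size_mm: float | None = None,
                  min_samples: int = 10, step_px: float = 1.0) -> CvSummary:
    """CV along a ray from a point-stimulation site.

    Samples activation times at ``step_px`` increments along the ray
    (nearest pixel) and regresses distance (mm) on time (ms); the slope is
    the speed in m/s, its standard error the dispersion.  Named for the
    transverse direction because on elongated tissue only the component
    perpendicular to the fibers spans enough pixels, but the measured
    direction is simply the supplied ray.
    """
    px_mm = pixel_size_mm if pixel_size_mm is not None else act.pixel_size_mm
    t = act.times_ms
    h, w = t.shape
    r0, c0 = source_px
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("source pixel outside grid")
    dr, dc = np.sin(ray_angle_rad), np.cos(ray_angle_rad)
    dists, times = [], []
    k = 0.0
    while True:
        rr = int(round(r0 + k * dr))
        cc = int(round(c0 + k * dc))
        if not (0 <= rr < h and 0 <= cc < w):
            break
        if np.isfinite(t[rr, cc]):
            dists.append(k * px_mm)
            times.append(t[rr, cc])
        k += step_px
    if len(dists) < min_samples:
        raise ValueError(
            f"ray leaves the defined map after {len(dists)} samples "
            f"(minimum {min_samples})"
        )
    res = stats.linregress(times, dists)
    return CvSummary(float(res.slope), float(res.stderr),
                     len(dists), "ray slope/SE")


def field_to_frame(field: VelocityField) -> pd.DataFrame:
    """Long-format (row, col, speed, angle, quality) table of defined pixels."""
    rows, cols = np.nonzero(field.defined)
    return pd.DataFrame({
        "row": rows,
        "col": cols,
        "speed_m_per_s": field.speed_m_per_s[rows, cols],
        "direction_rad": field.direction_rad[rows, cols],
        "fit_quality": field.fit_quality[rows, cols],
    })
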