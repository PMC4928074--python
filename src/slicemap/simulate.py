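"""Kinematic simulator of cardiac-slice optical-mapping recordings.

Generates voltage/calcium fluorescence movies with known per-pixel ground
truth, emulating a 1 x 1 cm slice imaged on a 100 x 100 pixel sensor.  The
model is deliberately kinematic, not biophysical:

* Excitation spreads from a source (a stimulated edge, a point electrode,
  or a spontaneously firing pacemaker region) at a configured conduction
  velocity; arrival times follow an elliptical travel-time metric that
  supports anisotropy (longitudinal/transverse speeds about a fiber angle).
* Each region has an effective refractory period (ERP): a wavefront
  captures a region iff the time since the region's last local activation
  strictly exceeds its ERP.  This strict rule makes the ERP the longest
  failing interval and yields k:1 capture with k = floor(ERP/PCL) + 1
  under periodic pacing.
* Regions with an intrinsic cycle length fire spontaneously whenever the
  time since their last activation reaches that cycle; any activation
  (paced or spontaneous) resets the clock (phase reset).
* Action-potential/calcium-transient duration follows a mono-exponential
  restitution function of the preceding diastolic interval.

Pixel traces are rendered from a piecewise waveform template (sigmoidal
upstroke, plateau, exponential repolarization shoulder) whose 50%-upstroke
crossing lands at the scheduled activation time and whose 80%-repolarization
crossing lands at the restitution-determined duration.  Gaussian noise,
linear baseline drift and voltage-dye polarity inversion are applied last.

Units: time ms, space mm, speed m/s (= mm/ms).  Frame i is timestamped
i/fps, pixels are (row, col), row-major.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .conditioning import FrameStack, write_stack

__all__ = [
    "Rect",
    "Ellipse",
    "WaveformParams",
    "RegionSpec",
    "SimProtocol",
    "ConductionSpec",
    "ArtifactParams",
    "Grid",
    "WaveEvent",
    "GroundTruth",
    "restitution_function",
    "steady_state_duration",
    "beats_to_steady_state",
    "build_activation_schedule",
    "render_movie",
    "write_fixture",
    "read_ground_truth",
]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass
class Rect:
    """Axis-aligned rectangle, [row0, row1) x [col0, col1) in pixels."""

    row0: int
    col0: int
    row1: int
    col1: int

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            (rows >= self.row0) & (rows < self.row1)
            & (cols >= self.col0) & (cols < self.col1)
        )

    def within(self, shape: tuple[int, int]) -> bool:
        return (0 <= self.row0 < self.row1 <= shape[0]
                and 0 <= self.col0 < self.col1 <= shape[1])


@dataclass
class Ellipse:
    """Ellipse with pixel-coordinate center and semi-axes."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            ((rows - self.center_row) / self.semi_row) ** 2
            + ((cols - self.center_col) / self.semi_col) ** 2
        ) <= 1.0

    def within(self, shape: tuple[int, int]) -> bool:
        return (
            self.center_row - self.semi_row > -1
            and self.center_col - self.semi_col > -1
            and self.center_row + self.semi_row < shape[0]
            and self.center_col + self.semi_col < shape[1]
        )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class WaveformParams:
    """Shape and restitution parameters of one region's AP or CaT.

    ``apd_max_ms`` is the fully-rested duration; restitution shortens it by
    ``restitution_amplitude_ms * exp(-DI/restitution_tau_ms)``.
    ``upstroke_ms`` is the 10-90% rise time of the sigmoidal upstroke.
    Calcium rendering delays activation by ``ca_delay_ms`` and slows the
    upstroke by ``ca_upstroke_factor``.  ``amplitude``/``diastolic_level``
    are in camera counts.
    """

    apd_max_ms: float = 380.0
    restitution_amplitude_ms: float = 140.0
    restitution_tau_ms: float = 120.0
    upstroke_ms: float = 5.0
    ca_delay_ms: float = 10.0
    amplitude: float = 3000.0
    diastolic_level: float = 1000.0
    ca_upstroke_factor: float = 3.0
    plateau_fraction: float = 0.6
    tail_tau_ms: float = 6.0

    def __post_init__(self) -> None:
        if not self.apd_max_ms > 0:
            raise ValueError("apd_max_ms must be positive")
        if self.restitution_amplitude_ms < 0:
            raise ValueError("restitution_amplitude_ms must be non-negative")
        if self.restitution_amplitude_ms >= self.apd_max_ms:
            raise ValueError("apd_max_ms must exceed restitution_amplitude_ms "
                             "(duration must stay positive at DI=0)")
        if not self.restitution_tau_ms > 0:
            raise ValueError("restitution_tau_ms must be positive")
        if not 0 < self.upstroke_ms < self.apd_max_ms:
            raise ValueError("upstroke_ms must be positive and below apd_max_ms")
        if self.ca_delay_ms < 0:
            raise ValueError("ca_delay_ms must be non-negative")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not 0 < self.plateau_fraction < 1:
            raise ValueError("plateau_fraction must be in (0, 1)")


@dataclass
class RegionSpec:
    """A labeled tissue region with its refractoriness and waveform.

    Later regions override earlier ones where they overlap, so a typical
    slice is a full-grid working-myocardium region plus a sinoatrial-node
    ellipse on top.  ``intrinsic_cycle_ms`` enables automaticity.
    """

    label: str
    geometry: Rect | Ellipse
    erp_ms: float
    waveform: WaveformParams = field(default_factory=WaveformParams)
    intrinsic_cycle_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.erp_ms > 0:
            raise ValueError("erp_ms must be positive")
        if self.intrinsic_cycle_ms is not None and not self.intrinsic_cycle_ms > self.erp_ms:
            raise ValueError("intrinsic_cycle_ms must exceed erp_ms")


@dataclass
class SimProtocol:
    """Stimulation protocol.

    ``mode``: ``"field"`` (whole-edge stimulus, default left edge),
    ``"point"`` (local electrode at ``point_site``) or ``"none"``
    (automaticity only).  ``cycle_lengths_ms`` lists S1-S1 pacing cycle
    lengths, one step of ``pulses_per_step`` stimuli each; for restitution
    they run from long to short (the study paced from 2000 ms down to
    200 ms).
    """

    mode: str = "field"
    cycle_lengths_ms: list[float] = field(default_factory=list)
    pulses_per_step: int = 10
    total_duration_ms: float | None = None
    point_site: tuple[int, int] | None = None
    field_edge: str = "left"
    start_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("field", "point", "none"):
            raise ValueError("mode must be 'field', 'point' or 'none'")
        if self.mode == "point" and self.point_site is None:
            raise ValueError("point mode requires point_site")
        if any(cl <= 0 for cl in self.cycle_lengths_ms):
            raise ValueError("cycle lengths must be positive")
        if len(self.cycle_lengths_ms) > 1:
            diffs = np.diff(self.cycle_lengths_ms)
            if not np.all(diffs < 0):
                raise ValueError("cycle_lengths_ms must be strictly decreasing")
        if self.pulses_per_step < 1:
            raise ValueError("pulses_per_step must be at least 1")

    def stim_times(self) -> list[float]:
        times: list[float] = []
        t = self.start_ms
        if self.mode == "none":
            return times
        for cl in self.cycle_lengths_ms:
            for _ in range(self.pulses_per_step):
                times.append(t)
                t += cl
        return times

    def duration_ms(self, tail_ms: float = 800.0) -> float:
        if self.total_duration_ms is not None:
            return self.total_duration_ms
        stims = self.stim_times()
        last = stims[-1] if stims else self.start_ms
        return last + tail_ms


@dataclass
class ConductionSpec:
    """Wave speeds: isotropic or an ellipse about a fiber angle.

    ``fiber_angle_rad`` is measured from the +col (x) axis; speeds in m/s.
    """

    longitudinal_m_per_s: float = 0.5
    transverse_m_per_s: float | None = None
    fiber_angle_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.transverse_m_per_s is None:
            self.transverse_m_per_s = self.longitudinal_m_per_s
        if not (self.longitudinal_m_per_s > 0 and self.transverse_m_per_s > 0):
            raise ValueError("speeds must be positive")

    @property
    def isotropic(self) -> bool:
        return self.longitudinal_m_per_s == self.transverse_m_per_s


@dataclass
class ArtifactParams:
    """Recording artifacts the conditioning stage is expected to remove."""

    noise_sd: float = 0.0           # Gaussian SD as a fraction of amplitude
    drift_slope: float = 0.0        # fraction of amplitude per second
    polarity: int = 1               # -1 emulates a voltage dye (dimming on depolarization)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class Grid:
    """Image grid: shape in pixels and physical pixel pitch in mm."""

    shape: tuple[int, int] = (100, 100)
    pixel_size_mm: float = 0.1

    def __post_init__(self) -> None:
        if not (self.shape[0] > 0 and self.shape[1] > 0):
            raise ValueError("grid shape must be positive")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.mgrid[0:self.shape[0], 0:self.shape[1]]
        return rows * self.pixel_size_mm, cols * self.pixel_size_mm


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class WaveEvent:
    """One propagated beat: origin, per-pixel arrival and duration."""

    time_ms: float
    kind: str                       # "stimulus" | "spontaneous"
    origin: str                     # edge name, "point", or firing region label
    arrival_ms: np.ndarray          # H x W, nan where not activated
    duration_ms: np.ndarray         # H x W, nan where not activated
    captured: dict[str, bool] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Complete simulator truth for test oracles.

    ``region_labels`` holds, per pixel, the index into ``label_names``;
    ``events`` carry per-pixel arrival times and durations per beat.
    """

    grid: Grid
    label_names: list[str]
    region_labels: np.ndarray       # H x W int
    events: list[WaveEvent]
    cv_true: ConductionSpec
    stim_times_ms: list[float]
    params: dict = field(default_factory=dict)

    def activation_times(self, row: int, col: int) -> np.ndarray:
        """Strictly increasing activation times at one pixel."""
        t = [ev.arrival_ms[row, col] for ev in self.events
             if np.isfinite(ev.arrival_ms[row, col])]
        return np.asarray(t)

    def durations(self, row: int, col: int) -> np.ndarray:
        d = [ev.duration_ms[row, col] for ev in self.events
             if np.isfinite(ev.arrival_ms[row, col])]
        return np.asarray(d)

    def region_mask(self, label: str) -> np.ndarray:
        return self.region_labels == self.label_names.index(label)

    def last_offset_ms(self) -> float:
        """Time of last repolarization anywhere in the grid."""
        off = 0.0
        for ev in self.events:
            end = ev.arrival_ms + ev.duration_ms
            if np.isfinite(end).any():
                off = max(off, float(np.nanmax(end)))
        return off


# ---------------------------------------------------------------------------
# Restitution
# ---------------------------------------------------------------------------


def restitution_function(di_ms, w: WaveformParams):
    """Mono-exponential restitution: duration as a function of the
    preceding diastolic interval.

    D(DI) = apd_max - restitution_amplitude * exp(-DI / restitution_tau)

    Strictly increasing in DI and bounded above by ``apd_max_ms``.
    """
    di = np.asarray(di_ms, dtype=float)
    if np.any(di < 0):
        raise ValueError("diastolic interval must be non-negative")
    out = w.apd_max_ms - w.restitution_amplitude_ms * np.exp(-di / w.restitution_tau_ms)
    return float(out) if np.isscalar(di_ms) else out


def steady_state_duration(pcl_ms: float, w: WaveformParams, tol: float = 1e-9,
                          max_iter: int = 10_000) -> float:
    """Fixed point of D = f(PCL - D) under 1:1 pacing at ``pcl_ms``.

    Solved by damped fixed-point iteration; the DI is clamped at 0, so the
    result is valid even when the cycle length undercuts the rested
    duration.
    """
    d = min(w.apd_max_ms, 0.8 * pcl_ms)
    for _ in range(max_iter):
        di = max(pcl_ms - d, 0.0)
        d_new = restitution_function(di, w)
        d = 0.5 * d + 0.5 * d_new
        if abs(d_new - d) < tol:
            break
    return d


def beats_to_steady_state(pcl_ms: float, w: WaveformParams, tol_ms: float = 1.0,
                          max_beats: int = 500) -> int:
    """Paced beats needed for the duration to settle within ``tol_ms``.

    The restitution iteration D_{n+1} = f(PCL - D_n) converges slowly when
    the restitution slope approaches 1 (short cycle lengths), so an S1-S1
    step at a short PCL needs far more conditioning beats than one at a
    long PCL.
    """
    dss = steady_state_duration(pcl_ms, w)
    d = w.apd_max_ms
    last_exceed = 0
    for n in range(1, max_beats + 1):
        d = restitution_function(max(pcl_ms - d, 0.0), w)
        if abs(d - dss) >= tol_ms:
            last_exceed = n
    return min(last_exceed + 1, max_beats)


# ---------------------------------------------------------------------------
# Travel times and scheduling
# ---------------------------------------------------------------------------


def _travel_time_map(grid: Grid, seeds_px: np.ndarray, cv: ConductionSpec) -> np.ndarray:
    """Minimal elliptical-metric travel time (ms) from a seed set.

    For one seed the wavefront is an ellipse (anisotropy about the fiber
    angle); for a full-edge seed line the minimum over seeds reproduces a
    plane wave.
    """
    y_mm, x_mm = grid.coords_mm()     # y=row, x=col coordinates
    vl = cv.longitudinal_m_per_s
    vt = cv.transverse_m_per_s
    cos_a, sin_a = math.cos(cv.fiber_angle_rad), math.sin(cv.fiber_angle_rad)
    tt = np.full(grid.shape, np.inf)
    for r, c in np.atleast_2d(seeds_px):
        dy = y_mm - r * grid.pixel_size_mm
        dx = x_mm - c * grid.pixel_size_mm
        d_long = cos_a * dx + sin_a * dy
        d_trans = -sin_a * dx + cos_a * dy
        t = np.sqrt((d_long / vl) ** 2 + (d_trans / vt) ** 2)
        np.minimum(tt, t, out=tt)
    return tt


def _edge_seeds(shape: tuple[int, int], edge: str) -> np.ndarray:
    h, w = shape
    if edge == "left":
        return np.array([(r, 0) for r in range(h)])
    if edge == "right":
        return np.array([(r, w - 1) for r in range(h)])
    if edge == "top":
        return np.array([(0, c) for c in range(w)])
    if edge == "bottom":
        return np.array([(h - 1, c) for c in range(w)])
    raise ValueError(f"unknown edge {edge!r}")


def _label_map(grid: Grid, regions: list[RegionSpec]) -> np.ndarray:
    rows, cols = np.mgrid[0:grid.shape[0], 0:grid.shape[1]]
    labels = np.full(grid.shape, -1, dtype=int)
    for i, reg in enumerate(regions):
        inside = reg.geometry.contains(rows, cols)
        if not reg.geometry.within(grid.shape):
            raise ValueError(f"region {reg.label!r} extends outside the image grid")
        if not inside.any():
            raise ValueError(f"region {reg.label!r} covers no pixel")
        labels[inside] = i
    if (labels < 0).any():
        raise ValueError(
            "regions must cover the whole grid (make the first region a "
            "full-grid background)"
        )
    return labels


def build_activation_schedule(protocol: SimProtocol, regions: list[RegionSpec],
                              grid: Grid, cv: ConductionSpec | float) -> GroundTruth:
    """Run the event-driven capture/automaticity scheduler.

    Stimuli and spontaneous pacemaker firings are processed in time order.
    Each event launches a kinematic wave from its source; a region is
    captured iff the wave's arrival at the region exceeds the region's
    last activation by more than its ERP (strict).  Captured pixels get an
    arrival time (source time + travel time) and a restitution-determined
    duration; every activation resets the pacemaker clock of its region.
    """
    if not regions:
        raise ValueError("at least one region is required")
    if isinstance(cv, (int, float)):
        cv = ConductionSpec(longitudinal_m_per_s=float(cv))
    labels = _label_map(grid, regions)
    if protocol.mode == "point":
        r, c = protocol.point_site
        if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
            raise ValueError(f"point_site {protocol.point_site} outside grid {grid.shape}")

    # per-region pixel index lists and centroids
    region_pixels = [np.nonzero(labels == i) for i in range(len(regions))]
    centroids = []
    for rows, cols in region_pixels:
        cr, cc = rows.mean(), cols.mean()
        k = np.argmin((rows - cr) ** 2 + (cols - cc) ** 2)
        centroids.append((int(rows[k]), int(cols[k])))

    # travel-time map of the protocol source (shared by all stimuli)
    if protocol.mode == "field":
        stim_tt = _travel_time_map(grid, _edge_seeds(grid.shape, protocol.field_edge), cv)
        stim_origin = f"field:{protocol.field_edge}"
    elif protocol.mode == "point":
        stim_tt = _travel_time_map(grid, np.array([protocol.point_site]), cv)
        stim_origin = "point"
    else:
        stim_tt, stim_origin = None, ""
    spont_tt: dict[int, np.ndarray] = {}

    total = protocol.duration_ms()
    stim_times = [t for t in protocol.stim_times() if t < total]
    last_act = np.full(len(regions), -np.inf)        # region entry times
    for i, reg in enumerate(regions):
        if reg.intrinsic_cycle_ms is not None:
            last_act[i] = -reg.intrinsic_cycle_ms    # pacemaker due at t=0

    h, w = grid.shape
    last_act_px = np.full((h, w), -np.inf)
    last_dur_px = np.zeros((h, w))
    events: list[WaveEvent] = []
    stim_idx = 0

    def next_spontaneous() -> tuple[float, int]:
        t_best, i_best = np.inf, -1
        for i, reg in enumerate(regions):
            if reg.intrinsic_cycle_ms is None:
                continue
            due = last_act[i] + reg.intrinsic_cycle_ms
            if due < t_best:
                t_best, i_best = due, i
        return t_best, i_best

    while True:
        t_stim = stim_times[stim_idx] if stim_idx < len(stim_times) else np.inf
        t_spont, i_spont = next_spontaneous()
        t_ev = min(t_stim, t_spont)
        if not np.isfinite(t_ev) or t_ev >= total:
            break
        if t_stim <= t_spont:           # stimulus wins ties
            tt, origin, kind = stim_tt, stim_origin, "stimulus"
            stim_idx += 1
        else:
            if i_spont not in spont_tt:
                spont_tt[i_spont] = _travel_time_map(
                    grid, np.array([centroids[i_spont]]), cv)
            tt, kind = spont_tt[i_spont], "spontaneous"
            origin = regions[i_spont].label

        arrival = np.full((h, w), np.nan)
        duration = np.full((h, w), np.nan)
        captured: dict[str, bool] = {}
        for i, reg in enumerate(regions):
            rows, cols = region_pixels[i]
            entry = t_ev + tt[rows, cols].min()
            ok = (entry - last_act[i]) > reg.erp_ms
            captured[reg.label] = bool(ok)
            if not ok:
                continue
            a = t_ev + tt[rows, cols]
            di = np.maximum(a - (last_act_px[rows, cols] + last_dur_px[rows, cols]), 0.0)
            d = restitution_function(di, reg.waveform)
            # enforce strictly increasing per-pixel activation sequences
            valid = a > last_act_px[rows, cols]
            arrival[rows[valid], cols[valid]] = a[valid]
            duration[rows[valid], cols[valid]] = d[valid]
            last_act_px[rows[valid], cols[valid]] = a[valid]
            last_dur_px[rows[valid], cols[valid]] = d[valid]
            last_act[i] = entry
        events.append(WaveEvent(t_ev, kind, origin, arrival, duration, captured))

    return GroundTruth(
        grid=grid,
        label_names=[r.label for r in regions],
        region_labels=labels,
        events=events,
        cv_true=cv,
        stim_times_ms=stim_times,
        params={
            "protocol": asdict(protocol),
            "regions": [asdict(r) for r in regions],
            "grid": asdict(grid),
            "conduction": asdict(cv),
        },
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _template(tau: np.ndarray, duration: np.ndarray, upstroke_ms: float,
              plateau_fraction: float, tail_tau_ms: float = 6.0) -> np.ndarray:
    """Normalized beat template; tau is time since the 50%-upstroke point.

    Raised-cosine upstroke (10-90% width = ``upstroke_ms``; exactly 0
    before and exactly 1 after, so the 50% crossing sits at tau = 0 even
    for very slow nodal/calcium upstrokes) times a plateau /
    exponential-shoulder repolarization scaled so the 80%-repolarization
    crossing lands exactly at ``duration``.  Below the 20% level the decay
    switches to a fast terminal phase (``tail_tau_ms``), emulating rapid
    late phase-3 repolarization, so the trace is back at baseline before a
    subsequent beat even at short diastolic intervals.
    """
    # sin reaches +-0.8 (the 10/90% levels) at +-0.2952*pi, hence the span
    span = upstroke_ms / (2 * 0.295167) / 2.0   # half-width of the rise
    up = np.where(
        tau <= -span, 0.0,
        np.where(tau >= span, 1.0,
                 0.5 * (1.0 + np.sin(0.5 * math.pi * np.clip(tau, -span, span)
                                     / span))))
    t_plateau = plateau_fraction * duration
    tau_rep = (duration - t_plateau) / math.log(5.0)   # exp shoulder hits 0.2 at D
    with np.errstate(over="ignore"):
        shoulder = np.exp(-np.clip((tau - t_plateau) / tau_rep, 0, 60))
        tail = 0.2 * np.exp(-np.clip((tau - duration) / tail_tau_ms, 0, 60))
        rep = np.where(tau <= t_plateau, 1.0, np.where(tau <= duration, shoulder, tail))
    return up * rep


def render_movie(truth: GroundTruth, artifacts: ArtifactParams | None = None,
                 fps: float = 1000.0, modality: str = "Vm") -> FrameStack:
    """Render a FrameStack from a ground-truth activation schedule.

    Per-pixel trace = diastolic_level + polarity * amplitude * template,
    beats combined by maximum (tails never exceed the next upstroke).
    Calcium movies delay each activation by the region's ``ca_delay_ms``
    and slow the upstroke by ``ca_upstroke_factor``.  Noise and drift are
    seeded and reproducible.
    """
    if artifacts is None:
        artifacts = ArtifactParams()
    if fps < 100:
        raise ValueError("fps must be at least 100 Hz for meaningful activation timing")
    if modality not in ("Vm", "Ca"):
        raise ValueError("modality must be 'Vm' or 'Ca'")
    duration_ms = truth.params.get("protocol", {}).get("total_duration_ms")
    if duration_ms is None:
        stims = truth.stim_times_ms
        last_ev = max((ev.time_ms for ev in truth.events), default=0.0)
        duration_ms = max(stims[-1] if stims else 0.0, last_ev) + 800.0
    last_off = truth.last_offset_ms()
    ca_pad = max(
        WaveformParams(**_waveform_kwargs(r["waveform"])).ca_delay_ms
        for r in truth.params["regions"]
    ) if modality == "Ca" else 0.0
    if duration_ms < last_off + ca_pad:
        raise ValueError(
            f"movie duration {duration_ms:.0f} ms is shorter than the last "
            f"repolarization at {last_off + ca_pad:.0f} ms"
        )

    n_frames = int(round(duration_ms / 1000.0 * fps))
    t_ms = np.arange(n_frames) / fps * 1000.0
    h, w = truth.grid.shape
    n_px = h * w
    tpl_flat = np.zeros((n_frames, n_px))
    waveforms = [WaveformParams(**_waveform_kwargs(r["waveform"]))
                 for r in truth.params["regions"]]

    labels_flat = truth.region_labels.ravel()
    for ev in truth.events:
        arr_flat = ev.arrival_ms.ravel()
        dur_flat = ev.duration_ms.ravel()
        for i, wf in enumerate(waveforms):
            sel = np.isfinite(arr_flat) & (labels_flat == i)
            if not sel.any():
                continue
            a = arr_flat[sel]
            d = dur_flat[sel]
            up = wf.upstroke_ms
            if modality == "Ca":
                a = a + wf.ca_delay_ms
                up = up * wf.ca_upstroke_factor
            lo = max(0, int((a.min() - 6 * up) / 1000.0 * fps))
            hi = min(n_frames, int((a.max() + d.max() + 6 * (1 - wf.plateau_fraction)
                                    * d.max()) / 1000.0 * fps) + 2)
            if hi <= lo:
                continue
            tau = t_ms[lo:hi, None] - a[None, :]
            contrib = _template(tau, d[None, :], up, wf.plateau_fraction,
                                wf.tail_tau_ms)
            idx = np.nonzero(sel)[0]
            tpl_flat[lo:hi, idx] = np.maximum(tpl_flat[lo:hi, idx], contrib)

    amp = np.array([wf.amplitude for wf in waveforms])[labels_flat]
    dia = np.array([wf.diastolic_level for wf in waveforms])[labels_flat]
    frames = dia[None, :] + artifacts.polarity * amp[None, :] * tpl_flat
    if artifacts.drift_slope != 0.0:
        frames = frames + artifacts.drift_slope * amp[None, :] * (t_ms[:, None] / 1000.0)
    if artifacts.noise_sd > 0.0:
        rng = np.random.default_rng(artifacts.seed)
        frames = frames + rng.normal(0.0, artifacts.noise_sd, frames.shape) * amp[None, :]
    return FrameStack(
        frames=frames.reshape(n_frames, h, w),
        fps_hz=fps,
        pixel_size_mm=truth.grid.pixel_size_mm,
        modality=modality,
        stim_times_ms=[t for t in truth.stim_times_ms if t < duration_ms],
        provenance="slicemap simulator",
    )


def _waveform_kwargs(d: dict) -> dict:
    names = WaveformParams.__dataclass_fields__.keys()
    return {k: v for k, v in d.items() if k in names}


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------


def _truth_to_json(truth: GroundTruth) -> dict:
    def arr(a):
        return np.where(np.isfinite(a), a, None).tolist()

    return {
        "grid": asdict(truth.grid),
        "label_names": truth.label_names,
        "region_labels": truth.region_labels.tolist(),
        "cv_true": asdict(truth.cv_true),
        "stim_times_ms": list(truth.stim_times_ms),
        "params": truth.params,
        "events": [
            {
                "time_ms": ev.time_ms,
                "kind": ev.kind,
                "origin": ev.origin,
                "captured": ev.captured,
                "arrival_ms": arr(ev.arrival_ms),
                "duration_ms": arr(ev.duration_ms),
            }
            for ev in truth.events
        ],
    }


def _truth_from_json(d: dict) -> GroundTruth:
    def arr(a):
        return np.array([[np.nan if v is None else v for v in row] for row in a],
                        dtype=float)

    grid = Grid(shape=tuple(d["grid"]["shape"]), pixel_size_mm=d["grid"]["pixel_size_mm"])
    return GroundTruth(
        grid=grid,
        label_names=d["label_names"],
        region_labels=np.asarray(d["region_labels"], dtype=int),
        events=[
            WaveEvent(
                time_ms=ev["time_ms"],
                kind=ev["kind"],
                origin=ev["origin"],
                arrival_ms=arr(ev["arrival_ms"]),
                duration_ms=arr(ev["duration_ms"]),
                captured=ev["captured"],
            )
            for ev in d["events"]
        ],
        cv_true=ConductionSpec(**d["cv_true"]),
        stim_times_ms=d["stim_times_ms"],
        params=d["params"],
    )


def write_fixture(stack: FrameStack, truth: GroundTruth, out_dir) -> dict[str, Path]:
    """Write a movie fixture: 16-bit TIFF, metadata sidecar, ground truth.

    Round-trips losslessly through :func:`slicemap.conditioning.read_stack`
    for integer-valued (camera-count) frames.
    """
    if stack.shape != truth.grid.shape:
        raise ValueError("stack and ground truth have different grids")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": out / "movie.tif",
        "sidecar": out / "movie.json",
        "truth": out / "truth.json",
    }
    write_stack(stack, paths["tiff"], paths["sidecar"])
    paths["truth"].write_text(json.dumps(_truth_to_json(truth)))
    return paths


def read_ground_truth(path) -> GroundTruth:
    return _truth_from_json(json.loads(Path(path).read_text()))
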