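"""Protocol-level analyses: restitution, ERP, capture, automaticity,
and sinoatrial-vs-working-myocardium region classification.

The effective refractory period (ERP) is probed with an S1-S1 pacing
protocol: the cycle length is shortened step by step until 1:1 capture is
lost, and the ERP is reported as the midpoint of the bracketing cycle
lengths.  Below the 1:1 limit a region locks into k:1 capture (k stimuli
per propagated response); a sinoatrial-node region with a 900 ms ERP shows
2:1 capture at a 600 ms cycle length and 3:1 at 400 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .conditioning import FrameStack, TissueMask, Trace, extract_trace
from .mapping import DurationMap, duration80, segment_beats, activation_time

__all__ = [
    "RestitutionCurve",
    "ErpEstimate",
    "CaptureResult",
    "capture_ratio",
    "region_capture",
    "estimate_erp",
    "build_restitution",
    "detect_automaticity",
    "classify_regions",
]


@dataclass
class CaptureResult:
    """Capture at one pacing cycle length: ``ratio`` stimuli per response.

    ``ratio`` is None when the response pattern is irregular (no integer
    locking) or when nothing captures.
    """

    pcl_ms: float
    stimuli: int
    responses: int
    ratio: int | None

    def __post_init__(self) -> None:
        if self.responses > self.stimuli:
            raise ValueError("more responses than stimuli")
        if self.ratio is not None and self.ratio < 1:
            raise ValueError("capture ratio must be >= 1")


@dataclass
class ErpEstimate:
    """ERP bracket from an S1-S1 protocol: midpoint of the last cycle
    length with 1:1 capture and the first with capture loss."""

    erp_ms: float
    last_captured_pcl_ms: float
    first_lost_pcl_ms: float
    step_ms: float


@dataclass
class RestitutionCurve:
    """Mean duration (with SD and n) per pacing cycle length."""

    points: list[dict] = field(default_factory=list)
    modality: str = "Vm"
    condition_label: str = ""

    def __post_init__(self) -> None:
        pcls = [p["pcl_ms"] for p in self.points]
        if len(set(pcls)) != len(pcls):
            raise ValueError("duplicate pacing cycle lengths in curve")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points)


# ---------------------------------------------------------------------------
# Capture and ERP
# ---------------------------------------------------------------------------


def capture_ratio(activation_times_ms, stim_times_ms, tolerance_ms: float = 50.0,
                  n_discard: int = 2) -> CaptureResult:
    """Steady-state capture ratio (stimuli per propagated response).

    The first ``n_discard`` stimuli are dropped as a pacing transient.  A
    stimulus counts as captured when an activation falls within
    ``tolerance_ms`` after it.  Periodic locking is identified from the
    spacing of captured stimuli: if every captured stimulus is k stimuli
    after the previous one, the ratio is k; inconsistent spacing is
    reported as irregular (ratio None).
    """
    stims = np.sort(np.asarray(list(stim_times_ms), dtype=float))
    if stims.size == 0:
        raise ValueError("no stimuli supplied")
    acts = np.sort(np.asarray(list(activation_times_ms), dtype=float))
    pcl = float(np.median(np.diff(stims))) if stims.size > 1 else np.nan
    stims_ss = stims[n_discard:]
    if stims_ss.size < 2:
        raise ValueError("need at least 2 steady-state stimuli after discarding "
                         f"the first {n_discard}")
    captured_idx = []
    for i, s in enumerate(stims_ss):
        hit = np.any((acts >= s) & (acts <= s + tolerance_ms))
        if hit:
            captured_idx.append(i)
    responses = len(captured_idx)
    if responses == 0:
        return CaptureResult(pcl, int(stims_ss.size), 0, None)
    if responses == 1:
        # a single response in the window cannot establish a period
        return CaptureResult(pcl, int(stims_ss.size), 1, None)
    gaps = np.diff(captured_idx)
    ratio = int(gaps[0]) if np.all(gaps == gaps[0]) else None
    return CaptureResult(pcl, int(stims_ss.size), responses, ratio)


def estimate_erp(results: list[CaptureResult], step_ms: float) -> ErpEstimate:
    """ERP from a descending S1-S1 scan: midpoint of the capture bracket.

    ``last_captured`` is the shortest cycle length still showing 1:1
    capture; ``first_lost`` the longest one that lost it.
    """
    captured = [r.pcl_ms for r in results if r.ratio == 1]
    lost = [r.pcl_ms for r in results if r.ratio != 1]
    if not lost:
        raise ValueError("ERP outside tested range: 1:1 capture at every cycle length")
    if not captured:
        raise ValueError("ERP outside tested range: capture lost at every cycle length")
    last_captured = min(captured)
    first_lost = max(lost)
    if first_lost >= last_captured:
        warnings.warn(
            "non-monotone capture pattern: capture lost at a longer cycle "
            "length than the shortest captured one", stacklevel=2)
    return ErpEstimate(
        erp_ms=0.5 * (last_captured + first_lost),
        last_captured_pcl_ms=last_captured,
        first_lost_pcl_ms=first_lost,
        step_ms=step_ms,
    )


def region_capture(stack: FrameStack, pixels, tolerance_ms: float = 50.0,
                   n_discard: int = 2, cutoff_hz: float = 100.0
                   ) -> tuple[CaptureResult, list[float]]:
    """Capture analysis of a regional mean trace from a movie.

    Extracts the mean trace over ``pixels`` (a boolean map or TissueMask),
    low-pass filters and normalizes it, detects beats, and computes the
    steady-state capture ratio against the stack's stimulus times.
    Returns the :class:`CaptureResult` and the detected activation times.
    """
    from .conditioning import extract_trace, lowpass, normalize

    trace = normalize(lowpass(extract_trace(stack, pixels), cutoff_hz))
    windows = segment_beats(trace, stack.stim_times_ms,
                            capture_tolerance_ms=tolerance_ms)
    acts = [activation_time(trace, w) for w in windows]
    acts = [a for a in acts if np.isfinite(a)]
    result = capture_ratio(acts, stack.stim_times_ms, tolerance_ms, n_discard)
    return result, acts


# ---------------------------------------------------------------------------
# Restitution
# ---------------------------------------------------------------------------


def build_restitution(per_pcl_stacks, mask: TissueMask, modality: str = "Vm",
                      n_discard: int = 5, use_last: int | None = None,
                      condition_label: str = "",
                      capture_tolerance_ms: float = 50.0) -> RestitutionCurve:
    """Restitution curve: mean +/- SD of duration80 per pacing cycle length.

    ``per_pcl_stacks`` is an iterable of (pcl_ms, FrameStack) with
    conditioned movies, one per cycle length.  The first ``n_discard``
    beats of each record are dropped to reach steady state (alternatively
    ``use_last`` keeps only the final beats, useful when short cycle
    lengths need long conditioning trains); cycle lengths that lost 1:1
    capture are excluded with a warning.  Durations are pooled over
    in-mask pixels and post-transient beats.
    """
    points = []
    for pcl_ms, stack in per_pcl_stacks:
        mean_trace = extract_trace(stack, mask)
        windows = segment_beats(mean_trace, stack.stim_times_ms,
                                capture_tolerance_ms=capture_tolerance_ms)
        stims = stack.stim_times_ms
        if stims:
            acts = [activation_time(mean_trace, win) for win in windows]
            res = capture_ratio([a for a in acts if np.isfinite(a)], stims,
                                tolerance_ms=capture_tolerance_ms, n_discard=2)
            if res.ratio != 1:
                warnings.warn(
                    f"PCL {pcl_ms:g} ms lost 1:1 capture "
                    f"(ratio {res.ratio}); excluded from restitution curve",
                    stacklevel=2)
                continue
        use = windows[-use_last:] if use_last else windows[n_discard:]
        if not use:
            warnings.warn(f"PCL {pcl_ms:g} ms has no post-transient beat; excluded",
                          stacklevel=2)
            continue
        rows, cols = np.nonzero(mask.mask)
        durs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for win in use:
                for r, c in zip(rows, cols):
                    tr = Trace(stack.frames[:, r, c], stack.fps_hz, (int(r), int(c)))
                    d = duration80(tr, win)
                    if np.isfinite(d):
                        durs.append(d)
        if not durs:
            warnings.warn(f"PCL {pcl_ms:g} ms yielded no defined duration; excluded",
                          stacklevel=2)
            continue
        durs = np.asarray(durs)
        points.append({
            "pcl_ms": float(pcl_ms),
            "mean_duration_ms": float(durs.mean()),
            "sd_ms": float(durs.std(ddof=1)) if durs.size > 1 else 0.0,
            "n_beats": len(use),
            "n_samples": int(durs.size),
        })
    points.sort(key=lambda p: -p["pcl_ms"])
    return RestitutionCurve(points=points, modality=modality,
                            condition_label=condition_label)


# ---------------------------------------------------------------------------
# Automaticity
# ---------------------------------------------------------------------------


def detect_automaticity(activation_times_ms, stim_times_ms=None,
                        tolerance_ms: float = 50.0) -> dict:
    """Spontaneous (non-paced) activity and its rate.

    An activation is spontaneous when it is not within ``tolerance_ms``
    after any stimulus.  The rate (Hz) is 1000 over the median
    inter-activation interval of the spontaneous beats, reported when at
    least 3 are present.
    """
    acts = np.sort(np.asarray(list(activation_times_ms), dtype=float))
    stims = np.asarray(list(stim_times_ms or []), dtype=float)
    spont = []
    for a in acts:
        paced = np.any((a > stims) & (a <= stims + tolerance_ms)) if stims.size else False
        if not paced:
            spont.append(a)
    out = {"spontaneous": len(spont) > 0, "n_spontaneous": len(spont)}
    if len(spont) >= 3:
        out["rate_hz"] = 1000.0 / float(np.median(np.diff(spont)))
    return out


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------


def classify_regions(duration_map: DurationMap, risetime_map: np.ndarray,
                     mask: TissueMask, min_pixels: int = 100,
                     silhouette_threshold: float = 0.5) -> np.ndarray:
    """Partition tissue into nodal-like and working myocardium.

    Sinoatrial-node tissue shows longer AP/CaT duration and slower
    upstrokes than working myocardium, so pixels are 2-means clustered on
    standardized (duration, rise time); the cluster with the larger
    centroid sum is labeled nodal-like.  Initialization is deterministic
    (clusters seeded at the 10th/90th percentile feature points).  When the
    mean silhouette of the 2-way split falls below
    ``silhouette_threshold`` the feature distribution is considered
    unimodal (a forced split of one Gaussian scores ~0.35): everything is
    labeled working with a warning.

    Returns an H x W integer map: -1 outside mask, 0 working, 1 nodal-like.
    """
    dur = duration_map.durations_ms
    rise = np.asarray(risetime_map, dtype=float)
    sel = mask.mask & np.isfinite(dur) & np.isfinite(rise)
    n = int(sel.sum())
    if n < min_pixels:
        raise ValueError(f"only {n} pixels have both features (minimum {min_pixels})")
    feats = np.column_stack([dur[sel], rise[sel]])
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    score = z.sum(axis=1)
    init = np.vstack([
        z[np.argmin(np.abs(score - np.percentile(score, 10)))],
        z[np.argmin(np.abs(score - np.percentile(score, 90)))],
    ])
    km = KMeans(n_clusters=2, init=init, n_init=1, random_state=0).fit(z)
    centers = km.cluster_centers_
    if silhouette_score(z, km.labels_) < silhouette_threshold:
        warnings.warn("feature distribution looks unimodal; single label assigned",
                      stacklevel=2)
        labels = np.full(mask.mask.shape, -1, dtype=int)
        labels[sel] = 0
        return labels
    nodal_cluster = int(np.argmax(centers.sum(axis=1)))
    out = np.full(mask.mask.shape, -1, dtype=int)
    out[sel] = (km.labels_ == nodal_cluster).astype(int)
    return out
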