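"""Ready-made simulation scenarios mirroring the study's recordings.

These builders wire together regions, protocol and conduction settings for
the configurations exercised throughout the package: a homogeneous
ventricular slice under field stimulation (plane wave), a point-stimulated
slice for transverse CV, and an atrial slice containing a sinoatrial-node
(SAN) subregion with a long effective refractory period and, optionally,
intrinsic automaticity.

Default SAN waveform values are the package's own choices (slow ~80 ms
upstroke, long duration, 900 ms ERP, ~1 Hz intrinsic rate); the source
recordings characterize the SAN qualitatively, so these defaults aim for
a clearly separable nodal phenotype rather than a fitted one.
"""

from __future__ import annotations

import numpy as np

from .conditioning import FrameStack
from .simulate import (
    ArtifactParams,
    ConductionSpec,
    Ellipse,
    Grid,
    GroundTruth,
    Rect,
    RegionSpec,
    SimProtocol,
    WaveformParams,
    build_activation_schedule,
    render_movie,
)

__all__ = [
    "ventricular_waveform",
    "atrial_waveform",
    "san_waveform",
    "san_atrial_regions",
    "simulate_plane_wave",
    "simulate_point_source",
    "simulate_san_atrial",
    "simulate_restitution_series",
]


def ventricular_waveform(**overrides) -> WaveformParams:
    """Working ventricular myocardium: fast upstroke, APD ~340 ms at 1 Hz."""
    kw = dict(apd_max_ms=380.0, restitution_amplitude_ms=140.0,
              restitution_tau_ms=120.0, upstroke_ms=5.0)
    kw.update(overrides)
    return WaveformParams(**kw)


def atrial_waveform(**overrides) -> WaveformParams:
    """Working atrial myocardium: fast upstroke, shorter durations."""
    kw = dict(apd_max_ms=260.0, restitution_amplitude_ms=90.0,
              restitution_tau_ms=110.0, upstroke_ms=5.0)
    kw.update(overrides)
    return WaveformParams(**kw)


def san_waveform(**overrides) -> WaveformParams:
    """Sinoatrial node: slow (80 ms) upstroke and long duration."""
    kw = dict(apd_max_ms=420.0, restitution_amplitude_ms=80.0,
              restitution_tau_ms=150.0, upstroke_ms=80.0)
    kw.update(overrides)
    return WaveformParams(**kw)


def san_atrial_regions(shape=(40, 40), san_erp_ms: float = 900.0,
                       atrial_erp_ms: float = 250.0,
                       intrinsic_cycle_ms: float | None = None
                       ) -> list[RegionSpec]:
    """Atrial background with a SAN ellipse in the right half of the slice."""
    h, w = shape
    san = RegionSpec(
        label="san",
        geometry=Ellipse(center_row=h / 2 - 0.5, center_col=0.72 * w,
                         semi_row=0.22 * h, semi_col=0.18 * w),
        erp_ms=san_erp_ms,
        waveform=san_waveform(),
        intrinsic_cycle_ms=intrinsic_cycle_ms,
    )
    atrium = RegionSpec(
        label="atrium",
        geometry=Rect(0, 0, h, w),
        erp_ms=atrial_erp_ms,
        waveform=atrial_waveform(),
    )
    return [atrium, san]


def _grid_for(shape, fov_mm: float = 10.0) -> Grid:
    # keep the 1 cm field of view regardless of pixel count
    return Grid(shape=tuple(shape), pixel_size_mm=fov_mm / shape[1])


def simulate_plane_wave(speed_m_per_s: float = 0.5, shape=(40, 40),
                        fps: float = 1000.0, pcl_ms: float = 1000.0,
                        n_pulses: int = 1, waveform: WaveformParams | None = None,
                        artifacts: ArtifactParams | None = None,
                        modality: str = "Vm",
                        erp_ms: float = 250.0) -> tuple[FrameStack, GroundTruth]:
    """Field-stimulated homogeneous slice: a plane wave from the left edge."""
    wf = waveform or ventricular_waveform()
    regions = [RegionSpec("tissue", Rect(0, 0, shape[0], shape[1]),
                          erp_ms=erp_ms, waveform=wf)]
    protocol = SimProtocol(mode="field", cycle_lengths_ms=[pcl_ms],
                           pulses_per_step=n_pulses)
    truth = build_activation_schedule(protocol, regions, _grid_for(shape),
                                      ConductionSpec(speed_m_per_s))
    return render_movie(truth, artifacts, fps=fps, modality=modality), truth


def simulate_point_source(cv: ConductionSpec, shape=(40, 40),
                          fps: float = 1000.0, source_px=None,
                          waveform: WaveformParams | None = None,
                          artifacts: ArtifactParams | None = None
                          ) -> tuple[FrameStack, GroundTruth]:
    """Point-stimulated slice for transverse-CV measurement."""
    if source_px is None:
        source_px = (shape[0] // 2, shape[1] // 2)
    wf = waveform or ventricular_waveform()
    regions = [RegionSpec("tissue", Rect(0, 0, shape[0], shape[1]),
                          erp_ms=250.0, waveform=wf)]
    protocol = SimProtocol(mode="point", point_site=tuple(source_px),
                           cycle_lengths_ms=[1000.0], pulses_per_step=1)
    truth = build_activation_schedule(protocol, regions, _grid_for(shape), cv)
    return render_movie(truth, artifacts, fps=fps), truth


def simulate_restitution_series(pcls_ms, shape=(12, 12), fps: float = 500.0,
                                waveform: WaveformParams | None = None,
                                speed_m_per_s: float = 0.5,
                                measured_beats: int = 3,
                                artifacts: ArtifactParams | None = None,
                                tol_ms: float = 1.0):
    """One field-paced movie per cycle length for a restitution protocol.

    Each S1-S1 step runs enough conditioning beats for the duration to
    settle within ``tol_ms`` of its steady state (restitution converges
    slowly at short cycle lengths) plus ``measured_beats`` to analyze.
    Returns ``[(pcl_ms, FrameStack, n_conditioning_beats), ...]``.
    """
    from .simulate import beats_to_steady_state

    wf = waveform or ventricular_waveform()
    out = []
    for pcl in pcls_ms:
        n_settle = beats_to_steady_state(pcl, wf, tol_ms=tol_ms)
        n_pulses = n_settle + measured_beats
        regions = [RegionSpec("tissue", Rect(0, 0, shape[0], shape[1]),
                              erp_ms=min(250.0, 0.8 * pcl), waveform=wf)]
        protocol = SimProtocol(mode="field", cycle_lengths_ms=[pcl],
                               pulses_per_step=n_pulses)
        truth = build_activation_schedule(protocol, regions, _grid_for(shape),
                                          ConductionSpec(speed_m_per_s))
        stack = render_movie(truth, artifacts, fps=fps)
        out.append((pcl, stack, n_settle))
    return out


def simulate_san_atrial(pcl_ms: float, n_pulses: int, shape=(40, 40),
                        fps: float = 1000.0, san_erp_ms: float = 900.0,
                        atrial_erp_ms: float = 250.0,
                        intrinsic_cycle_ms: float | None = None,
                        speed_m_per_s: float = 0.5,
                        artifacts: ArtifactParams | None = None,
                        modality: str = "Vm",
                        total_duration_ms: float | None = None,
                        stim_start_ms: float = 20.0
                        ) -> tuple[FrameStack, GroundTruth]:
    """Atrial slice with a SAN subregion, S1-S1 field pacing from the left.

    With ``san_erp_ms=900`` this reproduces the study's observation of
    1:1 / 2:1 / 3:1 SAN capture at 1000 / 600 / 400 ms cycle lengths while
    the atrium follows 1:1 throughout.
    """
    regions = san_atrial_regions(shape, san_erp_ms, atrial_erp_ms,
                                 intrinsic_cycle_ms)
    protocol = SimProtocol(
        mode="field" if pcl_ms else "none",
        cycle_lengths_ms=[pcl_ms] if pcl_ms else [],
        pulses_per_step=max(n_pulses, 1),
        total_duration_ms=total_duration_ms,
        start_ms=stim_start_ms,
    )
    truth = build_activation_schedule(protocol, regions, _grid_for(shape),
                                      ConductionSpec(speed_m_per_s))
    stack = render_movie(truth, artifacts, fps=fps, modality=modality)
    return stack, truth
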