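# Methods

`slicemap` analyzes optical-mapping movies of cardiac tissue slices —
fluorescence recordings of transmembrane voltage (Vm) or intracellular
calcium (Ca) from a high-speed camera — and validates every estimator
against a bundled kinematic simulator whose ground truth is known exactly.
This note documents the models, the defaults and why, the numerical
choices, and what the simulator does and does not emulate.

## The kinematic simulator

The simulator is deliberately *kinematic*: it prescribes when each pixel
activates and what its waveform looks like, rather than solving a
reaction–diffusion (monodomain) model. That is what makes per-pixel ground
truth exact, and it is sufficient for validating measurement code, which
only sees arrival times and waveforms.

**Geometry and propagation.** A slice is a grid of pixels (default
100 × 100 over a 1 × 1 cm field of view, i.e. 0.1 mm pixels) partitioned
into labeled regions (rectangles/ellipses; later regions override earlier
ones). A wave launched at time *t₀* from a source — a stimulated image
edge (field stimulation), an electrode pixel (point stimulation), or a
spontaneously firing region's centroid — reaches pixel *p* at
*t₀ + τ(p)*, where *τ* is the minimum over source seeds of the elliptical
travel-time metric

τ = sqrt((d∥/v_L)² + (d⊥/v_T)²),

with d∥, d⊥ the displacement components along/across a configurable fiber
angle and v_L, v_T the longitudinal/transverse speeds (isotropic by
default, 0.5 m/s; human slice measurements span roughly 0.25–0.9 m/s).
An edge seed line yields a plane wave; a point seed yields elliptical
isochrones. Wave collisions and conduction block *within* a region are not
modeled; block is a region-level property (below).

**Refractoriness and capture.** Each region has an effective refractory
period (ERP). A wavefront captures a region iff its arrival at the region
(earliest in-region pixel) exceeds the region's last activation by
*strictly more* than the ERP. The strict rule makes the ERP equal to the
longest failing interval, matching the S1-S1 protocol definition, and
yields k:1 locking with k = floor(ERP/PCL) + 1 under periodic pacing at
cycle length PCL (property-tested over a grid of ERP × PCL). A region with
an intrinsic cycle length fires spontaneously whenever the time since its
last activation reaches that cycle, and *any* activation resets the clock
(phase reset); pacemakers are due at t = 0 when a record starts unpaced.

**Restitution.** Beat duration follows a mono-exponential restitution
function of the preceding diastolic interval DI (time from the previous
beat's 80%-repolarization to the next activation):

D(DI) = D_max − A · exp(−DI / τ_r),

clamped to DI ≥ 0. This is the minimal standard form that reproduces
monotone restitution curves. Defaults for working ventricular myocardium:
D_max = 380 ms, A = 140 ms, τ_r = 120 ms (≈ 340 ms APD at 1 Hz, in the
range reported for human ventricular slices); atrial: 260/90/110 ms;
sinoatrial node (SAN): 420/80/150 ms with an 80 ms upstroke. The SAN
numbers are this package's own choices — the source recordings
characterize nodal tissue qualitatively (slow upstroke, long duration,
long ERP, ~1 Hz automaticity) — and are chosen to give a clearly separable
nodal phenotype, not to fit data.

The fixed-point iteration D ← D(PCL − D) converges slowly where the
restitution slope approaches 1 (short cycle lengths): `beats_to_steady_state`
computes how many conditioning beats an S1-S1 step needs for the duration
to settle within a tolerance, and `simulate_restitution_series` sizes each
step accordingly (a 300 ms step needs ~40 beats; a 2000 ms step needs 1).

**Waveform template.** A beat at a pixel is rendered as
amplitude × f(t − t_act), with f a piecewise template: a raised-cosine
upstroke whose 10–90% rise time is the region's `upstroke_ms` (compact
support, so the 50% crossing is exactly at the scheduled activation time
even for very slow nodal upstrokes), a plateau to 60% of the duration, an
exponential shoulder scaled so the 80%-repolarization crossing lands
exactly at the restitution-determined duration, and a fast terminal decay
(τ = 6 ms) below the 20% level emulating rapid late phase-3
repolarization — without it the residual tail biases the measured APD at
short cycle lengths. Overlapping beats combine by maximum. Calcium movies
use the same schedule with activation delayed by `ca_delay_ms` (default
10 ms) and the upstroke slowed 3× (calcium transients rise and fall more
slowly than the action potential).

**Artifacts.** Additive Gaussian noise (SD as a fraction of amplitude),
linear baseline drift (fraction of amplitude per second), and polarity
inversion (voltage dyes dim on depolarization) are applied last, from a
seeded generator; rendering is bit-reproducible given the seed. Not
emulated: motion/contraction artifacts (the experiments this emulates used
an excitation–contraction uncoupler), photon shot noise statistics,
heterogeneous dye loading, vignetting, and depth-averaged (transmural)
signals. Passing the recovery tests therefore demonstrates estimator
correctness on clean-to-moderately-noisy, motion-free data — not
robustness to every artifact of real recordings.

## Signal conditioning

The analysis chain mirrors standard optical-mapping practice: 3 × 3
in-mask spatial averaging (shrinking neighborhoods at mask borders, no
zero padding, so edges are not dimmed), zero-phase low-pass filtering,
first-order drift removal, 0–1 normalization per pixel, polarity
orientation.

- **Low-pass**: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), default cutoff 100 Hz (the conventional range is
  100–150 Hz). Zero-phase filtering is essential: a causal filter would
  bias every activation time late. Cutoffs at or above Nyquist are
  rejected.
- **Drift removal** fits one least-squares line over the full trace and
  subtracts it (keeping the constant term). With several beats in the
  record the beat-shape contribution to the fitted slope cancels; for
  short records dominated by a single beat a `diastolic_only` option fits
  the line on the lowest 30% of samples instead.
- **Masking**: a pixel is tissue if its robust beat amplitude
  (0.5–99.5 percentile range) exceeds `snr_threshold` × the SD of its
  diastolic (below mid-range) samples. Threshold 0 keeps everything;
  a mask that excludes every pixel is an error, not an empty result.
- **Polarity** is auto-detected from the skewness of the (mask-mean)
  signal: transient-dominated traces are skewed toward the transient
  direction. |skew| below 0.05 is ambiguous → warning plus explicit
  override. Flipping is about the median (baseline), and the operation is
  idempotent.

## Feature extraction

Activation time is the first upward crossing of 50% of the beat's
upstroke amplitude; duration (APD80/CaTD80) runs from activation to the
first downward crossing of the 80%-repolarization level after the beat
peak. Both are linearly interpolated between samples (sub-frame
resolution); "first crossing" is the deterministic tie-break. Amplitude
(min/max) is computed per beat window, not per record, so beat-to-beat
amplitude changes (e.g. alternans) do not couple beats. Duration is
measured from the 50% activation time, the literal reading of
"time between activation and repolarization".

Beats are segmented on the in-mask mean trace: derivative peaks above 25%
of the maximum derivative, minimum separation 150 ms, each window opening
60 ms before its upstroke. A beat is tagged to a stimulus when its
upstroke falls within 50 ms after it (configurable; the tolerance exceeds
any simulated conduction latency and is below the shortest tested cycle
length); untagged beats are spontaneous. Per-pixel maps apply the shared
windows so that one beat means the same beat everywhere; pixels without a
valid crossing are NaN, and a beat missing in more than half the mask is
an error.

## Conduction velocity

A local plane t(x, y) = a + g·(x, y) is least-squares fitted to the
activation map in a (2r+1)² window (default r = 2) around each pixel;
speed = 1/|g| in mm/ms = m/s and the propagation direction is g/|g|.
Pixels are undefined when fewer than half the window is defined, the fit
is degenerate, R² < 0.8, or speed exceeds 2 m/s (an outlier gate ~2× the
fastest plausible slice CV; near-synchronous activation at a stimulated
edge otherwise produces unbounded speeds). On exactly affine activation
fields the fit is exact for any radius; near a point source the plane
approximation biases speed upward ∝ curvature, falling below 1% beyond
~10 pixels from the source. The per-slice summary is the median with IQR
(robust to residual fit outliers); mean ± SD is available. Transverse CV
from point stimulation is the regression slope of distance-versus-time
along a caller-supplied ray — the direction is an input, as in practice,
where it is chosen relative to fiber orientation by eye.

## Protocol analyses

- **Capture ratio**: after discarding the first 2 stimuli as a pacing
  transient, a stimulus is captured when an activation falls within the
  tolerance window after it. The ratio is the common spacing (in stimuli)
  of captured stimuli — exact for periodic locking regardless of window
  length, and "irregular" (None) when spacings disagree. Dividing total
  stimuli by responses would misreport whenever the window is not a
  multiple of the locking period.
- **ERP**: from a descending S1-S1 scan, the estimate is the midpoint of
  the bracket [longest cycle length that lost 1:1, shortest that kept
  1:1], with the half-step as the implied uncertainty. All-captured or
  all-lost scans are errors ("ERP outside tested range").
- **Restitution curves**: per cycle length, mean ± SD of per-pixel
  durations over post-transient beats (default: discard the first 5
  beats, or keep only the last k via `use_last` when convergence-aware
  trains are used); cycle lengths that lost 1:1 capture are excluded with
  a warning, and points are ordered by descending cycle length.
- **Automaticity**: an activation not attributable to any stimulus is
  spontaneous; with ≥ 3 spontaneous beats the rate is 1000 / median
  inter-beat interval (median: robust to a missed or doubled detection).
- **Region classification**: pixels are 2-means clustered on standardized
  (duration, rise time); the cluster with the larger centroid sum is
  nodal-like. Initialization is deterministic (seeds at the 10th/90th
  percentile of the summed standardized features), so results are
  reproducible. A mean silhouette below 0.5 marks the split as unimodal
  (a forced 2-way split of a single Gaussian scores ≈ 0.35; two separated
  phenotypes score ≳ 0.7) and a single label is returned with a warning.

## Statistics

Group summaries are mean ± SEM (SD on restitution curves), two-group
comparisons use the two-tailed Welch t-test, and multi-group comparisons
use one-way ANOVA with post-hoc Tukey HSD via the studentized range
distribution; restitution curves are compared with an independent
ANOVA + Tukey at each cycle length. The experimental unit is the slice:
pixels within a slice are spatially correlated, so between-condition tests
take one summary value per slice per condition. Pixel-level entry points
exist but should be treated as exploratory. Summary-statistic entry points
(`welch_t_from_summary`, `tukey_from_summary`) allow re-analysis of
printed (n, mean, SD) tables. Tests cross-check the parametric p-values
against hand-written label-permutation oracles (Welch statistic;
max studentized range) and verify the k = 2 Tukey ↔ pooled-t equivalence
exactly. Degenerate inputs are explicit: two zero-variance groups with
equal means give p = 1, with unequal means an error.

## Problem sizes in the test suite

Recovery tests run at the sizes that first make the property measurable:
full 100 × 100 grids at 1000 fps for duration-map recovery, 40 × 40 for
capture and CV (capture is region-level and CV is window-level, so the
sensor-resolution grid adds pixels but no new structure), 12–16 pixel
grids at 500 fps for restitution/ERP scans where only the regional mean
trace matters. Each choice is stated in the corresponding test.

## Known limitations

- Kinematic propagation cannot represent curvature-dependent velocity,
  source-sink block, or re-entry; the simulator validates measurement,
  not electrophysiology.
- A wave blocked by a refractory region still reaches pixels beyond it
  (travel times ignore the block), which is wrong for geometries where the
  blocked region is the only path.
- The plane-fit CV is a documented stand-in for the semi-automated
  tooling used in practice, validated only against simulation truth.
- Classification assumes exactly two phenotypes; more-than-two-region
  slices would need k selection, which is out of scope.
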