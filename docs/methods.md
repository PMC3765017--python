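# Methods

## The measurement model

A force-plate actometer records the ground-reaction force of a freely
moving small rodent through four strain-gauge load cells, one under each
corner of a rigid 20 cm × 20 cm sensing plate. Each cell is digitized to
12-bit integer counts at 100 samples/s and mapped back to gram-force by a
per-channel affine calibration `force = gain · (count − offset)`. The
default gain of 0.2 gf/count equals the instrument's force resolution;
offsets default to zero because the acquisition chain balances the
channels before a session. Both are exposed as calibration inputs since
real hardware drifts.

Two signals are derived from the four channels:

* **Fz**, the net vertical force — the sum of the four channels at each
  0.01-s instant. Tremor appears as oscillation of Fz about the standing
  body-weight load.
* **The center of force (COP)** — the principle of moments,
  `x = Σ xᵢFᵢ / ΣFᵢ` (likewise y), with (xᵢ, yᵢ) the corner positions.
  With non-negative loads this is a convex combination of the corners and
  always lies on the plate. Frames whose total load falls below 25% of
  body weight (animal rearing against the cage wall, partially unloading
  the plate) are flagged invalid rather than divided through; the
  threshold is configurable.

## Tremor spectra

Fz from the first 60 s of a session (movement is maximal early on) is
expressed as a percent of body weight — a motionless animal sits at 100% —
so spectra are comparable between a ~10 g mutant and a ~17 g control
without weight confounds. The series is cut into 12 consecutive,
non-overlapping 5.00-s segments of 500 samples. Each segment is
mean-removed, multiplied by a 500-point periodic Hanning window, and
Fourier transformed; the one-sided squared magnitude is compensated for
the window's power loss:

    P[k] = c_k |FFT(w·x)[k]|² / (N · Σw²),   c_k = 2 except DC/Nyquist.

With this scaling the total one-sided power of a segment estimates the
segment variance (Parseval consistency), and power carries units of
(%body weight)² per 0.2-Hz bin. The 12 per-segment spectra are averaged
bin-wise (a Welch-style estimate with non-overlapping windows) and the
average restricted to the closed band 2.5–30.0 Hz by bin selection — not
a time-domain filter — which excludes both slow postural drift and
frequencies near Nyquist.

Design points that were genuinely open, and the choices made:

* **DC handling.** The ~100% standing load would dominate every spectrum;
  the per-segment mean is removed before windowing because tremor is an
  oscillation about the standing load. Without removal, every metric
  would describe the 0-Hz bin.
* **Per-bin vs per-Hz power.** Power is reported per 0.2-Hz bin, not as a
  density; the spectrum writer records this in its header.
* **Half-power geometry.** The five summary metrics are: peak power (the
  maximum bin), frequency at peak power (that bin's frequency; ties break
  to the lowest frequency for determinism), the half-power **bandwidth**
  (distance between the outermost frequencies where power crosses half
  the maximum, located by linear interpolation between adjacent bins;
  when the spectrum is still above half power at a band edge the edge is
  the crossing), the **center frequency** (the midpoint of those two
  crossings), and the **13–20 Hz band power** (trapezoidal area under the
  spectrum with interpolated endpoints at exactly 13 and 20 Hz — the
  summary band for broadband high-frequency tremor). For multimodal
  spectra the *outermost* crossings are the only parameter-free reading
  of a single lower and upper limit.
* **Degenerate spectra.** A spectrum whose maximum power is below
  1e-24 (%BW)² is treated as "no oscillation" and metrics raise an error:
  a bit-constant recording leaves ~1e-61 of double-precision rounding
  residue after mean removal, which must not masquerade as a peak.

## Locomotion

COP positions at 100 Hz are reduced to one point per 0.5 s by **block
averaging** the valid samples of each 50-sample block. Averaging (rather
than sampling the instantaneous position every 0.5 s, available as a
config switch) suppresses tremor-induced COP jitter that would otherwise
inflate apparent travel precisely in the most tremulous animals. A block
with no valid sample carries the previous block's position forward.
Each trajectory point stands for one elapsed half-second; timestamps are
block end-times.

**Distance traveled** is the summed Euclidean step length over the full
6-min session. **Low-mobility bouts** use a virtual circle of radius
15.0 mm: a 5.00-s timer runs while the animal stays within the circle
around its anchor; leaving the circle re-anchors at the exit point and
resets the timer; surviving 5.00 s tallies a bout, re-anchors at the
current point and resets the timer. This renewal reading makes a
motionless animal tally exactly `floor(T / 5.00)` bouts in `T` seconds.
Whether the circle should instead track the animal continuously is not
decidable from the verbal rule; a trailing-window variant is implemented
behind `mode="trailing"` (default `renewal`), and the two agree for
motionless sessions.

## Group comparisons

Each of the seven per-animal variables (five spectral, distance, bouts)
is compared across groups with a Kruskal–Wallis omnibus test followed by
all-pairs Mann–Whitney U tests, Bonferroni-adjusted by the number of
pairs (capped at 1). The rank-based default was chosen because the
metrics are skewed, heavy-tailed scalars at modest group sizes; a
parametric path (one-way ANOVA omnibus, Welch t pairwise) is available by
flag, and degenerate zero-variance input falls back to the rank path with
p = 1 when every observation is identical.

## The simulator

`actometry.synthetic` generates sessions with the statistical structure
of the eight study groups, because no raw recordings of the original
cohorts exist in machine-readable form. A session is: body weight drawn
from the group's normal distribution (twitcher 10.4 ± 1.6 g, wildtype
16.9 ± 1.8 g at 36 days); a bounded random-walk COP path (per-block
speeds, diffusing heading, a two-state pause Markov chain, reflecting
walls at ±95 mm); Fz = weight × (1 + tremor); the force distributed onto
the four corners by the bilinear weights that exactly invert the moment
computation; white sensor noise of 0.1 gf per channel (electronic noise
at half the quantization step); and 12-bit quantization through the
calibration. Everything is reproducible from one seed
(`numpy.random.SeedSequence` spawning per animal).

Tremor components, all parameterized by RMS amplitude as a percent of
body weight so the normalization stage can be tested across weight
distributions:

* **narrowband** (harmaline-like): a phase-diffused sinusoid; the
  half-width parameter sets the approximate Lorentzian half-linewidth.
  Preset: 12.2 Hz, 4% RMS.
* **broadband** (twitcher-like): Gaussian white noise brick-wall
  band-passed to [f0 − hw, f0 + hw]. Preset: 15.8 ± 3 Hz, 2% RMS.
* **blunted** (harmaline on a twitcher or transplanted background): the
  broadband model plus the narrowband component attenuated to 10% of the
  wildtype-harmaline amplitude — a modeling knob mirroring the damped
  drug response, not a claimed biological constant.
* The untreated wildtype preset is low-frequency (< 8 Hz) movement-band
  power only (2.5–7.5 Hz, 1% RMS); true wildtype movement spectra are not
  tabulated anywhere, so this is an explicit assumption.

Transplanted-group weights (15.5 g / 10.0 g means) and every locomotion
parameter (wildtype ~40 mm/s with rare pauses, mutants slower with long
pauses, harmaline suppressing locomotion) are modeling choices fixed once;
they shape only the locomotor metrics, not the spectral recovery tests.

**What the simulator does not emulate:** gait-cycle structure and footfall
impacts, rearing and wall-supported postures (COP validity is exercised
synthetically instead), slow sensor drift, inter-animal tremor-frequency
variability within a group, and any coupling between locomotion and
tremor amplitude. Passing recovery tests therefore shows the *pipeline*
is correct and well-calibrated on signals with the right spectral and
kinematic structure — not that real animals would yield these exact
numbers.

## Numerical and scale choices

* Frequency grid: exactly sample_rate/500 = 0.2 Hz; peak frequencies are
  always grid points.
* The single-segment Parseval identity holds only in expectation: one
  windowed 500-sample segment estimates the variance with a sampling sd
  of ≈6% (the Hanning weights reduce the effective sample count), so the
  5% consistency property is asserted on the averaged multi-segment
  estimator the pipeline actually uses.
* Statistical recovery tests run on 60-s simulated sessions (the tremor
  analysis consumes only the first minute) with fixed seed sets; the
  cohort-separation check uses 100 cohorts of 10 animals per group.
* Quantization round-trip error is bounded by gain/2 per sample; the
  recording text format is lossless for integer counts.

## Known limitations

* The bout rule's circle semantics (renewal vs continuously tracking) is
  an interpretation; both are implemented but only the renewal reading is
  pinned by the floor(T/5) identity.
* Brick-wall band-passing gives the broadband preset slightly heavier
  spectral shoulders than a physiological tremor band would have; center
  frequency recovery is insensitive to this, bandwidth estimates less so.
* The simulator draws one body weight per session and holds it constant;
  real sessions include slow weight-shift artifacts.
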