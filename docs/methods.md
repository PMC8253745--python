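# Methods

This note documents the models, estimators and numerical choices behind
`vestigait`, what the synthetic walking simulator does and does not
emulate, and the limitations a user should keep in mind.

## Stimulus model

The electrical vestibular stimulus (EVS) is zero-mean Gaussian white
noise, low-pass filtered with a Butterworth filter applied forward and
backward (zero phase), mean-removed, and linearly scaled so the largest
absolute sample equals the target peak current. Defaults: 200 samples/s,
25 Hz cutoff, 4th order (the stated order is the designed filter; the
bidirectional pass doubles the effective roll-off to ≈48 dB/octave),
5.0 mA peak. Peak and RMS cannot both be exact under a single linear
scale; the peak is treated as the binding constraint because it is the
safety-relevant hardware limit, and the RMS is emergent. For an
8-minute realization the extreme-value ratio peak/σ ≈ √(2 ln N_eff)
with N_eff ≈ 2·cutoff·duration effective independent samples predicts
an RMS near 5.0/4.4 ≈ 1.1 mA; the measured seed-averaged value is
≈1.13 mA. Rates below twice the cutoff are refused (aliasing).

## Synthetic walking trials

The simulator produces the streams an instrumented-treadmill experiment
records — per-belt 3-axis forces and moments at 200 samples/s, EMG-like
activity at 2000 samples/s, marker-cluster centroids at 100 samples/s —
with exact ground truth. It is a signal-level emulator, not a
musculoskeletal model.

* **Timing.** Stride period 2·60/78 ≈ 1.538 s (78 steps/min metronome),
  with 2% coefficient-of-variation timing jitter; feet alternate at
  half-stride offsets.
* **Vertical load.** Each stance (60% of the stride) follows a
  double-bump profile (loading and push-off peaks near 22% and 78% of
  stance) scaled to a 700 N body weight, with fast onset/offset ramps so
  contact begins with a realistic loading rate; this is what makes
  threshold-based event detection accurate to a few milliseconds.
* **Center of pressure.** Plate moments are generated from the foot's
  mediolateral landing position and an anterior–posterior sweep at belt
  speed (0.8 m/s), so `cop = (−My/Fz, Mx/Fz)` recovers the true foot
  trajectory. Measurement noise: 2 N on vertical force, 0.3 N·m on
  moments — the few-millimeter CoP resolution typical of instrumented
  treadmills at stance loads.
* **Foot placement.** Step widths are drawn per step around the
  condition's mean; landings are anchored to the midline (not a random
  walk) so the sample mean converges. With probability
  `cross_step_prob` a foot lands across the belt midline, as happens in
  narrow-base walking; the belt a stance loads is chosen by the landing
  position, so cross-steps naturally corrupt per-belt event detection.
* **Coupling.** Each output channel receives
  `gain · gate(φ) · (kernel ⊛ evs)(t − delay)` on top of a phasic
  baseline, where `gate` is a raised-cosine window in stride phase
  (value 1 at its center; integral over one stride = width/2 · T). This
  realizes the assumed linear stimulus–response relationship with
  phase- and muscle-specific modulation. Default kernels are normalized
  to unit peak transfer magnitude so `gain` is the peak transfer in
  output units per mA: a biphasic ≈200 ms pulse (band ≈0–20 Hz) for
  EMG, a Gaussian low-pass (≈0–10 Hz) for the mediolateral GRF.
  Baseline EMG envelopes imitate the qualitative phasing of the three
  muscles (gastrocnemius burst in late stance, gluteus medius in early
  stance, bimodal erector spinae around both heel strikes); exact shapes
  are free parameters. EMG is floored at zero (half-wave), so
  rectification downstream is near-linear on it.
* **Trunk dynamics.** T6 velocity comes from a noise-driven stable
  limit-cycle oscillator: a radial Ornstein–Uhlenbeck amplitude
  (contraction 4 per stride) and a diffusing phase, with a second
  harmonic for waveform realism. `noise_sd` controls the divergence of
  neighboring trajectories and hence the LDE. The noise-free phase ramp
  is built from the wrapped sample index so the orbit repeats bitwise —
  a cumulative-sum ramp accumulates float rounding that masquerades as
  divergence (≈0.3–0.5 per stride on noiseless data).
* **Condition presets.** normal (step width 0.27 ± 0.02 m, trunk noise
  0.08, full gains), stabilized (0.09 ± 0.01 m, trunk noise 0.03, gains
  ×0.4), wide (0.35 m, +0.08 m vs normal, gains ×0.6), narrow (0.16 m,
  −0.11 m vs normal, trunk noise 0.05, 25% cross-steps, gastrocnemius
  ×0.6 / erector spinae ×1.8 / net GRF ×1.5). The width deltas mirror
  the magnitudes reported for these manipulations; coupling-gain ratios
  across conditions are free parameters chosen to point in the reported
  directions, not asserted as measured values.

What the simulator does **not** emulate: volume-conducted stimulus
artifacts in EMG, electromechanical delay structure, anatomical force
sharing, arm swing, sagittal-plane control, marker soft-tissue motion,
or any quantitative relation between stabilization demand and coupling
gain. Passing tests therefore show that the estimators recover known
injected structure under realistic rates, jitter and noise — not that
real tissue behaves like the generator.

## Gait events

Primary detector: per-belt vertical force rising/falling through 5% of
the median peak stance force (0.2 s refractory, sub-sample crossing by
linear interpolation). The primary path is abandoned when left/right
strikes fail to interleave strictly **or** when a per-belt stride time
exceeds 1.5× its median — cross-steps merge two stances on one belt
without breaking alternation, so the alternation check alone is not
sufficient. Fallback: the summed-belt CoP. At the instant of new-foot
contact the combined CoP reverses from its most posterior excursion and
sweeps forward, so heel strikes are taken at posterior extrema of the
summed anterior–posterior CoP (minimum peak distance 0.7 step periods,
step period from the dominant CoP frequency); anterior maxima mark the
completion of weight transfer and are assigned as opposite-foot
toe-offs. Feet are assigned from the mediolateral CoP during the
following single support, with the global left/right parity chosen by
majority vote so individual cross-steps cannot flip labels. Stride
times are first differences of same-foot strikes; step widths are the
absolute mediolateral distance between heel-cluster centroids at the
strike sample, flagged missing on marker dropout.

## Signal conditioning and stride segmentation

EMG envelopes: full-wave rectification, zero-phase 6th-order
Butterworth low-pass at 20 Hz, per-stride time normalization onto a
1000-point cycle grid, averaging across strides, then division by the
channel's maximum across all conditions (a study-level, not per-trial,
normalization). Coherence inputs: (rectified) signals are zero-phase
6th-order low-pass filtered at 100 Hz and brought to 200 samples/s
(integer decimation where possible, polyphase resampling otherwise;
inputs already at 200 samples/s pass through; upsampling is refused).
The two mediolateral belt forces are summed before conditioning, since
cross-stepping makes per-belt forces unattributable.

Stride segments span `[strike_i − 0.5·T_i, strike_{i+1} + 0.5·T_i]` —
half a stride of neighboring data per side, so wavelet edge distortion
falls outside the analyzed stride. Segments are aligned on each limb's
own heel strike so left and right responses can be pooled. Pad
boundaries are stored per segment: cropped cores concatenate back to
the original signal bit-exactly, and pad cropping after the transform
is exact. Strides lacking a neighbor are excluded and counted, never
silently dropped.

## Wavelet coherence and gain

The analytic Morlet wavelet ψ(t) = π^(−1/4) e^(iω₀t) e^(−t²/2) with
ω₀ = 6 is used at scales s = ω₀/(2πf) with energy normalization
(1/√s); kernels are truncated at ±5 s and applied by FFT convolution.
Coherence is invariant to the normalization convention; gain is
reported with this energy convention. The frequency grid is 0.5–25 Hz
in 0.25 Hz steps, covering the band where EVS–EMG coupling is expected
(EVS–GRF coupling concentrates below ~10 Hz).

Per stride, Pxx = |Wx|², Pyy = |Wy|² and Pxy = Wx·conj(Wy) are formed
on the padded segment; the time axis of each per-stride spectrum (auto
and cross alike) is linearly resampled to the grand-average stride
duration; pads are cropped; spectra are averaged across strides. A
fixed target grid (the nominal stride length, 308 samples at 200
samples/s) is used inside the study pipeline so limbs, channels and
subjects share one (τ, f) grid. C = |Pxy|²/(Pxx·Pyy) lies in [0, 1] by
Cauchy–Schwarz applied to the stride average — no clipping; grid points
with vanishing auto-spectra are flagged undefined (NaN), never
zero-filled. G = |Pxy/Pxx|. Left/right limb maps are pooled by
averaging at the coherence level.

Significance: the standard bound for magnitude-squared coherence from
N independent segments, `1 − α^(1/(N−1))` — 0.0179 ≈ 0.018 for N = 256
at α = 0.01. Padding-induced overlap is removed by cropping before
averaging, but consecutive strides are not perfectly independent at the
lowest frequencies, where one wavelet spans several strides; the
measured null exceedance on uncoupled 256-stride data stays within
[0.002, 0.03] over the 0.5–25 Hz grid.

## Local divergence exponent

Trunk velocity is obtained by three-point (central) differentiation of
the T6 mediolateral position (one-sided at the endpoints), then
time-normalized so every stride spans 100 samples (25,600 samples for
256 strides). The series is delay-embedded (dimension 5, delay 10
samples = 0.1 stride — conventional for treadmill-gait LDE analyses;
both configurable); each point's nearest neighbor outside a Theiler
window of half a stride is found with a KD-tree (exact: at most
2·theiler+1 indices can be inadmissible, and 2·theiler+8 candidates are
queried, so the first admissible hit is the global nearest admissible
neighbor); the mean log Euclidean distance is tracked over one stride.
The LDE is the ordinary least-squares slope of this curve over 0–0.5
stride. Zero distances are floored at 10⁻¹⁵ of the signal range (only
reachable on exactly periodic input). The estimate is invariant to
amplitude scaling of the input. A three-dimensional marker state can be
substituted by embedding any velocity component; the mediolateral
component is the default because the stimulus perturbs frontal-plane
balance.

## Statistics

Cluster-based permutation test (paired, two conditions): pointwise
paired t statistics; suprathreshold clusters at the two-sided α = 0.05
critical value under 4-connectivity on the (τ, f) grid; cluster
statistic = signed t mass; null distribution of the maximum absolute
cluster mass over random per-subject condition-order flips (the exact
exchangeable scheme for paired data); cluster
p = (1 + #{null ≥ |mass|})/(n_perm + 1), so p ≥ 1/(n_perm+1). All grid
points enter the test; no pre-masking by significant coherence.

Repeated-measures ANOVA: one-way within-subject decomposition,
F = MS_condition/MS_error with df (k−1, (k−1)(n−1)); both classical
η² = SS_condition/SS_total and partial η² are reported since published
values do not always identify the variant. Planned pairwise
comparisons are uncorrected paired t-tests (normal vs each modified
condition). No sphericity correction is applied. Missing cells raise.

## Problem sizes used by the tests

The validation suite scales simulations to desk size: null calibration
and gate-phase recovery use the full 256 strides; the coupling-gain
ladder (4 levels) and the stabilized-vs-normal directional checks use
128 strides with 20 (LDE) and 10–20 (coherence) seeds on one muscle
channel; cluster-test error control uses 100 null repetitions of 500
permutations on a 40×30 grid with 11 subjects; the Rosenstein oracle
comparison uses an 1,800-sample series against an all-pairs reference.
The full suite runs in about four minutes on a single core.

## Known limitations

* The segment-count significance bound treats strides as independent;
  low-frequency wavelet overlap makes this approximate below ~2 Hz.
* Duration normalization uses linear interpolation of spectra along the
  time axis; strongly non-stationary spectra within a stride would be
  slightly smoothed.
* The LDE is a whole-cycle summary; phase-dependent stability is out of
  scope.
* Gain is reported without pointwise confidence intervals; partial or
  conditional coherence is not implemented.
* The CoP fallback assumes treadmill walking (anterior landings swept
  backward at belt speed); it is not suitable for overground data.
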