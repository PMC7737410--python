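# Methods

`synergyemg` implements a complete analysis chain for multi-channel
forearm surface EMG recorded during eight-direction index-finger
movements at two elbow postures, together with a synthetic-data
generator that provides ground truth for every stage. This note
documents the models, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Signal model and synthetic data

The generator emulates a 96-electrode cylindrical forearm grid (12
rings x 8 electrodes, 20 mm axial spacing, 40 mm radius; 95 recording
channels plus one ground electrode on the hand dorsum). Muscle sources
are point sources on or under the surface:

- **Superficial sources** couple to electrodes through an exponential
  surface-distance decay with a length constant of about one
  inter-electrode spacing, giving a localized footprint.
- **Deep sources** use a circumferential length constant of half the
  forearm circumference, so their footprint spreads over the whole ring
  at their axial position — the cross-sectional signature of deep
  muscle activity.

Each tuned source carries a cosine direction tuning: its activation
envelope in a trial toward direction theta is
`max(0, a0 + W cos(theta_eff − PD))`, gated by a smooth ramp that rises
0.4 s after trial start. Intrinsic-frame sources see the screen
direction rotated by the elbow angle (`theta_eff = theta − 90°` at
Elbow 90), which is the mechanism that makes intrinsic-coordinate
decoding outperform extrinsic decoding. The default source set plants
4 superficial and 3 deep tuned sources (PDs spread over the circle,
a0 = 0.5, W = 0.4) plus two untuned noise generators: a broadband
cross-sectional artifact and 50 Hz line noise.

The fast carrier under each envelope is Gaussian noise band-passed to
20–450 Hz (clamped to 0.45 fs at reduced sampling rates), so the
rectified mean of a source signal is proportional to its envelope.
Sensor noise has two parts, each calibrated against the clean mixed
signal power: spectrally white noise (`snr_db`) and per-channel
movement-artifact noise — broadband carriers with independent 1 Hz
amplitude wander (`baseline_snr_db`). Both default to 0 dB (noise power
equal to the mixed signal power, so total noise is 3 dB above signal).
The level was calibrated during design so that the classification
stage operates in the non-saturated regime the study's confusion
matrices show: at 10 dB the synthetic task saturates (several input
types at accuracy 1.0) and comparisons between input types degenerate
to ties; at 0 dB the EMG-side inputs are clearly off-ceiling while the
denoised ICA path stays near its ceiling, which is the regime the
study describes. The ground electrode couples to
no source and receives 10x less noise, making it the least-vibrating
channel by construction.

Default desk-scale conditions: 1024 Hz EMG, 100 Hz cursor, 2 s trials,
0.5 s rest gaps, 8 directions x 2 postures x 10 repetitions (160
trials, about 6.7 min of recording). Full-scale settings (2048 Hz, 80
repetitions) remain available through `SimConfig`.

What the generator does **not** emulate: motor-unit discharge
statistics, volume-conduction frequency shaping with depth, electrode
impedance drift, fatigue, posture-dependent electrode shift, and
trial-to-trial amplitude variability. Consequently, passing tests show
that the pipeline recovers planted structure under realistic mixing and
noise — not that it would recover the same quantities from human
recordings.

## Preprocessing

Raw EMG is filtered with a zero-phase 4th-order Butterworth band-pass
(10–1000 Hz, upper edge clamped to 0.45 fs) plus a Q = 35 IIR notch at
50 Hz; forward-backward application doubles the effective order and
gives > 26 dB attenuation at 50 Hz. The ground reference is identified
as the channel with minimal standard deviation (ties to the lowest
index) and removed, leaving 95 channels. Movement onset is the first
cursor sample whose Euclidean displacement from the trial-start
position exceeds 2 % of the final displacement magnitude.
Classification windows are half-open [−0.2 s, 0.3 s) around onset at
50 Hz — exactly 25 samples. Direction labels are extrinsic (screen
frame) as recorded; the intrinsic frame rotates Elbow-90 labels 90°
clockwise, i.e. two 45° index steps (the sign is configurable because
the screen numbering convention fixes the rotation only up to
reflection).

## ICA stage

The decomposition follows X = AS with a symmetric FastICA (log-cosh
contrast), restarted with an incremented seed on non-convergence. The
component count is the signal-subspace dimension: covariance
eigenvalues above 1.5x the median eigenvalue (the white-noise floor),
capped at 24. A fixed large count is deliberately avoided: with
broadband sensor noise the whitened data contain a Gaussian subspace in
which the ICA rotation is unidentifiable and symmetric FastICA cannot
converge. The unmixing may be estimated on a temporal subsample
(default every 8th sample) and is applied to the full recording.

Component rejection is automated: a component is excluded when its
spectral flatness (Wiener entropy of the Welch PSD) exceeds 0.6 AND the
autocorrelation of its rectified signal at a 20 ms lag is below 0.2 —
i.e. it is spectrally white and carries no slow amplitude modulation.
This criterion stands in for expert visual screening; thresholds are
configurable and reported in the pipeline log.

## Synergy extraction (E = TM)

Signals are converted to pseudo-joint-torque envelopes: divide by the
mean rectified amplitude over the whole recording, rectify, apply a
zero-phase 2nd-order Butterworth low-pass at 5 Hz, clip filter ringing
at zero, and resample to 50 Hz. The factorization E = TM uses
hierarchical alternating least squares: every column of T and row of M
is replaced by its exact non-negative least-squares minimizer given the
others, so the Euclidean objective is non-increasing by construction
(asserted to 1e-10 in the tests). Denominators are guarded at 1e-12;
synergy rows that collapse to zero are re-initialized once (followed
immediately by an exact update, preserving monotonicity) and then
allowed to die. Initialization is uniform random scaled by
sqrt(mean(E)/s); non-convexity is handled by random restarts.

The synergy count is the smallest rank with VAF > 0.9 whose VAF plateau
{(r, VAF(r)) : r >= s} fits a line with MSE < 1e-4. VAF is the
uncentered global ratio 1 − ||E − TM||²/||E||² (the muscle-synergy
literature standard); a per-signal-averaged variant is exposed
(`vaf_mode="per_signal"`) for comparison. Each candidate rank keeps the
best of several random restarts plus a warm start grown from the best
lower-rank solution, which makes the global VAF curve non-decreasing by
construction. The rank scan runs on every 2nd envelope sample (25 Hz):
the envelopes are 5 Hz band-limited, so this halves the cost without
information loss; the selected rank is then refit at 50 Hz. Candidate
ranges follow the study design (3–15 for IC input, 3–30 for EMG input
at full scale; 3–12 and 3–16 at desk scale).

A structural property of the synthetic data worth knowing: because the
planted tuning is exactly cosine, the true envelope amplitudes across
trials lie in span{1, cos(theta), sin(theta)} — a rank-3 cone — so on
synthetic data the selected rank sits near 3 for both input types
regardless of the source count. Real EMG envelope spaces are richer,
which is why the study's EMG-synergy counts (about 18) exceed its
ICA-synergy counts (about 12); that ordering is not reproduced by this
generator, and the module/classification comparisons below do not
depend on it.

## Modules, cosine tuning, preferred directions

Synergies are extracted from three condition datasets (Elbow 0, Elbow
90, Total) at the rank selected on the Total dataset. All condition
synergy vectors (in channel space for EMG-synergy, IC space for
ICA-synergy) are compared by their scalar product — the normalized
inner product, in [0, 1] for non-negative vectors — and clustered by
UPGMA (average linkage on 1 − SP), merging while the average
inter-cluster SP stays strictly above 0.75, ties broken toward the
lowest-index pair. The implementation is a direct O(n³) agglomeration;
scipy's linkage/fcluster and an exhaustive from-scratch average-linkage
oracle serve as independent cross-checks in the tests.

Direction tuning of each synergy uses the mean activation per trial
over a [0, 1.5) s post-onset window (the classification epoch is too
short to average over the tuned plateau), averaged per direction, and
fitted by ordinary least squares to m(theta) = a0 + a1 cos(theta) +
a2 sin(theta). On 8 equally spaced directions the design is orthogonal,
so the coefficients equal the discrete Fourier terms and the fit is
exact for any true cosine tuning. The preferred direction is
atan2(a2, a1) mod 360°; the tuning weight W = sqrt(a1² + a2²). m is
divided by its maximum before the fit, making W a dimensionless
modulation ratio (divide-by-mean and no normalization are exposed). PD
is flagged undefined when W <= 1e-3.

Within a module, Elbow-90 PDs are compensated by 90° clockwise and the
PD error is the mean absolute circular deviation from the circular mean
(resultant-vector mean; deviations as minimal angular distances).
Modules are typed by their channel-space footprint (ICA-synergy vectors
are mapped through |A| of the retained mixing columns): the
weight-weighted standard deviation of axial position (normalized by the
grid's axial extent) against the circumferential deviation around the
weighted circular mean (normalized by 360°); axial spread >=
circumferential spread means *parallel* (superficial signature),
otherwise *local* (deep signature). Group comparisons of tuning weights
use Welch's two-sample t-test.

## Classification

The four input types — EMG-input (95 channel envelopes), IC-input
(retained-IC envelopes), EMG-synergy and ICA-synergy (activation rows
of T from the full-dataset factorization) — are epoched identically
(25 samples at 50 Hz) and evaluated in both coordinate frames with
stratified fivefold cross-validation; stratification is joint over
direction x posture so every input type and both frames share identical
splits. Note the EMG/IC input types are envelopes: decimating the raw
20–450 Hz carrier to 50 Hz would alias it into noise and destroy the
amplitude information that carries direction.

The classifier is a small convolutional network written directly in
numpy: one 3x3 convolution with 32 filters over the signals x 25 trial
image, ReLU, 2x2 max-pooling, a 64-unit ReLU hidden layer and an 8-way
softmax; training uses Adam (1e-3), batch size 32, up to 50 epochs with
early stopping (patience 8) on a 10 % validation split of the training
folds, restoring the best weights. Features are z-scored with
training-fold statistics only. Training is bit-deterministic given the
seed. With fewer than 20 trials per class the epoch budget is capped
at 40 and a warning is emitted.

## Pipeline

`synergyemg all --config cfg.yaml` (or `run_all` from Python) executes
simulate → preprocess → ica → synergy → modules → classify against one
HDF5 container, with per-stage seeds derived by hashing one global seed
with the stage name, a JSON manifest (config snapshot, seeds, wall
times, SHA-256 content hashes per stage group) and stage-level resume:
a stage whose container group exists is reloaded, and anything
downstream of a recomputed stage is recomputed. Each stage reloads its
own outputs from the container after writing, so resumed and fresh runs
see bit-identical inputs.

## Known limitations

- The component-rejection criterion is a heuristic stand-in for expert
  IC screening and is reported as such in the pipeline log.
- The selected synergy rank on synthetic data reflects the rank-3
  structure of planted cosine tuning (see above), not the richer rank
  structure of real EMG.
- The CNN architecture is a fixed minimal stand-in; no hyperparameter
  search is performed.
- Circular statistics use the resultant-vector mean; with PDs spread
  near-uniformly the circular mean is ill-conditioned and PD errors
  near 90° should be read as "no consistent direction".
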