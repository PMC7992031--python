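# Methods

This note documents the models and procedures implemented in `ictonet`,
the assumptions behind them, the tunable parameters that matter, and the
design choices made where the methodology is genuinely open.

## Signal model of the synthetic cohorts

The generator (`ictonet.synth`) emulates source-level resting-state
recordings: `n_regions` regional time series (default 90) at `fs` = 600 Hz
for `duration` = 300 s.  Region *i* emits

    x_i(t) = a_i(t) · cos(2π f_i t + φ_i) + ε_i(t),        X ← M X

- **Carriers.** `f_i` is drawn uniformly in the alpha band (8–13 Hz) per
  region, with a random phase offset.  The per-region frequency jitter
  avoids degenerate phase-locking between regions.
- **Envelopes.** `a_i = exp(s·z_i − s²/2)` with `s = log_amp_sigma`
  (default 0.5) and `z_i` stationary unit-variance Ornstein–Uhlenbeck
  processes with relaxation time `envelope_timescale` (default 0.3 s, a
  typical cortical envelope timescale; it also sets the envelope bandwidth
  ≈ 1/(2πτ) ≈ 0.5 Hz, keeping signal power inside the band).  The
  exponentiation keeps envelopes strictly positive; it mildly shrinks the
  driver correlation ρ to (e^{s²ρ}−1)/(e^{s²}−1), about 3% at ρ = 0.8.
- **Ground-truth coupling.** The OU drivers' correlation matrix is
  `I + W_truth`, where `W_truth` is an Erdős–Rényi-style graph: each pair
  carries correlation `base_strength` (default 0.5) with probability
  `base_density` (default 0.15, i.e. expected degree ≈ 13 at 90 regions).
  Patients get `patient_effect` (default 1.6) applied multiplicatively to
  density (optionally strength), capped at valid values with a warning.
  If the assembled correlation matrix is not positive semidefinite the
  spectrum is clipped at zero and rescaled to unit diagonal.
- **Leakage.** `M = I + leakage_strength·B` with `B` random (zero
  diagonal, entries ~ N(0, 1/n)) mixes channels instantaneously — the
  zero-lag artifact that orthogonalized AEC is designed to cancel.  No
  lagged leakage is modelled.
- **Sensor noise.** White noise at `sensor_noise` (default 0.2) times the
  median signal RMS, added before mixing.

What the generator does **not** emulate: 1/f background spectra, activity
outside the alpha band, non-stationary artifacts, inter-regional lags,
volume-conduction geometry, or realistic covariate–connectivity
relationships (covariates are independent synthetic draws that only
exercise the correlation statistics).  Tests passing on this generator
therefore validate the pipeline's statistical machinery — leakage
suppression, null calibration, effect recovery — not its behaviour on any
particular real dataset.

## Preprocessing

Zero-phase 6th-order Butterworth band-pass (applied forward–backward, so
the net response is |H|²; attenuation 2 Hz beyond the band edges exceeds
40 dB), polyphase resampling 600 → 250 Hz (ratio 5/12), truncation to the
first 200 s, and ten contiguous non-overlapping 20 s segments.  The filter
runs on the full recording before segmentation so segment interiors carry
no filter edge effects.  The stage order is fixed:
bandpass → downsample → truncate → segment.

## Connectivity and the surrogate null

For each segment and each unordered region pair, the zero-lag projection
is removed by time-domain least squares in both directions; the Hilbert
envelopes of the residuals are Pearson-correlated with the partner's raw
envelope, and the two directed values are averaged — making the weight
exactly symmetric.  Negative envelope correlations are clipped to zero by
default (the downstream node model is excitatory and needs nonnegative
weights); absolute-value mode is selectable.  Envelopes are computed per
segment, not on the whole recording, so the per-segment surrogate null is
matched; no additional envelope smoothing is applied.

The null destroys cross-channel dependence while preserving each
channel's amplitude distribution exactly and its spectrum approximately:
every channel is replaced by an independent IAAFT surrogate (default 99
surrogates, 10 iterations, ending on the amplitude-adjustment step so the
surrogate is an exact value permutation), and the full network is
recomputed per surrogate dataset.  A connection is retained — with its
original weight, not binarized — iff its rank-based one-sided p-value
(1 + #{null ≥ obs})/(1 + n_surrogates) is ≤ 0.05; ties count against
retention.  With 99 surrogates the smallest attainable p is 0.01; a
configuration whose surrogate count cannot attain the requested level is
rejected at validation.  Weighted retention was chosen over binarization
because it preserves information and the global coupling sweep absorbs
scale; both conventions are config-selectable.

## Node dynamics

Each node is a canonical theta neuron:

    dθ_i = [(1 − cos θ_i) + (1 + cos θ_i)(I₀ + K Σ_j w_ij (1 − cos(θ_j − θ_s)))] dt
           + (1 + cos θ_i) σ dW_i

- `I₀ = −1.2`: subthreshold excitability; the uncoupled noise-free node
  has a stable phase θ_s = −arccos((1+I₀)/(1−I₀)) and an unstable phase
  θ_u = +arccos(·).  At I₀ > 0 the fixed points annihilate (SNIC) and the
  node rotates with period π/√I₀.
- Noise enters through the input current (multiplied by the same
  (1 + cos θ) factor as the drive); an additive-phase variant is not
  provided.  `σ = 1.0` by default, chosen once so that an uncoupled node
  truly rests (occupancy ≈ 0.01 over 2000 time units) while noise-driven
  escapes still occur on observable timescales — the regime in which
  network coupling, not the noise floor, drives the statistic.
- Coupling `(1 − cos(θ_j − θ_s))` is nonnegative, ≈ 0 at rest and maximal
  mid-rotation, so seizure activity spreads excitatorily along edges; no
  degree normalization (the shared K interval absorbs scale).
- Euler–Maruyama with `dt = 0.01` (noise kicks stay well under π/4 per
  step; a warning fires if more than 1% of steps exceed it), all nodes
  initialized at rest θ_s so every transition is noise-driven, and the
  first `t_transient = 100` time units discarded of `t_total = 2000`.
  The integrator is a compiled kernel; trajectories are only stored on
  request.

**Seizure labelling.** A node is instantaneously *escaped* when its phase,
wrapped relative to θ_s, lies beyond θ_u and outside a `rest_margin`
(default 1.0 rad) arc just below θ_s — i.e. on the rotating branch.  A
rotating node necessarily re-transits the neighbourhood of θ_s once per
cycle, and the transit time does not vanish relative to the rotation
period, so purely instantaneous labels would cap the measurable seizure
fraction well below 1 even under sustained rotation.  Since one rotation
episode is one continuous seizure, the labels are morphologically closed
over `t_close = 1.5` time units (≈ one rotation period): gaps shorter than
the window are bridged.  With this convention BNI spans the full range 0
to 1 as K grows; `t_close = 0` recovers the raw instantaneous labels.
A mirrored-margin rule (margin below θ_s equal to θ_u − θ_s) was rejected
because at I₀ = −1.2 the fixed points are nearly antipodal
(θ_u − θ_s ≈ 3.32 > π) and the mirrored rest arc covers the whole circle.

## BNI and the coupling interval

`BNI(K)` is the mean over noise realizations of the node-and-time mean
seizure occupancy after the transient; it is 0 exactly for K = 0, σ = 0.
Because any single K is arbitrary, the subject statistic integrates the
BNI curve over an interval [K1, K2] calibrated **once per study** on
held-out control-like reference networks: the upper search bound is
expanded geometrically (×1.5) until the pooled reference BNI reaches the
upper target, a fixed linear grid (default 10–16 points) is laid over
[0, K_max], and K1/K2 are the outermost grid points with pooled BNI ≤ 0.05
and ≥ 0.95.  The same grid and interval are then frozen for every subject
and segment, and echoed into the output metadata.  BNI^ is the trapezoidal
integral over [K1, K2] divided by (K2 − K1), so it lives in [0, 1];
raw-area mode is selectable and rankings are identical because the
interval is fixed.  ⟨BNI^⟩ and its standard error summarize a subject's
segments.

Two degenerate regimes are detected rather than silently tolerated: if
the pooled BNI plateaus below the ceiling target (more coupling no longer
raises occupancy), calibration fails with diagnostics reporting the
fraction of isolated reference nodes, and reference candidates whose
thresholded network leaves any node isolated are skipped at the draw
stage — an isolated node's occupancy stays at the noise floor at every K,
so such a network cannot express the full BNI range.  Subject networks
are never filtered; their isolated nodes are genuine signal.

## Group statistics

One-sided Mann-Whitney U with the directional alternative "patients
greater" (exact null when both groups ≤ 30 without ties, otherwise normal
approximation with tie and continuity corrections; the method used is
recorded).  The ROC sweeps unique score thresholds; AUC by trapezoid
equals U/(n₁n₂) exactly under the shared half-credit tie convention — an
identity asserted in the tests on arbitrary tied data.  The operating
point maximizes the Youden index, ties broken toward higher sensitivity
("optimal operating point" admits several readings; Youden is the standard
one and the choice is recorded in output).  Covariate correlations are
plain two-sided Pearson r with pairwise deletion; covariates with fewer
than 3 complete pairs or zero variance are skipped with a flag, and no
multiple-testing correction is applied across covariates.

## Problem sizes and numerical choices

Full-scale defaults (90 regions, 300 s, 99 surrogates, t_total = 2000 per
K-point) are configuration values intended for study runs.  The shipped
tests and the acceptance script exercise the identical code paths at
desk scale, as the package's own choice of validation conditions: 16
regions (12 for the null-calibration replicate), 60 s recordings cut to
two 20 s segments, 19 surrogates (the smallest count attaining the 5%
level), a 10-point coupling grid, and t_total = 1000.  At reduced region
count the coupling density is raised (0.45) so the thresholded networks
keep an expected degree comparable to the 90-region setting — degree, not
density, is the dynamically relevant scale.  The no-effect rejection-rate
check exploits exchangeability: with `patient_effect = 1` all subjects are
drawn i.i.d., so random relabelings of one pipeline run estimate the null
rejection rate without re-running the dynamics hundreds of times.

Other numerics: correlation matrices are repaired by eigenvalue clipping
only when needed; Hilbert transforms are batched per chunk of pairs; all
randomness flows from one master seed through named child streams
(subject, segment, surrogate index, K-point, realization), so every stage
is independently reproducible and two runs with the same config and seed
are bit-identical.

## Known limitations

- The seizure-labelling rule and the dynamics constants (σ, dt, t_total)
  are package choices documented above, not published values; conclusions
  that depend on their exact values should be checked by sweeping them.
- BNI^ of a subject whose thresholded network has isolated nodes is
  bounded below 1 by construction; this is informative, not an artifact,
  but it makes the statistic sensitive to the edge-pruning level.
- The synthetic cohort's effect size is a free parameter; recovery tests
  demonstrate sensitivity of the pipeline, not expected effect sizes in
  any real population.
- Envelope correlation is the only connectivity metric implemented; no
  lagged couplings, no other frequency bands.
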