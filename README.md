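# ictonet

Brain network ictogenicity (BNI) analysis for source-level resting-state
electrophysiology.  The package asks a mechanistic question: *how prone is a
subject's functional brain network to generating seizures in silico?*  It
infers alpha-band functional networks from regional time series, places a
canonical phase-oscillator model of seizure transitions on every network
node, and summarizes each subject by the fraction of simulated time the
network spends in the seizure state, integrated over a calibrated range of
global coupling strengths.  The resulting statistic separates patient from
control cohorts and can be evaluated as a diagnostic classifier.

It is written for computational neuroscientists and methodologists who want
a tested, reproducible reference implementation of the full pipeline, plus
a synthetic-cohort generator with known ground truth for validating every
stage.

## The pipeline

1. **Preprocess** — zero-phase band-pass to the alpha band (8–13 Hz),
   anti-aliased resampling to 250 Hz, truncation to the first 200 s, and
   division into ten non-overlapping 20 s segments.
2. **Connectivity** — per segment, a 90×90 functional network from the
   amplitude envelope correlation (AEC) of pairwise-orthogonalized signals:
   for each region pair the zero-lag component is regressed out in both
   directions, Hilbert envelopes are correlated, and the two directed
   estimates are averaged, cancelling instantaneous source leakage.
3. **Surrogate pruning** — 99 IAAFT surrogates (10 iterations) of every
   regional series give a per-connection null distribution; connections
   that do not exceed the 95% significance level are removed.
4. **Dynamics** — each node is a theta neuron near a SNIC bifurcation,

   dθᵢ = [(1 − cos θᵢ) + (1 + cos θᵢ)(I₀ + ξᵢ(t) + K Σⱼ wᵢⱼ (1 − cos(θⱼ − θ_s)))] dt,

   with excitability I₀ = −1.2, white noise ξ, and global coupling K
   scaling the thresholded weights wᵢⱼ.  Rest is the stable phase θ_s;
   seizure is the rotating phase.
5. **BNI** — BNI(K) is the average fraction of time nodes spend in the
   seizure state.  A coupling interval [K1, K2] is calibrated once per
   study on reference networks so that BNI spans ~0 to ~1, and each
   segment's statistic BNI^ is the (width-normalized) integral of BNI
   over that fixed interval; ⟨BNI^⟩ averages a subject's 10 segments.
6. **Group statistics** — one-sided Mann-Whitney U (patients > controls),
   ROC/AUC with the exact AUC = U/(n₁n₂) identity, Youden operating point
   (sensitivity, specificity, accuracy), and Pearson correlations of
   ⟨BNI^⟩ with clinical covariates.

Because the underlying MEG recordings of the motivating cohort are not
public, a first-class synthetic generator (`ictonet.synth`) emulates the
data: narrow-band oscillations with log-normal envelopes driven by
correlated Ornstein–Uhlenbeck processes (a known ground-truth coupling
graph, denser in the patient group) plus instantaneous linear mixing that
the orthogonalization stage must cancel.

## Worked example

```python
import numpy as np
from ictonet import (GroundTruthSpec, generate_ground_truth, simulate_recording,
                     preprocess, network_from_segment, edge_null, threshold,
                     ThetaParams, bni_curve, bni_hat)

spec = GroundTruthSpec(n_regions=16, duration=60.0, base_density=0.45,
                       base_strength=0.6, seed=0)
truth = generate_ground_truth(spec, "control", rng_seed=1)
rec = simulate_recording(truth, spec, "control", "subj0", rng_seed=2)

seg = preprocess(rec, total_s=40.0, segment_s=20.0)[0]   # (16, 5000) at 250 Hz
net = network_from_segment(seg)
ens = edge_null(seg, n_surrogates=19, rng_seed=3)
pruned = threshold(net, ens, alpha=0.05)
print(f"density raw {net.density:.2f} -> pruned {pruned.density:.2f}")

params = ThetaParams(t_total=1000.0, t_transient=100.0, seed=4)
curve = bni_curve(pruned, np.linspace(0.0, 12.0, 7), params, n_realizations=2)
print(np.round(curve.bni_values, 3))
print(f"BNI^ over [0, 12] = {bni_hat(curve, 0.0, 12.0):.3f}")
```

Output:

```
density raw 0.79 -> pruned 0.26
[0.011 0.342 0.828 0.941 0.955 0.961 0.969]
BNI^ over [0, 12] = 0.753
```

The raw network is dense (envelope correlations are biased upward by
finite segments and residual leakage); the surrogate test prunes it to a
density (0.26) near the generator's ground truth (0.45, minus true edges
lost to the significance test, plus a ~5% false-positive floor).  The BNI
curve rises from the uncoupled noise floor (~0.01) to saturation as
coupling grows; the area under it, normalized by the interval width, is
the segment's seizure-propensity statistic.

A whole cohort runs through the CLI:

```bash
ictonet run --config study.yaml --seed 7 --out runs/study01
```

which writes per-stage artifacts (cohort, segments, raw and thresholded
networks, per-subject BNI table, `results.json` with U, p, AUC and the
operating point) plus a provenance manifest under one directory.

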