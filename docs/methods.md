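# Methods

## Distortion extraction

The MHD voltage induced by aortic blood flow reverses sign when the
subject's orientation in the bore flips from head-first to feet-first,
while the cardiac signal does not. Beat-aligned differencing of the two
recordings therefore cancels the shared ECG and recovers the distortion:
`D = (ECG_HF − ECG_FF) / 2`. The assumptions are that (a) beat morphology
is identical across the two sessions, (b) the i-th annotated beat in HF
corresponds to the i-th in FF, and (c) the distortion is beat-locked.
Assumption (b) is the weakest: the two recordings are separate
acquisitions, so pairing by beat index is a heuristic, and the resulting
pair count (the minimum of the two segment counts, logged per subject) is
reported rather than asserted. Residual morphology differences appear as
leakage of cardiac signal into the templates.

Processing chain and defaults:

| step | default | note |
|---|---|---|
| working rate | 500 Hz | recordings at other rates (e.g. Holter 257 or 1024 Hz) are polyphase-resampled first; annotations are remapped arithmetically, never re-detected |
| band-pass | Butterworth order 3, 0.05–150 Hz | applied forward-backward (zero phase), so annotations stay aligned |
| notch | 50 Hz, Q = 30 | European mains; configurable |
| high-pass | Butterworth order 3, 0.05 Hz | kept as a separate stage although the band-pass low edge is also 0.05 Hz — the chain is reproduced as specified rather than rationalized |
| segment | 0.5 s → 250 samples | R-peak at `floor(0.25·L)` = sample 62; beats whose window crosses a recording edge are skipped and counted |

The 12-lead distortion beats are projected to a 3-component
vectorcardiogram with the standard Kors regression matrix (3 × 8
coefficients over leads I, II, V1–V6; derived limb leads are ignored).
Normalization divides all three components of a template by the single
maximum absolute value of the 250 × 3 window — per template, not per
database — preserving X/Y/Z amplitude ratios and matching the generator's
Tanh output range. Zero-phase filtering was chosen because the templates
are subsequently aligned sample-by-sample; causal filtering would shift
the distortion relative to the annotation by the group delay.

## The template GAN

Architecture (parameter counts in `build_*` reports): generator
dense(250→250, weights N(0, 0.02)) → reshape(250 × 1) → BiLSTM(24, sum
merge) → dropout(0.5) → dense(24→3, Tanh); discriminator four
Conv1D(kernel 16, stride 1, same padding, LeakyReLU) with 32/64/128/256
filters, max-pool(2) after layers 2 and 4, flatten, dense sigmoid unit.
"Same" padding for the even kernel pads 7 left / 8 right; pooling uses
valid semantics, so 250 → 125 → 62 and the flattened width is
62 · 256 = 15,872.

Training: per batch, one discriminator update on an equal mix of measured
and generated templates (labels 1/0, no smoothing), then one generator
update driving fresh samples toward label 1. Adam with β₁ = 0.5,
β₂ = 0.9; initial learning rates 2·10⁻⁴ (discriminator) and 4·10⁻⁴
(generator); both are halved every 5 epochs as a discrete step
(`lr·0.5^(epoch//5)`, 0-based), not a continuous exponential. The latent
prior is standard normal (unspecified upstream; the conventional choice).
Full-scale defaults are 100 epochs and batch 32; the test suite and the
acceptance script train 5 epochs on ~100 synthetic templates, which is
enough to verify stability (finite, non-diverging losses) and the output
contract (shape 250 × 3, values strictly inside (−1, 1)) but not
distributional convergence — similarity numbers at that scale are
indicative only.

The layer library (`mhdecg.nn`) is a self-contained numpy implementation
with manual backpropagation, float32 arithmetic, and Keras-compatible
conventions (gate order i/f/g/o with forget bias 1, Glorot/orthogonal
initializers, inverted dropout). Gradient correctness is verified against
central finite differences in float64. Training is reproducible for a
fixed seed on one platform; bit-identical histories across BLAS builds
are not promised. NaN losses abort with a diagnostic rather than
continuing silently.

## Similarity metrics

MMD uses the Gaussian RBF kernel `exp(−γ‖a−b‖²)` with the unbiased-style
estimator: off-diagonal means within each set minus twice the full cross
mean. A consequence worth knowing: for two copies of the same finite
sample the estimator is slightly *negative* (the diagonal is excluded
within sets but present in the cross term); values are reported as
computed, never clamped. γ defaults to the median heuristic
(`1/(2·median²)` of pooled pairwise distances) and is recorded in the
report so a run can be reproduced.

DTW is the minimal accumulated *squared* Euclidean distance over monotone
alignment paths anchored at both ends — no square root, since the
dissimilarity is defined as the summed squared cost. The recursion is
numba-accelerated with a pure-Python fallback. Aggregating DTW between
two template *sets* is not uniquely defined; the default is the mean over
synthesized templates of the minimum DTW to any measured template
(distance to the measured manifold), with `median-median` and `mean-mean`
available behind a flag.

## Augmentation

One template is tiled per recording, R-anchored (sample 62 on each
annotated beat); windows crossing recording edges are clipped. When
consecutive beats are closer than 0.5 s the copies overlap-add by
default; a truncate mode clips each copy at the RR midpoints instead.
Between-beat gaps carry zero distortion — whether measured inter-beat
baseline distortion persists is not resolvable from beat-locked
templates. Carriers are jointly max-abs normalized per recording before
injection so the unit-scale templates are commensurate; the injection
`scale` defaults to 1.0. Template assignment across a dataset is drawn
without replacement when the database is large enough (e.g. 150 templates
onto 75 recordings at 2 per recording), otherwise with replacement plus a
warning. The count identity `(1 + templates_per_recording)·n_recordings`
and exact recoverability `(augmented − original)/scale = track` are
tested invariants.

## Detection and scoring

Matching is greedy in annotation order: each annotation takes the nearest
unmatched detection within ±75 ms, applied as the real-valued bound
`|Δ| ≤ 0.075·fs` samples (37.5 at 500 Hz, so integer offset 37 passes and
38 fails). Greedy matching can in principle fall below the optimal
one-to-one assignment on adversarial clusters; property tests check it
never exceeds the optimum and agrees exactly when events are separated by
more than twice the tolerance. P/R/F1 are computed from counts pooled
across a dataset; undefined denominators raise instead of silently
reporting zero.

Two detectors are provided. Pan–Tompkins (5–15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, adaptive dual thresholds,
200 ms refractory) is the fixed classical reference. The trainable
detector is a deliberately small windowed 1-D convolutional classifier
(two Conv1D/pool stages and a sigmoid unit over 0.24 s windows of the
per-recording max-abs-normalized VCG magnitude, scanned at a 5-sample
stride with probability peaks ≥ 0.5 separated by a 0.25 s refractory).
It is a desk-scale stand-in whose only purpose is to expose how
distortion-augmented training data changes false-positive behaviour; it
is not a state-of-the-art detector and its absolute accuracy is not a
claim.

## Synthetic data

Clean ECGs are sums of Gaussian bumps (P, Q, R, S, T) with physiologic
default timings/amplitudes, placed at jittered RR intervals, projected to
12 leads by fixed per-lead gains; R-peak ground truth is the analytic
bump center, exact by construction. The synthetic distortion has two
parts: a band-limited (2–12 Hz) oscillation enveloped over the T-wave
region, and one narrow (16 ms) pseudo-peak placed uniformly in
diastole (70–88 % of the window) at 1.0–1.6 × the oscillation's peak,
shared in time and polarity across components. The pseudo-peak is what
makes the artifact operationally harmful — a detector trained on clean
data mistakes it for a beat — so a synthetic distortion without it would
not reproduce the failure mode under study. Energy is concentrated after
the R-peak by construction (asserted as an invariant). HF/FF pairs are
`clean ± D` plus independent noise, so noise-free extraction recovery is
algebraically exact and is verified end to end at correlation > 0.99
after identical filtering.

The benchmark suite defaults model a miniature version of the full study:
6 clean training recordings and 3 HF/FF subject pairs of 30 s each at
heart rates drawn from 55–85 bpm, observation noise 5 µV-scale
(0.005 mV), extraction-pair distortion amplitude 0.6 mV, and one held-out
distorted recording whose distortion seed is disjoint from training.

What passing these tests does *not* show: the generators contain no
blood-flow physics, no torso volume conduction, no electrode or motion
artifacts, and lead morphologies are proportional across leads; results
on clinical in-scanner recordings will differ, and the desk-scale
augmentation benefit is a directional finding, not a performance claim.

## Numerical and design notes

- R-peak indices are 0-based everywhere internally, independent of
  source-format convention.
- `floor(0.25·L)` puts the R-peak at sample 62 of 250 ("25 %" is
  ambiguous at 62.5; floor is exposed as a constant).
- WFDB support is a minimal in-package reader/writer (text header,
  16-bit little-endian signals, MIT-format annotations with the SKIP
  escape for long intervals) sufficient for Holter-style records;
  CSV + plain-text annotation sidecars are the lossless interchange
  format.
- The resampling ratio is realized as a rational approximation with
  denominator ≤ 10⁴ (exact for all rates of interest: 257, 1000,
  1024 → 500).
- Degenerate inputs fail loudly: all-zero templates cannot be
  normalized, empty databases cannot be trained on or summarized,
  undefined P/R raise.
- Problem sizes in tests and the acceptance script (≈100 templates,
  5 epochs, 30 s recordings, 3 experiment replicates) were chosen as the
  smallest that exercise every code path and stabilize the directional
  conclusions.
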