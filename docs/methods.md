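# Methods

## Scope and data model

The package treats a digital ECG the way clinical hardware delivers it:
an integer matrix of ADC counts, 500 Hz, 4.88 µV per least significant
bit, 12 leads in the standard order (I, II, III, aVR, aVL, aVF, V1–V6).
Two record shapes exist — a 1.2-s median representative beat (600
samples) and a 10-s rhythm strip (5000 samples).  Seven measurements are
derived from fiducial points: PR = QRS_on − P_on, QRS = QRS_off − QRS_on,
QT = T_off − QRS_on (ms), HR = 60000/RR (beats/min, RR in ms), and three
amplitudes relative to the baseline — R peak, T peak and STJ (the value
at the J point, i.e. QRS offset).  Amplitudes are lead-specific; lead V5
is the reference.

## Synthetic generator

Real annotated population cohorts are not shareable, so the generator
plays the role of the recording hardware *and* its annotation algorithm:
it emits signals together with exact fiducials and measurements.

**Beat model.** One beat is a sum of Gaussian components
`amp · exp(−(t−c)²/2σ²)`: the five physiological waves P, Q, R, S, T plus
two auxiliary shape components — an ST-segment bump anchored at the J
point, and a "downslope notch" used by the sex-like class (below).  A
Gaussian-sum beat is not a biophysical model, but every quantity the
package predicts or explains depends only on wave timing and amplitude,
which the model controls exactly.

**Fiducials by definition.** Wave onset/offset are *defined* as
`c ± k_sigma·σ` with `k_sigma = 2.5` (the wave has fallen to ≈4% of its
peak there, a visible but not razor-sharp boundary, similar in spirit to
where annotation algorithms place wave ends against noise).  The QRS
complex runs from the Q onset to the S offset (the J point).  No signal
processing is involved, so ground truth is exact; measurement times are
snapped to the 2-ms sample grid so sampled peak values reproduce the
targets bit-for-bit before noise.

**Hitting measurement targets exactly.** Interval targets are met by
placing supports (e.g. the T support ends exactly QT after QRS onset).
Amplitude targets (R, T, STJ, plus a nominal P amplitude) are met by
solving a 4×4 linear system for the P/R/ST/T amplitudes at the four
evaluation points, with the freely drawn Q, S and notch amplitudes moved
to the right-hand side; the design matrix is strongly diagonally
dominant (each column peaks at its own evaluation point), so the solve is
well conditioned.

**Population marginals.** Each measurement is drawn from a split-normal
distribution pinned at a median and 5th/95th percentile — the summary
format of epidemiological cohort tables.  Defaults (HR 64 [48; 85] bpm,
QT 408 [364; 460] ms, PR 158 [126; 204] ms, QRS 92 [76; 118] ms,
STJ −5 [−54; 48] µV, R 1376 [698; 2426] µV, T 346 [122; 698] µV)
describe a general adult population.  Draws are clipped to physiological
sanity ranges and intervals snapped to the sample grid; tests require the
generated 5th/50th/95th percentiles to sit within 10% of the target span
at n = 2000.

**Leads.** A per-lead projection vector (V5 ≡ 1, mild per-record jitter)
scales the baseline-removed template onto the 12 leads.  Only 8 of the 12
leads of a real ECG are linearly independent; the full-size network
therefore consumes channels I, II, V1–V6.

**Noise.** No noise model comes with the problem statement, so the
defaults are free parameters chosen once: white noise of 5 µV SD per
lead (median beats average many beats, so their noise floor is low) and
optional slow sinusoidal baseline wander, off by default.  Labels are
computed from the clean template before noise and quantization, so they
are exact regardless of the noise setting.

**Rhythm strips.** Beats are tiled at RR intervals with per-beat jitter
(SD 15 ms), random strip phase, and edge-truncated beats included; HR
ground truth is 60000 over the realized mean RR of the strip, so heart
rate is only estimable from multiple beats.  Interval/amplitude labels
for rhythm records come from the beat template.

**The sex-like class.** Class 1 differs from class 0 only in the R-wave
downslope: the S wave arrives slightly earlier and deeper (at an
unchanged J point, so the QRS-duration distribution is identical across
classes) and a narrow negative notch is planted halfway down the R→S
descent.  The notch is the dominant cue and is deliberately invisible to
wave-level features (peak amplitudes and timings): a linear probe given
the exact generative features (QRS duration, R/S amplitudes and timings)
recovers part of the signal (≈0.75 accuracy at the default effect size),
QRS duration alone none (≈0.5), and the network, which sees the raw
morphology, most (≈0.95+).  This planted hierarchy is what the
attention/probe discovery loop is tested against.  `sex_effect = 0`
removes every class difference.

**Quantization.** Microvolt → LSB counts by rounding half away from
zero (symmetric for negative voltages); the round trip is within half an
LSB (2.44 µV) per sample.

## Network and training

The architecture is declarative (`ArchitectureSpec`) and built into an
explicit numpy layer graph with hand-written backward passes; no
deep-learning framework is used.  Design points where the description of
the reference architecture leaves freedom:

* **Average pooling** after the initial block: size 2, stride 2 — halves
  the sequence once and keeps the residual stack length-uniform.
* **Padding**: "same" everywhere (forced inside residual modules by the
  skip addition; applied uniformly for simplicity).  Even kernels pad the
  extra sample on the right.
* **Dropout** (rate 0.5) after the second convolution of each residual
  module, before the skip addition.
* **Heads and losses**: linear head + mean-squared error for regression;
  single logistic neuron + cross-entropy for classification.
* **Input scaling**: records are fed in microvolt; the first batch
  normalization standardizes activations, and regression *labels* are
  z-scored inside `fit` (the affine is stored on the network and undone
  by `predict_denorm`), so voltage and time targets train identically.
* **Initialization**: glorot-uniform, seeded; batch normalization uses
  momentum 0.99 and ε = 1e-3; Nadam uses β₁ 0.9, β₂ 0.999, ε = 1e-7,
  learning rate 5e-4.
* **Learning-rate schedule**: step decay ×0.5 at 60% and 85% of the
  epoch budget (skipped under 10 epochs).  Without it, long runs
  occasionally destabilize late and end in a bad basin.

**Parameter counting.** `count_parameters` reports trainable weights
only, or all parameters including batch-norm moving statistics (the
"total params" convention of Keras-style frameworks).  The full-size
network consuming the 8 independent channels totals 1,652,993
(1,651,265 trainable); built for all 12 channels instead it would total
1,655,041 (1,653,313 trainable).  The 8-channel, total-params convention
is the one under which the architecture reproduces its published size,
and is the package's documented convention.

**Augmentation.** Median beats are circularly time-shifted by a uniform
integer shift in ±40 ms (±20 samples), fresh per record per epoch, so
the network must find the waves rather than exploit the fixed beat
centering; interval labels are invariant under the shift.  Rhythm strips
are never shifted (their phase is already random).

**Cross-validation.** Shuffled k-fold (stratified for sex), fold sizes
differing by at most one; fold statistics aggregated as mean ± SD with
the n−1 denominator; ZeroR references computed from labels only.

**Desk scale.** The full-size network is built and counted but not
trained here.  All trained experiments use the desk preset — filters
16/8, kernel 15, two residual modules, all 12 channels — on 2000
median beats, 12–30 epochs per task, batch 64, a 75/25 holdout.  These
problem sizes are the package's CPU-scale study conditions; the
qualitative claims (beats ZeroR by a large margin, attention localizes
in the defining wave, occlusion concordance) survive this scaling, the
absolute error magnitudes of cluster-scale training do not and are out
of scope.

## Attention maps

`layer_gradcam` implements the GradCAM construction for 1-D signals
(evaluation mode; dropout off; batch-norm moving statistics).  The ReLU
rectification is kept for regression outputs per convention; a signed
variant exists for diagnostics since negative contributions are
meaningful in regression.  The default explanation layer is the output
of the last residual module — the final feature map before prediction.

Per-lead maps distribute the upsampled layer profile over leads with
normalized absolute input gradients (uniform 1/12 where all input
gradients vanish).  This construction is chosen because it is exactly
mass-conserving: the rows sum to the layer profile, and the arithmetic
lead-average reduces to the profile up to the 1/12 factor.  Raw maps are
averaged first; normalization to the unit interval (max → 1, identically
zero maps stay zero) is applied only for display and scoring.  Linear
interpolation is used for upsampling (monotone, endpoint-preserving).

`localization_score` quantifies attention claims: the fraction of
lead-averaged mass inside a time window.  A uniform map scores the
window's length fraction, giving a natural null reference.

## Wave blanking

`blank_wave` replaces the open interval between a wave's onset and
offset, per lead, with the straight line joining the signal values *at*
the onset and offset samples (the endpoints are kept so the
interpolation is anchored at true signal values), then re-quantizes so
records remain integer.  The operation is idempotent and bit-identical
outside the interval.  No padding margin is applied around the wave.
Blanking is defined for median beats; applying it beat-by-beat to rhythm
strips via `beat_times` is possible but treated as an extension.

## Numerical notes

All network computation is float32 over BLAS matmuls (im2col for the
convolutions).  Determinism: populations are bit-reproducible from the
spec seed; fold splits, weight initialization, shuffling, augmentation
and dropout all derive from explicit seeds, and repeated runs produce
identical loss traces.  Degenerate inputs are defined rather than
silent: missing fiducials yield undefined (None) measurements, never
zero; identically zero attention maps are returned with a warning and
score zero; zero-variance inputs make Pearson's r an error; AUC uses the
half-credit tie convention; single-class label sets make AUC an error.

## Known limitations

* Gaussian beats carry no pathology morphology (bundle branch block,
  AV block, abnormal T waves) and no notching/slurring beyond the
  planted class effect; conclusions about real ECGs require real ECGs.
* The generator's wave overlap structure is mild by construction;
  annotation ambiguity of real wave ends (especially flat T waves) is
  not modeled, so measurement errors here are optimistic.
* Lead projection is a scale vector, not a dipole model: inter-lead
  morphology differences (e.g. discordant T waves) are absent.
* The desk preset's absolute errors are not comparable to full-scale
  training; only orderings and ratios are asserted.
* Passing the occlusion and attention tests shows the *tools* behave as
  specified and that desk models read the expected waves on synthetic
  data — not that any clinical model is trustworthy.
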