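# ecglens

Explainable deep measurement of 12-lead electrocardiograms: a residual
convolutional network that regresses the standard ECG measurements
(PR, QRS, QT intervals, heart rate, R-peak/T-peak amplitudes, J-point
elevation) or classifies sex directly from the raw signal, together with
the two tools that make such a model auditable —

* **gradient-weighted attention maps** for multichannel 1-D signals
  (per-lead and lead-averaged importance over time, at any layer), and
* **wave-blanking occlusion**: replace the P, QRS or T wave with a
  lead-specific linear interpolation and measure how much each model
  degrades.

Because population ECG datasets with manufacturer annotations are rarely
shareable, the package ships a **synthetic 12-lead generator** with exact
ground-truth fiducials: beats are sums of Gaussian wave components, so
every interval and amplitude is known by construction, and a binary
"sex-like" class can be planted whose only systematic difference is
R-wave downslope morphology.  Every claim the package makes about the
network and its explanations is tested end to end on that generator.

It is aimed at researchers in biomedical signal processing and
explainable ML who want a fully inspectable, CPU-scale reference
implementation — no deep-learning framework is required; the network,
its backward passes and the Nadam optimizer are plain numpy.

## The model

A record is an integer matrix (12 leads × N samples, 500 Hz, 4.88 µV per
least significant bit), either a 1.2-s median beat (N = 600) or a 10-s
rhythm strip (N = 5000).  The network consumes the 8 linearly independent
channels (I, II, V1–V6) and applies

    conv(64, k=8) → BN → ReLU → conv(32, k=3) → BN → ReLU → avgpool(2)
    → 8 × [ conv(64, k=50) → BN → ReLU → conv(32, k=50) → BN
            → dropout(0.5) → (+ skip) → ReLU ]
    → global average pool → 1 neuron (linear, or logistic for sex)

Same padding keeps length constant inside the residual modules, and the
global-average-pooling head makes the parameter count independent of
input length: **1,652,993 parameters** including batch-normalization
moving statistics (1,651,265 trainable).

Attention maps follow the GradCAM construction: at a layer with feature
maps A^k(t), channel weights α_k = mean_t ∂y/∂A^k(t) give the profile
M(t) = ReLU(Σ_k α_k A^k(t)), which is upsampled to input resolution and
distributed over leads with normalized input-gradient weights
w_l(t) = |∂y/∂x_l(t)| / Σ_m |∂y/∂x_m(t)|, so the lead-average provably
reduces to the layer profile.

## Worked example

`examples/` contains one short script per capability.  Training a
desk-size preset (16/8 filters, kernel 15, two residual modules) on 1200
synthetic median beats for QRS duration (`03_train_and_explain.py`)
prints:

```
validation MAE 3.41 ms vs ZeroR 10.27 ms
attention mass in the QRS window: 0.51 (window is 9.50% of the record)
```

The model beats the constant-mean (ZeroR) predictor threefold, and half
of its attention mass sits inside the QRS complex although that window
covers under a tenth of the beat — the model measures the wave it is
supposed to measure.  The sex study (`05_sex_study.py`) prints:

```
network        : acc 0.98  AUC 1.00
rich probe     : acc 0.71  AUC 0.80   (QRS + R/S amp + timing)
duration probe : acc 0.51  AUC 0.53   (QRS duration only)
attention mass by wave window: {'P': 0.03, 'QRS': 0.46, 'T': 0.02}
```

The network outperforms a logistic probe given the ground-truth wave
features, which outperforms QRS duration alone, and the attention sits in
the QRS window — the discovery loop that attributes the class signal to
R-downslope morphology.  `04_wave_blanking.py` shows the occlusion tool
that verifies such attributions directly.

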