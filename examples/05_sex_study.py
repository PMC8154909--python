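"""The attention-driven feature-discovery loop on the sex-like class.

Trains the binary classifier, reads where its attention sits, then checks
logistic probes on ground-truth wave features: the full network should
beat a probe given QRS duration + R/S amplitudes and timings, which in
turn beats QRS duration alone — evidence that the discriminating signal
is R-downslope morphology, not an interval.
Runtime: a few minutes on one CPU core.
"""

from ecglens import StudyConfig, make_dataset, run_sex_study

cfg = StudyConfig(n=1400, seed=5, tasks=("sex",),
                  epochs_by_task={"sex": 20})
dataset = make_dataset(cfg)
result, _ = run_sex_study(cfg, dataset)

print(f"network        : acc {result.network_acc:.2f}  "
      f"AUC {result.network_auc:.2f}")
print(f"rich probe     : acc {result.rich_probe_acc:.2f}  "
      f"AUC {result.rich_probe_auc:.2f}   (QRS + R/S amp + timing)")
print(f"duration probe : acc {result.duration_probe_acc:.2f}  "
      f"AUC {result.duration_probe_auc:.2f}   (QRS duration only)")
print("attention mass by wave window:",
      {k: round(v, 2) for k, v in result.window_scores.items()})
print("QRS-window dominance plus the probe ordering locates the class "
      "signal in QRS morphology.")
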