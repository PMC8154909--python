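"""Wave-blanking occlusion analysis.

A direct, model-agnostic check of what a measurement model depends on:
remove one wave (P, QRS or T) from a median beat by replacing it, lead by
lead, with the straight line joining the signal values at the wave's onset
and offset, then measure how much each model's error inflates.  If a model
truly reads the QRS complex to measure QRS duration, QRS blanking should
degrade it drastically while P blanking should not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .metrics import classification_metrics, mae
from .model import ResidualECGNet, predict_denorm
from .records import ECGRecord, FiducialSet
from .synth import LabeledECG

__all__ = ["blank_wave", "blanking_study", "BlankingReport", "WAVE_WINDOWS"]

#: Fiducial pair delimiting each blankable wave.
WAVE_WINDOWS = {"P": ("P_on", "P_off"),
                "QRS": ("QRS_on", "QRS_off"),
                "T": ("T_on", "T_off")}


def blank_wave(record: ECGRecord, fid: FiducialSet, wave: str) -> ECGRecord:
    """Replace one wave with a lead-specific linear interpolation.

    The onset and offset samples themselves are kept (they anchor the
    interpolation at true signal values); strictly interior samples are
    replaced by the straight line between them, independently per lead,
    and the result is re-quantized to integer LSB counts.  Idempotent, and
    bit-identical outside the open interval.
    """
    if wave not in WAVE_WINDOWS:
        raise ValueError(f"unknown wave {wave!r}; choose from {list(WAVE_WINDOWS)}")
    on_name, off_name = WAVE_WINDOWS[wave]
    onset, offset = getattr(fid, on_name), getattr(fid, off_name)
    if onset is None or offset is None:
        raise ValueError(f"fiducials {on_name}/{off_name} missing")
    if onset > offset:
        raise ValueError(f"{on_name}={onset} exceeds {off_name}={offset}")
    i0, i1 = record.sample_index(onset), record.sample_index(offset)
    if not (0 <= i0 < record.n_samples and 0 <= i1 < record.n_samples):
        raise ValueError("wave boundaries fall outside the record")
    if i1 - i0 < 2:       # no interior samples
        return record
    counts = record.voltages.astype(float)
    frac = np.arange(1, i1 - i0) / (i1 - i0)
    v0 = counts[:, i0][:, None]
    v1 = counts[:, i1][:, None]
    line = v0 + (v1 - v0) * frac[None, :]
    out = record.voltages.copy()
    out[:, i0 + 1:i1] = (np.sign(line) * np.floor(np.abs(line) + 0.5)
                         ).astype(record.voltages.dtype)
    return ECGRecord(out, fs=record.fs, lsb=record.lsb,
                     record_kind=record.record_kind,
                     record_id=record.record_id)


@dataclass
class BlankingReport:
    """Metric per (task, blanked wave), with the unblanked baseline.

    ``values[(task, wave)]`` is the fold-mean metric (MAE for regression
    tasks, accuracy for the sex task) and ``sds`` the fold SD (0 with a
    single model per task).  ``wave == "none"`` is the baseline row.
    """

    metric: Dict[str, str] = field(default_factory=dict)       # task -> "MAE"|"ACC"
    values: Dict[Tuple[str, str], float] = field(default_factory=dict)
    sds: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def baseline(self, task: str) -> float:
        return self.values[(task, "none")]

    def ratio(self, task: str, wave: str) -> float:
        """Error inflation (or accuracy retention) relative to baseline."""
        return self.values[(task, wave)] / self.values[(task, "none")]

    def to_frame(self) -> pd.DataFrame:
        waves = sorted({w for _, w in self.values},
                       key=lambda w: ("none", "P", "QRS", "T").index(w))
        rows = []
        for task in self.metric:
            row = {"task": task, "metric": self.metric[task]}
            for w in waves:
                row[w] = self.values.get((task, w))
                row[f"{w}_sd"] = self.sds.get((task, w))
            rows.append(row)
        return pd.DataFrame(rows)


def _evaluate(nets: Sequence[ResidualECGNet], dataset: Sequence[LabeledECG],
              task: str) -> Tuple[float, float]:
    """Fold-mean and SD of the task metric over one (possibly blanked) set."""
    labels = np.array([d.measurements.label(task) for d in dataset])
    scores = []
    for net in nets:
        pred = predict_denorm(net, dataset)
        if task == "sex":
            scores.append(classification_metrics(pred, labels)[0])
        else:
            scores.append(mae(pred, labels))
    arr = np.asarray(scores, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def blanking_study(nets_per_task: Dict[str, Sequence[ResidualECGNet]],
                   dataset: Sequence[LabeledECG],
                   waves: Sequence[str] = ("P", "QRS", "T")) -> BlankingReport:
    """Evaluate every task model on the intact set and each blanked variant.

    ``nets_per_task`` maps a task name (a regression measurement or
    ``"sex"``) to one or more trained networks (folds).  Regression tasks
    report MAE (lower is better), the sex task accuracy (higher is
    better).  Blanked variants are built once and shared by all tasks.
    """
    if not nets_per_task:
        raise ValueError("no models supplied")
    for task, nets in nets_per_task.items():
        if not nets:
            raise ValueError(f"no model for task {task!r}")
    blanked: Dict[str, List[LabeledECG]] = {}
    for w in waves:
        blanked[w] = [LabeledECG(blank_wave(d.record, d.fiducials, w),
                                 d.fiducials, d.measurements, d.params)
                      for d in dataset]
    report = BlankingReport()
    for task, nets in nets_per_task.items():
        report.metric[task] = "ACC" if task == "sex" else "MAE"
        v, sd = _evaluate(nets, dataset, task)
        report.values[(task, "none")] = v
        report.sds[(task, "none")] = sd
        for w in waves:
            v, sd = _evaluate(nets, blanked[w], task)
            report.values[(task, w)] = v
            report.sds[(task, w)] = sd
    return report
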