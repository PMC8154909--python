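"""Desk-scale study orchestration on synthetic populations.

Mirrors the three study designs the library exists for, at CPU scale:

* a regression study (train one model per measurement, score against the
  ZeroR mean-predictor, render attention galleries),
* a sex study (train the binary classifier, locate its attention, and
  compare against logistic probes on ground-truth wave features — the
  attention-driven feature-discovery loop), and
* a wave-blanking study (the occlusion verification grid).

All studies run on one shared synthetic population and one shared
train/holdout split, so their numbers are directly comparable, and all
accept pre-trained models so reports can be regenerated without
retraining.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .gradcam import AttentionMap, localization_score, per_lead_maps
from .metrics import EvalReport, classification_metrics, mae, rmse, zeror
from .model import ArchitectureSpec, ResidualECGNet, build_network
from .occlusion import BlankingReport, blanking_study
from .synth import LabeledECG, PopulationSpec, generate_population
from .train import TrainConfig, fit, predict_denorm, split_folds
from .model import records_to_input

__all__ = ["StudyConfig", "TaskModels", "make_dataset", "train_task_models",
           "run_regression_study", "run_sex_study", "run_blanking_study",
           "SexStudyResult", "attention_window_scores", "save_models",
           "load_models", "render_attention_gallery"]

#: The wave whose fiducials define each regression measurement.
DEFINING_WAVE = {"QRS": "QRS", "R_amp": "QRS", "STJ": "QRS",
                 "T_amp": "T", "QT": "T", "PR": "P", "sex": "QRS"}


@dataclass
class StudyConfig:
    """Shared configuration of the desk-scale studies."""

    population: PopulationSpec = field(default_factory=PopulationSpec)
    n: int = 2000
    record_kind: str = "median"
    tasks: Tuple[str, ...] = ("QRS", "R_amp", "T_amp", "sex")
    epochs: int = 30
    epochs_by_task: Dict[str, int] = field(default_factory=dict)
    batch_size: int = 64
    learning_rate: float = 5e-4
    holdout_fraction: float = 0.25
    seed: int = 0
    out_dir: Optional[Path] = None

    def arch(self, task: str) -> ArchitectureSpec:
        return ArchitectureSpec.desk(
            head="classification" if task == "sex" else "regression")

    def train_config(self, task: str) -> TrainConfig:
        return TrainConfig(
            task=task, record_kind=self.record_kind,
            epochs=self.epochs_by_task.get(task, self.epochs),
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            seed=self.seed,
            augment_shift=(self.record_kind == "median"))


@dataclass
class TaskModels:
    """One trained network per task plus the shared split."""
    models: Dict[str, ResidualECGNet]
    train_idx: np.ndarray
    test_idx: np.ndarray
    histories: Dict[str, Dict[str, List[float]]] = field(default_factory=dict)


def make_dataset(cfg: StudyConfig) -> List[LabeledECG]:
    """The study population (every task has generator ground truth)."""
    for task in cfg.tasks:
        if task not in DEFINING_WAVE:
            raise ValueError(f"no ground-truth label for task {task!r}")
    return generate_population(cfg.population, cfg.n, cfg.record_kind)


def _holdout_split(cfg: StudyConfig, n: int,
                   labels: Optional[np.ndarray] = None
                   ) -> Tuple[np.ndarray, np.ndarray]:
    k = max(2, int(round(1.0 / cfg.holdout_fraction)))
    tr, te = split_folds(n, k, seed=cfg.seed, stratify=labels)[0]
    return tr, te


def train_task_models(cfg: StudyConfig,
                      dataset: Sequence[LabeledECG]) -> TaskModels:
    """Train one desk-preset network per configured task on a shared split."""
    sex_labels = None
    if "sex" in cfg.tasks:
        sex_labels = np.array([d.measurements.label("sex") for d in dataset],
                              dtype=int)
    tr, te = _holdout_split(cfg, len(dataset), sex_labels)
    models: Dict[str, ResidualECGNet] = {}
    histories = {}
    for task in cfg.tasks:
        arch = cfg.arch(task)
        tc = cfg.train_config(task)
        X = records_to_input(dataset, arch.input_channels)
        y = np.array([d.measurements.label(task) for d in dataset])
        task_seed = cfg.seed + zlib.crc32(task.encode()) % 10000
        net = build_network(arch, seed=task_seed)
        histories[task] = fit(net, X[tr], y[tr], tc)
        models[task] = net
    return TaskModels(models, tr, te, histories)


def _eval_task(net: ResidualECGNet, dataset: Sequence[LabeledECG],
               idx: np.ndarray, task: str) -> EvalReport:
    X = records_to_input([dataset[i] for i in idx], net.spec.input_channels)
    y = np.array([dataset[i].measurements.label(task) for i in idx])
    pred = predict_denorm(net, X)
    if task == "sex":
        rep = EvalReport(task=task, kind="classification")
        rep.add_classification_fold(pred, y)
    else:
        rep = EvalReport(task=task, kind="regression")
        rep.add_regression_fold(pred, y)
        rep.zeror_mae, rep.zeror_rmse = zeror(y)
    return rep


def attention_window_scores(net: ResidualECGNet,
                            records: Sequence[LabeledECG],
                            windows: Sequence[str] = ("P", "QRS", "T"),
                            layer_name: Optional[str] = None
                            ) -> Dict[str, float]:
    """Mean attention mass inside each wave window over a set of records."""
    sums = {w: [] for w in windows}
    for d in records:
        amap = per_lead_maps(net, d, layer_name)
        f = d.fiducials
        spans = {"P": (f.P_on, f.P_off), "QRS": (f.QRS_on, f.QRS_off),
                 "T": (f.T_on, f.T_off)}
        for w in windows:
            sums[w].append(localization_score(amap, spans[w]))
    return {w: float(np.mean(v)) for w, v in sums.items()}


def run_regression_study(cfg: StudyConfig,
                         dataset: Optional[Sequence[LabeledECG]] = None,
                         task_models: Optional[TaskModels] = None,
                         n_attention_records: int = 25):
    """Regression tasks: holdout MAE/RMSE vs ZeroR plus attention scores.

    Returns ``(reports, attention, task_models)`` where ``reports`` maps
    each regression task to its holdout :class:`EvalReport` and
    ``attention`` to the mean localization score inside the task's
    defining wave window.
    """
    dataset = make_dataset(cfg) if dataset is None else dataset
    reg_tasks = tuple(t for t in cfg.tasks if t != "sex")
    if task_models is None:
        task_models = train_task_models(cfg, dataset)
    reports, attention = {}, {}
    sample = [dataset[i] for i in task_models.test_idx[:n_attention_records]]
    for task in reg_tasks:
        net = task_models.models[task]
        reports[task] = _eval_task(net, dataset, task_models.test_idx, task)
        scores = attention_window_scores(net, sample)
        attention[task] = scores[DEFINING_WAVE[task]]
        if cfg.out_dir is not None:
            reports[task].to_frame().to_csv(
                Path(cfg.out_dir) / f"regression_{task}.csv", index=False)
            render_attention_gallery(net, sample[:4],
                                     Path(cfg.out_dir) / f"attention_{task}.svg")
    return reports, attention, task_models


@dataclass
class SexStudyResult:
    """Classifier vs ground-truth-feature logistic probes, plus attention."""
    network_acc: float
    network_auc: float
    rich_probe_acc: float
    rich_probe_auc: float
    duration_probe_acc: float
    duration_probe_auc: float
    window_scores: Dict[str, float]


def _probe_features(dataset: Sequence[LabeledECG], rich: bool) -> np.ndarray:
    """QRS duration alone, or QRS + R/S amplitudes and timings.

    Features are read from generator ground truth (the wave parameters),
    isolating the probe comparison from any wave-detection error.
    """
    rows = []
    for d in dataset:
        qrs = d.measurements.QRS
        if not rich:
            rows.append([qrs])
            continue
        p = d.params
        r_w, s_w = p.waves["R"], p.waves["S"]
        from .synth import make_beat
        beat = make_beat(p)
        s_idx = int(round(s_w.center * d.record.fs / 1000.0))
        s_amp = float(beat[s_idx]) - p.baseline_level
        rows.append([qrs, d.measurements.R_amp, s_amp,
                     r_w.center, s_w.center])
    return np.asarray(rows)


def _fit_probe(features: np.ndarray, y: np.ndarray, tr: np.ndarray,
               te: np.ndarray) -> Tuple[float, float]:
    probe = make_pipeline(StandardScaler(),
                          LogisticRegression(max_iter=2000))
    probe.fit(features[tr], y[tr])
    prob = probe.predict_proba(features[te])[:, 1]
    return classification_metrics(prob, y[te])


def run_sex_study(cfg: StudyConfig,
                  dataset: Optional[Sequence[LabeledECG]] = None,
                  task_models: Optional[TaskModels] = None,
                  n_attention_records: int = 25):
    """Sex classifier vs logistic probes on ground-truth wave features.

    Reproduces the discovery logic: the network's attention points at the
    QRS complex (specifically the R downslope); a logistic probe given the
    corresponding ground-truth features (QRS duration, R/S amplitudes and
    timings) recovers much of the network's accuracy, while QRS duration
    alone does not.  Returns ``(SexStudyResult, task_models)``.
    """
    dataset = make_dataset(cfg) if dataset is None else dataset
    if task_models is None:
        if "sex" not in cfg.tasks:
            raise ValueError("cfg.tasks must include 'sex'")
        task_models = train_task_models(cfg, dataset)
    net = task_models.models["sex"]
    y = np.array([d.measurements.label("sex") for d in dataset])
    if len(np.unique(y[task_models.train_idx])) < 2:
        raise ValueError("degenerate class balance in training split")
    rep = _eval_task(net, dataset, task_models.test_idx, "sex")
    tr, te = task_models.train_idx, task_models.test_idx
    rich_acc, rich_auc = _fit_probe(_probe_features(dataset, True), y, tr, te)
    dur_acc, dur_auc = _fit_probe(_probe_features(dataset, False), y, tr, te)
    sample = [dataset[i] for i in te[:n_attention_records]]
    scores = attention_window_scores(net, sample)
    result = SexStudyResult(
        network_acc=rep.acc_mean, network_auc=rep.auc_mean,
        rich_probe_acc=rich_acc, rich_probe_auc=rich_auc,
        duration_probe_acc=dur_acc, duration_probe_auc=dur_auc,
        window_scores=scores)
    if cfg.out_dir is not None:
        render_attention_gallery(net, sample[:8],
                                 Path(cfg.out_dir) / "attention_sex.svg")
    return result, task_models


def run_blanking_study(cfg: StudyConfig,
                       dataset: Optional[Sequence[LabeledECG]] = None,
                       task_models: Optional[TaskModels] = None
                       ) -> Tuple[BlankingReport, TaskModels]:
    """Task x blanked-wave grid evaluated on the holdout records."""
    dataset = make_dataset(cfg) if dataset is None else dataset
    if task_models is None:
        task_models = train_task_models(cfg, dataset)
    holdout = [dataset[i] for i in task_models.test_idx]
    nets = {t: [m] for t, m in task_models.models.items()}
    report = blanking_study(nets, holdout)
    if cfg.out_dir is not None:
        report.to_frame().to_csv(Path(cfg.out_dir) / "blanking.csv",
                                 index=False)
    return report, task_models


def save_models(task_models: TaskModels, directory) -> Path:
    """Persist trained weights (npz per task) plus the split indices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "split.npz", train_idx=task_models.train_idx,
             test_idx=task_models.test_idx)
    for task, net in task_models.models.items():
        np.savez(directory / f"model_{task}.npz", **net.state_dict())
    return directory


def load_models(directory, cfg: StudyConfig) -> TaskModels:
    """Rebuild networks from persisted weights without retraining."""
    directory = Path(directory)
    split = np.load(directory / "split.npz")
    models = {}
    for task in cfg.tasks:
        net = build_network(cfg.arch(task))
        state = dict(np.load(directory / f"model_{task}.npz"))
        net.load_state_dict(state)
        models[task] = net
    return TaskModels(models, split["train_idx"], split["test_idx"])


def render_attention_gallery(net: ResidualECGNet,
                             records: Sequence[LabeledECG],
                             path, lead: int = 10) -> None:
    """Save an SVG/PNG gallery: the lead trace colored by attention.

    Red marks high importance, blue low (coolwarm colormap over the
    unit-interval-normalized lead-averaged map).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(records)
    fig, axes = plt.subplots(n, 1, figsize=(8, 2.2 * n), squeeze=False)
    for ax, d in zip(axes[:, 0], records):
        amap = per_lead_maps(net, d).normalized()
        sig = d.record.microvolts()[lead]
        t = np.arange(sig.size) / d.record.fs
        ax.scatter(t, sig, c=amap.averaged / max(amap.averaged.max(), 1e-12),
                   cmap="coolwarm", s=4, vmin=0.0, vmax=1.0)
        ax.set_ylabel("uV")
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
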