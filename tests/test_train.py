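"""Training-protocol tests: fold splitting, fitting contracts,
reproducibility, augmentation, and learning sanity on small problems."""

import numpy as np
import pytest

from ecglens.metrics import mae, zeror
from ecglens.model import (ArchitectureSpec, build_network, predict_denorm,
                           records_to_input)
from ecglens.synth import (MeasurementDistribution, PopulationSpec,
                           generate_population)
from ecglens.train import TrainConfig, cross_validate, fit, split_folds


def micro_arch(head="regression"):
    """A very small net for fast training tests."""
    return ArchitectureSpec(initial_filters=(8, 4), initial_kernels=(8, 3),
                            n_residual_modules=1, residual_filters=(8, 4),
                            residual_kernel=9, dropout_rate=0.2, head=head)


def quiet_pop(n, seed):
    return generate_population(PopulationSpec(seed=seed, noise_sd=0.0), n)


class TestSplitFolds:
    def test_five_folds_of_ten(self):
        folds = split_folds(10, 5, seed=0)
        assert all(len(va) == 2 for _, va in folds)

    def test_validation_sets_partition_everything(self):
        folds = split_folds(103, 5, seed=1)
        union = np.sort(np.concatenate([va for _, va in folds]))
        assert np.array_equal(union, np.arange(103))
        for tr, va in folds:
            assert np.intersect1d(tr, va).size == 0

    def test_cohort_sized_split_sizes(self):
        """8939 records in 5 folds: four validation folds of 1788 and one
        of 1787 (so ~7152 train / ~1787 validate)."""
        sizes = sorted(len(va) for _, va in split_folds(8939, 5, seed=0))
        assert sizes == [1787, 1788, 1788, 1788, 1788]

    def test_deterministic_given_seed(self):
        a = split_folds(50, 3, seed=9)
        b = split_folds(50, 3, seed=9)
        for (_, va), (_, vb) in zip(a, b):
            assert np.array_equal(va, vb)

    def test_more_folds_than_records_rejected(self):
        with pytest.raises(ValueError):
            split_folds(3, 5)

    def test_stratified_split_balances_classes(self):
        y = np.array([0] * 40 + [1] * 20)
        folds = split_folds(60, 4, seed=0, stratify=y)
        for _, va in folds:
            assert np.sum(y[va] == 1) == 5


class TestFitContracts:
    def test_zero_epochs_leaves_network_unchanged(self):
        pop = quiet_pop(12, 0)
        net = build_network(micro_arch(), seed=0)
        before = {k: v.copy() for k, v in net.state_dict().items()}
        X = records_to_input(pop, 12)
        y = np.array([d.measurements.R_amp for d in pop])
        fit(net, X, y, TrainConfig(task="R_amp", epochs=0))
        for k, v in net.state_dict().items():
            if k.startswith("__"):
                continue
            assert np.array_equal(before[k], v), k

    def test_constant_label_task_converges_to_constant(self):
        pop = quiet_pop(40, 1)
        net = build_network(micro_arch(), seed=0)
        X = records_to_input(pop, 12)
        y = np.full(40, 250.0)
        fit(net, X, y, TrainConfig(task="QRS", epochs=5, batch_size=16))
        pred = predict_denorm(net, X)
        assert mae(pred, y) < 3.0

    def test_loss_trace_reproducible_given_seed(self):
        pop = quiet_pop(30, 2)
        X = records_to_input(pop, 12)
        y = np.array([d.measurements.QRS for d in pop])
        traces = []
        for _ in range(2):
            net = build_network(micro_arch(), seed=5)
            h = fit(net, X, y, TrainConfig(task="QRS", epochs=3, seed=17,
                                           batch_size=10))
            traces.append(h["loss"])
        assert traces[0] == traces[1]

    def test_augmentation_never_touches_labels(self):
        pop = quiet_pop(20, 3)
        X = records_to_input(pop, 12)
        y = np.array([d.measurements.QRS for d in pop])
        y_before = y.copy()
        net = build_network(micro_arch(), seed=0)
        fit(net, X, y, TrainConfig(task="QRS", epochs=2, augment_shift=True))
        assert np.array_equal(y, y_before)

    def test_rhythm_augmentation_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(task="HR", record_kind="rhythm", augment_shift=True)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(task="QTc")


class TestCrossValidate:
    def setup_method(self):
        self.pop = quiet_pop(40, 4)
        self.cfg = TrainConfig(task="QRS", folds=2, epochs=1, seed=0)

    def test_oracle_predictor_scores_zero_in_every_fold(self):
        oracle = lambda recs: [d.measurements.QRS for d in recs]
        rep = cross_validate(self.pop, self.cfg, predictor=oracle)
        assert rep.fold_mae == [0.0, 0.0]
        assert rep.fold_rmse == [0.0, 0.0]

    def test_zeror_predictor_matches_zeror_of_validation_labels(self):
        zr = lambda recs: np.full(len(recs), np.mean(
            [d.measurements.QRS for d in recs]))
        rep = cross_validate(self.pop, self.cfg, predictor=zr)
        folds = split_folds(len(self.pop), 2, seed=0)
        y = np.array([d.measurements.QRS for d in self.pop])
        for f, (_, va) in enumerate(folds):
            assert rep.fold_mae[f] == pytest.approx(zeror(y[va])[0])
            assert rep.fold_rmse[f] == pytest.approx(zeror(y[va])[1])

    def test_replication_report_scores_untouched_dataset(self):
        rep_pop = quiet_pop(20, 5)
        oracle = lambda recs: [d.measurements.QRS for d in recs]
        main, rep = cross_validate(self.pop, self.cfg, replication=rep_pop,
                                   predictor=oracle)
        assert rep.fold_mae == [0.0, 0.0]
        y = np.array([d.measurements.QRS for d in rep_pop])
        assert rep.zeror_mae == pytest.approx(zeror(y)[0])

    def test_too_small_folds_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(self.pop[:6], TrainConfig(task="QRS", folds=5))


class TestLearningSanity:
    def test_validation_mae_improves_with_data_and_epochs(self):
        """On noiseless data the R-amplitude error decreases monotonically
        over three training-set sizes and three epoch budgets."""
        val = quiet_pop(80, 99)
        Xv = records_to_input(val, 12)
        yv = np.array([d.measurements.R_amp for d in val])

        def run(n, epochs, seed):
            pop = quiet_pop(n, 50 + seed)
            X = records_to_input(pop, 12)
            y = np.array([d.measurements.R_amp for d in pop])
            net = build_network(micro_arch(), seed=seed)
            fit(net, X, y, TrainConfig(task="R_amp", epochs=epochs,
                                       batch_size=32, seed=seed))
            return mae(predict_denorm(net, Xv), yv)

        by_n = [run(n, 8, 1) for n in (60, 180, 540)]
        assert by_n[0] > by_n[1] > by_n[2], by_n
        by_epochs = [run(300, e, 2) for e in (1, 4, 16)]
        assert by_epochs[0] > by_epochs[1] > by_epochs[2], by_epochs
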