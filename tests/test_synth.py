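"""Generator unit and property tests: beats, fiducials, measurements,
quantization, time-shift augmentation and population marginals."""

import numpy as np
import pytest

from ecglens.records import ECGRecord, FiducialSet, MeasurementSet, V5
from ecglens.synth import (DEFAULT_K_SIGMA, GaussianWave, LabeledECG,
                           MeasurementDistribution, PopulationSpec,
                           WaveParams, dequantize, derive_fiducials,
                           generate_population, make_beat, measure, quantize,
                           time_shift)


def degenerate_spec(**kw) -> PopulationSpec:
    """Population whose every measurement is pinned at its median."""
    dists = {k: MeasurementDistribution(v.median, v.median, v.median)
             for k, v in PopulationSpec().distributions.items()}
    return PopulationSpec(distributions=dists, noise_sd=0.0,
                          lead_scale_jitter=0.0, **kw)


class TestMakeBeat:
    def test_zero_amplitudes_give_flat_zero(self):
        waves = {"R": GaussianWave(500.0, 10.0, 0.0)}
        y = make_beat(WaveParams(waves=waves, baseline_level=0.0))
        assert np.all(y == 0.0)

    def test_single_r_wave_peaks_at_center(self):
        waves = {"R": GaussianWave(500.0, 12.0, 1000.0)}
        y = make_beat(WaveParams(waves=waves))
        assert y.max() == pytest.approx(1000.0)
        assert np.argmax(y) == 250   # 500 ms at 500 Hz

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            WaveParams(waves={"R": GaussianWave(500.0, 0.0, 100.0)})

    def test_median_beat_at_population_medians_has_qrs_92(self):
        pop = generate_population(degenerate_spec(seed=0), 1, "median")
        assert pop[0].measurements.QRS == pytest.approx(92.0)
        assert pop[0].measurements.QT == pytest.approx(408.0)
        assert pop[0].measurements.PR == pytest.approx(158.0)


class TestFiducials:
    def test_qrs_duration_is_offset_minus_onset(self):
        fid = FiducialSet(QRS_on=100.0, QRS_off=192.0)
        m = measure(fid, np.zeros(600))
        assert m.QRS == pytest.approx(92.0)

    def test_zero_width_limit_collapses_to_center(self):
        waves = {"R": GaussianWave(500.0, 1e-9, 800.0)}
        fid = derive_fiducials(WaveParams(waves=waves))
        assert fid.QRS_on == pytest.approx(500.0, abs=1e-6)
        assert fid.QRS_off == pytest.approx(500.0, abs=1e-6)

    def test_round_trip_qt_target(self):
        pop = generate_population(degenerate_spec(seed=1), 1, "median")
        d = pop[0]
        fid = derive_fiducials(d.params, DEFAULT_K_SIGMA)
        assert fid.T_off - fid.QRS_on == pytest.approx(408.0)

    def test_overlapping_supports_warn_and_clip(self):
        waves = {"P": GaussianWave(460.0, 20.0, 100.0),
                 "R": GaussianWave(500.0, 10.0, 1000.0)}
        with pytest.warns(UserWarning):
            fid = derive_fiducials(WaveParams(waves=waves))
        assert fid.P_off == fid.QRS_on

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            FiducialSet(P_on=100.0, P_off=90.0)


class TestMeasure:
    def test_hr_from_1000ms_rr_is_60(self):
        m = measure(FiducialSet(), np.zeros(600), rr_ms=1000.0)
        assert m.HR == pytest.approx(60.0)

    def test_hr_from_beat_times_uses_mean_rr(self):
        fid = FiducialSet(beat_times=[100.0, 900.0, 1900.0])
        m = measure(fid, np.zeros(5000))
        assert m.HR == pytest.approx(60000.0 / 900.0)

    def test_r_amplitude_relative_to_baseline(self):
        y = np.zeros(600)
        y[250] = 1380.0
        m = measure(FiducialSet(R_peak_time=500.0), y, baseline=4.0)
        assert m.R_amp == pytest.approx(1376.0)

    def test_stj_zero_when_waveform_equals_baseline(self):
        y = np.full(600, 7.0)
        m = measure(FiducialSet(QRS_on=100.0, QRS_off=200.0), y, baseline=7.0)
        assert m.STJ == pytest.approx(0.0)

    def test_missing_fiducial_yields_undefined_not_zero(self):
        m = measure(FiducialSet(QRS_on=100.0, QRS_off=200.0), np.zeros(600))
        assert m.PR is None and m.QT is None and m.HR is None


class TestQuantize:
    @pytest.mark.parametrize("uv,counts", [(4.88, 1), (0.0, 0), (9.76, 2),
                                           (-4.88, -1), (2.44, 1), (-2.44, -1)])
    def test_examples(self, uv, counts):
        assert quantize(np.array([uv]))[0] == counts

    def test_round_trip_within_half_lsb(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3000, 3000, size=10_000)
        err = np.abs(dequantize(quantize(x)) - x)
        assert err.max() <= 2.44 + 1e-9

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.array([np.nan]))


class TestTimeShift:
    @pytest.fixture()
    def one(self, population_small):
        return population_small[0]

    def test_zero_shift_identity(self, one):
        from ecglens.synth import shift_record
        rec2, fid2, s = shift_record(one.record, one.fiducials, 0)
        assert s == 0.0
        assert np.array_equal(rec2.voltages, one.record.voltages)

    def test_20ms_shift_moves_fiducials_10_samples(self, one):
        from ecglens.synth import shift_record
        rec2, fid2, s = shift_record(one.record, one.fiducials, 10)
        assert s == pytest.approx(20.0)
        assert fid2.QRS_on - one.fiducials.QRS_on == pytest.approx(20.0)
        # intervals unchanged
        m1, m2 = one.measurements, measure(fid2, np.zeros(600))
        assert m2.QRS == pytest.approx(m1.QRS)
        assert m2.QT == pytest.approx(m1.QT)

    def test_rhythm_records_refused(self):
        pop = generate_population(PopulationSpec(seed=3), 1, "rhythm")
        with pytest.raises(ValueError):
            time_shift(pop[0].record, pop[0].fiducials,
                       np.random.default_rng(0))

    def test_draws_bounded_and_centered(self, one):
        rng = np.random.default_rng(7)
        shifts = [time_shift(one.record, one.fiducials, rng)[2]
                  for _ in range(1000)]
        shifts = np.asarray(shifts)
        assert np.all(np.abs(shifts) <= 40.0)
        assert abs(shifts.mean()) < 2.5
        assert shifts.std() > 15.0


class TestPopulation:
    def test_empty_population(self):
        assert generate_population(PopulationSpec(seed=0), 0) == []

    def test_bit_reproducible(self):
        a = generate_population(PopulationSpec(seed=9), 5)
        b = generate_population(PopulationSpec(seed=9), 5)
        for x, y in zip(a, b):
            assert np.array_equal(x.record.voltages, y.record.voltages)
            assert x.measurements == y.measurements

    def test_ground_truth_consistency_exact(self, population_small):
        """measure(derive_fiducials(p), make_beat(p)) returns the
        parameterizing intervals/amplitudes exactly, pre-noise."""
        for d in population_small[:25]:
            m = measure(derive_fiducials(d.params), make_beat(d.params),
                        d.params.baseline_level, rr_ms=d.params.rr_ms)
            for f in ("PR", "QRS", "QT", "HR", "R_amp", "T_amp", "STJ"):
                assert getattr(m, f) == pytest.approx(
                    getattr(d.measurements, f), abs=1e-9), f

    def test_marginals_match_spec_at_n2000(self, population_2000):
        spec = PopulationSpec()
        meas = {k: np.array([getattr(d.measurements, k)
                             for d in population_2000])
                for k in ("PR", "QRS", "QT", "HR", "R_amp", "T_amp", "STJ")}
        for k, dist in spec.distributions.items():
            v = meas[k]
            lo, hi = np.percentile(v, [5, 95])
            span = dist.p95 - dist.p5
            assert abs(np.median(v) - dist.median) <= 0.1 * abs(span), k
            assert abs(lo - dist.p5) <= 0.1 * span, k
            assert abs(hi - dist.p95) <= 0.1 * span, k

    def test_fiducials_ordered_and_in_range(self, population_small):
        for d in population_small:
            f = d.fiducials
            assert f.P_on < f.P_off <= f.QRS_on < f.QRS_off < f.T_off
            f.check_within(d.record.duration_ms)

    def test_sex_effect_zero_removes_all_class_signal(self):
        """With sex_effect = 0 the two classes are identically distributed:
        even a probe given exact generative wave features scores at
        chance."""
        from ecglens.experiments import _fit_probe, _probe_features
        pop = generate_population(PopulationSpec(seed=13, sex_effect=0.0), 500)
        y = np.array([d.measurements.label("sex") for d in pop])
        feats = _probe_features(pop, rich=True)
        idx = np.arange(len(pop))
        acc, auc = _fit_probe(feats, y, idx[:350], idx[350:])
        assert abs(auc - 0.5) < 0.09
        assert abs(acc - 0.5) < 0.09

    def test_rhythm_records_have_estimable_heart_rate(self):
        pop = generate_population(PopulationSpec(seed=4), 10, "rhythm")
        for d in pop:
            assert d.record.n_samples == 5000
            assert len(d.fiducials.beat_times) >= 4
            rr = np.diff(d.fiducials.beat_times)
            assert d.measurements.HR == pytest.approx(60000.0 / rr.mean())

    def test_quantized_record_matches_clean_template_within_noise(self):
        """The V5 lead of a noiseless record reproduces the clean template
        to within half an LSB."""
        pop = generate_population(degenerate_spec(seed=2), 1, "median")
        d = pop[0]
        template = make_beat(d.params)
        v5 = d.record.microvolts()[V5]
        assert np.abs(v5 - template).max() <= 2.44 + 1e-9
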