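"""Attention-map algorithm tests.

The core check is an arithmetic oracle: on a one-convolution toy network
with fixed, known weights the gradient-weighted map is recomputed by hand
(explicit loops, no library code) and compared to 1e-5 relative error.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from ecglens import nn
from ecglens.gradcam import (AttentionMap, intermediate_maps, layer_gradcam,
                             localization_score, per_lead_maps, upsample)
from ecglens.model import ArchitectureSpec, build_network
from ecglens.synth import PopulationSpec, generate_population


class ToyNet:
    """conv -> global average pool -> linear head, with fixed weights.

    Implements the feature-map/gradient protocol the attention-map code
    consumes.
    """

    def __init__(self, W, b, V, b0):
        c_out, c_in, k = W.shape
        self.conv = nn.Conv1D(c_in, c_out, k)
        self.conv.params["W"] = W.astype(np.float32)
        self.conv.params["b"] = b.astype(np.float32)
        self.V = V.astype(np.float32)
        self.b0 = float(b0)
        self.spec = SimpleNamespace(input_channels=c_in, head="regression")
        self._acts = {}
        self._grads = {}

    @property
    def feature_map_names(self):
        return ["input", "conv"]

    @property
    def residual_module_names(self):
        return ["conv"]

    def activation(self, name):
        return self._acts[name]

    def activation_grad(self, name):
        return self._grads[name]

    def output_gradients(self, x):
        x = np.asarray(x, dtype=np.float32)
        A = self.conv.forward(x, training=False)
        L = A.shape[2]
        y = (A.mean(axis=2) * self.V).sum(axis=1) + self.b0
        dA = np.broadcast_to(self.V[None, :, None] / L, A.shape).astype(
            np.float32)
        dx = self.conv.backward(dA)
        self._acts = {"input": x, "conv": A}
        self._grads = {"input": dx, "conv": dA}
        return y


@pytest.fixture()
def toy():
    rng = np.random.default_rng(42)
    W = rng.normal(size=(3, 2, 5))
    b = rng.normal(size=3)
    V = rng.normal(size=3)
    return ToyNet(W, b, V, b0=0.7), rng.normal(size=(1, 2, 20))


def hand_map(W, b, V, x, signed=False):
    """Independent loop-based recomputation of the layer map."""
    c_out, c_in, k = W.shape
    _, C, L = x.shape
    pl = (k - 1) // 2
    xp = np.zeros((C, L + k - 1))
    xp[:, pl:pl + L] = x[0]
    A = np.zeros((c_out, L))
    for o in range(c_out):
        for t in range(L):
            s = b[o]
            for c in range(C):
                for j in range(k):
                    s += W[o, c, j] * xp[c, t + j]
            A[o, t] = s
    alpha = V / L                      # d y / d A averaged over time
    m = np.zeros(L)
    for t in range(L):
        m[t] = sum(alpha[o] * A[o, t] for o in range(c_out))
    return m if signed else np.maximum(m, 0.0)


class TestLayerGradcamOracle:
    def test_matches_hand_computation(self, toy):
        net, x = toy
        got = layer_gradcam(net, x, "conv")
        want = hand_map(net.conv.params["W"], net.conv.params["b"],
                        net.V, x)
        scale = np.abs(want).max()
        assert np.abs(got - want).max() <= 1e-5 * scale

    def test_signed_variant_keeps_negative_lobes(self, toy):
        net, x = toy
        got = layer_gradcam(net, x, "conv", signed=True)
        want = hand_map(net.conv.params["W"], net.conv.params["b"],
                        net.V, x, signed=True)
        assert np.abs(got - want).max() <= 1e-5 * np.abs(want).max()
        assert (got < 0).any()

    def test_zeroed_head_gives_all_zero_map_with_warning(self, toy):
        net, x = toy
        net.V = np.zeros_like(net.V)
        with pytest.warns(UserWarning):
            m = layer_gradcam(net, x, "conv")
        assert np.all(m == 0.0)

    def test_unknown_layer_rejected(self, toy):
        net, x = toy
        with pytest.raises(KeyError):
            layer_gradcam(net, x, "res9.conv1")

    def test_scale_covariance(self, toy):
        """Scaling the head by c > 0 scales raw maps by c and leaves
        unit-interval-normalized maps unchanged."""
        net, x = toy
        base = per_lead_maps(net, x, "conv")
        net.V = 3.0 * net.V
        net.b0 = 3.0 * net.b0
        scaled = per_lead_maps(net, x, "conv")
        assert np.allclose(scaled.per_lead, 3.0 * base.per_lead, rtol=1e-5)
        assert np.allclose(scaled.normalized().per_lead,
                           base.normalized().per_lead, rtol=1e-5, atol=1e-8)


class TestUpsample:
    def test_identity_at_same_length(self):
        v = np.array([1.0, 3.0, 2.0])
        assert np.array_equal(upsample(v, 3), v)

    def test_constant_stays_constant(self):
        assert np.allclose(upsample(np.full(4, 2.5), 11), 2.5)

    def test_hand_interpolation(self):
        assert np.allclose(upsample(np.array([0.0, 1.0]), 5),
                           [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            upsample(np.array([]), 5)


class TestPerLeadMaps:
    def test_average_is_mean_of_rows_and_nonnegative(self, toy):
        net, x = toy
        amap = per_lead_maps(net, x, "conv")
        assert np.allclose(amap.averaged, amap.per_lead.mean(axis=0))
        assert np.all(amap.per_lead >= 0.0)

    def test_lead_weights_sum_to_layer_profile(self, toy):
        """The per-lead decomposition conserves mass: summing rows
        recovers the upsampled layer profile."""
        net, x = toy
        amap = per_lead_maps(net, x, "conv")
        G = upsample(layer_gradcam(net, x, "conv"), x.shape[2])
        assert np.allclose(amap.per_lead.sum(axis=0), G, rtol=1e-5)

    def test_single_active_lead_carries_the_mass(self):
        """A network reading only lead V5 concentrates >= 99% of per-lead
        attention mass on V5."""
        rng = np.random.default_rng(1)
        W = np.zeros((4, 12, 7))
        W[:, 10, :] = rng.normal(size=(4, 7))
        net = ToyNet(W, rng.normal(size=4), rng.normal(size=4), 0.0)
        x = rng.normal(size=(1, 12, 50))
        amap = per_lead_maps(net, x, "conv")
        mass = amap.per_lead.sum(axis=1)
        assert mass[10] / mass.sum() >= 0.99

    def test_identical_rows_average_equals_each_row(self):
        amap = AttentionMap(per_lead=np.ones((12, 10)),
                            averaged=np.ones(10), layer_name="x")
        assert np.allclose(amap.averaged, amap.per_lead[3])

    def test_frame_export_has_lead_and_averaged_rows(self):
        amap = AttentionMap(per_lead=np.ones((12, 10)),
                            averaged=np.ones(10), layer_name="x")
        df = amap.to_frame()
        assert list(df.index)[:2] == ["I", "II"]
        assert df.index[-1] == "averaged"
        assert df.shape == (13, 10)

    def test_normalization_maps_max_to_one_and_zero_stays_zero(self):
        amap = AttentionMap(per_lead=np.array([[0.0, 2.0], [1.0, 0.0]]),
                            averaged=np.array([0.5, 1.0]), layer_name="x")
        norm = amap.normalized()
        assert norm.per_lead.max() == 1.0
        zero = AttentionMap(per_lead=np.zeros((2, 2)),
                            averaged=np.zeros(2), layer_name="x").normalized()
        assert np.all(zero.per_lead == 0.0)


class TestIntermediateMaps:
    def test_one_map_per_residual_module_and_last_matches(self):
        pop = generate_population(PopulationSpec(seed=3), 1, "median")
        net = build_network(ArchitectureSpec.desk(), seed=1)
        x = np.asarray([pop[0].record.microvolts()], dtype=np.float32)
        net.forward(x, training=True)   # initialize BN statistics
        maps = intermediate_maps(net, x)
        assert len(maps) == net.spec.n_residual_modules
        last = per_lead_maps(net, x, net.residual_module_names[-1])
        assert np.allclose(maps[-1].per_lead, last.per_lead)


class TestFocusProgression:
    def test_attention_narrows_through_residual_modules(self, study):
        """On the trained R-amplitude model, attention mass inside the QRS
        window does not decrease from the first to the last residual
        module for at least 70% of holdout records."""
        net = study.models.models["R_amp"]
        records = [study.dataset[i] for i in study.models.test_idx[:40]]
        hits = 0
        for d in records:
            maps = intermediate_maps(net, d)
            win = (d.fiducials.QRS_on, d.fiducials.QRS_off)
            scores = [localization_score(m, win) for m in maps]
            hits += scores[-1] >= scores[0]
        assert hits >= 0.7 * len(records), hits


class TestLocalizationScore:
    def make_map(self, averaged):
        averaged = np.asarray(averaged, dtype=float)
        return AttentionMap(per_lead=np.tile(averaged, (12, 1)),
                            averaged=averaged, layer_name="x", fs=500.0)

    def test_whole_record_scores_one(self):
        amap = self.make_map(np.random.default_rng(0).random(600))
        dur = 600 / 500.0 * 1000.0
        assert localization_score(amap, (0.0, dur)) == pytest.approx(1.0)

    def test_map_inside_window_scores_one(self):
        v = np.zeros(600)
        v[100:150] = 1.0
        assert localization_score(self.make_map(v),
                                  (200.0, 300.0)) == pytest.approx(1.0)

    def test_uniform_map_scores_window_fraction(self):
        amap = self.make_map(np.ones(600))
        assert localization_score(amap, (0.0, 300.0)) == pytest.approx(0.25)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            localization_score(self.make_map(np.ones(600)), (100.0, 100.0))

    def test_zero_map_scores_zero(self):
        assert localization_score(self.make_map(np.zeros(600)),
                                  (0.0, 100.0)) == 0.0
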