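"""The residual ECG measurement network.

Topology: two initial convolutions (64 then 32 feature maps, kernels 8 and
3), each followed by batch normalization and ReLU; one average pooling;
eight residual modules (two convolutions of 64 and 32 maps, kernel 50,
batch-normalized, with dropout after the second convolution, a skip
addition and a final ReLU); global average pooling; a single-neuron head
(linear for regression, logistic for binary classification).  Same padding
keeps the temporal length constant inside the residual modules so the skip
addition is well defined, and the global-average-pooling head makes the
parameter count independent of the input length: the same network accepts
1.2-s median beats (600 samples) and 10-s rhythm strips (5000 samples).

Parameter counting convention
-----------------------------
``count_parameters`` reports either trainable weights only or all
parameters including the batch-normalization moving statistics (the
"total params" convention of Keras-style frameworks).  The full-size
network consumes the 8 linearly independent channels of a 12-lead ECG
(I, II, V1-V6; the four remaining limb leads are fixed linear combinations
and add no information).  Under that input convention the total-parameter
count is 1,652,993; with all 12 channels it would be 1,655,041
(total) / 1,653,313 (trainable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .records import ECGRecord, LEAD_NAMES
from .synth import LabeledECG

__all__ = ["ArchitectureSpec", "ResidualECGNet", "build_network",
           "count_parameters", "predict", "predict_denorm",
           "records_to_input"]


@dataclass
class ArchitectureSpec:
    """Declarative description of the network."""

    n_leads: int = 12              # leads in the consumed ECG record
    in_channels: Optional[int] = None  # network input channels (None = n_leads)
    initial_filters: Tuple[int, int] = (64, 32)
    initial_kernels: Tuple[int, int] = (8, 3)
    n_residual_modules: int = 8
    residual_filters: Tuple[int, int] = (64, 32)
    residual_kernel: int = 50
    dropout_rate: float = 0.5
    pool_size: int = 2
    head: str = "regression"       # or "classification"

    def __post_init__(self) -> None:
        if self.head not in ("regression", "classification"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.initial_filters[1] != self.residual_filters[1]:
            raise ValueError(
                "residual skip addition requires the initial block output "
                f"channels ({self.initial_filters[1]}) to equal the residual "
                f"module output channels ({self.residual_filters[1]})")

    @property
    def input_channels(self) -> int:
        return self.in_channels if self.in_channels is not None else self.n_leads

    def to_json(self) -> str:
        """Versioned JSON serialization of the architecture description."""
        import dataclasses
        import json
        payload = {"format_version": 1, **dataclasses.asdict(self)}
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        import json
        payload = json.loads(text)
        if payload.pop("format_version", 1) != 1:
            raise ValueError("unsupported architecture format version")
        for k in ("initial_filters", "initial_kernels", "residual_filters"):
            payload[k] = tuple(payload[k])
        return cls(**payload)

    @classmethod
    def full(cls, head: str = "regression") -> "ArchitectureSpec":
        """Full-size architecture; consumes the 8 independent channels."""
        return cls(in_channels=8, head=head)

    @classmethod
    def desk(cls, head: str = "regression") -> "ArchitectureSpec":
        """Reduced preset for CPU-scale experiments (all 12 channels).

        Filters 16/8, residual kernel 15, two residual modules.  The
        qualitative behavior of the full network (what it attends to, what
        breaks it) survives this scaling; its absolute errors do not.
        """
        return cls(initial_filters=(16, 8), initial_kernels=(8, 3),
                   n_residual_modules=2, residual_filters=(16, 8),
                   residual_kernel=15, head=head)


class ResidualECGNet:
    """The constructed differentiable model.

    ``forward`` caches every named feature map; ``backward`` populates the
    matching gradient table, including the gradient with respect to the
    input (``"input"``) — the plumbing gradient-weighted attention maps
    are built on.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f1, f2 = spec.initial_filters
        k1, k2 = spec.initial_kernels
        rf1, rf2 = spec.residual_filters
        self.layers: Dict[str, nn.Layer] = {}

        def add(name: str, layer: nn.Layer) -> nn.Layer:
            layer.name = name
            self.layers[name] = layer
            return layer

        add("conv1", nn.Conv1D(spec.input_channels, f1, k1, rng))
        add("bn1", nn.BatchNorm1D(f1))
        add("relu1", nn.ReLU())
        add("conv2", nn.Conv1D(f1, f2, k2, rng))
        add("bn2", nn.BatchNorm1D(f2))
        add("relu2", nn.ReLU())
        add("pool", nn.AvgPool1D(spec.pool_size))
        for i in range(1, spec.n_residual_modules + 1):
            if rf2 != f2:
                raise ValueError("residual module output channels must match "
                                 "its input channels for the skip addition")
            add(f"res{i}.conv1", nn.Conv1D(rf2, rf1, spec.residual_kernel, rng))
            add(f"res{i}.bn1", nn.BatchNorm1D(rf1))
            add(f"res{i}.relu1", nn.ReLU())
            add(f"res{i}.conv2", nn.Conv1D(rf1, rf2, spec.residual_kernel, rng))
            add(f"res{i}.bn2", nn.BatchNorm1D(rf2))
            add(f"res{i}.drop", nn.Dropout(spec.dropout_rate))
            add(f"res{i}.out", nn.ReLU())
        add("gap", nn.GlobalAvgPool())
        add("dense", nn.Dense(rf2, 1, rng))
        self._acts: Dict[str, np.ndarray] = {}
        self._act_grads: Dict[str, np.ndarray] = {}

    # -- introspection -----------------------------------------------------
    @property
    def layer_names(self) -> List[str]:
        return list(self.layers)

    @property
    def feature_map_names(self) -> List[str]:
        """Names usable as attention-map layers (temporal feature maps)."""
        keep = ("conv", "bn", "relu", "pool", "out", "drop")
        return ["input"] + [n for n in self.layers
                            if any(t in n.split(".")[-1] for t in keep)]

    @property
    def residual_module_names(self) -> List[str]:
        return [f"res{i}.out"
                for i in range(1, self.spec.n_residual_modules + 1)]

    def activation(self, name: str) -> np.ndarray:
        return self._acts[name]

    def activation_grad(self, name: str) -> np.ndarray:
        return self._act_grads[name]

    def set_seed(self, seed: int) -> None:
        """Reseed stochastic layers (dropout)."""
        for i, layer in enumerate(l for l in self.layers.values()
                                  if isinstance(l, nn.Dropout)):
            layer.rng = np.random.default_rng((seed, i))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input ``(batch, channels, length)`` in microvolt -> ``(batch,)`` scalars."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 3:
            raise ValueError("input must be (batch, channels, length)")
        if x.shape[1] != self.spec.input_channels:
            raise ValueError(f"expected {self.spec.input_channels} input "
                             f"channels, got {x.shape[1]}")
        A = self._acts
        A.clear()
        self._act_grads.clear()
        A["input"] = x
        h = x
        for name in ("conv1", "bn1", "relu1", "conv2", "bn2", "relu2", "pool"):
            h = self.layers[name].forward(h, training)
            A[name] = h
        for i in range(1, self.spec.n_residual_modules + 1):
            skip = h
            for part in ("conv1", "bn1", "relu1", "conv2", "bn2", "drop"):
                name = f"res{i}.{part}"
                h = self.layers[name].forward(h, training)
                A[name] = h
            h = self.layers[f"res{i}.out"].forward(h + skip, training)
            A[f"res{i}.out"] = h
        g = self.layers["gap"].forward(h, training)
        A["gap"] = g
        z = self.layers["dense"].forward(g, training)
        A["dense"] = z
        return z[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output); returns d(loss)/d(input).

        Every entry of the gradient table holds d(loss)/d(activation) for
        the activation stored under the same name in ``forward``.
        """
        G = self._act_grads
        dy = np.asarray(dy, dtype=np.float32)[:, None]
        G["dense"] = dy
        d = self.layers["dense"].backward(dy)
        G["gap"] = d
        d = self.layers["gap"].backward(d)
        for i in range(self.spec.n_residual_modules, 0, -1):
            G[f"res{i}.out"] = d
            d = self.layers[f"res{i}.out"].backward(d)
            d_skip = d
            for part in ("drop", "bn2", "conv2", "relu1", "bn1", "conv1"):
                name = f"res{i}.{part}"
                G[name] = d
                d = self.layers[name].backward(d)
            d = d + d_skip
        for name in ("pool", "relu2", "bn2", "conv2", "relu1", "bn1", "conv1"):
            G[name] = d
            d = self.layers[name].backward(d)
        G["input"] = d
        return d

    def output_gradients(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward + backward of the raw output.

        After this call ``activation_grad(name)`` holds d(output)/d(map)
        for every named feature map (summed over the batch outputs).
        """
        y = self.forward(x, training=False)
        self.backward(np.ones_like(y))
        return y

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {}
        for attr in ("y_loc", "y_scale"):   # label affine set by train.fit
            if hasattr(self, attr):
                out[f"__{attr}__"] = np.array(getattr(self, attr))
        for lname, layer in self.layers.items():
            for k, p in layer.params.items():
                out[f"{lname}/{k}"] = p
            for k, s in layer.stats.items():
                out[f"{lname}/stats/{k}"] = s
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for attr in ("y_loc", "y_scale"):
            if f"__{attr}__" in state:
                setattr(self, attr, float(state[f"__{attr}__"]))
        for lname, layer in self.layers.items():
            for k in layer.params:
                layer.params[k] = np.array(state[f"{lname}/{k}"],
                                           dtype=np.float32)
            for k in layer.stats:
                layer.stats[k] = np.array(state[f"{lname}/stats/{k}"],
                                          dtype=np.float32)

    def zero_grad(self) -> None:
        for layer in self.layers.values():
            layer.zero_grad()


def build_network(spec: ArchitectureSpec, seed: int = 0) -> ResidualECGNet:
    """Construct the network with deterministic (seeded) initial weights."""
    return ResidualECGNet(spec, seed=seed)


def count_parameters(net: ResidualECGNet,
                     include_nontrainable: bool = True) -> int:
    """Total parameter count.

    ``include_nontrainable=True`` adds the batch-normalization moving mean
    and variance ("total params" convention), the convention under which
    the full-size 12-lead network counts 1,652,993 parameters.
    """
    return sum(layer.n_params(include_nontrainable)
               for layer in net.layers.values())


def records_to_input(records: Sequence[Union[ECGRecord, LabeledECG]],
                     in_channels: int) -> np.ndarray:
    """Stack records into a network input batch (microvolt units).

    With ``in_channels == 8`` the 8 independent channels of each 12-lead
    record are used; otherwise all leads are fed as-is.
    """
    mats = []
    for r in records:
        rec = r.record if isinstance(r, LabeledECG) else r
        if in_channels == 8 and rec.n_leads == 12:
            mats.append(rec.independent_channels())
        else:
            if rec.n_leads != in_channels:
                raise ValueError(f"record has {rec.n_leads} leads; network "
                                 f"expects {in_channels} channels")
            mats.append(rec.microvolts())
    return np.asarray(mats, dtype=np.float32)


def predict(net: ResidualECGNet,
            records: Union[np.ndarray, Sequence[Union[ECGRecord, LabeledECG]]],
            batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode predictions, one scalar per record.

    Classification heads return the logistic probability of class 1;
    regression heads return the raw output.  Deterministic: dropout is
    off and batch normalization uses its moving statistics, so the
    prediction for a record does not depend on its batch companions.
    """
    if not isinstance(records, np.ndarray):
        X = records_to_input(records, net.spec.input_channels)
    else:
        X = np.asarray(records, dtype=np.float32)
    outs = []
    for i in range(0, X.shape[0], batch_size):
        outs.append(net.forward(X[i:i + batch_size], training=False))
    z = np.concatenate(outs) if outs else np.zeros(0)
    if net.spec.head == "classification":
        return 1.0 / (1.0 + np.exp(-z))
    return z


def predict_denorm(net: ResidualECGNet, records,
                   batch_size: int = 256) -> np.ndarray:
    """Predictions on the original label scale.

    Training z-scores regression labels and stores the affine on the
    network (``y_loc``, ``y_scale``); this undoes it.  Classification
    probabilities pass through unchanged.
    """
    p = predict(net, records, batch_size)
    if net.spec.head == "classification":
        return p
    return p * getattr(net, "y_scale", 1.0) + getattr(net, "y_loc", 0.0)
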