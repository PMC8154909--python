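"""Gradient-weighted class-activation maps for multichannel 1-D ECG.

The classic formulation computes, at a chosen convolutional layer with
feature maps :math:`A^k(t)`, the channel weights
:math:`\\alpha_k = \\overline{\\partial y / \\partial A^k}` (temporal
average of the output gradient) and the rectified combination
:math:`M(t) = \\mathrm{ReLU}(\\sum_k \\alpha_k A^k(t))` — a temporal
importance profile at the layer's resolution.

For 12-lead ECG the leads are mixed by the first convolution, so a single
profile cannot say *which lead* mattered.  The per-lead construction here
distributes the upsampled profile :math:`G(t)` over leads with the
input-gradient weights
:math:`w_l(t) = |\\partial y/\\partial x_l(t)| / \\sum_m |\\partial
y/\\partial x_m(t)|` (uniform where all input gradients vanish), giving
``per_lead[l, t] = G(t) * w_l(t)``.  By construction the weights sum to 1
at every t, so the arithmetic lead-average of the per-lead maps is exactly
``G(t) / n_leads`` — the lead-averaged map reduces to the layer profile.
A plain input-saliency alternative (``lead_weighting="saliency"``) is
available for diagnostics.

Raw maps are averaged first and normalized (to the unit interval) only
for display or scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Union

import numpy as np

from .model import ResidualECGNet, records_to_input
from .records import DEFAULT_FS, ECGRecord
from .synth import LabeledECG

__all__ = ["AttentionMap", "layer_gradcam", "per_lead_maps", "upsample",
           "intermediate_maps", "localization_score"]


@dataclass
class AttentionMap:
    """Per-lead and lead-averaged temporal importance of one record."""

    per_lead: np.ndarray          # (n_leads, N), >= 0
    averaged: np.ndarray          # (N,), the arithmetic mean over leads
    layer_name: str
    output_index: int = 0
    normalization: str = "raw"    # "raw" | "unit-interval"
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.per_lead = np.asarray(self.per_lead, dtype=float)
        self.averaged = np.asarray(self.averaged, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.averaged.size

    def to_frame(self):
        """Export as a table: one row per lead plus an ``averaged`` row,
        one column per sample."""
        import pandas as pd
        from .records import LEAD_NAMES
        n = self.per_lead.shape[0]
        names = list(LEAD_NAMES[:n]) if n <= 12 else [f"ch{i}" for i in range(n)]
        data = np.vstack([self.per_lead, self.averaged])
        return pd.DataFrame(data, index=names + ["averaged"])

    def normalized(self) -> "AttentionMap":
        """Scale so the global maximum maps to 1 (identically-zero maps stay 0)."""
        peak = self.per_lead.max() if self.per_lead.size else 0.0
        if peak <= 0.0:
            return replace(self, normalization="unit-interval")
        return replace(self, per_lead=self.per_lead / peak,
                       averaged=self.averaged / peak,
                       normalization="unit-interval")


def _to_input(record, net: ResidualECGNet) -> np.ndarray:
    if isinstance(record, np.ndarray):
        x = np.asarray(record, dtype=np.float32)
        return x[None, :, :] if x.ndim == 2 else x
    return records_to_input([record], net.spec.input_channels)


def layer_gradcam(net: ResidualECGNet,
                  record: Union[ECGRecord, LabeledECG, np.ndarray],
                  layer_name: str, output_index: int = 0,
                  signed: bool = False) -> np.ndarray:
    """Temporal importance profile at one layer's resolution.

    Runs an evaluation-mode forward/backward pass, averages the output
    gradient over time per channel, and combines the feature maps with
    those weights, rectifying the result (``signed=True`` skips the
    rectification — negative contributions are meaningful diagnostics for
    regression heads).  A map that is identically zero (e.g. the output
    does not depend on the input) is returned as-is with a warning.
    """
    if layer_name not in net.feature_map_names:
        raise KeyError(f"unknown feature map {layer_name!r}; "
                       f"choose from {net.feature_map_names}")
    x = _to_input(record, net)
    if x.shape[0] != 1:
        raise ValueError("attention maps are computed one record at a time")
    net.output_gradients(x)
    A = net.activation(layer_name)[0]          # (C, L)
    dA = net.activation_grad(layer_name)[0]    # (C, L)
    alpha = dA.mean(axis=1)                    # channel weights
    m = (alpha[:, None] * A).sum(axis=0)
    if not signed:
        m = np.maximum(m, 0.0)
    if not np.any(m):
        warnings.warn(f"attention map at {layer_name!r} is identically zero")
    return m.astype(float)


def upsample(profile: np.ndarray, target_len: int) -> np.ndarray:
    """Linear interpolation to ``target_len`` samples, endpoints preserved."""
    p = np.asarray(profile, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("cannot upsample an empty map")
    if target_len < p.size:
        raise ValueError("target length must be >= map length")
    if p.size == 1:
        return np.full(target_len, p[0])
    xi = np.linspace(0.0, p.size - 1.0, target_len)
    return np.interp(xi, np.arange(p.size), p)


def per_lead_maps(net: ResidualECGNet,
                  record: Union[ECGRecord, LabeledECG, np.ndarray],
                  layer_name: Optional[str] = None, output_index: int = 0,
                  lead_weighting: str = "gradient") -> AttentionMap:
    """Full attention map: layer profile distributed over leads.

    ``layer_name`` defaults to the output of the last residual module (the
    final feature map before prediction).  ``lead_weighting="gradient"``
    is the normalized-input-gradient construction documented in the module
    docstring; ``"saliency"`` returns plain |input gradient| maps scaled
    to the same total mass per time step.
    """
    if layer_name is None:
        layer_name = net.residual_module_names[-1]
    x = _to_input(record, net)
    G = layer_gradcam(net, x, layer_name, output_index)
    n = x.shape[2]
    Gup = upsample(G, n)
    gin = np.abs(net.activation_grad("input")[0])    # (C, N)
    if lead_weighting not in ("gradient", "saliency"):
        raise ValueError(f"unknown lead_weighting {lead_weighting!r}")
    tot = gin.sum(axis=0, keepdims=True)
    w = np.where(tot > 0, gin / np.where(tot > 0, tot, 1.0),
                 1.0 / x.shape[1])
    if lead_weighting == "saliency":
        per_lead = gin
    else:
        per_lead = Gup[None, :] * w
    return AttentionMap(per_lead=per_lead, averaged=per_lead.mean(axis=0),
                        layer_name=layer_name, output_index=output_index,
                        fs=net_fs(record))


def net_fs(record) -> float:
    if isinstance(record, LabeledECG):
        return record.record.fs
    if isinstance(record, ECGRecord):
        return record.fs
    return DEFAULT_FS


def intermediate_maps(net: ResidualECGNet,
                      record: Union[ECGRecord, LabeledECG, np.ndarray],
                      output_index: int = 0) -> List[AttentionMap]:
    """Attention maps at the final layer of every residual module, in order.

    Lets one follow how the network's focus narrows from the early modules
    (broad, multiple waves) to the final one (the wave that defines the
    predicted variable).
    """
    return [per_lead_maps(net, record, name, output_index)
            for name in net.residual_module_names]


def localization_score(amap: AttentionMap, window_ms: Sequence[float]) -> float:
    """Fraction of total (lead-averaged) attention mass inside a time window.

    ``window_ms = (t0, t1)`` in ms from record start; returns
    ``sum(averaged[t0:t1]) / sum(averaged)``, and 0 for an identically
    zero map.  A uniform map scores the window's length fraction, so a
    score above that fraction means the window is preferentially attended.
    """
    t0, t1 = window_ms
    i0 = max(0, int(round(t0 * amap.fs / 1000.0)))
    i1 = min(amap.n_samples, int(round(t1 * amap.fs / 1000.0)))
    if i1 <= i0:
        raise ValueError(f"empty attention window {window_ms}")
    total = amap.averaged.sum()
    if total <= 0.0:
        return 0.0
    return float(amap.averaged[i0:i1].sum() / total)
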