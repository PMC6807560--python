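"""Epsilon-rule layer-wise relevance propagation and gradient*input.

LRP decomposes a network's scalar classification score into signed per-voxel
relevance values.  For a linear (dense or convolutional) layer with forward
pre-activations ``z_j = sum_k x_k w_jk``, the epsilon rule distributes the
upstream relevance ``R_j`` over the layer's inputs as

    R_i = sum_j  x_i w_ji / (z_j + eps * sign(z_j)) * R_j

where ``eps`` (default 0.001) stabilizes near-zero denominators and
``sign(0) := +1``.  With ``eps = 0`` and no bias the rule conserves relevance
exactly: ``sum_i R_i = sum_j R_j`` at every layer, and the total input
relevance equals the starting score.  Max-pooling routes relevance
winner-take-all to the input position that attained the maximum (first
maximal index on ties); monotone elementwise layers (ELU, dropout in eval
mode, flatten) pass relevance through unchanged.

Propagation starts by default from the pre-sigmoid logit, so that the map's
sign carries class evidence: positive voxels support the positive (patient)
class, negative voxels speak against it.  Starting from the sigmoid output
instead is available via :class:`RelpropConfig`.

``gradient_times_input`` computes the voxelwise product of the logit's input
gradient with the input itself — an alternative global attribution method
that coincides with LRP at ``eps = 0`` on bias-free linear (activation-free)
networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv3D, Dense, MaxPool3D, Network
from .volume_io import Volume

__all__ = [
    "RelpropConfig",
    "RelevanceMap",
    "propagate_linear",
    "propagate_maxpool",
    "propagate_elementwise",
    "lrp_explain",
    "gradient_times_input",
    "symmetric_window",
]


@dataclass(frozen=True)
class RelpropConfig:
    """Options of the epsilon rule.

    ``bias_policy`` controls the denominator of the rule: ``"discard"``
    (default) uses ``z_j = sum_k x_k w_jk`` exactly as written above — the
    bias is ignored entirely, and layer-wise conservation holds at eps=0;
    ``"absorb"`` adds the bias into ``z_j``, so the bias soaks up the share
    ``b_j / z_j`` of the relevance, which is then dropped.
    """

    epsilon: float = 0.001
    start_from: str = "logit"  # or "sigmoid"
    bias_policy: str = "discard"  # or "absorb"

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.start_from not in ("logit", "sigmoid"):
            raise ValueError(f"unknown start_from {self.start_from!r}")
        if self.bias_policy not in ("discard", "absorb"):
            raise ValueError(f"unknown bias_policy {self.bias_policy!r}")


@dataclass
class RelevanceMap:
    """Signed per-voxel relevance aligned to the input volume."""

    data: np.ndarray
    start_score: float
    method: str  # "lrp_epsilon" or "gradient_input"
    epsilon: float = 0.0
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("relevance map contains non-finite values")

    @property
    def shape(self):
        return tuple(self.data.shape)

    def total(self) -> float:
        return float(self.data.sum())


def _stabilize(z: np.ndarray, eps: float) -> np.ndarray:
    """z + eps*sign(z) with sign(0) := +1; errors on exact zeros at eps=0."""
    if eps == 0.0:
        if np.any(z == 0.0):
            raise ZeroDivisionError(
                "zero pre-activation denominator with epsilon=0; "
                "use a positive epsilon stabilizer"
            )
        return z
    return np.where(z >= 0, z + eps, z - eps)


def propagate_linear(layer, input_x: np.ndarray, upstream_R: np.ndarray, cfg: RelpropConfig):
    """Apply the epsilon rule through one dense or conv3d layer.

    ``input_x`` must be the recorded forward input of the layer; a conv layer
    is treated as the equivalent sparse linear map over its receptive fields.
    """
    if isinstance(layer, Dense):
        z = layer.W @ input_x
        if cfg.bias_policy == "absorb":
            z = z + layer.b
        s = np.asarray(upstream_R, dtype=np.float64) / _stabilize(z, cfg.epsilon)
        return input_x * (layer.W.T @ s)
    if isinstance(layer, Conv3D):
        cols = layer.im2col(input_x)  # (N, C_in*k^3)
        Wm = layer.W.reshape(layer.out_channels, -1)
        z = cols @ Wm.T  # (N, C_out)
        if cfg.bias_policy == "absorb":
            z = z + layer.b
        R_up = np.asarray(upstream_R, dtype=np.float64).reshape(layer.out_channels, -1).T
        s = R_up / _stabilize(z, cfg.epsilon)  # (N, C_out)
        dcols = cols * (s @ Wm)
        return layer._cols_to_input(dcols, input_x.shape)
    raise TypeError(f"propagate_linear expects a dense or conv3d layer, got {layer.kind}")


def propagate_maxpool(layer: MaxPool3D, input_x: np.ndarray, upstream_R: np.ndarray):
    """Winner-take-all: all relevance of a pooled output goes to the input
    position that attained the maximum (first index in scan order on ties)."""
    win = layer._windows(input_x)
    arg = win.argmax(axis=-1)
    C, D2, H2, W2 = arg.shape
    R_up = np.asarray(upstream_R, dtype=np.float64)
    dwin = np.zeros((C, D2, H2, W2, 8))
    np.put_along_axis(dwin, arg[..., None], R_up[..., None], axis=-1)
    dxc = dwin.reshape(C, D2, H2, W2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
    dxc = dxc.reshape(C, 2 * D2, 2 * H2, 2 * W2)
    dx = np.zeros(input_x.shape)
    dx[:, : 2 * D2, : 2 * H2, : 2 * W2] = dxc
    return dx


def propagate_elementwise(layer, input_x: np.ndarray, upstream_R: np.ndarray):
    """Identity pass-through for monotone elementwise layers; flatten only
    reshapes (the relevance sum is preserved exactly)."""
    R = np.asarray(upstream_R, dtype=np.float64)
    if layer.kind == "flatten":
        return R.reshape(input_x.shape)
    if layer.kind in ("elu", "dropout", "sigmoid"):
        return R.reshape(np.asarray(input_x).shape)
    raise TypeError(f"propagate_elementwise cannot handle layer kind {layer.kind!r}")


def _as_input_array(net: Network, volume) -> np.ndarray:
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume, dtype=np.float64)
    if data.shape != net.input_shape:
        raise ValueError(f"volume shape {data.shape} != network input {net.input_shape}")
    return data


def lrp_explain(net: Network, volume, cfg: RelpropConfig | None = None) -> RelevanceMap:
    """Decompose the network's score for one volume into a relevance map.

    Runs an eval-mode forward pass (dropout inactive), seeds the relevance
    with the pre-sigmoid logit (or the sigmoid score, per config) and applies
    the per-layer rules backward through the stack.
    """
    cfg = cfg or RelpropConfig()
    data = _as_input_array(net, volume)
    score, logit, trace = net.forward(data, train=False, record=True)
    start = logit if cfg.start_from == "logit" else score
    R: np.ndarray = np.array([start], dtype=np.float64)
    for layer, layer_input in zip(reversed(net.layers), reversed(trace.inputs)):
        kind = layer.kind
        if kind == "sigmoid":
            continue  # the seed already sits below the sigmoid
        if kind in ("dense", "conv3d"):
            R = propagate_linear(layer, layer_input, R, cfg)
        elif kind == "maxpool3d":
            R = propagate_maxpool(layer, layer_input, R)
        elif kind in ("elu", "dropout", "flatten"):
            R = propagate_elementwise(layer, layer_input, R)
        else:
            raise TypeError(f"unsupported layer kind for LRP: {kind!r}")
    sid = volume.subject_id if isinstance(volume, Volume) else ""
    return RelevanceMap(
        data=R.reshape(net.input_shape),
        start_score=float(start),
        method="lrp_epsilon",
        epsilon=cfg.epsilon,
        subject_id=sid,
    )


def gradient_times_input(net: Network, volume) -> RelevanceMap:
    """Voxelwise (d logit / d x) * x for one volume (eval mode)."""
    data = _as_input_array(net, volume)
    score, logit, _ = net.forward(data, train=False)
    dx = net.backward_logit(1.0)  # gradient of the logit w.r.t. the input
    net.zero_grad()  # discard parameter-gradient side effects
    sid = volume.subject_id if isinstance(volume, Volume) else ""
    return RelevanceMap(
        data=dx.reshape(net.input_shape) * data,
        start_score=float(logit),
        method="gradient_input",
        epsilon=0.0,
        subject_id=sid,
    )


def symmetric_window(heatmap: RelevanceMap, quantile: float = 0.99) -> tuple[float, float]:
    """Symmetric display window (-w, +w) with w the given quantile of |R|.

    Fixed presets such as (-0.03, 0.03) or (-0.02, 0.02) can be passed to
    plotting code directly instead.
    """
    if not (0 < quantile <= 1):
        raise ValueError("quantile must be in (0,1]")
    w = float(np.quantile(np.abs(heatmap.data), quantile))
    return (-w, w)
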