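"""Minimal 3D CNN engine with explicit per-layer state.

Layers operate on single samples in channel-first layout ``(C, D, H, W)``
(dense layers on flat vectors) and expose exactly what relevance propagation
needs: weights, per-layer forward caches (im2col patches, max-pool argmax)
and analytic backward passes.  Convolutions use stride 1 with zero "same"
padding, so spatial shape is controlled solely by pooling; max-pooling uses
2x2x2 windows with stride 2, cropping a trailing odd slice.

The engine is deliberately small: it implements the one architecture family
this package trains (conv3d / ELU / maxpool / dropout / flatten / dense /
sigmoid) rather than a general autodiff framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Conv3D",
    "ELU",
    "MaxPool3D",
    "Dropout",
    "Flatten",
    "Dense",
    "Sigmoid",
    "Network",
    "ActivationTrace",
    "build_network",
    "save_network",
    "load_network",
]

_IM2COL_CACHE: dict[tuple, tuple] = {}


def _im2col_indices(C: int, D: int, H: int, W: int, k: int):
    """Flat gather indices mapping a zero-padded (C,Dp,Hp,Wp) volume to the
    (N_positions, C*k^3) patch matrix of a stride-1 'same' convolution."""
    key = (C, D, H, W, k)
    if key in _IM2COL_CACHE:
        return _IM2COL_CACHE[key]
    p = k // 2
    Dp, Hp, Wp = D + 2 * p, H + 2 * p, W + 2 * p
    dd, hh, ww = np.meshgrid(np.arange(D), np.arange(H), np.arange(W), indexing="ij")
    base = (dd * Hp * Wp + hh * Wp + ww).ravel()  # (N,)
    cc, kd, kh, kw = np.meshgrid(
        np.arange(C), np.arange(k), np.arange(k), np.arange(k), indexing="ij"
    )
    off = (cc * Dp * Hp * Wp + kd * Hp * Wp + kh * Wp + kw).reshape(-1)  # (C*k^3,)
    idx = base[:, None] + off[None, :]
    out = (idx, (Dp, Hp, Wp), p)
    _IM2COL_CACHE[key] = out
    return out


class Conv3D:
    """3D convolution, stride 1, zero 'same' padding.

    Weights ``W`` have shape (out_channels, in_channels, k, k, k).
    """

    kind = "conv3d"

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = int(kernel_size)
        self.W = np.zeros((out_channels, in_channels, self.k, self.k, self.k))
        self.b = np.zeros(out_channels)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    def init_weights(self, rng: np.random.Generator, dtype=np.float64) -> None:
        fan_in = self.in_channels * self.k**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=self.W.shape).astype(dtype)
        self.b = np.zeros(self.out_channels, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def out_shape(self, in_shape):
        C, D, H, W = in_shape
        if C != self.in_channels:
            raise ValueError(f"conv expects {self.in_channels} channels, got {C}")
        return (self.out_channels, D, H, W)

    def im2col(self, x: np.ndarray) -> np.ndarray:
        C, D, H, W = x.shape
        idx, _, p = _im2col_indices(C, D, H, W, self.k)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        return xp.ravel()[idx]  # (N, C*k^3)

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        C, D, H, W = x.shape
        cols = self.im2col(x)
        self._cols, self._in_shape = cols, x.shape
        Wm = self.W.reshape(self.out_channels, -1)
        out = cols @ Wm.T + self.b  # (N, C_out)
        return out.T.reshape(self.out_channels, D, H, W)

    def _cols_to_input(self, dcols: np.ndarray, in_shape) -> np.ndarray:
        """Scatter-add a (N, C*k^3) patch-gradient back onto the input grid."""
        C, D, H, W = in_shape
        idx, (Dp, Hp, Wp), p = _im2col_indices(C, D, H, W, self.k)
        flat = np.bincount(idx.ravel(), weights=dcols.ravel(), minlength=C * Dp * Hp * Wp)
        dxp = flat.reshape(C, Dp, Hp, Wp).astype(dcols.dtype, copy=False)
        if p == 0:
            return dxp
        return dxp[:, p:-p, p:-p, p:-p]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        C_out, D, H, W = dout.shape
        doutm = dout.reshape(C_out, -1).T  # (N, C_out)
        Wm = self.W.reshape(C_out, -1)
        self.gW += (doutm.T @ self._cols).reshape(self.W.shape)
        self.gb += dout.reshape(C_out, -1).sum(axis=1)
        dcols = doutm @ Wm
        return self._cols_to_input(dcols, self._in_shape)


class ELU:
    kind = "elu"

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._x = None
        self._out = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False, rng=None):
        out = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._x, self._out = x, out
        return out

    def backward(self, dout):
        return dout * np.where(self._x > 0, 1.0, self._out + self.alpha)


class MaxPool3D:
    """2x2x2 max pooling, stride 2; trailing odd slices are cropped."""

    kind = "maxpool3d"
    size = 2

    def __init__(self):
        self._arg = None
        self._in_shape = None

    def out_shape(self, in_shape):
        C, D, H, W = in_shape
        D2, H2, W2 = D // 2, H // 2, W // 2
        if min(D2, H2, W2) < 1:
            raise ValueError(f"input {in_shape} too small for 2x2x2 pooling")
        return (C, D2, H2, W2)

    def _windows(self, x):
        C, D, H, W = x.shape
        D2, H2, W2 = D // 2, H // 2, W // 2
        xc = x[:, : 2 * D2, : 2 * H2, : 2 * W2]
        win = xc.reshape(C, D2, 2, H2, 2, W2, 2).transpose(0, 1, 3, 5, 2, 4, 6)
        return win.reshape(C, D2, H2, W2, 8)

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        win = self._windows(x)
        # argmax returns the first maximal index in window scan order, which
        # fixes the documented tie-break for relevance routing.
        self._arg = win.argmax(axis=-1)
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def scatter(self, dout: np.ndarray) -> np.ndarray:
        """Route per-output values to the argmax input positions (used by both
        the gradient and the winner-take-all relevance rule)."""
        C, D, H, W = self._in_shape
        C2, D2, H2, W2 = dout.shape[0], *dout.shape[1:]
        dwin = np.zeros((C2, D2, H2, W2, 8), dtype=dout.dtype)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dxc = dwin.reshape(C2, D2, H2, W2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        dxc = dxc.reshape(C2, 2 * D2, 2 * H2, 2 * W2)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : 2 * D2, : 2 * H2, : 2 * W2] = dxc
        return dx

    def backward(self, dout):
        return self.scatter(dout)


class Dropout:
    """Inverted dropout; identity in eval mode."""

    kind = "dropout"

    def __init__(self, p: float):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout p must be in [0,1)")
        self.p = p
        self._mask = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False, rng=None):
        if train and self.p > 0:
            if rng is None:
                raise ValueError("dropout in train mode needs an rng")
            self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten:
    kind = "flatten"

    def __init__(self):
        self._in_shape = None

    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(-1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense:
    """Fully connected layer; W has shape (out_dim, in_dim)."""

    kind = "dense"

    def __init__(self, in_dim: int, out_dim: int):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W = np.zeros((out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def init_weights(self, rng: np.random.Generator, dtype=np.float64) -> None:
        limit = np.sqrt(6.0 / (self.in_dim + self.out_dim))
        self.W = rng.uniform(-limit, limit, size=self.W.shape).astype(dtype)
        self.b = np.zeros(self.out_dim, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def out_shape(self, in_shape):
        if int(np.prod(in_shape)) != self.in_dim:
            raise ValueError(f"dense expects {self.in_dim} inputs, got {in_shape}")
        return (self.out_dim,)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return self.W @ x + self.b

    def backward(self, dout):
        self.gW += np.outer(dout, self._x)
        self.gb += dout
        return self.W.T @ dout


class Sigmoid:
    kind = "sigmoid"

    def __init__(self):
        self._out = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, train=False, rng=None):
        # numerically stable for both signs
        xx = np.asarray(x, dtype=np.float64)
        out = np.empty_like(xx)
        pos = xx >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-xx[pos]))
        ex = np.exp(xx[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


@dataclass
class ActivationTrace:
    """Recorded per-layer input/output activations of one forward pass."""

    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    logit: float = 0.0
    score: float = 0.0

    def __len__(self) -> int:
        return len(self.inputs)


class Network:
    """An ordered layer stack ending in dense(1) + sigmoid."""

    def __init__(self, layers: list, input_shape: tuple[int, int, int], meta: dict | None = None):
        self.layers = layers
        self.input_shape = tuple(int(s) for s in input_shape)
        self.meta = dict(meta or {})
        self.shape_walk()  # validate composition at construction

    @property
    def dtype(self):
        for layer in self.layers:
            if hasattr(layer, "W"):
                return layer.W.dtype
        return np.float64

    # ---- structure ----------------------------------------------------
    def shape_walk(self) -> list[tuple]:
        """Symbolically compose layer shapes from the input; raises if the
        stack is inconsistent or the pooling cascade exhausts a dimension."""
        shapes = [(1, *self.input_shape)]
        for layer in self.layers:
            shapes.append(layer.out_shape(shapes[-1]))
        if shapes[-1] != (1,):
            raise ValueError(f"network must end in a scalar score, got {shapes[-1]}")
        return shapes

    def conv_layers(self) -> list[Conv3D]:
        return [l for l in self.layers if isinstance(l, Conv3D)]

    def trainable(self) -> list:
        return [l for l in self.layers if hasattr(l, "params")]

    def zero_grad(self) -> None:
        for layer in self.trainable():
            for _, _, g in layer.params():
                g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.trainable():
            for _, w, _ in layer.params():
                out.append(w.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.trainable():
            for name, w, _ in layer.params():
                w[...] = weights[i]
                i += 1

    def copy(self) -> "Network":
        import copy as _copy

        return _copy.deepcopy(self)

    # ---- execution -----------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        record: bool = False,
    ) -> tuple[float, float, ActivationTrace | None]:
        """Run one volume through the stack.

        Returns ``(score, logit, trace)`` where ``score`` is the sigmoid
        output in (0,1) and ``logit`` the pre-sigmoid scalar.  With
        ``record=True`` every layer's input/output is kept in the trace.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.shape == self.input_shape:
            x = x[None]  # add channel axis
        if x.shape != (1, *self.input_shape):
            raise ValueError(f"expected input shape {self.input_shape}, got {x.shape}")
        trace = ActivationTrace() if record else None
        logit = None
        for layer in self.layers:
            out = layer.forward(x, train=train, rng=rng)
            if record:
                trace.inputs.append(x)
                trace.outputs.append(out)
            if layer.kind == "sigmoid":
                logit = float(np.asarray(x).reshape(-1)[0])
            x = out
        score = float(np.asarray(x).reshape(-1)[0])
        if logit is None:
            raise ValueError("network has no sigmoid output layer")
        if record:
            trace.logit, trace.score = logit, score
        return score, logit, trace

    def backward_logit(self, dlogit: float = 1.0) -> np.ndarray:
        """Backpropagate a gradient seed at the logit (pre-sigmoid) down to
        the input, using the caches of the most recent forward pass."""
        grad = np.array([dlogit], dtype=np.float64)
        for layer in reversed(self.layers):
            if layer.kind == "sigmoid":
                continue  # seed sits below the sigmoid
            grad = layer.backward(grad)
        return grad


def build_network(
    input_shape: tuple[int, int, int],
    filters: int = 64,
    kernel_size: int = 3,
    dropout_p: float = 0.3,
    pool_placement: str = "1-2-4-final",
    seed: int | np.random.Generator = 0,
    dtype=np.float64,
) -> Network:
    """Build the default 4-conv architecture.

    Four conv(filters, k^3)+ELU blocks with four max-pooling layers and
    dropout after each pool, then flatten, dense(1), sigmoid.  Two pooling
    placements are supported, reflecting two readings of "four max-pooling
    layers applied after the first, second and fourth ELU":

    * ``"1-2-4-final"`` (default): pools after conv1, conv2 and conv4, plus a
      final pool before flattening;
    * ``"every"``: one pool after each of the four convs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if pool_placement not in ("1-2-4-final", "every"):
        raise ValueError(f"unknown pool_placement {pool_placement!r}")
    pools_after = {0, 1, 3} if pool_placement == "1-2-4-final" else {0, 1, 2, 3}

    layers: list = []
    in_ch = 1
    for ci in range(4):
        conv = Conv3D(in_ch, filters, kernel_size)
        conv.init_weights(rng, dtype=dtype)
        layers.append(conv)
        layers.append(ELU())
        if ci in pools_after:
            layers.append(MaxPool3D())
            layers.append(Dropout(dropout_p))
        in_ch = filters
    if pool_placement == "1-2-4-final":
        layers.append(MaxPool3D())
        layers.append(Dropout(dropout_p))

    # Walk shapes to size the dense layer (raises if pooling exhausts a dim).
    shape = (1, *input_shape)
    for layer in layers:
        shape = layer.out_shape(shape)
    layers.append(Flatten())
    dense = Dense(int(np.prod(shape)), 1)
    dense.init_weights(rng, dtype=dtype)
    layers.append(dense)
    layers.append(Sigmoid())
    meta = dict(
        filters=filters,
        kernel_size=kernel_size,
        dropout_p=dropout_p,
        pool_placement=pool_placement,
    )
    return Network(layers, input_shape, meta=meta)


# ---- checkpointing -----------------------------------------------------


def save_network(net: Network, path: str) -> None:
    """Save a network as an .npz archive (layer list + weights + meta)."""
    arch = []
    arrays = {}
    for i, layer in enumerate(net.layers):
        entry: dict = {"kind": layer.kind}
        if isinstance(layer, Conv3D):
            entry.update(in_channels=layer.in_channels, out_channels=layer.out_channels, k=layer.k)
            arrays[f"W{i}"], arrays[f"b{i}"] = layer.W, layer.b
        elif isinstance(layer, Dense):
            entry.update(in_dim=layer.in_dim, out_dim=layer.out_dim)
            arrays[f"W{i}"], arrays[f"b{i}"] = layer.W, layer.b
        elif isinstance(layer, Dropout):
            entry.update(p=layer.p)
        arch.append(entry)
    header = json.dumps(
        {"arch": arch, "input_shape": list(net.input_shape), "meta": net.meta}
    )
    np.savez(path, _header=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_network(path: str) -> Network:
    with np.load(path) as data:
        header = json.loads(bytes(data["_header"]).decode())
        layers: list = []
        for i, entry in enumerate(header["arch"]):
            kind = entry["kind"]
            if kind == "conv3d":
                layer = Conv3D(entry["in_channels"], entry["out_channels"], entry["k"])
                layer.W, layer.b = data[f"W{i}"], data[f"b{i}"]
                layer.gW, layer.gb = np.zeros_like(layer.W), np.zeros_like(layer.b)
            elif kind == "dense":
                layer = Dense(entry["in_dim"], entry["out_dim"])
                layer.W, layer.b = data[f"W{i}"], data[f"b{i}"]
                layer.gW, layer.gb = np.zeros_like(layer.W), np.zeros_like(layer.b)
            elif kind == "elu":
                layer = ELU()
            elif kind == "maxpool3d":
                layer = MaxPool3D()
            elif kind == "dropout":
                layer = Dropout(entry["p"])
            elif kind == "flatten":
                layer = Flatten()
            elif kind == "sigmoid":
                layer = Sigmoid()
            else:
                raise ValueError(f"unknown layer kind {kind!r}")
            layers.append(layer)
        return Network(layers, tuple(header["input_shape"]), meta=header.get("meta"))
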