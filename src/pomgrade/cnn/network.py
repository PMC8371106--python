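"""Forward and reverse passes of the grading CNN, in plain NumPy.

Layout conventions
------------------
Activations are NHWC float64 tensors; convolution kernels are
(kh, kw, C_in, C_out); inputs are expected pre-scaled to [0, 1].

The forward pass is: SAME convolution -> ReLU -> (3x3, stride-2 max pool
with floor-halving) per conv stage, then rasterization (row-major flatten
of the last feature maps), two ReLU full-connection layers, and a softmax
over the class logits.

The reverse pass propagates errors layer by layer: through the softmax /
cross-entropy head (probs - onehot), through each full connection, through
the rasterization (a reshape), through pooling by routing each error to the
location that won the max, and through each convolution — where the input
error is the size-preserving correlation of the output error with the
spatially flipped, channel-transposed kernel, and the kernel gradient is the
correlation of the layer input with the output error.

Everything here is checked against central finite differences (see
``training.gradient_check``).
"""

from __future__ import annotations

import json
from typing import Dict, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .arch import ArchitectureSpec, LayerSpec, build_architecture, flattened_dim

Params = Dict[str, Dict[str, np.ndarray]]

CHECKPOINT_FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# primitive ops
# --------------------------------------------------------------------------

def conv2d_same(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray] = None
                ) -> np.ndarray:
    """Stride-1 SAME cross-correlation. x: NHWC, w: (kh, kw, Cin, Cout)."""
    n, h, wd, c = x.shape
    kh, kw, cin, cout = w.shape
    if c != cin:
        raise ValueError(f"channel mismatch: input {c}, kernel expects {cin}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # patches: (n, h, wd, c, kh, kw) -> flatten to rows of kh*kw*c
    patches = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = patches.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wd, kh * kw * c)
    out = cols @ w.reshape(kh * kw * cin, cout)
    if b is not None:
        out += b
    return out.reshape(n, h, wd, cout)


def conv2d_backward(x: np.ndarray, w: np.ndarray, dout: np.ndarray
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a stride-1 SAME cross-correlation.

    Returns (dx, dw, db). dx is the SAME cross-correlation of dout with the
    180°-rotated, channel-transposed kernel; dw correlates the padded input
    with dout.
    """
    n, h, wd, c = x.shape
    kh, kw, cin, cout = w.shape
    ph, pw = kh // 2, kw // 2
    # dx
    w_flip = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (kh, kw, cout, cin)
    dx = conv2d_same(dout, w_flip)
    # dw: correlate input patches with the output error
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    patches = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = patches.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wd, kh * kw * c)
    dw = (cols.T @ dout.reshape(n * h * wd, cout)).reshape(kh, kw, cin, cout)
    db = dout.sum(axis=(0, 1, 2))
    return dx, dw, db


def _pool_geometry(n: int) -> Tuple[int, int]:
    """(output size, right/bottom pad) for a 3x3 stride-2 floor-halving pool."""
    out = n // 2
    if out < 1:
        raise ValueError(f"spatial size {n} too small to pool")
    needed = 2 * (out - 1) + 3
    return out, max(0, needed - n)


def maxpool_floor_half(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """3x3, stride-2 max pool realizing n -> floor(n/2) per axis.

    The window grid starts at 0 with stride 2; the bottom/right edge is
    padded with -inf so exactly floor(n/2) windows fit. Returns (pooled,
    argmax) where argmax holds the flat 0..8 in-window index of the winner
    (needed to route errors backward).
    """
    n, h, w, c = x.shape
    oh, pad_h = _pool_geometry(h)
    ow, pad_w = _pool_geometry(w)
    xp = np.pad(x, ((0, 0), (0, pad_h), (0, pad_w), (0, 0)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))[:, ::2, ::2]
    win = win[:, :oh, :ow].reshape(n, oh, ow, c, 9)
    idx = win.argmax(axis=-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def maxpool_backward(dout: np.ndarray, idx: np.ndarray,
                     in_shape: Tuple[int, ...]) -> np.ndarray:
    """Scatter each pooled error back to the element that won the max."""
    n, h, w, c = in_shape
    oh, pad_h = _pool_geometry(h)
    ow, pad_w = _pool_geometry(w)
    hp, wp = h + pad_h, w + pad_w
    dxp = np.zeros((n, hp, wp, c))
    ni, oi, oj, ci = np.indices(idx.shape)
    ri = 2 * oi + idx // 3
    cj = 2 * oj + idx % 3
    np.add.at(dxp, (ni, ri, cj, ci), dout)
    return dxp[:, :h, :w]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

class Network:
    """The grading CNN: parameters plus forward / loss-gradient evaluation."""

    def __init__(self, arch: ArchitectureSpec, seed: int = 0,
                 params: Optional[Params] = None):
        arch.validate()
        self.arch = arch
        self.params: Params = params if params is not None else self._init_params(seed)
        self._check_shapes()

    # -- initialization ----------------------------------------------------
    def _init_params(self, seed: int) -> Params:
        rng = np.random.default_rng(seed)
        params: Params = {}
        c_in = self.arch.in_channels
        n_in = None
        for layer in self.arch.layers:
            if layer.op == "conv":
                kh, kw = layer.kernel
                fan_in = kh * kw * c_in
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                               size=(kh, kw, c_in, layer.n_out))
                c_in = layer.n_out
            else:
                if n_in is None:
                    n_in = flattened_dim(self.arch)
                w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, layer.n_out))
                n_in = layer.n_out
            params[layer.name] = {"W": w, "b": np.zeros(layer.n_out)}
        return params

    def _check_shapes(self) -> None:
        for layer in self.arch.layers:
            p = self.params[layer.name]
            if layer.op == "conv":
                kh, kw = layer.kernel
                if p["W"].shape[:2] != (kh, kw) or p["W"].shape[3] != layer.n_out:
                    raise ValueError(f"bad kernel shape for {layer.name}")
            if p["b"].shape != (layer.n_out,):
                raise ValueError(f"bad bias shape for {layer.name}")

    def n_parameters(self) -> int:
        return sum(p["W"].size + p["b"].size
                   for p in self.params.values())

    # -- forward -----------------------------------------------------------
    def _validate_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        s = self.arch.input_size
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (s, s, self.arch.in_channels):
            raise ValueError(
                f"expected input of shape (N, {s}, {s}, {self.arch.in_channels}),"
                f" got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, cache: Optional[list] = None) -> np.ndarray:
        """Class probabilities, one row per sample, each summing to 1."""
        a = self._validate_input(x)
        flattened = False
        for layer in self.arch.layers:
            p = self.params[layer.name]
            if layer.op == "conv":
                pre = conv2d_same(a, p["W"], p["b"])
                act = relu(pre)
                if layer.pool_after:
                    pooled, idx = maxpool_floor_half(act)
                else:
                    pooled, idx = act, None
                if cache is not None:
                    cache.append(dict(layer=layer, x=a, pre=pre, act=act, idx=idx))
                a = pooled
            else:
                if not flattened:
                    if cache is not None:
                        cache.append(dict(layer=None, shape=a.shape))
                    a = a.reshape(a.shape[0], -1)  # rasterization
                    flattened = True
                pre = a @ p["W"] + p["b"]
                out = relu(pre) if layer.op == "fc" else pre
                if cache is not None:
                    cache.append(dict(layer=layer, x=a, pre=pre))
                a = out
        return softmax(a)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class per sample; ties resolve to the lowest class index."""
        return self.forward(x).argmax(axis=1)

    # -- loss and gradients --------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, y: np.ndarray
                       ) -> Tuple[float, Dict[str, Dict[str, np.ndarray]], np.ndarray]:
        """Mean cross-entropy over the batch, its parameter gradients, probs."""
        y = np.asarray(y, dtype=np.int64)
        cache: list = []
        probs = self.forward(x, cache=cache)
        n = probs.shape[0]
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + eps)))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss")

        grads: Dict[str, Dict[str, np.ndarray]] = {}
        # softmax + cross-entropy head
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        for entry in reversed(cache):
            layer = entry["layer"]
            if layer is None:  # rasterization boundary: un-flatten the error
                delta = delta.reshape(entry["shape"])
                continue
            p = self.params[layer.name]
            if layer.op in ("fc", "softmax"):
                if layer.op == "fc":
                    delta = delta * (entry["pre"] > 0)
                grads[layer.name] = {"W": entry["x"].T @ delta,
                                     "b": delta.sum(axis=0)}
                delta = delta @ p["W"].T
            else:  # conv stage: un-pool, un-activate, un-convolve
                if entry["idx"] is not None:
                    delta = maxpool_backward(delta, entry["idx"],
                                             entry["act"].shape)
                delta = delta * (entry["pre"] > 0)
                dx, dw, db = conv2d_backward(entry["x"], p["W"], delta)
                grads[layer.name] = {"W": dw, "b": db}
                delta = dx
        return loss, grads, probs

    # -- checkpointing -------------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: parameters + architecture + format version."""
        arch_meta = dict(
            format_version=CHECKPOINT_FORMAT_VERSION,
            input_size=self.arch.input_size,
            in_channels=self.arch.in_channels,
            n_classes=self.arch.n_classes,
            layers=[
                dict(name=l.name, op=l.op, kernel=l.kernel, n_out=l.n_out,
                     stride=l.stride, pool_after=l.pool_after)
                for l in self.arch.layers
            ],
        )
        arrays = {}
        for name, p in self.params.items():
            arrays[f"{name}.W"] = p["W"]
            arrays[f"{name}.b"] = p["b"]
        with open(path, "wb") as fh:
            np.savez(fh, __meta__=np.frombuffer(
                json.dumps(arch_meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "Network":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint format {meta['format_version']}")
            layers = [
                LayerSpec(d["name"], d["op"],
                          tuple(d["kernel"]) if d["kernel"] else None,
                          d["n_out"], d["stride"], d["pool_after"])
                for d in meta["layers"]
            ]
            arch = ArchitectureSpec(input_size=meta["input_size"],
                                    in_channels=meta["in_channels"],
                                    n_classes=meta["n_classes"], layers=layers)
            params: Params = {}
            for layer in layers:
                params[layer.name] = {"W": data[f"{layer.name}.W"].copy(),
                                      "b": data[f"{layer.name}.b"].copy()}
        return cls(arch, params=params)


def default_network(input_size: int = 208, n_classes: int = 3, seed: int = 0
                    ) -> Network:
    return Network(build_architecture(input_size, n_classes), seed=seed)
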