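"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the segmentation network needs: 2-D
convolution ("same" padding, stride 1), 2x2 max pooling, nearest-neighbor
x2 upsampling, ReLU/sigmoid, elementwise add/multiply with broadcasting,
channel concatenation, dropout, and a fused weighted softmax cross-entropy.
Gradients are checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2",
    "upsample2",
    "relu",
    "sigmoid",
    "add",
    "mul",
    "concat",
    "dropout",
    "softmax_channels",
    "weighted_softmax_ce",
]


class Tensor:
    """A numpy array node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, data, parents=(), backward=None, requires_grad=False,
                 name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self.parents
        )
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def accumulate(self, g) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    def back(g):
        a.accumulate(_unbroadcast(g, a.shape))
        b.accumulate(_unbroadcast(g, b.shape))

    return Tensor(a.data + b.data, (a, b), back)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def back(g):
        a.accumulate(_unbroadcast(g * b.data, a.shape))
        b.accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(a.data * b.data, (a, b), back)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        x.accumulate(g * mask)

    return Tensor(x.data * mask, (x,), back)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -40, 40)))

    def back(g):
        x.accumulate(g * y * (1.0 - y))

    return Tensor(y, (x,), back)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' 2-D convolution (cross-correlation), stride 1, odd kernel."""
    n, c, h, wd = x.shape
    f, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {c2}")
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((n, f, h, wd), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            # (F,C) @ (N,C,H,W) contracted over C -> (F,N,H,W)
            out += np.tensordot(
                w.data[:, :, ki, kj], xp[:, :, ki:ki + h, kj:kj + wd],
                axes=([1], [1]),
            ).transpose(1, 0, 2, 3)
    if b is not None:
        out += b.data.reshape(1, f, 1, 1)

    def back(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for ki in range(kh):
                for kj in range(kw):
                    dw[:, :, ki, kj] = np.tensordot(
                        g, xp[:, :, ki:ki + h, kj:kj + wd],
                        axes=([0, 2, 3], [0, 2, 3]),
                    )
            w.accumulate(dw)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki:ki + h, kj:kj + wd] += np.tensordot(
                        g, w.data[:, :, ki, kj], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
            x.accumulate(dxp[:, :, ph:ph + h, pw:pw + wd])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, back)


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    onehot = np.eye(4, dtype=np.float32)[idx]

    def back(g):
        gr = (g[..., None] * onehot).reshape(n, c, h // 2, w // 2, 2, 2)
        gr = gr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x.accumulate(gr)

    return Tensor(out, (x,), back)


def upsample2(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def back(g):
        n, c, h, w = g.shape
        gr = g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
        x.accumulate(gr)

    return Tensor(out, (x,), back)


def concat(tensors, axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, gs in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(gs)

    return Tensor(data, tuple(tensors), back)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            train: bool = True) -> Tensor:
    if not train or rate <= 0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)

    def back(g):
        x.accumulate(g * keep)

    return Tensor(x.data * keep, (x,), back)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over axis 1 of a plain array."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_softmax_ce(logits: Tensor, target: np.ndarray,
                        class_weights: np.ndarray) -> Tensor:
    """Mean weighted cross-entropy between per-voxel class scores and
    integer targets: ``-mean_v w_{y_v} log p_{y_v}(v)``."""
    p = softmax_channels(logits.data.astype(np.float64))
    n, c, h, w = logits.shape
    t = np.asarray(target).astype(np.int64)
    wvox = np.asarray(class_weights, dtype=np.float64)[t]  # (N,H,W)
    onehot = np.moveaxis(np.eye(c, dtype=np.float64)[t], -1, 1)  # (N,C,H,W)
    pt = np.clip((p * onehot).sum(axis=1), 1e-12, None)
    nvox = n * h * w
    loss = -(wvox * np.log(pt)).sum() / nvox

    def back(g):
        grad = (p - onehot) * wvox[:, None, :, :] / nvox
        logits.accumulate((g * grad).astype(np.float32))

    return Tensor(np.float32(loss), (logits,), back)
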