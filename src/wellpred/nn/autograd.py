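"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the convolutional recurrent predictor
needs: elementwise arithmetic, sigmoid/tanh, channel concatenation, 2-D
"same" convolution (via im2col) and reductions.  Gradients propagate by
topological sort of the recorded graph, as in the classic define-by-run
autodiff pattern.

This is deliberately small and CPU-only; it is the substrate for the model,
not a general framework.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # ------------------------------------------------------------- algebra
    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data - other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.data.shape))
        out._backward = bw
        return out

    def __mul__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))
        out._backward = bw
        return out

    def mean_sq(self) -> "Tensor":
        """Mean of squared entries (building block for MSE losses)."""
        out = Tensor(np.mean(self.data ** 2), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * 2.0 * self.data / self.data.size)
        out._backward = bw
        return out

    # ------------------------------------------------------------ structure
    def slice_channels(self, start: int, stop: int) -> "Tensor":
        """Select channels [start:stop) of an (N, C, H, W) tensor."""
        out = Tensor(self.data[:, start:stop], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accum(full)
        out._backward = bw
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ------------------------------------------------------------- backward
    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from 19-step BPTT get deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    """Concatenate (N, C_i, H, W) tensors along the channel axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), _prev=tuple(tensors))
    sizes = [t.data.shape[1] for t in tensors]

    def bw(g):
        start = 0
        for t, c in zip(tensors, sizes):
            if t.requires_grad:
                t._accum(g[:, start:start + c])
            start += c
    out._backward = bw
    return out


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for same-size conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, k, k, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3]))
    return view.reshape(n, c * k * k, h * w)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """2-D cross-correlation with "same" zero padding.

    ``x``: (N, C_in, H, W); ``weight``: (C_out, C_in, k, k) with k odd;
    ``bias``: (C_out,) or None.  Output: (N, C_out, H, W).
    """
    n, c_in, h, w = x.data.shape
    c_out, c_in_w, k, k2 = weight.data.shape
    if c_in != c_in_w or k != k2 or k % 2 != 1:
        raise ValueError(f"conv2d shape mismatch: x {x.data.shape}, w {weight.data.shape}")
    pad = k // 2
    col = _im2col(x.data, k, pad)                       # (N, C*k*k, H*W)
    wmat = weight.data.reshape(c_out, c_in * k * k)
    out_data = np.einsum("oc,ncp->nop", wmat, col).reshape(n, c_out, h, w)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    prev = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, _prev=prev)

    def bw(g):
        gmat = g.reshape(n, c_out, h * w)
        if weight.requires_grad:
            dw = np.einsum("nop,ncp->oc", gmat, col).reshape(weight.data.shape)
            weight._accum(dw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = np.einsum("oc,nop->ncp", wmat, gmat)  # (N, C*k*k, H*W)
            dcol = dcol.reshape(n, c_in, k, k, h, w)
            dxp = np.zeros((n, c_in, h + 2 * pad, w + 2 * pad))
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + h, j:j + w] += dcol[:, :, i, j]
            x._accum(dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp)
    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}
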