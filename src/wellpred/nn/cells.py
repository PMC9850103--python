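"""Convolutional recurrent cells.

Two cell types are provided:

* :class:`STLSTMCell` — a spatiotemporal LSTM with dual memories: a
  per-layer temporal memory ``c`` carried across timesteps, and a spatial
  memory ``m`` that zigzags upward through the layer stack within a
  timestep and returns from the top layer to the bottom layer of the next
  timestep.  This is the cell family behind modern video-prediction
  recurrent networks.
* :class:`ConvGatedCell` — a plain convolutional LSTM (no spatial memory),
  kept as a simpler fallback.

Both operate on (N, C, H, W) feature maps with "same" convolutions.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat_channels, conv2d


def _init_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> Tensor:
    scale = 1.0 / np.sqrt(c_in * k * k)
    return Tensor(rng.normal(0.0, scale, (c_out, c_in, k, k)), requires_grad=True)


class STLSTMCell:
    """Dual-memory spatiotemporal LSTM cell.

    Gate equations (all convs are "same"-padded, ``*`` is convolution,
    ``.`` elementwise product)::

        g  = tanh(W_xg * x + W_hg * h)          # update, temporal branch
        i  = sigmoid(W_xi * x + W_hi * h)
        f  = sigmoid(W_xf * x + W_hf * h + b_f)
        c' = f . c + i . g
        g' = tanh(W_xg' * x + W_mg * m)         # update, spatial branch
        i' = sigmoid(W_xi' * x + W_mi * m)
        f' = sigmoid(W_xf' * x + W_mf * m + b_f)
        m' = f' . m + i' . g'
        o  = sigmoid(W_xo * x + W_ho * h + W_co * c' + W_mo * m')
        h' = o . tanh(W_11 * [c'; m'])          # 1x1 conv over concat

    The x-convolution is fused into one weight of 7*hidden output channels
    (chunks g,i,f,g',i',f',o), the h-convolution into 4*hidden (g,i,f,o)
    and the m-convolution into 3*hidden (g',i',f').
    """

    def __init__(self, in_channels: int, hidden: int, kernel: int,
                 rng: np.random.Generator, forget_bias: float = 1.0):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.in_channels, self.hidden, self.kernel = in_channels, hidden, kernel
        c = hidden
        self.w_x = _init_conv(rng, 7 * c, in_channels, kernel)
        self.b_x = Tensor(np.zeros(7 * c), requires_grad=True)
        # forget gates open at init so memories persist early in training
        self.b_x.data[2 * c:3 * c] = forget_bias
        self.b_x.data[5 * c:6 * c] = forget_bias
        self.w_h = _init_conv(rng, 4 * c, c, kernel)
        self.w_m = _init_conv(rng, 3 * c, c, kernel)
        self.w_co = _init_conv(rng, c, c, 1)
        self.w_mo = _init_conv(rng, c, c, 1)
        self.w_11 = _init_conv(rng, c, 2 * c, 1)

    def params(self) -> list[Tensor]:
        return [self.w_x, self.b_x, self.w_h, self.w_m, self.w_co, self.w_mo,
                self.w_11]

    def __call__(self, x: Tensor, h: Tensor, c: Tensor, m: Tensor
                 ) -> tuple[Tensor, Tensor, Tensor]:
        n = self.hidden
        if x.shape[2:] != h.shape[2:]:
            raise ValueError(f"spatial size mismatch: x {x.shape}, h {h.shape}")
        xs = conv2d(x, self.w_x, self.b_x)
        hs = conv2d(h, self.w_h)
        ms = conv2d(m, self.w_m)
        g = (xs.slice_channels(0, n) + hs.slice_channels(0, n)).tanh()
        i = (xs.slice_channels(n, 2 * n) + hs.slice_channels(n, 2 * n)).sigmoid()
        f = (xs.slice_channels(2 * n, 3 * n) + hs.slice_channels(2 * n, 3 * n)).sigmoid()
        c_new = f * c + i * g
        g2 = (xs.slice_channels(3 * n, 4 * n) + ms.slice_channels(0, n)).tanh()
        i2 = (xs.slice_channels(4 * n, 5 * n) + ms.slice_channels(n, 2 * n)).sigmoid()
        f2 = (xs.slice_channels(5 * n, 6 * n) + ms.slice_channels(2 * n, 3 * n)).sigmoid()
        m_new = f2 * m + i2 * g2
        o = (xs.slice_channels(6 * n, 7 * n) + hs.slice_channels(3 * n, 4 * n)
             + conv2d(c_new, self.w_co) + conv2d(m_new, self.w_mo)).sigmoid()
        h_new = o * conv2d(concat_channels([c_new, m_new]), self.w_11).tanh()
        return h_new, c_new, m_new


class ConvGatedCell:
    """Plain convolutional LSTM: gates from conv(x) + conv(h), single memory.

    Accepts and passes through ``m`` untouched so both cell types share the
    layer-stack plumbing.
    """

    def __init__(self, in_channels: int, hidden: int, kernel: int,
                 rng: np.random.Generator, forget_bias: float = 1.0):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.in_channels, self.hidden, self.kernel = in_channels, hidden, kernel
        c = hidden
        self.w_x = _init_conv(rng, 4 * c, in_channels, kernel)
        self.b_x = Tensor(np.zeros(4 * c), requires_grad=True)
        self.b_x.data[2 * c:3 * c] = forget_bias
        self.w_h = _init_conv(rng, 4 * c, c, kernel)

    def params(self) -> list[Tensor]:
        return [self.w_x, self.b_x, self.w_h]

    def __call__(self, x: Tensor, h: Tensor, c: Tensor, m: Tensor
                 ) -> tuple[Tensor, Tensor, Tensor]:
        n = self.hidden
        xs = conv2d(x, self.w_x, self.b_x)
        hs = conv2d(h, self.w_h)
        g = (xs.slice_channels(0, n) + hs.slice_channels(0, n)).tanh()
        i = (xs.slice_channels(n, 2 * n) + hs.slice_channels(n, 2 * n)).sigmoid()
        f = (xs.slice_channels(2 * n, 3 * n) + hs.slice_channels(2 * n, 3 * n)).sigmoid()
        c_new = f * c + i * g
        o = (xs.slice_channels(3 * n, 4 * n) + hs.slice_channels(3 * n, 4 * n)).sigmoid()
        h_new = o * c_new.tanh()
        return h_new, c_new, m
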