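"""A compact NumPy neural-network engine with reverse-mode gradients.

The package trains its classifiers on CPU with float32 tensors.  Layers
implement explicit ``forward``/``backward`` passes; image-style layers use
NHWC layout and im2col-based convolutions, sequence layers use (N, T, D).
Supported building blocks cover what the architectures in
:mod:`smireg.models` need: dense, 2-D/depthwise/1-D convolutions, max
pooling, batch normalization, residual connections, LSTM and
convolutional-LSTM recurrences, bidirectional wrappers, and channel /
spatial attention.  Optimization is Adam on softmax cross-entropy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


def _uniform(rng: np.random.Generator, shape, bound: float) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


# ---------------------------------------------------------------------------
# basic layers


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = float(np.sqrt(1.0 / d_in))
        self.w = Param(_uniform(rng, (d_in, d_out), bound))
        self.b = Param(np.zeros(d_out, dtype=DTYPE))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class GELU(Layer):
    """tanh-approximated Gaussian error linear unit."""

    _C = DTYPE(np.sqrt(2.0 / np.pi))

    def forward(self, x, train=False):
        self._x = x
        inner = self._C * (x + DTYPE(0.044715) * x**3)
        self._t = np.tanh(inner)
        return DTYPE(0.5) * x * (1 + self._t)

    def backward(self, grad):
        x, t = self._x, self._t
        dinner = self._C * (1 + 3 * DTYPE(0.044715) * x**2)
        dy = DTYPE(0.5) * (1 + t) + DTYPE(0.5) * x * (1 - t**2) * dinner
        return grad * dy


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out


# ---------------------------------------------------------------------------
# convolutions (NHWC)


def _same_padding(size: int, k: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad) -> tuple[np.ndarray, tuple]:
    """Extract conv patches: returns (N, OH, OW, kh, kw, C) and pad used."""
    n, h, w, c = x.shape
    if pad == "same":
        ph = _same_padding(h, kh, stride)
        pw = _same_padding(w, kw, stride)
    else:
        ph = pw = (int(pad), int(pad))
    xp = np.pad(x, ((0, 0), ph, pw, (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N, H', W', C, kh, kw)
    win = win[:, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols, (ph, pw, xp.shape)


def _col2im(gcols: np.ndarray, pads, stride: int, in_shape) -> np.ndarray:
    """Scatter patch gradients back to the input tensor."""
    ph, pw, padded_shape = pads
    n, h, w, c = in_shape
    _, oh, ow, kh, kw, _ = gcols.shape
    gxp = np.zeros(padded_shape, dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            gxp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += gcols[
                :, :, :, i, j, :
            ]
    return gxp[:, ph[0] : ph[0] + h, pw[0] : pw[0] + w, :]


class Conv2D(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad="same"):
        self.k, self.stride, self.pad = k, stride, pad
        bound = float(np.sqrt(1.0 / (k * k * c_in)))
        self.w = Param(_uniform(rng, (k * k * c_in, c_out), bound))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))

    def forward(self, x, train=False):
        self._in_shape = x.shape
        cols, self._pads = _im2col(x, self.k, self.k, self.stride, self.pad)
        n, oh, ow = cols.shape[:3]
        self._cols = cols.reshape(n * oh * ow, -1)
        out = self._cols @ self.w.value + self.b.value
        return out.reshape(n, oh, ow, -1)

    def backward(self, grad):
        n, oh, ow, c_out = grad.shape
        g2 = grad.reshape(n * oh * ow, c_out)
        self.w.grad = self._cols.T @ g2
        self.b.grad = g2.sum(axis=0)
        gcols = (g2 @ self.w.value.T).reshape(n, oh, ow, self.k, self.k, -1)
        return _col2im(gcols, self._pads, self.stride, self._in_shape)

    def params(self):
        return [self.w, self.b]


class DepthwiseConv2D(Layer):
    """Per-channel spatial convolution with an optional depth multiplier."""

    def __init__(self, c_in: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad="same", depth_multiplier: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.dm = c_in, depth_multiplier
        bound = float(np.sqrt(1.0 / (k * k)))
        self.w = Param(_uniform(rng, (k, k, c_in, depth_multiplier), bound))
        self.b = Param(np.zeros(c_in * depth_multiplier, dtype=DTYPE))

    def forward(self, x, train=False):
        self._in_shape = x.shape
        cols, self._pads = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._cols = cols  # (N, OH, OW, k, k, C)
        out = np.einsum("nhwijc,ijcm->nhwcm", cols, self.w.value)
        n, oh, ow = out.shape[:3]
        out = out.reshape(n, oh, ow, self.c_in * self.dm)
        return out + self.b.value

    def backward(self, grad):
        n, oh, ow, _ = grad.shape
        g = grad.reshape(n, oh, ow, self.c_in, self.dm)
        self.w.grad = np.einsum("nhwijc,nhwcm->ijcm", self._cols, g)
        self.b.grad = grad.sum(axis=(0, 1, 2))
        gcols = np.einsum("nhwcm,ijcm->nhwijc", g, self.w.value)
        return _col2im(gcols, self._pads, self.stride, self._in_shape)

    def params(self):
        return [self.w, self.b]


class MaxPool2D(Layer):
    """Non-overlapping valid max pooling (step = pool size)."""

    def __init__(self, pool: int = 2):
        self.p = pool

    def forward(self, x, train=False):
        p = self.p
        n, h, w, c = x.shape
        self._in_shape = x.shape
        oh, ow = h // p, w // p
        win = sliding_window_view(x, (p, p), axis=(1, 2))[:, ::p, ::p]
        win = win.reshape(n, oh, ow, c, p * p)
        self._arg = win.argmax(axis=4)
        return np.ascontiguousarray(win.max(axis=4))

    def backward(self, grad):
        p = self.p
        n, h, w, c = self._in_shape
        oh, ow = h // p, w // p
        gwin = np.zeros((n, oh, ow, c, p * p), dtype=DTYPE)
        np.put_along_axis(gwin, self._arg[..., None], grad[..., None], axis=4)
        gwin = gwin.reshape(n, oh, ow, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        gx = np.zeros(self._in_shape, dtype=DTYPE)
        gx[:, : oh * p, : ow * p, :] = gwin.reshape(n, oh * p, ow * p, c)
        return gx


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._in_shape).astype(DTYPE)


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=DTYPE))
        self.beta = Param(np.zeros(c, dtype=DTYPE))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c, dtype=DTYPE)
        self.run_var = np.ones(c, dtype=DTYPE)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE)
        self._xhat = ((x - mean) * self._istd).astype(DTYPE)
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        axes = self._axes
        self.gamma.grad = (grad * self._xhat).sum(axis=axes)
        self.beta.grad = grad.sum(axis=axes)
        if not self._train:
            return grad * self.gamma.value * self._istd
        m = self._m
        gxhat = grad * self.gamma.value
        term = gxhat - gxhat.mean(axis=axes) - self._xhat * (gxhat * self._xhat).mean(axis=axes)
        return (term * self._istd).astype(DTYPE)

    def params(self):
        return [self.gamma, self.beta]


class Residual(Layer):
    """y = activation(body(x) + shortcut(x)); identity shortcut by default."""

    def __init__(self, body: Layer, shortcut: Layer | None = None, post_relu: bool = True):
        self.body = body
        self.shortcut = shortcut
        self.post_relu = post_relu

    def forward(self, x, train=False):
        y = self.body.forward(x, train)
        s = self.shortcut.forward(x, train) if self.shortcut is not None else x
        out = y + s
        if self.post_relu:
            self._mask = out > 0
            out = np.where(self._mask, out, 0)
        return out

    def backward(self, grad):
        if self.post_relu:
            grad = np.where(self._mask, grad, 0)
        gb = self.body.backward(grad)
        gs = self.shortcut.backward(grad) if self.shortcut is not None else grad
        return gb + gs

    def params(self):
        out = self.body.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out


# ---------------------------------------------------------------------------
# attention (channel + spatial, CBAM-style)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class ChannelAttention(Layer):
    """Scale channels by a gate from pooled descriptors through a shared MLP."""

    def __init__(self, c: int, rng: np.random.Generator, reduction: int = 4):
        hidden = max(c // reduction, 1)
        b1 = float(np.sqrt(1.0 / c))
        b2 = float(np.sqrt(1.0 / hidden))
        self.w1 = Param(_uniform(rng, (c, hidden), b1))
        self.w2 = Param(_uniform(rng, (hidden, c), b2))

    def _mlp(self, s):
        h = s @ self.w1.value
        hr = np.where(h > 0, h, 0)
        return h, hr, hr @ self.w2.value

    def forward(self, x, train=False):
        self._x = x
        n, h, w, c = x.shape
        self._hw = h * w
        flat = x.reshape(n, h * w, c)
        self._s_avg = flat.mean(axis=1)
        self._arg = flat.argmax(axis=1)  # (N, C)
        s_max = np.take_along_axis(flat, self._arg[:, None, :], axis=1)[:, 0, :]
        self._h_a, self._hr_a, z_a = self._mlp(self._s_avg)
        self._h_m, self._hr_m, z_m = self._mlp(s_max)
        self._a = _sigmoid(z_a + z_m).astype(DTYPE)
        return x * self._a[:, None, None, :]

    def backward(self, grad):
        x, a = self._x, self._a
        n, h, w, c = x.shape
        gx = grad * a[:, None, None, :]
        ga = (grad * x).sum(axis=(1, 2))
        gz = ga * a * (1 - a)
        # shared-MLP backward for both descriptor paths
        self.w1.grad = np.zeros_like(self.w1.value)
        self.w2.grad = np.zeros_like(self.w2.value)
        gs = []
        for h_pre, hr, s in (
            (self._h_a, self._hr_a, self._s_avg),
            (self._h_m, self._hr_m, None),
        ):
            self.w2.grad += hr.T @ gz
            ghr = gz @ self.w2.value.T
            gh = np.where(h_pre > 0, ghr, 0)
            src = s if s is not None else np.take_along_axis(
                x.reshape(n, h * w, c), self._arg[:, None, :], axis=1
            )[:, 0, :]
            self.w1.grad += src.T @ gh
            gs.append(gh @ self.w1.value.T)
        gs_avg, gs_max = gs
        gx += (gs_avg / self._hw)[:, None, None, :]
        gflat = np.zeros((n, h * w, c), dtype=DTYPE)
        np.put_along_axis(gflat, self._arg[:, None, :], gs_max[:, None, :], axis=1)
        return gx + gflat.reshape(n, h, w, c)

    def params(self):
        return [self.w1, self.w2]


class SpatialAttention(Layer):
    """Scale positions by a gate from channel mean/max maps through a conv."""

    def __init__(self, rng: np.random.Generator, k: int = 7):
        self.conv = Conv2D(2, 1, k, rng, stride=1, pad="same")

    def forward(self, x, train=False):
        self._x = x
        self._c = x.shape[-1]
        m_avg = x.mean(axis=3, keepdims=True)
        self._arg = x.argmax(axis=3)
        m_max = np.take_along_axis(x, self._arg[..., None], axis=3)
        z = self.conv.forward(np.concatenate([m_avg, m_max], axis=3), train)
        self._a = _sigmoid(z).astype(DTYPE)
        return x * self._a

    def backward(self, grad):
        x, a = self._x, self._a
        gx = grad * a
        gz = (grad * x).sum(axis=3, keepdims=True) * a * (1 - a)
        gm = self.conv.backward(gz)
        gx += gm[..., 0:1] / self._c
        gmax = np.zeros_like(x)
        np.put_along_axis(gmax, self._arg[..., None], gm[..., 1:2], axis=3)
        return gx + gmax

    def params(self):
        return self.conv.params()


# ---------------------------------------------------------------------------
# recurrent layers


class LSTM(Layer):
    """Single-direction LSTM over (N, T, D) input."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.h = hidden
        self.return_sequences = return_sequences
        bound = float(np.sqrt(1.0 / hidden))
        self.w = Param(_uniform(rng, (d_in + hidden, 4 * hidden), bound))
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias starts open
        self.b = Param(b)

    def forward(self, x, train=False):
        n, t, d = x.shape
        hdim = self.h
        self._x = x
        h = np.zeros((n, hdim), dtype=DTYPE)
        c = np.zeros((n, hdim), dtype=DTYPE)
        self._cache = []
        outs = np.empty((n, t, hdim), dtype=DTYPE)
        for step in range(t):
            xt = x[:, step, :]
            z = np.concatenate([xt, h], axis=1)
            gates = z @ self.w.value + self.b.value
            i = _sigmoid(gates[:, :hdim])
            f = _sigmoid(gates[:, hdim : 2 * hdim])
            g = np.tanh(gates[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(gates[:, 3 * hdim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((z, i, f, g, o, c, tc))
            h, c = h_new, c_new
            outs[:, step, :] = h
        self._outs = outs
        return outs if self.return_sequences else outs[:, -1, :]

    def backward(self, grad):
        n, t, d = self._x.shape
        hdim = self.h
        if self.return_sequences:
            gseq = grad
        else:
            gseq = np.zeros((n, t, hdim), dtype=DTYPE)
            gseq[:, -1, :] = grad
        self.w.grad = np.zeros_like(self.w.value)
        self.b.grad = np.zeros_like(self.b.value)
        gx = np.empty_like(self._x)
        gh_next = np.zeros((n, hdim), dtype=DTYPE)
        gc_next = np.zeros((n, hdim), dtype=DTYPE)
        for step in reversed(range(t)):
            z, i, f, g, o, c_prev, tc = self._cache[step]
            gh = gseq[:, step, :] + gh_next
            go = gh * tc
            gc = gc_next + gh * o * (1 - tc**2)
            gi = gc * g
            gf = gc * c_prev
            gg = gc * i
            ggates = np.concatenate(
                [gi * i * (1 - i), gf * f * (1 - f), gg * (1 - g**2), go * o * (1 - o)],
                axis=1,
            ).astype(DTYPE)
            self.w.grad += z.T @ ggates
            self.b.grad += ggates.sum(axis=0)
            gz = ggates @ self.w.value.T
            gx[:, step, :] = gz[:, :d]
            gh_next = gz[:, d:]
            gc_next = gc * f
        return gx

    def params(self):
        return [self.w, self.b]


class Bidirectional(Layer):
    """Run one LSTM forward and one on the time-reversed input.

    Output features are the concatenation of both directions; with
    ``return_sequences=False`` each direction contributes its final state.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.return_sequences = return_sequences
        self.fwd = LSTM(d_in, hidden, rng, return_sequences=return_sequences)
        self.bwd = LSTM(d_in, hidden, rng, return_sequences=return_sequences)

    def forward(self, x, train=False):
        yf = self.fwd.forward(x, train)
        yb = self.bwd.forward(x[:, ::-1, :], train)
        if self.return_sequences:
            yb = yb[:, ::-1, :]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, grad):
        hdim = self.fwd.h
        gf, gb = grad[..., :hdim], grad[..., hdim:]
        if self.return_sequences:
            gb = gb[:, ::-1, :]
        gxf = self.fwd.backward(np.ascontiguousarray(gf))
        gxb = self.bwd.backward(np.ascontiguousarray(gb))
        return gxf + gxb[:, ::-1, :]

    def params(self):
        return self.fwd.params() + self.bwd.params()


def _conv1d_cols(x: np.ndarray, k: int) -> np.ndarray:
    """(N, W, C) -> (N, W, k*C) same-padded width-wise patches."""
    pl, pr = _same_padding(x.shape[1], k, 1)
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    win = sliding_window_view(xp, k, axis=1)  # (N, W, C, k)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1], k * x.shape[2]
    )


def _conv1d_cols_backward(gcols: np.ndarray, k: int, w: int, c: int) -> np.ndarray:
    n = gcols.shape[0]
    pl, pr = _same_padding(w, k, 1)
    g = gcols.reshape(n, w, k, c)
    gxp = np.zeros((n, w + pl + pr, c), dtype=DTYPE)
    for i in range(k):
        gxp[:, i : i + w, :] += g[:, :, i, :]
    return gxp[:, pl : pl + w, :]


class ConvLSTM1D(Layer):
    """Convolutional LSTM scanning the rows of a 2-D feature map.

    Input is (N, T, W, C): T timesteps (matrix rows), each a width-W
    feature strip.  Gate pre-activations are 1-D convolutions (kernel k)
    over the concatenated input strip and hidden strip.  Returns the full
    hidden sequence (N, T, W, F).
    """

    def __init__(self, c_in: int, filters: int, rng: np.random.Generator, k: int = 3):
        self.f, self.k, self.c_in = filters, k, c_in
        bound = float(np.sqrt(1.0 / (k * (c_in + filters))))
        self.w = Param(_uniform(rng, (k * (c_in + filters), 4 * filters), bound))
        b = np.zeros(4 * filters, dtype=DTYPE)
        b[filters : 2 * filters] = 1.0  # forget-gate bias starts open
        self.b = Param(b)

    def forward(self, x, train=False):
        n, t, w, c = x.shape
        f, k = self.f, self.k
        self._in_shape = x.shape
        h = np.zeros((n, w, f), dtype=DTYPE)
        cst = np.zeros((n, w, f), dtype=DTYPE)
        self._cache = []
        outs = np.empty((n, t, w, f), dtype=DTYPE)
        for step in range(t):
            z = np.concatenate([x[:, step], h], axis=2)  # (N, W, C+F)
            cols = _conv1d_cols(z, k)  # (N, W, k*(C+F))
            gates = cols @ self.w.value + self.b.value  # (N, W, 4F)
            i = _sigmoid(gates[..., :f])
            fg = _sigmoid(gates[..., f : 2 * f])
            g = np.tanh(gates[..., 2 * f : 3 * f])
            o = _sigmoid(gates[..., 3 * f :])
            c_new = fg * cst + i * g
            tc = np.tanh(c_new)
            self._cache.append((cols, i, fg, g, o, cst, tc))
            h = o * tc
            cst = c_new
            outs[:, step] = h
        return outs

    def backward(self, grad):
        n, t, w, c = self._in_shape
        f, k = self.f, self.k
        self.w.grad = np.zeros_like(self.w.value)
        self.b.grad = np.zeros_like(self.b.value)
        gx = np.empty(self._in_shape, dtype=DTYPE)
        gh_next = np.zeros((n, w, f), dtype=DTYPE)
        gc_next = np.zeros((n, w, f), dtype=DTYPE)
        for step in reversed(range(t)):
            cols, i, fg, g, o, c_prev, tc = self._cache[step]
            gh = grad[:, step] + gh_next
            go = gh * tc
            gc = gc_next + gh * o * (1 - tc**2)
            gi = gc * g
            gf = gc * c_prev
            gg = gc * i
            ggates = np.concatenate(
                [gi * i * (1 - i), gf * fg * (1 - fg), gg * (1 - g**2), go * o * (1 - o)],
                axis=2,
            ).astype(DTYPE)
            flat = ggates.reshape(n * w, 4 * f)
            self.w.grad += cols.reshape(n * w, -1).T @ flat
            self.b.grad += flat.sum(axis=0)
            gcols = (flat @ self.w.value.T).reshape(n, w, -1)
            gz = _conv1d_cols_backward(gcols, k, w, c + f)
            gx[:, step] = gz[..., :c]
            gh_next = gz[..., c:]
            gc_next = gc * fg
        return gx

    def params(self):
        return [self.w, self.b]


class TimeMajorPool(Layer):
    """2x2 max pooling of a (N, T, W, C) sequence over the (T, W) plane."""

    def __init__(self, pool: int = 2):
        self._pool = MaxPool2D(pool)

    def forward(self, x, train=False):
        return self._pool.forward(x, train)

    def backward(self, grad):
        return self._pool.backward(grad)


class LastStep(Layer):
    """Take the final timestep of a (N, T, D) sequence."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, grad):
        g = np.zeros(self._shape, dtype=DTYPE)
        g[:, -1, :] = grad
        return g


class AddChannel(Layer):
    """(N, H, W) -> (N, H, W, 1)."""

    def forward(self, x, train=False):
        return x[..., None]

    def backward(self, grad):
        return grad[..., 0]


# ---------------------------------------------------------------------------
# module traversal (for checkpointing non-parameter state)


def iter_modules(layer: Layer):
    """Yield a layer and, recursively, every layer nested inside it."""
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_modules(sub)
    elif isinstance(layer, Residual):
        yield from iter_modules(layer.body)
        if layer.shortcut is not None:
            yield from iter_modules(layer.shortcut)
    elif isinstance(layer, Bidirectional):
        yield from iter_modules(layer.fwd)
        yield from iter_modules(layer.bwd)
    elif isinstance(layer, SpatialAttention):
        yield from iter_modules(layer.conv)
    elif isinstance(layer, TimeMajorPool):
        yield from iter_modules(layer._pool)


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    grad = p
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.value -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(DTYPE)
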