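"""Minimal reverse-mode neural-network layers on NumPy + numba.

Everything operates on single samples shaped ``(channels, slice, row, col)``
-- batch size one is the training regime used throughout the package, so the
layers avoid a batch axis entirely and batching is handled by gradient
accumulation in the training loop.  Each layer caches what its backward pass
needs during ``forward(..., training=True)``; ``backward`` consumes the cache
and *accumulates* into ``Parameter.grad``.

Convolutions run as numba-compiled direct loops.  The working set of a
single-sample 3D convolution at these widths fits in cache, so a direct
row-accumulating loop beats an im2col+GEMM formulation, whose column buffer
multiplies the traffic by the kernel volume.  Strided convolutions are first
parity-decomposed (the input is split into its stride-phase sub-grids) so
the innermost in-plane loop is always unit-stride and vectorizes.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
from numba import njit

__all__ = [
    "Adam",
    "AdaptiveAvgPool3d",
    "BatchNorm3d",
    "Conv3d",
    "Dropout",
    "Linear",
    "Module",
    "Parameter",
    "ReLU",
    "ShapeError",
]


class ShapeError(ValueError):
    """A feature map would become empty along some axis."""


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class with explicit child/parameter registration."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    # -- registration ------------------------------------------------------
    def add_param(self, name: str, value: np.ndarray) -> Parameter:
        p = Parameter(value)
        self._params[name] = p
        return p

    def add_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = value
        return value

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._children.items():
            yield from m.named_parameters(f"{prefix}{n}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n, b in self._buffers.items():
            yield prefix + n, b
        for n, m in self._children.items():
            yield from m.named_buffers(f"{prefix}{n}.")

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for n, m in self._children.items():
            yield from m.named_modules(f"{prefix}.{n}" if prefix else n)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 tuple, got {v!r}")
    return t


@njit(cache=True)
def _parity_split(xp, sh, sw):
    """Split the padded input into its (row, col) stride-phase sub-grids, so
    strided kernels can read unit-stride rows."""
    ci, d, h, w = xp.shape
    hh = (h + sh - 1) // sh
    wh = (w + sw - 1) // sw + 1  # +1 slack so base[x + cc//sw] stays in range
    xpp = np.zeros((sh * sw, ci, d, hh, wh), dtype=xp.dtype)
    for i in range(ci):
        for z in range(d):
            for yo in range(h):
                p = (yo % sh) * sw
                hy = yo // sh
                for xo in range(w):
                    xpp[p + xo % sw, i, z, hy, xo // sw] = xp[i, z, yo, xo]
    return xpp


@njit(cache=True)
def _parity_merge(dxpp, sh, sw, d, h, w):
    ci = dxpp.shape[1]
    dxp = np.empty((ci, d, h, w), dtype=dxpp.dtype)
    for i in range(ci):
        for z in range(d):
            for yo in range(h):
                p = (yo % sh) * sw
                hy = yo // sh
                for xo in range(w):
                    dxp[i, z, yo, xo] = dxpp[p + xo % sw, i, z, hy, xo // sw]
    return dxp


@njit(cache=True, fastmath=True)
def _conv_fwd(xpp, w, sd, sh, sw, od, oh, ow):
    co, ci, kd, kh, kw = w.shape
    y = np.empty((co, od, oh, ow), dtype=xpp.dtype)
    acc = np.empty(ow, dtype=xpp.dtype)
    plain = (sh == 1) and (sw == 1)
    for c in range(co):
        for z in range(od):
            zi0 = z * sd
            for yy in range(oh):
                acc[:] = 0.0
                for i in range(ci):
                    for a in range(kd):
                        for b in range(kh):
                            if plain:
                                base = xpp[0, i, zi0 + a, yy + b]
                                for cc in range(kw):
                                    wv = w[c, i, a, b, cc]
                                    for x in range(ow):
                                        acc[x] += wv * base[x + cc]
                            else:
                                pb = (b % sh) * sw
                                hy = yy + b // sh
                                for q in range(sw):
                                    base = xpp[pb + q, i, zi0 + a, hy]
                                    ncc = (kw - q + sw - 1) // sw
                                    for j in range(ncc):
                                        cc = q + j * sw
                                        wv = w[c, i, a, b, cc]
                                        x0 = cc // sw
                                        for x in range(ow):
                                            acc[x] += wv * base[x + x0]
                y[c, z, yy, :] = acc
    return y


@njit(cache=True, fastmath=True)
def _conv_bwd(xpp, w, dy, sd, sh, sw, need_dx):
    co, ci, kd, kh, kw = w.shape
    _, od, oh, ow = dy.shape
    dw = np.zeros_like(w)
    dxpp = np.zeros_like(xpp) if need_dx else np.zeros((1, 1, 1, 1, 1), dtype=xpp.dtype)
    plain = (sh == 1) and (sw == 1)
    zero = dy[0, 0, 0, 0] * 0  # dtype-matched accumulator seed
    for c in range(co):
        for z in range(od):
            zi0 = z * sd
            for yy in range(oh):
                drow = dy[c, z, yy]
                for i in range(ci):
                    for a in range(kd):
                        for b in range(kh):
                            if plain:
                                base = xpp[0, i, zi0 + a, yy + b]
                                if need_dx:
                                    dbase = dxpp[0, i, zi0 + a, yy + b]
                                    for cc in range(kw):
                                        wv = w[c, i, a, b, cc]
                                        accw = zero
                                        for x in range(ow):
                                            dv = drow[x]
                                            accw += dv * base[x + cc]
                                            dbase[x + cc] += wv * dv
                                        dw[c, i, a, b, cc] += accw
                                else:
                                    for cc in range(kw):
                                        accw = zero
                                        for x in range(ow):
                                            accw += drow[x] * base[x + cc]
                                        dw[c, i, a, b, cc] += accw
                            else:
                                pb = (b % sh) * sw
                                hy = yy + b // sh
                                for q in range(sw):
                                    base = xpp[pb + q, i, zi0 + a, hy]
                                    ncc = (kw - q + sw - 1) // sw
                                    if need_dx:
                                        dbase = dxpp[pb + q, i, zi0 + a, hy]
                                        for j in range(ncc):
                                            cc = q + j * sw
                                            wv = w[c, i, a, b, cc]
                                            x0 = cc // sw
                                            accw = zero
                                            for x in range(ow):
                                                dv = drow[x]
                                                accw += dv * base[x + x0]
                                                dbase[x + x0] += wv * dv
                                            dw[c, i, a, b, cc] += accw
                                    else:
                                        for j in range(ncc):
                                            cc = q + j * sw
                                            x0 = cc // sw
                                            accw = zero
                                            for x in range(ow):
                                                accw += drow[x] * base[x + x0]
                                            dw[c, i, a, b, cc] += accw
    return dw, dxpp


class Conv3d(Module):
    """Bias-free 3D convolution with kernel/stride/padding in (slice,row,col) order.

    Degenerate kernel extents express the in-plane "2D" case (1,3,3) and the
    slice-axis "1D" case (3,1,1) used by the factorized architectures.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel,
        stride=(1, 1, 1),
        padding=(0, 0, 0),
        *,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.engine = "auto"  # "auto" | "direct" | "gemm"
        # He fan-out initialization: keeps forward variance stable under ReLU.
        fan_out = self.out_channels * int(np.prod(self.kernel))
        w = rng.normal(0.0, math.sqrt(2.0 / fan_out),
                       size=(self.out_channels, self.in_channels) + self.kernel)
        self.weight = self.add_param("weight", w.astype(dtype))

    def _out_dims(self, shape: tuple[int, ...]) -> tuple[int, int, int]:
        out = []
        for d, k, s, p in zip(shape, self.kernel, self.stride, self.padding):
            o = (d + 2 * p - k) // s + 1
            if o < 1:
                raise ShapeError(
                    f"input extent {d} too small for kernel {k} (stride {s}, padding {p})"
                )
            out.append(o)
        return tuple(out)  # type: ignore[return-value]

    def _offset_slices(self, out_dims):
        od, oh, ow = out_dims
        sd, sh, sw = self.stride
        kd, kh, kw = self.kernel
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    yield (
                        slice(None),
                        slice(a, a + sd * (od - 1) + 1, sd),
                        slice(b, b + sh * (oh - 1) + 1, sh),
                        slice(c, c + sw * (ow - 1) + 1, sw),
                    )

    def _weight_matrix(self) -> np.ndarray:
        k = int(np.prod(self.kernel))
        return np.ascontiguousarray(
            self.weight.value.reshape(self.out_channels, self.in_channels, k)
            .swapaxes(1, 2)
            .reshape(self.out_channels, k * self.in_channels)
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[0] != self.in_channels:
            raise ValueError(
                f"expected (C={self.in_channels}, slice, row, col) input, got {x.shape}"
            )
        od, oh, ow = self._out_dims(x.shape[1:])
        pd, ph, pw = self.padding
        sd, sh, sw = self.stride
        x = np.ascontiguousarray(x, dtype=self.weight.value.dtype)
        xp = np.pad(x, ((0, 0), (pd, pd), (ph, ph), (pw, pw))) if (pd or ph or pw) else x
        # wide in-plane rows vectorize in the direct loops; narrow deep maps
        # are better served by im2col + GEMM
        direct = ow >= 16 if self.engine == "auto" else self.engine == "direct"
        if direct:
            if sh == 1 and sw == 1:
                xpp = xp.reshape((1,) + xp.shape)
            else:
                xpp = _parity_split(xp, sh, sw)
            y = _conv_fwd(xpp, self.weight.value, sd, sh, sw, od, oh, ow)
            self._cache = ("direct", xpp, xp.shape, x.shape, (od, oh, ow))
            return y
        ci = self.in_channels
        k = int(np.prod(self.kernel))
        n = od * oh * ow
        cols5 = np.empty((k, ci, od, oh, ow), dtype=x.dtype)
        for o, sl in enumerate(self._offset_slices((od, oh, ow))):
            np.copyto(cols5[o], xp[sl])
        cols = cols5.reshape(k * ci, n)
        y = self._weight_matrix() @ cols
        self._cache = ("gemm", cols, xp.shape, x.shape, (od, oh, ow))
        return y.reshape(self.out_channels, od, oh, ow)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        engine, stored, xpshape, xshape, (od, oh, ow) = self._cache
        pd, ph, pw = self.padding
        sd, sh, sw = self.stride
        dy = np.ascontiguousarray(dy, dtype=self.weight.value.dtype)
        if engine == "direct":
            dw, dxpp = _conv_bwd(stored, self.weight.value, dy, sd, sh, sw, need_dx)
            self.weight.grad += dw
            if not need_dx:
                return None
            if sh == 1 and sw == 1:
                dxp = dxpp[0]
            else:
                dxp = _parity_merge(dxpp, sh, sw, *xpshape[1:])
        else:
            cols = stored
            ci = self.in_channels
            k = int(np.prod(self.kernel))
            n = od * oh * ow
            dyf = dy.reshape(self.out_channels, n)
            dw = (dyf @ cols.T).reshape(self.out_channels, k, ci).swapaxes(1, 2)
            self.weight.grad += dw.reshape(self.weight.value.shape)
            if not need_dx:
                return None
            dcols = (self._weight_matrix().T @ dyf).reshape(k, ci, od, oh, ow)
            dxp = np.zeros(xpshape, dtype=dy.dtype)
            for o, sl in enumerate(self._offset_slices((od, oh, ow))):
                dxp[sl] += dcols[o]
        if pd or ph or pw:
            _, d, h, w = xshape
            return dxp[:, pd:pd + d, ph:ph + h, pw:pw + w]
        return dxp


class BatchNorm3d(Module):
    """Per-channel normalization over the spatial axes, affine.

    With batch size one the training-mode statistics are computed over
    (slice,row,col) of the single sample.  ``track_running_stats`` selects
    the evaluation-mode behaviour: with tracking, exponentially averaged
    running estimates are used (the classic large-batch convention); without
    it, per-sample statistics are used in evaluation as well -- the standard
    configuration for batch-size-one training, and still deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 track_running_stats: bool = True, dtype=np.float32):
        super().__init__()
        self.channels = int(channels)
        self.momentum = momentum
        self.eps = eps
        self.track_running_stats = track_running_stats
        self.gamma = self.add_param("weight", np.ones(channels, dtype=dtype))
        self.beta = self.add_param("bias", np.zeros(channels, dtype=dtype))
        self.running_mean = self.add_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.running_var = self.add_buffer("running_var", np.ones(channels, dtype=np.float64))
        self._cumulative_n: int | None = None

    def start_stat_refresh(self) -> None:
        """Reset running statistics and switch to cumulative averaging, so a
        sweep of training-mode forwards re-estimates them as plain means."""
        self.running_mean[...] = 0.0
        self.running_var[...] = 0.0
        self._cumulative_n = 0

    def finish_stat_refresh(self) -> None:
        self._cumulative_n = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        batch_stats = training or not self.track_running_stats
        if batch_stats:
            mu = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            if training and self.track_running_stats:
                n = x[0].size
                if self._cumulative_n is not None:
                    self._cumulative_n += 1
                    m = 1.0 / self._cumulative_n
                else:
                    m = self.momentum
                unbiased = var * (n / (n - 1)) if n > 1 else var
                self.running_mean[...] = (1 - m) * self.running_mean + m * mu
                self.running_var[...] = (1 - m) * self.running_var + m * unbiased
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None, None]) * ivar[:, None, None, None].astype(x.dtype)
        self._cache = (xhat, ivar.astype(x.dtype), batch_stats)
        return self.gamma.value[:, None, None, None] * xhat + self.beta.value[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, batch_stats = self._cache
        dgamma = (dy * xhat).sum(axis=(1, 2, 3))
        dbeta = dy.sum(axis=(1, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value
        scale = (g * ivar)[:, None, None, None]
        if not batch_stats:
            return scale * dy
        n = dy[0].size
        return scale / n * (n * dy - dbeta[:, None, None, None] - xhat * dgamma[:, None, None, None])


class ReLU(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class AdaptiveAvgPool3d(Module):
    """Global average pooling to 1x1x1, returned as a flat feature vector."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        n = d * h * w
        return np.broadcast_to(dy[:, None, None, None] / n, self._shape).astype(dy.dtype)


class Linear(Module):
    """Fully connected layer on a flat feature vector, with bias."""

    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.in_features = int(in_features)
        self.out_features = int(out_features)
        rng = rng if rng is not None else np.random.default_rng(0)
        bound = 1.0 / math.sqrt(in_features)
        self.weight = self.add_param(
            "weight", rng.uniform(-bound, bound, size=(out_features, in_features)).astype(dtype)
        )
        self.bias = self.add_param(
            "bias", rng.uniform(-bound, bound, size=out_features).astype(dtype)
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return self.weight.value @ x + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += np.outer(dy, self._x)
        self.bias.grad += dy
        return self.weight.value.T @ dy


class Adam:
    """Adam with L2-style weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-5, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
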