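"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical core behind the shape decoders, the autodecoder
training loop, latent fitting, and the ordinal classification head.  It
implements exactly the operations those components need — dense matmul,
broadcasting elementwise arithmetic, ReLU/tanh/sine/sigmoid, strided 2-D
transpose convolution, and bilinear reads from feature planes — together with
an AdamW optimizer with decoupled weight decay and per-group learning rates.

All tensors are float32.  Gradients are accumulated by a topological-order
backward sweep; graph nodes hold closures over their parents.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- graph machinery ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def _bw(g):
            if self.requires_grad:
                if self.data.ndim == 1:
                    self._accum(g @ other.data.T)
                else:
                    self._accum(g @ other.data.T)
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accum(np.outer(self.data, g))
                else:
                    other._accum(self.data.T @ g)

        out._backward = _bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = _bw
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.data.shape))

        out._backward = _bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- activations ------------------------------------------------------------
def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))

    out._backward = _bw
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * (1.0 - y * y))

    out._backward = _bw
    return out


def sin(x: Tensor) -> Tensor:
    out = Tensor(np.sin(x.data), x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * np.cos(x.data))

    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * y * (1.0 - y))

    out._backward = _bw
    return out


def abs_(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.data), x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * np.sign(x.data))

    out._backward = _bw
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with zero gradient outside [lo, hi]."""
    out = Tensor(np.clip(x.data, lo, hi), x.requires_grad, (x,))

    def _bw(g):
        if x.requires_grad:
            x._accum(g * ((x.data >= lo) & (x.data <= hi)))

    out._backward = _bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = _bw
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x @ w + b for x of shape (N, d_in) or (d_in,)."""
    return x @ w + b


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; apply only during training."""
    if p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(DTYPE) / (1.0 - p)
    return x * Tensor(mask)


# -- 2-D transpose convolution ----------------------------------------------
def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor, stride: int = 2, padding: int = 1
) -> Tensor:
    """Strided transpose convolution.

    x: (C_in, H, W); w: (C_in, C_out, k, k); b: (C_out,).
    Output spatial size = (H - 1) * stride - 2 * padding + k.
    With k=4, stride=2, padding=1 this exactly doubles H and W.
    """
    cin, H, W = x.data.shape
    _, cout, k, _ = w.data.shape
    s = stride
    big_h = (H - 1) * s + k
    big_w = (W - 1) * s + k
    out_big = np.zeros((cout, big_h, big_w), dtype=DTYPE)
    for ki in range(k):
        for li in range(k):
            # out_big[o, i*s+ki, j*s+li] += sum_c x[c,i,j] w[c,o,ki,li]
            out_big[:, ki : ki + s * (H - 1) + 1 : s, li : li + s * (W - 1) + 1 : s] += np.einsum(
                "co,chw->ohw", w.data[:, :, ki, li], x.data, optimize=True
            )
    out_h = big_h - 2 * padding
    out_w = big_w - 2 * padding
    y = out_big[:, padding : padding + out_h, padding : padding + out_w]
    y = y + b.data[:, None, None]
    out = Tensor(y, x.requires_grad or w.requires_grad or b.requires_grad, (x, w, b))

    def _bw(g):
        g_big = np.zeros((cout, big_h, big_w), dtype=DTYPE)
        g_big[:, padding : padding + out_h, padding : padding + out_w] = g
        if b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        gx = np.zeros((cin, H, W), dtype=DTYPE) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for ki in range(k):
            for li in range(k):
                sl = g_big[:, ki : ki + s * (H - 1) + 1 : s, li : li + s * (W - 1) + 1 : s]
                if gx is not None:
                    gx += np.einsum("co,ohw->chw", w.data[:, :, ki, li], sl, optimize=True)
                if gw is not None:
                    gw[:, :, ki, li] = np.einsum("chw,ohw->co", x.data, sl, optimize=True)
        if gx is not None:
            x._accum(gx)
        if gw is not None:
            w._accum(gw)

    out._backward = _bw
    return out


# -- bilinear plane sampling --------------------------------------------------
def plane_bilinear(planes: Tensor, coords: np.ndarray) -> Tensor:
    """Read features from stacked 2-D planes by bilinear interpolation.

    planes: (P, F, R, R) feature planes on a corner-aligned [-1, 1]^2 grid
    (node 0 at -1, node R-1 at +1).  coords: (P, N, 2) in-plane coordinates
    (constant w.r.t. differentiation).  Returns (N, F): the per-plane reads
    summed over the P planes.
    """
    P, F, R, _ = planes.data.shape
    u = (np.clip(coords, -1.0, 1.0) + 1.0) * 0.5 * (R - 1)  # (P, N, 2)
    i0 = np.floor(u).astype(np.int64)
    i0 = np.clip(i0, 0, R - 2)
    frac = (u - i0).astype(DTYPE)
    i1 = i0 + 1
    fx, fy = frac[..., 0], frac[..., 1]  # coords order: (axis0, axis1) -> grid rows/cols
    w00 = (1 - fx) * (1 - fy)
    w01 = (1 - fx) * fy
    w10 = fx * (1 - fy)
    w11 = fx * fy
    pidx = np.arange(P)[:, None]
    d = planes.data
    vals = (
        d[pidx, :, i0[..., 0], i0[..., 1]] * w00[..., None]
        + d[pidx, :, i0[..., 0], i1[..., 1]] * w01[..., None]
        + d[pidx, :, i1[..., 0], i0[..., 1]] * w10[..., None]
        + d[pidx, :, i1[..., 0], i1[..., 1]] * w11[..., None]
    )  # (P, N, F)
    out = Tensor(vals.sum(axis=0), planes.requires_grad, (planes,))

    def _bw(g):
        if not planes.requires_grad:
            return
        gp = np.zeros_like(planes.data)
        gmov = np.transpose(gp, (0, 2, 3, 1))  # view (P, R, R, F)
        for w_, ia, ib in (
            (w00, i0[..., 0], i0[..., 1]),
            (w01, i0[..., 0], i1[..., 1]),
            (w10, i1[..., 0], i0[..., 1]),
            (w11, i1[..., 0], i1[..., 1]),
        ):
            contrib = g[None, :, :] * w_[..., None]  # (P, N, F)
            np.add.at(gmov, (pidx, ia, ib), contrib)
        planes._accum(gp)

    out._backward = _bw
    return out


# -- optimizer ----------------------------------------------------------------
class AdamW:
    """Adam with decoupled weight decay and per-group learning rates.

    `groups` is a list of dicts: {"params": [Tensor, ...], "lr": float,
    "weight_decay": float}.  Learning rates may be overridden per step, which
    is how the epoch-dependent schedules are applied.
    """

    def __init__(self, groups: Iterable[dict], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.groups = [dict(g) for g in groups]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for g in self.groups:
            g.setdefault("weight_decay", 0.0)
            for p in g["params"]:
                self._state[id(p)] = (
                    np.zeros_like(p.data),
                    np.zeros_like(p.data),
                )

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self, lr_overrides: Sequence[float] | None = None) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for gi, g in enumerate(self.groups):
            lr = g["lr"] if lr_overrides is None else lr_overrides[gi]
            wd = g["weight_decay"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                m, v = self._state[id(p)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad**2
                if wd:
                    p.data -= DTYPE(lr * wd) * p.data
                p.data -= DTYPE(lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


def glorot_init(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(DTYPE)


def siren_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...], first: bool) -> np.ndarray:
    """Initialization for sinusoidal layers.

    The first layer (which carries the frequency scale omega0) uses
    U(-1/fan_in, 1/fan_in); hidden layers, whose inputs are approximately
    arcsine-distributed sine outputs, use U(+-sqrt(6/fan_in)) so
    pre-activation variance stays near 1.
    """
    lim = 1.0 / fan_in if first else np.sqrt(6.0 / fan_in)
    return rng.uniform(-lim, lim, size=shape).astype(DTYPE)
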