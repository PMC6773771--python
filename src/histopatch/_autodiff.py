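"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its patch classifier with this engine rather than an
external deep-learning framework.  It implements exactly the operations the
network needs — 2-D convolution, max/average pooling, dense layers, channel
concatenation, elementwise nonlinearities, dropout and fused softmax
cross-entropy — in NHWC layout, with gradients accumulated through an
iterative topological sweep.

Convolutions are lowered to GEMMs via im2col over bounded batch chunks;
their backward pass combines per-offset tensordots (weight gradient) with a
GEMM plus scatter-add (input gradient).  Everything is single-threaded
numpy, so results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

DTYPE = np.float32

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextmanager
def precision(dtype):
    """Run ops under a different float dtype (e.g. float64 for analytic
    checks); existing parameters keep their storage dtype, arithmetic is
    upcast."""
    global DTYPE
    prev = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = prev


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_owned")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._grad_owned = False
        self._parents = tuple(parents) if _GRAD_ENABLED else ()
        self._backward = backward if _GRAD_ENABLED else None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None
        self._grad_owned = False

    def _accumulate(self, g):
        # First contribution is kept by reference; a second contribution
        # forces a private buffer so shared arrays are never mutated.
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self):
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo, seen, stack = [], set(), [(self, False)]
        while stack:  # iterative DFS: the full network is >150 nodes deep
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
        self.grad = np.ones_like(self.data)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _needs(*tensors):
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in tensors)


def _wrap(data, parents, backward, needs):
    if not needs:
        return Tensor(data)
    return Tensor(data, parents=parents, backward=backward)


# ---------------------------------------------------------------- primitives

def add(a: Tensor, b: Tensor) -> Tensor:
    needs = _needs(a, b)

    def bw(g):
        a._accumulate(g)
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _wrap(a.data + b.data, (a, b), bw, needs)


def _unbroadcast(g, shape):
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def mul_scalar(a: Tensor, c: float) -> Tensor:
    needs = _needs(a)

    def bw(g):
        a._accumulate(g * c)

    return _wrap(a.data * c, (a,), bw, needs)


def mul(a: Tensor, b: Tensor) -> Tensor:
    needs = _needs(a, b)

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _wrap(a.data * b.data, (a, b), bw, needs)


def relu(x: Tensor) -> Tensor:
    needs = _needs(x)
    out = np.maximum(x.data, 0)

    def bw(g):
        x._accumulate(g * (x.data > 0))

    return _wrap(out, (x,), bw, needs)


def sigmoid(x: Tensor) -> Tensor:
    needs = _needs(x)
    out = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * out * (1.0 - out))

    return _wrap(out, (x,), bw, needs)


def concat(tensors, axis=-1) -> Tensor:
    needs = _needs(*tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, gs in zip(tensors, splits):
            t._accumulate(gs)

    return _wrap(out, tuple(tensors), bw, needs)


def reshape(x: Tensor, shape) -> Tensor:
    needs = _needs(x)

    def bw(g):
        x._accumulate(g.reshape(x.data.shape))

    return _wrap(x.data.reshape(shape), (x,), bw, needs)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    needs = _needs(x, w)

    def bw(g):
        x._accumulate(g @ w.data.T)
        w._accumulate(x.data.T @ g)

    return _wrap(x.data @ w.data, (x, w), bw, needs)


def pick(x: Tensor, index) -> Tensor:
    """Select a single element (e.g. one logit) as a scalar tensor."""
    needs = _needs(x)

    def bw(g):
        full = np.zeros_like(x.data)
        full[index] = g
        x._accumulate(full)

    return _wrap(x.data[index], (x,), bw, needs)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    if p <= 0.0:
        return x
    needs = _needs(x)
    mask = (rng.random(x.data.shape) >= p).astype(DTYPE) / (1.0 - p)

    def bw(g):
        x._accumulate(g * mask)

    return _wrap(x.data * mask, (x,), bw, needs)


# ------------------------------------------------------------- spatial ops
# All spatial ops take NHWC input.

def _pad_amount(kernel, padding):
    kh, kw = kernel
    if padding == "valid":
        return (0, 0), (0, 0)
    if padding == "same":
        # odd kernels only; keeps spatial size at stride 1
        return ((kh - 1) // 2, kh // 2), ((kw - 1) // 2, kw // 2)
    raise ValueError(f"unknown padding {padding!r}")


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride=(1, 1), padding="valid") -> Tensor:
    """2-D convolution; ``w`` has shape (kh, kw, Cin, Cout).

    Lowered to GEMMs via im2col over batch chunks; column buffers are
    bounded in size and never retained for the backward pass.
    """
    kh, kw, ci, co = w.data.shape
    sh, sw = stride
    (pt, pb), (pl, pr) = _pad_amount((kh, kw), padding)
    xd = x.data
    if pt or pb or pl or pr:
        xd = np.pad(xd, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    n, hp, wp, _ = xd.shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"conv kernel {kh}x{kw} stride {sh} does not fit input {x.data.shape}"
        )
    # Column buffers are built per batch chunk (bounded ~64 MB) and
    # recomputed in the backward pass rather than retained.
    k_elems = kh * kw * ci
    chunk = max(1, int(64e6 / max(1, ho * wo * k_elems * 4)))

    def _col(sub):
        if kh == kw == 1 and sh == sw == 1:
            return sub.reshape(-1, ci)
        windows = np.lib.stride_tricks.sliding_window_view(sub, (kh, kw), axis=(1, 2))
        windows = windows[:, ::sh, ::sw]  # (m, ho, wo, ci, kh, kw)
        return np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3)).reshape(-1, k_elems)

    wflat = w.data.reshape(k_elems, co)
    out = np.empty((n, ho, wo, co), dtype=DTYPE)
    for s in range(0, n, chunk):
        sub = xd[s : s + chunk]
        out[s : s + chunk] = (_col(sub) @ wflat).reshape(len(sub), ho, wo, co)
    out += b.data
    needs = _needs(x, w, b)

    def bw(g):
        # Weight gradient by per-offset tensordot over strided views (no
        # column buffer); input gradient by one GEMM plus a scatter-add,
        # skipped entirely when the input is a constant leaf.
        b._accumulate(g.sum(axis=(0, 1, 2)))
        gw = np.empty_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = xd[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :]
                gw[i, j] = np.tensordot(xs, g, axes=([0, 1, 2], [0, 1, 2]))
        w._accumulate(gw)
        if not (x._parents or x.requires_grad):
            return
        gx = np.zeros_like(xd)
        for s in range(0, n, chunk):
            m = len(xd[s : s + chunk])
            g2 = g[s : s + chunk].reshape(m * ho * wo, co)
            gcol = (g2 @ wflat.T).reshape(m, ho, wo, kh, kw, ci)
            for i in range(kh):
                for j in range(kw):
                    gx[s : s + chunk, i : i + sh * ho : sh, j : j + sw * wo : sw, :] += (
                        gcol[:, :, :, i, j, :]
                    )
        hx, wx = x.data.shape[1], x.data.shape[2]
        if pt or pb or pl or pr:
            gx = gx[:, pt : pt + hx, pl : pl + wx, :]
        x._accumulate(gx)

    return _wrap(out, (x, w, b), bw, needs)


def _pool_windows(xd, kernel, stride, padding, fill):
    kh, kw = kernel
    sh, sw = stride
    (pt, pb), (pl, pr) = _pad_amount(kernel, padding)
    if pt or pb or pl or pr:
        xd = np.pad(xd, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=fill)
    n, hp, wp, c = xd.shape
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"pool kernel {kh}x{kw} does not fit input of shape {xd.shape}")
    return xd, (pt, pl), ho, wo


def max_pool2d(x: Tensor, kernel=(2, 2), stride=(2, 2), padding="valid") -> Tensor:
    kh, kw = kernel
    sh, sw = stride
    xd, (pt, pl), ho, wo = _pool_windows(x.data, kernel, stride, padding, -np.inf)
    out = None
    for i in range(kh):
        for j in range(kw):
            xs = xd[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :]
            out = xs.copy() if out is None else np.maximum(out, xs, out=out)
    needs = _needs(x)

    def bw(g):
        # Gradient routed to every element equal to the window maximum; for
        # continuous activations exact ties have measure zero.
        gx = np.zeros_like(xd)
        for i in range(kh):
            for j in range(kw):
                xs = xd[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :]
                gx[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :] += g * (xs == out)
        hx, wx = x.data.shape[1], x.data.shape[2]
        x._accumulate(gx[:, pt : pt + hx, pl : pl + wx, :])

    return _wrap(out, (x,), bw, needs)


def avg_pool2d(x: Tensor, kernel=(3, 3), stride=(1, 1), padding="same") -> Tensor:
    kh, kw = kernel
    sh, sw = stride
    xd, (pt, pl), ho, wo = _pool_windows(x.data, kernel, stride, padding, 0.0)
    inv = 1.0 / (kh * kw)
    out = np.zeros((xd.shape[0], ho, wo, xd.shape[3]), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            out += xd[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :]
    out *= inv
    needs = _needs(x)

    def bw(g):
        gx = np.zeros_like(xd)
        gs = g * inv
        for i in range(kh):
            for j in range(kw):
                gx[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :] += gs
        hx, wx = x.data.shape[1], x.data.shape[2]
        x._accumulate(gx[:, pt : pt + hx, pl : pl + wx, :])

    return _wrap(out, (x,), bw, needs)


def global_avg_pool(x: Tensor) -> Tensor:
    """NHWC -> NC spatial mean."""
    n, h, w, c = x.data.shape
    needs = _needs(x)
    out = x.data.mean(axis=(1, 2))

    def bw(g):
        x._accumulate(np.broadcast_to(g[:, None, None, :] / (h * w), x.data.shape))

    return _wrap(out, (x,), bw, needs)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray, floor=1e-12) -> Tensor:
    """Mean two-class cross-entropy from per-row softmax probabilities."""
    probs = softmax(logits.data)
    k = logits.data.shape[0]
    loss = -np.mean(np.sum(onehot * np.log(np.maximum(probs, floor)), axis=-1))
    needs = _needs(logits)

    def bw(g):
        logits._accumulate(g * (probs - onehot) / k)

    return _wrap(np.asarray(loss), (logits,), bw, needs)


# ------------------------------------------------------------------ optimizer

class Adadelta:
    """Adadelta (Zeiler 2012) with an external learning-rate multiplier."""

    def __init__(self, params, rho=0.95, eps=1e-6):
        self.params = [p for p in params if p.requires_grad]
        self.rho = rho
        self.eps = eps
        self._eg2 = [np.zeros_like(p.data) for p in self.params]
        self._edx2 = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self, lr=1.0):
        for p, eg2, edx2 in zip(self.params, self._eg2, self._edx2):
            if p.grad is None:
                continue
            g = p.grad
            eg2 *= self.rho
            eg2 += (1.0 - self.rho) * g * g
            dx = -np.sqrt((edx2 + self.eps) / (eg2 + self.eps)) * g
            edx2 *= self.rho
            edx2 += (1.0 - self.rho) * dx * dx
            p.data += DTYPE(lr) * dx
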