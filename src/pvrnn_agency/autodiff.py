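"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Besides generic elementwise/matmul/reduction ops, a handful of fused
primitives (`multi_affine`, `leaky`, `reparam`, `kl_diag_gaussian`,
`sq_err`, `add_n`) keep the graph small enough for long
backpropagation-through-time unrolls in pure Python.  Gradient
correctness of every op is enforced by central-finite-difference oracles
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "gather", "scatter_add",
           "multi_affine", "leaky", "reparam", "kl_diag_gaussian",
           "sq_err", "add_n"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _acc(self, g):
        # grads are accumulated out-of-place so incoming arrays are never
        # mutated (they may be shared with other children)
        self.grad = g if self.grad is None else self.grad + g

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative post-order topological sort
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- binary ops ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, req, (self, other) if req else ())
        if req:
            def bwd(g):
                if self.requires_grad:
                    self._acc(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._acc(_unbroadcast(g, other.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data - other.data, req, (self, other) if req else ())
        if req:
            def bwd(g):
                if self.requires_grad:
                    self._acc(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._acc(_unbroadcast(-g, other.data.shape))
            out._backward = bwd
        return out

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, req, (self, other) if req else ())
        if req:
            def bwd(g):
                if self.requires_grad:
                    self._acc(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._acc(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data / other.data, req, (self, other) if req else ())
        if req:
            def bwd(g):
                if self.requires_grad:
                    self._acc(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._acc(_unbroadcast(
                        -g * self.data / other.data ** 2, other.data.shape))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, req, (self, other) if req else ())
        if req:
            def bwd(g):
                # supports 2-D @ 2-D and batched N-D @ 2-D
                if self.requires_grad:
                    self._acc(g @ other.data.swapaxes(-1, -2))
                if other.requires_grad:
                    k, m = other.data.shape[-2], other.data.shape[-1]
                    other._acc(self.data.reshape(-1, k).T @ g.reshape(-1, m))
            out._backward = bwd
        return out

    def __pow__(self, k):
        assert np.isscalar(k)
        req = self.requires_grad
        out = Tensor(self.data ** k, req, (self,) if req else ())
        if req:
            def bwd(g):
                self._acc(g * k * self.data ** (k - 1))
            out._backward = bwd
        return out

    # -- elementwise unary ---------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        req = self.requires_grad
        out = Tensor(y, req, (self,) if req else ())
        if req:
            def bwd(g):
                self._acc(g * (1.0 - y ** 2))
            out._backward = bwd
        return out

    def exp(self):
        y = np.exp(self.data)
        req = self.requires_grad
        out = Tensor(y, req, (self,) if req else ())
        if req:
            def bwd(g):
                self._acc(g * y)
            out._backward = bwd
        return out

    def log(self):
        req = self.requires_grad
        out = Tensor(np.log(self.data), req, (self,) if req else ())
        if req:
            def bwd(g):
                self._acc(g / self.data)
            out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        req = self.requires_grad
        out = Tensor(self.data * mask, req, (self,) if req else ())
        if req:
            def bwd(g):
                self._acc(g * mask)
            out._backward = bwd
        return out

    def clip(self, lo, hi):
        """Clamp; gradient passes through only inside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)
        req = self.requires_grad
        out = Tensor(np.clip(self.data, lo, hi), req, (self,) if req else ())
        if req:
            def bwd(g):
                self._acc(g * mask)
            out._backward = bwd
        return out

    # -- reductions & shape --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        req = self.requires_grad
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     req, (self,) if req else ())
        if req:
            def bwd(g):
                if axis is None:
                    self._acc(np.broadcast_to(g, self.data.shape))
                elif keepdims:
                    self._acc(np.broadcast_to(g, self.data.shape))
                else:
                    self._acc(np.broadcast_to(
                        np.expand_dims(g, axis), self.data.shape))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        req = self.requires_grad
        out = Tensor(self.data.reshape(*shape), req, (self,) if req else ())
        if req:
            def bwd(g):
                self._acc(g.reshape(self.data.shape))
            out._backward = bwd
        return out

    def __getitem__(self, idx):
        req = self.requires_grad
        out = Tensor(self.data[idx], req, (self,) if req else ())
        if req:
            def bwd(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._acc(full)
            out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 req, tuple(tensors) if req else ())
    if req:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._acc(g[tuple(sl)])
        out._backward = bwd
    return out


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """out[b, k] = x[b].ravel()[idx.ravel()[k]], reshaped to (B, *idx.shape).

    The adjoint is a scatter-add, which makes conv and conv-transpose
    exact transposes of each other.
    """
    x = as_tensor(x)
    b = x.data.shape[0]
    flat = x.data.reshape(b, -1)
    req = x.requires_grad
    out = Tensor(flat[:, idx.ravel()].reshape((b,) + idx.shape),
                 req, (x,) if req else ())
    if req:
        def bwd(g):
            gflat = np.zeros_like(flat)
            np.add.at(gflat, (slice(None), idx.ravel()), g.reshape(b, -1))
            x._acc(gflat.reshape(x.data.shape))
        out._backward = bwd
    return out


def scatter_add(x: Tensor, idx: np.ndarray, out_size: int, out_shape: tuple) -> Tensor:
    """Adjoint of :func:`gather`: accumulate x[b, k] into flat[idx[k]]."""
    x = as_tensor(x)
    b = x.data.shape[0]
    flat = np.zeros((b, out_size))
    np.add.at(flat, (slice(None), idx.ravel()), x.data.reshape(b, -1))
    req = x.requires_grad
    out = Tensor(flat.reshape((b,) + out_shape), req, (x,) if req else ())
    if req:
        def bwd(g):
            gflat = g.reshape(b, -1)
            x._acc(gflat[:, idx.ravel()].reshape(x.data.shape))
        out._backward = bwd
    return out


# ----------------------------------------------------------------------
# fused primitives
# ----------------------------------------------------------------------

def multi_affine(pairs, bias=None, adds=(), act=None, clip_lo=None,
                 clip_hi=None) -> Tensor:
    """act( sum_i x_i @ W_i + sum_j adds_j + bias ), one graph node.

    act is None, 'tanh' or 'exp'; an optional clamp applies after 'exp'
    (gradient masked outside the clamp).
    """
    pairs = [(as_tensor(x), as_tensor(W)) for x, W in pairs]
    adds = [as_tensor(a) for a in adds]
    bias = as_tensor(bias) if bias is not None else None
    pre = pairs[0][0].data @ pairs[0][1].data
    for x, W in pairs[1:]:
        pre = pre + x.data @ W.data
    for a in adds:
        pre = pre + a.data
    if bias is not None:
        pre = pre + bias.data
    if act == "tanh":
        y = np.tanh(pre)
        mask = None
    elif act == "exp":
        y = np.exp(pre)
        if clip_lo is not None:
            mask = (y >= clip_lo) & (y <= clip_hi)
            y = np.clip(y, clip_lo, clip_hi)
        else:
            mask = True
    else:
        y = pre
        mask = None
    parents = tuple(t for x, W in pairs for t in (x, W)) + tuple(adds) \
        + ((bias,) if bias is not None else ())
    req = any(p.requires_grad for p in parents)
    out = Tensor(y, req, parents if req else ())
    if req:
        def bwd(g):
            if act == "tanh":
                gp = g * (1.0 - y ** 2)
            elif act == "exp":
                gp = g * y * mask
            else:
                gp = g
            for x, W in pairs:
                if x.requires_grad:
                    x._acc(gp @ W.data.swapaxes(-1, -2))
                if W.requires_grad:
                    k, m = W.data.shape
                    W._acc(x.data.reshape(-1, k).T @ gp.reshape(-1, m))
            for a in adds:
                if a.requires_grad:
                    a._acc(_unbroadcast(gp, a.data.shape))
            if bias is not None and bias.requires_grad:
                bias._acc(_unbroadcast(gp, bias.data.shape))
        out._backward = bwd
    return out


def leaky(h_prev, u, tau: float) -> Tensor:
    """(1 - 1/tau) * h_prev + (1/tau) * u, one node."""
    h_prev, u = as_tensor(h_prev), as_tensor(u)
    a = 1.0 - 1.0 / tau
    req = h_prev.requires_grad or u.requires_grad
    out = Tensor(a * h_prev.data + (1.0 - a) * u.data, req,
                 (h_prev, u) if req else ())
    if req:
        def bwd(g):
            if h_prev.requires_grad:
                h_prev._acc(g * a)
            if u.requires_grad:
                u._acc(g * (1.0 - a))
        out._backward = bwd
    return out


def reparam(mu, sigma, eps: np.ndarray) -> Tensor:
    """mu + sigma * eps with constant eps, one node."""
    mu, sigma = as_tensor(mu), as_tensor(sigma)
    eps = np.asarray(eps, dtype=np.float64)
    req = mu.requires_grad or sigma.requires_grad
    out = Tensor(mu.data + sigma.data * eps, req, (mu, sigma) if req else ())
    if req:
        def bwd(g):
            if mu.requires_grad:
                mu._acc(_unbroadcast(g, mu.data.shape))
            if sigma.requires_grad:
                sigma._acc(_unbroadcast(g * eps, sigma.data.shape))
        out._backward = bwd
    return out


def kl_diag_gaussian(mu_q, sg_q, mu_p, sg_p) -> Tensor:
    """Closed-form KL(q||p) of diagonal Gaussians, summed over the last axis."""
    mu_q, sg_q = as_tensor(mu_q), as_tensor(sg_q)
    mu_p, sg_p = as_tensor(mu_p), as_tensor(sg_p)
    dmu = mu_p.data - mu_q.data
    val = (np.log(sg_p.data / sg_q.data)
           + (dmu ** 2 + sg_q.data ** 2) / (2.0 * sg_p.data ** 2)
           - 0.5).sum(axis=-1)
    parents = (mu_q, sg_q, mu_p, sg_p)
    req = any(p.requires_grad for p in parents)
    out = Tensor(val, req, parents if req else ())
    if req:
        def bwd(g):
            ge = g[..., None]
            if mu_q.requires_grad:
                mu_q._acc(_unbroadcast(-ge * dmu / sg_p.data ** 2,
                                       mu_q.data.shape))
            if sg_q.requires_grad:
                sg_q._acc(_unbroadcast(
                    ge * (-1.0 / sg_q.data + sg_q.data / sg_p.data ** 2),
                    sg_q.data.shape))
            if mu_p.requires_grad:
                mu_p._acc(_unbroadcast(ge * dmu / sg_p.data ** 2,
                                       mu_p.data.shape))
            if sg_p.requires_grad:
                sg_p._acc(_unbroadcast(
                    ge * (1.0 / sg_p.data
                          - (dmu ** 2 + sg_q.data ** 2) / sg_p.data ** 3),
                    sg_p.data.shape))
        out._backward = bwd
    return out


def sq_err(pred, target: np.ndarray, scale: float = 1.0) -> Tensor:
    """scale * sum((pred - target)^2) with constant target, one scalar node."""
    pred = as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target
    req = pred.requires_grad
    out = Tensor(scale * (diff ** 2).sum(), req, (pred,) if req else ())
    if req:
        def bwd(g):
            pred._acc((2.0 * scale * g) * diff)
        out._backward = bwd
    return out


def add_n(tensors) -> Tensor:
    """Sum of scalar tensors as a single node."""
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(sum(float(t.data) for t in tensors), req,
                 tuple(tensors) if req else ())
    if req:
        def bwd(g):
            for t in tensors:
                if t.requires_grad:
                    t._acc(g)
        out._backward = bwd
    return out
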