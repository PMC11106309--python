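"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's networks need: broadcasted
arithmetic, matmul, 1-D patch extraction (im2col) for convolutions,
reductions, and the elementwise nonlinearities.  Gradients flow through a
topologically-sorted tape; correctness is pinned by finite-difference tests.

Arrays are float32 by default (float64 available for gradient checking via
``set_dtype``).
"""

from __future__ import annotations

import numpy as np

_DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the global tensor dtype (float32 for speed, float64 for checks)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype)


def get_dtype():
    return _DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self._grad_owned = False

    # ---- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = None
            node._grad_owned = False
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # Lazy-copy accumulation: adopt the incoming array without copying;
        # only materialize an owned buffer on a second contribution.  An
        # adopted array may be shared with a sibling, so it is never
        # mutated in place.
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return _as_tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def bwd(g, a=self, e=exponent, od=out_data):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def affine(self, W: "Tensor", b: "Tensor") -> "Tensor":
        """Fused x @ W + b for 2-D x (saves one full-array pass)."""
        out = self.data @ W.data
        out += b.data

        def bwd(g, a=self, W=W, b=b):
            if a.requires_grad:
                a._accum(g @ W.data.T)
            if W.requires_grad:
                W._accum(a.data.T @ g)
            if b.requires_grad:
                b._accum(g.sum(axis=0))

        return Tensor(out, parents=(self, W, b), backward=bwd)

    # ---- shaping ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.shape

        def bwd(g, a=self, orig=orig):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def pad1d(self, left: int, right: int) -> "Tensor":
        """Zero-pad axis 1 of a (B, L, C) tensor."""
        if left == 0 and right == 0:
            return self
        L = self.shape[1]

        def bwd(g, a=self, left=left, L=L):
            if a.requires_grad:
                a._accum(g[:, left:left + L, :])

        padded = np.pad(self.data, ((0, 0), (left, right), (0, 0)))
        return Tensor(padded, parents=(self,), backward=bwd)

    def unfold1d(self, kernel: int) -> "Tensor":
        """Extract sliding windows along axis 1: (B, L, C) -> (B, L-K+1, K*C)."""
        B, L, C = self.shape
        Lo = L - kernel + 1
        win = np.lib.stride_tricks.sliding_window_view(self.data, kernel, axis=1)
        # win: (B, Lo, C, K) -> (B, Lo, K, C) -> (B, Lo, K*C)
        out = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, Lo, kernel * C)

        def bwd(g, a=self, B=B, L=L, C=C, K=kernel, Lo=Lo):
            if not a.requires_grad:
                return
            gk = g.reshape(B, Lo, K, C)
            acc = np.zeros((B, L, C), dtype=g.dtype)
            for k in range(K):
                acc[:, k:k + Lo, :] += gk[:, :, k, :]
            a._accum(acc)

        return Tensor(out, parents=(self,), backward=bwd)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.shape

        def bwd(g, a=self, axis=axis, keepdims=keepdims, shape=shape):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- elementwise -----------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def abs(self) -> "Tensor":
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))

        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)

    def leaky_relu(self, negative_slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, negative_slope).astype(self.data.dtype)

        def bwd(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def relu(self) -> "Tensor":
        return self.leaky_relu(0.0)

    def batchnorm(self, gamma: "Tensor", beta: "Tensor",
                  eps: float = 1e-5) -> tuple["Tensor", np.ndarray, np.ndarray]:
        """Fused training-mode batch normalization over all leading axes.

        Normalizes per trailing channel using biased batch statistics and
        returns (output, batch_mean, batch_var) with a closed-form backward.
        """
        axes = tuple(range(self.ndim - 1))
        x = self.data
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv_std
        g = gamma.data.reshape((1,) * (self.ndim - 1) + (-1,))
        b = beta.data.reshape((1,) * (self.ndim - 1) + (-1,))
        out_data = xhat * g + b
        m = x.size // x.shape[-1]

        def bwd(grad, a=self, gamma=gamma, beta=beta, xhat=xhat,
                inv_std=inv_std, g=g, axes=axes, m=m):
            if gamma.requires_grad:
                gamma._accum((grad * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(grad.sum(axis=axes))
            if a.requires_grad:
                gm = grad.mean(axis=axes, keepdims=True)
                gxm = (grad * xhat).mean(axis=axes, keepdims=True)
                a._accum((g * inv_std) * (grad - gm - xhat * gxm))

        return (Tensor(out_data, parents=(self, gamma, beta), backward=bwd),
                mu.reshape(-1), var.reshape(-1))

    def log_softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable log-softmax along ``axis`` (composite op)."""
        shift = self.data.max(axis=axis, keepdims=True)  # constant wrt grad
        x = self - Tensor(shift)
        return x - x.exp().sum(axis=axis, keepdims=True).log()


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)
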