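"""Layers and structured ops built on the autograd core."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution (cross-correlation), NCHW layout.

    ``weight`` has shape (Cout, Cin, k, k) with odd k.
    """
    n, cin, h, w = x.data.shape
    cout, cin_w, k, k2 = weight.data.shape
    if cin != cin_w or k != k2 or k % 2 != 1:
        raise ValueError(f"bad conv shapes x={x.data.shape} w={weight.data.shape}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    # shift-and-matmul: one BLAS product per kernel tap, no im2col blow-up
    shifts = [
        np.ascontiguousarray(xp[:, :, i : i + h, j : j + w]).reshape(n, cin, h * w)
        for i in range(k)
        for j in range(k)
    ]
    wtaps = weight.data.reshape(cout, cin, k * k)
    out = np.zeros((n, cout, h * w), dtype=x.data.dtype)
    for t, xs in enumerate(shifts):
        out += np.matmul(wtaps[:, :, t], xs)
    out = out.reshape(n, cout, h, w)
    if bias is not None:
        out = out + bias.data[:, None, None]

    def back(g):
        g2 = np.ascontiguousarray(g.reshape(n, cout, h * w))
        dw = np.empty_like(wtaps)
        dxp = np.zeros_like(xp)
        for t, xs in enumerate(shifts):
            # sum over batch of g2 @ xs^T
            dw[:, :, t] = np.tensordot(g2, xs, axes=([0, 2], [0, 2]))
            i, j = divmod(t, k)
            dxp[:, :, i : i + h, j : j + w] += np.matmul(
                wtaps[:, :, t].T, g2
            ).reshape(n, cin, h, w)
        db = None if bias is None else g.sum(axis=(0, 2, 3))
        dx = dxp[:, :, p : p + h, p : p + w] if p else dxp
        return (dx, dw.reshape(weight.data.shape)) if bias is None else (
            dx,
            dw.reshape(weight.data.shape),
            db,
        )

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out, _parents=parents, _backward=back)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def back(g):
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (dx.reshape(n, c, h, w),)

    return Tensor(out, _parents=(x,), _backward=back)


def upsample2x_nearest(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def back(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor(out, _parents=(x,), _backward=back)


def gather_channel(logp: Tensor, labels: np.ndarray) -> Tensor:
    """Pick logp[n, labels[n,h,w], h, w] -> (n, h, w); for NLL losses."""
    n, c, h, w = logp.data.shape
    ni, hi, wi = np.ogrid[:n, :h, :w]
    out = logp.data[ni, labels, hi, wi]

    def back(g):
        dl = np.zeros_like(logp.data)
        np.add.at(dl, (ni, labels, hi, wi), g)
        return (dl,)

    return Tensor(out, _parents=(logp,), _backward=back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data

    def back(g):
        dgamma = (g * xhat).reshape(-1, x.data.shape[-1]).sum(axis=0)
        dbeta = g.reshape(-1, x.data.shape[-1]).sum(axis=0)
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        dx = (dxhat - m1 - xhat * m2) * inv
        return dx, dgamma, dbeta

    return Tensor(out, _parents=(x, gamma, beta), _backward=back)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.ascontiguousarray(data), requires_grad=True)


class Module:
    """Minimal parameter container with recursive discovery by attribute."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out, seen):
        for v in self.__dict__.values():
            if isinstance(v, Parameter) and id(v) not in seen:
                seen.add(id(v))
                out.append(v)
            elif isinstance(v, Module):
                v._collect(out, seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter) and id(item) not in seen:
                        seen.add(id(item))
                        out.append(item)
                    elif isinstance(item, Module):
                        item._collect(out, seen)

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(f"{name}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
                    elif isinstance(item, Module):
                        out.extend(item.named_parameters(f"{name}.{i}."))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class ModuleList(Module, list):
    def __init__(self, mods=()):
        list.__init__(self, mods)

    def _collect(self, out, seen):
        for m in self:
            if isinstance(m, Module):
                m._collect(out, seen)

    def named_parameters(self, prefix: str = ""):
        out = []
        for i, m in enumerate(self):
            out.extend(m.named_parameters(f"{prefix}{i}."))
        return out


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias=True):
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3):
        self.weight = Parameter(_kaiming(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Adam:
    """Adam optimizer; ``beta1`` is the momentum coefficient."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
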