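"""Neural-network layers built on the autograd core."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Conv1d",
    "BatchNorm1d",
    "MaxPool1d",
    "Linear",
    "conv1d_out_len",
    "softmax",
    "cross_entropy",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight module base: tracks parameters, sub-modules and mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def conv1d_out_len(L, k, s, p):
    return (L + 2 * p - k) // s + 1


class Conv1d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias=True, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng()
        # Kaiming fan-out init, matching the usual residual-net recipe
        std = np.sqrt(2.0 / (out_channels * kernel_size))
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        B, C, L = x.data.shape
        if C != self.in_channels:
            raise ValueError(f"Conv1d expected {self.in_channels} input channels, got {C}")
        k, s, p = self.kernel_size, self.stride, self.padding
        if L + 2 * p < k:
            raise ValueError(f"input length {L} too short for kernel {k} with padding {p}")
        weight, bias = self.weight, self.bias
        parents = (x, weight) + (() if bias is None else (bias,))

        if k == 1 and s == 1 and p == 0:
            # pointwise conv: one batched GEMM over the channel axis
            w2 = weight.data[:, :, 0]
            out = np.matmul(w2, x.data)
            if bias is not None:
                out += bias.data[:, None]

            def bw(g):
                weight.accumulate(
                    np.matmul(g, x.data.transpose(0, 2, 1)).sum(axis=0)[:, :, None])
                if bias is not None:
                    bias.accumulate(g.sum(axis=(0, 2)))
                x.accumulate(np.matmul(w2.T, g))

            return Tensor(out, True, parents, bw)

        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p))) if p else x.data
        windows = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]  # (B,C,Lout,k)
        Lout = windows.shape[2]
        # contiguous im2col matrix reused by the backward pass
        col = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(B * Lout, C * k)
        wmat = weight.data.reshape(self.out_channels, C * k)
        out = (col @ wmat.T).reshape(B, Lout, self.out_channels).transpose(0, 2, 1)
        if self.bias is not None:
            out += bias.data[:, None]
        stride = s

        def bw(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lout, -1)
            weight.accumulate((g2.T @ col).reshape(weight.data.shape))
            if bias is not None:
                bias.accumulate(g2.sum(axis=0))
            gcol = (g2 @ wmat).reshape(B, Lout, C, k)
            gxp = np.zeros_like(xp)
            for kk in range(k):
                gxp[:, :, kk:kk + stride * Lout:stride] += gcol[:, :, :, kk].transpose(0, 2, 1)
            x.accumulate(gxp[:, :, p:p + L] if p else gxp)

        return Tensor(out, True, parents, bw)


class MaxPool1d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel_size, self.stride, self.padding
        B, C, L = x.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf) if p else x.data
        windows = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        Lout = out.shape[-1]

        def bw(g):
            gxp = np.zeros_like(xp)
            b, c, t = np.meshgrid(np.arange(B), np.arange(C), np.arange(Lout), indexing="ij")
            np.add.at(gxp, (b, c, t * s + idx), g)
            x.accumulate(gxp[:, :, p:p + L] if p else gxp)

        return Tensor(out, True, (x,), bw)


class BatchNorm1d(Module):
    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta, eps = self.weight, self.bias, self.eps
        xd = x.data
        n = xd.shape[0] * xd.shape[2]
        if self.training:
            mu = xd.mean(axis=(0, 2))
            # single-pass second moment keeps this layer off the hot path
            var = np.einsum("bct,bct->c", xd, xd) / n - mu * mu
            np.maximum(var, 0.0, out=var)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + eps)
        scale = gamma.data / std
        shift = beta.data - mu * scale
        out = xd * scale[:, None] + shift[:, None]
        use_batch_stats = self.training

        def bw(g):
            xhat = (xd - mu[:, None]) / std[:, None]
            gamma.accumulate(np.einsum("bct,bct->c", g, xhat))
            beta.accumulate(g.sum(axis=(0, 2)))
            if use_batch_stats:
                gm = g.mean(axis=(0, 2), keepdims=True)
                gxm = np.einsum("bct,bct->c", g, xhat)[None, :, None] / n
                gx = (gamma.data[:, None] / std[:, None]) * (g - gm - xhat * gxm)
            else:
                gx = gamma.data[:, None] / std[:, None] * g
            x.accumulate(gx)

        return Tensor(out, True, (x, gamma, beta), bw)


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features))

    def __call__(self, x: Tensor) -> Tensor:
        weight, bias = self.weight, self.bias
        out = x.data @ weight.data.T + bias.data

        def bw(g):
            weight.accumulate(g.T @ x.data)
            bias.accumulate(g.sum(axis=0))
            x.accumulate(g @ weight.data)

        return Tensor(out, True, (x, weight, bias), bw)


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: Tensor, labels) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` (B, K)."""
    labels = np.asarray(labels)
    p = softmax(logits.data)
    B = logits.data.shape[0]
    nll = -np.log(np.clip(p[np.arange(B), labels], 1e-300, None)).mean()

    def bw(g):
        grad = p.copy()
        grad[np.arange(B), labels] -= 1.0
        logits.accumulate(g * grad / B)

    return Tensor(nll, True, (logits,), bw)
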