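"""Fused differentiable operations used by the network layers.

Each function here has a hand-written backward pass, chosen over composition
of primitives either for numerical stability (the loss functions) or because
the operation dominates runtime (convolution, batch normalisation).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv1d", "leaky_relu", "batch_norm", "dropout_mask", "linear",
    "softmax_cross_entropy", "binary_cross_entropy_with_logits",
    "mean_squared_error", "gradient_reversal", "softmax", "log_softmax",
]


def _pad_time(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    n, c, t = x.shape
    out = np.zeros((n, c, t + 2 * pad), dtype=x.dtype)
    out[:, :, pad:pad + t] = x
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Temporal convolution with stride 1 and "same" zero padding.

    ``x`` is (N, C_in, T); ``weight`` is (C_out, C_in, k) with odd ``k``;
    output is (N, C_out, T).  The six sensor axes enter as input channels, so
    the first convolution mixes axes while sliding along time only.
    Implemented as one GEMM per kernel tap over shifted views, which avoids
    materialising an im2col buffer.
    """
    n, c_in, t = x.data.shape
    c_out, c_in_w, k = weight.data.shape
    if c_in != c_in_w:
        raise ValueError(f"input has {c_in} channels, kernel expects {c_in_w}")
    if k % 2 != 1:
        raise ValueError("kernel length must be odd for symmetric same-padding")
    if t < 1:
        raise ValueError("temporal length must be >= 1")
    pad = k // 2
    xp = _pad_time(x.data, pad)
    w = weight.data
    out_data = np.matmul(w[:, :, 0], xp[:, :, 0:t])
    for j in range(1, k):
        out_data += np.matmul(w[:, :, j], xp[:, :, j:j + t])
    if bias is not None:
        out_data += bias.data[:, None]

    def backward(g):
        if weight.requires_grad:
            dw = np.empty_like(w)
            for j in range(k):
                dw[:, :, j] = np.tensordot(g, xp[:, :, j:j + t],
                                           axes=([0, 2], [0, 2]))
            weight._accumulate(dw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j:j + t] += np.matmul(w[:, :, j].T, g)
            x._accumulate(dxp[:, :, pad:pad + t] if pad else dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Affine map: (N, in) @ weight.T + bias, weight is (out, in)."""
    out_data = x.data @ weight.data.T
    if bias is not None:
        out_data += bias.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ weight.data)
        if weight.requires_grad:
            weight._accumulate(g.T @ x.data)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=0))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    # a single reusable scale array serves both passes
    scale = np.where(x.data > 0, np.asarray(1.0, dtype=x.data.dtype),
                     np.asarray(negative_slope, dtype=x.data.dtype))
    out_data = x.data * scale

    def backward(g):
        x._accumulate(g * scale)

    return Tensor._make(out_data, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalisation over the batch (and time, if present) axes.

    Accepts (N, C) or (N, C, T) input; statistics are per channel.  In
    training mode the running estimates are updated in place with the
    conventional exponential moving average.
    """
    data = x.data
    axes = (0,) if data.ndim == 2 else (0, 2)
    shape = (1, -1) if data.ndim == 2 else (1, -1, 1)
    dtype = data.dtype
    m = data.size // data.shape[1]
    if training:
        # single pass over the array for both moments
        if data.ndim == 2:
            s = data.sum(axis=0)
            ss = np.einsum("nc,nc->c", data, data)
        else:
            s = data.sum(axis=(0, 2))
            ss = np.einsum("nct,nct->c", data, data)
        mu = (s / m).astype(dtype, copy=False)
        var = np.maximum(ss / m - mu * mu, 0.0).astype(dtype, copy=False)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        # unbiased estimate in the running buffer, biased in the pass
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(dtype, copy=False)
    xhat = (data - mu.reshape(shape)) * inv_std.reshape(shape)
    g_ = gamma.data.reshape(shape)
    out_data = g_ * xhat
    out_data += beta.data.reshape(shape)

    def backward(grad):
        if gamma.requires_grad:
            gamma._accumulate((grad * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(grad.sum(axis=axes))
        if x.requires_grad:
            scaled = grad * g_
            if training:
                mean_g = scaled.mean(axis=axes).reshape(shape)
                mean_gx = (scaled * xhat).mean(axis=axes).reshape(shape)
                dx = (scaled - mean_g - xhat * mean_gx)
                dx *= inv_std.reshape(shape)
            else:
                dx = scaled * inv_std.reshape(shape)
            x._accumulate(dx.astype(dtype, copy=False))

    return Tensor._make(out_data, (x, gamma, beta), backward)


def dropout_mask(x: Tensor, mask: np.ndarray) -> Tensor:
    """Multiply by a precomputed inverted-dropout mask (constant w.r.t. grad)."""
    out_data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._make(out_data, (x,), backward)


def gradient_reversal(x: Tensor, beta: float = 1.0) -> Tensor:
    """Identity in the forward pass; scales the gradient by ``-beta`` backward.

    The reversal sits between the feature extractor and the domain classifier
    so that minimising the domain-discrimination loss pushes the extractor
    toward domain-indistinguishable features.
    """

    def backward(g):
        x._accumulate(-beta * g)

    return Tensor._make(x.data.copy(), (x,), backward)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean over the batch of -log softmax(logits)[label]."""
    labels = np.asarray(labels)
    n, c = logits.data.shape
    if labels.shape != (n,):
        raise ValueError("labels must be a 1-D array matching the batch size")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    logp = log_softmax(logits.data)
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        dlogits = np.exp(logp)
        dlogits[np.arange(n), labels] -= 1.0
        logits._accumulate((g / n) * dlogits)

    return Tensor._make(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on a single logit per sample (stable form)."""
    z = logits.data.reshape(-1)
    t = np.asarray(targets, dtype=z.dtype).reshape(-1)
    if z.shape != t.shape:
        raise ValueError("logits and targets must have matching lengths")
    # softplus(z) - t*z, with softplus computed as max(z,0) + log1p(exp(-|z|))
    loss = (np.maximum(z, 0) - t * z + np.log1p(np.exp(-np.abs(z)))).mean()
    n = z.size

    def backward(g):
        sig = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(((g / n) * (sig - t)).reshape(logits.data.shape))

    return Tensor._make(np.asarray(loss, dtype=z.dtype), (logits,), backward)


def mean_squared_error(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean of squared differences over every element."""
    t = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - t
    loss = np.mean(diff ** 2)
    n = diff.size

    def backward(g):
        pred._accumulate((2.0 * g / n) * diff)

    return Tensor._make(np.asarray(loss, dtype=pred.data.dtype), (pred,), backward)
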