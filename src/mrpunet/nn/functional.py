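"""Differentiable operations for the numpy NN backend.

Every function takes/returns :class:`~mrpunet.nn.autograd.Tensor` and attaches
a backward closure returning one gradient per parent (or ``None``).  Feature
maps are ``[batch, channel, height, width]``.  Convolutions are stride-1,
zero-padded to preserve the spatial size ("same"), with odd kernels; dilated
kernels are padded by ``dilation * (k // 2)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "add", "mul", "relu", "sigmoid", "concat", "conv2d", "conv_transpose2x2",
    "max_pool2x2", "batch_norm2d", "dropout", "linear", "global_avg_pool",
    "channel_scale", "softmax_cross_entropy", "softmax",
]


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise sum of two same-shaped tensors (residual connections)."""
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    out_data = a.data + b.data

    def backward(g):
        return g, g

    return Tensor._node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise product (same shapes)."""
    if a.shape != b.shape:
        raise ValueError(f"mul: shape mismatch {a.shape} vs {b.shape}")
    out_data = a.data * b.data

    def backward(g):
        return g * b.data, g * a.data

    return Tensor._node(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        return (g * mask,)

    return Tensor._node(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    s[~pos] = e / (1.0 + e)

    def backward(g):
        return (g * s * (1.0 - s),)

    return Tensor._node(s, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (channel axis by default)."""
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """Extract dilated k*k patches of a padded input.

    Returns ``(B*H*W, C*k*k)`` where H, W are the *unpadded* spatial dims.
    Input must already be zero-padded by ``dilation * (k // 2)``.
    """
    k_eff = (k - 1) * dilation + 1
    win = sliding_window_view(x, (k_eff, k_eff), axis=(2, 3))
    if dilation > 1:
        win = win[..., ::dilation, ::dilation]
    b, c, h, w = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    return np.ascontiguousarray(col)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, dilation: int = 1) -> Tensor:
    """Stride-1 "same" 2-D convolution (cross-correlation).

    ``weight`` is ``[out_ch, in_ch, k, k]`` with k odd; ``bias`` is
    ``[out_ch]`` or None.  1x1 kernels skip the im2col path.
    """
    B, C, H, W = x.shape
    O, Cw, k, k2 = weight.shape
    if Cw != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")
    if k != k2 or k % 2 == 0:
        raise ValueError("conv2d: kernel must be square with odd side")

    if k == 1:
        w2 = weight.data[:, :, 0, 0]  # (O, C)
        out = np.tensordot(x.data, w2, axes=([1], [1]))  # (B,H,W,O)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        if bias is not None:
            out += bias.data[None, :, None, None]

        def backward1(g):
            gx = None
            if x.requires_grad:
                gx = np.tensordot(g, w2, axes=([1], [0]))  # (B,H,W,C)
                gx = np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
            gw2 = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))  # (O,C)
            gw = gw2[:, :, None, None]
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb) if bias is not None else (gx, gw)

        parents = (x, weight, bias) if bias is not None else (x, weight)
        return Tensor._node(out, parents, backward1)

    pad = dilation * (k // 2)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    col = _im2col(xp, k, dilation)  # (B*H*W, C*k*k)
    wmat = weight.data.reshape(O, C * k * k)
    out = col @ wmat.T  # (B*H*W, O)
    out = out.reshape(B, H, W, O).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(g):
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * H * W, O)
        gw = (g_mat.T @ col).reshape(O, C, k, k)
        gx = None
        if x.requires_grad:
            # grad wrt input: full correlation of g with the flipped kernel
            gp = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            col_g = _im2col(gp, k, dilation)  # (B*H*W, O*k*k)
            wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(C, O * k * k)
            gx = (col_g @ wflip.T).reshape(B, H, W, C).transpose(0, 3, 1, 2)
            gx = np.ascontiguousarray(gx)
        if bias is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return Tensor._node(out, parents, backward)


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """2x spatial upsampling by a stride-2, kernel-2 transposed convolution.

    ``weight`` is ``[in_ch, out_ch, 2, 2]``; output is ``[B, out_ch, 2H, 2W]``.
    """
    B, C, H, W = x.shape
    Cw, O = weight.shape[:2]
    if Cw != C:
        raise ValueError(f"conv_transpose2x2: input has {C} channels, weight expects {Cw}")
    t = np.tensordot(x.data, weight.data, axes=([1], [0]))  # (B,H,W,O,2,2)
    out = t.transpose(0, 3, 1, 4, 2, 5).reshape(B, O, 2 * H, 2 * W)
    out = np.ascontiguousarray(out)
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(g):
        gr = g.reshape(B, O, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # (B,H,W,O,2,2)
        gx = np.tensordot(gr, weight.data, axes=([3, 4, 5], [1, 2, 3]))  # (B,H,W,C)
        gx = np.ascontiguousarray(gx.transpose(0, 3, 1, 2))
        gw = np.tensordot(x.data, gr, axes=([0, 2, 3], [0, 1, 2]))  # (C,O,2,2)
        if bias is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return Tensor._node(out, parents, backward)


# ---------------------------------------------------------------------------
# pooling / normalisation / regularisation
# ---------------------------------------------------------------------------

def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2. Requires even H and W."""
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2x2: spatial size ({H}, {W}) must be even")
    r = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(B, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    out = np.ascontiguousarray(out)

    def backward(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (np.ascontiguousarray(gx.reshape(B, C, H, W)),)

    return Tensor._node(out, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, decay: float = 0.998,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (batch, height, width).

    In training mode batch statistics are used and running statistics are
    updated in place as ``running = decay * running + (1 - decay) * batch``.
    In evaluation mode the stored running statistics are used, making the
    forward pass deterministic.
    """
    B, C, H, W = x.shape
    m = B * H * W
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= decay
        running_mean += (1.0 - decay) * mu
        running_var *= decay
        running_var += (1.0 - decay) * var
    else:
        mu = running_mean
        var = running_var
    mu = np.asarray(mu, dtype=x.dtype)
    inv_std = (1.0 / np.sqrt(var + eps)).astype(x.dtype)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        if training:
            gx = (gamma.data * inv_std)[None, :, None, None] * (
                g
                - gbeta[None, :, None, None] / m
                - xhat * ggamma[None, :, None, None] / m
            )
        else:
            gx = g * (gamma.data * inv_std)[None, :, None, None]
        return gx, ggamma, gbeta

    return Tensor._node(out, (x, gamma, beta), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when rate == 0 or in evaluation mode."""
    if not training or rate <= 0.0:
        return x
    keep = (rng.random(x.shape) >= rate).astype(x.dtype)
    scale = 1.0 / (1.0 - rate)
    out = x.data * keep * scale

    def backward(g):
        return (g * keep * scale,)

    return Tensor._node(out, (x,), backward)


# ---------------------------------------------------------------------------
# dense / attention helpers
# ---------------------------------------------------------------------------

def linear(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Affine map on the last axis: ``x @ weight.T + bias``.

    ``x`` is ``[B, in]``; ``weight`` is ``[out, in]``.
    """
    out = x.data @ weight.data.T
    if bias is not None:
        out = out + bias.data

    def backward(g):
        gx = g @ weight.data
        gw = g.T @ x.data
        if bias is not None:
            return gx, gw, g.sum(axis=0)
        return gx, gw

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return Tensor._node(out, parents, backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Squeeze step of channel attention: mean over (H, W) -> [B, C]."""
    B, C, H, W = x.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        gx = np.broadcast_to(g[:, :, None, None] / (H * W), x.shape)
        return (np.ascontiguousarray(gx),)

    return Tensor._node(out, (x,), backward)


def channel_scale(x: Tensor, w: Tensor) -> Tensor:
    """Multiply each channel plane by a per-(batch, channel) scalar weight."""
    B, C = w.shape
    if x.shape[:2] != (B, C):
        raise ValueError(f"channel_scale: {x.shape[:2]} vs weights {w.shape}")
    out = x.data * w.data[:, :, None, None]

    def backward(g):
        gx = g * w.data[:, :, None, None]
        gw = (g * x.data).sum(axis=(2, 3))
        return gx, gw

    return Tensor._node(out, (x, w), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Plain (non-differentiable) softmax used at inference time."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Mean pixelwise cross-entropy for ``[B, n_classes, H, W]`` scores.

    ``labels`` holds integer class ids ``[B, H, W]``.  Optional per-class
    weights rescale each pixel's contribution.
    """
    B, K, H, W = logits.shape
    labels = np.asarray(labels)
    if labels.shape != (B, H, W):
        raise ValueError(f"labels shape {labels.shape} != {(B, H, W)}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp  # (B,K,H,W)
    picked = np.take_along_axis(logp, labels[:, None], axis=1)[:, 0]  # (B,H,W)
    if class_weights is not None:
        wpix = np.asarray(class_weights, dtype=logits.dtype)[labels]
        denom = wpix.sum()
        loss = -(picked * wpix).sum() / denom
    else:
        wpix = None
        denom = B * H * W
        loss = -picked.sum() / denom

    probs = np.exp(logp)

    def backward(g):
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
        gz = (probs - onehot) / denom
        if wpix is not None:
            gz = gz * wpix[:, None]
        return (gz * g,)

    return Tensor._node(np.asarray(loss, dtype=logits.dtype), (logits,), backward)
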