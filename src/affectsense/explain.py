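"""Attribution and embedding visualisation.

All methods return plain arrays so every property is assertable without
rendering: 1-D Grad-CAM heatmaps (single and multichannel), Integrated
Gradients with an explicit completeness gap, raw attention tensors from the
conformer encoder, and a seeded 2-D t-SNE projection of pooled embeddings.

A degenerate Grad-CAM map (all zero after the ReLU) is returned as zeros
rather than raising: a flat map is a legitimate finding about the model, not
an error condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import Model
from .nn.layers import Conv1D

__all__ = [
    "Heatmap1d", "Attribution",
    "grad_cam_1d", "grad_cam_multichannel",
    "integrated_gradients", "extract_attention", "tsne_embed",
]


@dataclass
class Heatmap1d:
    values: np.ndarray  # in [0, 1], length = input length
    target_class: int
    layer_name: str


@dataclass
class Attribution:
    values: np.ndarray  # signed, same shape as the input
    baseline: np.ndarray
    completeness_gap: float


def _prep_single(model: Model, x) -> np.ndarray:
    """Shape one input for explanation: (L,) → (1, L, 1); (L, C) → (1, L, C)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :, None]
    if x.ndim == 2:
        return x[None, :, :]
    if x.ndim == 3 and x.shape[0] == 1:
        return x
    raise ValueError("explanation methods take a single input at a time")


def _score_backward(model: Model, x: np.ndarray, target: int):
    """Forward in eval mode, then backpropagate the target-class score (the
    pre-softmax logit, or the raw output component for regressors).  Returns
    (layer outputs, gradients at each layer output, gradient wrt input)."""
    net = model.network
    out = net.forward(x, training=False)
    if not 0 <= target < out.shape[-1]:
        raise IndexError(f"target index {target} out of range for output "
                         f"dimension {out.shape[-1]}")
    dy = np.zeros_like(out)
    dy[:, target] = 1.0
    dx = net.backward(dy)
    return net.outputs, net.boundary_grads, dx


def _upsample_linear(values: np.ndarray, length: int) -> np.ndarray:
    if values.size == length:
        return values
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, values)


def grad_cam_1d(model: Model, x, target_class: int,
                conv_layer: str = "conv2") -> Heatmap1d:
    """Class-discriminative heatmap from a convolutional layer.

    Filter weights are the time-averaged gradients of the class score with
    respect to the layer's activations; the weighted activation sum is
    rectified, linearly upsampled to the input length, and min–max normalised
    to [0, 1] (identically zero maps stay zero).
    """
    layer = model.network.get(conv_layer)
    if not isinstance(layer, Conv1D):
        raise ValueError(f"layer {conv_layer!r} is not convolutional")
    xp = _prep_single(model, x)
    outputs, grads, _ = _score_backward(model, xp, target_class)
    activ = outputs[conv_layer][0]          # (L', filters)
    grad = grads[conv_layer][0]             # (L', filters)
    weights = grad.mean(axis=0)             # time-averaged per filter
    cam = np.maximum(activ @ weights, 0.0)  # ReLU(Σ_k w_k A_k)
    cam = _upsample_linear(cam, xp.shape[1])
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min())
    return Heatmap1d(values=cam, target_class=target_class, layer_name=conv_layer)


def grad_cam_multichannel(model: Model, x, target_class: int,
                          conv_layer: str = "conv2",
                          normalize: str = "joint") -> np.ndarray:
    """Per-input-channel heatmaps aligned to the time axis.

    The shared Grad-CAM time profile from the convolutional layer is
    distributed across input channels proportionally to each channel's share
    of the input-gradient magnitude at that time step (uniform where the
    gradient vanishes), then normalised: ``"joint"`` scales so the global
    maximum is 1, ``"per_channel"`` normalises each channel separately.
    Reduces exactly to :func:`grad_cam_1d` for single-channel input.
    """
    if normalize not in ("joint", "per_channel"):
        raise ValueError("normalize must be 'joint' or 'per_channel'")
    layer = model.network.get(conv_layer)
    if not isinstance(layer, Conv1D):
        raise ValueError(f"layer {conv_layer!r} is not convolutional")
    xp = _prep_single(model, x)
    outputs, grads, dx = _score_backward(model, xp, target_class)
    activ = outputs[conv_layer][0]
    grad = grads[conv_layer][0]
    cam = np.maximum(activ @ grad.mean(axis=0), 0.0)
    cam = _upsample_linear(cam, xp.shape[1])            # (L,)

    g = np.abs(dx[0])                                   # (L, C)
    totals = g.sum(axis=1, keepdims=True)
    share = np.where(totals > 0, g / np.where(totals > 0, totals, 1.0),
                     1.0 / g.shape[1])
    maps = (cam[:, None] * share).T                     # (C, L)
    if normalize == "joint":
        peak = maps.max()
        if peak > 0:
            maps = maps / peak
    else:
        peaks = maps.max(axis=1, keepdims=True)
        maps = np.where(peaks > 0, maps / np.where(peaks > 0, peaks, 1.0), 0.0)
    return maps


def integrated_gradients(model: Model, x, target: int,
                         baseline: np.ndarray | None = None,
                         steps: int = 50) -> Attribution:
    """Path-integral attribution from ``baseline`` (default zeros) to ``x``.

    Uses a midpoint Riemann approximation of the path integral:
    IG_i = (x_i − b_i) · mean_α ∂F_target/∂x_i at b + α(x − b); the
    completeness gap Σ IG − (F(x) − F(b)) is reported, and shrinks as
    ``steps`` grows.
    """
    xp = _prep_single(model, x)
    b = np.zeros_like(xp) if baseline is None else _prep_single(model, baseline)
    if b.shape != xp.shape:
        raise ValueError("baseline shape must match input shape")
    alphas = (np.arange(steps) + 0.5) / steps
    interp = b + alphas[:, None, None] * (xp - b)  # (steps, L, C)
    _, _, dx = _score_backward(model, interp, target)
    avg_grad = dx.mean(axis=0)
    ig = (xp[0] - b[0]) * avg_grad

    fx = model.network.forward(xp, training=False)[0, target]
    fb = model.network.forward(b, training=False)[0, target]
    gap = float(ig.sum() - (fx - fb))
    orig_shape = np.asarray(x, dtype=float).shape
    return Attribution(values=ig.reshape(orig_shape), baseline=b[0],
                       completeness_gap=gap)


def extract_attention(model: Model, x) -> np.ndarray:
    """Attention tensors from every encoder block of a conformer.

    Returns (layers × heads × length × length); every row is a distribution.
    """
    if model.kind != "conformer":
        raise ValueError("attention extraction requires a conformer model")
    xp = _prep_single(model, x)
    model.network.forward(xp, training=False)
    tensors = []
    for lyr in model.network:
        mha = getattr(lyr, "mha", None)
        if mha is not None and mha.last_attention is not None:
            tensors.append(mha.last_attention[0])
    if not tensors:
        raise ValueError("model has no attention layers to extract from")
    return np.stack(tensors)


def tsne_embed(features: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> np.ndarray:
    """Seeded 2-D t-SNE of embedding vectors (e.g. the pooled CNN features)."""
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"need more than 3×perplexity = {3 * perplexity:.0f} samples, got {n}"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(features)
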