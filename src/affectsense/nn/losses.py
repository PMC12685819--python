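"""Losses returning (scalar loss, gradient with respect to the logits/output).

All reductions are the batch mean; per-sample class weights multiply the
per-sample loss before reduction (so uniform weights of 1 reduce exactly to
the unweighted loss).
"""

from __future__ import annotations

import numpy as np

__all__ = ["softmax", "softmax_cross_entropy", "focal_loss_from_logits",
           "focal_loss", "smooth_l1_loss"]

_EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sample_weights(labels: np.ndarray,
                    class_weights: np.ndarray | None) -> np.ndarray:
    if class_weights is None:
        return np.ones(labels.shape[0])
    return np.asarray(class_weights, dtype=float)[labels]


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Sparse categorical cross-entropy with optional per-class weighting."""
    labels = np.asarray(labels, dtype=int)
    b = logits.shape[0]
    p = softmax(logits)
    w = _sample_weights(labels, class_weights)
    py = np.clip(p[np.arange(b), labels], _EPS, 1.0)
    loss = float((w * -np.log(py)).mean())
    grad = p.copy()
    grad[np.arange(b), labels] -= 1.0
    grad *= (w / b)[:, None]
    return loss, grad


def focal_loss_from_logits(
    logits: np.ndarray, labels: np.ndarray, gamma: float = 2.0,
    alpha: np.ndarray | float | None = None,
) -> tuple[float, np.ndarray]:
    """Focal loss −α_y (1 − p_y)^γ log p_y (natural log), mean over the batch.

    γ = 0 with α = 1 reduces exactly to cross-entropy.  The gradient with
    respect to the logits is analytic:
    dL/dz_j = (dL/dp_y) · p_y (δ_jy − p_j).
    """
    labels = np.asarray(labels, dtype=int)
    b = logits.shape[0]
    p = softmax(logits)
    py = np.clip(p[np.arange(b), labels], _EPS, 1.0 - _EPS)
    if alpha is None:
        a = np.ones(b)
    elif np.isscalar(alpha):
        a = np.full(b, float(alpha))
    else:
        a = np.asarray(alpha, dtype=float)[labels]
    one_minus = 1.0 - py
    loss = float((a * one_minus ** gamma * -np.log(py)).mean())
    # dL/dp_y for a single sample
    dldp = a * (gamma * one_minus ** (gamma - 1.0) * np.log(py)
                - one_minus ** gamma / py)
    onehot = np.zeros_like(p)
    onehot[np.arange(b), labels] = 1.0
    grad = (dldp * py)[:, None] * (onehot - p) / b
    return loss, grad


def focal_loss(probs: np.ndarray, labels: np.ndarray, gamma: float = 2.0,
               alpha: np.ndarray | float | None = None) -> float:
    """Focal loss evaluated on probabilities (rows summing to 1)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    b = probs.shape[0]
    py = np.clip(probs[np.arange(b), labels], _EPS, 1.0)
    if alpha is None:
        a = np.ones(b)
    elif np.isscalar(alpha):
        a = np.full(b, float(alpha))
    else:
        a = np.asarray(alpha, dtype=float)[labels]
    return float((a * (1.0 - py) ** gamma * -np.log(py)).mean())


def smooth_l1_loss(pred: np.ndarray, target: np.ndarray,
                   beta: float = 1.0) -> tuple[float, np.ndarray]:
    """Smooth-L1 (Huber): e²/(2β) for |e| < β, |e| − β/2 otherwise; mean over
    all entries."""
    e = pred - target
    ae = np.abs(e)
    loss = float(np.where(ae < beta, e ** 2 / (2 * beta), ae - beta / 2).mean())
    grad = np.where(ae < beta, e / beta, np.sign(e)) / e.size
    return loss, grad
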