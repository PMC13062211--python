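"""Training objective: pixel-wise cross-entropy plus focal loss.

For per-pixel class probabilities ``p`` and one-hot targets ``y``::

    L_CE    = -sum_c y_c log p_c
    L_focal = -sum_c alpha_c (1 - p_c)^gamma y_c log p_c
    L_total = L_CE + L_focal

Both terms are averaged over all pixels in the batch (scale-invariant
across image sizes).  Defaults alpha_c = 1 and gamma = 2 are the canonical
focal-loss setting; probabilities are clamped at 1e-12 before the log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = ["LossConfig", "ce_loss", "focal_loss", "total_loss", "total_loss_on_logits"]

_CLAMP = 1e-12


@dataclass(frozen=True)
class LossConfig:
    alpha: tuple[float, ...] | None = None   # per-class weights; None -> all ones
    gamma: float = 2.0
    reduction: str = "mean_over_pixels"

    def validate(self, n_classes: int) -> np.ndarray:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.reduction != "mean_over_pixels":
            raise ValueError(f"unsupported reduction {self.reduction!r}")
        if self.alpha is None:
            return np.ones(n_classes)
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (n_classes,):
            raise ValueError(f"alpha must have length {n_classes}, got {alpha.shape}")
        if (alpha < 0).any():
            raise ValueError("alpha weights must be >= 0")
        return alpha


def _as_probs_target(probs, target):
    p = np.asarray(getattr(probs, "probs", probs), dtype=float)
    t = np.asarray(target)
    if p.shape[:-1] != t.shape:
        raise ValueError(f"probs spatial shape {p.shape[:-1]} != target shape {t.shape}")
    k = p.shape[-1]
    if t.min() < 0 or t.max() >= k:
        raise ValueError(f"target ids must be in [0, {k}), got range [{t.min()}, {t.max()}]")
    return p.reshape(-1, k), t.ravel(), k


def ce_loss(probs, target, cfg: LossConfig = LossConfig()) -> float:
    """Mean per-pixel cross-entropy of channel-last probabilities."""
    p, t, k = _as_probs_target(probs, target)
    cfg.validate(k)
    p_true = np.clip(p[np.arange(t.size), t], _CLAMP, None)
    return float(-np.log(p_true).mean())


def focal_loss(probs, target, cfg: LossConfig = LossConfig()) -> float:
    """Mean per-pixel focal loss with class weights alpha and focus gamma."""
    p, t, k = _as_probs_target(probs, target)
    alpha = cfg.validate(k)
    p_true = np.clip(p[np.arange(t.size), t], _CLAMP, None)
    mod = alpha[t] * (1.0 - p_true) ** cfg.gamma
    return float(-(mod * np.log(p_true)).mean())


def total_loss(probs, target, cfg: LossConfig = LossConfig()) -> float:
    """Sum of cross-entropy and focal terms (equal weighting)."""
    return ce_loss(probs, target, cfg) + focal_loss(probs, target, cfg)


def total_loss_on_logits(logits: Tensor, target: np.ndarray,
                         cfg: LossConfig = LossConfig()) -> Tensor:
    """Differentiable CE + focal loss on raw logits of shape (N, K, H, W).

    Numerically identical (up to the log-softmax clamp) to evaluating
    :func:`total_loss` on the softmax probabilities; used by the training
    loop where gradients are required.
    """
    n, k, h, w = logits.shape
    t = np.asarray(target).reshape(n, h, w)
    alpha = cfg.validate(k)
    logp = logits.log_softmax(axis=1)              # (n, k, h, w)
    onehot = np.zeros((n, k, h, w), dtype=logits.data.dtype)
    np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
    logp_true = (logp * Tensor(onehot)).sum(axis=1)          # (n, h, w)
    ce = -logp_true.mean()
    p_true = logp_true.exp()
    a = alpha[t].astype(logits.data.dtype)
    focal = -((1.0 - p_true) ** cfg.gamma * Tensor(a) * logp_true).mean()
    return ce + focal
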