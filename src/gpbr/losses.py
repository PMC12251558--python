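"""Competitive fusion learning objective.

Three terms drive the dual-branch training:

* focal loss ``L_fl`` on the softmax of the mean branch scores, with
  class-balancing weights alpha (inverse class frequency, normalised so
  that a balanced set gives alpha = 1) and focusing exponent gamma
  (default 2) — handles the heavy class imbalance of behaviour data;
* overlapped activation penalty ``L_oap = (1/C) sum_j sum_{x,y}
  a1_j * a2_j`` on the sigmoid masks of the two branches' CAMs — pushes
  the branches to attend to different time-frequency regions (the sum
  runs over all spatial cells, so the value scales with h*w);
* balance score penalty ``L_bsp = (1/C) sum_j |S1_j - S2_j|`` — mean
  absolute difference of the branch scores, keeping the competition even
  and, once the competition weight decays, pulling the branches together.

The total is ``L = L_fl + lambda * L_oap + L_bsp`` with lambda decaying
linearly from 1 to 0 over the training epochs, so competition is strong
early and vanishes by the final epoch.

Everything here funnels through the CAM tensors M1, M2 (scores are their
spatial means), so :func:`total_loss_grads` returns d L/d M1 and
d L/d M2 for backpropagation into the heads and backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaskField", "ClassWeights", "LossBreakdown",
    "mask_from_cam", "oap_loss", "bsp_loss", "class_weights", "focal_loss",
    "lambda_schedule", "total_loss", "total_loss_grads",
]

_LOG_CLAMP = 1e-12


@dataclass
class MaskField:
    """Sigmoid CAM masks, elementwise in the open interval (0, 1)."""

    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        if np.any(self.a <= 0) or np.any(self.a >= 1):
            raise ValueError("mask values must lie strictly in (0, 1)")


@dataclass
class ClassWeights:
    """Non-negative class-balancing factors summing to C."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if np.any(self.alpha < 0):
            raise ValueError("class weights must be non-negative")
        if not math.isclose(self.alpha.sum(), self.alpha.size, rel_tol=1e-9):
            raise ValueError("class weights must sum to the number of classes")


@dataclass
class LossBreakdown:
    l_fl: float
    l_oap: float
    l_bsp: float
    lambda_t: float

    @property
    def l_total(self) -> float:
        return self.l_fl + self.lambda_t * self.l_oap + self.l_bsp


def mask_from_cam(M: np.ndarray) -> MaskField:
    """Elementwise sigmoid of a CAM tensor."""
    M = np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(M)):
        raise ValueError("CAM contains non-finite values")
    a = 1.0 / (1.0 + np.exp(-M))
    eps = np.finfo(np.float64).tiny
    return MaskField(a=np.clip(a, eps, 1.0 - np.finfo(np.float64).epsneg))


def oap_loss(a1: MaskField, a2: MaskField, n_classes: int | None = None) -> float:
    """Overlap penalty: spatial sum of the mask product, averaged over classes.

    Masks are indexed (..., C, h, w); the class axis is assumed to be the
    third from the end (a leading batch axis, if present, is averaged).
    """
    x1, x2 = a1.a, a2.a
    if x1.shape != x2.shape:
        raise ValueError(f"mask shape mismatch: {x1.shape} vs {x2.shape}")
    C = n_classes if n_classes is not None else x1.shape[-3]
    per = (x1 * x2).sum(axis=(-1, -2, -3)) / C
    return float(np.mean(per))


def bsp_loss(S1: np.ndarray, S2: np.ndarray) -> float:
    """Balance score penalty: mean absolute difference of branch scores."""
    S1, S2 = np.asarray(S1, dtype=np.float64), np.asarray(S2, dtype=np.float64)
    if S1.shape != S2.shape:
        raise ValueError(f"score shape mismatch: {S1.shape} vs {S2.shape}")
    return float(np.mean(np.abs(S1 - S2).mean(axis=-1)))


def class_weights(class_counts) -> ClassWeights:
    """Inverse-frequency class weights normalised to sum to C."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if np.any(counts < 1):
        raise ValueError("every class must have at least one training sample")
    inv = 1.0 / counts
    return ClassWeights(alpha=inv * counts.size / inv.sum())


def focal_loss(y: np.ndarray, t: np.ndarray, alpha: ClassWeights,
               gamma: float = 2.0) -> float:
    """Focal loss -sum_j alpha_j (1 - y_j)^gamma t_j log(y_j).

    ``y`` is a probability vector (or batch of them), ``t`` the matching
    one-hot label(s).
    """
    y = np.asarray(y, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if y.shape != t.shape:
        raise ValueError("probability and label shapes differ")
    if not np.allclose(y.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("probabilities must sum to 1")
    if np.any(y[t > 0] <= 0):
        raise ValueError("probability at the true class must be positive")
    logy = np.log(np.maximum(y, _LOG_CLAMP))
    per = -(alpha.alpha * (1.0 - y) ** gamma * t * logy).sum(axis=-1)
    return float(np.mean(per))


def lambda_schedule(epoch: int, total_epochs: int, kind: str = "linear") -> float:
    """Competition weight, decaying from 1 (first epoch) to 0 (last epoch)."""
    if total_epochs < 2:
        raise ValueError("total_epochs must be >= 2")
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    frac = epoch / (total_epochs - 1)
    if kind == "linear":
        return 1.0 - frac
    if kind == "cosine":
        return 0.5 * (1.0 + math.cos(math.pi * frac))
    raise ValueError(f"unknown lambda schedule {kind!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def total_loss(M1: np.ndarray, M2: np.ndarray, t: np.ndarray,
               alpha: ClassWeights, gamma: float = 2.0,
               lambda_t: float = 1.0, bsp_weight: float = 1.0) -> LossBreakdown:
    """Composite loss from the two branches' CAM tensors.

    ``M1``/``M2`` are (N, C, h, w) (or unbatched (C, h, w)); ``t`` the
    one-hot labels (N, C). Scores are the CAMs' spatial means, the focal
    term uses the softmax of the mean scores.
    """
    M1, M2 = np.asarray(M1, dtype=np.float64), np.asarray(M2, dtype=np.float64)
    if M1.ndim == 3:
        M1, M2, t = M1[None], M2[None], np.asarray(t)[None]
    S1, S2 = M1.mean(axis=(-1, -2)), M2.mean(axis=(-1, -2))
    y = _softmax(0.5 * (S1 + S2))
    l_fl = focal_loss(y, t, alpha, gamma)
    l_oap = oap_loss(mask_from_cam(M1), mask_from_cam(M2))
    l_bsp = bsp_weight * bsp_loss(S1, S2)
    return LossBreakdown(l_fl=l_fl, l_oap=l_oap, l_bsp=l_bsp, lambda_t=lambda_t)


def total_loss_grads(M1: np.ndarray, M2: np.ndarray, t: np.ndarray,
                     alpha: ClassWeights, gamma: float = 2.0,
                     lambda_t: float = 1.0, bsp_weight: float = 1.0):
    """Analytic d L_total / d M1 and d M2, batch-averaged like the loss.

    Returns ``(breakdown, gM1, gM2)``. The focal term reaches the CAMs
    through the mean scores (each score is the spatial mean of its map and
    the branch mean halves the gradient); the overlap term acts pointwise
    through the sigmoid masks; the balance term contributes the sign of
    the score gap spread uniformly over each map.
    """
    M1, M2 = np.asarray(M1, dtype=np.float64), np.asarray(M2, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    squeeze = M1.ndim == 3
    if squeeze:
        M1, M2, t = M1[None], M2[None], t[None]
    n, C, h, w = M1.shape
    hw = h * w
    S1, S2 = M1.mean(axis=(-1, -2)), M2.mean(axis=(-1, -2))
    y = _softmax(0.5 * (S1 + S2))

    # focal term: dL/dy then softmax Jacobian product, batch-averaged
    logy = np.log(np.maximum(y, _LOG_CLAMP))
    one_my = 1.0 - y
    dl_dy = -alpha.alpha * t * (
        one_my ** gamma / np.maximum(y, _LOG_CLAMP)
        - gamma * one_my ** np.maximum(gamma - 1.0, 0.0) * logy
    )
    dl_dSbar = y * (dl_dy - (dl_dy * y).sum(axis=-1, keepdims=True))
    g_score_fl = dl_dSbar / (2.0 * n)          # per-branch score gradient
    # bsp term (bsp_weight = 0 disables it for ablations)
    g_score_bsp = bsp_weight * np.sign(S1 - S2) / (C * n)
    gS1 = g_score_fl + g_score_bsp
    gS2 = g_score_fl - g_score_bsp
    gM1 = np.broadcast_to(gS1[:, :, None, None], M1.shape) / hw
    gM2 = np.broadcast_to(gS2[:, :, None, None], M2.shape) / hw
    # oap term
    a1, a2 = mask_from_cam(M1).a, mask_from_cam(M2).a
    scale = lambda_t / (C * n)
    gM1 = gM1 + scale * a2 * a1 * (1.0 - a1)
    gM2 = gM2 + scale * a1 * a2 * (1.0 - a2)

    breakdown = LossBreakdown(
        l_fl=focal_loss(y, t, alpha, gamma),
        l_oap=oap_loss(MaskField(a1), MaskField(a2)),
        l_bsp=bsp_weight * bsp_loss(S1, S2),
        lambda_t=lambda_t,
    )
    if squeeze:
        gM1, gM2 = gM1[0], gM2[0]
    return breakdown, np.ascontiguousarray(gM1), np.ascontiguousarray(gM2)
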