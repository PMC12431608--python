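"""Task-adaptive late fusion of the image and text branches.

Per episode, both branches predict the *support* set; their cross-entropy
losses L_img and L_txt gauge how reliable each modality is on this task.
Raw weights are the inverse losses w = 1/(L + eps), normalized to convex
coefficients alpha, then smoothed toward the equal split:

    alpha_final = (1 - beta) * alpha + beta * 0.5,     beta in [0, 1]

(beta = 0: fully dynamic; beta = 1: plain averaging).  Query probability
vectors are fused as alpha_img * P_img + alpha_txt * P_txt.

Also provided: degenerate unimodal weights when one modality is missing, a
confidence-based weighting used as an ablation arm, and weighted fusion of
normalized activation maps for qualitative inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ModalityLosses",
    "FusionWeights",
    "support_set_loss",
    "dynamic_weights",
    "smooth_weights",
    "fuse_predictions",
    "unimodal_weights",
    "confidence_weights",
    "fuse_activation_maps",
]

#: floor applied to predicted probabilities before taking logs
PROB_FLOOR = 1e-12
#: default guard against division by a zero loss
DEFAULT_EPSILON = 1e-8
#: default smoothing factor
DEFAULT_BETA = 0.5


@dataclass(frozen=True)
class ModalityLosses:
    """Support-set cross-entropy losses of the two branches."""

    loss_img: float
    loss_txt: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        for name in ("loss_img", "loss_txt"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class FusionWeights:
    """Convex modality coefficients at a given processing stage."""

    alpha_img: float
    alpha_txt: float
    beta: float = DEFAULT_BETA
    stage: Literal["raw", "normalized", "smoothed"] = "normalized"

    def __post_init__(self) -> None:
        if self.stage in ("normalized", "smoothed"):
            if not (0.0 <= self.alpha_img <= 1.0 and 0.0 <= self.alpha_txt <= 1.0):
                raise ValueError("normalized weights must lie in [0, 1]")
            if abs(self.alpha_img + self.alpha_txt - 1.0) > 1e-12:
                raise ValueError("normalized weights must sum to 1")


def support_set_loss(
    predictions: Sequence[np.ndarray], labels: Sequence[int]
) -> float:
    """Mean cross-entropy of predicted distributions against true labels.

    The mean (not the sum) is used so the number of support items does not
    rescale the loss; probabilities are floored at 1e-12 before the log.
    """
    if len(predictions) == 0:
        raise ValueError("support set is empty")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    total = 0.0
    for p, y in zip(predictions, labels):
        p = np.asarray(p, dtype=float)
        if not 0 <= y < p.size:
            raise ValueError(f"label {y} out of range for {p.size} classes")
        total += -np.log(max(p[y], PROB_FLOOR))
    return total / len(predictions)


def dynamic_weights(ml: ModalityLosses) -> FusionWeights:
    """Inverse-loss weights, normalized to a convex pair (stage=normalized)."""
    w_img = 1.0 / (ml.loss_img + ml.epsilon)
    w_txt = 1.0 / (ml.loss_txt + ml.epsilon)
    s = w_img + w_txt
    return FusionWeights(alpha_img=w_img / s, alpha_txt=w_txt / s, stage="normalized")


def smooth_weights(fw: FusionWeights, beta: float = DEFAULT_BETA) -> FusionWeights:
    """Interpolate dynamic weights toward the equal 0.5/0.5 split."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must lie in [0, 1], got {beta}")
    if fw.stage != "normalized":
        raise ValueError("smoothing expects normalized weights")
    a_img = (1.0 - beta) * fw.alpha_img + beta * 0.5
    a_txt = (1.0 - beta) * fw.alpha_txt + beta * 0.5
    return FusionWeights(alpha_img=a_img, alpha_txt=a_txt, beta=beta, stage="smoothed")


def fuse_predictions(
    p_img: np.ndarray, p_txt: np.ndarray, fw: FusionWeights
) -> np.ndarray:
    """Convex combination of the two branch probability vectors."""
    if fw.stage == "raw":
        raise ValueError("fusion requires normalized or smoothed weights")
    a = np.asarray(p_img, dtype=float)
    b = np.asarray(p_txt, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"branch predictions differ in shape: {a.shape} vs {b.shape}")
    return fw.alpha_img * a + fw.alpha_txt * b


def unimodal_weights(available: Literal["image_only", "text_only"]) -> FusionWeights:
    """Degenerate weights when one modality is unavailable (no smoothing)."""
    if available == "image_only":
        return FusionWeights(alpha_img=1.0, alpha_txt=0.0, stage="normalized")
    if available == "text_only":
        return FusionWeights(alpha_img=0.0, alpha_txt=1.0, stage="normalized")
    raise ValueError("available must be 'image_only' or 'text_only'")


def confidence_weights(
    support_preds_img: Sequence[np.ndarray],
    support_preds_txt: Sequence[np.ndarray],
) -> FusionWeights:
    """Confidence-based ablation arm: weight by mean max class probability.

    An interpretation of adaptive confidence-weighted dynamic fusion used
    only as a comparison strategy; the raw weight of each modality is its
    mean top-1 probability over support items, normalized as usual.
    """
    if len(support_preds_img) == 0 or len(support_preds_txt) == 0:
        raise ValueError("support predictions must be non-empty for both modalities")
    w_img = float(np.mean([np.asarray(p, dtype=float).max() for p in support_preds_img]))
    w_txt = float(np.mean([np.asarray(p, dtype=float).max() for p in support_preds_txt]))
    s = w_img + w_txt
    return FusionWeights(alpha_img=w_img / s, alpha_txt=w_txt / s, stage="normalized")


def _minmax(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi == lo:  # constant map carries no localization signal
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def fuse_activation_maps(
    map_img: np.ndarray, map_txt: np.ndarray, fw: FusionWeights
) -> np.ndarray:
    """Min-max normalize each activation map to [0, 1], then weight-sum them."""
    a = np.asarray(map_img, dtype=float)
    b = np.asarray(map_txt, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"activation maps differ in shape: {a.shape} vs {b.shape}")
    return fw.alpha_img * _minmax(a) + fw.alpha_txt * _minmax(b)
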