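"""Training objectives for recall-first segmentation.

The main branch is optimised with HistoLoss, a fixed 0.3/0.7 blend of
binary cross-entropy and Tversky loss. The Tversky term weights false
negatives more heavily than false positives (beta = 0.7 vs alpha = 0.3),
which mechanically biases optimisation toward recall. The auxiliary edge
branch is supervised with BCE against a morphological-gradient edge map
(dilation minus erosion, both approximated by 3x3 max-pooling so the
construction stays differentiable). The total objective is
1.0 * HistoLoss + 0.4 * edge BCE.

Soft confusion counts are pooled over the whole batch; epsilon smoothing
and a probability clamp of 1e-7 keep everything finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter, minimum_filter

from .nn import Tensor

__all__ = [
    "LossWeights", "bce_loss", "tversky_loss", "histo_loss",
    "edge_target", "edge_loss", "total_loss",
]

_CLAMP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.3        # Tversky false-positive weight
    beta: float = 0.7         # Tversky false-negative weight
    epsilon: float = 1e-6
    w_bce: float = 0.3
    w_tversky: float = 0.7
    w_histo: float = 1.0
    w_edge: float = 0.4

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.epsilon, self.w_bce,
                self.w_tversky, self.w_histo, self.w_edge)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be non-negative")
        if abs(self.w_bce + self.w_tversky - 1.0) > 1e-12:
            raise ValueError("w_bce + w_tversky must equal 1")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _check_shapes(pred: Tensor, target: Tensor) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")


def bce_loss(pred, target) -> Tensor:
    """Mean binary cross-entropy over all pixels."""
    pred, target = _as_tensor(pred), _as_tensor(target)
    _check_shapes(pred, target)
    p = pred.clip(_CLAMP, 1.0 - _CLAMP)
    nll = -(target * p.log() + (1.0 - target) * (1.0 - p).log())
    return nll.mean()


def tversky_loss(pred, target, w: LossWeights = LossWeights()) -> Tensor:
    """1 - (TP + eps) / (TP + alpha*FP + beta*FN + eps) on batch-pooled
    soft counts TP = sum(p*y), FP = sum(p*(1-y)), FN = sum((1-p)*y)."""
    pred, target = _as_tensor(pred), _as_tensor(target)
    _check_shapes(pred, target)
    tp = (pred * target).sum()
    fp = (pred * (1.0 - target)).sum()
    fn = ((1.0 - pred) * target).sum()
    return 1.0 - (tp + w.epsilon) / (tp + w.alpha * fp + w.beta * fn + w.epsilon)


def histo_loss(pred, target, w: LossWeights = LossWeights()) -> Tensor:
    return w.w_bce * bce_loss(pred, target) + \
        w.w_tversky * tversky_loss(pred, target, w)


def edge_target(mask: np.ndarray) -> np.ndarray:
    """Binary morphological-gradient edge map of a binary mask.

    Dilation is a 3x3 maximum filter; erosion is 1 - maxfilter(1 - X),
    i.e. a minimum filter. Out-of-frame pixels count as foreground for
    the erosion (cval=1) and background for the dilation (cval=0), so a
    mask touching the border produces no spurious frame edge and an
    all-ones mask yields no edge at all. Accepts (..., H, W) arrays.
    """
    mask = np.asarray(mask)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("edge_target expects a binary {0,1} mask")
    mask = mask.astype(np.float64)
    size = (1,) * (mask.ndim - 2) + (3, 3)
    dil = maximum_filter(mask, size=size, mode="constant", cval=0.0)
    ero = minimum_filter(mask, size=size, mode="constant", cval=1.0)
    return (dil - ero).astype(np.uint8)


def edge_loss(edge_pred, edge_tgt) -> Tensor:
    """Mean BCE between the edge probability map and its binary target."""
    return bce_loss(edge_pred, _as_tensor(np.asarray(edge_tgt, dtype=np.float64)))


def total_loss(pred, edge_pred, target,
               w: LossWeights = LossWeights()) -> tuple[Tensor, dict]:
    """w_histo * HistoLoss + w_edge * edge BCE.

    The edge target is derived internally from `target`. Returns the
    scalar loss tensor plus a component breakdown for logging. When the
    model has no edge branch pass edge_pred=None; the edge term is then
    dropped (equivalent to w_edge = 0).
    """
    target_arr = np.asarray(target if not isinstance(target, Tensor) else target.data)
    lh = histo_loss(pred, target, w)
    components = {
        "bce": bce_loss(pred, target).item(),
        "tversky": tversky_loss(pred, target, w).item(),
        "histo": lh.item(),
    }
    total = w.w_histo * lh
    if edge_pred is not None and w.w_edge > 0:
        tgt = edge_target(target_arr.astype(np.uint8))
        le = edge_loss(edge_pred, tgt)
        components["edge"] = le.item()
        total = total + w.w_edge * le
    else:
        components["edge"] = 0.0
    components["total"] = total.item()
    return total, components
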