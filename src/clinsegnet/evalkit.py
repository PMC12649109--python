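"""Recall-first evaluation utilities.

All metrics derive from pixel confusion counts at a fixed 0.5 threshold:
recall = TP/(TP+FN), precision = TP/(TP+FP), Dice = 2TP/(2TP+FP+FN),
IoU = TP/(TP+FP+FN). Reports average per-image metrics (a pixel-pooled
alternative is available behind a flag). The false-negative-reduction
statistic converts a recall difference into the relative change in missed
detections under an equal-true-positive assumption:

    FNR = 1 - (1/R_ours - 1) / (1/R_baseline - 1)

positive when the evaluated model misses fewer pixels than the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts", "confusion", "metrics", "fn_reduction",
    "improvement_pct", "per_organ_report", "paired_tests", "heatmap_overlay",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(prob: np.ndarray, mask: np.ndarray,
              threshold: float = 0.5) -> ConfusionCounts:
    """Pixel confusion counts of `prob >= threshold` against a binary mask."""
    prob = np.asarray(prob)
    mask = np.asarray(mask)
    if prob.shape != mask.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {mask.shape}")
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary {0,1}")
    pred = prob >= threshold
    pos = mask.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)), FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)), TN=int(np.sum(~pred & ~pos)))


def _safe_ratio(num: int, den: int, empty_value: float) -> float:
    return num / den if den > 0 else empty_value


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Confusion-derived metrics with the empty-image convention: when an
    image has no positive ground truth, metrics are 1.0 if the prediction
    is also empty and 0.0 otherwise."""
    empty_gt = (c.TP + c.FN) == 0
    empty_pred = (c.TP + c.FP) == 0
    degenerate = 1.0 if (empty_gt and empty_pred) else 0.0
    return {
        "recall": _safe_ratio(c.TP, c.TP + c.FN, degenerate),
        "precision": _safe_ratio(c.TP, c.TP + c.FP, degenerate),
        "dice": _safe_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, degenerate),
        "iou": _safe_ratio(c.TP, c.TP + c.FP + c.FN, degenerate),
    }


def fn_reduction(r_ours: float, r_baseline: float) -> float:
    """Relative false-negative reduction versus a baseline, as a fraction.

    Requires recalls in (0, 1] and a baseline recall strictly below 1
    (a perfect baseline has no misses to reduce).
    """
    for name, r in (("r_ours", r_ours), ("r_baseline", r_baseline)):
        if not 0.0 < r <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {r}")
    if r_baseline == 1.0:
        raise ValueError("fn_reduction undefined for a baseline recall of 1")
    return 1.0 - (1.0 / r_ours - 1.0) / (1.0 / r_baseline - 1.0)


def improvement_pct(before: float, after: float) -> float:
    """Relative change in percent, 100 * (after - before) / before."""
    if before <= 0:
        raise ValueError("before must be positive")
    return 100.0 * (after - before) / before


def per_organ_report(probs, masks, organs, threshold: float = 0.5,
                     pixel_pooled: bool = False) -> pd.DataFrame:
    """Per-organ metric table plus an aggregate row.

    Default: metrics per image, then averaged within organ; the aggregate
    row is the mean over all images. With pixel_pooled=True, confusion
    counts are pooled over pixels before computing metrics.
    """
    organs = list(organs)
    if not (len(probs) == len(masks) == len(organs)):
        raise ValueError("probs, masks and organs must have equal length")
    per_image = []
    counts = []
    for prob, mask, organ in zip(probs, masks, organs):
        c = confusion(np.asarray(prob), np.asarray(mask), threshold)
        counts.append((organ, c))
        per_image.append({"organ": organ, **metrics(c)})
    df = pd.DataFrame(per_image)
    metric_cols = ["recall", "precision", "dice", "iou"]
    if pixel_pooled:
        rows = []
        for organ in sorted(df["organ"].unique()):
            pooled = _pool([c for o, c in counts if o == organ])
            rows.append({"organ": organ, "n_images":
                         int((df["organ"] == organ).sum()), **metrics(pooled)})
        agg = {"organ": "all", "n_images": len(df),
               **metrics(_pool([c for _, c in counts]))}
    else:
        rows = [{"organ": organ,
                 "n_images": int((df["organ"] == organ).sum()),
                 **df[df["organ"] == organ][metric_cols].mean().to_dict()}
                for organ in sorted(df["organ"].unique())]
        agg = {"organ": "all", "n_images": len(df),
               **df[metric_cols].mean().to_dict()}
    return pd.DataFrame(rows + [agg])


def _pool(counts: list[ConfusionCounts]) -> ConfusionCounts:
    return ConfusionCounts(TP=sum(c.TP for c in counts),
                           FP=sum(c.FP for c in counts),
                           FN=sum(c.FN for c in counts),
                           TN=sum(c.TN for c in counts))


def paired_tests(before, after) -> dict:
    """Two-sided paired t-test and Wilcoxon signed-rank test on per-organ
    values, with the mean difference and its 95% CI. All-zero differences
    leave the Wilcoxon statistic undefined (reported as NaN)."""
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length 1-D vectors")
    n = before.size
    if n < 5:
        raise ValueError("need at least 5 paired values")
    diff = after - before
    mean_diff = float(diff.mean())
    if np.allclose(diff, 0.0):
        t_p = w_p = float("nan")
        ci = (0.0, 0.0)
    else:
        t_res = stats.ttest_rel(after, before)
        t_p = float(t_res.pvalue)
        try:
            w_p = float(stats.wilcoxon(after, before).pvalue)
        except ValueError:
            w_p = float("nan")
        sem = diff.std(ddof=1) / np.sqrt(n)
        half = stats.t.ppf(0.975, n - 1) * sem
        ci = (mean_diff - half, mean_diff + half)
    return {"t_p": t_p, "wilcoxon_p": w_p, "mean_diff": mean_diff,
            "ci95": (float(ci[0]), float(ci[1]))}


def heatmap_overlay(image: np.ndarray, prob: np.ndarray, out) -> np.ndarray:
    """Write a probability heatmap alpha-blended on the greyscale image.

    Warmer colours mean higher probability; a zero probability map leaves
    the greyscale base untouched. Returns the blended RGB array.
    """
    from matplotlib import cm
    import imageio.v3 as iio

    image = np.asarray(image, dtype=np.float64)
    prob = np.asarray(prob, dtype=np.float64)
    if image.ndim == 3:
        from .dataprep import to_greyscale
        image = to_greyscale(image)
    if image.shape != prob.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {prob.shape}")
    base = np.dstack([image] * 3)
    colour = cm.jet(prob)[..., :3]
    alpha = prob[..., None]
    blended = (1.0 - alpha) * base + alpha * colour
    arr = np.clip(np.round(blended * 255), 0, 255).astype(np.uint8)
    if out is not None:
        iio.imwrite(out, arr)
    return blended
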