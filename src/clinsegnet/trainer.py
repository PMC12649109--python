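"""Training loop and the offline human-in-the-loop (HITL) stage.

Main training optimises the composite objective (HistoLoss + 0.4 * edge
BCE) with Adam at lr 5e-4, batch size 8, for up to 50 epochs, keeping the
checkpoint with the best validation recall at threshold 0.5 — recall is
the selection criterion because the framework is built to minimise missed
detections.

The offline HITL stage simulates expert correction: per-pixel predictive
entropy ranks the pool, the most uncertain samples of each organ class
are selected (ratio 0.30 of the class, floor of 2 per class), and only
the last two decoder stages, their FiLM conditioning and the output layer
are fine-tuned (Adam lr 2e-4, weight decay 1e-2, batch size 8, 8 epochs,
one-cycle schedule, EMA of the unfrozen weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evalkit
from .dataprep import SampleRecord, load_pair
from .losses import LossWeights, total_loss
from .network import ClinSegNet, SegmentationOutput
from .nn import EMA, Adam, OneCycleLR, no_grad

__all__ = [
    "TrainConfig", "HITLConfig", "UncertaintyScore",
    "train", "sample_entropy", "select_hitl_subset", "finetune_hitl",
    "hitl_round", "evaluate",
]

# parameter-name prefixes of decoder stages 6 and 7 (their up-convolutions,
# conv blocks, SE and FiLM modules) and the output 1x1 convolution
HITL_UNFROZEN_PREFIXES = ("up6", "dec6", "up7", "dec7", "out_conv")


@dataclass(frozen=True)
class TrainConfig:
    optimiser: str = "adam"
    lr: float = 5e-4
    batch_size: int = 8
    max_epochs: int = 50
    input_size: int = 224
    selection_metric: str = "recall"
    threshold: float = 0.5
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)


@dataclass(frozen=True)
class HITLConfig:
    hitl_ratio: float = 0.30
    min_per_class: int = 2
    lr: float = 2e-4
    weight_decay: float = 1e-2
    batch_size: int = 8
    epochs: int = 8
    scheduler: str = "one-cycle"
    ema_decay: float = 0.999
    threshold: float = 0.5
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)


@dataclass(frozen=True)
class UncertaintyScore:
    sample_id: str
    entropy: float      # nats, in [0, ln 2]


# ----------------------------------------------------------------------
# data plumbing
# ----------------------------------------------------------------------

def _prepare(records: list[SampleRecord], model: ClinSegNet, size: int):
    images, masks, labels, organs = [], [], [], []
    for rec in records:
        img, msk = load_pair(rec, size=size)
        images.append(img)
        masks.append(msk)
        labels.append(model.vocabulary.label(rec.organ))
        organs.append(rec.organ)
    return (np.stack(images), np.stack(masks),
            np.asarray(labels, dtype=np.int64), organs)


def _batches(n: int, batch_size: int, rng: np.random.Generator | None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def evaluate(model: ClinSegNet, images: np.ndarray, masks: np.ndarray,
             labels: np.ndarray, threshold: float = 0.5,
             batch_size: int = 8) -> dict[str, float]:
    """Mean per-image metrics at the given threshold."""
    rows = []
    with no_grad():
        for idx in _batches(len(images), batch_size, None):
            prob = model.forward(images[idx], labels[idx]).prob.data
            for p, m in zip(prob, masks[idx]):
                rows.append(evalkit.metrics(
                    evalkit.confusion(p, m, threshold)))
    return {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}


# ----------------------------------------------------------------------
# main training
# ----------------------------------------------------------------------

def train(model: ClinSegNet, train_records: list[SampleRecord],
          val_records: list[SampleRecord],
          cfg: TrainConfig = TrainConfig()) -> pd.DataFrame:
    """Optimise the composite loss; restore the best-validation-recall
    weights into the model on return. Returns the epoch history."""
    if not train_records or not val_records:
        raise ValueError("train and validation splits must be non-empty")
    size = cfg.input_size
    tr_imgs, tr_masks, tr_labels, _ = _prepare(train_records, model, size)
    va_imgs, va_masks, va_labels, _ = _prepare(val_records, model, size)

    params = model.named_parameters()
    opt = Adam(params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history = []
    best_metric = -np.inf
    best_state = model.state_dict()
    for epoch in range(cfg.max_epochs):
        comp_sums: dict[str, float] = {}
        n_batches = 0
        for idx in _batches(len(tr_imgs), cfg.batch_size, rng):
            out: SegmentationOutput = model.forward(tr_imgs[idx], tr_labels[idx])
            loss, comps = total_loss(out.prob, out.edge_prob, tr_masks[idx],
                                     cfg.loss_weights)
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k, v in comps.items():
                comp_sums[k] = comp_sums.get(k, 0.0) + v
            n_batches += 1
        val = evaluate(model, va_imgs, va_masks, va_labels, cfg.threshold,
                       cfg.batch_size)
        row = {"epoch": epoch,
               **{f"loss_{k}": v / n_batches for k, v in comp_sums.items()},
               **{f"val_{k}": v for k, v in val.items()}}
        history.append(row)
        if val[cfg.selection_metric] > best_metric:
            best_metric = val[cfg.selection_metric]
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return pd.DataFrame(history)


# ----------------------------------------------------------------------
# HITL: uncertainty, selection, targeted fine-tuning
# ----------------------------------------------------------------------

def sample_entropy(prob: np.ndarray) -> float:
    """Mean per-pixel binary entropy of a probability map, in nats.

    Bounded by ln 2 (attained at p = 0.5 everywhere); 0 for a fully
    confident map.
    """
    p = np.clip(np.asarray(prob, dtype=np.float64), 1e-12, 1.0 - 1e-12)
    ent = -p * np.log(p) - (1.0 - p) * np.log(1.0 - p)
    return float(ent.mean())


def select_hitl_subset(scores: list[UncertaintyScore], organs: dict,
                       cfg: HITLConfig = HITLConfig()) -> list[str]:
    """Stratified top-entropy selection: per organ, the k most uncertain
    samples with k = max(min_per_class, round(ratio * n)), capped at the
    class size. Ties break by sample id, so selection is deterministic
    and independent of input order."""
    by_organ: dict[str, list[UncertaintyScore]] = {}
    for score in scores:
        organ = organs[score.sample_id]
        by_organ.setdefault(organ, []).append(score)
    selected: list[str] = []
    for organ in sorted(by_organ):
        class_scores = by_organ[organ]
        if not class_scores:
            warnings.warn(f"organ {organ!r} has no scored samples; skipped")
            continue
        n = len(class_scores)
        k = int(np.floor(cfg.hitl_ratio * n + 0.5))     # round half up
        k = min(max(cfg.min_per_class, k), n)
        ranked = sorted(class_scores, key=lambda s: (-s.entropy, s.sample_id))
        selected.extend(s.sample_id for s in ranked[:k])
    return selected


def finetune_hitl(model: ClinSegNet, subset_records: list[SampleRecord],
                  cfg: HITLConfig = HITLConfig(),
                  input_size: int | None = None) -> pd.DataFrame:
    """Targeted fine-tuning: only decoder stages 6-7 (with their FiLM and
    SE modules), their up-convolutions and the output layer receive
    gradients; every other tensor is bit-identical afterwards. EMA shadow
    weights of the unfrozen set are written back at the end."""
    if not subset_records:
        raise ValueError("HITL subset must be non-empty")
    size = input_size or model.config.input_size
    imgs, masks, labels, _ = _prepare(subset_records, model, size)

    all_params = model.named_parameters()
    unfrozen = {k: p for k, p in all_params.items()
                if k.startswith(HITL_UNFROZEN_PREFIXES)}
    frozen = {k: p for k, p in all_params.items() if k not in unfrozen}
    for p in frozen.values():
        p.requires_grad = False

    opt = Adam(unfrozen, lr=cfg.lr, weight_decay=cfg.weight_decay)
    steps_per_epoch = max(1, int(np.ceil(len(imgs) / cfg.batch_size)))
    sched = OneCycleLR(opt, max_lr=cfg.lr,
                       total_steps=cfg.epochs * steps_per_epoch) \
        if cfg.scheduler == "one-cycle" else None
    ema = EMA(unfrozen, decay=cfg.ema_decay)
    rng = np.random.default_rng(cfg.seed)

    history = []
    try:
        for epoch in range(cfg.epochs):
            losses = []
            for idx in _batches(len(imgs), cfg.batch_size, rng):
                out = model.forward(imgs[idx], labels[idx])
                loss, _ = total_loss(out.prob, out.edge_prob, masks[idx],
                                     cfg.loss_weights)
                opt.zero_grad()
                loss.backward()
                opt.step()
                if sched is not None:
                    sched.step()
                ema.update()
                losses.append(loss.item())
            # epoch-end loss over the whole subset, deterministic batching:
            # smoother than the shuffled minibatch average for convergence
            # monitoring
            subset_losses = []
            with no_grad():
                for idx in _batches(len(imgs), cfg.batch_size, None):
                    out = model.forward(imgs[idx], labels[idx])
                    l, _ = total_loss(out.prob, out.edge_prob, masks[idx],
                                      cfg.loss_weights)
                    subset_losses.append(l.item())
            history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                            "subset_loss": float(np.mean(subset_losses))})
    finally:
        for p in frozen.values():
            p.requires_grad = True
    ema.copy_to(unfrozen)
    return pd.DataFrame(history)


def hitl_round(model: ClinSegNet, pool_records: list[SampleRecord],
               cfg: HITLConfig = HITLConfig(),
               input_size: int | None = None) -> tuple[ClinSegNet, dict]:
    """One offline HITL cycle: predict -> entropy -> stratified selection
    -> targeted fine-tuning -> before/after evaluation on the pool."""
    size = input_size or model.config.input_size
    imgs, masks, labels, organs = _prepare(pool_records, model, size)

    probs = []
    with no_grad():
        for idx in _batches(len(imgs), cfg.batch_size, None):
            probs.append(model.forward(imgs[idx], labels[idx]).prob.data)
    probs = np.concatenate(probs)

    scores = [UncertaintyScore(sample_id=rec.filename,
                               entropy=sample_entropy(p))
              for rec, p in zip(pool_records, probs)]
    organ_of = {rec.filename: rec.organ for rec in pool_records}
    selected = select_hitl_subset(scores, organ_of, cfg)
    subset = [rec for rec in pool_records if rec.filename in set(selected)]

    before = evalkit.per_organ_report(list(probs), list(masks),
                                      organs, cfg.threshold)
    ft_history = finetune_hitl(model, subset, cfg, input_size=size)
    probs_after = []
    with no_grad():
        for idx in _batches(len(imgs), cfg.batch_size, None):
            probs_after.append(model.forward(imgs[idx], labels[idx]).prob.data)
    probs_after = np.concatenate(probs_after)
    after = evalkit.per_organ_report(list(probs_after), list(masks),
                                     organs, cfg.threshold)

    report = {
        "selected": selected,
        "scores": scores,
        "before": before,
        "after": after,
        "finetune_history": ft_history,
        "recall_before": float(before.loc[before.organ == "all", "recall"].iloc[0]),
        "recall_after": float(after.loc[after.organ == "all", "recall"].iloc[0]),
    }
    return model, report
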