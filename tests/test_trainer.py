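"""Training loop and human-in-the-loop mechanics."""

import hashlib

import numpy as np
import pytest

from clinsegnet.trainer import (HITL_UNFROZEN_PREFIXES, HITLConfig,
                                TrainConfig, UncertaintyScore, evaluate,
                                finetune_hitl, hitl_round, sample_entropy,
                                select_hitl_subset, train)
from conftest import ORGANS3, tiny_network

LN2 = np.log(2.0)


# ----------------------------------------------------------------------
# entropy
# ----------------------------------------------------------------------

def test_uniform_half_map_attains_maximum_entropy():
    assert sample_entropy(np.full((8, 8), 0.5)) == pytest.approx(LN2, abs=1e-12)


def test_confident_map_has_zero_entropy():
    prob = np.zeros((4, 4))
    prob[:2] = 1.0
    assert sample_entropy(prob) == pytest.approx(0.0, abs=1e-9)


def test_half_uncertain_map_entropy_closed_form():
    prob = np.full((2, 8), 1.0)
    prob[0] = 0.5
    assert sample_entropy(prob) == pytest.approx(LN2 / 2, abs=1e-9)


def test_entropy_bounds_on_random_maps():
    rng = np.random.default_rng(0)
    for _ in range(20):
        e = sample_entropy(rng.random((6, 6)))
        assert 0.0 <= e <= LN2 + 1e-12


# ----------------------------------------------------------------------
# stratified selection
# ----------------------------------------------------------------------

def make_scores(organ, n, base=0.0):
    return [UncertaintyScore(sample_id=f"{organ}_{i}", entropy=base + i * 0.01)
            for i in range(n)]


def test_selection_takes_top_entropy_fraction_per_class():
    scores = make_scores("a", 10)
    organs = {s.sample_id: "a" for s in scores}
    chosen = select_hitl_subset(scores, organs, HITLConfig())
    assert sorted(chosen) == ["a_7", "a_8", "a_9"]      # 3 = round(0.3 * 10)


def test_selection_respects_min_per_class_floor_and_cap():
    cfg = HITLConfig()
    small = make_scores("b", 4)
    organs = {s.sample_id: "b" for s in small}
    assert len(select_hitl_subset(small, organs, cfg)) == 2   # floor of 2
    single = make_scores("c", 1)
    organs = {s.sample_id: "c" for s in single}
    assert select_hitl_subset(single, organs, cfg) == ["c_0"]  # capped


def test_selection_order_independent_with_tie_breaking():
    scores = [UncertaintyScore(f"s{i}", 0.5) for i in range(6)]
    organs = {s.sample_id: "a" for s in scores}
    forward = select_hitl_subset(scores, organs, HITLConfig())
    backward = select_hitl_subset(list(reversed(scores)), organs, HITLConfig())
    assert forward == backward == ["s0", "s1"]


def test_ratio_one_selects_entire_pool():
    scores = make_scores("a", 7)
    organs = {s.sample_id: "a" for s in scores}
    chosen = select_hitl_subset(scores, organs, HITLConfig(hitl_ratio=1.0))
    assert len(chosen) == 7


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def small_train_setup(small_records, n=8):
    model = tiny_network(seed=1)
    recs = small_records[:n]
    return model, recs


def test_training_is_deterministic(small_records):
    histories = []
    for _ in range(2):
        model = tiny_network(seed=1)
        h = train(model, small_records[:6], small_records[6:9],
                  TrainConfig(max_epochs=2, input_size=32, seed=3))
        histories.append(h)
    assert histories[0].equals(histories[1])


def test_zero_learning_rate_changes_nothing(small_records):
    model = tiny_network(seed=1)
    before = {k: v.copy() for k, v in model.state_dict().items()}
    train(model, small_records[:6], small_records[6:9],
          TrainConfig(max_epochs=1, lr=0.0, input_size=32, seed=0))
    after = model.state_dict()
    for k in before:
        np.testing.assert_array_equal(before[k], after[k])


def test_training_requires_non_empty_splits(small_records):
    model = tiny_network()
    with pytest.raises(ValueError, match="non-empty"):
        train(model, [], small_records[:2], TrainConfig(max_epochs=1))


def test_capacity_overfit_on_separable_synthetic_data(small_records):
    """A short run on a handful of images must reach high training recall:
    the lesions are separable, so failure indicates a learning defect."""
    model = tiny_network(seed=2, stage_channels=(8, 16, 32, 64, 32, 16, 8),
                         input_size=64)
    recs = small_records[:16]
    history = train(model, recs, recs,
                    TrainConfig(max_epochs=10, input_size=64, seed=0))
    assert history["val_recall"].max() >= 0.95


# ----------------------------------------------------------------------
# targeted fine-tuning
# ----------------------------------------------------------------------

def tensor_hashes(model, predicate):
    return {k: hashlib.sha256(v.data.tobytes()).hexdigest()
            for k, v in model.named_parameters().items() if predicate(k)}


def test_finetune_updates_only_decoder_tail(small_records):
    model = tiny_network(seed=3)
    frozen_before = tensor_hashes(
        model, lambda k: not k.startswith(HITL_UNFROZEN_PREFIXES))
    unfrozen_before = tensor_hashes(
        model, lambda k: k.startswith(HITL_UNFROZEN_PREFIXES))
    finetune_hitl(model, small_records[:4],
                  HITLConfig(epochs=1, seed=0), input_size=32)
    frozen_after = tensor_hashes(
        model, lambda k: not k.startswith(HITL_UNFROZEN_PREFIXES))
    unfrozen_after = tensor_hashes(
        model, lambda k: k.startswith(HITL_UNFROZEN_PREFIXES))
    assert frozen_before == frozen_after
    assert any(unfrozen_before[k] != unfrozen_after[k]
               for k in unfrozen_before)


def test_finetune_rejects_empty_subset():
    with pytest.raises(ValueError, match="non-empty"):
        finetune_hitl(tiny_network(), [], HITLConfig())


def test_finetune_loss_decreases_and_plateaus(small_records):
    """Eight epochs on a small subset: the loss drops from its starting
    value and settles, mirroring the rapid-convergence behaviour the
    fine-tuning stage is designed for."""
    model = tiny_network(seed=4)
    train(model, small_records[:12], small_records[12:15],
          TrainConfig(max_epochs=4, input_size=32, seed=0))
    history = finetune_hitl(model, small_records[:12],
                            HITLConfig(epochs=8, lr=2e-3, ema_decay=0.0,
                                       seed=0),
                            input_size=32)
    losses = history["subset_loss"].to_numpy()
    assert losses[-1] < losses[0]
    # plateau: the final epochs move less than the steepest descent step
    tail = np.abs(np.diff(losses[-3:]))
    assert tail.max() <= 0.5 * np.abs(np.diff(losses)).max()


def test_ema_zero_decay_keeps_live_weights(small_records):
    model = tiny_network(seed=5)
    ref = tiny_network(seed=5)
    cfg = HITLConfig(epochs=1, ema_decay=0.0, scheduler="none", seed=0)
    finetune_hitl(model, small_records[:4], cfg, input_size=32)
    finetune_hitl(ref, small_records[:4], cfg, input_size=32)
    for (ka, va), (kb, vb) in zip(sorted(model.state_dict().items()),
                                  sorted(ref.state_dict().items())):
        assert ka == kb
        np.testing.assert_array_equal(va, vb)


# ----------------------------------------------------------------------
# full HITL round
# ----------------------------------------------------------------------

def test_hitl_round_reports_per_organ_recall_and_targets_uncertain_class(
        small_records):
    """An organ whose labels were corrupted to noise stays unlearnable, so
    its predictions carry the highest entropy and its samples are all
    selected at ratio 1 of the stratified budget."""
    rng = np.random.default_rng(0)
    pool = list(small_records)
    corrupted = []
    for rec in pool:
        if rec.organ == "kidney":
            import dataclasses
            noisy = dataclasses.replace(
                rec, mask=(rng.random(rec.mask.shape) > 0.5).astype(np.uint8))
            corrupted.append(noisy)
        else:
            corrupted.append(rec)
    model = tiny_network(seed=6, stage_channels=(8, 16, 32, 64, 32, 16, 8))
    # train to confidence on the clean organs (dice selection: recall-based
    # selection would keep an early all-uncertain checkpoint that hides the
    # organ contrast)
    train(model, corrupted, corrupted,
          TrainConfig(max_epochs=30, lr=1e-3, input_size=32, seed=0,
                      selection_metric="dice"))
    model, report = hitl_round(model, corrupted,
                               HITLConfig(epochs=1, seed=0), input_size=32)
    by_organ = {}
    for s in report["scores"]:
        organ = s.sample_id.split("_")[1]
        by_organ.setdefault(organ, []).append(s.entropy)
    means = {o: np.mean(v) for o, v in by_organ.items()}
    assert max(means, key=means.get) == "kidney"
    for frame in (report["before"], report["after"]):
        assert set(ORGANS3) <= set(frame["organ"])
        assert "recall" in frame.columns


def test_hitl_round_ratio_one_selects_all(small_records):
    model = tiny_network(seed=7)
    pool = small_records[:6]
    model, report = hitl_round(
        model, pool, HITLConfig(hitl_ratio=1.0, epochs=1, seed=0),
        input_size=32)
    assert sorted(report["selected"]) == sorted(r.filename for r in pool)
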