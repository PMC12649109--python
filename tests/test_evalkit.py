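"""Confusion metrics, the FN-reduction statistic and report plumbing."""

import numpy as np
import pytest

from clinsegnet.evalkit import (ConfusionCounts, confusion, fn_reduction,
                                heatmap_overlay, improvement_pct, metrics,
                                paired_tests, per_organ_report)


def toy_case():
    """4x4 image, 4 true positives; prediction hits 2 and adds 6."""
    mask = np.zeros((4, 4))
    mask.flat[:4] = 1
    prob = np.zeros((4, 4))
    prob.flat[:2] = 1.0      # 2 hits
    prob.flat[4:10] = 1.0    # 6 false alarms
    return prob, mask


def test_confusion_brute_force_tabulation():
    prob, mask = toy_case()
    c = confusion(prob, mask)
    assert (c.TP, c.FP, c.FN, c.TN) == (2, 6, 2, 6)
    assert c.total == 16


def test_confusion_perfect_and_inverted():
    mask = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(float)
    perfect = confusion(mask, mask)
    assert perfect.FP == perfect.FN == 0
    inverted = confusion(1.0 - mask, mask)
    assert inverted.TP == inverted.TN == 0


def test_confusion_validates_inputs():
    with pytest.raises(ValueError, match="shape mismatch"):
        confusion(np.zeros((2, 2)), np.zeros((2, 3)))
    with pytest.raises(ValueError, match="binary"):
        confusion(np.zeros((2, 2)), np.full((2, 2), 0.5))


def test_metrics_hand_arithmetic():
    m = metrics(ConfusionCounts(TP=2, FP=6, FN=2, TN=6))
    assert m["recall"] == pytest.approx(0.5)
    assert m["precision"] == pytest.approx(0.25)
    assert m["dice"] == pytest.approx(1 / 3)
    assert m["iou"] == pytest.approx(0.2)


def test_metrics_perfect_prediction_all_one():
    m = metrics(ConfusionCounts(TP=5, FP=0, FN=0, TN=11))
    assert all(v == 1.0 for v in m.values())


def test_dice_iou_identity_holds():
    rng = np.random.default_rng(1)
    for _ in range(20):
        tp, fp, fn, tn = rng.integers(1, 50, size=4)
        m = metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
        assert m["dice"] == pytest.approx(2 * m["iou"] / (1 + m["iou"]))


def test_empty_ground_truth_convention():
    both_empty = metrics(ConfusionCounts(TP=0, FP=0, FN=0, TN=16))
    assert all(v == 1.0 for v in both_empty.values())
    spurious = metrics(ConfusionCounts(TP=0, FP=3, FN=0, TN=13))
    assert spurious["recall"] == 0.0 and spurious["dice"] == 0.0


def test_metrics_invariant_under_transposition():
    prob, mask = toy_case()
    a = metrics(confusion(prob, mask))
    b = metrics(confusion(prob.T, mask.T))
    assert a == b


# ----------------------------------------------------------------------
# FN reduction and improvement
# ----------------------------------------------------------------------

def test_fn_reduction_zero_at_equal_recall():
    assert fn_reduction(0.9, 0.9) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("baseline,printed", [
    (0.8701, 18.6), (0.8842, 7.3), (0.8380, 37.2),
    (0.8873, 4.4), (0.8421, 35.2), (0.9562, -165.1),
])
def test_fn_reduction_reproduces_published_benchmark_column(baseline, printed):
    """The FN-reduction statistic applied to the published recall column
    must reproduce every printed percentage to one decimal."""
    assert round(100 * fn_reduction(0.8917, baseline), 1) == printed


def test_fn_reduction_domain_errors():
    with pytest.raises(ValueError):
        fn_reduction(0.0, 0.9)
    with pytest.raises(ValueError):
        fn_reduction(0.9, 1.0)


def test_improvement_pct_published_values():
    assert improvement_pct(0.5, 0.5) == 0.0
    assert round(improvement_pct(0.8917, 0.9053), 2) == 1.53
    assert round(improvement_pct(0.6869, 0.7759), 2) == 12.96
    with pytest.raises(ValueError):
        improvement_pct(0.0, 0.5)


# ----------------------------------------------------------------------
# reports
# ----------------------------------------------------------------------

def test_single_organ_aggregate_equals_organ_row():
    prob, mask = toy_case()
    report = per_organ_report([prob, prob], [mask, mask], ["kidney", "kidney"])
    kidney = report[report.organ == "kidney"].iloc[0]
    agg = report[report.organ == "all"].iloc[0]
    for col in ("recall", "precision", "dice", "iou"):
        assert kidney[col] == agg[col]


def test_per_organ_rows_reflect_per_image_recall():
    mask = np.ones((2, 2))
    perfect = np.ones((2, 2))
    half = np.array([[1.0, 1.0], [0.0, 0.0]])
    report = per_organ_report([perfect, half], [mask, mask], ["a", "b"])
    assert report.set_index("organ").loc["a", "recall"] == 1.0
    assert report.set_index("organ").loc["b", "recall"] == 0.5
    assert report.set_index("organ").loc["all", "recall"] == 0.75


def test_organ_means_match_flat_regrouping():
    rng = np.random.default_rng(3)
    probs = [rng.random((6, 6)) for _ in range(9)]
    masks = [(rng.random((6, 6)) > 0.5).astype(float) for _ in range(9)]
    organs = ["a", "b", "c"] * 3
    report = per_organ_report(probs, masks, organs).set_index("organ")
    from clinsegnet.evalkit import confusion as conf, metrics as mets
    flat = [{"organ": o, **mets(conf(p, m))}
            for p, m, o in zip(probs, masks, organs)]
    for organ in "abc":
        vals = [f["recall"] for f in flat if f["organ"] == organ]
        assert report.loc[organ, "recall"] == pytest.approx(np.mean(vals))


# ----------------------------------------------------------------------
# paired tests
# ----------------------------------------------------------------------

def test_identical_vectors_give_nan_pvalues_and_zero_diff():
    before = np.linspace(0.5, 0.9, 8)
    res = paired_tests(before, before)
    assert res["mean_diff"] == 0.0
    assert np.isnan(res["t_p"]) and np.isnan(res["wilcoxon_p"])


def test_constant_shift_detected():
    before = np.linspace(0.5, 0.9, 10)
    res = paired_tests(before, before + 0.05)
    assert res["mean_diff"] == pytest.approx(0.05)
    assert res["wilcoxon_p"] < 0.05


def test_pvalues_match_independent_implementation():
    """Cross-check against pingouin's paired t-test on random pairs."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(7)
    before = rng.random(10)
    after = before + rng.normal(0.02, 0.01, size=10)
    res = paired_tests(before, after)
    ref = pingouin.ttest(after, before, paired=True)
    pcol = "p_val" if "p_val" in ref.columns else "p-val"
    ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
    assert res["t_p"] == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-9)
    lo, hi = ref[ci_col].iloc[0]
    assert res["ci95"][0] == pytest.approx(lo, abs=5e-3)
    assert res["ci95"][1] == pytest.approx(hi, abs=5e-3)


# ----------------------------------------------------------------------
# heatmap
# ----------------------------------------------------------------------

def test_zero_probability_overlay_is_the_greyscale_base(tmp_path):
    image = np.random.default_rng(0).random((16, 16))
    blended = heatmap_overlay(image, np.zeros((16, 16)),
                              tmp_path / "overlay.png")
    np.testing.assert_allclose(blended, np.dstack([image] * 3))
    assert (tmp_path / "overlay.png").exists()


def test_overlay_dimensions_and_warmth_monotonicity(tmp_path):
    image = np.zeros((8, 8))
    prob = np.zeros((8, 8))
    prob[0, 0] = 0.95
    prob[0, 1] = 0.35
    blended = heatmap_overlay(image, prob, None)
    assert blended.shape == (8, 8, 3)
    warmth = blended[..., 0] - blended[..., 2]      # red minus blue
    assert warmth[0, 0] > warmth[0, 1]
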