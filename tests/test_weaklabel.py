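"""Weak-label pipeline: alignment, patching, DAB mask generators, fusion."""

import warnings

import numpy as np
import pytest
from skimage.color import hsv2rgb

from clinsegnet.synthdata import SynthConfig, default_organ_styles, generate_roi_pair
from clinsegnet.weaklabel import (AlignParams, MaskGenConfig, align_pair,
                                  extract_patches, fuse_masks, hed_mask,
                                  hsv_mask)


def dab_patch(size=128, square=60, background="white"):
    """RGB patch with a centred DAB-brown square on a plain background."""
    hsv = np.zeros((size, size, 3))
    if background == "white":
        hsv[..., 2] = 1.0
    elif background == "blue":
        hsv[..., 0] = 220 / 360.0
        hsv[..., 1] = 0.6
        hsv[..., 2] = 0.8
    gt = np.zeros((size, size), dtype=bool)
    if square:
        lo = (size - square) // 2
        gt[lo:lo + square, lo:lo + square] = True
        hsv[gt, 0] = 30 / 360.0
        hsv[gt, 1] = 0.7
        hsv[gt, 2] = 0.55
    return hsv2rgb(hsv), gt


# ----------------------------------------------------------------------
# alignment
# ----------------------------------------------------------------------

def test_identity_alignment_is_exact():
    img = np.random.default_rng(0).random((40, 50, 3))
    out = align_pair(img, AlignParams(0, 0, 0))
    np.testing.assert_allclose(out, img, atol=1e-12)


def test_translation_roundtrip_recovers_interior():
    img = np.random.default_rng(1).random((60, 60))
    back = align_pair(align_pair(img, AlignParams(0, 10, 0)),
                      AlignParams(0, -10, 0))
    np.testing.assert_allclose(back[15:-15, 15:-15], img[15:-15, 15:-15],
                               atol=1e-9)


def test_nonfinite_params_rejected():
    with pytest.raises(ValueError):
        AlignParams(np.nan, 0, 0)


def test_known_misalignment_is_recovered_on_synthetic_pair():
    """Aligning a misaligned synthetic IHC with the true transform puts
    >=99% of the DAB signal back on the ground-truth mask."""
    cfg = SynthConfig(image_size=512, lesion_radius=(30, 70), n_lesions=(3, 5),
                      organ_styles=default_organ_styles(["melanomaLN"]), seed=3)
    pair = generate_roi_pair(cfg, (5, 30, -12), roi_shape=(500, 640))
    aligned = align_pair(pair.ihc_roi, AlignParams(*pair.true_transform))
    from skimage.color import rgb2hsv
    hue = rgb2hsv(np.clip(aligned, 0, 1))[..., 0] * 360.0
    dab = (hue >= 15) & (hue <= 45)
    gt = pair.mask_roi.astype(bool)
    # erode the reference by one pixel: bilinear resampling feathers edges
    from scipy.ndimage import binary_erosion
    core = binary_erosion(gt, iterations=2)
    assert np.mean(dab[core]) >= 0.99
    assert np.mean(dab[~gt]) < 0.01


# ----------------------------------------------------------------------
# patch extraction
# ----------------------------------------------------------------------

@pytest.mark.parametrize("shape,expected", [
    ((512, 512), 1),
    ((768, 512), 2),
    ((1500, 2100), 28),      # 4 rows x 7 cols on the clinical ROI size
])
def test_patch_counts_on_stride_lattice(shape, expected):
    he = np.zeros(shape + (3,))
    pairs = extract_patches(he, he, patch=512, stride=256)
    assert len(pairs) == expected
    for p in pairs:
        assert p.origin[0] % 256 == 0 and p.origin[1] % 256 == 0
        assert p.he_patch.shape[:2] == (512, 512)


def test_patch_count_formula_matches_brute_force_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(50):
        patch = int(rng.integers(4, 40))
        stride = int(rng.integers(1, patch + 1))
        H = int(rng.integers(patch, 4 * patch))
        W = int(rng.integers(patch, 4 * patch))
        img = np.zeros((H, W))
        got = len(extract_patches(img, img, patch=patch, stride=stride))
        brute = sum(1 for r in range(0, H + 1) for c in range(0, W + 1)
                    if r % stride == 0 and c % stride == 0
                    and r + patch <= H and c + patch <= W)
        assert got == brute == \
            ((H - patch) // stride + 1) * ((W - patch) // stride + 1)


def test_small_raster_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="smaller than patch"):
        assert extract_patches(np.zeros((100, 600)), np.zeros((100, 600))) == []


def test_patch_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        extract_patches(np.zeros((512, 512)), np.zeros((512, 513)))


# ----------------------------------------------------------------------
# HSV mask
# ----------------------------------------------------------------------

def test_pure_blue_patch_yields_empty_hsv_mask():
    img, _ = dab_patch(square=0, background="blue")
    assert hsv_mask(img).mask.sum() == 0


def test_dab_square_recovered_up_to_corner_rounding():
    img, gt = dab_patch(square=60)
    mask = hsv_mask(img).mask.astype(bool)
    assert mask[~gt].sum() == 0                 # nothing outside the square
    assert 3500 <= mask.sum() <= 3600           # opening rounds the corners


def test_small_speck_removed_by_area_filter():
    img, _ = dab_patch(square=0)
    hsv = np.zeros((64, 64, 3))
    hsv[..., 2] = 1.0
    hsv[20:25, 20:22, 0] = 30 / 360.0           # 10-pixel speck
    hsv[20:25, 20:22, 1] = 0.7
    hsv[20:25, 20:22, 2] = 0.55
    cfg = MaskGenConfig(min_area=50, open_radius=0, close_radius=0)
    assert hsv_mask(hsv2rgb(hsv), cfg).mask.sum() == 0


def test_hsv_mask_rejects_greyscale():
    with pytest.raises(ValueError, match="hue is undefined"):
        hsv_mask(np.zeros((32, 32)))


# ----------------------------------------------------------------------
# HED mask
# ----------------------------------------------------------------------

def test_blank_patch_warns_and_returns_empty_hed_mask():
    blank = np.ones((64, 64, 3))
    with pytest.warns(UserWarning, match="Otsu undefined"):
        assert hed_mask(blank).mask.sum() == 0


def test_hed_mask_recovers_dab_blob():
    img, gt = dab_patch(square=60, background="blue")
    mask = hed_mask(img).mask.astype(bool)
    inter = (mask & gt).sum()
    dice = 2 * inter / (mask.sum() + gt.sum())
    assert dice >= 0.90


def test_hed_mask_empty_on_chromogen_free_textured_patch():
    """On a patch without any DAB, Otsu would threshold background noise;
    the optical-density floor keeps the mask empty."""
    rng = np.random.default_rng(4)
    hsv = np.zeros((128, 128, 3))
    hsv[..., 0] = 220 / 360.0
    hsv[..., 1] = 0.5 + 0.1 * rng.random((128, 128))
    hsv[..., 2] = 0.7 + 0.2 * rng.random((128, 128))
    assert hed_mask(hsv2rgb(hsv)).mask.sum() == 0


def test_hed_mask_stable_under_small_brightness_change():
    img, _ = dab_patch(square=60, background="blue")
    base = hed_mask(img).mask.astype(bool)
    for factor in (0.95, 1.05):
        shifted = hed_mask(np.clip(img * factor, 0, 1)).mask.astype(bool)
        inter = (base & shifted).sum()
        dice = 2 * inter / max(base.sum() + shifted.sum(), 1)
        assert dice >= 0.95


# ----------------------------------------------------------------------
# fusion
# ----------------------------------------------------------------------

def test_fusion_identity_and_union_counts():
    z = np.zeros((20, 20), dtype=np.uint8)
    a = z.copy()
    a[:5, :20] = 1                               # 100 px
    b = z.copy()
    b[10:15, :10] = 1                            # 50 px, disjoint
    assert fuse_masks(z, z).sum() == 0
    np.testing.assert_array_equal(fuse_masks(a, z), a)
    assert fuse_masks(a, b).sum() == 150


def test_fusion_contains_each_candidate():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        b = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        fused = fuse_masks(a, b)
        assert np.all(fused >= a) and np.all(fused >= b)


def test_fusion_rejects_shape_mismatch():
    with pytest.raises(ValueError):
        fuse_masks(np.zeros((4, 4)), np.zeros((4, 5)))
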