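"""IHC-to-H&E weak-label generation.

Pipeline for paired-stain regions of interest: rigid alignment of the
IHC image onto its H&E partner (manually determined rotation +
translation), sliding-window patch extraction over the overlap, two
complementary DAB mask generators — an HSV hue-gate and an HED stain
deconvolution with Otsu thresholding — and a logical-OR fusion of the
candidates. The union fusion is deliberately recall-biased: a pixel
flagged by either colour model enters the weak label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import morphology
from skimage.color import rgb2hed, rgb2hsv
from skimage.filters import gaussian, threshold_otsu
from skimage.transform import AffineTransform, warp

__all__ = [
    "AlignParams", "PatchPair", "MaskGenConfig", "CandidateMask",
    "align_pair", "extract_patches", "hsv_mask", "hed_mask", "fuse_masks",
    "generate_weak_labels",
]


@dataclass(frozen=True)
class AlignParams:
    rotation: float = 0.0   # degrees, about the image centre
    dx: float = 0.0         # pixels, columns
    dy: float = 0.0         # pixels, rows

    def __post_init__(self):
        if not all(np.isfinite([self.rotation, self.dx, self.dy])):
            raise ValueError("alignment parameters must be finite")


@dataclass
class PatchPair:
    he_patch: np.ndarray
    ihc_patch: np.ndarray
    origin: tuple           # (row, col) in ROI coordinates


@dataclass(frozen=True)
class MaskGenConfig:
    """Thresholds for the two DAB mask generators.

    Defaults are the package's own calibration (hue band wide enough for
    typical DAB brown, blue band covering haematoxylin background); every
    value is exposed because no canonical settings exist.
    """
    hue_band: tuple = (15.0, 45.0)      # degrees kept as DAB
    blue_band: tuple = (180.0, 260.0)   # degrees excluded as background
    sat_min: float = 0.15
    val_max: float = 1.0
    gaussian_sigma: float = 2.0
    dab_min: float = 0.05               # minimum DAB optical density
    min_area: int = 64
    open_radius: int = 2
    close_radius: int = 2
    fill_holes: bool = True

    def __post_init__(self):
        for band in (self.hue_band, self.blue_band):
            if not (0 <= band[0] < 360 and 0 <= band[1] < 360):
                raise ValueError("hue bands must lie in [0, 360)")
        if self.min_area < 0 or self.open_radius < 0 or self.close_radius < 0:
            raise ValueError("min_area and radii must be >= 0")


@dataclass
class CandidateMask:
    mask: np.ndarray        # uint8 in {0, 1}
    method: str             # "HSV" or "HED"


# ----------------------------------------------------------------------
# rigid alignment
# ----------------------------------------------------------------------

def _rigid_transform(params: AlignParams, shape: tuple) -> AffineTransform:
    """Forward map: rotate about the image centre, then translate."""
    cy = (shape[0] - 1) / 2.0
    cx = (shape[1] - 1) / 2.0
    to_centre = AffineTransform(translation=(-cx, -cy))
    rot = AffineTransform(rotation=np.deg2rad(params.rotation))
    back = AffineTransform(translation=(cx + params.dx, cy + params.dy))
    return to_centre + rot + back


def align_pair(ihc_roi: np.ndarray, params: AlignParams,
               fill: float = 1.0) -> np.ndarray:
    """Rotate about the centre then translate; bilinear resampling,
    out-of-frame pixels filled with the slide background (white)."""
    if not isinstance(params, AlignParams):
        params = AlignParams(*params)
    ihc_roi = np.asarray(ihc_roi, dtype=np.float64)
    if ihc_roi.size == 0:
        raise ValueError("empty raster")
    tform = _rigid_transform(params, ihc_roi.shape[:2])
    return warp(ihc_roi, tform.inverse, order=1, cval=fill,
                mode="constant", preserve_range=True)


def apply_inverse_alignment(image: np.ndarray, params: AlignParams,
                            fill: float = 1.0) -> np.ndarray:
    """Displace an image by the exact inverse of the alignment warp
    (rotation and translation do not commute, so the matrix is inverted
    rather than the parameters negated). Used by the synthetic generator
    to manufacture a misaligned stain pair."""
    tform = _rigid_transform(params, np.asarray(image).shape[:2])
    inv = AffineTransform(matrix=np.linalg.inv(tform.params))
    return warp(np.asarray(image, dtype=np.float64), inv.inverse, order=1,
                cval=fill, mode="constant", preserve_range=True)


# ----------------------------------------------------------------------
# patch extraction
# ----------------------------------------------------------------------

def extract_patches(he: np.ndarray, ihc: np.ndarray, patch: int = 512,
                    stride: int = 256) -> list[PatchPair]:
    """Sliding-window pairs on the stride lattice r = 0, stride, ...,
    keeping only windows fully inside the rasters (no edge snapping)."""
    he = np.asarray(he)
    ihc = np.asarray(ihc)
    if he.shape[:2] != ihc.shape[:2]:
        raise ValueError(f"shape mismatch: {he.shape[:2]} vs {ihc.shape[:2]}")
    H, W = he.shape[:2]
    if H < patch or W < patch:
        warnings.warn(f"raster {H}x{W} smaller than patch {patch}; no patches")
        return []
    pairs = []
    for r in range(0, H - patch + 1, stride):
        for c in range(0, W - patch + 1, stride):
            pairs.append(PatchPair(he_patch=he[r:r + patch, c:c + patch],
                                   ihc_patch=ihc[r:r + patch, c:c + patch],
                                   origin=(r, c)))
    return pairs


# ----------------------------------------------------------------------
# candidate masks
# ----------------------------------------------------------------------

def _in_band(hue_deg: np.ndarray, band: tuple) -> np.ndarray:
    lo, hi = band
    if lo <= hi:
        return (hue_deg >= lo) & (hue_deg <= hi)
    return (hue_deg >= lo) | (hue_deg <= hi)      # wrap-around band


def _morph_cleanup(mask: np.ndarray, cfg: MaskGenConfig,
                   fill_holes: bool = False) -> np.ndarray:
    out = mask.astype(bool)
    if cfg.open_radius > 0:
        out = morphology.opening(out, morphology.disk(cfg.open_radius))
    if cfg.close_radius > 0:
        out = morphology.closing(out, morphology.disk(cfg.close_radius))
    if cfg.min_area > 0:
        # drop connected components strictly smaller than min_area
        out = morphology.remove_small_objects(out, max_size=cfg.min_area - 1)
    if fill_holes and cfg.fill_holes and cfg.min_area > 0:
        out = morphology.remove_small_holes(out, max_size=cfg.min_area - 1)
    return out.astype(np.uint8)


def hsv_mask(ihc_patch: np.ndarray, cfg: MaskGenConfig = MaskGenConfig()
             ) -> CandidateMask:
    """DAB candidate from HSV gating: keep hue in the DAB band, reject the
    blue background band, require minimum saturation, then open/close and
    drop small components."""
    ihc_patch = np.asarray(ihc_patch)
    if ihc_patch.ndim != 3 or ihc_patch.shape[2] != 3:
        raise ValueError("hsv_mask needs an RGB raster (hue is undefined "
                         "for greyscale input)")
    hsv = rgb2hsv(ihc_patch)
    hue = hsv[..., 0] * 360.0
    keep = (_in_band(hue, cfg.hue_band)
            & ~_in_band(hue, cfg.blue_band)
            & (hsv[..., 1] >= cfg.sat_min)
            & (hsv[..., 2] <= cfg.val_max))
    return CandidateMask(mask=_morph_cleanup(keep, cfg), method="HSV")


def hed_mask(ihc_patch: np.ndarray, cfg: MaskGenConfig = MaskGenConfig()
             ) -> CandidateMask:
    """DAB candidate from HED stain deconvolution (Ruifrok-Johnston
    matrix): DAB channel -> Gaussian smoothing -> Otsu threshold ->
    open/close -> small-object removal and small-hole filling.

    Otsu always splits the histogram, even on a chromogen-free patch
    where it would threshold pure background noise; the effective
    threshold is therefore floored at `dab_min` optical density. A
    constant DAB channel leaves Otsu undefined; the generator then warns
    and returns an empty mask.
    """
    ihc_patch = np.asarray(ihc_patch)
    if ihc_patch.ndim != 3 or ihc_patch.shape[2] != 3:
        raise ValueError("hed_mask needs an RGB raster")
    dab = rgb2hed(ihc_patch)[..., 2]
    smoothed = gaussian(dab, sigma=cfg.gaussian_sigma)
    if np.ptp(smoothed) < 1e-8:
        warnings.warn("constant DAB channel; Otsu undefined, returning "
                      "an empty mask")
        return CandidateMask(mask=np.zeros(ihc_patch.shape[:2], dtype=np.uint8),
                             method="HED")
    thr = max(threshold_otsu(smoothed), cfg.dab_min)
    mask = smoothed > thr
    return CandidateMask(mask=_morph_cleanup(mask, cfg, fill_holes=True),
                         method="HED")


def fuse_masks(a: CandidateMask | np.ndarray,
               b: CandidateMask | np.ndarray) -> np.ndarray:
    """Logical OR of two candidate masks (union fusion)."""
    ma = a.mask if isinstance(a, CandidateMask) else np.asarray(a)
    mb = b.mask if isinstance(b, CandidateMask) else np.asarray(b)
    if ma.shape != mb.shape:
        raise ValueError(f"shape mismatch: {ma.shape} vs {mb.shape}")
    return (ma.astype(bool) | mb.astype(bool)).astype(np.uint8)


# ----------------------------------------------------------------------
# end-to-end convenience
# ----------------------------------------------------------------------

def generate_weak_labels(he_roi: np.ndarray, ihc_roi: np.ndarray,
                         params: AlignParams,
                         cfg: MaskGenConfig = MaskGenConfig(),
                         patch: int = 512, stride: int = 256,
                         out_dir=None, roi_id: int = 0) -> list[dict]:
    """align -> patch -> HSV mask | HED mask -> OR fusion.

    Returns one record per patch with the fused weak label; optionally
    writes `human_melanomaLN_{roi}_{r}_{c}` PNG triplets to out_dir.
    """
    aligned = align_pair(ihc_roi, params)
    pairs = extract_patches(he_roi, aligned, patch=patch, stride=stride)
    records = []
    for pair in pairs:
        cand_hsv = hsv_mask(pair.ihc_patch, cfg)
        cand_hed = hed_mask(pair.ihc_patch, cfg)
        fused = fuse_masks(cand_hsv, cand_hed)
        records.append({
            "origin": pair.origin,
            "he_patch": pair.he_patch,
            "ihc_patch": pair.ihc_patch,
            "hsv_mask": cand_hsv.mask,
            "hed_mask": cand_hed.mask,
            "weak_label": fused,
        })
    if out_dir is not None:
        import imageio.v3 as iio
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            r, c = rec["origin"]
            stem = f"human_melanomaLN_{roi_id}_{r}_{c}"
            iio.imwrite(out / f"{stem}.png",
                        np.clip(np.round(rec["he_patch"] * 255), 0, 255)
                        .astype(np.uint8))
            iio.imwrite(out / f"{stem}_mask.png",
                        (rec["weak_label"] * 255).astype(np.uint8))
    return records
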