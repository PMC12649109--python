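"""Seeded synthetic histology fixtures.

Generates what the rest of the pipeline assumes about real slides without
any downloads: single-stain patches with exact binary lesion masks and an
organ identity, plus misaligned paired-stain regions of interest.

The pseudo-IHC rendering places a DAB-brown chromogen signal (hue in a
configurable band around 20-40 degrees, well separated in both HSV hue
and the Ruifrok-Johnston HED stain basis) exactly on the lesion mask over
a haematoxylin-blue background. The pseudo-H&E rendering shows the same
tissue with only subtle lesion contrast, so recovering the label from the
IHC image is the non-trivial part, as in real Melan-A weak labelling.

Lesions are unions of randomly perturbed ellipses (low-frequency radial
Fourier perturbation), giving irregular border contours while keeping the
ground truth pixel-exact. All randomness flows through one RNG stream
keyed by (seed, organ, id), so dataset generation is order-independent
and bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

__all__ = [
    "SynthConfig", "SynthSample", "SynthROIPair", "default_organ_styles",
    "generate_sample", "generate_dataset", "generate_roi_pair",
]

# H x W of a paired-stain region of interest (width 2100, height 1500)
ROI_SHAPE = (1500, 2100)


def default_organ_styles(organs: list[str]) -> dict[str, dict]:
    """Per-organ texture/intensity parameters, derived deterministically
    from the organ name so any vocabulary gets a distinct style."""
    styles = {}
    for organ in organs:
        r = np.random.default_rng(zlib.crc32(organ.encode()))
        styles[organ] = {
            "texture_sigma": float(r.uniform(2.0, 8.0)),
            "background_value": float(r.uniform(0.75, 0.92)),
            "nuclear_density": float(r.uniform(0.2, 0.5)),
            "lesion_contrast": float(r.uniform(0.04, 0.10)),
        }
    return styles


@dataclass(frozen=True)
class SynthConfig:
    image_size: int = 512
    n_lesions: tuple = (2, 5)            # inclusive count range
    lesion_radius: tuple = (20, 60)      # pixel range of ellipse semi-axes
    dab_hue: tuple = (20.0, 40.0)        # degrees, brown chromogen band
    background_hue: float = 220.0        # degrees, haematoxylin blue
    stain_jitter: float = 0.05           # fractional saturation/value jitter
    organ_styles: dict = field(default_factory=lambda: default_organ_styles(
        ["kidney", "liver", "lung"]))
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if not (0 <= self.dab_hue[0] < 360 and 0 <= self.dab_hue[1] < 360):
            raise ValueError("dab_hue must lie in [0, 360)")
        if not 0 <= self.background_hue < 360:
            raise ValueError("background_hue must lie in [0, 360)")
        if self.n_lesions[0] < 0 or self.n_lesions[0] > self.n_lesions[1]:
            raise ValueError("n_lesions must be a non-negative (lo, hi) range")


@dataclass
class SynthSample:
    he_image: np.ndarray    # (H, W, 3) in [0, 1]
    ihc_image: np.ndarray   # (H, W, 3) in [0, 1]
    mask: np.ndarray        # (H, W) uint8 in {0, 1}
    organ: str
    id: int


@dataclass
class SynthROIPair:
    he_roi: np.ndarray
    ihc_roi: np.ndarray        # displaced by the inverse of true_transform
    true_transform: tuple      # (rotation deg, dx, dy) restoring alignment
    mask_roi: np.ndarray       # aligned to he_roi


def _rng_for(config: SynthConfig, organ: str, id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(organ.encode()), id]))


def _draw_lesion_mask(rng: np.random.Generator, shape: tuple,
                      config: SynthConfig) -> np.ndarray:
    """Union of radially perturbed ellipses; retries until coverage is in
    the 1-50% band the downstream pipeline assumes."""
    H, W = shape
    lo, hi = config.n_lesions
    n = int(rng.integers(lo, hi + 1))
    if n == 0:
        return np.zeros(shape, dtype=np.uint8)
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(20):
        mask = np.zeros(shape, dtype=bool)
        for _ in range(n):
            a = rng.uniform(*config.lesion_radius)
            b = rng.uniform(*config.lesion_radius)
            cy = rng.uniform(0.15 * H, 0.85 * H)
            cx = rng.uniform(0.15 * W, 0.85 * W)
            phi = rng.uniform(0, np.pi)
            u = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
            v = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
            rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
            theta = np.arctan2(v / b, u / a)
            wobble = np.ones_like(theta)
            for k in (2, 3, 5):
                wobble += rng.uniform(-0.12, 0.12) * np.cos(
                    k * theta + rng.uniform(0, 2 * np.pi))
            mask |= rho <= np.clip(wobble, 0.6, 1.5)
        frac = mask.mean()
        if 0.01 <= frac <= 0.5:
            return mask.astype(np.uint8)
    raise RuntimeError(
        "could not draw a lesion mask with 1-50% coverage; "
        "lesion_radius is out of proportion with image_size")


def _render_pair(rng: np.random.Generator, mask: np.ndarray, style: dict,
                 config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render (pseudo-H&E, pseudo-IHC) for a given lesion mask."""
    H, W = mask.shape
    sig = style["texture_sigma"]
    texture = gaussian_filter(rng.normal(size=(H, W)), sig)
    texture /= max(np.abs(texture).max(), 1e-9)
    nuclei = gaussian_filter(rng.normal(size=(H, W)), 1.0)
    nuclei = (nuclei > np.quantile(nuclei, 1.0 - style["nuclear_density"]))

    jitter = config.stain_jitter
    m = mask.astype(bool)

    # --- pseudo-IHC: blue haematoxylin background, DAB brown on lesions
    hue = np.full((H, W), config.background_hue / 360.0)
    hue += rng.uniform(-10, 10) / 360.0 * texture        # stays far from DAB band
    lo, hi = config.dab_hue
    margin = 0.05 * (hi - lo)
    hue[m] = rng.uniform(lo + margin, hi - margin, size=int(m.sum())) / 360.0
    sat = np.clip(0.25 + 0.1 * texture + 0.25 * nuclei, 0.05, 1.0)
    sat[m] = np.clip(rng.uniform(0.55, 0.8, size=int(m.sum()))
                     * (1 + jitter * texture[m]), 0.3, 1.0)
    val = np.clip(style["background_value"] + 0.08 * texture - 0.3 * nuclei
                  + jitter * rng.normal(size=(H, W)) * 0.2, 0.35, 1.0)
    val[m] = np.clip(0.55 + 0.1 * texture[m], 0.3, 0.8)
    ihc = hsv2rgb(np.dstack([hue % 1.0, sat, val]))

    # --- pseudo-H&E: same tissue, only subtle lesion contrast
    hue_he = np.full((H, W), 0.78) + 0.03 * texture       # purple-pink range
    hue_he[nuclei] = 0.72                                 # haematoxylin nuclei
    sat_he = np.clip(0.2 + 0.1 * texture + 0.3 * nuclei, 0.05, 1.0)
    val_he = np.clip(style["background_value"] + 0.06 * texture - 0.35 * nuclei,
                     0.3, 1.0)
    val_he[m] -= style["lesion_contrast"]                 # faint darkening only
    he = hsv2rgb(np.dstack([hue_he % 1.0, sat_he, np.clip(val_he, 0.0, 1.0)]))
    return he, ihc


def generate_sample(config: SynthConfig, organ: str, id: int) -> SynthSample:
    """Deterministic (seed, organ, id)-keyed synthetic patch with mask."""
    if organ not in config.organ_styles:
        raise KeyError(
            f"unknown organ {organ!r}; configured: {sorted(config.organ_styles)}")
    rng = _rng_for(config, organ, id)
    shape = (config.image_size, config.image_size)
    mask = _draw_lesion_mask(rng, shape, config)
    he, ihc = _render_pair(rng, mask, config.organ_styles[organ], config)
    return SynthSample(he_image=he, ihc_image=ihc, mask=mask, organ=organ, id=id)


def _to_png8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.round(arr * 255), 0, 255).astype(np.uint8)


def generate_dataset(config: SynthConfig, organs: list[str], per_organ: int,
                     out_dir: str | Path) -> pd.DataFrame:
    """Write `human_{organ}_{id}` PNG image/mask pairs and a manifest CSV."""
    import imageio.v3 as iio

    if per_organ < 1:
        raise ValueError("per_organ must be >= 1")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for organ in organs:
        for i in range(per_organ):
            sample = generate_sample(config, organ, i)
            name = f"human_{organ}_{i}"
            iio.imwrite(out / "images" / f"{name}.png", _to_png8(sample.he_image))
            iio.imwrite(out / "masks" / f"{name}.png",
                        (sample.mask * 255).astype(np.uint8))
            rows.append({"filename": name, "organ": organ, "id": i})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def generate_roi_pair(config: SynthConfig, transform: tuple,
                      organ: str = "melanomaLN", id: int = 0,
                      roi_shape: tuple = ROI_SHAPE) -> SynthROIPair:
    """Paired-stain ROI with a known rigid misalignment.

    The H&E ROI, mask and an aligned IHC rendering are generated first;
    the delivered IHC ROI is then displaced by the *inverse* of
    `transform`, so applying `weaklabel.align_pair(ihc_roi, transform)`
    superimposes the DAB signal back onto the mask.
    """
    from .weaklabel import AlignParams, align_pair, apply_inverse_alignment

    deg, dx, dy = transform
    if abs(deg) > 15 or abs(dx) > 200 or abs(dy) > 200:
        raise ValueError("transform outside the plausible manual-alignment "
                         "range (|deg| <= 15, |dx|,|dy| <= 200)")
    style_key = organ if organ in config.organ_styles else None
    styles = config.organ_styles if style_key else {
        **config.organ_styles, organ: default_organ_styles([organ])[organ]}
    rng = _rng_for(config, organ, id)
    mask = _draw_lesion_mask(rng, roi_shape, config)
    he, ihc_aligned = _render_pair(rng, mask, styles[organ], config)

    params = AlignParams(rotation=float(deg), dx=float(dx), dy=float(dy))
    ihc_roi = apply_inverse_alignment(ihc_aligned, params, fill=1.0)

    # sanity: the lesion must survive the displacement
    recovered = align_pair(ihc_roi, params, fill=1.0)
    lesion_visible = recovered[mask.astype(bool)]
    if mask.sum() and lesion_visible.size and \
            np.all(np.abs(lesion_visible - 1.0) < 1e-6):
        raise RuntimeError("transform moved the lesion fully out of frame")
    return SynthROIPair(he_roi=he, ihc_roi=ihc_roi,
                        true_transform=(float(deg), float(dx), float(dy)),
                        mask_roi=mask)
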