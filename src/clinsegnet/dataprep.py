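"""Dataset preparation: augmentation, greyscale conversion, filename
conventions, the stratified 8:2 split and resize-to-network loading.

Every image file follows the `human_{organ}_{id}` convention; organ names
may themselves contain underscores (e.g. salivary_gland) and are resolved
by longest match against the organ vocabulary. Augmentation multiplies
the dataset exactly by four (original, horizontal flip, vertical flip,
colour-perturbed copy), and splitting happens at the source-image level
so augmented copies of one image never straddle train and test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from math import ceil
from pathlib import Path

import numpy as np
from skimage.transform import resize

__all__ = [
    "ORGAN_VOCABULARY", "SampleRecord", "SplitConfig",
    "augment_sample", "to_greyscale", "parse_filename", "encode_filename",
    "stratified_split", "load_pair",
]

# The multi-organ human-tissue vocabulary of the nucleus-segmentation
# benchmark, plus the melanoma lymph-node class contributed by the
# clinical paired-stain data.
ORGAN_VOCABULARY = (
    "bladder", "brain", "cardia", "cerebellum", "epiglottis", "jejunum",
    "kidney", "liver", "lung", "melanoma", "melanomaLN", "muscle",
    "oesophagus", "pancreas", "peritoneum", "placenta", "pylorus", "rectum",
    "salivary_gland", "spleen", "testis", "tongue", "tonsil",
    "umbilical_cord",
)

LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class SampleRecord:
    filename: str                      # human_{organ}_{id} stem
    image: np.ndarray | None           # raster in [0, 1], (H, W) or (H, W, 3)
    mask: np.ndarray | None            # binary (H, W)
    organ: str
    id: int
    split: str | None = None           # "train" | "test"
    image_path: Path | None = None
    mask_path: Path | None = None
    source_id: int | None = None       # pre-augmentation source image id
    augmentation: str = "original"

    def __post_init__(self):
        if self.source_id is None:
            self.source_id = self.id
        if self.image is not None and self.mask is not None:
            if self.image.shape[:2] != self.mask.shape[:2]:
                raise ValueError(
                    f"{self.filename}: image {self.image.shape[:2]} and mask "
                    f"{self.mask.shape[:2]} differ")


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.8
    seed: int = 42

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def to_greyscale(image: np.ndarray) -> np.ndarray:
    """Luma-weighted conversion (0.299 R + 0.587 G + 0.114 B)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected RGB (H, W, 3), got {image.shape}")
    return image @ np.asarray(LUMA_WEIGHTS)


def _colour_perturb(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mild brightness/contrast/saturation jitter, each U(-0.1, 0.1)."""
    img = np.asarray(image, dtype=np.float64)
    b, c, s = rng.uniform(-0.1, 0.1, size=3)
    out = img + b
    out = (out - out.mean()) * (1.0 + c) + out.mean()
    if out.ndim == 3:                   # saturation: pull toward/away from luma
        luma = to_greyscale(np.clip(out, 0, 1))[..., None]
        out = luma + (out - luma) * (1.0 + s)
    return np.clip(out, 0.0, 1.0)


def augment_sample(rec: SampleRecord, seed: int = 0) -> list[SampleRecord]:
    """Original + horizontal flip + vertical flip + colour-perturbed copy.

    Flips are applied identically to the mask; the colour perturbation
    leaves the mask untouched. Deterministic for a given seed.
    """
    if rec.image is None or rec.mask is None:
        raise ValueError(f"{rec.filename}: record has no in-memory arrays")
    rng = np.random.default_rng([seed, rec.source_id])
    hflip = replace(rec, filename=f"{rec.filename}_hflip",
                    image=rec.image[:, ::-1].copy(),
                    mask=rec.mask[:, ::-1].copy(), augmentation="hflip")
    vflip = replace(rec, filename=f"{rec.filename}_vflip",
                    image=rec.image[::-1].copy(),
                    mask=rec.mask[::-1].copy(), augmentation="vflip")
    colour = replace(rec, filename=f"{rec.filename}_colour",
                     image=_colour_perturb(rec.image, rng),
                     mask=rec.mask.copy(), augmentation="colour")
    return [rec, hflip, vflip, colour]


def encode_filename(organ: str, id: int) -> str:
    return f"human_{organ}_{id}"


def parse_filename(name: str, vocabulary=ORGAN_VOCABULARY) -> tuple[str, int]:
    """Parse `human_{organ}_{id}` by longest match against the vocabulary.

    Patch files from the weak-label pipeline carry extra row/col fields
    after the id (`human_melanomaLN_{roi}_{r}_{c}`); the id is the first
    integer field after the organ.
    """
    stem = Path(name).stem
    parts = stem.split("_")
    if parts[0] != "human" or len(parts) < 3:
        raise ValueError(
            f"{name!r} does not match 'human_{{organ}}_{{id}}'; known organs: "
            f"{sorted(vocabulary)}")
    for n_organ in range(len(parts) - 2, 0, -1):      # longest organ first
        organ = "_".join(parts[1:1 + n_organ])
        rest = parts[1 + n_organ:]
        if organ in vocabulary and all(p.isdigit() for p in rest):
            return organ, int(rest[0])
    raise ValueError(
        f"{name!r}: organ not in vocabulary or non-integer id; known organs: "
        f"{sorted(vocabulary)}")


def stratified_split(records: list[SampleRecord],
                     cfg: SplitConfig = SplitConfig()) -> list[SampleRecord]:
    """Assign train/test per organ at the source-image level.

    Per organ, ceil(train_fraction * n_sources) sources go to train after
    a seeded shuffle; augmented copies inherit their source's split. An
    organ with a single source is placed entirely in train with a warning.
    """
    rng = np.random.default_rng(cfg.seed)
    by_organ: dict[str, list] = {}
    for rec in records:
        by_organ.setdefault(rec.organ, [])
        if rec.source_id not in by_organ[rec.organ]:
            by_organ[rec.organ].append(rec.source_id)
    assignment: dict[tuple, str] = {}
    for organ in sorted(by_organ):
        sources = sorted(by_organ[organ])
        if len(sources) == 1:
            warnings.warn(f"organ {organ!r} has a single source image; "
                          "placing it entirely in train")
            assignment[(organ, sources[0])] = "train"
            continue
        order = rng.permutation(len(sources))
        # ceil toward train, but keep every organ represented in test
        n_train = min(ceil(cfg.train_fraction * len(sources)), len(sources) - 1)
        for rank, idx in enumerate(order):
            assignment[(organ, sources[idx])] = \
                "train" if rank < n_train else "test"
    out = []
    for rec in records:
        out.append(replace(rec, split=assignment[(rec.organ, rec.source_id)]))
    return out


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr


def load_pair(rec: SampleRecord, size: int = 224) -> tuple[np.ndarray, np.ndarray]:
    """(image, mask) tensors of shape (1, size, size).

    The image is greyscaled and bilinearly resized; the mask is resized
    with nearest-neighbour sampling so it stays strictly binary.
    """
    image = rec.image if rec.image is not None else _read_image(rec.image_path)
    mask = rec.mask if rec.mask is not None else _read_image(rec.mask_path)
    grey = to_greyscale(image) if image.ndim == 3 else image
    mask = (np.asarray(mask) > 0.5).astype(np.float64)
    if grey.shape != (size, size):
        grey = resize(grey, (size, size), order=1, anti_aliasing=True,
                      preserve_range=True)
    if mask.shape != (size, size):
        mask = resize(mask, (size, size), order=0, anti_aliasing=False,
                      preserve_range=True)
    return grey[None].astype(np.float64), mask[None].astype(np.float64)
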