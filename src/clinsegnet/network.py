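"""ClinSegNet: organ-conditioned SEU-Net with edge-assisted supervision.

The backbone is a symmetric encoder-decoder (U-Net) with seven stages of
channel widths (64, 128, 256, 512, 256, 128, 64) at the default size:
four encoder stages (the fourth is the bottleneck) and three decoder
stages. Each stage is a double 3x3 conv block optionally followed by
squeeze-and-excitation channel recalibration and FiLM conditioning on a
learned organ embedding. An auxiliary edge head reads the last decoder
stage's features and predicts a boundary probability map through a STEM
block and three parallel dilated convolutions (dilation 1, 2, 3).

Turning the three mechanisms (SE, FiLM, edge) on and off yields the eight
ablation variants of the framework, down to the plain backbone.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (
    Adam, Conv2d, ConvTranspose2x2, DoubleConv, Embedding, FiLM, Module,
    SEBlock, Tensor, concat, no_grad,
)

__all__ = [
    "NetworkConfig", "OrganVocabulary", "SegmentationOutput", "ClinSegNet",
    "count_parameters", "save_checkpoint", "load_checkpoint",
]

DEFAULT_STAGE_CHANNELS = (64, 128, 256, 512, 256, 128, 64)


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    stage_channels: tuple = DEFAULT_STAGE_CHANNELS
    embed_dim: int = 32
    se_reduction: int = 16
    dilations: tuple = (1, 2, 3)
    use_se: bool = True
    use_film: bool = True
    use_edge: bool = True
    input_size: int = 224
    seed: int = 0

    def __post_init__(self):
        sc = tuple(self.stage_channels)
        if len(sc) != 7:
            raise ValueError("stage_channels must list seven stages")
        if sc[2] != sc[4] or sc[1] != sc[5] or sc[0] != sc[6]:
            raise ValueError("decoder stages must mirror encoder widths")
        if tuple(self.dilations) != (1, 2, 3):
            raise ValueError("edge-branch dilations are fixed at (1, 2, 3)")
        if self.embed_dim < 1 or self.in_channels < 1:
            raise ValueError("embed_dim and in_channels must be positive")


class OrganVocabulary:
    """Ordered organ-name list with a bijective name <-> label mapping.

    Labels are 1-based (1..K); the ordering is persisted with checkpoints
    so conditioning stays consistent across sessions.
    """

    def __init__(self, names: list[str]):
        names = list(names)
        if len(set(names)) != len(names):
            raise ValueError("organ names must be unique")
        if not names:
            raise ValueError("vocabulary must not be empty")
        self.names = names
        self._to_label = {n: i + 1 for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._to_label

    def label(self, name: str) -> int:
        try:
            return self._to_label[name]
        except KeyError:
            raise KeyError(
                f"unknown organ {name!r}; vocabulary: {self.names}") from None

    def name(self, label: int) -> str:
        if not 1 <= label <= len(self.names):
            raise ValueError(f"label {label} outside 1..{len(self.names)}")
        return self.names[label - 1]

    def labels(self, names) -> np.ndarray:
        return np.array([self.label(n) for n in names], dtype=np.int64)


@dataclass
class SegmentationOutput:
    prob: Tensor                 # (B, 1, H, W) sigmoid lesion probability
    edge_prob: Tensor | None     # (B, 1, H, W) sigmoid edge probability


class _Stage(Module):
    """Double conv -> [SE] -> [FiLM]; the FiLM order puts conditioning last
    so it acts on recalibrated channels."""

    def __init__(self, cin: int, cout: int, cfg: NetworkConfig,
                 rng: np.random.Generator):
        self.block = DoubleConv(cin, cout, rng=rng)
        self.se = SEBlock(cout, cfg.se_reduction, rng=rng) if cfg.use_se else None
        self.film = FiLM(cfg.embed_dim, cout, rng=rng, zero_init=True) \
            if cfg.use_film else None

    def forward(self, x: Tensor, z: Tensor | None) -> Tensor:
        out = self.block(x)
        if self.se is not None:
            out = self.se(out)
        if self.film is not None:
            out = self.film(out, z)
        return out


class _EdgeHead(Module):
    """STEM (two 3x3 conv + ReLU) -> three parallel dilated 3x3 convs
    (d = 1, 2, 3, padding = dilation) -> concat -> two 1x1 convs -> sigmoid."""

    def __init__(self, cin: int, rng: np.random.Generator):
        self.stem1 = Conv2d(cin, 32, rng=rng)
        self.stem2 = Conv2d(32, 32, rng=rng)
        self.branches = [Conv2d(32, 32, dilation=d, rng=rng) for d in (1, 2, 3)]
        self.fuse1 = Conv2d(96, 32, k=1, padding=0, rng=rng)
        self.fuse2 = Conv2d(32, 1, k=1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem2(self.stem1(x).relu()).relu()
        multi = concat([b(h).relu() for b in self.branches], axis=1)
        return self.fuse2(self.fuse1(multi).relu()).sigmoid()


class ClinSegNet(Module):
    def __init__(self, config: NetworkConfig, vocabulary: OrganVocabulary):
        self.config = config
        self.vocabulary = vocabulary
        rng = np.random.default_rng(config.seed)
        c = tuple(config.stage_channels)
        K = len(vocabulary)

        if config.use_film:
            self.embedding = Embedding(K, config.embed_dim, rng=rng)
        else:
            self.embedding = None

        self.enc1 = _Stage(config.in_channels, c[0], config, rng)
        self.enc2 = _Stage(c[0], c[1], config, rng)
        self.enc3 = _Stage(c[1], c[2], config, rng)
        self.enc4 = _Stage(c[2], c[3], config, rng)       # bottleneck
        self.up5 = ConvTranspose2x2(c[3], c[4], rng=rng)
        self.dec5 = _Stage(c[2] + c[4], c[4], config, rng)
        self.up6 = ConvTranspose2x2(c[4], c[5], rng=rng)
        self.dec6 = _Stage(c[1] + c[5], c[5], config, rng)
        self.up7 = ConvTranspose2x2(c[5], c[6], rng=rng)
        self.dec7 = _Stage(c[0] + c[6], c[6], config, rng)
        self.out_conv = Conv2d(c[6], 1, k=1, padding=0, rng=rng)
        self.edge_head = _EdgeHead(c[6], rng) if config.use_edge else None

    # ------------------------------------------------------------------
    def embed_organ(self, labels: np.ndarray) -> Tensor:
        """Look up the (B, d) organ embedding for 1-based labels."""
        if self.embedding is None:
            raise RuntimeError("FiLM conditioning is disabled in this config")
        labels = np.asarray(labels, dtype=np.int64)
        K = len(self.vocabulary)
        if labels.min() < 1 or labels.max() > K:
            raise ValueError(f"organ labels must lie in 1..{K}")
        return self.embedding(labels - 1)

    def forward(self, image: np.ndarray | Tensor,
                organ: np.ndarray | list | None = None) -> SegmentationOutput:
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (B, {self.config.in_channels}, H, W), got {x.shape}")
        H, W = x.shape[2], x.shape[3]
        if H % 8 or W % 8:
            raise ValueError(f"spatial size must be divisible by 8, got {H}x{W}")

        z = None
        if self.config.use_film:
            if organ is None:
                raise ValueError("organ labels required when FiLM is enabled")
            labels = np.asarray(organ)
            if labels.dtype.kind in "US":
                labels = self.vocabulary.labels(list(labels))
            z = self.embed_organ(labels)

        e1 = self.enc1(x, z)
        e2 = self.enc2(e1.maxpool2x2(), z)
        e3 = self.enc3(e2.maxpool2x2(), z)
        e4 = self.enc4(e3.maxpool2x2(), z)
        d5 = self.dec5(concat([self.up5(e4), e3], axis=1), z)
        d6 = self.dec6(concat([self.up6(d5), e2], axis=1), z)
        d7 = self.dec7(concat([self.up7(d6), e1], axis=1), z)
        prob = self.out_conv(d7).sigmoid()
        edge = self.edge_head(d7) if self.edge_head is not None else None
        return SegmentationOutput(prob=prob, edge_prob=edge)

    def predict_proba(self, image: np.ndarray, organ=None) -> np.ndarray:
        """Inference helper: forward pass without building a graph."""
        with no_grad():
            return self.forward(image, organ).prob.data


def count_parameters(model: ClinSegNet) -> dict[str, int]:
    """Learnable scalar counts per top-level submodule, plus 'total'."""
    counts: dict[str, int] = {}
    for name, p in model.named_parameters().items():
        top = name.split(".")[0]
        counts[top] = counts.get(top, 0) + p.data.size
    counts["total"] = sum(v for k, v in counts.items())
    return counts


def save_checkpoint(path: str | Path, model: ClinSegNet,
                    extra: dict | None = None) -> None:
    """Self-describing checkpoint: weights + config + organ vocabulary."""
    payload = {
        "state_dict": model.state_dict(),
        "config": model.config.__dict__ | {
            "stage_channels": tuple(model.config.stage_channels),
            "dilations": tuple(model.config.dilations),
        },
        "vocabulary": list(model.vocabulary.names),
        "extra": extra or {},
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path: str | Path) -> tuple[ClinSegNet, dict]:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg = NetworkConfig(**payload["config"])
    model = ClinSegNet(cfg, OrganVocabulary(payload["vocabulary"]))
    model.load_state_dict(payload["state_dict"])
    return model, payload.get("extra", {})
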