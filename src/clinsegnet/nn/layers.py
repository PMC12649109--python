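"""Neural building blocks on top of the autograd engine.

Modules hold named parameters (a flat dict of dotted names -> Tensor),
mirroring the familiar named_parameters() convention so that freezing by
name prefix is straightforward.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "Conv2d", "ConvTranspose2x2", "Linear", "Embedding",
    "DoubleConv", "SEBlock", "FiLM", "concat",
]


class Module:
    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(attr, Tensor):
                params[full] = attr
            elif isinstance(attr, Module):
                params.update(attr.named_parameters(full))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{full}.{i}"))
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict key mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """kxk stride-1 convolution with `padding = dilation * (k-1) / 2` default."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.dilation = dilation
        self.padding = padding if padding is not None else dilation * (k - 1) // 2
        self.w = Tensor(_he(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b, padding=self.padding, dilation=self.dilation)


class ConvTranspose2x2(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(_he(rng, (cin, cout, 2, 2), cin * 4), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2x2(self.w, self.b)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        w = np.zeros((fin, fout)) if zero_init else _he(rng, (fin, fout), fin)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(fout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class Embedding(Module):
    """Learnable (K, d) lookup table for organ labels."""

    def __init__(self, num: int, dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.table = Tensor(rng.normal(0.0, 1.0, size=(num, dim)), requires_grad=True)

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.table.embedding_lookup(idx)


class DoubleConv(Module):
    """The U-Net stage block: two 3x3 convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(cin, cout, rng=rng)
        self.conv2 = Conv2d(cout, cout, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


class SEBlock(Module):
    """Squeeze-and-Excitation channel recalibration.

    Global average pool -> FC(C -> C/r) -> ReLU -> FC(-> C) -> sigmoid,
    then per-channel rescaling of the feature map. Weights lie in (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=(2, 3))                       # (B, C)
        weights = self.fc2(self.fc1(squeezed).relu()).sigmoid()
        B, C = weights.shape
        return x * weights.reshape(B, C, 1, 1)


class FiLM(Module):
    """Feature-wise linear modulation conditioned on an organ embedding.

    gamma = sigmoid(W_g z + b_g), beta = W_b z + b_b; the feature map is
    transformed channel-wise as (1 + gamma) * F + beta, so the scale is
    always in (1, 2). With all-zero parameters the block multiplies by
    exactly 1.5 (sigmoid(0) = 0.5) and shifts by 0.
    """

    def __init__(self, embed_dim: int, channels: int,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        self.gamma = Linear(embed_dim, channels, rng=rng, zero_init=zero_init)
        self.beta = Linear(embed_dim, channels, rng=rng, zero_init=zero_init)
        if zero_init:
            self.beta.b.data[:] = 0.0

    def forward(self, x: Tensor, z: Tensor) -> Tensor:
        B = x.shape[0]
        C = x.shape[1]
        gamma = self.gamma(z).sigmoid()
        beta = self.beta(z)
        scale = (1.0 + gamma).reshape(B, C, 1, 1)
        return x * scale + beta.reshape(B, C, 1, 1)
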