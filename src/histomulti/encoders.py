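"""Dual-branch reference encoders with Monte-Carlo-dropout heads.

The multiscale pipeline uses a convolutional *context* branch for the 10x
patch and a small vision-transformer *cellular* branch for the 40x patch.
The branch contract is deliberately minimal — image in, features out (plus
per-layer per-head attention for the transformer) — so production backbones
can be swapped in; the classes here are small randomly initialised reference
networks sized so a full forward on a 64x64 input runs in milliseconds on a
CPU.  Uncertainty comes from Monte-Carlo dropout applied in the
classification heads only: T stochastic passes with independent dropout
masks approximate the predictive distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, as_tensor, softmax
from .nn import Conv2d, LayerNorm, Linear, dropout_mask

__all__ = [
    "EncoderConfig",
    "FeatureMap",
    "TokenSequence",
    "StochasticPasses",
    "ContextEncoder",
    "CellularEncoder",
    "MCHead",
    "encode_context",
    "encode_cellular",
    "mc_forward",
]


@dataclass(frozen=True)
class EncoderConfig:
    branch: str  # {"context10", "cellular40"}
    hidden_dim: int = 64  # paper-scale default is 768
    n_heads: int = 4  # paper-scale default is 12
    n_layers: int = 2
    token_patch_px: int = 16
    dropout_rate: float = 0.3
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.branch not in ("context10", "cellular40"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class FeatureMap:
    values: np.ndarray  # (channels, rows, cols)


@dataclass
class TokenSequence:
    tokens: np.ndarray  # (n_tokens, hidden_dim)
    token_grid: tuple  # (rows, cols)
    attn: np.ndarray  # (layers, heads, n_tokens, n_tokens), rows stochastic


@dataclass
class StochasticPasses:
    passes: list  # T class-probability vectors (numpy)
    T: int
    seed: int


class ContextEncoder:
    """Purely convolutional 10x branch; total stride 8."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None):
        if cfg.branch != "context10":
            raise ValueError("ContextEncoder requires branch='context10'")
        rng = rng or np.random.default_rng(cfg.seed)
        h = cfg.hidden_dim
        self.cfg = cfg
        self.c1 = Conv2d(3, max(8, h // 4), k=4, stride=4, pad=0, rng=rng)
        self.c2 = Conv2d(max(8, h // 4), max(16, h // 2), k=3, stride=1, pad=1, rng=rng)
        self.c3 = Conv2d(max(16, h // 2), h, k=2, stride=2, pad=0, rng=rng)
        self.stride = 8

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, 3, H, W) in [0, 1] -> (B, hidden, H/8, W/8)."""
        return self.c3(self.c2(self.c1(as_tensor(x)).relu()).relu())

    def pooled(self, x: Tensor) -> Tensor:
        f = self.forward(x)
        return f.mean(axis=(2, 3))

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters() + self.c3.parameters()


class _ViTBlock:
    def __init__(self, h: int, n_heads: int, rng):
        self.h, self.n_heads = h, n_heads
        self.ln1 = LayerNorm(h)
        self.qkv = Linear(h, 3 * h, rng)
        self.proj = Linear(h, h, rng)
        self.ln2 = LayerNorm(h)
        self.fc1 = Linear(h, 2 * h, rng)
        self.fc2 = Linear(2 * h, h, rng)

    def __call__(self, x: Tensor):
        B, n, h = x.shape
        dh = h // self.n_heads
        qkv = self.qkv(self.ln1(x)).reshape(B, n, 3, self.n_heads, dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, heads, n, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)  # (B, heads, n, n)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, n, h)
        x = x + self.proj(out)
        x = x + self.fc2(self.fc1(self.ln2(x)).relu())
        return x, attn

    def parameters(self):
        return (self.ln1.parameters() + self.qkv.parameters() + self.proj.parameters()
                + self.ln2.parameters() + self.fc1.parameters() + self.fc2.parameters())


class CellularEncoder:
    """Tiny ViT for the 40x branch; exposes every layer/head attention matrix."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None,
                 in_channels: int = 3, image_px: int | None = None):
        if cfg.branch != "cellular40":
            raise ValueError("CellularEncoder requires branch='cellular40'")
        rng = rng or np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.in_channels = in_channels
        p, h = cfg.token_patch_px, cfg.hidden_dim
        self.embed = Linear(in_channels * p * p, h, rng)
        self.pos: Tensor | None = None
        self._pos_rng = np.random.default_rng(int(rng.integers(2**31)))
        self.blocks = [_ViTBlock(h, cfg.n_heads, rng) for _ in range(cfg.n_layers)]
        self.ln_f = LayerNorm(h)

    def _ensure_pos(self, n_tokens: int):
        if self.pos is None:
            self.pos = Tensor(
                self._pos_rng.normal(0.0, 0.02, (n_tokens, self.cfg.hidden_dim)), True
            )
        elif self.pos.shape[0] != n_tokens:
            raise ValueError("token count changed after positional table was built")

    def patchify(self, images: np.ndarray) -> tuple[np.ndarray, tuple]:
        """(B, C, H, W) -> (B, n_tokens, C*p*p) row-major token order."""
        p = self.cfg.token_patch_px
        B, C, H, W = images.shape
        if H % p or W % p:
            raise ValueError("image side must be divisible by token_patch_px")
        gh, gw = H // p, W // p
        t = images.reshape(B, C, gh, p, gw, p).transpose(0, 2, 4, 1, 3, 5)
        return t.reshape(B, gh * gw, C * p * p), (gh, gw)

    def forward(self, images: np.ndarray):
        """Returns (tokens Tensor (B, n, h), attn list of (B, heads, n, n), grid)."""
        patches, grid = self.patchify(np.asarray(images, dtype=np.float64))
        self._ensure_pos(patches.shape[1])
        x = self.embed(Tensor(patches)) + self.pos
        attns = []
        for blk in self.blocks:
            x, a = blk(x)
            attns.append(a)
        return self.ln_f(x), attns, grid

    def parameters(self):
        ps = self.embed.parameters() + self.ln_f.parameters()
        if self.pos is not None:
            ps.append(self.pos)
        for blk in self.blocks:
            ps += blk.parameters()
        return ps


class MCHead:
    """Two-layer classification head with dropout between the layers."""

    def __init__(self, n_in: int, n_classes: int, rng: np.random.Generator,
                 n_hidden: int | None = None):
        n_hidden = n_hidden or max(16, n_in // 2)
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_classes, rng)
        self.n_hidden = n_hidden
        self.n_classes = n_classes

    def forward(self, x, mask: np.ndarray | None = None) -> Tensor:
        h = self.fc1(as_tensor(x)).relu()
        if mask is not None:
            h = h * Tensor(mask)
        return softmax(self.fc2(h), axis=-1)

    def mc_passes(self, x, T: int, dropout_rate: float,
                  rng: np.random.Generator) -> list[Tensor]:
        x = as_tensor(x)
        batch_shape = x.shape[:-1]
        out = []
        for _ in range(T):
            mask = dropout_mask(batch_shape + (self.n_hidden,), dropout_rate, rng)
            out.append(self.forward(x, mask))
        return out

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


# -- functional surface ------------------------------------------------------


def encode_context(image10: np.ndarray, cfg: EncoderConfig,
                   encoder: ContextEncoder | None = None) -> FeatureMap:
    """Run the (deterministically initialised) context branch on one image."""
    enc = encoder or ContextEncoder(cfg)
    x = np.asarray(image10, dtype=np.float64) / 255.0
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("image10 must be (H, W, 3)")
    out = enc.forward(Tensor(x.transpose(2, 0, 1)[None]))
    return FeatureMap(values=out.data[0])


def encode_cellular(image40: np.ndarray, cfg: EncoderConfig,
                    encoder: CellularEncoder | None = None) -> TokenSequence:
    """Run the cellular branch on one image; returns tokens plus attention."""
    enc = encoder or CellularEncoder(cfg)
    x = np.asarray(image40, dtype=np.float64) / 255.0
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("image40 must be (H, W, 3)")
    tokens, attns, grid = enc.forward(x.transpose(2, 0, 1)[None])
    attn = np.stack([a.data[0] for a in attns])  # (layers, heads, n, n)
    return TokenSequence(tokens=tokens.data[0], token_grid=grid, attn=attn)


def mc_forward(head: MCHead, features, T: int, dropout_rate: float,
               seed: int) -> StochasticPasses:
    """T stochastic softmax passes with independent dropout masks (seeded)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    feats = np.asarray(features, dtype=np.float64)
    passes = [p.data.copy() for p in head.mc_passes(Tensor(feats), T, dropout_rate, rng)]
    return StochasticPasses(passes=passes, T=T, seed=seed)
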