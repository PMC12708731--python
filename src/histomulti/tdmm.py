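"""Dual-modality morphometry fusion (TDMM).

Nuclei centroids induce a discrete Voronoi tessellation of the patch (each
pixel owned by its nearest centroid, ties broken toward the lowest centroid
index).  Three per-pixel morphometry channels are derived from it — owning
region area, distance to the nearest centroid, and the owning region's
neighbour count — each min-max normalised over the patch.  The morphometry
map and the image are embedded by separate tokenisers and fused by
scaled-dot-product cross-attention, Q from the image tokens and K, V from
the morphometry tokens; a small MLP head classifies the mean-pooled fused
embedding.

The tessellation is computed exactly by (chunked) brute-force nearest
centroid on the pixel grid rather than by geometric polygon clipping: on a
discrete raster the brute force *is* the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, as_tensor, softmax
from .nn import Linear
from .synthetic import NucleusRecord

__all__ = [
    "MorphometryMap",
    "ModalityEmbedding",
    "AttentionParams",
    "FusedEmbedding",
    "ClassifierHead",
    "voronoi_morphometry",
    "cross_modal_attention",
    "classify",
    "write_morphometry_tiff",
]


@dataclass
class MorphometryMap:
    channels: np.ndarray  # (3, H, W) in [0, 1]: area, nearest-distance, neighbour count
    empty_flag: bool


@dataclass
class ModalityEmbedding:
    E_img: np.ndarray  # (n_img_tokens, d)
    E_morph: np.ndarray  # (n_morph_tokens, d)


@dataclass
class AttentionParams:
    W_Q: np.ndarray  # (d, d_k)
    W_K: np.ndarray
    W_V: np.ndarray
    d_k: int


@dataclass
class FusedEmbedding:
    F: np.ndarray  # (n_img_tokens, d_k)


class ClassifierHead:
    """Two-layer perceptron over the mean-pooled fused embedding."""

    def __init__(self, d_in: int, n_classes: int, rng: np.random.Generator,
                 d_hidden: int | None = None):
        d_hidden = d_hidden or max(16, d_in)
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, pooled) -> Tensor:
        return softmax(self.fc2(self.fc1(as_tensor(pooled)).relu()), axis=-1)

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters()


def _min_max(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def voronoi_morphometry(centroids, patch_px: int) -> MorphometryMap:
    """Exact nearest-centroid tessellation and its morphometry channels."""
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    k = len(centroids)
    if k == 0:
        return MorphometryMap(channels=np.zeros((3, patch_px, patch_px)), empty_flag=True)
    cx = np.array([c.x for c in centroids], dtype=np.float64)
    cy = np.array([c.y for c in centroids], dtype=np.float64)
    owner = np.empty((patch_px, patch_px), dtype=np.int64)
    dist = np.empty((patch_px, patch_px), dtype=np.float64)
    cols = np.arange(patch_px, dtype=np.float64)
    chunk = max(1, (1 << 22) // max(1, patch_px * k))  # ~32 MB of float64 per chunk
    for r0 in range(0, patch_px, chunk):
        rows = np.arange(r0, min(r0 + chunk, patch_px), dtype=np.float64)
        d2 = (rows[:, None, None] - cy[None, None, :]) ** 2 + \
             (cols[None, :, None] - cx[None, None, :]) ** 2
        owner[r0 : r0 + len(rows)] = d2.argmin(axis=2)  # argmin -> lowest index on ties
        dist[r0 : r0 + len(rows)] = np.sqrt(d2.min(axis=2))
    areas = np.bincount(owner.ravel(), minlength=k).astype(np.float64)
    # region neighbour counts from 4-adjacency of the ownership map
    nb = np.zeros((k, k), dtype=bool)
    for a, b in ((owner[:, :-1], owner[:, 1:]), (owner[:-1, :], owner[1:, :])):
        m = a != b
        nb[a[m], b[m]] = True
        nb[b[m], a[m]] = True
    n_neighbors = nb.sum(axis=1).astype(np.float64)
    ch = np.stack([_min_max(areas[owner]), _min_max(dist), _min_max(n_neighbors[owner])])
    return MorphometryMap(channels=ch, empty_flag=False)


def cross_modal_attention(E, P: AttentionParams):
    """F = softmax(Q K^T / sqrt(d_k)) V with Q from image, K/V from morphometry.

    Accepts ndarray embeddings (returns FusedEmbedding) or Tensors (returns
    a Tensor, differentiable w.r.t. embeddings and projections).  Batched
    inputs (B, n, d) are supported.
    """
    E_img = E.E_img if isinstance(E, ModalityEmbedding) else E[0]
    E_morph = E.E_morph if isinstance(E, ModalityEmbedding) else E[1]
    tensor_mode = any(isinstance(x, Tensor) for x in (E_img, E_morph, P.W_Q))
    if E_img.shape[-1] != P.W_Q.shape[0] or E_morph.shape[-1] != P.W_K.shape[0]:
        raise ValueError("embedding dimension does not match projection matrices")
    if tensor_mode:
        Q = as_tensor(E_img) @ as_tensor(P.W_Q)
        K = as_tensor(E_morph) @ as_tensor(P.W_K)
        V = as_tensor(E_morph) @ as_tensor(P.W_V)
        scores = (Q @ K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)) * (
            1.0 / np.sqrt(P.d_k)
        )
        return softmax(scores, axis=-1) @ V
    Q = E_img @ P.W_Q
    K = E_morph @ P.W_K
    V = E_morph @ P.W_V
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(P.d_k)
    return FusedEmbedding(F=softmax(scores, axis=-1) @ V)


def classify(F, head: ClassifierHead) -> np.ndarray:
    """Mean-pool fused token rows, run the MLP head, return class probabilities."""
    feats = F.F if isinstance(F, FusedEmbedding) else F
    if isinstance(feats, Tensor):
        single = feats.ndim == 2
        pooled = feats.mean(axis=-2, keepdims=single)  # keep 2-D for the matmuls
        out = head.forward(pooled)
        return out[0] if single else out
    pooled = np.asarray(feats, dtype=np.float64).mean(axis=-2)
    single = pooled.ndim == 1
    out = head.forward(Tensor(pooled[None] if single else pooled)).data
    return out[0] if single else out


def write_morphometry_tiff(path, mm: MorphometryMap):
    """3-channel 16-bit TIFF export (values scaled by 65535)."""
    import tifffile

    arr = np.round(mm.channels * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, arr.transpose(1, 2, 0))
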