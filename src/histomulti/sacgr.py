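"""Structural attention-constrained graph regularisation (SACGR).

Tissue topology is summarised as a superpixel graph: nodes are superpixels,
edges join spatially adjacent superpixels (sharing a 4-connected pixel
boundary), and edge weights follow a Gaussian kernel on mean-color
distance.  Rows are sparsified to at most ``max_neighbors`` entries (the
pipeline default is 8), re-symmetrised, and row-normalised.  The
transformer's token-level attention is pooled onto the same node set —
average over selected layers and all heads, symmetrise, then mean over
token pairs belonging to each node pair — and the structural loss is the
mean squared difference between the two (row-normalised) adjacencies over
ordered off-diagonal pairs.  A companion smoothness term penalises feature
differences along strong graph edges.

`attention_adjacency`, `sacgr_loss` and `smoothness_loss` accept autodiff
Tensors, so gradients flow back into the transformer during training.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, tsum

log = logging.getLogger(__name__)

__all__ = [
    "TissueGraph",
    "TokenAssignment",
    "AttentionAdjacency",
    "build_tissue_graph",
    "assign_tokens",
    "attention_adjacency",
    "sacgr_loss",
    "smoothness_loss",
    "off_graph_attention_mass",
]


@dataclass
class TissueGraph:
    n_nodes: int
    A: np.ndarray  # (n, n) symmetric-support, zero diagonal, row-normalised
    node_centroid: np.ndarray  # (n, 2) mean (row, col) per node
    node_color: np.ndarray  # (n, 3) mean RGB per node

    def to_edge_json(self) -> str:
        edges = [
            {"i": int(i), "j": int(j), "weight": float(self.A[i, j])}
            for i, j in zip(*np.nonzero(self.A))
        ]
        return json.dumps(edges)

    def write_node_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node", "row", "col", "r", "g", "b"])
            for i in range(self.n_nodes):
                w.writerow([i, *(f"{v:.3f}" for v in self.node_centroid[i]),
                            *(f"{v:.3f}" for v in self.node_color[i])])


@dataclass
class TokenAssignment:
    token_to_node: np.ndarray  # (n_tokens,) int
    n_tokens: int
    n_nodes: int


@dataclass
class AttentionAdjacency:
    A_attn: np.ndarray  # (n_nodes, n_nodes)


def _check_contiguous(labels: np.ndarray) -> int:
    uniq = np.unique(labels)
    n = labels.max() + 1
    if uniq.size != n or uniq[0] != 0:
        raise ValueError("superpixel labels must be contiguous from 0")
    return int(n)


def _adjacent_pairs(labels: np.ndarray) -> np.ndarray:
    """Unordered pairs of labels sharing a 4-connected boundary."""
    pairs = []
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        m = a != b
        pairs.append(np.stack([a[m], b[m]], axis=1))
    pairs = np.concatenate(pairs)
    pairs.sort(axis=1)
    return np.unique(pairs, axis=0)


def build_tissue_graph(superpixel_labels: np.ndarray, image: np.ndarray,
                       max_neighbors: int = 8, color_bandwidth: float = 51.0) -> TissueGraph:
    """Superpixel adjacency with Gaussian mean-color edge weights.

    color_bandwidth defaults to 0.2 * 255 (mid-range color sensitivity).
    """
    n = _check_contiguous(superpixel_labels)
    flat = superpixel_labels.ravel()
    counts = np.bincount(flat, minlength=n).astype(np.float64)
    img = np.asarray(image, dtype=np.float64).reshape(-1, image.shape[-1])
    color = np.stack([np.bincount(flat, weights=img[:, c], minlength=n) for c in range(3)],
                     axis=1) / counts[:, None]
    rows_idx, cols_idx = np.indices(superpixel_labels.shape)
    centroid = np.stack(
        [np.bincount(flat, weights=rows_idx.ravel(), minlength=n),
         np.bincount(flat, weights=cols_idx.ravel(), minlength=n)], axis=1
    ) / counts[:, None]

    W = np.zeros((n, n))
    if n > 1:
        pairs = _adjacent_pairs(superpixel_labels)
        d2 = np.sum((color[pairs[:, 0]] - color[pairs[:, 1]]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * color_bandwidth**2))
        W[pairs[:, 0], pairs[:, 1]] = w
        W[pairs[:, 1], pairs[:, 0]] = w
        # top-k sparsification per row, then re-symmetrise by max
        if n - 1 > max_neighbors:
            keep = np.zeros_like(W, dtype=bool)
            order = np.argsort(-W, axis=1)[:, :max_neighbors]
            np.put_along_axis(keep, order, True, axis=1)
            keep &= W > 0
            Wk = np.where(keep, W, 0.0)
            W = np.maximum(Wk, Wk.T)
        np.fill_diagonal(W, 0.0)
        s = W.sum(axis=1, keepdims=True)
        W = np.divide(W, s, out=np.zeros_like(W), where=s > 0)
    return TissueGraph(n_nodes=n, A=W, node_centroid=centroid, node_color=color)


def assign_tokens(superpixel_labels: np.ndarray, token_grid: tuple,
                  token_patch_px: int) -> TokenAssignment:
    """Majority superpixel label inside each token footprint; ties -> smallest id."""
    gh, gw = token_grid
    p = token_patch_px
    H, W = superpixel_labels.shape
    if gh * p != H or gw * p != W:
        raise ValueError("token grid x patch size must equal the label-map size")
    n_nodes = _check_contiguous(superpixel_labels)
    tiles = superpixel_labels.reshape(gh, p, gw, p).transpose(0, 2, 1, 3).reshape(gh * gw, p * p)
    t2n = np.array([np.bincount(t, minlength=n_nodes).argmax() for t in tiles])
    return TokenAssignment(token_to_node=t2n, n_tokens=gh * gw, n_nodes=n_nodes)


def _pool_matrix(assignment: TokenAssignment) -> tuple[np.ndarray, np.ndarray]:
    M = np.zeros((assignment.n_tokens, assignment.n_nodes))
    M[np.arange(assignment.n_tokens), assignment.token_to_node] = 1.0
    counts = M.sum(axis=0)
    return M, counts


def attention_adjacency(attn, assignment: TokenAssignment, layer_set: str = "last"):
    """Pool token attention onto superpixel node pairs.

    attn: (layers, heads, n_tokens, n_tokens) ndarray or Tensor with
    stochastic rows.  Returns AttentionAdjacency (ndarray input) or a Tensor
    (Tensor input) so the pooling stays differentiable during training.
    """
    if layer_set not in ("last", "all"):
        raise ValueError("layer_set must be 'last' or 'all'")
    is_t = isinstance(attn, Tensor)
    shape = attn.shape
    if shape[-1] != assignment.n_tokens:
        raise ValueError("attention token count does not match the assignment")
    sel = attn[-1] if layer_set == "last" else attn  # (heads, n, n) or (L, heads, n, n)
    T = sel.mean(axis=tuple(range(sel.ndim - 2)))
    sym = (T + T.T) * 0.5
    M, counts = _pool_matrix(assignment)
    pair_counts = np.outer(counts, counts)
    np.fill_diagonal(pair_counts, counts * counts)
    pair_counts = np.maximum(pair_counts, 1.0)
    offdiag = 1.0 - np.eye(assignment.n_nodes)
    if is_t:
        S = Tensor(M.T) @ sym @ Tensor(M)
        pooled = S * (1.0 / pair_counts) * offdiag
        denom = pooled.sum(axis=1, keepdims=True) + 1e-30
        return pooled / denom
    S = M.T @ sym @ M
    pooled = S / pair_counts * offdiag
    s = pooled.sum(axis=1, keepdims=True)
    pooled = np.divide(pooled, s, out=np.zeros_like(pooled), where=s > 0)
    return AttentionAdjacency(A_attn=pooled)


def _attn_array(A_attn):
    return A_attn.A_attn if isinstance(A_attn, AttentionAdjacency) else A_attn


def sacgr_loss(G, A_attn):
    """Mean squared adjacency mismatch over ordered off-diagonal pairs."""
    A = G.A if isinstance(G, TissueGraph) else np.asarray(G, dtype=np.float64)
    B = _attn_array(A_attn)
    n = A.shape[0]
    if tuple(B.shape) != (n, n):
        raise ValueError("node counts differ")
    if n < 2:
        return Tensor(0.0) if isinstance(B, Tensor) else 0.0
    offdiag = 1.0 - np.eye(n)
    n_pairs = n * (n - 1)
    if isinstance(B, Tensor):
        d = Tensor(A) - B
        return tsum(d * d * offdiag) * (1.0 / n_pairs)
    d = (A - B) * offdiag
    return float((d**2).sum() / n_pairs)


def smoothness_loss(token_features, assignment: TokenAssignment, G: TissueGraph):
    """Graph-Laplacian-style feature smoothness along tissue edges.

    Node feature = mean of its tokens' features; returns
    sum_{i<j} A_ij ||f_i - f_j||^2 / sum_{i<j} A_ij.  Nodes with no tokens
    are excluded (a warning is logged).
    """
    feats = getattr(token_features, "tokens", token_features)
    M, counts = _pool_matrix(assignment)
    nonempty = counts > 0
    if not nonempty.all() and not getattr(smoothness_loss, "_warned", False):
        log.warning("smoothness_loss: %d empty node(s) excluded "
                    "(further occurrences suppressed)", (~nonempty).sum())
        smoothness_loss._warned = True
    idx = np.nonzero(nonempty)[0]
    if idx.size < 2:
        return Tensor(0.0) if isinstance(feats, Tensor) else 0.0
    P = (M / np.maximum(counts, 1.0))[:, idx].T  # (n_used, n_tokens)
    A = G.A[np.ix_(idx, idx)]
    Wup = np.triu(A, k=1)
    total = Wup.sum()
    if total <= 0:
        return Tensor(0.0) if isinstance(feats, Tensor) else 0.0
    if isinstance(feats, Tensor):
        f = Tensor(P) @ feats
        s = (f * f).sum(axis=1, keepdims=True)
        d2 = s + s.T - (f @ f.T) * 2.0
        return tsum(d2 * Wup) * (1.0 / total)
    f = P @ np.asarray(feats, dtype=np.float64)
    s = (f**2).sum(axis=1, keepdims=True)
    d2 = s + s.T - 2.0 * f @ f.T
    return float((d2 * Wup).sum() / total)


def off_graph_attention_mass(G: TissueGraph, A_attn) -> float:
    """Fraction of pooled attention mass on node pairs NOT adjacent in the graph."""
    B = _attn_array(A_attn)
    B = B.data if isinstance(B, Tensor) else np.asarray(B, dtype=np.float64)
    offdiag = 1.0 - np.eye(B.shape[0])
    total = (B * offdiag).sum()
    if total <= 0:
        return 0.0
    on = (B * offdiag * (G.A > 0)).sum()
    return float(1.0 - on / total)
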