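"""Positional contrastive alignment across magnifications (CCCRA).

Embeddings of the same entity seen at two magnifications form positive
pairs; every other entity's opposite-view embedding is a negative.  The
objective is InfoNCE over a combined score

    s(i, k) = [ sim(z_i, z_k) + gamma * sim(p_i, p_k) ] / tau

with cosine similarity throughout, gamma the positional-sensitivity weight
(default 0.3) and tau the softmax temperature (default 0.07).  Positions are
normalised (row, col) coordinates in [0, 1]^2, shifted to be centred at
(0.5, 0.5) before the cosine so that raw coordinates' all-positive cosine
degeneracy is avoided; an exactly-central position has zero offset and is
assigned positional similarity 0.

`cccra_loss_matrix` is the differentiable work-horse used by the trainer;
`cccra_loss` is the batch-container front-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, log, softmax, tmean

__all__ = ["CellViewPair", "ContrastiveBatch", "cosine_sim", "cccra_loss",
           "cccra_loss_matrix", "read_batch_csv", "write_batch_csv"]

_EPS = 1e-12


@dataclass
class CellViewPair:
    entity_id: int
    z_i: np.ndarray  # first-view embedding
    z_j: np.ndarray  # second-view embedding (the positive)
    p_i: np.ndarray  # (row, col) in [0,1]^2
    p_j: np.ndarray


@dataclass
class ContrastiveBatch:
    anchors: list  # CellViewPair
    gamma: float = 0.3
    tau: float = 0.07

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise ValueError("a contrastive batch needs at least 2 entities")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def cosine_sim(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= _EPS or nb <= _EPS:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(a @ b / (na * nb))


def _row_normalize(X):
    if isinstance(X, Tensor):
        n = ((X * X).sum(axis=1, keepdims=True) + _EPS).sqrt()
        return X / n
    n = np.sqrt((X**2).sum(axis=1, keepdims=True) + _EPS)
    return X / n


def _center_positions(P: np.ndarray) -> np.ndarray:
    """Shift [0,1]^2 positions to offsets in [-0.5, 0.5]^2 around the centre."""
    return np.asarray(P, dtype=np.float64) - 0.5


def cccra_loss_matrix(Z1, Z2, P1: np.ndarray, P2: np.ndarray,
                      gamma: float = 0.3, tau: float = 0.07):
    """Positional InfoNCE with row i of view 1 anchored against all of view 2.

    Z1, Z2: (N, d) embeddings (ndarray or Tensor); P1, P2: (N, 2) positions
    in [0,1]^2.  Positives sit on the diagonal.  Returns the mean loss over
    the N anchors.
    """
    N = Z1.shape[0]
    if N < 2:
        raise ValueError("need at least 2 entities")
    pc1, pc2 = _center_positions(P1), _center_positions(P2)
    n1 = np.linalg.norm(pc1, axis=1, keepdims=True)
    n2 = np.linalg.norm(pc2, axis=1, keepdims=True)
    # zero-offset rows get positional similarity 0 everywhere
    pos_sim = (pc1 / np.maximum(n1, _EPS)) @ (pc2 / np.maximum(n2, _EPS)).T
    pos_sim *= (n1 > _EPS) * (n2 > _EPS).T
    zn1, zn2 = _row_normalize(Z1), _row_normalize(Z2)
    if isinstance(zn1, Tensor) or isinstance(zn2, Tensor):
        scores = (zn1 @ zn2.T + Tensor(gamma * pos_sim)) * (1.0 / tau)
        probs = softmax(scores, axis=1)
        diag = probs[np.arange(N), np.arange(N)]
        return tmean(-log(diag + _EPS))
    scores = (zn1 @ zn2.T + gamma * pos_sim) / tau
    scores -= scores.max(axis=1, keepdims=True)
    logits = np.exp(scores)
    p = logits[np.arange(N), np.arange(N)] / logits.sum(axis=1)
    return float(np.mean(-np.log(p)))


def write_batch_csv(path, batch: ContrastiveBatch):
    """Table form: one row per (entity, view): entity_id,view,z_0..z_{d-1},p_row,p_col."""
    import csv

    d = batch.anchors[0].z_i.shape[0]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["entity_id", "view"] + [f"z_{k}" for k in range(d)]
                   + ["p_row", "p_col"])
        for a in batch.anchors:
            for view, z, p in ((0, a.z_i, a.p_i), (1, a.z_j, a.p_j)):
                w.writerow([a.entity_id, view] + [f"{v:.9g}" for v in z]
                           + [f"{p[0]:.9g}", f"{p[1]:.9g}"])


def read_batch_csv(path, gamma: float = 0.3, tau: float = 0.07) -> ContrastiveBatch:
    """Load a batch table written by :func:`write_batch_csv`."""
    import csv

    rows: dict = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            eid = int(row["entity_id"])
            d = len([k for k in row if k.startswith("z_")])
            z = np.array([float(row[f"z_{k}"]) for k in range(d)])
            p = np.array([float(row["p_row"]), float(row["p_col"])])
            rows.setdefault(eid, {})[int(row["view"])] = (z, p)
    anchors = []
    for eid in sorted(rows):
        if set(rows[eid]) != {0, 1}:
            raise ValueError(f"entity {eid} is missing one of its two views")
        (zi, pi), (zj, pj) = rows[eid][0], rows[eid][1]
        anchors.append(CellViewPair(eid, zi, zj, pi, pj))
    return ContrastiveBatch(anchors=anchors, gamma=gamma, tau=tau)


def cccra_loss(batch: ContrastiveBatch) -> float:
    """Mean positional InfoNCE over the batch's anchors (first view anchored)."""
    Z1 = np.stack([a.z_i for a in batch.anchors])
    Z2 = np.stack([a.z_j for a in batch.anchors])
    if (np.linalg.norm(Z1, axis=1) <= _EPS).any() or (np.linalg.norm(Z2, axis=1) <= _EPS).any():
        raise ValueError("embeddings must be non-zero for cosine similarity")
    P1 = np.stack([np.asarray(a.p_i, dtype=np.float64) for a in batch.anchors])
    P2 = np.stack([np.asarray(a.p_j, dtype=np.float64) for a in batch.anchors])
    return cccra_loss_matrix(Z1, Z2, P1, P2, gamma=batch.gamma, tau=batch.tau)
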