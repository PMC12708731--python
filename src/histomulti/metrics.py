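"""Evaluation metrics for the multiscale pipeline.

dice and auc are the standard segmentation/classification measures.
cross_mag_nmi quantifies embedding consistency across magnifications by
clustering each view's embeddings (seeded k-means, 10 restarts) and scoring
the normalised mutual information between the two label vectors.
attention_precision asks what fraction of the model's most concentrated
attention mass falls inside an annotated target region: pixels are taken in
descending attention order until a given share of total mass is covered,
and the precision of that selected set against the target mask is returned.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score, roc_auc_score

__all__ = ["dice", "auc", "cross_mag_nmi", "attention_precision"]


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """2|P∩T| / (|P|+|T|); two empty masks score 1.0 by convention."""
    p = np.asarray(pred_mask).astype(bool)
    t = np.asarray(true_mask).astype(bool)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney; ties count 0.5)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def cross_mag_nmi(emb10: np.ndarray, emb40: np.ndarray, k: int, seed: int) -> float:
    """NMI between seeded k-means clusterings of the two views' embeddings."""
    emb10 = np.asarray(emb10, dtype=np.float64)
    emb40 = np.asarray(emb40, dtype=np.float64)
    if emb10.shape[0] != emb40.shape[0]:
        raise ValueError("views must have equal row counts")
    if k < 2 or emb10.shape[0] < k:
        raise ValueError("need at least k rows and k >= 2")
    km = dict(n_clusters=k, n_init=10, random_state=seed)
    l10 = KMeans(**km).fit_predict(emb10)
    l40 = KMeans(**km).fit_predict(emb40)
    return float(normalized_mutual_info_score(l10, l40))


def attention_precision(attn_map: np.ndarray, target_mask: np.ndarray,
                        mass: float = 0.2) -> float:
    """Precision of the smallest top-attention pixel set holding >= `mass`."""
    a = np.asarray(attn_map, dtype=np.float64).ravel()
    t = np.asarray(target_mask).astype(bool).ravel()
    if a.shape != t.shape:
        raise ValueError("shapes differ")
    if (a < 0).any() or a.sum() <= 0:
        raise ValueError("attention map must be non-negative with positive total")
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must lie in (0, 1]")
    # walk groups of equal attention value in descending order; pixels tied at
    # the selection boundary contribute their group's expected target fraction,
    # so the result does not depend on an arbitrary tie order
    values = np.unique(a)[::-1]
    target_mass = mass * a.sum()
    acc_mass = 0.0
    n_sel = 0
    hit_credit = 0.0
    for v in values:
        grp = a == v
        g_size = int(grp.sum())
        g_hits = int(t[grp].sum())
        g_mass = v * g_size
        if v > 0 and acc_mass + g_mass < target_mass - 1e-12:
            acc_mass += g_mass
            n_sel += g_size
            hit_credit += g_hits
        else:
            need = 0 if v == 0 else int(np.ceil((target_mass - acc_mass) / v - 1e-12))
            need = max(0, min(need, g_size))
            n_sel += need
            hit_credit += need * (g_hits / g_size)
            break
    return float(hit_credit / n_sel)
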