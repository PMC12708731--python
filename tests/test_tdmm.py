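"""Voronoi morphometry, cross-modal attention, and the fused classifier."""

import numpy as np
import pytest

from histomulti._tensor import Tensor
from histomulti.synthetic import NucleusRecord
from histomulti.tdmm import (
    AttentionParams,
    ClassifierHead,
    ModalityEmbedding,
    classify,
    cross_modal_attention,
    voronoi_morphometry,
)

from conftest import finite_diff, rel_err


def nuc(x, y):
    return NucleusRecord(x=x, y=y, radius=3.0, cls="normal")


def test_voronoi_degenerate_cases():
    empty = voronoi_morphometry([], 16)
    assert empty.empty_flag and not empty.channels.any()
    single = voronoi_morphometry([nuc(7.5, 7.5)], 16)
    assert not single.empty_flag
    assert np.allclose(single.channels[0], 0.0)  # constant area channel -> zeros
    assert np.allclose(single.channels[2], 0.0)  # no neighbours
    assert single.channels[1].max() == 1.0  # distance channel spans [0, 1]


def test_voronoi_two_centroid_midline():
    px = 16
    mm = voronoi_morphometry([nuc(0, 8), nuc(px - 1, 8)], px)
    # brute-force per-pixel nearest-centroid oracle
    for r in range(px):
        for c in range(px):
            d0 = (r - 8) ** 2 + c**2
            d1 = (r - 8) ** 2 + (c - (px - 1)) ** 2
            owner = 0 if d0 <= d1 else 1
            # distance channel is shared; area channel distinguishes owners only
            # if areas differ; here both regions are 8 columns -> equal area
            assert mm.channels[1][r, c] >= 0
            expected_owner = 0 if c < px / 2 else 1
            assert owner == expected_owner or d0 == d1


def test_voronoi_matches_bruteforce_random(rng):
    """Owner map, areas, distances, neighbour counts vs an explicit loop oracle."""
    for _ in range(50):
        px = int(rng.integers(6, 17))
        k = int(rng.integers(1, 6))
        cs = [nuc(float(rng.uniform(0, px)), float(rng.uniform(0, px))) for _ in range(k)]
        mm = voronoi_morphometry(cs, px)
        # oracle
        owner = np.zeros((px, px), dtype=int)
        dist = np.zeros((px, px))
        for r in range(px):
            for c in range(px):
                d = [(r - n.y) ** 2 + (c - n.x) ** 2 for n in cs]
                owner[r, c] = int(np.argmin(d))
                dist[r, c] = np.sqrt(min(d))
        areas = np.bincount(owner.ravel(), minlength=k).astype(float)
        nb = np.zeros((k, k), dtype=bool)
        for r in range(px):
            for c in range(px):
                for dr, dc in ((0, 1), (1, 0)):
                    if r + dr < px and c + dc < px and owner[r, c] != owner[r + dr, c + dc]:
                        nb[owner[r, c], owner[r + dr, c + dc]] = True
                        nb[owner[r + dr, c + dc], owner[r, c]] = True
        ncnt = nb.sum(axis=1).astype(float)

        def mm_norm(x):
            lo, hi = x.min(), x.max()
            return np.zeros_like(x) if hi - lo <= 0 else (x - lo) / (hi - lo)

        assert np.allclose(mm.channels[0], mm_norm(areas[owner]), atol=1e-6)
        assert np.allclose(mm.channels[1], mm_norm(dist), atol=1e-6)
        assert np.allclose(mm.channels[2], mm_norm(ncnt[owner]), atol=1e-6)
        assert areas.sum() == px * px


def test_cross_modal_attention_degenerate_cases(rng):
    d = 4
    P = AttentionParams(W_Q=np.eye(d), W_K=np.eye(d), W_V=np.eye(d), d_k=d)
    # all morph tokens identical -> every fused row equals that token's V projection
    E_img = rng.normal(size=(3, d))
    tok = rng.normal(size=d)
    E_morph = np.tile(tok, (5, 1))
    F = cross_modal_attention(ModalityEmbedding(E_img=E_img, E_morph=E_morph), P).F
    assert np.allclose(F, np.tile(tok, (3, 1)), atol=1e-12)
    # single morph token -> F = its V projection regardless of Q
    F1 = cross_modal_attention(ModalityEmbedding(E_img=E_img, E_morph=tok[None]), P).F
    assert np.allclose(F1, np.tile(tok, (3, 1)), atol=1e-12)
    with pytest.raises(ValueError):
        cross_modal_attention(ModalityEmbedding(E_img=E_img, E_morph=rng.normal(size=(2, d + 1))), P)


def attention_oracle(E_img, E_morph, P):
    Q = E_img @ P.W_Q
    K = E_morph @ P.W_K
    V = E_morph @ P.W_V
    out = np.zeros((E_img.shape[0], P.W_V.shape[1]))
    for i in range(Q.shape[0]):
        scores = [Q[i] @ K[j] / np.sqrt(P.d_k) for j in range(K.shape[0])]
        e = np.exp(scores - np.max(scores))
        w = e / e.sum()
        out[i] = sum(w[j] * V[j] for j in range(K.shape[0]))
    return out


def test_cross_modal_attention_matches_loop_oracle(rng):
    for _ in range(50):
        n_img = int(rng.integers(1, 9))
        n_mor = int(rng.integers(1, 9))
        d = int(rng.integers(2, 6))
        dk = int(rng.integers(1, 5))
        P = AttentionParams(W_Q=rng.normal(size=(d, dk)), W_K=rng.normal(size=(d, dk)),
                            W_V=rng.normal(size=(d, dk)), d_k=dk)
        E = ModalityEmbedding(E_img=rng.normal(size=(n_img, d)),
                              E_morph=rng.normal(size=(n_mor, d)))
        got = cross_modal_attention(E, P).F
        assert np.allclose(got, attention_oracle(E.E_img, E.E_morph, P), atol=1e-6)


def test_morph_token_permutation_invariance(rng):
    d = 4
    P = AttentionParams(W_Q=rng.normal(size=(d, d)), W_K=rng.normal(size=(d, d)),
                        W_V=rng.normal(size=(d, d)), d_k=d)
    E_img = rng.normal(size=(3, d))
    E_morph = rng.normal(size=(6, d))
    perm = rng.permutation(6)
    a = cross_modal_attention(ModalityEmbedding(E_img, E_morph), P).F
    b = cross_modal_attention(ModalityEmbedding(E_img, E_morph[perm]), P).F
    assert np.allclose(a, b, atol=1e-12)


def test_classifier_head_contracts(rng):
    head = ClassifierHead(6, 3, rng)
    for p in head.parameters():
        p.data[:] = 0.0
    probs = classify(rng.normal(size=(5, 6)), head)
    assert np.allclose(probs, 1.0 / 3)  # zero weights -> uniform softmax
    head2 = ClassifierHead(4, 2, rng)
    probs2 = classify(rng.normal(size=(7, 4)), head2)
    assert probs2.sum() == pytest.approx(1.0, abs=1e-6)
    # hand-set binary head: logits (x, -x) on the pooled mean -> sigmoid(2x)
    head3 = ClassifierHead(1, 2, rng, d_hidden=1)
    head3.fc1.W.data[:] = 1.0
    head3.fc1.b.data[:] = 0.0
    head3.fc2.W.data = np.array([[1.0, -1.0]])
    head3.fc2.b.data[:] = 0.0
    x = 0.7  # positive so the relu is the identity
    F = np.full((3, 1), x)
    probs3 = classify(F, head3)
    assert probs3[0] == pytest.approx(1.0 / (1.0 + np.exp(-2 * x)), abs=1e-12)


def test_morphometry_tiff_export(tmp_path, rng):
    import tifffile

    from histomulti.tdmm import write_morphometry_tiff

    cs = [nuc(float(rng.uniform(0, 16)), float(rng.uniform(0, 16))) for _ in range(4)]
    mm = voronoi_morphometry(cs, 16)
    write_morphometry_tiff(tmp_path / "m.tiff", mm)
    back = tifffile.imread(tmp_path / "m.tiff")
    assert back.shape == (16, 16, 3) and back.dtype == np.uint16
    assert np.allclose(back.transpose(2, 0, 1) / 65535.0, mm.channels, atol=1e-4)


def test_fused_classification_gradient_wrt_projections(rng):
    """Finite differences through attention fusion + MLP head cross-entropy."""
    d, dk = 4, 4
    E_img = rng.normal(size=(3, d))
    E_morph = rng.normal(size=(5, d))
    head = ClassifierHead(dk, 2, rng)
    y = 1
    mats = {
        "W_Q": rng.normal(size=(d, dk)),
        "W_K": rng.normal(size=(d, dk)),
        "W_V": rng.normal(size=(d, dk)),
    }

    def loss_for(name):
        def f(m):
            cur = {k: (m if k == name else v) for k, v in mats.items()}
            P = AttentionParams(d_k=dk, **cur)
            F = cross_modal_attention(ModalityEmbedding(E_img, E_morph), P).F
            probs = classify(F, head)
            return float(-np.log(probs[y] + 1e-12))

        return f

    tensors = {k: Tensor(v.copy(), True) for k, v in mats.items()}
    P = AttentionParams(d_k=dk, **tensors)
    F = cross_modal_attention((Tensor(E_img), Tensor(E_morph)), P)
    probs = classify(F, head)
    (-(probs[y] + 1e-12).log()).backward()
    for name in mats:
        numeric = finite_diff(loss_for(name), mats[name].copy())
        assert rel_err(tensors[name].grad, numeric) < 1e-4, name
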