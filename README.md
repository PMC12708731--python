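# histomulti

Multiscale histopathology patch analysis at desk scale: five composable
training mechanisms for paired-magnification (10x/40x) H&E patch
classification, a deterministic synthetic generator of co-registered patch
pairs with full ground truth, a small seeded trainer, and the matching
evaluation metrics. Everything runs on a CPU in seconds to minutes; no real
whole-slide images, GPUs, or pretrained weights are required.

Intended users: researchers studying multiscale consistency, attention
regularisation, curriculum scheduling, morphometry fusion, or contrastive
alignment in computational pathology who want each mechanism as a tested,
differentiable, composable primitive rather than as a line in a monolithic
training script.

## The model

Patches are seen at two magnifications, `X(10x)` (tissue context) and
`X(40x)` (cellular detail), encoded by a convolutional branch `f10` and a
small vision transformer `f40`. Training minimises

```
L_total = L_sup + λ¹·L_PAUAC + λ²·L_SACGR + λ³·L_CCCRA
```

where

- **L_PAUAC** — uncertainty-aware consistency: Monte-Carlo-dropout heads
  (T stochastic passes) give per-branch predictive distributions `P(i)` and
  predictive entropies `H(i)`;
  `L = mean_j exp(−α(H_j(10) + H_j(40))) · KL(P_j(10) ‖ P_j(40))`.
- **L_SACGR** — structural attention regularisation: SLIC superpixels form
  a tissue graph `A`; transformer attention is pooled onto superpixel pairs
  as `A_attn`; `L = mean_{i≠j} (A_ij − A_attn,ij)²`, plus a graph
  smoothness term on node features.
- **L_CCCRA** — positional InfoNCE across magnifications:
  `L = −log exp(s_ij)/Σ_k exp(s_ik)` with
  `s_ik = [cos(z_i, z_k) + γ·cos(p_i, p_k)]/τ`.
- **L_sup** — cross-entropy of the TDMM head: nuclei centroids produce
  Voronoi morphometry maps (region area / nearest-centroid distance /
  neighbour count), fused with image tokens by scaled-dot-product
  cross-attention `softmax(QKᵀ/√d_k)V` (Q from image, K,V from
  morphometry).

A curriculum scheduler (MPCS) orders training batches by patch complexity
`ξ = λ¹·E + λ²·σ²_nuc` (texture entropy in bits + nuclei-density variance)
through a sigmoid selection probability against a quantile threshold that
ramps across epochs — easy patches first, complex patches later.

Defaults follow the operating point of the method: T = 10, dropout 0.3,
τ = 0.07, γ = 0.3, up to 8 graph neighbours per superpixel, AdamW
lr 1e-4 / weight decay 0.01 with warm-up + cosine decay. All differentiable
pieces run on a built-in float64 reverse-mode autodiff engine, so analytic
gradients are finite-difference-checked in the test suite.

## Worked example

```python
import numpy as np
from histomulti.synthetic import SyntheticSlideSpec, generate_patch_pair
from histomulti import training

spec = SyntheticSlideSpec(seed=11, canvas_px=128)          # 32x32 patch pairs
pairs = [generate_patch_pair(spec, i) for i in range(200)]
cfg = training.ModelConfig()                               # tiny reference model
ds = training.prepare_dataset(pairs, cfg)
run = training.train(
    ds, cfg, training.CompositeLossConfig(),
    training.TrainConfig(lr=3e-3, epochs=8, warmup_epochs=2, batch_size=16, seed=0),
    out_dir="runs/demo",
)
print(open(run / "metrics.json").read())
```

prints (exactly reproducible with these seeds):

```json
{
 "auc": 1.0,
 "nmi": 1.0,
 "supervised_ce": 0.026701125337552492,
 "cross_mag_kl": 5.499313371174703e-05,
 "mean_entropy10": 0.9999357753644035,
 "mean_entropy40": 0.9999969615765132,
 "off_graph_mass": 0.6084494919744227,
 "attention_precision": 0.9050955795614234
}
```

Reading the numbers: validation AUC 1.0 — the synthetic tumor/normal
contrast (nuclear density and pleomorphism) is fully learnable at this
scale; cross-magnification KL ≈ 5e-5 — the two branches agree almost
perfectly once PAUAC is active (ablating it raises this by ~100x); NMI 1.0
— k-means clusterings of the 10x and 40x embeddings coincide on this run,
the alignment CCCRA is responsible for (ablating it drops the median NMI to
≈ 0.1); mean predictive entropy ≈ 1 bit reflects the MC-dropout heads'
residual uncertainty; off-graph attention mass is the share of pooled
attention falling outside tissue-graph edges (lower with SACGR than without
it); attention precision is the fraction of the top-20%-mass attention
pixels that fall inside the tumor mask.

The same pipeline is available from the shell:

```
histomulti generate --seed 11 --n-pairs 200 --out data/
histomulti train --manifest data/manifest.json --seed 0 --out runs/demo
histomulti evaluate --manifest data/manifest.json --run-dir runs/demo
histomulti ablate --manifest data/manifest.json --out runs/ablation
histomulti score --manifest data/manifest.json --out complexity.csv
```

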