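"""Composite objective, desk-scale trainer, evaluation, and ablation harness.

The training objective combines the supervised cross-entropy with the three
regularisers:

    L_total = L_sup + l1 * L_PAUAC + l2 * L_SACGR + l3 * L_CCCRA

(the graph smoothness term is logged separately and added with its own
weight, 0.1 * l2 by default).  Optimisation uses AdamW with linear warm-up
followed by cosine decay.  Training order follows the curriculum scheduler:
per-patch complexity scores are computed once, the threshold ramps across
epochs, and mini-batches are drawn by the two-phase easy-to-hard weighting.

Everything is seeded — data order, parameter init, dropout masks — so two
runs with the same seed produce identical logs.  Runs write
``config.resolved.yaml``, ``log.jsonl`` (one JSON object per epoch),
``metrics.json``, ``complexity.csv``, and ``checkpoint_{best,last}.npz``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import mpcs, pauac, sacgr, tdmm
from ._tensor import Tensor, log as tlog
from .cccra import cccra_loss_matrix
from .encoders import CellularEncoder, ContextEncoder, EncoderConfig, MCHead
from .metrics import auc as auc_metric
from .metrics import attention_precision, cross_mag_nmi
from .nn import AdamW, Linear, load_params, save_params
from .synthetic import DatasetManifest, generate_superpixels, load_pair

__all__ = [
    "CompositeLossConfig",
    "TrainConfig",
    "ModelConfig",
    "MetricsReport",
    "total_loss",
    "MultiScaleModel",
    "prepare_dataset",
    "train",
    "evaluate",
    "ablate",
]

_EPS = 1e-12
CLASSES = ("normal", "tumor")


@dataclass(frozen=True)
class CompositeLossConfig:
    lambda_pauac: float = 1.0
    lambda_sacgr: float = 0.5
    lambda_cccra: float = 0.5
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 0.3
    tau: float = 0.07
    smoothness_weight: float | None = None  # default 0.1 * lambda_sacgr

    def __post_init__(self):
        for name in ("lambda_pauac", "lambda_sacgr", "lambda_cccra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.smoothness_weight is not None and self.smoothness_weight < 0:
            raise ValueError("smoothness_weight must be >= 0")

    @property
    def smooth_w(self) -> float:
        return 0.1 * self.lambda_sacgr if self.smoothness_weight is None else self.smoothness_weight


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.01
    betas: tuple = (0.9, 0.999)
    batch_size: int = 32
    epochs: int = 100
    warmup_epochs: int = 10
    T_mc: int = 10
    dropout_rate: float = 0.3
    seed: int = 0
    early_stop_patience: int | None = None
    curriculum: bool = True
    curriculum_schedule: tuple = (0.2, 0.8, 5)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be < epochs")


@dataclass(frozen=True)
class ModelConfig:
    hidden_dim: int = 32
    n_heads: int = 4
    n_layers: int = 1
    token_patch_px: int = 8
    image_px: int = 32  # side of the 40x patch the model is built for
    proj_dim: int = 16
    n_classes: int = 2


@dataclass
class MetricsReport:
    dice: float | None
    auc: float
    nmi: float
    attention_precision: float | None
    mean_entropy10: float
    mean_entropy40: float
    cross_mag_kl: float
    off_graph_mass: float
    supervised_ce: float


def total_loss(l_sup, l_pauac, l_sacgr, l_cccra, cfg: CompositeLossConfig):
    """The composite objective, exactly the printed linear combination."""
    return (l_sup + l_pauac * cfg.lambda_pauac + l_sacgr * cfg.lambda_sacgr
            + l_cccra * cfg.lambda_cccra)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class PreparedPair:
    pair_id: int
    x10: np.ndarray  # (3, H, W) float in [0,1]
    x40: np.ndarray
    y: int
    mask40: np.ndarray
    graph: sacgr.TissueGraph
    assignment: sacgr.TokenAssignment
    morph: np.ndarray  # (3, H, W)
    complexity: mpcs.ComplexityRecord
    position: np.ndarray  # centre of the 40x field of view in the 10x frame, [0,1]^2


@dataclass
class PreparedDataset:
    pairs: list
    n_classes: int = 2


def prepare_dataset(pairs_or_manifest, model_cfg: ModelConfig,
                    n_superpixels: int = 16, superpixel_method: str = "slic",
                    loss_cfg: CompositeLossConfig | None = None) -> PreparedDataset:
    """Precompute per-pair artifacts: graphs, assignments, morphometry, complexity."""
    if isinstance(pairs_or_manifest, DatasetManifest):
        m = pairs_or_manifest
        pairs = [load_pair(m, r) for r in m.records]
    else:
        pairs = list(pairs_or_manifest)
    prepared = []
    for p in pairs:
        H = p.image40.shape[0]
        labels = generate_superpixels(p.image40, n_superpixels, method=superpixel_method)
        graph = sacgr.build_tissue_graph(labels, p.image40)
        gh = H // model_cfg.token_patch_px
        assignment = sacgr.assign_tokens(labels, (gh, gh), model_cfg.token_patch_px)
        morph = tdmm.voronoi_morphometry(p.centroids, H).channels
        E = mpcs.texture_entropy(p.image40)
        var = mpcs.nuclei_density_variance(p.centroids, H, grid=min(8, H))
        xi = mpcs.complexity_score(E, var)
        h10 = p.image10.shape[0]
        centre = (np.asarray(p.crop_offset, dtype=np.float64) + h10 / 8.0) / h10
        prepared.append(
            PreparedPair(
                pair_id=p.pair_id,
                x10=p.image10.astype(np.float64).transpose(2, 0, 1) / 255.0,
                x40=p.image40.astype(np.float64).transpose(2, 0, 1) / 255.0,
                y=CLASSES.index(p.label),
                mask40=p.mask40,
                graph=graph,
                assignment=assignment,
                morph=morph,
                complexity=mpcs.ComplexityRecord(p.pair_id, E, var, xi),
                position=centre,
            )
        )
    return PreparedDataset(pairs=prepared, n_classes=model_cfg.n_classes)


def split_pairs(ds: PreparedDataset, val_fraction: float = 0.2):
    """Deterministic 80/20 split by a multiplicative hash of pair_id."""
    tr, va = [], []
    for p in ds.pairs:
        h = (p.pair_id * 2654435761) % (2**32)
        (va if h < val_fraction * 2**32 else tr).append(p)
    return tr, va


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class MultiScaleModel:
    """Dual-branch encoders + MC heads + TDMM fusion + CCCRA projections."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        h = cfg.hidden_dim
        ctx_cfg = EncoderConfig(branch="context10", hidden_dim=h, n_heads=cfg.n_heads,
                                n_layers=cfg.n_layers, token_patch_px=cfg.token_patch_px,
                                n_classes=cfg.n_classes)
        cell_cfg = EncoderConfig(branch="cellular40", hidden_dim=h, n_heads=cfg.n_heads,
                                 n_layers=cfg.n_layers, token_patch_px=cfg.token_patch_px,
                                 n_classes=cfg.n_classes)
        self.ctx = ContextEncoder(ctx_cfg, rng)
        self.cell = CellularEncoder(cell_cfg, rng)
        self.morph_cell = CellularEncoder(cell_cfg, rng, in_channels=3)
        n_tok = (cfg.image_px // cfg.token_patch_px) ** 2
        self.cell._ensure_pos(n_tok)  # size positional tables now so that
        self.morph_cell._ensure_pos(n_tok)  # checkpoints have a stable layout
        self.head10 = MCHead(h, cfg.n_classes, rng)
        self.head40 = MCHead(h, cfg.n_classes, rng)
        self.attn_params = tdmm.AttentionParams(
            W_Q=Tensor(rng.normal(0, np.sqrt(1.0 / h), (h, h)), True),
            W_K=Tensor(rng.normal(0, np.sqrt(1.0 / h), (h, h)), True),
            W_V=Tensor(rng.normal(0, np.sqrt(1.0 / h), (h, h)), True),
            d_k=h,
        )
        self.classifier = tdmm.ClassifierHead(h, cfg.n_classes, rng)
        self.proj10 = Linear(h, cfg.proj_dim, rng)
        self.proj40 = Linear(h, cfg.proj_dim, rng)

    def parameters(self):
        ps = (self.ctx.parameters() + self.cell.parameters() + self.morph_cell.parameters()
              + self.head10.parameters() + self.head40.parameters()
              + [self.attn_params.W_Q, self.attn_params.W_K, self.attn_params.W_V]
              + self.classifier.parameters() + self.proj10.parameters()
              + self.proj40.parameters())
        return ps

    def named_parameters(self):
        return {f"p{i}": p for i, p in enumerate(self.parameters())}

    def forward_batch(self, batch, T: int, dropout_rate: float,
                      rng: np.random.Generator):
        """Full forward pass; returns a dict of Tensors and constants."""
        x10 = np.stack([p.x10 for p in batch])
        x40 = np.stack([p.x40 for p in batch])
        morph = np.stack([p.morph for p in batch])
        f10 = self.ctx.pooled(Tensor(x10))  # (B, h)
        tokens, attns, _ = self.cell.forward(x40)  # (B, n, h)
        pooled40 = tokens.mean(axis=1)
        passes10 = self.head10.mc_passes(f10, T, dropout_rate, rng)
        passes40 = self.head40.mc_passes(pooled40, T, dropout_rate, rng)
        P10 = pauac.predictive_distribution(passes10).probs
        P40 = pauac.predictive_distribution(passes40).probs
        morph_tokens, _, _ = self.morph_cell.forward(morph)
        fused = tdmm.cross_modal_attention((tokens, morph_tokens), self.attn_params)
        yhat = self.classifier.forward(fused.mean(axis=-2))  # (B, C)
        z10 = self.proj10(f10)
        z40 = self.proj40(pooled40)
        return {
            "P10": P10, "P40": P40, "tokens": tokens, "attns": attns,
            "yhat": yhat, "z10": z10, "z40": z40,
        }


def _batch_losses(model: MultiScaleModel, batch, out, loss_cfg: CompositeLossConfig):
    """All loss components for one forward pass, as Tensors."""
    B = len(batch)
    y = np.array([p.y for p in batch])
    l_sup = (-tlog(out["yhat"][np.arange(B), y] + _EPS)).mean()
    pc = pauac.PauacConfig(alpha=loss_cfg.alpha)
    l_pauac = pauac.pauac_loss(out["P10"], out["P40"], cfg=pc)
    last_attn = out["attns"][-1]  # (B, heads, n, n) Tensor
    l_sacgr = Tensor(0.0)
    l_smooth = Tensor(0.0)
    for b, p in enumerate(batch):
        a = last_attn[b].reshape(1, *last_attn.shape[1:])
        A_attn = sacgr.attention_adjacency(a, p.assignment, layer_set="last")
        l_sacgr = l_sacgr + sacgr.sacgr_loss(p.graph, A_attn)
        l_smooth = l_smooth + sacgr.smoothness_loss(out["tokens"][b], p.assignment, p.graph)
    l_sacgr = l_sacgr * (1.0 / B)
    l_smooth = l_smooth * (1.0 / B)
    pos = np.stack([p.position for p in batch])
    l_cccra = cccra_loss_matrix(out["z10"], out["z40"], pos, pos,
                                gamma=loss_cfg.gamma, tau=loss_cfg.tau)
    total = total_loss(l_sup, l_pauac, l_sacgr, l_cccra, loss_cfg) + \
        l_smooth * loss_cfg.smooth_w
    return {"total": total, "sup": l_sup, "pauac": l_pauac, "sacgr": l_sacgr,
            "smooth": l_smooth, "cccra": l_cccra}


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _token_attention_map(attn: np.ndarray, grid: tuple, patch_px: int) -> np.ndarray:
    """Head-averaged attention received per token, painted onto the pixel grid."""
    recv = attn.mean(axis=0).mean(axis=0)  # column mean over heads: (n,)
    gh, gw = grid
    return np.kron(recv.reshape(gh, gw), np.ones((patch_px, patch_px)))


def evaluate(model: MultiScaleModel, pairs, loss_cfg: CompositeLossConfig,
             T: int, dropout_rate: float, seed: int) -> dict:
    """Validation metrics for a list of PreparedPair."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12345]))
    out = model.forward_batch(pairs, T, dropout_rate, rng)
    P10, P40 = out["P10"].data, out["P40"].data
    y = np.array([p.y for p in pairs])
    scores = out["yhat"].data[:, CLASSES.index("tumor")]
    ce = float(np.mean(-np.log(out["yhat"].data[np.arange(len(pairs)), y] + _EPS)))
    h10 = pauac.predictive_entropy(P10).H
    h40 = pauac.predictive_entropy(P40).H
    kl = float(np.mean(np.sum(
        np.where(P10 > 0, P10 * (np.log(P10 + _EPS) - np.log(P40 + _EPS)), 0.0), axis=-1)))
    try:
        auc_v = auc_metric(scores, y)
    except ValueError:
        auc_v = float("nan")
    z10, z40 = out["z10"].data, out["z40"].data
    k = min(model.cfg.n_classes, len(pairs))
    nmi = cross_mag_nmi(z10, z40, k=k, seed=seed) if len(pairs) >= k and k >= 2 else float("nan")
    last_attn = out["attns"][-1].data  # (B, heads, n, n)
    off_mass, att_prec = [], []
    patch_px = model.cfg.token_patch_px
    for b, p in enumerate(pairs):
        A_attn = sacgr.attention_adjacency(last_attn[b][None], p.assignment)
        off_mass.append(sacgr.off_graph_attention_mass(p.graph, A_attn))
        if p.mask40.any() and not p.mask40.all():
            gh = p.mask40.shape[0] // patch_px
            amap = _token_attention_map(last_attn[b], (gh, gh), patch_px)
            att_prec.append(attention_precision(amap, p.mask40))
    return {
        "auc": auc_v,
        "nmi": nmi,
        "supervised_ce": ce,
        "cross_mag_kl": kl,
        "mean_entropy10": float(h10.mean()),
        "mean_entropy40": float(h40.mean()),
        "off_graph_mass": float(np.mean(off_mass)),
        "attention_precision": float(np.mean(att_prec)) if att_prec else None,
    }


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _lr_at(epoch: int, cfg: TrainConfig) -> float:
    if epoch < cfg.warmup_epochs:
        return cfg.lr * (epoch + 1) / cfg.warmup_epochs
    span = max(1, cfg.epochs - cfg.warmup_epochs)
    t = (epoch - cfg.warmup_epochs) / span
    return cfg.lr * 0.5 * (1.0 + np.cos(np.pi * t))


def _dump_yaml(path, obj):
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def train(dataset, model_cfg: ModelConfig = ModelConfig(),
          loss_cfg: CompositeLossConfig = CompositeLossConfig(),
          train_cfg: TrainConfig = TrainConfig(), out_dir="runs/run") -> Path:
    """Train the desk-scale model; returns the run directory."""
    ds = dataset if isinstance(dataset, PreparedDataset) else prepare_dataset(dataset, model_cfg)
    tr, va = split_pairs(ds)
    if not tr or not va:
        raise ValueError("empty train or validation split")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = MultiScaleModel(model_cfg, seed=train_cfg.seed)
    opt = AdamW(model.parameters(), lr=train_cfg.lr, betas=train_cfg.betas,
                weight_decay=train_cfg.weight_decay)
    drop_rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 777]))
    records = [p.complexity for p in tr]
    state = mpcs.CurriculumState(beta=loss_cfg.beta,
                                 schedule=train_cfg.curriculum_schedule)
    by_id = {p.pair_id: p for p in tr}
    n_batches = max(1, len(tr) // train_cfg.batch_size)
    bs = min(train_cfg.batch_size, len(tr))

    _dump_yaml(out / "config.resolved.yaml", {
        "model": dataclasses.asdict(model_cfg),
        "loss": dataclasses.asdict(loss_cfg),
        "train": dataclasses.asdict(train_cfg),
    })

    log_fh = open(out / "log.jsonl", "w")
    best = (-np.inf, None)
    bad_epochs = 0

    def log_epoch(entry):
        log_fh.write(json.dumps(entry) + "\n")
        log_fh.flush()

    # train-split CE is tracked on a fixed, capped subset so the per-epoch
    # number is comparable across epochs (batch sampling is curriculum-weighted)
    tr_probe = tr[: min(64, len(tr))]

    # epoch 0: pre-training evaluation baseline
    val0 = evaluate(model, va, loss_cfg, train_cfg.T_mc, train_cfg.dropout_rate,
                    train_cfg.seed)
    tr0 = evaluate(model, tr_probe, loss_cfg, train_cfg.T_mc,
                   train_cfg.dropout_rate, train_cfg.seed)
    log_epoch({"epoch": 0, "phase": "init", "train_ce": tr0["supervised_ce"],
               **{f"val_{k}": v for k, v in val0.items()}})

    for epoch in range(train_cfg.epochs):
        state = replace(state, epoch=epoch)
        state = mpcs.update_threshold(records, state)
        lr = _lr_at(epoch, train_cfg)
        sums: dict = {}
        batch_xi = []
        for bi in range(n_batches):
            if train_cfg.curriculum:
                bseed = int(np.random.default_rng(
                    np.random.SeedSequence([train_cfg.seed, epoch, bi])).integers(2**31))
                ids = mpcs.sample_batch(records, state, bs, seed=bseed)
            else:
                perm_rng = np.random.default_rng(
                    np.random.SeedSequence([train_cfg.seed, epoch, bi]))
                ids = [records[i].pair_id for i in perm_rng.choice(len(records), bs,
                                                                   replace=False)]
            batch = [by_id[i] for i in ids]
            batch_xi.append(float(np.mean([by_id[i].complexity.xi for i in ids])))
            fwd = model.forward_batch(batch, train_cfg.T_mc, train_cfg.dropout_rate,
                                      drop_rng)
            losses = _batch_losses(model, batch, fwd, loss_cfg)
            opt.zero_grad()
            losses["total"].backward()
            opt.step(lr=lr)
            for k, v in losses.items():
                sums[k] = sums.get(k, 0.0) + v.item()
        val = evaluate(model, va, loss_cfg, train_cfg.T_mc, train_cfg.dropout_rate,
                       train_cfg.seed)
        tr_ce = evaluate(model, tr_probe, loss_cfg, train_cfg.T_mc,
                         train_cfg.dropout_rate, train_cfg.seed)["supervised_ce"]
        entry = {"epoch": epoch + 1, "lr": lr, "mu_t": state.mu_t,
                 "train_ce": tr_ce,
                 "mean_batch_xi": float(np.mean(batch_xi)),
                 **{f"loss_{k}": v / n_batches for k, v in sums.items()},
                 **{f"val_{k}": v for k, v in val.items()}}
        log_epoch(entry)
        score = val["auc"]
        if np.isnan(score):
            score = -val["supervised_ce"]
        if score > best[0]:
            best = (score, {k: p.data.copy() for k, p in model.named_parameters().items()})
            save_params(out / "checkpoint_best.npz", model.named_parameters())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if (train_cfg.early_stop_patience is not None
                    and bad_epochs >= train_cfg.early_stop_patience):
                break

    save_params(out / "checkpoint_last.npz", model.named_parameters())
    mpcs.write_complexity_csv(out / "complexity.csv", records, state)
    final = evaluate(model, va, loss_cfg, train_cfg.T_mc, train_cfg.dropout_rate,
                     train_cfg.seed)
    with open(out / "metrics.json", "w") as fh:
        json.dump(final, fh, indent=1)
    log_fh.close()
    return out


def load_model(checkpoint_path, model_cfg: ModelConfig, seed: int = 0) -> MultiScaleModel:
    model = MultiScaleModel(model_cfg, seed=seed)
    # one dummy forward is not needed: pos table is sized lazily, so load after sizing
    load_params(checkpoint_path, model.named_parameters())
    return model


ABLATION_MODES = ("full", "no_pauac", "no_sacgr", "no_cccra")


def _mode_cfg(base: CompositeLossConfig, mode: str) -> CompositeLossConfig:
    if mode == "full":
        return base
    if mode == "no_pauac":
        return replace(base, lambda_pauac=0.0)
    if mode == "no_sacgr":
        return replace(base, lambda_sacgr=0.0, smoothness_weight=0.0)
    if mode == "no_cccra":
        return replace(base, lambda_cccra=0.0)
    raise ValueError(f"unknown ablation mode {mode!r}")


def ablate(dataset, model_cfg: ModelConfig, loss_cfg: CompositeLossConfig,
           train_cfg: TrainConfig, modes, seeds, out_dir="runs/ablation"):
    """Train per mode x seed; write per-run and median/IQR summary CSVs."""
    ds = dataset if isinstance(dataset, PreparedDataset) else prepare_dataset(dataset, model_cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for mode in modes:
        cfg_m = _mode_cfg(loss_cfg, mode)
        for seed in seeds:
            run_dir = train(ds, model_cfg, cfg_m, replace(train_cfg, seed=seed),
                            out / f"{mode}_s{seed}")
            with open(run_dir / "metrics.json") as fh:
                m = json.load(fh)
            rows.append({"mode": mode, "seed": seed, **m})
    import csv as _csv

    keys = [k for k in rows[0] if k not in ("mode", "seed")]
    with open(out / "ablation.csv", "w", newline="") as fh:
        w = _csv.DictWriter(fh, fieldnames=["mode", "seed"] + keys)
        w.writeheader()
        w.writerows(rows)
    summary = {}
    for mode in modes:
        sub = [r for r in rows if r["mode"] == mode]
        summary[mode] = {}
        for k in keys:
            vals = np.array([r[k] for r in sub if r[k] is not None], dtype=np.float64)
            if vals.size:
                q1, med, q3 = np.nanpercentile(vals, [25, 50, 75])
                summary[mode][k] = {"median": float(med), "iqr": float(q3 - q1)}
    with open(out / "ablation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return rows, summary
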