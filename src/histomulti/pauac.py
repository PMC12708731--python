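"""Uncertainty-aware cross-magnification consistency (PAUAC).

The two magnification branches each produce a Monte-Carlo predictive
distribution (mean of T stochastic softmax passes).  Agreement between the
branches is enforced by a KL divergence per unit (patch, or pixel in dense
mode), down-weighted where either branch is uncertain:

    L = mean_j  w_j * KL(P_j(10x) || P_j(40x)),
    w_j = exp(-alpha * (H_j(10x) + H_j(40x)))

with H the Shannon predictive entropy.  Entropies are *reported* in bits
(matching the curriculum threshold convention elsewhere in the pipeline) but
converted to nats inside the weight so that alpha shares a scale with the
natural-log KL.  The loss is averaged (not summed) over units, making its
magnitude batch-size invariant; the composite-objective lambda absorbs any
rescaling.

All functions accept plain numpy arrays (returning floats) or autodiff
Tensors (returning Tensors), so the same code path is used for evaluation
and for gradient-based training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from ._tensor import Tensor, log, tmean, tsum
from .encoders import StochasticPasses

__all__ = [
    "PauacConfig",
    "PredictiveDistribution",
    "UncertaintyMap",
    "predictive_distribution",
    "predictive_entropy",
    "consistency_weight",
    "pauac_loss",
]

_EPS = 1e-12
_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class PauacConfig:
    alpha: float = 1.0  # sharpness of the uncertainty down-weighting
    direction: str = "as_printed"  # or "symmetric"
    unit_mode: str = "patch"  # or "dense"

    def __post_init__(self):
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and >= 0")
        if self.direction not in ("as_printed", "symmetric"):
            raise ValueError("direction must be 'as_printed' or 'symmetric'")
        if self.unit_mode not in ("patch", "dense"):
            raise ValueError("unit_mode must be 'patch' or 'dense'")


@dataclass
class PredictiveDistribution:
    probs: np.ndarray  # (..., n_classes); last axis sums to 1
    n_classes: int


@dataclass
class UncertaintyMap:
    H: np.ndarray  # bits, shape = probs.shape[:-1]


def predictive_distribution(passes) -> PredictiveDistribution:
    """Mean over T stochastic passes. Accepts StochasticPasses or a list."""
    ps = passes.passes if isinstance(passes, StochasticPasses) else list(passes)
    if len(ps) == 0:
        raise ValueError("need at least one stochastic pass")
    if isinstance(ps[0], Tensor):
        acc = ps[0]
        for p in ps[1:]:
            acc = acc + p
        mean = acc * (1.0 / len(ps))
        return PredictiveDistribution(probs=mean, n_classes=mean.shape[-1])
    arr = np.mean(np.stack([np.asarray(p, dtype=np.float64) for p in ps]), axis=0)
    return PredictiveDistribution(probs=arr, n_classes=arr.shape[-1])


def _probs(P):
    return P.probs if isinstance(P, PredictiveDistribution) else P


def predictive_entropy(P) -> UncertaintyMap:
    """Shannon entropy of the predictive distribution, in bits; 0*log0 := 0."""
    p = _probs(P)
    if isinstance(p, Tensor):
        h = -tsum(p * log(p + _EPS), axis=-1) * (1.0 / _LN2)
        return UncertaintyMap(H=h)
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    h = -xlogy(p, p).sum(axis=-1) / _LN2
    return UncertaintyMap(H=np.maximum(h, 0.0))


def _H(x):
    return x.H if isinstance(x, UncertaintyMap) else x


def consistency_weight(H10, H40, cfg: PauacConfig = PauacConfig()):
    """w = exp(-alpha * (H10 + H40)); entropies supplied in bits."""
    h10, h40 = _H(H10), _H(H40)
    if isinstance(h10, Tensor) or isinstance(h40, Tensor):
        s = (h10 + h40) * _LN2  # bits -> nats so alpha matches the nat-scale KL
        return (s * (-cfg.alpha)).exp()
    s = (np.asarray(h10, dtype=np.float64) + np.asarray(h40, dtype=np.float64)) * _LN2
    if (s < -1e-12).any():
        raise ValueError("entropies must be >= 0")
    return np.exp(-cfg.alpha * s)


def _kl(p, q):
    """Natural-log KL per unit along the last axis, eps-floored denominator."""
    if isinstance(p, Tensor) or isinstance(q, Tensor):
        return tsum(p * (log(p + _EPS) - log(q + _EPS)), axis=-1)
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    return (xlogy(p, p) - xlogy(p, q + _EPS)).sum(axis=-1)


def pauac_loss(P10, P40, H10=None, H40=None, cfg: PauacConfig = PauacConfig()):
    """Uncertainty-weighted cross-magnification consistency loss (mean over units).

    If entropies are omitted they are computed from the distributions.
    """
    p10, p40 = _probs(P10), _probs(P40)
    shape10 = p10.shape if not isinstance(p10, Tensor) else p10.shape
    shape40 = p40.shape if not isinstance(p40, Tensor) else p40.shape
    if tuple(shape10) != tuple(shape40):
        raise ValueError(f"unit grids differ: {shape10} vs {shape40}")
    h10 = predictive_entropy(p10).H if H10 is None else _H(H10)
    h40 = predictive_entropy(p40).H if H40 is None else _H(H40)
    w = consistency_weight(h10, h40, cfg)
    if cfg.direction == "symmetric":
        kl = (_kl(p10, p40) + _kl(p40, p10)) * 0.5
    else:
        kl = _kl(p10, p40)
    out = tmean(w * kl)
    return out if isinstance(out, Tensor) else float(out)


def resample_dense(prob_map: np.ndarray, target_hw: tuple) -> np.ndarray:
    """Nearest-neighbour resample of a (H, W, C) probability map onto target (h, w).

    Used by dense mode to put the 40x prediction map on the co-registered
    10x crop grid before the per-pixel KL.
    """
    H, W = prob_map.shape[:2]
    h, w = target_hw
    ri = np.minimum((np.arange(h) * H) // h, H - 1)
    ci = np.minimum((np.arange(w) * W) // w, W - 1)
    return prob_map[ri[:, None], ci[None, :]]
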