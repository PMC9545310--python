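"""Prediction routes: standard, bagged, and Monte-Carlo dropout (MCD).

The *standard* route is one deterministic forward pass with dropout off.
*Bagging* averages the standard predictions of the five cross-validation
fold models voxel by voxel.  The *MCD* route keeps dropout active at
estimation time and samples repeated forward passes — a Bernoulli
approximation of a Gaussian-process posterior — yielding a per-voxel
sample mean (the prediction), sample SD (the uncertainty), and the
coefficient of variation SD/mean (the *scaled uncertainty*, comparable
across regions of different ventilation intensity).

MCD sampling keeps only running first/second moments (Welford update), so
memory does not grow with the number of samples; the result matches the
naive two-pass mean/SD computation to floating tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import UNet3D
from .training import TrainedModel
from .volumes import VolumeGrid

__all__ = [
    "UncertaintyResult",
    "predict",
    "predict_bagged",
    "predict_mcd",
    "predict_mcd_bagged",
    "display_normalize",
    "CV_MEAN_GUARD",
]

#: voxels with |mean| below this (normalized ventilation units) get cv = 0
#: and are excluded from region-wise CV averages — sd/mean is meaningless
#: on the zeroed background.
CV_MEAN_GUARD = 1e-6


@dataclass
class UncertaintyResult:
    """Per-voxel MCD statistics over ``n_samples`` stochastic passes."""

    mean_map: VolumeGrid
    sd_map: VolumeGrid
    cv_map: VolumeGrid
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_samples >= 2 and (self.sd_map.data < 0).any():
            raise ValueError("sd_map must be non-negative")


def _network(model: TrainedModel | UNet3D) -> UNet3D:
    return model.network if isinstance(model, TrainedModel) else model


def _as_grid(data: np.ndarray, like: VolumeGrid | None) -> VolumeGrid:
    if like is None:
        return VolumeGrid(data=data)
    return like.with_data(data)


def _ct_array(ct) -> tuple[np.ndarray, VolumeGrid | None]:
    if isinstance(ct, VolumeGrid):
        return np.asarray(ct.data, dtype=np.float32), ct
    return np.asarray(ct, dtype=np.float32), None


def predict(model: TrainedModel | UNet3D, ct) -> VolumeGrid:
    """Single deterministic forward pass (dropout inactive); output ≥ 0."""
    arr, like = _ct_array(ct)
    out = _network(model).forward(arr, training=False)
    return _as_grid(out, like)


def predict_bagged(models: list, ct) -> VolumeGrid:
    """Voxel-wise mean of the standard predictions of several fold models."""
    if not models:
        raise ValueError("need at least one model to bag")
    arr, like = _ct_array(ct)
    preds = np.stack(
        [_network(m).forward(arr, training=False).astype(np.float64) for m in models]
    )
    return _as_grid(np.mean(preds, axis=0), like)


def cv_from_mean_sd(mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Scaled uncertainty SD/mean with the near-zero-mean guard applied."""
    valid = np.abs(mean) >= CV_MEAN_GUARD
    out = np.zeros_like(sd, dtype=np.float64)
    np.divide(sd, mean, out=out, where=valid)
    return out


def _welford_sample(net: UNet3D, arr: np.ndarray, n_samples: int, rng):
    mean = np.zeros(arr.shape, dtype=np.float64)
    m2 = np.zeros(arr.shape, dtype=np.float64)
    for i in range(1, n_samples + 1):
        y = net.forward(arr, training=True, rng=rng).astype(np.float64)
        delta = y - mean
        mean += delta / i
        m2 += delta * (y - mean)
    return mean, m2


def predict_mcd(
    model: TrainedModel | UNet3D, ct, n_samples: int = 200, seed: int = 0
) -> UncertaintyResult:
    """Monte-Carlo dropout: ``n_samples`` stochastic passes with dropout on.

    Returns the per-voxel sample mean, sample SD (ddof = 1), and
    CV = SD/mean maps.  Reproducible from ``seed``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    arr, like = _ct_array(ct)
    rng = np.random.default_rng(seed)
    mean, m2 = _welford_sample(_network(model), arr, n_samples, rng)
    sd = np.sqrt(m2 / (n_samples - 1))
    return UncertaintyResult(
        mean_map=_as_grid(mean, like),
        sd_map=_as_grid(sd, like),
        cv_map=_as_grid(cv_from_mean_sd(mean, sd), like),
        n_samples=n_samples,
        seed=seed,
    )


def predict_mcd_bagged(
    models: list, ct, n_samples: int = 200, seed: int = 0
) -> UncertaintyResult:
    """MCD over the fold ensemble: pool all ``k × n_samples`` passes.

    With k = 5 folds and 200 samples each this is the "1000 models"
    ensemble: the mean map equals the average of the per-fold mean maps
    (equal sample counts), and the SD is the pooled-sample SD.
    """
    if not models:
        raise ValueError("need at least one model to bag")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    arr, like = _ct_array(ct)
    seeds = np.random.SeedSequence(seed).generate_state(len(models)) >> 1
    means, m2s = [], []
    for m, s in zip(models, seeds):
        mean, m2 = _welford_sample(_network(m), arr, n_samples, np.random.default_rng(int(s)))
        means.append(mean)
        m2s.append(m2)
    grand_mean = np.mean(means, axis=0)
    total = len(models) * n_samples
    # pooled M2: within-fold spread plus the spread of fold means
    m2 = np.sum(m2s, axis=0) + n_samples * np.sum(
        [(mu - grand_mean) ** 2 for mu in means], axis=0
    )
    sd = np.sqrt(m2 / (total - 1))
    return UncertaintyResult(
        mean_map=_as_grid(grand_mean, like),
        sd_map=_as_grid(sd, like),
        cv_map=_as_grid(cv_from_mean_sd(grand_mean, sd), like),
        n_samples=total,
        seed=seed,
    )


def display_normalize(vol: VolumeGrid, mask: VolumeGrid) -> VolumeGrid:
    """Affine display scaling: in-mask 1st percentile → 0, 99th → 1, clipped.

    For visualization only; quantitative metrics always use the
    unmodified volumes.
    """
    inside = mask.data == 1
    if not inside.any():
        raise ValueError("mask is empty")
    vals = np.asarray(vol.data, dtype=float)[inside]
    p1, p99 = np.percentile(vals, [1, 99])
    if p99 <= p1:
        raise ValueError("degenerate intensity range (1st and 99th percentiles equal)")
    out = (np.asarray(vol.data, dtype=float) - p1) / (p99 - p1)
    return vol.with_data(np.clip(out, 0.0, 1.0))
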