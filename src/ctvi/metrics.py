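"""Evaluation of predicted vs reference ventilation within the lung.

The suite compares voxel intensity ordering (Spearman rank correlation),
functional geometry (Dice similarity of the high / moderate / low
ventilation tertiles), raw intensity agreement (masked MSE), defect
burden (non-defect ventilation fraction at 50 % of the in-lung 90th
percentile), the classic CT surrogate (low-attenuation area below
−856 HU), and region-wise mean scaled uncertainty.

The Spearman coefficient is computed by substituting average ranks into
the product-moment correlation form — with tie-free data this equals the
classical ``1 − 6·Σd²/(n(n²−1))`` expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volumes import VolumeGrid

__all__ = [
    "VoxelSeries",
    "FunctionalRegions",
    "CaseMetrics",
    "spearman_rs",
    "dsc",
    "functional_regions",
    "mse_masked",
    "non_defect_fraction",
    "low_attenuation_mask",
    "matched_volume_low_region",
    "region_mean_cv",
    "evaluate_case",
    "summarize_cohort",
]


@dataclass
class VoxelSeries:
    """Paired in-lung voxel values: reference ``y`` and prediction ``p``."""

    y: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.p = np.asarray(self.p, dtype=float).ravel()
        if self.y.shape != self.p.shape:
            raise ValueError("y and p must have equal length")
        if self.y.size < 2:
            raise ValueError("need at least 2 voxels")

    @classmethod
    def from_volumes(cls, ref: VolumeGrid, pred: VolumeGrid, lung_mask: VolumeGrid):
        inside = lung_mask.data == 1
        return cls(y=np.asarray(ref.data)[inside], p=np.asarray(pred.data)[inside])

    @property
    def n(self) -> int:
        return int(self.y.size)


@dataclass
class FunctionalRegions:
    """High / moderate / low ventilation tertiles of the lung.

    ``low`` holds values strictly below the 33.3rd in-lung percentile,
    ``high`` values at or above the 66.7th, ``moderate`` the remainder;
    the three regions partition the lung mask and are near-equal in
    volume (ties may unbalance them slightly).
    """

    high: VolumeGrid
    moderate: VolumeGrid
    low: VolumeGrid
    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        h, m, l = (np.asarray(r.data, dtype=bool) for r in (self.high, self.moderate, self.low))
        if (h & m).any() or (h & l).any() or (m & l).any():
            raise ValueError("functional regions must be pairwise disjoint")

    def as_dict(self) -> dict[str, VolumeGrid]:
        return {"high": self.high, "moderate": self.moderate, "low": self.low}


@dataclass
class CaseMetrics:
    """Per-case evaluation record."""

    case_id: str
    spearman_rs: float
    dsc_high: float
    dsc_moderate: float
    dsc_low: float
    mse: float
    non_defect_pct: float
    region_cv: dict[str, float] | None = None
    mask_dsc: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.spearman_rs <= 1.0:
            raise ValueError("spearman_rs outside [-1, 1]")
        for v in (self.dsc_high, self.dsc_moderate, self.dsc_low):
            if not 0.0 <= v <= 1.0:
                raise ValueError("DSC outside [0, 1]")
        if self.mse < 0 or not 0.0 <= self.non_defect_pct <= 100.0:
            raise ValueError("mse must be >= 0 and non_defect_pct a percentage")

    def to_row(self) -> dict:
        row = {
            "case_id": self.case_id,
            "spearman_rs": self.spearman_rs,
            "dsc_high": self.dsc_high,
            "dsc_moderate": self.dsc_moderate,
            "dsc_low": self.dsc_low,
            "mse": self.mse,
            "non_defect_pct": self.non_defect_pct,
            "mask_dsc": self.mask_dsc,
        }
        if self.region_cv:
            row.update({f"cv_{k}": v for k, v in self.region_cv.items()})
        row.update(self.extras)
        return row


def spearman_rs(series: VoxelSeries) -> float:
    """Spearman rank correlation of prediction vs reference.

    Average ranks (ties shared) are substituted into the product-moment
    correlation; the result lies in [−1, 1].

    Raises
    ------
    ValueError
        If either series is constant (correlation undefined).
    """
    ry = stats.rankdata(series.y)
    rp = stats.rankdata(series.p)
    dy = ry - ry.mean()
    dp = rp - rp.mean()
    denom = np.sqrt((dy * dy).sum() * (dp * dp).sum())
    if denom == 0:
        raise ValueError("Spearman correlation undefined for a constant series")
    return float(np.clip((dy * dp).sum() / denom, -1.0, 1.0))


def dsc(a: VolumeGrid | np.ndarray, b: VolumeGrid | np.ndarray) -> float:
    """Dice similarity coefficient ``2|a∩b| / (|a| + |b|)`` of binary regions.

    Two empty regions are an error (a silent 1.0 would mask degenerate
    inputs).
    """
    aa = np.asarray(a.data if isinstance(a, VolumeGrid) else a).astype(bool)
    bb = np.asarray(b.data if isinstance(b, VolumeGrid) else b).astype(bool)
    if aa.shape != bb.shape:
        raise ValueError("regions must share a grid")
    na, nb = int(aa.sum()), int(bb.sum())
    if na + nb == 0:
        raise ValueError("DSC undefined: both regions are empty")
    return 2.0 * int((aa & bb).sum()) / (na + nb)


def functional_regions(vol: VolumeGrid, lung_mask: VolumeGrid) -> FunctionalRegions:
    """Split the lung into low / moderate / high ventilation tertiles.

    Thresholds are the 33.3rd and 66.7th percentiles of the in-lung
    intensity (linear interpolation between order statistics).  ``low``
    is strict ``<`` at the lower threshold, ``high`` is ``≥`` at the
    upper — a deterministic rule that guarantees a partition; ties can
    leave the volumes slightly unequal.
    """
    inside = np.asarray(lung_mask.data) == 1
    n = int(inside.sum())
    if n < 3:
        raise ValueError("lung mask must contain at least 3 voxels")
    vals = np.asarray(vol.data, dtype=float)[inside]
    t_low, t_high = np.percentile(vals, [100.0 / 3.0, 200.0 / 3.0])
    if t_low == t_high and (vals == t_low).all():
        raise ValueError("all in-lung values tied; tertiles undefined")
    data = np.asarray(vol.data, dtype=float)
    low = inside & (data < t_low)
    high = inside & (data >= t_high)
    moderate = inside & ~low & ~high
    mk = lambda m: vol.with_data(m.astype(np.uint8))  # noqa: E731
    return FunctionalRegions(
        high=mk(high), moderate=mk(moderate), low=mk(low),
        t_low=float(t_low), t_high=float(t_high),
    )


def mse_masked(series: VoxelSeries) -> float:
    """Mean squared difference over the in-lung voxel series."""
    d = series.p - series.y
    return float(np.mean(d * d))


def non_defect_fraction(vent: VolumeGrid, lung_mask: VolumeGrid) -> float:
    """Percent of lung voxels at or above 50 % of the in-lung 90th percentile."""
    inside = np.asarray(lung_mask.data) == 1
    if not inside.any():
        raise ValueError("lung mask is empty")
    vals = np.asarray(vent.data, dtype=float)[inside]
    threshold = 0.5 * np.percentile(vals, 90)
    return float(100.0 * np.count_nonzero(vals >= threshold) / vals.size)


def low_attenuation_mask(ct_hu: VolumeGrid, lung_mask: VolumeGrid) -> VolumeGrid:
    """Lung voxels below −856 HU — the CT emphysema surrogate for low function."""
    laa = (np.asarray(ct_hu.data, dtype=float) < -856.0) & (np.asarray(lung_mask.data) == 1)
    return ct_hu.with_data(laa.astype(np.uint8))


def matched_volume_low_region(
    vol: VolumeGrid, lung_mask: VolumeGrid, target_count: int
) -> VolumeGrid:
    """The ``target_count`` lowest-intensity lung voxels as a binary region.

    Used to compare functional images at equal segmented volume (matched
    to the case's low-attenuation volume).  Ties break by voxel index
    order (C-order scan), so the region size is exact.
    """
    inside_flat = np.flatnonzero(np.asarray(lung_mask.data).ravel() == 1)
    n = inside_flat.size
    if not 0 < target_count <= n:
        raise ValueError(f"target_count must lie in (0, {n}]")
    vals = np.asarray(vol.data, dtype=float).ravel()[inside_flat]
    # stable sort: equal values keep ascending voxel index
    take = inside_flat[np.argsort(vals, kind="stable")[:target_count]]
    out = np.zeros(np.asarray(vol.data).size, dtype=np.uint8)
    out[take] = 1
    return vol.with_data(out.reshape(vol.shape))


def region_mean_cv(cv_map: VolumeGrid, regions: FunctionalRegions) -> dict[str, float]:
    """Mean scaled uncertainty per functional region.

    Guard-zeroed voxels (near-zero MCD mean) are excluded from the
    averages; an empty region is an error.
    """
    out = {}
    data = np.asarray(cv_map.data, dtype=float)
    for name, region in regions.as_dict().items():
        m = np.asarray(region.data) == 1
        if not m.any():
            raise ValueError(f"region '{name}' is empty")
        vals = data[m]
        vals = vals[vals != 0.0] if (vals == 0.0).any() else vals
        out[name] = float(vals.mean()) if vals.size else 0.0
    return out


def evaluate_case(
    pred: VolumeGrid,
    ref: VolumeGrid,
    lung_mask: VolumeGrid,
    ct_hu: VolumeGrid | None = None,
    cv_map: VolumeGrid | None = None,
    spect_mask: VolumeGrid | None = None,
    case_id: str = "case",
) -> CaseMetrics:
    """Full per-case evaluation of a predicted ventilation map.

    Functional tertiles are computed independently on prediction and
    reference and compared region by corresponding region with Dice;
    Spearman and MSE run on the in-lung voxel series.  Optional inputs
    add the CT low-attenuation Dice (``ct_hu``), region-wise mean scaled
    uncertainty (``cv_map``), and the registration-quality mask Dice
    (``spect_mask``).
    """
    series = VoxelSeries.from_volumes(ref, pred, lung_mask)
    reg_p = functional_regions(pred, lung_mask)
    reg_r = functional_regions(ref, lung_mask)
    extras: dict = {}
    if ct_hu is not None:
        laa = low_attenuation_mask(ct_hu, lung_mask)
        n_laa = int(np.count_nonzero(laa.data))
        if n_laa:
            extras["laa_dsc_pred"] = dsc(
                matched_volume_low_region(pred, lung_mask, n_laa), laa
            )
            extras["laa_dsc_ref"] = dsc(
                matched_volume_low_region(ref, lung_mask, n_laa), laa
            )
    return CaseMetrics(
        case_id=case_id,
        spearman_rs=spearman_rs(series),
        dsc_high=dsc(reg_p.high, reg_r.high),
        dsc_moderate=dsc(reg_p.moderate, reg_r.moderate),
        dsc_low=dsc(reg_p.low, reg_r.low),
        mse=mse_masked(series),
        non_defect_pct=non_defect_fraction(ref, lung_mask),
        region_cv=region_mean_cv(cv_map, reg_p) if cv_map is not None else None,
        mask_dsc=dsc(lung_mask, spect_mask) if spect_mask is not None else None,
        extras=extras,
    )


def summarize_cohort(metrics: list[CaseMetrics]) -> pd.DataFrame:
    """Per-case rows plus a ``mean ± SD`` summary row (population SD, ddof=1)."""
    df = pd.DataFrame([m.to_row() for m in metrics])
    num = df.select_dtypes("number")
    summary = pd.DataFrame(
        {c: [num[c].mean(), num[c].std(ddof=1)] for c in num.columns},
        index=["mean", "sd"],
    )
    summary.insert(0, "case_id", ["mean", "sd"])
    return pd.concat([df, summary], ignore_index=True)
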