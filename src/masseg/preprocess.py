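"""Intensity clipping, normalization and resampling.

The intensity pipeline mirrors the common CT practice: HU values are
clipped to a fixed window (default [-325, 400], which corresponds to the
0.5/99.5 foreground quantiles of the clinical dataset this method was
developed on), then z-scored with a pooled foreground mean/SD so that one
model can consume CBCT and CT volumes on the same intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap, Volume

DEFAULT_CLIP = (-325.0, 400.0)


@dataclass
class PreprocessConfig:
    clip_lo: float = DEFAULT_CLIP[0]
    clip_hi: float = DEFAULT_CLIP[1]
    quantile_lo: float = 0.005
    quantile_hi: float = 0.995
    normalization: str = "zscore"
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.clip_lo >= self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")
        if not (0 <= self.quantile_lo < self.quantile_hi <= 1):
            raise ValueError("quantiles must satisfy 0 <= qlo < qhi <= 1")


@dataclass
class NormStats:
    """Pooled foreground mean/SD used for z-scoring."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("normalization SD must be positive")


def clip_hu(v: Volume, lo: float = DEFAULT_CLIP[0], hi: float = DEFAULT_CLIP[1]) -> Volume:
    """Clamp every voxel to [lo, hi]; geometry unchanged."""
    if lo >= hi:
        raise ValueError(f"invalid clip window ({lo}, {hi})")
    return v.with_voxels(np.clip(v.voxels, lo, hi))


def foreground_quantile_bounds(
    volumes: list[Volume],
    masks: list[LabelMap],
    qlo: float = 0.005,
    qhi: float = 0.995,
) -> tuple[float, float]:
    """Quantiles of the pooled HU values at foreground (label != 0) voxels.

    Linear-interpolation quantiles over all cases pooled together; this is
    the rule used to derive a dataset-specific clip window.
    """
    if len(volumes) != len(masks):
        raise ValueError("volumes and masks must be aligned")
    pools = []
    for v, m in zip(volumes, masks):
        if v.shape != m.shape:
            raise ValueError("volume/mask shape mismatch")
        pools.append(v.voxels[m.labels != 0])
    fg = np.concatenate(pools) if pools else np.array([])
    if fg.size == 0:
        raise ValueError("no foreground voxels present")
    lo, hi = np.quantile(fg.astype(np.float64), [qlo, qhi], method="linear")
    return float(lo), float(hi)


def compute_norm_stats(
    volumes: list[Volume],
    masks: list[LabelMap],
    clip: tuple[float, float] = DEFAULT_CLIP,
) -> NormStats:
    """Pooled foreground mean/SD after clipping, for z-score normalization."""
    fg = np.concatenate(
        [np.clip(v.voxels[m.labels != 0], *clip) for v, m in zip(volumes, masks)]
    ).astype(np.float64)
    if fg.size == 0:
        raise ValueError("no foreground voxels present")
    return NormStats(mean=float(fg.mean()), sd=float(fg.std()))


def normalize(v: Volume, stats: NormStats) -> Volume:
    """Z-score the (already clipped) volume with pooled foreground stats."""
    return v.with_voxels((v.voxels - stats.mean) / stats.sd)


def preprocess_volume(
    v: Volume, cfg: PreprocessConfig, stats: NormStats
) -> Volume:
    """clip -> normalize, the full intensity pipeline for one volume."""
    return normalize(clip_hu(v, cfg.clip_lo, cfg.clip_hi), stats)


def resample(obj, target_spacing) -> "Volume | LabelMap":
    """Resample to a new voxel spacing, preserving physical extent.

    Intensity volumes use trilinear interpolation, label maps
    nearest-neighbor (so no new label values can appear).
    """
    target = tuple(float(s) for s in np.broadcast_to(target_spacing, (3,)))
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be positive")
    if np.allclose(obj.spacing, target):
        return obj
    zoom = [s_old / s_new for s_old, s_new in zip(obj.spacing, target)]
    if isinstance(obj, LabelMap):
        out = ndimage.zoom(obj.labels, zoom, order=0, mode="nearest", grid_mode=True)
        return LabelMap(out.astype(np.uint8), target, obj.origin)
    out = ndimage.zoom(
        obj.voxels.astype(np.float32), zoom, order=1, mode="nearest", grid_mode=True
    )
    return Volume(out, target, obj.origin)
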