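"""Full-volume prediction by sliding-window patch inference.

Per-voxel class probabilities (softmax of the network's fused or finest
full-resolution output) are averaged uniformly over all overlapping
windows; the final label is the argmax, ties resolved toward the lower
class index.  An optional largest-connected-component filter per
foreground class is available as post-processing (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .network import MasseterNet
from .nn import softmax_channels
from .volume_io import LabelMap, Volume


@dataclass
class InferenceConfig:
    patch_size: int = 48
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must lie in [0, 1)")


def _window_starts(n: int, p: int, stride: int) -> list[int]:
    if n == p:
        return [0]
    starts = list(range(0, n - p, stride))
    starts.append(n - p)  # always cover the far edge
    return sorted(set(starts))


def predict_probabilities(net: MasseterNet, v: Volume, cfg: InferenceConfig) -> np.ndarray:
    """Blended per-voxel class probabilities over the whole grid."""
    p = cfg.patch_size
    shape = v.shape
    pad = [max(0, p - n) for n in shape]
    vox = v.voxels
    if any(pad):
        vox = np.pad(vox, [(0, q) for q in pad], mode="edge")
    stride = max(1, int(round(p * (1.0 - cfg.overlap))))
    C = net.cfg.num_classes
    acc = np.zeros(vox.shape + (C,), dtype=np.float64)
    cnt = np.zeros(vox.shape, dtype=np.float64)
    starts = [_window_starts(n, p, stride) for n in vox.shape]
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                patch = vox[i : i + p, j : j + p, k : k + p]
                scores = net.forward(patch)[-1][0]  # fused (or finest) output
                acc[i : i + p, j : j + p, k : k + p] += softmax_channels(scores)
                cnt[i : i + p, j : j + p, k : k + p] += 1.0
    probs = acc / cnt[..., None]
    return probs[: shape[0], : shape[1], : shape[2]]


def predict(net: MasseterNet, v: Volume, cfg: InferenceConfig | None = None) -> LabelMap:
    """Segment a preprocessed volume; output grid equals the input grid."""
    cfg = cfg or InferenceConfig()
    probs = predict_probabilities(net, v, cfg)
    labels = probs.argmax(axis=-1).astype(np.uint8)  # argmax ties -> lower class
    return LabelMap(labels, v.spacing, v.origin)


def largest_components_filter(lab: LabelMap, k: int = 1) -> LabelMap:
    """Keep the k largest 26-connected components of each foreground class."""
    if k < 1:
        raise ValueError("k must be >= 1")
    structure = np.ones((3, 3, 3), dtype=bool)
    out = lab.labels.copy()
    for cls in (1, 2):
        mask = lab.labels == cls
        comp, n = ndimage.label(mask, structure=structure)
        if n <= k:
            continue
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[::-1][:k] + 1
        out[mask & ~np.isin(comp, keep)] = 0
    return LabelMap(out, lab.spacing, lab.origin)
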