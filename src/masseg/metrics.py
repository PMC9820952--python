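"""Segmentation agreement metrics: Dice overlap and average Hausdorff distance.

Conventions, chosen to reproduce the aggregation arithmetic of the clinical
results this toolkit re-implements:

* the "mean" DSC of a three-class map is the unweighted mean over
  {background, left, right} per-class Dice values;
* the average Hausdorff distance (aHD) is computed per structure in
  physical millimetres, the symmetric value is the mean of the two directed
  values, and the side-mean is the mean of the left and right symmetric
  values;
* DSC of two empty sets is 1, of one empty set 0; aHD is undefined (an
  error) when either set is empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import summarize
from .volume_io import LabelMap


def dsc(a: np.ndarray, m: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩M|/(|A|+|M|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    m = np.asarray(m, dtype=bool)
    na, nm = int(a.sum()), int(m.sum())
    if na + nm == 0:
        return 1.0
    return 2.0 * int((a & m).sum()) / (na + nm)


@dataclass
class DscBreakdown:
    dsc_background: float
    dsc_left: float
    dsc_right: float
    dsc_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.dsc_mean = (self.dsc_background + self.dsc_left + self.dsc_right) / 3.0


def dsc_breakdown(auto: LabelMap, manual: LabelMap) -> DscBreakdown:
    """Per-class DSC plus the unweighted three-class mean."""
    if auto.shape != manual.shape:
        raise ValueError("label grids are not aligned")
    return DscBreakdown(
        dsc_background=dsc(auto.labels == 0, manual.labels == 0),
        dsc_left=dsc(auto.labels == 1, manual.labels == 1),
        dsc_right=dsc(auto.labels == 2, manual.labels == 2),
    )


def two_class_dsc_mean(auto_fg: np.ndarray, manual_fg: np.ndarray) -> float:
    """The two-class convention: (DSC of structure + DSC of background)/2."""
    return 0.5 * (dsc(auto_fg, manual_fg) + dsc(~np.asarray(auto_fg, bool),
                                                ~np.asarray(manual_fg, bool)))


@dataclass
class AhdResult:
    directed_a_to_m: float
    directed_m_to_a: float
    symmetric: float = field(init=False)

    def __post_init__(self) -> None:
        self.symmetric = 0.5 * (self.directed_a_to_m + self.directed_m_to_a)


def ahd(a: np.ndarray, m: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> AhdResult:
    """Average Hausdorff distance between two voxel sets, in mm.

    The directed value A→M is the mean over voxels of A of the Euclidean
    distance (voxel indices scaled by spacing) to the nearest voxel of M;
    computed with an exact Euclidean distance transform.
    """
    a = np.asarray(a, dtype=bool)
    m = np.asarray(m, dtype=bool)
    if not a.any() or not m.any():
        raise ValueError("aHD undefined for empty structure")
    dist_to_m = ndimage.distance_transform_edt(~m, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~a, sampling=spacing)
    return AhdResult(
        directed_a_to_m=float(dist_to_m[a].mean()),
        directed_m_to_a=float(dist_to_a[m].mean()),
    )


@dataclass
class AhdBreakdown:
    left: AhdResult
    right: AhdResult
    side_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.side_mean = 0.5 * (self.left.symmetric + self.right.symmetric)


def ahd_breakdown(auto: LabelMap, manual: LabelMap) -> AhdBreakdown:
    if auto.shape != manual.shape:
        raise ValueError("label grids are not aligned")
    return AhdBreakdown(
        left=ahd(auto.labels == 1, manual.labels == 1, auto.spacing),
        right=ahd(auto.labels == 2, manual.labels == 2, auto.spacing),
    )


@dataclass
class RevisionResult:
    left_pct: float
    right_pct: float
    mean_pct: float = field(init=False)
    empty_revised_warning: bool = False

    def __post_init__(self) -> None:
        self.mean_pct = 0.5 * (self.left_pct + self.right_pct)


def revision_fraction(original: LabelMap, revised: LabelMap) -> RevisionResult:
    """Percentage of voxels an expert changed, per structure.

    For class c: 100 × |voxels where exactly one of (original==c, revised==c)|
    divided by |revised==c|.  If the revised structure is empty while the
    original is not, the original count is used as denominator and a warning
    flag is set.
    """
    if original.shape != revised.shape:
        raise ValueError("label grids are not aligned")
    pcts, warned = [], False
    for cls in (1, 2):
        o = original.labels == cls
        r = revised.labels == cls
        changed = int(np.logical_xor(o, r).sum())
        denom = int(r.sum())
        if denom == 0:
            if o.sum() == 0:
                pcts.append(0.0)
                continue
            denom = int(o.sum())
            warned = True
        pcts.append(100.0 * changed / denom)
    res = RevisionResult(left_pct=pcts[0], right_pct=pcts[1])
    res.empty_revised_warning = warned
    return res


PER_CASE_METRICS = (
    "dsc_mean", "dsc_background", "dsc_left", "dsc_right",
    "ahd_mean", "ahd_left", "ahd_right",
)


@dataclass
class MetricsReport:
    per_case: pd.DataFrame  # one row per case, columns PER_CASE_METRICS
    aggregate: dict  # metric -> {mean, sd, ci_lo, ci_hi, n}

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index_label="case_id")


def evaluate_cases(predictions: dict[str, LabelMap],
                   truths: dict[str, LabelMap]) -> MetricsReport:
    """Per-case DSC/aHD rows plus mean, SD and 95% CI of each metric.

    The side-mean aHD is aggregated as the mean over cases of the per-case
    (left + right)/2, which equals (mean left + mean right)/2.
    """
    missing = set(predictions) ^ set(truths)
    if missing:
        raise ValueError(f"unmatched case ids: {sorted(missing)}")
    rows = {}
    for cid in sorted(predictions):
        d = dsc_breakdown(predictions[cid], truths[cid])
        try:
            h = ahd_breakdown(predictions[cid], truths[cid])
            ahd_vals = (h.side_mean, h.left.symmetric, h.right.symmetric)
        except ValueError:
            # aHD is undefined when a structure is empty; the DSC row (0 for
            # a missed structure) still carries the case
            ahd_vals = (np.nan, np.nan, np.nan)
        rows[cid] = {
            "dsc_mean": d.dsc_mean,
            "dsc_background": d.dsc_background,
            "dsc_left": d.dsc_left,
            "dsc_right": d.dsc_right,
            "ahd_mean": ahd_vals[0],
            "ahd_left": ahd_vals[1],
            "ahd_right": ahd_vals[2],
        }
    per_case = pd.DataFrame.from_dict(rows, orient="index")
    aggregate = {}
    for metric in PER_CASE_METRICS:
        vals = per_case[metric].to_numpy(dtype=float)
        if len(vals) >= 2:
            mean, sd, (lo, hi) = summarize(vals)
            aggregate[metric] = {
                "mean": mean, "sd": sd, "ci_lo": lo, "ci_hi": hi, "n": len(vals),
            }
        else:
            aggregate[metric] = {
                "mean": float(vals[0]), "sd": None, "ci_lo": None,
                "ci_hi": None, "n": 1, "sd_undefined": True,
            }
    return MetricsReport(per_case=per_case, aggregate=aggregate)
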