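"""Synthetic paired CBCT/CT phantom generation.

Each phantom is a small head-like scene: an ellipsoidal soft-tissue (fat)
body surrounded by air, a midline bone plate, and two mirrored
masseter-like muscle bodies lateral to the plate, each tapering toward its
superior tip.  The same geometry is rendered twice — once with CT noise
parameters and once with CBCT noise parameters — around identical
per-compartment mean HU values, emulating the empirical situation in which
the muscle compartment has a similar central HU in both modalities but a
larger HU variance in CBCT.

Voxel intensities are ``mean_map + sd_map * G`` where ``G`` is a unit-variance
smooth Gaussian random field, so the per-compartment sample mean and SD
converge to the configured values while the noise remains spatially
correlated.  Compartment boundaries are sharp (no partial-volume blur).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .volume_io import LabelMap, Volume


@dataclass
class TissueHU:
    """Per-compartment HU model: common mean, per-modality noise SD."""

    mean: float
    sd_ct: float
    sd_cbct: float


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic paired scene.

    Lengths are in mm; positions are offsets from the grid's physical center.
    ``muscle_center`` is the left (+x) muscle; the right muscle is its mirror
    image in the x = 0 plane.  ``taper`` in [0, 1) shrinks the muscle's
    lateral radii linearly toward its superior (+z) tip, creating the thin
    superior extent that is the hardest region to segment.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    body_semiaxes: tuple[float, float, float] = (14.0, 13.0, 15.0)
    bone_halfwidths: tuple[float, float, float] = (2.0, 9.0, 12.0)
    muscle_center: tuple[float, float, float] = (9.5, 0.0, -1.0)
    muscle_semiaxes: tuple[float, float, float] = (3.5, 5.5, 10.0)
    taper: float = 0.5
    jitter_mm: float = 0.5
    smoothing_mm: float = 0.6
    muscle: TissueHU = field(default_factory=lambda: TissueHU(60.0, 15.0, 60.0))
    fat: TissueHU = field(default_factory=lambda: TissueHU(-100.0, 20.0, 50.0))
    bone: TissueHU = field(default_factory=lambda: TissueHU(900.0, 60.0, 120.0))
    air: TissueHU = field(default_factory=lambda: TissueHU(-1000.0, 20.0, 40.0))
    single_side: bool = False

    def __post_init__(self) -> None:
        for name in ("muscle", "fat", "bone", "air"):
            t = getattr(self, name)
            if isinstance(t, dict):
                setattr(self, name, TissueHU(**t))
        self.validate()

    def validate(self) -> None:
        if any(a <= 0 for a in self.muscle_semiaxes):
            raise ValueError("muscle semi-axes must be positive")
        if any(a <= 0 for a in self.body_semiaxes):
            raise ValueError("body semi-axes must be positive")
        if not (0 <= self.taper < 1):
            raise ValueError("taper must lie in [0, 1)")
        if self.jitter_mm < 0 or self.smoothing_mm < 0:
            raise ValueError("jitter and smoothing magnitudes must be non-negative")
        if self.muscle.sd_cbct < self.muscle.sd_ct:
            raise ValueError(
                "CBCT muscle HU SD must be >= CT muscle HU SD "
                f"(got {self.muscle.sd_cbct} < {self.muscle.sd_ct})"
            )
        # muscles must stay clear of the bone plate and of the midline so
        # that compartments are disjoint and chirality is well defined
        medial = self.muscle_center[0] - self.muscle_semiaxes[0] - self.jitter_mm
        if medial <= self.bone_halfwidths[0]:
            raise ValueError("muscle overlaps the bone plate or the midline")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("shape", "spacing", "body_semiaxes", "bone_halfwidths",
                    "muscle_center", "muscle_semiaxes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PairedCase:
    """Same-subject CBCT and CT phantoms sharing one ground-truth label map."""

    case_id: str
    cbct: Volume
    ct: Volume
    truth: LabelMap


def _grid_mm(spec: PhantomSpec):
    """Physical coordinates of voxel centers, symmetric about the grid center."""
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2.0) * s
        for n, s in zip(spec.shape, spec.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _muscle_mask(x, y, z, center, semiaxes, taper):
    cx, cy, cz = center
    ax, ay, az = semiaxes
    u = np.clip((z - cz) / az, 0.0, 1.0)
    s = 1.0 - taper * u
    return ((x - cx) / (ax * s)) ** 2 + ((y - cy) / (ay * s)) ** 2 + (
        (z - cz) / az
    ) ** 2 <= 1.0


def rasterize_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Return (compartment map, truth labels) on the spec grid.

    Compartments: 0 air, 1 fat, 2 bone, 3 left muscle, 4 right muscle,
    assigned in that priority order so they are disjoint by construction.
    """
    x, y, z = _grid_mm(spec)
    body = (
        (x / spec.body_semiaxes[0]) ** 2
        + (y / spec.body_semiaxes[1]) ** 2
        + (z / spec.body_semiaxes[2]) ** 2
        <= 1.0
    )
    bx, by, bz = spec.bone_halfwidths
    bone = body & (np.abs(x) <= bx) & (np.abs(y) <= by) & (np.abs(z) <= bz)

    jit_l = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
    jit_r = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
    cl = np.asarray(spec.muscle_center) + jit_l
    cr = np.asarray(spec.muscle_center) * np.array([-1.0, 1.0, 1.0]) + jit_r
    left = _muscle_mask(x, y, z, cl, spec.muscle_semiaxes, spec.taper)
    right = _muscle_mask(x, y, z, cr, spec.muscle_semiaxes, spec.taper)

    comp = np.zeros(spec.shape, dtype=np.uint8)
    comp[body] = 1
    comp[bone] = 2
    comp[left] = 3
    if not spec.single_side:
        comp[right] = 4

    truth = np.zeros(spec.shape, dtype=np.uint8)
    truth[comp == 3] = 1
    truth[comp == 4] = 2
    return comp, truth


def _unit_smooth_field(shape, sigma_vox, rng: np.random.Generator):
    """Smooth Gaussian field rescaled to unit pointwise SD."""
    g = rng.standard_normal(shape)
    if np.any(np.asarray(sigma_vox) > 0):
        g = gaussian_filter(g, sigma=sigma_vox, mode="nearest")
        sd = g.std()
        if sd > 0:
            g = g / sd
    return g


def _render(comp, spec: PhantomSpec, modality: str, rng: np.random.Generator):
    tissues = [spec.air, spec.fat, spec.bone, spec.muscle, spec.muscle]
    means = np.array([t.mean for t in tissues])
    sds = np.array(
        [t.sd_ct if modality == "ct" else t.sd_cbct for t in tissues]
    )
    sigma_vox = [spec.smoothing_mm / s for s in spec.spacing]
    noise = _unit_smooth_field(comp.shape, sigma_vox, rng)
    img = means[comp] + sds[comp] * noise
    return img.astype(np.float32)


def generate_case(spec: PhantomSpec, seed: int, case_id: str = "case") -> PairedCase:
    """Generate one paired CBCT/CT phantom, fully reproducible from (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    comp, truth = rasterize_geometry(spec, rng)
    ct = _render(comp, spec, "ct", rng)
    cbct = _render(comp, spec, "cbct", rng)
    return PairedCase(
        case_id=case_id,
        cbct=Volume(cbct, spec.spacing),
        ct=Volume(ct, spec.spacing),
        truth=LabelMap(truth, spec.spacing),
    )


def _split_counts(n: int, ratios) -> list[int]:
    raw = [r * n for r in ratios]
    counts = [int(np.floor(v)) for v in raw]
    rem = n - sum(counts)
    order = np.argsort([-(v - int(np.floor(v))) for v in raw], kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def generate_dataset(
    spec: PhantomSpec,
    n: int,
    seed: int,
    split_ratios=(0.6, 0.2, 0.2),
) -> tuple[list[PairedCase], dict]:
    """Generate ``n`` cases with per-case sub-seeds derived from ``seed``.

    Returns the cases and a manifest recording ids, sub-seeds, the spec hash
    and a deterministic train/val/test split (cases assigned in order).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(sum(split_ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
    cases = []
    for i, sub in enumerate(sub_seeds):
        cid = f"case_{i:03d}"
        cases.append(generate_case(spec, sub, case_id=cid))
    ids = [c.case_id for c in cases]
    n_train, n_val, n_test = _split_counts(n, split_ratios)
    manifest = {
        "n": n,
        "master_seed": int(seed),
        "spec_hash": spec.digest(),
        "cases": [
            {"id": cid, "seed": sub} for cid, sub in zip(ids, sub_seeds)
        ],
        "split": {
            "train": ids[:n_train],
            "val": ids[n_train : n_train + n_val],
            "test": ids[n_train + n_val :],
        },
    }
    return cases, manifest


def simulate_observer(
    truth: LabelMap,
    magnitude_mm: float,
    seed: int,
    field_smoothing_mm: float = 3.0,
) -> LabelMap:
    """Emulate a human annotator by warping structure boundaries.

    The truth labels are resampled through a smooth random displacement
    field with pointwise SD ``magnitude_mm`` per component (nearest-neighbor
    interpolation, so the label alphabet is preserved).  Magnitude 0 returns
    the truth unchanged.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude_mm == 0:
        return LabelMap(truth.labels.copy(), truth.spacing, truth.origin)
    rng = np.random.default_rng(seed)
    shape = truth.shape
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    warped_coords = []
    for axis in range(3):
        sigma_vox = [field_smoothing_mm / s for s in truth.spacing]
        disp_mm = magnitude_mm * _unit_smooth_field(shape, sigma_vox, rng)
        warped_coords.append(coords[axis] + disp_mm / truth.spacing[axis])
    warped = map_coordinates(truth.labels, warped_coords, order=0, mode="nearest")
    return LabelMap(warped.astype(np.uint8), truth.spacing, truth.origin)
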