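"""Loss functions, learning-rate schedule, augmentation and the training loop.

Training minimizes an equally weighted sum of soft Dice loss (over the two
foreground classes) and cross-entropy, applied with deep supervision: the
ground truth is down-sampled (nearest-neighbor, so labels stay in {0,1,2})
to the resolution of every decoder output and the combined loss is summed
over scales.  Optimization is momentum SGD under a linear warm-up followed
by cosine decay to zero.  Geometric augmentation draws a random rotation
and isotropic rescale per patch; reflections are never sampled, because a
mirror image would swap the meaning of the left and right labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .network import MasseterNet, NetworkConfig, build_network
from .nn import Tape

DICE_EPS = 1e-5


@dataclass
class TrainConfig:
    total_iterations: int = 20000
    batch_size: int = 2
    base_lr: float = 1e-3
    warmup_iterations: int = 300
    momentum: float = 0.9
    weight_decay: float = 0.0
    patch_size: int = 48
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.85, 1.15)
    ds_weights: tuple[float, ...] | None = None  # None -> all scales weight 1
    fg_bias: float = 0.5  # fraction of patches forced to contain muscle
    augment_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup_iterations >= self.total_iterations:
            raise ValueError("warmup_iterations must be < total_iterations")
        if self.batch_size < 1 or self.base_lr <= 0:
            raise ValueError("batch_size must be >= 1 and base_lr > 0")
        if self.scale_range[0] <= 0 or self.scale_range[0] > self.scale_range[1]:
            raise ValueError("invalid scale range")


# ---------------------------------------------------------------------------
# losses


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    return np.eye(num_classes, dtype=np.float32)[labels]


def soft_dice_loss(probs: np.ndarray, target_onehot: np.ndarray,
                   eps: float = DICE_EPS) -> float:
    """1 - mean over foreground classes of the soft Dice coefficient.

    ``probs`` and ``target_onehot`` are (..., C) with per-voxel class
    probabilities summing to 1; class 0 is background and excluded.
    """
    if probs.shape != target_onehot.shape:
        raise ValueError("probability and target shapes must match")
    C = probs.shape[-1]
    ax = tuple(range(probs.ndim - 1))
    num = 2.0 * (probs * target_onehot).sum(axis=ax) + eps
    den = probs.sum(axis=ax) + target_onehot.sum(axis=ax) + eps
    dice = num[1:] / den[1:] if C > 1 else num / den
    return float(1.0 - dice.mean())


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class."""
    p_true = np.take_along_axis(probs, labels[..., None].astype(np.int64), axis=-1)
    return float(-np.log(np.clip(p_true, 1e-12, None)).mean())


def combined_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Soft Dice + cross-entropy with weight 1 each, from raw scores."""
    loss, _ = combined_loss_and_grad(scores, labels)
    return loss


def combined_loss_and_grad(scores: np.ndarray, labels: np.ndarray):
    """Return (dice + CE, d(loss)/d(scores)); scores are raw (unnormalized)."""
    if scores.shape[:-1] != labels.shape:
        raise ValueError(
            f"score spatial shape {scores.shape[:-1]} != label shape {labels.shape}"
        )
    C = scores.shape[-1]
    s = np.asarray(scores, dtype=np.float64)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    p = e / e.sum(axis=-1, keepdims=True)
    g = one_hot(labels, C).astype(np.float64)
    n_vox = float(labels.size)
    ax = tuple(range(scores.ndim - 1))

    # cross-entropy and its gradient w.r.t. scores
    p_true = np.take_along_axis(p, labels[..., None].astype(np.int64), axis=-1)
    ce = float(-np.log(np.clip(p_true, 1e-12, None)).mean())
    dscore = (p - g) / n_vox

    # soft Dice over foreground classes; gradient chained through softmax
    fg = list(range(1, C)) if C > 1 else [0]
    num = 2.0 * (p * g).sum(axis=ax) + DICE_EPS
    den = p.sum(axis=ax) + g.sum(axis=ax) + DICE_EPS
    dice_loss = float(1.0 - (num[fg] / den[fg]).mean())
    dp = np.zeros_like(p)
    for c in fg:
        dp[..., c] = -(2.0 * g[..., c] * den[c] - num[c]) / (den[c] ** 2 * len(fg))
    inner = (dp * p).sum(axis=-1, keepdims=True)
    dscore += p * (dp - inner)

    return dice_loss + ce, dscore.astype(np.float32)


def downsample_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor label down-sampling by an integer factor per axis."""
    if factor == 1:
        return labels
    sl = (slice(None),) * (labels.ndim - 3) + (slice(None, None, factor),) * 3
    return labels[sl]


def deep_supervision_loss(outputs: list[np.ndarray], labels: np.ndarray,
                          weights=None) -> float:
    """Weighted sum of combined losses over all output scales.

    ``outputs`` are score grids ordered fine to coarse (a trailing fused
    full-resolution output is allowed); each is matched to the ground truth
    down-sampled to its resolution.
    """
    loss, _ = deep_supervision_loss_and_grads(outputs, labels, weights)
    return loss


def deep_supervision_loss_and_grads(outputs, labels, weights=None):
    full = labels.shape[-3]
    if weights is None:
        weights = [1.0] * len(outputs)
    if len(weights) != len(outputs):
        raise ValueError("one weight per output scale required")
    total = 0.0
    grads = []
    for out, w in zip(outputs, weights):
        factor, rem = divmod(full, out.shape[-4])
        if rem:
            raise ValueError(
                f"output size {out.shape[-4]} does not divide ground truth {full}"
            )
        tgt = downsample_labels(labels, factor)
        loss, grad = combined_loss_and_grad(out, tgt)
        total += w * loss
        grads.append(np.float32(w) * grad)
    return float(total), grads


# ---------------------------------------------------------------------------
# schedule


def lr_at(iteration: int, cfg: TrainConfig) -> float:
    """Linear warm-up to base_lr, then cosine decay to zero."""
    it, warm, total = iteration, cfg.warmup_iterations, cfg.total_iterations
    if not (0 <= it <= total):
        raise ValueError(f"iteration {it} outside [0, {total}]")
    if it <= warm:
        return cfg.base_lr * it / warm if warm else cfg.base_lr
    frac = (it - warm) / (total - warm)
    return cfg.base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


# ---------------------------------------------------------------------------
# augmentation


def sample_affine(cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """Random rotation + isotropic rescale; determinant always positive."""
    angles = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg, size=3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scale = rng.uniform(*cfg.scale_range)
    return (rz @ ry @ rx) * scale


def augment(vol_patch: np.ndarray, lab_patch: np.ndarray, cfg: TrainConfig,
            rng: np.random.Generator):
    """Apply one random rotate+rescale to an aligned (intensity, label) pair.

    Trilinear resampling for the intensities, nearest-neighbor for the
    labels; the transform is about the patch center.  A zero rotation range
    with unit scale range is the identity.
    """
    if cfg.rotation_deg == 0 and cfg.scale_range == (1.0, 1.0):
        return vol_patch, lab_patch
    A = sample_affine(cfg, rng)
    center = (np.array(vol_patch.shape) - 1) / 2.0
    # map output coords to input coords: in = M @ (out - c) + c
    M = np.linalg.inv(A)
    offset = center - M @ center
    v = ndimage.affine_transform(vol_patch, M, offset=offset, order=1, mode="nearest")
    l = ndimage.affine_transform(lab_patch, M, offset=offset, order=0, mode="nearest")
    return v.astype(np.float32), l.astype(np.uint8)


# ---------------------------------------------------------------------------
# patch sampling and the loop


def _sample_patch(img, lab, p, rng, fg_bias):
    shape = np.array(img.shape)
    hi = shape - p
    if np.any(hi < 0):
        raise ValueError(f"patch size {p} exceeds volume shape {tuple(shape)}")
    if fg_bias > 0 and rng.random() < fg_bias:
        fg = np.argwhere(lab != 0)
        if len(fg):
            v = fg[rng.integers(len(fg))]
            origin = np.clip(v - rng.integers(0, p, size=3), 0, hi)
        else:
            origin = rng.integers(0, hi + 1)
    else:
        origin = rng.integers(0, hi + 1)
    sl = tuple(slice(int(o), int(o) + p) for o in origin)
    return img[sl], lab[sl]


def train(samples: list[tuple[np.ndarray, np.ndarray]],
          net_cfg: NetworkConfig,
          cfg: TrainConfig,
          net: MasseterNet | None = None):
    """Run momentum-SGD training on random augmented patches.

    ``samples`` is a list of (preprocessed intensity grid, label grid)
    pairs; CBCT and CT renderings of the same case enter as separate
    samples sharing one ground truth, so a batch can mix modalities.
    Returns the trained network and a log of (iteration, lr, loss) rows.
    """
    if not samples:
        raise ValueError("empty training dataset")
    init_child, data_child = np.random.SeedSequence(cfg.seed).spawn(2)
    init_seed = int(init_child.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(data_child)
    if net is None:
        net = build_network(net_cfg, seed=init_seed)
    velocity = {k: np.zeros_like(p.value) for k, p in net.params.items()}
    log = []
    p_size = cfg.patch_size
    for it in range(1, cfg.total_iterations + 1):
        imgs, labs = [], []
        for _ in range(cfg.batch_size):
            i = rng.integers(len(samples))
            vp, lp = _sample_patch(samples[i][0], samples[i][1], p_size, rng, cfg.fg_bias)
            if cfg.augment_enabled:
                vp, lp = augment(vp, lp, cfg, rng)
            imgs.append(vp)
            labs.append(lp)
        x = np.stack(imgs)[..., None]
        y = np.stack(labs)
        tape = Tape()
        nodes = net.forward_nodes(tape, x)
        loss, grads = deep_supervision_loss_and_grads(
            [n.value for n in nodes], y, cfg.ds_weights
        )
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}: loss={loss}")
        net.zero_grad()
        tape.backward(list(zip(nodes, grads)))
        lr = lr_at(it, cfg)
        for k, p in net.params.items():
            g = p.grad if p.grad is not None else 0.0
            if cfg.weight_decay:
                g = g + cfg.weight_decay * p.value
            velocity[k] = cfg.momentum * velocity[k] - lr * g
            p.value += velocity[k]
        log.append({"iteration": it, "lr": float(lr), "loss": float(loss)})
    return net, log
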