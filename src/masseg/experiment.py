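"""Scaled-down end-to-end phantom study.

Generates a dataset of paired CBCT/CT phantoms, trains the residual-U-block
network jointly on patches from both modalities, predicts the held-out
cases, and scores them against the shared ground truth — the complete
pipeline at desk scale.  The default problem sizes (12 cases of 64³ voxels
at 0.5 mm, 8 train / 4 test, stage channels 8/16/32/64, 500 iterations of
batch 2 on 32³ patches) are chosen so a full run finishes in minutes on a
single CPU core while still exercising every component end to end.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .inference import InferenceConfig, predict
from .metrics import dsc, evaluate_cases
from .network import NetworkConfig
from .phantom import PhantomSpec, generate_dataset
from .preprocess import (DEFAULT_CLIP, NormStats, clip_hu, compute_norm_stats,
                         normalize)
from .stats import bland_altman
from .training import TrainConfig, train


@dataclass
class ExperimentConfig:
    n_cases: int = 12
    n_train: int = 8
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    channels: tuple[int, ...] = (8, 16, 32, 64)
    rsu_depths: tuple[int, ...] = (5, 4, 3, 2)
    iterations: int = 500
    batch_size: int = 2
    patch_size: int = 32
    warmup_iterations: int = 50
    base_lr: float = 1e-3
    overlap: float = 0.5


def preprocess_cases(cases, clip=DEFAULT_CLIP, stats: NormStats | None = None):
    """Clip and z-score both modalities of every case with pooled stats.

    Returns (list of (case_id, modality, image, labels), stats).  The pooled
    foreground mean/SD is computed over CBCT and CT together when not given.
    """
    if stats is None:
        vols = [c.cbct for c in cases] + [c.ct for c in cases]
        masks = [c.truth for c in cases] * 2
        stats = compute_norm_stats(vols, masks, clip=clip)
    out = []
    for c in cases:
        for modality, vol in (("cbct", c.cbct), ("ct", c.ct)):
            v = normalize(clip_hu(vol, *clip), stats)
            out.append((c.case_id, modality, v, c.truth))
    return out, stats


def run_phantom_experiment(seed: int = 7, cfg: ExperimentConfig | None = None) -> dict:
    """Run the full phantom study and return all computed quantities."""
    cfg = cfg or ExperimentConfig()
    t0 = time.time()
    ratios = (cfg.n_train / cfg.n_cases, 0.0, 1.0 - cfg.n_train / cfg.n_cases)
    cases, manifest = generate_dataset(cfg.phantom, cfg.n_cases, seed, ratios)
    by_id = {c.case_id: c for c in cases}
    train_ids = manifest["split"]["train"]
    test_ids = manifest["split"]["test"]

    prepped, stats = preprocess_cases([by_id[i] for i in train_ids])
    samples = [(v.voxels, t.labels) for _, _, v, t in prepped]

    net_cfg = NetworkConfig(channels=cfg.channels, rsu_depths=cfg.rsu_depths)
    train_cfg = TrainConfig(
        total_iterations=cfg.iterations,
        batch_size=cfg.batch_size,
        base_lr=cfg.base_lr,
        warmup_iterations=cfg.warmup_iterations,
        patch_size=cfg.patch_size,
        seed=seed,
    )
    net, log = train(samples, net_cfg, train_cfg)

    inf_cfg = InferenceConfig(patch_size=cfg.patch_size, overlap=cfg.overlap)
    test_prepped, _ = preprocess_cases([by_id[i] for i in test_ids], stats=stats)
    preds = {"cbct": {}, "ct": {}}
    truths = {}
    for cid, modality, vol, truth in test_prepped:
        preds[modality][cid] = predict(net, vol, inf_cfg)
        truths[cid] = truth

    reports = {m: evaluate_cases(preds[m], truths) for m in ("cbct", "ct")}

    cross = {"dsc_left": [], "dsc_right": []}
    for cid in test_ids:
        a, b = preds["cbct"][cid].labels, preds["ct"][cid].labels
        cross["dsc_left"].append(dsc(a == 1, b == 1))
        cross["dsc_right"].append(dsc(a == 2, b == 2))
    cross_means = {k: float(np.mean(v)) for k, v in cross.items()}
    cross_means["dsc_foreground"] = 0.5 * (
        cross_means["dsc_left"] + cross_means["dsc_right"]
    )

    ba = bland_altman(
        reports["cbct"].per_case["dsc_mean"].to_numpy(),
        reports["ct"].per_case["dsc_mean"].to_numpy(),
    )

    losses = [row["loss"] for row in log]
    k = min(50, len(losses) // 2)
    return {
        "seed": int(seed),
        "manifest": manifest,
        "norm_stats": {"mean": stats.mean, "sd": stats.sd},
        "num_parameters": net.num_parameters(),
        "training_log": log,
        "loss_first_mean": float(np.mean(losses[:k])),
        "loss_last_mean": float(np.mean(losses[-k:])),
        "reports": reports,
        "cross_modal": cross_means,
        "bland_altman_dsc_mean": ba,
        "net": net,
        "predictions": preds,
        "truths": truths,
        "runtime_s": time.time() - t0,
    }


def experiment_summary(result: dict) -> dict:
    """Flat numeric summary of an experiment run (for reports and JSON)."""
    out = {
        "loss_first_mean": result["loss_first_mean"],
        "loss_last_mean": result["loss_last_mean"],
        "cross_modal_dsc": result["cross_modal"]["dsc_foreground"],
        "runtime_s": result["runtime_s"],
    }
    for m in ("cbct", "ct"):
        agg = result["reports"][m].aggregate
        for metric in ("dsc_left", "dsc_right", "ahd_left", "ahd_right", "ahd_mean",
                       "dsc_mean", "dsc_background"):
            out[f"{m}_{metric}"] = agg[metric]["mean"]
    return out
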