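"""Ablation harness: single members vs soft voting vs selective fusion.

Mirrors the experimental structure the framework is evaluated with: every
configuration — each U-Net variant alone, the soft-voting ensemble, the
rank-based selective ensemble, and selective fusion with the vessel-prior
constraint — is scored with Dice / sensitivity / specificity on the test
split of a phantom benchmark, inside the heart ROI the cascade provides.
An optional leave-one-out sweep drops each member in turn.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cascade import (OracleModel, bounding_box, crop_to_box,
                      dilate_vessel_prior, pad_to_multiple)
from .fusion import EnsemblePrediction, FusionConfig, fuse_volume, soft_vote
from .metrics import SegMetrics, compute_metrics
from .phantom import BenchmarkSuite, PhantomCase
from .unet_zoo import (ModelConfig, SegmentationModel, TrainConfig,
                       VARIANTS, build_model, predict_proba, train)

__all__ = [
    "RoiSample",
    "prepare_roi",
    "train_members",
    "member_probabilities",
    "run_ablation",
]


@dataclass(frozen=True)
class RoiSample:
    """One phantom cropped to its heart ROI, normalized and padded."""

    case: PhantomCase
    image: np.ndarray          # (Z, H, W) min-max normalized
    calcium: np.ndarray        # (Z, H, W) bool
    prior: np.ndarray          # (Z, H, W) bool
    decoy: np.ndarray          # (Z, H, W) bool


def prepare_roi(case: PhantomCase, margin_mm: float = 10.0,
                prior_dilation_mm: float = 2.0, pad_multiple: int = 4) -> RoiSample:
    """Crop to the ground-truth heart box (oracle stage-1) and normalize.

    Spatial axes are zero-padded up to a multiple of ``pad_multiple`` so
    slices feed the 2D networks directly.
    """
    box = bounding_box(case.heart, margin_mm=margin_mm, spacing=case.ct.spacing)
    img = crop_to_box(case.ct.voxels, box)
    lo, hi = float(img.min()), float(img.max())
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)

    def pad(a: np.ndarray) -> np.ndarray:
        out, _ = pad_to_multiple(a[None], pad_multiple)
        return out[0]

    prior = dilate_vessel_prior(crop_to_box(case.vessel, box),
                                prior_dilation_mm, case.ct.spacing).mask
    return RoiSample(
        case=case,
        image=pad(img.astype(np.float32)),
        calcium=pad(crop_to_box(case.calcium, box)),
        prior=pad(prior),
        decoy=pad(crop_to_box(case.decoy, box)),
    )


def train_members(suite: BenchmarkSuite,
                  model_cfg: ModelConfig = ModelConfig(depth=2, base_channels=8),
                  train_cfg: TrainConfig = TrainConfig(),
                  margin_mm: float = 10.0,
                  variants: tuple[str, ...] = VARIANTS,
                  ) -> dict[str, SegmentationModel]:
    """Train one tiny model per variant on calcification-positive ROI slices.

    Each member gets a distinct derived seed (init and batching), so the
    ensemble is heterogeneous both in topology and in randomness.
    """
    rois = [prepare_roi(c, margin_mm=margin_mm,
                        pad_multiple=2 ** model_cfg.depth) for c in suite.train]
    shapes = {r.image.shape[1:] for r in rois}
    target = tuple(np.max(list(shapes), axis=0))
    dataset = []
    for r in rois:
        img, cal = _pad_to(r.image, target), _pad_to(r.calcium, target)
        for z in np.where(cal.any(axis=(1, 2)))[0]:
            dataset.append((img[z][None], cal[z].astype(np.float32)))

    members: dict[str, SegmentationModel] = {}
    for i, variant in enumerate(variants):
        cfg = replace(model_cfg, variant=variant)
        seed = train_cfg.seed * 1000 + i
        model = build_model(cfg, seed=seed)
        train(model, dataset, replace(train_cfg, seed=seed))
        members[variant] = model
    return members


def _pad_to(a: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    ph, pw = hw[0] - a.shape[1], hw[1] - a.shape[2]
    return np.pad(a, ((0, 0), (0, ph), (0, pw)))


def member_probabilities(members: dict[str, SegmentationModel],
                         roi: RoiSample) -> dict[str, np.ndarray]:
    """Per-member probability volumes on one ROI grid (slice-wise 2D)."""
    out: dict[str, np.ndarray] = {}
    for name, model in members.items():
        x, _ = pad_to_multiple(roi.image[:, None], 2 ** model.config.depth)
        probs = predict_proba(model, x)
        out[name] = probs[:, : roi.image.shape[1], : roi.image.shape[2]]
    return out


def _pool(metrics_per_case: list[tuple[np.ndarray, np.ndarray]]) -> SegMetrics:
    pred = np.concatenate([p.reshape(-1) for p, _ in metrics_per_case])
    gt = np.concatenate([g.reshape(-1) for _, g in metrics_per_case])
    return compute_metrics(pred, gt)


def run_ablation(members: dict[str, SegmentationModel],
                 test_cases: list[PhantomCase] | tuple[PhantomCase, ...],
                 fusion_cfg: FusionConfig = FusionConfig(),
                 margin_mm: float = 10.0,
                 prior_dilation_mm: float = 2.0,
                 leave_one_out: bool = False) -> pd.DataFrame:
    """Score every configuration on the test split (voxel-pooled metrics).

    Rows: one per single member, ``soft_vote``, ``selective`` (no prior
    constraint), ``selective+prior``, and optionally ``loo-<member>``
    (selective+prior with that member removed).
    """
    rois = [prepare_roi(c, margin_mm=margin_mm,
                        prior_dilation_mm=prior_dilation_mm) for c in test_cases]
    probs = [member_probabilities(members, r) for r in rois]
    names = list(members)

    collected: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}

    def add(config: str, pred: np.ndarray, roi: RoiSample) -> None:
        collected.setdefault(config, []).append((pred, roi.calcium))

    no_prior = replace(fusion_cfg, use_prior=False)
    for roi, p in zip(rois, probs):
        vols = [p[n] for n in names]
        for n in names:
            add(n, p[n] >= fusion_cfg.member_threshold, roi)
        _, sv = soft_vote(EnsemblePrediction(tuple(vols), tuple(names)),
                          fusion_cfg.output_threshold)
        add("soft_vote", sv, roi)
        _, sel = fuse_volume(vols, None, no_prior, names)
        add("selective", sel, roi)
        _, selp = fuse_volume(vols, roi.prior, fusion_cfg, names)
        add("selective+prior", selp, roi)
        if leave_one_out and len(names) > 2:
            for drop in names:
                keep = [n for n in names if n != drop]
                k = min(fusion_cfg.top_k, len(keep))
                _, m = fuse_volume([p[n] for n in keep], roi.prior,
                                   replace(fusion_cfg, top_k=k), keep)
                add(f"loo-{drop}", m, roi)

    rows = []
    for config, pairs in collected.items():
        m = _pool(pairs)
        rows.append({"config": config, "dice": m.dice,
                     "sensitivity": m.sensitivity, "specificity": m.specificity,
                     "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn})
    return pd.DataFrame(rows)
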