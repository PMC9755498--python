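"""Training and evaluation orchestration.

Implements the experimental protocol around the network: patient-grouped
k-fold splitting (all frames of a patient stay on one side of every
split), the training loop (Adam, Kaiming initialization, collaborative
Dice loss, rotation/flip augmentation), batch prediction with geometric
AoP measurement, the ablation harness over the reduced network variants,
and the lower-branch loss-weight sweep.
"""

from __future__ import annotations

import csv
import json
import logging
import sys
import time
from dataclasses import dataclass, field, replace, asdict
import numpy as np
import pandas as pd

from . import metrics
from .geometry import AoPResult, AoPStatus, measure_aop_from_mask
from .model import (
    DBSN,
    NetworkConfig,
    build_dbsn,
    collaborative_loss,
    load_checkpoint,
    save_checkpoint,
)
from .nn import Adam
from .nn.autograd import Tensor
from .preprocess import AugmentationSpec, augment
from .synthetic import SyntheticSample

__all__ = [
    "TrainConfig",
    "FoldAssignment",
    "patient_grouped_kfold",
    "train_model",
    "train_fold",
    "cross_validate",
    "predict_and_measure",
    "evaluate_predictions",
    "ablation_harness",
    "sweep_w_lower",
    "measurements_to_csv",
    "write_report",
]

logger = logging.getLogger("aopnet")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 200
    batch_size: int = 1
    k_folds: int = 5
    seed: int = 0
    augment: bool = True
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.k_folds < 2 or self.batch_size < 1:
            raise ValueError("invalid training configuration")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            d["augmentation"] = AugmentationSpec(**d["augmentation"])
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkConfig.from_dict(d["network"])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


FoldAssignment = dict  # patient_id -> fold index


def patient_grouped_kfold(patient_ids, k: int, seed: int = 0) -> FoldAssignment:
    """Assign each unique patient to one of k folds, sizes differing by <= 1.

    Frames share their patient's fold, so no patient ever straddles a
    train/validation boundary.  Deterministic given the seed.
    """
    unique = sorted(set(patient_ids))
    if k < 2 or k > len(unique):
        raise ValueError(f"need 2 <= k <= number of patients ({len(unique)}), got {k}")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    return {pid: i % k for i, pid in enumerate(order)}


def check_no_leakage(samples, assignment: FoldAssignment, fold: int) -> None:
    train_p = {s.patient_id for s in samples if assignment[s.patient_id] != fold}
    val_p = {s.patient_id for s in samples if assignment[s.patient_id] == fold}
    if train_p & val_p:
        raise AssertionError(f"patient leakage across fold {fold}: {train_p & val_p}")


# ------------------------------------------------------------------ training


def train_model(
    samples: list[SyntheticSample],
    cfg: TrainConfig,
    log_prefix: str = "train",
) -> tuple[DBSN, list[float]]:
    """Train a DBSN on the given samples; returns (model, per-epoch mean loss)."""
    if not samples:
        raise ValueError("empty training set")
    model = build_dbsn(cfg.network, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    shuffle_rng = np.random.default_rng([cfg.seed, 1])
    aug_rng = np.random.default_rng([cfg.seed, cfg.augmentation.seed, 2])
    epoch_losses: list[float] = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(samples))
        losses = []
        t0 = time.time()
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            opt.zero_grad()
            for idx in batch:
                s = samples[idx]
                img, mask = s.image, s.mask
                if cfg.augment:
                    img, mask, _ = augment(img, mask, None, cfg.augmentation, aug_rng)
                out = model.forward_tensors(Tensor(img[None, None]))
                loss = collaborative_loss(out, mask, cfg.network)
                loss.backward(np.float32(1.0 / len(batch)))
                losses.append(loss.item())
            opt.step()
        epoch_losses.append(float(np.mean(losses)))
        logger.info(
            "%s epoch=%d loss=%.4f time=%.1fs",
            log_prefix, epoch, epoch_losses[-1], time.time() - t0,
        )
    return model, epoch_losses


def train_fold(
    samples: list[SyntheticSample],
    assignment: FoldAssignment,
    fold: int,
    cfg: TrainConfig,
    checkpoint_path=None,
) -> tuple[DBSN, list[float]]:
    """Train on every fold except ``fold``; optionally write a checkpoint."""
    if not 0 <= fold < cfg.k_folds:
        raise ValueError(f"fold {fold} out of range for k={cfg.k_folds}")
    check_no_leakage(samples, assignment, fold)
    train_set = [s for s in samples if assignment[s.patient_id] != fold]
    if not train_set:
        raise ValueError(f"fold {fold} leaves an empty training split")
    model, losses = train_model(train_set, cfg, log_prefix=f"fold{fold}")
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, model)
    return model, losses


# ---------------------------------------------------------------- inference


def predict_and_measure(
    model: DBSN | str,
    images: list[np.ndarray],
    image_ids: list[str] | None = None,
    tangent_rule: str = "max-angle",
) -> list[tuple[np.ndarray, AoPResult]]:
    """Segment each image with the upper branch and measure the AoP.

    Per-image failures are captured in the result status; the batch never
    aborts.  ``model`` may be a DBSN instance or a checkpoint path.
    """
    if not isinstance(model, DBSN):
        model = load_checkpoint(model)
    out = []
    ids = image_ids or [f"img{i:04d}" for i in range(len(images))]
    for img, iid in zip(images, ids):
        mask = model.predict_mask(img)
        try:
            result = measure_aop_from_mask(mask, tangent_rule=tangent_rule)
        except Exception as exc:  # geometry never raises, but belt and braces
            logger.warning("measurement failed for %s: %s", iid, exc)
            result = AoPResult(status=AoPStatus.empty_class)
        out.append((mask, result))
    return out


def evaluate_predictions(
    predictions: list[tuple[np.ndarray, AoPResult]],
    references: list[SyntheticSample],
    dice_all: str = "pooled",
) -> tuple[pd.DataFrame, dict]:
    """Per-image metric rows plus the aggregate report.

    Aggregates: mean segmentation metrics over images (ASD per image, then
    averaged over images where defined) and the absolute-angle-difference
    summary over images whose measurement succeeded.
    """
    rows = []
    pred_aops, true_aops = [], []
    for (mask, result), ref in zip(predictions, references):
        rep = metrics.segmentation_report(mask, ref.mask, dice_all=dice_all)
        row = {
            "image_id": ref.image_id,
            "patient_id": ref.patient_id,
            "status": result.status.value,
            "acc": rep.acc,
            "dice_all": rep.dice_all,
            "dice_ps": rep.dice_ps,
            "dice_fh": rep.dice_fh,
            "asd": rep.asd,
            "aop_pred": result.aop_deg,
            "aop_true": ref.gt_aop_deg,
        }
        if result.status == AoPStatus.ok:
            row["delta_aop"] = abs(result.aop_deg - ref.gt_aop_deg)
            ed_u, ed_l, ax = metrics.endpoint_errors(
                result.keypoints, (ref.gt_keypoints.Up, ref.gt_keypoints.Lp)
            )
            row.update({"ed_u": ed_u, "ed_l": ed_l, "ax": ax})
            pred_aops.append(result.aop_deg)
            true_aops.append(ref.gt_aop_deg)
        rows.append(row)
    df = pd.DataFrame(rows)
    agg = {
        "n_images": len(rows),
        "ok_fraction": float((df["status"] == "ok").mean()) if len(df) else 0.0,
        "acc": float(df["acc"].mean()),
        "dice_all": float(df["dice_all"].mean()),
        "dice_ps": float(df["dice_ps"].mean()),
        "dice_fh": float(df["dice_fh"].mean()),
        "asd": float(df["asd"].dropna().mean()),
    }
    if pred_aops:
        s = metrics.aop_error_summary(pred_aops, true_aops)
        agg.update(
            aop_mean=s.mean_deg, aop_median=s.median_deg, aop_std=s.std_deg,
            n_over_20=s.n_over_20,
        )
        agg["ed_u"] = float(df["ed_u"].dropna().mean())
        agg["ed_l"] = float(df["ed_l"].dropna().mean())
        agg["ax"] = float(df["ax"].dropna().mean())
    return df, agg


def cross_validate(
    samples: list[SyntheticSample], cfg: TrainConfig
) -> tuple[pd.DataFrame, dict]:
    """Full k-fold protocol: train each fold, evaluate its holdout, average."""
    assignment = patient_grouped_kfold([s.patient_id for s in samples], cfg.k_folds, cfg.seed)
    fold_aggs = []
    all_rows = []
    for fold in range(cfg.k_folds):
        model, _losses = train_fold(samples, assignment, fold, cfg)
        val = [s for s in samples if assignment[s.patient_id] == fold]
        preds = predict_and_measure(model, [s.image for s in val])
        df, agg = evaluate_predictions(preds, val)
        df["fold"] = fold
        agg["fold"] = fold
        fold_aggs.append(agg)
        all_rows.append(df)
        logger.info("fold %d: %s", fold, json.dumps(agg))
    mean_agg = {
        k: float(np.mean([a[k] for a in fold_aggs if k in a]))
        for k in fold_aggs[0]
        if k != "fold"
    }
    return pd.concat(all_rows, ignore_index=True), mean_agg


# ----------------------------------------------------------------- harnesses

ABLATION_VARIANTS = {
    "dbsn": {},
    "dbsn-ag": {"use_attention_gates": False},
    "dbsn-lb": {"use_attention_gates": False, "use_lower_branch": False},
    "dbsn-dc": {"use_deformable": False},
}


def ablation_harness(
    samples: list[SyntheticSample],
    variants: list[str] | list[NetworkConfig],
    cfg: TrainConfig,
    holdout_fold: int = 0,
) -> pd.DataFrame:
    """Train each network variant under identical seeds/splits and compare.

    Returns one row per variant with segmentation metrics, parameter count
    and angle-error summaries on the common holdout fold.
    """
    assignment = patient_grouped_kfold([s.patient_id for s in samples], cfg.k_folds, cfg.seed)
    val = [s for s in samples if assignment[s.patient_id] == holdout_fold]
    rows = []
    for variant in variants:
        if isinstance(variant, str):
            name = variant
            net_cfg = replace(cfg.network, **ABLATION_VARIANTS[variant.lower()])
        else:
            name = "custom"
            net_cfg = variant
        vcfg = replace(cfg, network=net_cfg)
        model, _ = train_fold(samples, assignment, holdout_fold, vcfg)
        preds = predict_and_measure(model, [s.image for s in val])
        _df, agg = evaluate_predictions(preds, val)
        rows.append(
            {
                "variant": name,
                "acc": agg["acc"],
                "dice_all": agg["dice_all"],
                "dice_ps": agg["dice_ps"],
                "dice_fh": agg["dice_fh"],
                "params": model.num_parameters(),
                "aop_mean": agg.get("aop_mean", float("nan")),
                "aop_median": agg.get("aop_median", float("nan")),
                "aop_std": agg.get("aop_std", float("nan")),
                "ok_fraction": agg["ok_fraction"],
            }
        )
    return pd.DataFrame(rows)


def sweep_w_lower(
    values,
    cfg: TrainConfig,
    samples: list[SyntheticSample],
    holdout_fold: int = 0,
) -> pd.DataFrame:
    """Grid over the lower-branch loss weight w_L with identical seeds.

    One model per value, same split and initialization; reports pixel
    accuracy and pooled foreground Dice on the common holdout.
    """
    if len(values) == 0:
        raise ValueError("empty sweep grid")
    assignment = patient_grouped_kfold([s.patient_id for s in samples], cfg.k_folds, cfg.seed)
    val = [s for s in samples if assignment[s.patient_id] == holdout_fold]
    rows = []
    for w in values:
        vcfg = replace(cfg, network=replace(cfg.network, w_lower=float(w)))
        model, _ = train_fold(samples, assignment, holdout_fold, vcfg)
        preds = predict_and_measure(model, [s.image for s in val])
        _df, agg = evaluate_predictions(preds, val)
        rows.append({"w_lower": float(w), "acc": agg["acc"], "dice": agg["dice_all"]})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- reporting

MEASUREMENT_COLUMNS = [
    "image_id", "status", "aop_deg",
    "Up_x", "Up_y", "Lp_x", "Lp_y", "Tp_x", "Tp_y",
    "ps_cx", "ps_cy", "ps_semi_major", "ps_semi_minor", "ps_theta",
    "fh_cx", "fh_cy", "fh_semi_major", "fh_semi_minor", "fh_theta",
]


def measurements_to_csv(results: list[tuple[str, AoPResult]], path) -> None:
    """One record per image: status, angle, key points, ellipse parameters."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MEASUREMENT_COLUMNS)
        writer.writeheader()
        for image_id, r in results:
            row = {"image_id": image_id, "status": r.status.value, "aop_deg": r.aop_deg}
            if r.keypoints is not None:
                k = r.keypoints
                row.update(
                    Up_x=k.Up.x, Up_y=k.Up.y, Lp_x=k.Lp.x, Lp_y=k.Lp.y,
                    Tp_x=k.Tp.x, Tp_y=k.Tp.y,
                )
            for prefix, e in (("ps", r.ps_ellipse), ("fh", r.fh_ellipse)):
                if e is not None:
                    row.update({
                        f"{prefix}_cx": e.center.x, f"{prefix}_cy": e.center.y,
                        f"{prefix}_semi_major": e.semi_major,
                        f"{prefix}_semi_minor": e.semi_minor,
                        f"{prefix}_theta": e.theta,
                    })
            writer.writerow(row)


def write_report(df: pd.DataFrame, agg: dict, csv_path, json_path) -> None:
    """Per-image CSV plus JSON aggregate."""
    df.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(agg, fh, indent=2)
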