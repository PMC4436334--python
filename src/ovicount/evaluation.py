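"""Accuracy metric, leave-one-out cross-validation and batch counting.

Accuracy is reported as ``100 - mean absolute relative count error in
percent``: a predictor that is 10% off on every vial scores 90%.  The
LOOCV protocol holds out one fully annotated image at a time, trains on
the rest (whole images as training regions), fits the bias-correction
line on the training images' own (predicted, actual) count pairs, and
evaluates the held-out image; the whole sweep is repeated for several
statistical replicates with derived seeds and summarised as mean +/- SE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .annotations import DotAnnotation
from .bias import MIN_PAIRS, BiasModel, RegionPair, apply_bias, corrected_count_interval, fit_bias
from .density import DensityConfig, count_from_density
from .features import FeatureConfig, compute_feature_stack
from .regressor import TrainedModel, build_training_set, fit, predict_density


@dataclass(frozen=True)
class EvalPair:
    """Ground truth vs prediction for one evaluated image."""

    image_id: str
    gt: float
    pc_raw: float
    cc: Optional[float] = None


def accuracy_percent(pairs: Sequence[EvalPair], use_corrected: bool = False) -> float:
    """100 minus the mean absolute relative count error in percent.

    May be negative when the mean relative error exceeds 100%.  Raises on
    any non-positive ground truth (the metric divides by it).
    """
    if not pairs:
        raise ValueError("need at least one evaluated image")
    errs = []
    for p in pairs:
        if p.gt <= 0:
            raise ValueError(f"image {p.image_id!r} has non-positive ground truth "
                             f"count {p.gt}; the accuracy metric is undefined")
        pred = p.cc if use_corrected else p.pc_raw
        if pred is None or not np.isfinite(pred):
            raise ValueError(f"image {p.image_id!r} has no "
                             f"{'corrected' if use_corrected else 'raw'} prediction")
        errs.append(abs(pred - p.gt) / p.gt)
    return 100.0 - float(np.mean(errs)) * 100.0


def mean_relative_error_percent(pairs: Sequence[EvalPair],
                                use_corrected: bool = False) -> float:
    return 100.0 - accuracy_percent(pairs, use_corrected)


@dataclass(frozen=True)
class LoocvConfig:
    n_replicates: int = 5
    n_training_images: Optional[int] = None   # None: all remaining images
    master_seed: Optional[int] = None
    bias_correction: bool = True
    n_trees: int = 30
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    density_config: DensityConfig = field(default_factory=DensityConfig)
    # Whole-image ROIs at photo resolution produce millions of training
    # pixels; a seeded uniform subsample keeps tree fitting tractable
    # without biasing the density targets.  None disables subsampling.
    max_train_pixels: Optional[int] = 40_000

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class LoocvReport:
    rows: pd.DataFrame            # one row per (replicate, held-out image)
    summary: dict

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out_dir / "loocv_rows.csv", index=False)
        with open(out_dir / "loocv_summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary, fh, indent=2)


def _derive_seed(master_seed: Optional[int], *stream) -> int:
    entropy = [0 if master_seed is None else int(master_seed)] + [int(s) for s in stream]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


def run_loocv(images: Sequence[np.ndarray],
              annotations: Sequence[DotAnnotation],
              cfg: Optional[LoocvConfig] = None,
              fold_trainer: Optional[Callable] = None) -> LoocvReport:
    """Hold-one-out evaluation with statistical replicates.

    ``fold_trainer(train_idx, seed) -> (predict_idx -> pc)`` may replace
    the standard train-and-predict routine (used to validate the protocol
    itself against an idealised predictor).
    """
    cfg = cfg or LoocvConfig()
    n = len(images)
    if n < 2:
        raise ValueError("LOOCV needs at least 2 images")
    if len(annotations) != n or any(a is None for a in annotations):
        raise ValueError("every image must have a complete dot annotation")
    gts = [float(len(a)) for a in annotations]

    if fold_trainer is None:
        # feature stacks and shapes are seed-independent: compute once
        stacks = [compute_feature_stack(np.asarray(img), cfg.feature_config,
                                        dtype=np.float32) for img in images]

        def fold_trainer(train_idx: Sequence[int], seed: int):
            ts = build_training_set(
                [images[i] for i in train_idx],
                [annotations[i] for i in train_idx],
                feature_cfg=cfg.feature_config,
                density_cfg=cfg.density_config,
                stacks=[stacks[i] for i in train_idx],
                max_pixels=cfg.max_train_pixels,
                seed=seed)
            model = fit(ts, n_trees=cfg.n_trees, seed=seed,
                        feature_cfg=cfg.feature_config,
                        density_cfg=cfg.density_config)
            return lambda j: count_from_density(predict_density(model, stacks[j]))

    records = []
    for rep in range(cfg.n_replicates):
        for held_out in range(n):
            seed = _derive_seed(cfg.master_seed, rep, held_out)
            rng = np.random.default_rng(seed)
            pool = [i for i in range(n) if i != held_out]
            if cfg.n_training_images is not None:
                if not (1 <= cfg.n_training_images <= len(pool)):
                    raise ValueError(
                        f"n_training_images must be in [1, {len(pool)}]")
                pool = sorted(rng.choice(pool, size=cfg.n_training_images,
                                         replace=False).tolist())
            predict = fold_trainer(pool, seed)
            pc_raw = float(predict(held_out))
            cc = math.nan
            if cfg.bias_correction and len(pool) >= MIN_PAIRS:
                pairs = [RegionPair(pc=float(predict(j)), ac=gts[j],
                                    region_id=(annotations[j].image_id, None))
                         for j in pool]
                try:
                    cc = float(apply_bias(fit_bias(pairs), pc_raw))
                except ValueError:
                    cc = math.nan   # e.g. all training predictions identical
            records.append({
                "replicate": rep, "image": annotations[held_out].image_id,
                "gt": gts[held_out], "pc_raw": pc_raw, "cc": cc, "seed": seed,
            })
    rows = pd.DataFrame.from_records(records)

    acc_raw, acc_cc = [], []
    for rep, grp in rows.groupby("replicate"):
        pairs = [EvalPair(r.image, r.gt, r.pc_raw, r.cc)
                 for r in grp.itertuples(index=False)]
        acc_raw.append(accuracy_percent(pairs, use_corrected=False))
        if np.isfinite(grp["cc"]).all():
            acc_cc.append(accuracy_percent(pairs, use_corrected=True))

    def _mean_se(values: List[float]):
        if not values:
            return None, None
        mean = float(np.mean(values))
        se = (float(np.std(values, ddof=1) / np.sqrt(len(values)))
              if len(values) > 1 else 0.0)
        return mean, se

    mean_raw, se_raw = _mean_se(acc_raw)
    mean_cc, se_cc = _mean_se(acc_cc)
    summary = {
        "n_images": n,
        "n_replicates": cfg.n_replicates,
        "n_training_images": cfg.n_training_images or n - 1,
        "accuracy_raw_per_replicate": acc_raw,
        "accuracy_corrected_per_replicate": acc_cc,
        "accuracy_raw_mean": mean_raw,
        "accuracy_raw_se": se_raw,
        "accuracy_corrected_mean": mean_cc,
        "accuracy_corrected_se": se_cc,
    }
    return LoocvReport(rows=rows, summary=summary)


def batch_evaluate(m: TrainedModel, image_paths: Sequence,
                   bias: Optional[BiasModel] = None) -> pd.DataFrame:
    """Count a batch of images; one row per image, failures isolated.

    Columns: image, raw_count, corrected_count, ci_low, ci_high, status.
    ``bias`` defaults to the model's embedded bias parameters (if any);
    without them the corrected columns are NaN.
    """
    bias = bias if bias is not None else m.bias
    records = []
    for path in image_paths:
        name = str(path)
        try:
            if isinstance(path, np.ndarray):
                image = path
            else:
                name = Path(path).name
                image = iio.imread(path)
            stack = compute_feature_stack(np.asarray(image), m.feature_config,
                                          dtype=np.float32)
            pc = count_from_density(predict_density(m, stack))
            cc = lo = hi = math.nan
            if bias is not None:
                cc = apply_bias(bias, pc)
                lo, hi = corrected_count_interval(bias, pc)
            records.append({"image": name, "raw_count": pc, "corrected_count": cc,
                            "ci_low": lo, "ci_high": hi, "status": "ok"})
        except Exception as exc:   # noqa: BLE001 -- row-level isolation
            records.append({"image": name, "raw_count": math.nan,
                            "corrected_count": math.nan, "ci_low": math.nan,
                            "ci_high": math.nan, "status": f"error: {exc}"})
    return pd.DataFrame.from_records(
        records, columns=["image", "raw_count", "corrected_count",
                          "ci_low", "ci_high", "status"])
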