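"""Active-learning round orchestration.

One round: predict the unlabeled design space with the current ensemble,
acquire a quantile-balanced maximum-uncertainty batch, obtain labels (from an
oracle callable or a pre-computed label table), optionally harmonize the new
labels onto the training scale, merge, retrain the ensemble from scratch on
the merged dataset, and report pre/post metrics on a fixed evaluation set that
is never acquired.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .acquisition import (AcquisitionConfig, quantile_balanced_sample,
                          random_sample)
from .ensemble import Ensemble, fit_ensemble, predict_with_uncertainty
from .features import encode_sequences
from .harmonize import HarmonizationMap, apply_map
from .regressor import (MetricsReport, RegressorSpec, TrainingConfig,
                        evaluate_metrics, stratified_split)


def _frame_hash(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv(index=False).encode()).hexdigest()[:16]


@dataclass
class RoundReport:
    round_index: int
    n_acquired: int
    pre_metrics: MetricsReport
    post_metrics: MetricsReport
    pre_median_uncertainty: float
    post_median_uncertainty: float
    acquired_tile_ids: list[str]
    seeds: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=str)


@dataclass(frozen=True)
class LoopConfig:
    spec: RegressorSpec
    training: TrainingConfig
    n_members: int = 5
    base_seed: int = 0
    acquisition: AcquisitionConfig = AcquisitionConfig(batch_size=100)
    strategy: str = "uncertainty"  # or "random"


def _train(train_frame: pd.DataFrame, cfg: LoopConfig, seed: int) -> Ensemble:
    x = encode_sequences(train_frame["sequence"])
    y = train_frame["activity"].to_numpy(dtype=float)
    split = stratified_split(y, (0.8, 0.1, 0.1), seed=seed)
    train_idx = np.concatenate([split.train, split.test])  # val only held out
    return fit_ensemble(x, y, train_idx, split.val, cfg.training, cfg.spec,
                        n_members=cfg.n_members, base_seed=seed)


def run_round(train_frame: pd.DataFrame, design_frame: pd.DataFrame,
              labeler: Callable[[str], float] | Mapping[str, float],
              eval_frame: pd.DataFrame, cfg: LoopConfig,
              ensemble: Ensemble | None = None,
              harmonization: HarmonizationMap | None = None,
              round_index: int = 1, out_dir=None
              ) -> tuple[pd.DataFrame, Ensemble, RoundReport]:
    """Run one acquisition round; returns (merged training table, retrained
    ensemble, report).

    Frames carry tile_id, sequence, and (train/eval) activity. ``labeler``
    maps either a tile's sequence (callable) or tile_id (mapping) to its new
    label. The design space must be disjoint from training and evaluation
    tiles; acquired labels can optionally be pushed through a fitted
    harmonization map before merging.
    """
    overlap = set(design_frame["tile_id"]) & set(train_frame["tile_id"])
    if overlap:
        raise ValueError(
            f"design space overlaps training data: {sorted(overlap)[:5]} ...")
    overlap = set(design_frame["tile_id"]) & set(eval_frame["tile_id"])
    if overlap:
        raise ValueError(
            f"design space overlaps evaluation set: {sorted(overlap)[:5]} ...")

    if ensemble is None:
        ensemble = _train(train_frame, cfg, cfg.base_seed)

    x_eval = encode_sequences(eval_frame["sequence"])
    y_eval = eval_frame["activity"].to_numpy(dtype=float)
    pre_eval = predict_with_uncertainty(ensemble, x_eval,
                                        eval_frame["tile_id"])
    pre_metrics = evaluate_metrics(pre_eval["mean_activity"].to_numpy(),
                                   y_eval)

    x_design = encode_sequences(design_frame["sequence"])
    design_preds = predict_with_uncertainty(ensemble, x_design,
                                            design_frame["tile_id"])
    pre_median_unc = float(design_preds["uncertainty"].median())

    if cfg.strategy == "uncertainty":
        acquired_ids = quantile_balanced_sample(design_preds, cfg.acquisition)
    elif cfg.strategy == "random":
        acquired_ids = random_sample(design_preds, cfg.acquisition.batch_size,
                                     seed=cfg.base_seed + 7919 * round_index)
    else:
        raise ValueError(f"unknown acquisition strategy {cfg.strategy!r}")

    acquired = design_frame[design_frame["tile_id"].isin(acquired_ids)].copy()
    if callable(labeler):
        labels = [labeler(seq) for seq in acquired["sequence"]]
    else:
        missing = [t for t in acquired["tile_id"] if t not in labeler]
        if missing:
            raise ValueError(f"labeler missing labels for tiles: "
                             f"{missing[:10]}")
        labels = [labeler[t] for t in acquired["tile_id"]]
    acquired["activity"] = np.asarray(labels, dtype=float)

    if harmonization is not None:
        mapped, _ = apply_map(acquired["activity"].to_numpy(), harmonization)
        acquired["activity"] = mapped

    merged = pd.concat(
        [train_frame[["tile_id", "sequence", "activity"]],
         acquired[["tile_id", "sequence", "activity"]]],
        ignore_index=True)
    assert len(merged) == len(train_frame) + len(acquired_ids)
    if merged["tile_id"].duplicated().any():
        raise ValueError("a tile would be labeled twice")

    retrain_seed = cfg.base_seed + 100_003 * round_index
    new_ensemble = _train(merged, cfg, retrain_seed)

    post_eval = predict_with_uncertainty(new_ensemble, x_eval,
                                         eval_frame["tile_id"])
    post_metrics = evaluate_metrics(post_eval["mean_activity"].to_numpy(),
                                    y_eval)
    remaining = ~design_frame["tile_id"].isin(acquired_ids).to_numpy()
    if remaining.any():
        post_design = predict_with_uncertainty(
            new_ensemble, x_design[remaining],
            design_frame["tile_id"].to_numpy()[remaining])
        post_median_unc = float(post_design["uncertainty"].median())
    else:
        post_median_unc = float("nan")

    report = RoundReport(
        round_index=round_index,
        n_acquired=len(acquired_ids),
        pre_metrics=pre_metrics,
        post_metrics=post_metrics,
        pre_median_uncertainty=pre_median_unc,
        post_median_uncertainty=post_median_unc,
        acquired_tile_ids=list(acquired_ids),
        seeds={"base_seed": cfg.base_seed, "retrain_seed": retrain_seed,
               "strategy": cfg.strategy},
        input_hashes={
            "train": _frame_hash(train_frame),
            "design": _frame_hash(design_frame),
            "eval": _frame_hash(eval_frame),
            "merged": _frame_hash(merged),
        },
    )

    if out_dir is not None:
        out = Path(out_dir) / f"round_{round_index}"
        out.mkdir(parents=True, exist_ok=True)
        acquired.to_csv(out / "acquired.tsv", sep="\t", index=False)
        merged.to_csv(out / "labels.tsv", sep="\t", index=False)
        (out / "report.json").write_text(report.to_json())
    return merged, new_ensemble, report
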