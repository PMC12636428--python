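"""Deep ensembles: independently seeded regressors whose prediction mean is
the activity estimate and whose prediction spread is the epistemic
uncertainty.

Member diversity comes from seeds only (random initialization and shuffling
order); all members share the train/validation split. Uncertainty is the
population (ddof=0) standard deviation over member predictions on the
de-normalized activity scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .regressor import (RegressorSpec, TrainedRegressor, TrainingConfig,
                        fit_regressor, load_checkpoint, save_checkpoint)

DEFAULT_N_MEMBERS = 20  # the production ensemble size


@dataclass
class Ensemble:
    members: list[TrainedRegressor]
    member_seeds: list[int]

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if len(set(self.member_seeds)) != len(self.member_seeds):
            raise ValueError("member seeds must be pairwise distinct")


def member_seeds(base_seed: int, n_members: int) -> list[int]:
    """Distinct per-member seeds derived from one base seed."""
    return [(base_seed + 10_007 * i) % (2 ** 31) for i in range(n_members)]


def fit_ensemble(encodings: np.ndarray, labels: np.ndarray,
                 train_idx: np.ndarray, val_idx: np.ndarray,
                 config: TrainingConfig | None = None,
                 spec: RegressorSpec | None = None,
                 n_members: int = DEFAULT_N_MEMBERS,
                 base_seed: int = 0) -> Ensemble:
    """Train ``n_members`` regressors on one shared split, distinct seeds."""
    if n_members < 2:
        raise ValueError("n_members must be >= 2")
    if config is None:
        config = TrainingConfig()
    seeds = member_seeds(base_seed, n_members)
    members = []
    for i, seed in enumerate(seeds):
        member_config = TrainingConfig(
            learning_rate=config.learning_rate, batch_size=config.batch_size,
            max_epochs=config.max_epochs, patience=config.patience, seed=seed)
        try:
            members.append(fit_regressor(encodings, labels, train_idx,
                                         val_idx, member_config, spec))
        except Exception as exc:
            raise RuntimeError(
                f"ensemble member {i} (seed {seed}) failed to train") from exc
    return Ensemble(members, seeds)


def predict_with_uncertainty(ensemble: Ensemble, encodings: np.ndarray,
                             tile_ids=None) -> pd.DataFrame:
    """Mean activity and epistemic uncertainty per tile.

    Returns a frame with tile_id (positional if not given), mean_activity,
    and uncertainty = population standard deviation across members.
    """
    preds = np.stack([m.predict(encodings) for m in ensemble.members])
    mean = preds.mean(axis=0)
    std = preds.std(axis=0, ddof=0)
    # identical member outputs mean exactly zero spread; guard against the
    # one-ulp residue of floating-point summation
    std[(preds == preds[0]).all(axis=0)] = 0.0
    if tile_ids is None:
        tile_ids = [str(i) for i in range(preds.shape[1])]
    return pd.DataFrame({"tile_id": list(tile_ids), "mean_activity": mean,
                         "uncertainty": std})


def save_ensemble(ensemble: Ensemble, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(ensemble.members):
        save_checkpoint(member, directory / f"member_{i:03d}")
    manifest = {
        "n_members": len(ensemble.members),
        "member_seeds": ensemble.member_seeds,
        "members": [f"member_{i:03d}" for i in range(len(ensemble.members))],
    }
    (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(directory) -> Ensemble:
    directory = Path(directory)
    manifest = json.loads((directory / "ensemble.json").read_text())
    members = [load_checkpoint(directory / name)
               for name in manifest["members"]]
    return Ensemble(members, manifest["member_seeds"])
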