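"""One full active-learning round against the synthetic oracle.

The ensemble is trained on background/acidic/basic tiles; the design pool is
rich in the unseen Leu/Phe regime. The round predicts the pool, acquires the
quantile-balanced maximum-uncertainty batch, labels it with the (noisy)
oracle, retrains from scratch on the merged data, and reports error and
uncertainty before and after on a fixed Leu/Phe evaluation set.
"""

import numpy as np

from adscout import synthetic
from adscout.acquisition import AcquisitionConfig
from adscout.active_loop import LoopConfig, run_round
from adscout.regressor import RegressorSpec, TrainingConfig

seen_mix = {"background": 0.6, "acidic": 0.3, "basic": 0.1}
pool_mix = {"background": 0.3, "acidic": 0.2, "leuphe": 0.4, "basic": 0.1}

train = synthetic.make_labeled_library(500, mix=seen_mix, seed=41)[
    ["tile_id", "sequence", "activity"]]
pool = synthetic.sample_library(600, mix=pool_mix, seed=42)
pool["tile_id"] = "pool_" + pool["tile_id"]
evaluation = synthetic.make_labeled_library(150, mix={"leuphe": 1.0},
                                            seed=43)[
    ["tile_id", "sequence", "activity"]]
evaluation["tile_id"] = "eval_" + evaluation["tile_id"]

oracle = synthetic.OracleSpec()
rng = np.random.default_rng(44)

cfg = LoopConfig(
    spec=RegressorSpec.compact(),
    training=TrainingConfig(seed=41, max_epochs=25),
    n_members=3, base_seed=41,
    acquisition=AcquisitionConfig(batch_size=200, n_quantile_bins=10))

merged, ensemble, report = run_round(
    train, pool[["tile_id", "sequence"]],
    lambda s: synthetic.oracle_activity(s, oracle, noise=True, rng=rng),
    evaluation, cfg)

print(f"round {report.round_index}: acquired {report.n_acquired} tiles, "
      f"training set {len(train)} -> {len(merged)}")
print(f"OOD eval RMSE:   {report.pre_metrics.rmse:.3f} -> "
      f"{report.post_metrics.rmse:.3f}")
print(f"OOD eval Pearson: {report.pre_metrics.pearson_r:.3f} -> "
      f"{report.post_metrics.pearson_r:.3f}")
print(f"median pool uncertainty: {report.pre_median_uncertainty:.3f} -> "
      f"{report.post_median_uncertainty:.3f}")
# Evaluation error drops after one round: the batch concentrated on the
# unseen composition regime, exactly where the ensemble disagreed most.
# Note the median pool uncertainty can rise even so — the retrained
# ensemble sees a more heterogeneous dataset and disagrees more globally
# while being more accurate where it matters.
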