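"""Per-position attribution of a trained ensemble's predictions.

Trains a small ensemble on synthetic tiles, then estimates sampled-Shapley
position attributions against training-tile backgrounds. The mean per-residue
contributions should mirror the generating activity law: basic residues
(K, R) suppress predicted activity, key hydrophobics (W, F) raise it.
"""

import numpy as np

from adscout import synthetic
from adscout.attribution import attribute_positions
from adscout.ensemble import fit_ensemble
from adscout.features import encode_sequences
from adscout.regressor import (RegressorSpec, TrainingConfig,
                               stratified_split)

library = synthetic.make_labeled_library(600, seed=51)
x = encode_sequences(library["sequence"])
y = library["activity"].to_numpy()
split = stratified_split(y, seed=51)
ensemble = fit_ensemble(x, y, split.train, split.val,
                        TrainingConfig(seed=51, max_epochs=30),
                        RegressorSpec.compact(), n_members=3, base_seed=51)


def predict_mean(batch):
    return np.mean([m.predict(batch) for m in ensemble.members], axis=0)


test = synthetic.make_labeled_library(60, seed=52)
rng = np.random.default_rng(53)
background = x[rng.choice(split.train, size=80, replace=False)]
matrix, per_tile, baselines = attribute_positions(
    predict_mean, encode_sequences(test["sequence"]), test["sequence"],
    background, n_permutations=8, seed=53)

print("mean attribution by residue (positive = raises predicted activity):")
for residue in "WFDEKR":
    print(f"  {residue}: {matrix.residue_mean(residue):+.3f}")
check = per_tile[0].sum() - (predict_mean(encode_sequences(
    test['sequence'][:1])) - baselines[0])[0]
print(f"completeness residual on tile 0: {check:.2e} (exact by design)")
# W/F positive and K/R negative reproduces the acidic exposure pattern the
# oracle encodes; attributions sum exactly to prediction minus baseline.
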