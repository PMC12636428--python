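"""Shared fixtures.

The expensive session fixture trains the seeded ensemble replicates used by
the ensemble-law, out-of-distribution-uncertainty, and attribution-sign
checks, so the cost is paid once.
"""

import numpy as np
import pytest

from adscout import synthetic
from adscout.ensemble import fit_ensemble
from adscout.features import encode_sequences
from adscout.regressor import RegressorSpec, TrainingConfig, stratified_split

#: Training regimes seen by the in-distribution model; the Leu/Phe-rich
#: regime is withheld as the out-of-distribution composition regime.
IN_DIST_MIX = {"background": 0.6, "acidic": 0.3, "basic": 0.1}
OOD_MIX = {"leuphe": 1.0}

N_REPLICATES = 5


@pytest.fixture(scope="session")
def ood_study():
    """Five seeded replicates of an in-distribution training run.

    Each replicate holds a labeled library (background/acidic/basic regimes
    only), a 5-member compact ensemble trained on it, and two held-out test
    sets: one in-distribution, one from the withheld Leu/Phe-rich regime.
    """
    replicates = []
    for seed in range(N_REPLICATES):
        train_lib = synthetic.make_labeled_library(800, mix=IN_DIST_MIX,
                                                   seed=100 + seed)
        test_in = synthetic.make_labeled_library(150, mix=IN_DIST_MIX,
                                                 seed=200 + seed)
        test_ood = synthetic.make_labeled_library(150, mix=OOD_MIX,
                                                  seed=300 + seed)
        x = encode_sequences(train_lib["sequence"])
        y = train_lib["activity"].to_numpy()
        split = stratified_split(y, seed=seed)
        ens = fit_ensemble(x, y, split.train, split.val,
                           TrainingConfig(seed=seed, max_epochs=40),
                           RegressorSpec.compact(), n_members=5,
                           base_seed=seed)
        replicates.append({
            "seed": seed, "train": train_lib, "x": x, "y": y, "split": split,
            "ensemble": ens, "test_in": test_in, "test_ood": test_ood,
        })
    return replicates


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
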