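"""Quantile-balanced batch selection against exhaustive search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from adscout.acquisition import (AcquisitionConfig, assign_quantile_bins,
                                 quantile_balanced_sample, random_sample,
                                 select_control_tiles,
                                 select_harmonization_tiles)


def _candidates(rng, n=20):
    return pd.DataFrame({
        "tile_id": [f"t{i:02d}" for i in range(n)],
        "mean_activity": rng.normal(size=n),
        "uncertainty": rng.uniform(0.0, 1.0, size=n),
    })


def _bruteforce_max(df, bins, batch, objective_col, cap):
    """Best quota-respecting selection by exhaustive enumeration."""
    ids = df["tile_id"].to_list()
    obj = dict(zip(ids, df[objective_col]))
    binmap = dict(zip(ids, bins))
    best, best_total = None, -np.inf
    for combo in itertools.combinations(ids, batch):
        counts = {}
        for t in combo:
            counts[binmap[t]] = counts.get(binmap[t], 0) + 1
        if max(counts.values()) > cap:
            continue
        total = sum(obj[t] for t in combo)
        if total > best_total:
            best, best_total = combo, total
    return set(best), best_total


class TestQuantileBalancedSample:
    def test_matches_bruteforce_on_toy_instance(self, rng):
        df = _candidates(rng, 20)
        config = AcquisitionConfig(batch_size=4, n_quantile_bins=4)
        selected = quantile_balanced_sample(df, config)
        bins = assign_quantile_bins(df["mean_activity"].to_numpy(),
                                    df["tile_id"].to_list(), 4)
        expected, expected_total = _bruteforce_max(df, bins, 4, "uncertainty",
                                                   cap=1)
        assert set(selected) == expected
        # every bin contributes exactly its own maximum-uncertainty member
        obj = dict(zip(df["tile_id"], df["uncertainty"]))
        assert sum(obj[t] for t in selected) == pytest.approx(expected_total)

    def test_equal_uncertainties_resolved_by_tile_id(self, rng):
        df = _candidates(rng, 12)
        df["uncertainty"] = 0.5
        config = AcquisitionConfig(batch_size=4, n_quantile_bins=4)
        selected = quantile_balanced_sample(df, config)
        bins = assign_quantile_bins(df["mean_activity"].to_numpy(),
                                    df["tile_id"].to_list(), 4)
        # one per bin, each the lexicographically first member of its bin
        for b in range(4):
            members = sorted(df["tile_id"][bins == b])
            assert members[0] in selected

    def test_single_bin_reduces_to_global_top_k(self, rng):
        df = _candidates(rng, 15)
        config = AcquisitionConfig(batch_size=5, n_quantile_bins=1)
        selected = quantile_balanced_sample(df, config)
        top = df.nlargest(5, "uncertainty")["tile_id"]
        assert set(selected) == set(top)

    def test_exact_batch_size_and_determinism(self, rng):
        df = _candidates(rng, 50)
        config = AcquisitionConfig(batch_size=17, n_quantile_bins=10)
        a = quantile_balanced_sample(df, config)
        b = quantile_balanced_sample(df.sample(frac=1.0, random_state=4),
                                     config)
        assert len(a) == 17
        assert a == b  # row order of the input is irrelevant

    def test_local_optimality_within_bins(self, rng):
        df = _candidates(rng, 40)
        config = AcquisitionConfig(batch_size=12, n_quantile_bins=4)
        selected = set(quantile_balanced_sample(df, config))
        bins = dict(zip(df["tile_id"],
                        assign_quantile_bins(df["mean_activity"].to_numpy(),
                                             df["tile_id"].to_list(), 4)))
        unc = dict(zip(df["tile_id"], df["uncertainty"]))
        for out in set(df["tile_id"]) - selected:
            same_bin = [t for t in selected if bins[t] == bins[out]]
            # swapping any selected tile for an unselected same-bin tile
            # never increases total uncertainty
            assert all(unc[out] <= unc[t] + 1e-12 for t in same_bin)

    def test_oversized_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            quantile_balanced_sample(_candidates(rng, 5),
                                     AcquisitionConfig(batch_size=6))

    def test_negative_uncertainty_rejected(self, rng):
        df = _candidates(rng, 10)
        df.loc[0, "uncertainty"] = -0.1
        with pytest.raises(ValueError):
            quantile_balanced_sample(df, AcquisitionConfig(batch_size=2))


class TestHarmonizationSelection:
    def test_perfect_predictions_give_zero_total_error(self, rng):
        df = pd.DataFrame({
            "tile_id": [f"t{i}" for i in range(12)],
            "activity": rng.normal(size=12),
        })
        df["predicted"] = df["activity"]
        selected = select_harmonization_tiles(df, n=6, n_bins=3)
        assert len(selected) == 6

    def test_matches_bruteforce_minimal_error(self, rng):
        df = pd.DataFrame({
            "tile_id": [f"t{i:02d}" for i in range(12)],
            "activity": rng.normal(size=12),
            "predicted": rng.normal(size=12),
        })
        selected = select_harmonization_tiles(df, n=3, n_bins=3)
        bins = assign_quantile_bins(df["activity"].to_numpy(),
                                    df["tile_id"].to_list(), 3)
        df["neg_error"] = -np.abs(df["activity"] - df["predicted"])
        expected, _ = _bruteforce_max(df, bins, 3, "neg_error", cap=1)
        assert set(selected) == expected

    def test_requesting_all_returns_all(self, rng):
        df = pd.DataFrame({
            "tile_id": [f"t{i}" for i in range(8)],
            "activity": rng.normal(size=8),
            "predicted": rng.normal(size=8),
        })
        assert len(select_harmonization_tiles(df, n=8, n_bins=4)) == 8


class TestControlSelection:
    def test_matches_bruteforce_on_empirical_bins(self, rng):
        df = pd.DataFrame({
            "tile_id": [f"t{i:02d}" for i in range(12)],
            "activity": rng.normal(size=12),
            "uncertainty": rng.uniform(size=12),
        })
        selected = select_control_tiles(df, n=3, n_bins=3)
        bins = assign_quantile_bins(df["activity"].to_numpy(),
                                    df["tile_id"].to_list(), 3)
        expected, _ = _bruteforce_max(df, bins, 3, "uncertainty", cap=1)
        assert set(selected) == expected

    def test_each_bin_contributes_when_quota_permits(self, rng):
        df = pd.DataFrame({
            "tile_id": [f"t{i:02d}" for i in range(30)],
            "activity": np.linspace(0, 5, 30),
            "uncertainty": rng.uniform(size=30),
        })
        selected = select_control_tiles(df, n=10, n_bins=5)
        bins = dict(zip(df["tile_id"],
                        assign_quantile_bins(df["activity"].to_numpy(),
                                             df["tile_id"].to_list(), 5)))
        assert {bins[t] for t in selected} == set(range(5))


class TestRandomBaseline:
    def test_seeded_and_sized(self, rng):
        df = _candidates(rng, 30)
        a = random_sample(df, 10, seed=3)
        b = random_sample(df, 10, seed=3)
        assert a == b and len(a) == 10
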