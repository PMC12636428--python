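"""Sort-seq quantification: perfect-match extraction, bin-normalized scoring,
and barcode aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adscout import synthetic
from adscout.sortseq import (DOWNSTREAM_FLANK, UPSTREAM_FLANK,
                             aggregate_tile_activity, build_library_index,
                             extract_reads, extract_tile_barcode,
                             score_barcodes, score_count_table)


@pytest.fixture(scope="module")
def library():
    tiles = synthetic.sample_library(5, length=10, mix={"background": 1.0},
                                     seed=3)
    return tiles, build_library_index(tiles)


def _read(tile_nt, barcode="ACGTACGTACGTAC"):
    return UPSTREAM_FLANK + tile_nt + DOWNSTREAM_FLANK + barcode


class TestExtraction:
    def test_constructed_read_extracts_exactly(self, library):
        tiles, index = library
        nt = synthetic.reverse_translate(tiles["sequence"].iloc[0])
        tile_id, barcode, reason = extract_tile_barcode(_read(nt), index)
        assert (tile_id, reason) == (tiles["tile_id"].iloc[0], "ok")
        assert barcode == "ACGTACGTACGTAC"

    def test_single_substitution_rejected_by_perfect_match_rule(self, library):
        tiles, index = library
        nt = synthetic.reverse_translate(tiles["sequence"].iloc[0])
        mutated = ("C" if nt[4] != "C" else "G").join([nt[:4], nt[5:]])
        assert extract_tile_barcode(_read(mutated), index)[2] == "no-match"

    @pytest.mark.parametrize("read,reason", [
        ("ACGTNNN", "malformed"),
        ("ACGT" * 20, "no-flank"),
        (UPSTREAM_FLANK + "ACG" + DOWNSTREAM_FLANK + "ACGT", "bad-length"),
    ])
    def test_rejection_reasons(self, read, reason, library):
        _, index = library
        assert extract_tile_barcode(read, index)[2] == reason

    def test_known_corruption_rate_recovered_exactly(self, library):
        tiles, index = library
        reads = synthetic.simulate_reads(tiles, n_reads=1000,
                                         corrupt_fraction=0.05, seed=9)
        assignments, rejections = extract_reads(reads["read"], index)
        assert len(assignments) == 950
        assert rejections == {"no-match": 50}
        # every accepted read maps back to its true tile
        merged = assignments.merge(reads[~reads["corrupted"]],
                                   on=["tile_id", "barcode"], how="left")
        assert merged["read"].notna().all()


@pytest.fixture()
def hand_table():
    """Three barcodes with analytically known scores, medians 1..8."""
    cols = [f"bin_{b}" for b in range(1, 9)]
    counts = pd.DataFrame([
        ("t1", "A" * 14, 0, 0, 100, 0, 0, 0, 0, 0),   # delta in bin 3
        ("t2", "C" * 14, *[50] * 8),                  # uniform
        ("t3", "G" * 14, 49, 0, 0, 0, 0, 0, 0, 0),    # below read filter
    ], columns=["tile_id", "barcode", *cols])
    bin_stats = pd.DataFrame({
        "bin": range(1, 9),
        "total_reads": [1000] * 8,
        "median_fluorescence": np.arange(1.0, 9.0),
    })
    return counts, bin_stats


class TestScoring:
    def test_delta_uniform_and_filter(self, hand_table):
        counts, bin_stats = hand_table
        scores, discarded = score_barcodes(counts, bin_stats, min_reads=50)
        byid = scores.set_index("tile_id")["activity"]
        assert byid["t1"] == pytest.approx(3.0)
        assert byid["t2"] == pytest.approx(4.5)
        assert list(discarded["tile_id"]) == ["t3"]

    def test_depth_rescaling_of_one_bin_cancels(self, hand_table):
        counts, bin_stats = hand_table
        # column totals used as depth normalizer: scale one bin's counts
        stats = bin_stats.drop(columns="total_reads")
        base, _ = score_barcodes(counts, stats, min_reads=0)
        scaled = counts.copy()
        scaled["bin_3"] *= 10
        rescaled, _ = score_barcodes(scaled, stats, min_reads=0)
        assert np.allclose(base["activity"], rescaled["activity"])

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=8,
                    max_size=8).filter(lambda c: sum(c) > 0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_activity_is_convex_combination_of_medians(self, row):
        counts = pd.DataFrame([("t", "A" * 14, *row)],
                              columns=["tile_id", "barcode",
                                       *[f"bin_{b}" for b in range(1, 9)]])
        bin_stats = pd.DataFrame({
            "bin": range(1, 9),
            "median_fluorescence": np.arange(1.0, 9.0),
        })
        scores, _ = score_barcodes(counts, bin_stats, min_reads=0)
        if len(scores):
            assert 1.0 <= scores["activity"].iloc[0] <= 8.0

    def test_zero_depth_bin_with_counts_raises(self, hand_table):
        counts, bin_stats = hand_table
        bin_stats.loc[2, "total_reads"] = 0  # bin 3 carries reads
        with pytest.raises(ValueError, match="zero depth"):
            score_barcodes(counts, bin_stats)

    def test_everywhere_empty_bin_excluded_with_warning(self, hand_table):
        counts, bin_stats = hand_table
        counts["bin_8"] = 0
        stats = bin_stats.drop(columns="total_reads")
        scores, _ = score_barcodes(counts, stats, min_reads=0)
        assert len(scores) == 3  # scoring proceeds on the remaining bins

    def test_nonmonotone_medians_rejected(self, hand_table):
        counts, bin_stats = hand_table
        bin_stats.loc[4, "median_fluorescence"] = 0.5
        with pytest.raises(ValueError, match="increasing"):
            score_barcodes(counts, bin_stats)


class TestAggregation:
    def test_single_and_mean_aggregation(self):
        scores = pd.DataFrame({
            "tile_id": ["a", "b", "b"],
            "barcode": ["G" * 14, "A" * 14, "C" * 14],
            "activity": [1.5, 2.0, 4.0],
            "total_reads": [100, 100, 100],
        })
        tiles, missing = aggregate_tile_activity(scores,
                                                 expected_tiles=["a", "b",
                                                                 "c"])
        byid = tiles.set_index("tile_id")
        assert byid.loc["a", "activity"] == 1.5
        assert byid.loc["b", "activity"] == pytest.approx(3.0)
        assert byid.loc["b", "n_barcodes"] == 2
        assert missing == ["c"]

    def test_simulated_tile_scores_near_barcode_mean(self):
        lib = synthetic.make_labeled_library(30, seed=21)
        counts, bin_stats = synthetic.simulate_sortseq_counts(
            lib.set_index("tile_id")["true_activity"], seed=22)
        scores, _ = score_barcodes(counts, bin_stats)
        tiles, _ = aggregate_tile_activity(scores)
        # per-tile score within 2 standard errors of its barcode mean
        for tid, group in scores.groupby("tile_id"):
            if len(group) >= 3:
                se = group["activity"].std(ddof=1) / np.sqrt(len(group))
                agg = tiles.set_index("tile_id").loc[tid, "activity"]
                assert abs(agg - group["activity"].mean()) <= 2 * se + 1e-12


class TestEndToEnd:
    def test_recovered_activities_track_truth(self):
        lib = synthetic.make_labeled_library(120, seed=30)
        counts, bin_stats = synthetic.simulate_sortseq_counts(
            lib.set_index("tile_id")["true_activity"], seed=31)
        tiles = score_count_table(counts, bin_stats,
                                  expected_tiles=lib["tile_id"])
        merged = tiles.merge(lib, on="tile_id", suffixes=("_rec", "_lib"))
        from scipy.stats import spearmanr

        rho = spearmanr(merged["activity_rec"],
                        merged["true_activity"]).statistic
        assert rho >= 0.9
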