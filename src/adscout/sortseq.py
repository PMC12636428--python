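"""Sort-seq quantification: from merged reads or bin count tables to per-tile
activity scores.

The assay sorts a pooled cell library into 8 fluorescence bins (each 10% of
the population) and sequences the tile barcodes recovered from each bin. A
tile's activity is the read-distribution-weighted average of the bin median
fluorescences: per (tile, barcode) row, counts are first normalized by each
bin's total sequencing depth, renormalized across the 8 bins into a relative
abundance, and the activity is the inner product of that abundance with the
bin medians. Rows with fewer than 50 raw reads are discarded; a tile's score
is the unweighted mean over its surviving barcodes.

Read extraction enforces the assay's perfect-match rule: a read is kept only
when both conserved flanks match exactly and the tile region is an exact
library sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Conserved flanks of the tile cassette in the oligo design.
UPSTREAM_FLANK = "GCGGGCTCTACTTCATCGGCTAGC"
DOWNSTREAM_FLANK = "TGATAACTAGCTGAGGGCCCG"

BARCODE_LENGTH = 14
DEFAULT_MIN_READS = 50


@dataclass(frozen=True)
class ActivityScore:
    tile_id: str
    activity: float
    n_barcodes: int
    total_reads: int


# ---------------------------------------------------------------------------
# Read extraction


def build_library_index(tiles: pd.DataFrame) -> dict[str, str]:
    """Map tile nucleotide sequence -> tile_id. ``tiles`` needs tile_id and
    either a ``cds`` column (nucleotides) or a ``sequence`` column (amino
    acids, reverse-translated with the fixed codon table)."""
    from .synthetic import reverse_translate

    index: dict[str, str] = {}
    for row in tiles.itertuples(index=False):
        nt = row.cds if hasattr(row, "cds") else reverse_translate(row.sequence)
        if nt in index and index[nt] != row.tile_id:
            logger.warning("duplicate CDS for %s and %s; keeping first",
                           index[nt], row.tile_id)
            continue
        index[nt] = row.tile_id
    return index


def extract_tile_barcode(read: str, library_index: dict[str, str]
                         ) -> tuple[str | None, str | None, str]:
    """Extract (tile_id, barcode) from a merged read, or a rejection reason.

    Returns (tile_id, barcode, "ok") on success, else (None, None, reason)
    with reason in {malformed, no-flank, bad-length, no-match}.
    """
    if not read or set(read) - set("ACGT"):
        return None, None, "malformed"
    up = read.find(UPSTREAM_FLANK)
    if up < 0:
        return None, None, "no-flank"
    down = read.find(DOWNSTREAM_FLANK, up + len(UPSTREAM_FLANK))
    if down < 0:
        return None, None, "no-flank"
    tile_nt = read[up + len(UPSTREAM_FLANK):down]
    barcode = read[down + len(DOWNSTREAM_FLANK):
                   down + len(DOWNSTREAM_FLANK) + BARCODE_LENGTH]
    if len(barcode) != BARCODE_LENGTH:
        return None, None, "bad-length"
    tile_id = library_index.get(tile_nt)
    if tile_id is None:
        return None, None, "no-match"
    return tile_id, barcode, "ok"


def extract_reads(reads, library_index: dict[str, str]
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Extract all reads; returns (assignments, rejection counts by reason)."""
    rows = []
    rejections: dict[str, int] = {}
    for read in reads:
        tile_id, barcode, reason = extract_tile_barcode(read, library_index)
        if reason == "ok":
            rows.append((tile_id, barcode))
        else:
            rejections[reason] = rejections.get(reason, 0) + 1
    assignments = pd.DataFrame(rows, columns=["tile_id", "barcode"])
    return assignments, rejections


def count_assignments(assignments: pd.DataFrame, bin_labels) -> pd.DataFrame:
    """Tally per-(tile, barcode, bin) read counts into a wide count table.

    ``bin_labels`` gives the bin index (1..8) per read, aligned with
    ``assignments`` rows.
    """
    df = assignments.copy()
    df["bin"] = np.asarray(bin_labels)
    wide = (df.groupby(["tile_id", "barcode", "bin"]).size()
              .unstack("bin", fill_value=0))
    wide.columns = [f"bin_{b}" for b in wide.columns]
    return wide.reset_index()


# ---------------------------------------------------------------------------
# Scoring


def _bin_columns(counts: pd.DataFrame) -> list[str]:
    cols = [c for c in counts.columns if c.startswith("bin_")]
    if not cols:
        raise ValueError("count table has no bin_* columns")
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def score_barcodes(counts: pd.DataFrame, bin_stats: pd.DataFrame,
                   min_reads: int = DEFAULT_MIN_READS
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(tile, barcode) activity scores.

    Per row: counts are divided by each bin's total sequencing depth,
    renormalized to a relative abundance across bins, and dotted with the bin
    median fluorescences. Rows with fewer than ``min_reads`` raw reads in
    total are discarded and returned separately.

    ``bin_stats`` needs columns bin and median_fluorescence; when a
    total_reads column is present and positive it is used as the depth
    normalizer, otherwise the count-table column sums are used. Bin medians
    must be strictly increasing. A bin with zero depth raises unless it is
    empty everywhere, in which case it is excluded with a warning.

    Returns (scores, discarded): scores has tile_id, barcode, activity,
    total_reads.
    """
    cols = _bin_columns(counts)
    stats = bin_stats.sort_values("bin").reset_index(drop=True)
    if len(stats) != len(cols):
        raise ValueError(
            f"{len(cols)} count bins but {len(stats)} bin-stat rows")
    medians = stats["median_fluorescence"].to_numpy(dtype=float)
    if not (np.diff(medians) > 0).all():
        raise ValueError("bin median fluorescences must be strictly increasing")
    mat = counts[cols].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative read counts")

    if "total_reads" in stats:
        totals = stats["total_reads"].to_numpy(dtype=float)
    else:
        totals = mat.sum(axis=0)
    keep_bins = np.ones(len(cols), dtype=bool)
    for b, total in enumerate(totals):
        if total <= 0:
            if mat[:, b].sum() > 0:
                raise ValueError(
                    f"bin {b + 1} has zero depth but nonzero counts")
            logger.warning("bin %d has no reads anywhere; excluding it", b + 1)
            keep_bins[b] = False
    mat = mat[:, keep_bins]
    totals = totals[keep_bins]
    medians = medians[keep_bins]

    raw_totals = mat.sum(axis=1)
    low = raw_totals < min_reads
    discarded = counts.loc[low].copy()
    kept = counts.loc[~low, ["tile_id", "barcode"]].copy()
    mat = mat[~low]
    raw_totals = raw_totals[~low]

    norm = mat / totals                      # depth normalization per bin
    rel = norm / norm.sum(axis=1, keepdims=True)  # relative abundance
    kept["activity"] = rel @ medians
    kept["total_reads"] = raw_totals.astype(int)
    return kept.reset_index(drop=True), discarded.reset_index(drop=True)


def aggregate_tile_activity(barcode_scores: pd.DataFrame,
                            expected_tiles=None
                            ) -> tuple[pd.DataFrame, list[str]]:
    """Mean barcode activity per tile.

    Returns (scores, missing): scores has tile_id, activity, n_barcodes,
    total_reads; missing lists expected tiles with no surviving barcode
    (recovery accounting).
    """
    grouped = barcode_scores.groupby("tile_id").agg(
        activity=("activity", "mean"),
        n_barcodes=("barcode", "nunique"),
        total_reads=("total_reads", "sum"),
    ).reset_index()
    missing: list[str] = []
    if expected_tiles is not None:
        have = set(grouped["tile_id"])
        missing = sorted(t for t in expected_tiles if t not in have)
        if missing:
            logger.info("%d expected tiles recovered no barcode", len(missing))
    return grouped, missing


def score_count_table(counts: pd.DataFrame, bin_stats: pd.DataFrame,
                      min_reads: int = DEFAULT_MIN_READS,
                      expected_tiles=None) -> pd.DataFrame:
    """Convenience: barcode scoring followed by tile aggregation."""
    scores, _ = score_barcodes(counts, bin_stats, min_reads)
    tiles, _ = aggregate_tile_activity(scores, expected_tiles)
    return tiles
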