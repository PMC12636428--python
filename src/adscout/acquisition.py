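"""Batch selection for labeling.

Quantile-balanced uncertainty sampling: candidates are partitioned into
equal-frequency bins of predicted activity; within each bin the most uncertain
candidates are taken, so the acquired batch has maximum uncertainty while
spanning the full range of predicted activity rather than piling onto one
extreme. The same mechanics select harmonization tiles (smallest
|empirical - predicted| per bin of empirical activity) and control tiles
(highest uncertainty per bin of empirical activity).

Selection semantics, fixed so exhaustive-search tests are well defined: with
quota = ceil(batch / bins) as a per-bin cap, first every non-empty bin
contributes its best candidate (when the batch is large enough to allow it),
then remaining slots are filled greedily by global rank subject to the caps.
Under these partition constraints the greedy fill maximizes the total
objective. Ties always break lexicographically by tile id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AcquisitionConfig:
    batch_size: int
    n_quantile_bins: int = 10

    def __post_init__(self):
        if self.n_quantile_bins < 1:
            raise ValueError("n_quantile_bins must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def assign_quantile_bins(values: np.ndarray, tile_ids, n_bins: int
                         ) -> np.ndarray:
    """Equal-frequency bin index per candidate (0..n_bins-1).

    Candidates are ordered by (value, tile_id) and cut into n_bins contiguous,
    as-equal-as-possible groups; the id tie-break makes binning deterministic
    under duplicated values.
    """
    values = np.asarray(values, dtype=float)
    order = sorted(range(len(values)), key=lambda i: (values[i], tile_ids[i]))
    bins = np.empty(len(values), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def _balanced_select(tile_ids: list[str], bin_index: np.ndarray,
                     objective: np.ndarray, batch_size: int) -> list[str]:
    """Max-objective selection with per-bin cap ceil(batch/bins) and, when the
    batch allows, at least one pick per non-empty bin."""
    n = len(tile_ids)
    if batch_size > n:
        raise ValueError(f"batch_size {batch_size} exceeds {n} candidates")
    n_bins = int(bin_index.max()) + 1 if n else 0
    cap = math.ceil(batch_size / n_bins)
    order = sorted(range(n), key=lambda i: (-objective[i], tile_ids[i]))
    taken: list[int] = []
    counts = np.zeros(n_bins, dtype=int)
    selected = np.zeros(n, dtype=bool)
    # floor pass: each non-empty bin contributes its best candidate
    nonempty = [b for b in range(n_bins) if (bin_index == b).any()]
    if len(nonempty) <= batch_size:
        for b in nonempty:
            best = min((i for i in range(n) if bin_index[i] == b),
                       key=lambda i: (-objective[i], tile_ids[i]))
            taken.append(best)
            selected[best] = True
            counts[b] += 1
    # greedy fill under caps
    for i in order:
        if len(taken) == batch_size:
            break
        if selected[i] or counts[bin_index[i]] >= cap:
            continue
        taken.append(i)
        selected[i] = True
        counts[bin_index[i]] += 1
    # caps can leave a shortfall when bins are sparse; relax them by rank
    for i in order:
        if len(taken) == batch_size:
            break
        if not selected[i]:
            taken.append(i)
            selected[i] = True
    return sorted(tile_ids[i] for i in taken)


def quantile_balanced_sample(candidates: pd.DataFrame,
                             config: AcquisitionConfig,
                             activity_col: str = "mean_activity",
                             uncertainty_col: str = "uncertainty"
                             ) -> list[str]:
    """Select ``batch_size`` tile ids with maximum uncertainty balanced across
    equal-frequency bins of predicted activity."""
    if (candidates[uncertainty_col] < 0).any():
        raise ValueError("uncertainties must be non-negative")
    ids = candidates["tile_id"].to_list()
    bins = assign_quantile_bins(candidates[activity_col].to_numpy(), ids,
                                config.n_quantile_bins)
    return _balanced_select(ids, bins,
                            candidates[uncertainty_col].to_numpy(dtype=float),
                            config.batch_size)


def select_harmonization_tiles(tiles: pd.DataFrame, n: int, n_bins: int = 10,
                               empirical_col: str = "activity",
                               predicted_col: str = "predicted"
                               ) -> list[str]:
    """Tiles with the smallest |empirical - predicted| across equal-frequency
    bins of empirical activity — the anchors used to map a new dataset onto
    the reference activity scale."""
    ids = tiles["tile_id"].to_list()
    bins = assign_quantile_bins(tiles[empirical_col].to_numpy(), ids, n_bins)
    error = np.abs(tiles[empirical_col].to_numpy(dtype=float)
                   - tiles[predicted_col].to_numpy(dtype=float))
    return _balanced_select(ids, bins, -error, n)


def select_control_tiles(tiles: pd.DataFrame, n: int, n_bins: int = 10,
                         empirical_col: str = "activity",
                         uncertainty_col: str = "uncertainty") -> list[str]:
    """Highest-uncertainty tiles spanning the range of empirical activity —
    external controls carried along with an acquisition batch."""
    if (tiles[uncertainty_col] < 0).any():
        raise ValueError("uncertainties must be non-negative")
    ids = tiles["tile_id"].to_list()
    bins = assign_quantile_bins(tiles[empirical_col].to_numpy(), ids, n_bins)
    return _balanced_select(ids, bins,
                            tiles[uncertainty_col].to_numpy(dtype=float), n)


def random_sample(candidates: pd.DataFrame, batch_size: int, seed: int
                  ) -> list[str]:
    """Uniform random batch — the baseline acquisition strategy."""
    ids = candidates["tile_id"].to_list()
    if batch_size > len(ids):
        raise ValueError("batch_size exceeds candidate count")
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(ids, size=batch_size, replace=False))
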