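"""Synthetic activation-domain libraries with a known activity law, plus a
sorted-bin sequencing simulator, so every pipeline stage is testable end to
end without any experimental data.

The activity oracle is a deliberately simple stand-in inspired by the acidic
exposure model of activation domains: hydrophobic/aromatic residues (W, F, L,
M, Y) contribute activity only when an acidic residue (D or E) lies within a
small sequence neighborhood that keeps them solvent-exposed; basic residues
(K, R) suppress activity; the summed raw score saturates through a
Michaelis-Menten-style curve, mimicking reporter saturation. Every constant in
``OracleSpec`` is a simulator invention chosen for a plausible dynamic range —
none is an experimental measurement.

The sort-seq simulator mirrors the assay design: cells carrying a tile
fluoresce around the tile's activity, 8 sorting gates each capture 10% of the
pooled population (the central 80%; the tails go unsampled), each tile carries
a handful of random 14-nt DNA barcodes (median 12), and each barcode yields a
fixed sequencing depth multinomially distributed over the bins the tile's
cells occupy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import CANONICAL_ALPHABET

# ---------------------------------------------------------------------------
# Activity oracle

DEFAULT_HYDROPHOBIC_WEIGHTS = {"W": 2.0, "F": 1.8, "L": 1.2, "M": 1.2, "Y": 1.0}


@dataclass(frozen=True)
class OracleSpec:
    """Parameters of the synthetic activity law (all simulator inventions)."""

    hydrophobic_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_HYDROPHOBIC_WEIGHTS))
    acidic_radius: int = 3       # D/E within +-radius licenses a hydrophobic
    basic_penalty: float = 0.5   # per K or R
    l_max: float = 10.0          # saturation ceiling of the activity scale
    k_half: float = 8.0          # raw score at half-saturation
    noise_sigma: float = 0.2     # sd of additive label noise, activity units

    def __post_init__(self):
        if self.l_max <= 0 or self.k_half <= 0:
            raise ValueError("l_max and k_half must be positive")


def oracle_activity(sequence: str, spec: OracleSpec | None = None,
                    noise: bool = False,
                    rng: np.random.Generator | None = None) -> float:
    """Ground-truth activity of a sequence under the synthetic law.

    raw = sum_i h(s_i) * [exists D/E within +-r of i] - p * count(K, R);
    activity = L_max * max(raw, 0) / (k_half + max(raw, 0)), optionally plus
    Gaussian label noise.
    """
    if spec is None:
        spec = OracleSpec()
    acidic = np.array([c in "DE" for c in sequence])
    raw = 0.0
    r = spec.acidic_radius
    for i, aa in enumerate(sequence):
        w = spec.hydrophobic_weights.get(aa, 0.0)
        if w and acidic[max(0, i - r):i + r + 1].any():
            raw += w
    raw -= spec.basic_penalty * sum(sequence.count(c) for c in "KR")
    raw = max(raw, 0.0)
    activity = spec.l_max * raw / (spec.k_half + raw)
    if noise:
        if rng is None:
            raise ValueError("noise=True requires an rng")
        activity += rng.normal(0.0, spec.noise_sigma)
    return activity


# ---------------------------------------------------------------------------
# Library generator

#: Residue-frequency multipliers per regime, applied to a uniform base and
#: renormalized. The acidic regime has the classic D/E-rich, hydrophobic-
#: bearing AD composition; the Leu/Phe-rich regime is depleted in D/E
#: (non-acidic in composition) yet Leu/Phe-loaded, so a subset reaches
#: activity through residual acidic context; the basic regime is inactive.
REGIME_WEIGHTS: dict[str, dict[str, float]] = {
    "background": {},
    "acidic": {"D": 5.0, "E": 5.0, "W": 2.0, "F": 2.0, "L": 2.0, "M": 2.0,
               "Y": 2.0, "K": 0.3, "R": 0.3},
    "leuphe": {"L": 5.0, "F": 5.0, "D": 0.6, "E": 0.6, "K": 0.5, "R": 0.5},
    "basic": {"K": 5.0, "R": 5.0, "D": 0.3, "E": 0.3},
}

#: Default regime mix: most tiles are inactive background, reflecting that
#: activation domains are rare in protein space.
DEFAULT_MIX = {"background": 0.55, "acidic": 0.25, "leuphe": 0.10,
               "basic": 0.10}


def _regime_probabilities(regime: str) -> np.ndarray:
    weights = REGIME_WEIGHTS[regime]
    p = np.array([weights.get(aa, 1.0) for aa in CANONICAL_ALPHABET])
    return p / p.sum()


def sample_library(n: int, length: int = 53,
                   mix: dict[str, float] | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Sample ``n`` tiles of ``length`` residues from a mixture of composition
    regimes. Returns a frame with tile_id, sequence, regime; deterministic
    given ``seed``.
    """
    if mix is None:
        mix = dict(DEFAULT_MIX)
    unknown = set(mix) - set(REGIME_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown regimes: {sorted(unknown)}")
    fractions = np.array(list(mix.values()), dtype=float)
    if (fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("mix fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    regimes = list(mix)
    assignment = rng.choice(len(regimes), size=n, p=fractions)
    alphabet = np.array(list(CANONICAL_ALPHABET))
    rows = []
    for i in range(n):
        regime = regimes[assignment[i]]
        seq = "".join(rng.choice(alphabet, size=length,
                                 p=_regime_probabilities(regime)))
        rows.append((f"syn{i:06d}", seq, regime))
    return pd.DataFrame(rows, columns=["tile_id", "sequence", "regime"])


def make_labeled_library(n: int, length: int = 53,
                         mix: dict[str, float] | None = None,
                         oracle: OracleSpec | None = None,
                         noise: bool = True, seed: int = 0) -> pd.DataFrame:
    """Library plus oracle labels: columns tile_id, sequence, regime,
    true_activity (noise-free), activity (observed, with label noise unless
    ``noise=False``), source.
    """
    if oracle is None:
        oracle = OracleSpec()
    frame = sample_library(n, length, mix, seed)
    rng = np.random.default_rng(seed + 1)
    truth = np.array([oracle_activity(s, oracle) for s in frame["sequence"]])
    frame["true_activity"] = truth
    if noise:
        frame["activity"] = truth + rng.normal(0.0, oracle.noise_sigma, size=n)
    else:
        frame["activity"] = truth
    frame["source"] = "synthetic"
    return frame


# ---------------------------------------------------------------------------
# Sort-seq simulator


@dataclass(frozen=True)
class SortSeqSimSpec:
    """Simulation settings for the sorted-bin sequencing readout."""

    n_bins: int = 8
    cell_sd: float = 0.75          # cell-to-cell fluorescence sd, activity units
    cells_per_tile: int = 500
    reads_per_barcode: int = 200
    median_barcodes: int = 12      # per-tile barcode count ~ max(Poisson, 1)
    lower_decile: float = 0.10     # sorted gates span the central 80%
    upper_decile: float = 0.90

    def __post_init__(self):
        if self.reads_per_barcode <= 0:
            raise ValueError("reads_per_barcode must be positive")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")


def _random_barcodes(n: int, rng: np.random.Generator,
                     length: int = 14) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(bases, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_sortseq_counts(activities: pd.Series | dict,
                            sim: SortSeqSimSpec | None = None,
                            seed: int = 0
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate barcode read counts across sorted fluorescence bins.

    ``activities`` maps tile_id -> true activity. Per tile, cell fluorescence
    is Normal(activity, cell_sd); gates are placed at the pooled population's
    deciles between ``lower_decile`` and ``upper_decile`` so each of the
    ``n_bins`` bins holds an equal share of cells; bin medians are the pooled
    within-bin medians. Each barcode receives exactly ``reads_per_barcode``
    reads, multinomially distributed over that tile's bin occupancy.

    Returns (counts, bin_stats): counts has tile_id, barcode, bin_1..bin_8;
    bin_stats has bin, total_reads, median_fluorescence.
    """
    if sim is None:
        sim = SortSeqSimSpec()
    series = pd.Series(activities, dtype=float)
    if not np.isfinite(series.to_numpy()).all():
        raise ValueError("activities must be finite")
    rng = np.random.default_rng(seed)
    tile_ids = series.index.to_list()
    cells = {tid: rng.normal(series[tid], sim.cell_sd, size=sim.cells_per_tile)
             for tid in tile_ids}
    pooled = np.concatenate(list(cells.values()))
    edges = np.quantile(pooled, np.linspace(sim.lower_decile, sim.upper_decile,
                                            sim.n_bins + 1))
    medians = np.array([
        np.median(pooled[(pooled >= lo) & (pooled <= hi)])
        for lo, hi in zip(edges[:-1], edges[1:])])

    bin_cols = [f"bin_{b}" for b in range(1, sim.n_bins + 1)]
    rows = []
    for tid in tile_ids:
        occupancy, _ = np.histogram(cells[tid], bins=edges)
        if occupancy.sum() == 0:
            # all cells fell outside the sorted gates; assign to nearest bin
            nearest = int(np.argmin(np.abs(medians - series[tid])))
            occupancy = np.zeros(sim.n_bins, dtype=int)
            occupancy[nearest] = 1
        probs = occupancy / occupancy.sum()
        n_bc = max(1, int(rng.poisson(sim.median_barcodes)))
        for bc in _random_barcodes(n_bc, rng):
            counts = rng.multinomial(sim.reads_per_barcode, probs)
            rows.append((tid, bc, *counts))
    counts = pd.DataFrame(rows, columns=["tile_id", "barcode", *bin_cols])
    bin_stats = pd.DataFrame({
        "bin": np.arange(1, sim.n_bins + 1),
        "total_reads": counts[bin_cols].sum(axis=0).to_numpy(),
        "median_fluorescence": medians,
    })
    return counts, bin_stats


# ---------------------------------------------------------------------------
# Nucleotide-level read simulation

#: One fixed codon per residue (common S. cerevisiae choices) for reverse
#: translation of tile sequences into the oligo design.
CODON_TABLE = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTG", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}


def reverse_translate(sequence: str) -> str:
    return "".join(CODON_TABLE[aa] for aa in sequence)


def simulate_reads(tiles: pd.DataFrame, n_reads: int,
                   corrupt_fraction: float = 0.0, seed: int = 0,
                   barcodes_per_tile: int = 3) -> pd.DataFrame:
    """Simulate merged amplicon reads: upstream flank + tile CDS + downstream
    flank + 14-nt barcode. A ``corrupt_fraction`` of reads receives one
    substitution inside the tile CDS (so perfect-match filtering rejects it).

    ``tiles`` needs tile_id and sequence (amino acids). Returns a frame with
    read, tile_id, barcode, corrupted.
    """
    from .sortseq import DOWNSTREAM_FLANK, UPSTREAM_FLANK

    rng = np.random.default_rng(seed)
    tile_ids = tiles["tile_id"].to_list()
    cds = {t.tile_id: reverse_translate(t.sequence)
           for t in tiles.itertuples(index=False)}
    barcode_sets = {tid: _random_barcodes(barcodes_per_tile, rng)
                    for tid in tile_ids}
    n_corrupt = int(round(corrupt_fraction * n_reads))
    corrupt_flags = np.zeros(n_reads, dtype=bool)
    corrupt_flags[:n_corrupt] = True
    rng.shuffle(corrupt_flags)
    bases = "ACGT"
    rows = []
    for i in range(n_reads):
        tid = tile_ids[rng.integers(len(tile_ids))]
        barcode = barcode_sets[tid][rng.integers(barcodes_per_tile)]
        tile_nt = cds[tid]
        if corrupt_flags[i]:
            pos = int(rng.integers(len(tile_nt)))
            alt = bases[(bases.index(tile_nt[pos]) + 1 + int(rng.integers(3))) % 4]
            tile_nt = tile_nt[:pos] + alt + tile_nt[pos + 1:]
        read = UPSTREAM_FLANK + tile_nt + DOWNSTREAM_FLANK + barcode
        rows.append((read, tid, barcode, bool(corrupt_flags[i])))
    return pd.DataFrame(rows, columns=["read", "tile_id", "barcode",
                                       "corrupted"])


# ---------------------------------------------------------------------------
# Paired-activity generator for harmonization


def make_harmonization_pairs(n: int, slope: float = 0.8,
                             intercept: float = 0.3, noise_sd: float = 0.1,
                             clip_quantiles: tuple[float, float] = (0.1, 0.9),
                             new_loc: float = 1.5, new_scale: float = 1.25,
                             seed: int = 0) -> pd.DataFrame:
    """Paired activities on two scales with saturation at the reference-scale
    tails: ref = slope * new + intercept + Gaussian noise, then hard-clipped
    outside the central quantile band (mimicking FACS saturation). New-scale
    activities are Gaussian: a bell-shaped score distribution concentrates
    mass mid-scale and puts the statistical leverage in the tails, which is
    exactly where saturation destroys it — the regime the linear-range search
    exists for. Columns: tile_id, new_activity, ref_activity, clipped.
    """
    rng = np.random.default_rng(seed)
    new = rng.normal(new_loc, new_scale, size=n)
    ref = slope * new + intercept + rng.normal(0.0, noise_sd, size=n)
    lo, hi = np.quantile(ref, clip_quantiles)
    clipped = (ref < lo) | (ref > hi)
    ref = np.clip(ref, lo, hi)
    return pd.DataFrame({
        "tile_id": [f"pair{i:05d}" for i in range(n)],
        "new_activity": new,
        "ref_activity": ref,
        "clipped": clipped,
    })
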