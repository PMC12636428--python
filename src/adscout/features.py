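"""Tile encodings and composition descriptors.

One-hot encoding over the fixed canonical alphabet is the default input
representation for the regressor. Richer per-residue embeddings (e.g. from a
pretrained protein language model) enter through the ``EmbeddingProvider``
contract — an injection point, deliberately not a bundled model — with results
cached by content hash so a provider upgrade can never silently mix
representations.

Composition descriptors (net charge, non-polar fraction, per-residue
fractions) characterize libraries and acquired batches. Net charge counts
K and R as +1 and D and E as -1; histidine is excluded. The non-polar set is
{A, V, L, I, M, F, W, P, G}. Both sets are conventions, overridable per call.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .corpus import CANONICAL_ALPHABET, Tile

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}

NONPOLAR_RESIDUES = frozenset("AVLIMFWPG")
POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


@dataclass(frozen=True)
class EncodedTile:
    tile_id: str
    matrix: np.ndarray  # positions x channels
    encoding_name: str


def one_hot_matrix(sequence: str, allow_mask: bool = False) -> np.ndarray:
    """(len, 20) binary matrix; channel order is the canonical alphabet.

    With ``allow_mask`` a masked residue ``X`` becomes an all-zero row;
    otherwise non-canonical residues raise.
    """
    mat = np.zeros((len(sequence), len(CANONICAL_ALPHABET)))
    for i, aa in enumerate(sequence):
        if aa in AA_INDEX:
            mat[i, AA_INDEX[aa]] = 1.0
        elif not (allow_mask and aa == "X"):
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")
    return mat


def one_hot_encode(tile: Tile, allow_mask: bool = False) -> EncodedTile:
    return EncodedTile(tile.tile_id, one_hot_matrix(tile.sequence, allow_mask),
                       "onehot")


def decode_one_hot(matrix: np.ndarray) -> str:
    out = []
    for row in matrix:
        if row.sum() == 0:
            out.append("X")
        else:
            out.append(CANONICAL_ALPHABET[int(np.argmax(row))])
    return "".join(out)


def encode_sequences(sequences, allow_mask: bool = False) -> np.ndarray:
    """Stack one-hot matrices for equal-length sequences: (n, len, 20)."""
    return np.stack([one_hot_matrix(s, allow_mask) for s in sequences])


# ---------------------------------------------------------------------------
# Embedding provider contract


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for pluggable per-residue embedding backends."""

    name: str

    def embed(self, sequence: str, layer: str) -> np.ndarray:
        """Return a (len(sequence), D) array for ``layer`` in {first, last}."""
        ...


class OneHotProvider:
    """Identity provider: embeddings are the one-hot matrix (any layer)."""

    name = "onehot"

    def embed(self, sequence: str, layer: str) -> np.ndarray:
        return one_hot_matrix(sequence)


@dataclass
class EmbeddingCache:
    """In-memory cache keyed by (sequence sha256, provider name, layer)."""

    _store: dict = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    @staticmethod
    def key(sequence: str, provider_name: str, layer: str) -> tuple:
        digest = hashlib.sha256(sequence.encode()).hexdigest()
        return (digest, provider_name, layer)

    def get_or_compute(self, sequence: str, provider: EmbeddingProvider,
                       layer: str) -> np.ndarray:
        k = self.key(sequence, provider.name, layer)
        if k in self._store:
            self.hits += 1
        else:
            self.misses += 1
            self._store[k] = np.asarray(provider.embed(sequence, layer))
        return self._store[k]


def embed_with_provider(tiles: list[Tile], provider: EmbeddingProvider,
                        layer: str = "last",
                        cache: EmbeddingCache | None = None
                        ) -> list[EncodedTile]:
    """Encode tiles through a provider, enforcing a uniform embedding width."""
    if layer not in ("first", "last"):
        raise ValueError(f"layer must be 'first' or 'last', got {layer!r}")
    if cache is None:
        cache = EmbeddingCache()
    encoded: list[EncodedTile] = []
    width: int | None = None
    for tile in tiles:
        try:
            mat = cache.get_or_compute(tile.sequence, provider, layer)
        except Exception as exc:
            raise RuntimeError(
                f"embedding provider {provider.name!r} failed on tile "
                f"{tile.tile_id!r}") from exc
        if mat.shape[0] != len(tile.sequence):
            raise ValueError(
                f"provider returned {mat.shape[0]} rows for a "
                f"{len(tile.sequence)}-residue tile {tile.tile_id!r}")
        if width is None:
            width = mat.shape[1]
        elif mat.shape[1] != width:
            raise ValueError(
                f"embedding width mismatch on {tile.tile_id!r}: "
                f"{mat.shape[1]} != {width}")
        encoded.append(EncodedTile(tile.tile_id, mat,
                                   f"{provider.name}:{layer}"))
    return encoded


# ---------------------------------------------------------------------------
# Encoding persistence


def save_encodings(encoded: list[EncodedTile], directory,
                   provider: str = "", layer: str = "") -> None:
    """Persist encoded tiles as an array container with a JSON sidecar
    naming the encoding, provider, layer, and channel alphabet."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = [e.encoding_name for e in encoded]
    if len(set(names)) > 1:
        raise ValueError(f"mixed encodings: {sorted(set(names))}")
    np.savez(directory / "encodings.npz",
             **{e.tile_id: e.matrix for e in encoded})
    sidecar = {
        "encoding": names[0] if names else "",
        "provider": provider,
        "layer": layer,
        "alphabet": CANONICAL_ALPHABET,
        "n_tiles": len(encoded),
    }
    (directory / "encodings.json").write_text(json.dumps(sidecar, indent=2))


def load_encodings(directory) -> tuple[list[EncodedTile], dict]:
    import json
    from pathlib import Path

    directory = Path(directory)
    sidecar = json.loads((directory / "encodings.json").read_text())
    with np.load(directory / "encodings.npz") as data:
        encoded = [EncodedTile(tile_id, data[tile_id], sidecar["encoding"])
                   for tile_id in data.files]
    return encoded, sidecar


# ---------------------------------------------------------------------------
# Composition descriptors


@dataclass(frozen=True)
class CompositionProfile:
    net_charge: int
    nonpolar_fraction: float
    residue_fractions: np.ndarray  # 20-vector in canonical alphabet order


def composition_profile(sequence: str,
                        nonpolar: frozenset = NONPOLAR_RESIDUES,
                        positive: frozenset = POSITIVE_RESIDUES,
                        negative: frozenset = NEGATIVE_RESIDUES
                        ) -> CompositionProfile:
    """Net charge, non-polar fraction, and residue fractions of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.zeros(len(CANONICAL_ALPHABET))
    net = 0
    npol = 0
    for aa in sequence:
        if aa not in AA_INDEX:
            raise ValueError(f"non-canonical residue {aa!r}")
        counts[AA_INDEX[aa]] += 1
        if aa in positive:
            net += 1
        elif aa in negative:
            net -= 1
        if aa in nonpolar:
            npol += 1
    return CompositionProfile(
        net_charge=net,
        nonpolar_fraction=npol / len(sequence),
        residue_fractions=counts / len(sequence),
    )
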