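"""Deduplicate and cluster a small protein set, then slice it into tiles.

Builds six proteins (two near-identical, one exact duplicate), clusters them
at 90% identity, and tiles the representatives into 53-residue windows at a
10-residue stride — the design space every downstream stage operates on.
"""

import numpy as np

from adscout.corpus import (ProteinRecord, deduplicate_and_represent,
                            tile_proteins)

rng = np.random.default_rng(0)
alphabet = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(pid, length):
    return ProteinRecord(pid, "".join(rng.choice(alphabet, size=length)))


base = random_protein("tfA", 120)
variant = list(base.sequence)
for pos in rng.choice(120, size=6, replace=False):  # 95% identity
    variant[pos] = alphabet[(alphabet.index(variant[pos]) + 1) % 20]
proteins = [
    base,
    ProteinRecord("tfA_paralog", "".join(variant)),
    ProteinRecord("tfA_copy", base.sequence),  # exact duplicate
    random_protein("tfB", 140),
    random_protein("tfC", 90),
    random_protein("tfD", 40),  # shorter than one window
]

reps, assignment, multiplicity = deduplicate_and_represent(proteins, 0.90)
tiles = tile_proteins(reps, window=53, stride=10)

print(f"{len(proteins)} proteins -> {len(reps)} cluster representatives")
for rep in reps:
    members = [p for p, r in assignment.items() if r == rep.protein_id]
    print(f"  {rep.protein_id} (len {len(rep.sequence)}): "
          f"members {sorted(members)}")
print(f"{len(tiles)} tiles of 53 AA at stride 10 "
      f"(tfD is shorter than one window and yields none)")
print("first tiles:", [t.tile_id for t in tiles[:4]])
# Each representative of length L yields floor((L-53)/10)+1 tiles; every
# tile records its parent and 0-based start offset for provenance.
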