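"""Encode one compound--miRNA pair into its fixed-length feature vector.

The miRNA contributes 360 features (k-mer compositions for k=1..4, the
t-spaced pair composition, and the average accumulated nucleotide
frequency); the compound contributes 1036 (a 1024-bit Morgan fingerprint,
its density, structural counts, EState extremes, an EState-weighted
surface-area term, LogP and molar refractivity).
"""

from smireg.features import (
    MIRNA_BLOCKS,
    SM_BLOCKS,
    as_matrix,
    as_sequence,
    encode_mirna,
    encode_pair,
    encode_sm,
)
from smireg.types import MirnaRecord, SmRecord

mirna = MirnaRecord(id="mir-21-like", sequence="UAGCUUAUCAGACUGAUGUUGA")
ibuprofen = SmRecord(id="CID3672", smiles="CC(C)Cc1ccc(cc1)C(C)C(=O)O")

v_mirna = encode_mirna(mirna)
v_sm = encode_sm(ibuprofen)
pair = encode_pair(mirna, ibuprofen)

print(f"miRNA vector: {v_mirna.shape[0]} features")
for name, (lo, hi) in MIRNA_BLOCKS.items():
    print(f"  {name:8s} [{lo:3d}:{hi:3d}]  sum={v_mirna[lo:hi].sum():.3f}")
print(f"compound vector: {v_sm.shape[0]} features")
lo, hi = SM_BLOCKS["counts"]
rings, heavy, no, nhoh, carbo, hetero = v_sm[lo:hi]
print(f"  rings={rings:.0f} heavy_atoms={heavy:.0f} N+O={no:.0f} "
      f"NH+OH={nhoh:.0f} aliphatic_carbocycles={carbo:.0f} heteroatoms={hetero:.0f}")
print(f"  fingerprint density={v_sm[1024]:.4f}")
print(f"pair vector: {pair.shape[0]} features "
      f"(= {v_mirna.shape[0]} miRNA + {v_sm.shape[0]} compound)")
print(f"as 37x37 matrix: {as_matrix(pair).shape}; "
      f"as sequence: {as_sequence(pair).shape} (37 steps of 37 features)")
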