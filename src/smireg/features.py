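"""Fixed-length biophysical encodings of miRNAs, compounds, and pairs.

A miRNA sequence is encoded as a 360-vector of k-mer compositions
(k = 1..4: NAC, DNC, TNC, QNC), t-spaced nucleotide-pair composition
(CTSNAP), and the average accumulated nucleotide frequency (aveANF), which
mixes positional with compositional information.  A compound is encoded as
a 1036-vector: 1024-bit Morgan fingerprint, its on-bit density, six
structural counts, extreme atomic electrotopological-state (EState)
indices, an EState-weighted van-der-Waals surface-area aggregate, LogP and
molar refractivity.  The concatenated pair vector (miRNA block first) has
length 1396 and is reshaped to a 37x37 single-channel matrix for
image-style models or to 37 timesteps of 37 features for sequence models;
both reshapes consume the first 1369 entries.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.EState.EState import EStateIndices
from rdkit.DataStructs import ExplicitBitVect

from .types import MirnaRecord, SmRecord

MIRNA_VECTOR_LENGTH = 360
SM_VECTOR_LENGTH = 1036
PAIR_VECTOR_LENGTH = MIRNA_VECTOR_LENGTH + SM_VECTOR_LENGTH  # 1396
MATRIX_SIDE = 37
MATRIX_CELLS = MATRIX_SIDE * MATRIX_SIDE  # 1369
FP_BITS = 1024
FP_RADIUS = 2

# Canonical nucleotide order; T on input is read as U.
NUCLEOTIDES = "ACGU"

#: Offsets of the blocks inside the miRNA vector, for sidecar metadata.
MIRNA_BLOCKS = {
    "NAC": (0, 4),
    "DNC": (4, 20),
    "TNC": (20, 84),
    "QNC": (84, 340),
    "CTSNAP": (340, 356),
    "aveANF": (356, 360),
}
SM_BLOCKS = {
    "morgan": (0, 1024),
    "density": (1024, 1025),
    "counts": (1025, 1031),
    "estate_max": (1031, 1032),
    "estate_min": (1032, 1033),
    "vsa_estate": (1033, 1034),
    "logp": (1034, 1035),
    "molar_refractivity": (1035, 1036),
}


def _canonical(sequence: str) -> str:
    return sequence.upper().replace("T", "U")


def _kmer_index(k: int) -> dict[str, int]:
    return {"".join(p): i for i, p in enumerate(product(NUCLEOTIDES, repeat=k))}


_KMER_INDEX = {k: _kmer_index(k) for k in (1, 2, 3, 4)}


def kmer_composition(mirna: MirnaRecord, k: int) -> np.ndarray:
    """Frequencies of all 4^k k-mers, lexicographic over A<C<G<U.

    Entry for k-mer w is count(w) / (L - k + 1); the vector sums to 1.
    """
    if k not in (1, 2, 3, 4):
        raise ValueError(f"k must be in 1..4, got {k}")
    seq = _canonical(mirna.sequence)
    L = len(seq)
    if L < k:
        raise ValueError(
            f"miRNA {mirna.id!r}: length {L} shorter than k={k}"
        )
    index = _KMER_INDEX[k]
    out = np.zeros(4**k)
    for start in range(L - k + 1):
        out[index[seq[start : start + k]]] += 1
    return out / (L - k + 1)


def ctsnap(mirna: MirnaRecord, t: int = 3) -> np.ndarray:
    """Composition of t-spaced nucleotide pairs (16 entries).

    A pair occupies the two ends of a length-t window (positions p and
    p + t - 1); the denominator L - t + 1 counts those windows, so t = 2
    reduces to the dinucleotide composition.
    """
    if t < 2:
        raise ValueError(f"window length t must be >= 2, got {t}")
    seq = _canonical(mirna.sequence)
    L = len(seq)
    if L < t:
        raise ValueError(f"miRNA {mirna.id!r}: length {L} shorter than t={t}")
    index = _KMER_INDEX[2]
    out = np.zeros(16)
    for start in range(L - t + 1):
        out[index[seq[start] + seq[start + t - 1]]] += 1
    return out / (L - t + 1)


def ave_anf(mirna: MirnaRecord) -> np.ndarray:
    """Average accumulated nucleotide frequency (4 entries).

    For nucleotide i occurring at 1-based positions p_1..p_N, each
    occurrence contributes its prefix density (count of i within the first
    p_n positions, divided by p_n); the entry is the mean contribution.
    Absent nucleotides map to 0.
    """
    seq = _canonical(mirna.sequence)
    out = np.zeros(4)
    for idx, nt in enumerate(NUCLEOTIDES):
        seen = 0
        acc = 0.0
        n = 0
        for pos, ch in enumerate(seq, start=1):
            if ch == nt:
                seen += 1
                acc += seen / pos
                n += 1
        if n:
            out[idx] = acc / n
    return out


def encode_mirna(mirna: MirnaRecord, t: int = 3) -> np.ndarray:
    """Full 360-length miRNA encoding: NAC|DNC|TNC|QNC|CTSNAP|aveANF."""
    L = len(mirna.sequence)
    if L < 4:
        raise ValueError(
            f"miRNA {mirna.id!r}: length {L} too short for QNC (needs >= 4)"
        )
    if L < t:
        raise ValueError(
            f"miRNA {mirna.id!r}: length {L} too short for CTSNAP t={t}"
        )
    parts = [kmer_composition(mirna, k) for k in (1, 2, 3, 4)]
    parts.append(ctsnap(mirna, t))
    parts.append(ave_anf(mirna))
    vec = np.concatenate(parts)
    assert vec.shape == (MIRNA_VECTOR_LENGTH,)
    return vec


def _mol_from_record(sm: SmRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(sm.smiles)
    if mol is None:
        raise ValueError(f"compound {sm.id!r}: unparseable SMILES {sm.smiles!r}")
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError(f"compound {sm.id!r}: no heavy atoms")
    return mol


try:  # modern fingerprint generator API
    from rdkit.Chem import rdFingerprintGenerator

    _MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(
        radius=FP_RADIUS, fpSize=FP_BITS
    )

    def _morgan_bitvect(mol: Chem.Mol) -> ExplicitBitVect:
        return _MORGAN_GEN.GetFingerprint(mol)

except ImportError:  # pragma: no cover
    from rdkit.Chem import AllChem

    def _morgan_bitvect(mol: Chem.Mol) -> ExplicitBitVect:
        return AllChem.GetMorganFingerprintAsBitVect(mol, FP_RADIUS, nBits=FP_BITS)


def morgan_fingerprint(sm: SmRecord) -> ExplicitBitVect:
    """1024-bit Morgan (circular) fingerprint, radius 2."""
    return _morgan_bitvect(_mol_from_record(sm))


def encode_sm(sm: SmRecord, radius: int = FP_RADIUS) -> np.ndarray:
    """Full 1036-length compound encoding.

    Layout: 1024 Morgan bits | on-bit density | 6 structural counts (rings,
    heavy atoms, N+O, NH+OH, aliphatic carbocycles, heteroatoms) | max and
    min atomic EState index | summed VSA-EState | LogP | molar refractivity.
    """
    mol = _mol_from_record(sm)
    if radius == FP_RADIUS:
        fp = _morgan_bitvect(mol)
    else:
        from rdkit.Chem import rdFingerprintGenerator

        fp = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=FP_BITS
        ).GetFingerprint(mol)
    bits = np.zeros(FP_BITS)
    bits[list(fp.GetOnBits())] = 1.0
    density = bits.sum() / FP_BITS

    counts = np.array(
        [
            rdMolDescriptors.CalcNumRings(mol),
            mol.GetNumHeavyAtoms(),
            Descriptors.NOCount(mol),
            Descriptors.NHOHCount(mol),
            rdMolDescriptors.CalcNumAliphaticCarbocycles(mol),
            rdMolDescriptors.CalcNumHeteroatoms(mol),
        ],
        dtype=float,
    )
    estates = np.asarray(EStateIndices(mol), dtype=float)
    est_max = float(estates.max())
    est_min = float(estates.min())
    # EState-weighted van-der-Waals surface area, aggregated over the
    # standard VSA_EState bins.
    vsa_estate = float(sum(getattr(Descriptors, f"VSA_EState{i}")(mol) for i in range(1, 11)))
    logp = Crippen.MolLogP(mol)
    mr = Crippen.MolMR(mol)

    vec = np.concatenate(
        [bits, [density], counts, [est_max, est_min, vsa_estate, logp, mr]]
    )
    assert vec.shape == (SM_VECTOR_LENGTH,)
    return vec


def encode_pair(mirna: MirnaRecord, sm: SmRecord, t: int = 3) -> np.ndarray:
    """1396-length pair encoding: miRNA block first, compound block second."""
    return np.concatenate([encode_mirna(mirna, t=t), encode_sm(sm)])


def as_matrix(vector: np.ndarray) -> np.ndarray:
    """Reshape a pair vector to a 37x37 matrix (row-major).

    Only the first 1369 entries fit the grid; the trailing 27 are dropped.
    """
    vector = np.asarray(vector)
    if vector.ndim != 1 or vector.shape[0] < MATRIX_CELLS:
        raise ValueError(
            f"need a 1-D vector of length >= {MATRIX_CELLS}, got shape {vector.shape}"
        )
    return vector[:MATRIX_CELLS].reshape(MATRIX_SIDE, MATRIX_SIDE)


def as_sequence(vector: np.ndarray) -> np.ndarray:
    """Reshape a pair vector to 37 timesteps of 37 features each."""
    return as_matrix(vector)


def encode_batch(pairs, t: int = 3) -> np.ndarray:
    """Encode an iterable of (MirnaRecord, SmRecord) into an (n, 1396) array.

    Per-entity encodings are cached by id, so repeated entities cost once.
    """
    mir_cache: dict[str, np.ndarray] = {}
    sm_cache: dict[str, np.ndarray] = {}
    rows = []
    for mirna, sm in pairs:
        if mirna.id not in mir_cache:
            mir_cache[mirna.id] = encode_mirna(mirna, t=t)
        if sm.id not in sm_cache:
            sm_cache[sm.id] = encode_sm(sm)
        rows.append(np.concatenate([mir_cache[mirna.id], sm_cache[sm.id]]))
    return np.asarray(rows) if rows else np.empty((0, PAIR_VECTOR_LENGTH))
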