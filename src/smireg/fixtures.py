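"""Seeded synthetic datasets with the statistical structure the method assumes.

The generator emulates a curated compound--miRNA regulation table: short
RNA sequences (~18-25 nt), chemically valid SMILES assembled from a
fragment vocabulary, and binary up/down labels planted by a rule that is
detectable from the encoded features --- UP iff (miRNA GC-fraction above
the corpus median) XOR (fingerprint on-bit density above the corpus
median) --- then flipped independently with a configurable noise rate.
Everything is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FP_BITS, morgan_fingerprint
from .types import Label, MirnaRecord, RelationRecord, RelationSet, SmRecord

# Fragment vocabulary for assembling valid SMILES: alkyl chains, aromatic
# carbo-/heterocycles as substituents, and polar terminal decorations.
_CHAINS = ["C", "CC", "CCC", "CCCC", "CCCCC", "C(C)C", "CC(C)C"]
_RINGS = ["c1ccccc1", "c1ccncc1", "C1CCCCC1", "c1ccc2ccccc2c1", "C1CCNCC1"]
_TERMINALS = ["O", "N", "C(=O)O", "C(=O)N", "OC", "NC", ""]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic relation-table generator."""

    n_mirnas: int = 60
    n_sms: int = 40
    n_relations: int = 400
    mirna_len_range: tuple[int, int] = (18, 25)
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_sms, self.n_relations) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError(f"noise_rate {self.noise_rate} outside [0, 1]")
        lo, hi = self.mirna_len_range
        if lo < 4 or hi < lo:
            raise ValueError(f"bad mirna_len_range {self.mirna_len_range}")


def _random_sequence(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list("ACGU"), size=length))


def _random_smiles(rng: np.random.Generator) -> str:
    parts = [str(rng.choice(_CHAINS))]
    if rng.random() < 0.8:
        parts.append(str(rng.choice(_RINGS)))
    if rng.random() < 0.6:
        parts.append(str(rng.choice(_CHAINS)))
        if rng.random() < 0.5:
            parts.append(str(rng.choice(_RINGS)))
    parts.append(str(rng.choice(_TERMINALS)))
    return "".join(parts)


def gc_fraction(sequence: str) -> float:
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def fingerprint_density(sm: SmRecord) -> float:
    return morgan_fingerprint(sm).GetNumOnBits() / FP_BITS


def generate_mirnas(config: FixtureConfig, rng: np.random.Generator) -> list[MirnaRecord]:
    lo, hi = config.mirna_len_range
    return [
        MirnaRecord(id=f"mir-{i:04d}", sequence=_random_sequence(rng, lo, hi))
        for i in range(config.n_mirnas)
    ]


def generate_sms(config: FixtureConfig, rng: np.random.Generator) -> list[SmRecord]:
    return [
        SmRecord(id=f"CID{i:06d}", smiles=_random_smiles(rng))
        for i in range(config.n_sms)
    ]


def planted_label(
    mirna: MirnaRecord,
    sm: SmRecord,
    gc_median: float,
    density_median: float,
) -> Label:
    """The noise-free planted rule: UP iff exactly one predicate holds."""
    high_gc = gc_fraction(mirna.sequence) > gc_median
    high_density = fingerprint_density(sm) > density_median
    return Label.UP if high_gc != high_density else Label.DOWN


def generate_fixture_relations(config: FixtureConfig) -> RelationSet:
    """Generate a labeled synthetic relation set under the planted rule.

    Pairs are sampled without replacement from the n_mirnas x n_sms grid;
    labels follow the GC-fraction XOR fingerprint-density rule with
    per-relation flips at probability ``noise_rate``.
    """
    if config.n_relations > config.n_mirnas * config.n_sms:
        raise ValueError(
            f"n_relations={config.n_relations} exceeds the "
            f"{config.n_mirnas} x {config.n_sms} pair grid"
        )
    rng = np.random.default_rng(config.seed)
    mirnas = generate_mirnas(config, rng)
    sms = generate_sms(config, rng)

    gc_median = float(np.median([gc_fraction(m.sequence) for m in mirnas]))
    density_median = float(np.median([fingerprint_density(s) for s in sms]))

    pair_indices = rng.choice(
        config.n_mirnas * config.n_sms, size=config.n_relations, replace=False
    )
    flips = rng.random(config.n_relations) < config.noise_rate
    relations = []
    for flat, flip in zip(pair_indices, flips):
        mirna = mirnas[int(flat) // config.n_sms]
        sm = sms[int(flat) % config.n_sms]
        label = planted_label(mirna, sm, gc_median, density_median)
        if flip:
            label = Label.DOWN if label is Label.UP else Label.UP
        relations.append(RelationRecord(sm=sm, mirna=mirna, label=label))
    return RelationSet(relations)


def generate_clustered_relations(
    n_per_class: int = 20,
    seed: int = 0,
    mutate: int = 2,
) -> tuple[RelationSet, RelationSet]:
    """Two similarity clusters of labeled relations, one per class.

    UP relations are built around one anchor miRNA/compound pair and DOWN
    relations around another; within a cluster, miRNAs are few-mutation
    variants of the anchor sequence and compounds are minor decorations of
    the anchor scaffold, so within-cluster similarities sit above the usual
    thresholds while cross-cluster similarities sit below them.  Used to
    exercise guilt-by-association and the similarity-network fallback.
    """
    rng = np.random.default_rng(seed)
    anchors = {
        Label.UP: ("ACGUACGUACGUACGUACGUAC", "c1ccccc1CCCCCC"),
        Label.DOWN: ("GGUUCCAAGGUUCCAAGGUUCC", "C1CCNCC1NCCNCCN"),
    }
    out = {}
    nts = list("ACGU")
    for label, (anchor_seq, anchor_smiles) in anchors.items():
        relations = []
        for i in range(n_per_class):
            seq = list(anchor_seq)
            for pos in rng.choice(len(seq), size=mutate, replace=False):
                seq[pos] = nts[int(rng.integers(4))]
            mirna = MirnaRecord(id=f"{label.value}-mir-{i:03d}", sequence="".join(seq))
            extra = "C" * int(rng.integers(0, 3))
            sm = SmRecord(id=f"{label.value}-sm-{i:03d}", smiles=anchor_smiles + extra)
            relations.append(RelationRecord(sm=sm, mirna=mirna, label=label))
        out[label] = RelationSet(relations)
    return out[Label.UP], out[Label.DOWN]
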