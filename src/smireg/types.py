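"""Core domain types shared across the pipeline.

The unit of every dataset is a compound--miRNA relation: a small molecule
(SMILES), a miRNA (RNA sequence), and optionally the direction of the
compound's effect on the miRNA's expression (up- or downregulation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

RNA_ALPHABET = frozenset("ACGUT")


class Label(enum.Enum):
    """Direction of a compound's regulatory effect on a miRNA."""

    UP = "up"
    DOWN = "down"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str) -> "Label":
        """Parse a label token case-insensitively by prefix.

        Source databases write labels inconsistently ("up", "Up-regulation",
        "downregulated" ...); any token whose lower-cased form starts with
        "up", "down" or "unknown" is accepted.
        """
        t = token.strip().lower()
        for lab in (cls.UP, cls.DOWN, cls.UNKNOWN):
            if t.startswith(lab.value):
                return lab
        raise ValueError(f"unrecognized label token: {token!r}")


@dataclass(frozen=True)
class MirnaRecord:
    """A miRNA identified by id, with its nucleotide sequence.

    Sequences are stored uppercase as read; T and U are both accepted and
    treated as interchangeable by the encoders and similarity measures.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"miRNA {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"miRNA {self.id!r}: invalid characters {sorted(bad)!r} "
                f"(alphabet is A/C/G/U/T)"
            )


@dataclass(frozen=True)
class SmRecord:
    """A small molecule identified by a CID-like id, with its SMILES."""

    id: str
    smiles: str


@dataclass(frozen=True)
class RelationRecord:
    """One compound--miRNA relation, optionally labeled UP or DOWN."""

    sm: SmRecord
    mirna: MirnaRecord
    label: Label = Label.UNKNOWN

    @property
    def key(self) -> tuple[str, str]:
        return (self.sm.id, self.mirna.id)

    def with_label(self, label: Label) -> "RelationRecord":
        return replace(self, label=label)


@dataclass
class RelationSet:
    """An ordered collection of relations with unique (sm, mirna) pairs."""

    relations: list[RelationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.relations:
            if r.key in seen:
                raise ValueError(f"duplicate relation for pair {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.relations)

    def __iter__(self) -> Iterator[RelationRecord]:
        return iter(self.relations)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.keys()

    def keys(self) -> set[tuple[str, str]]:
        return {r.key for r in self.relations}

    @property
    def unique_mirnas(self) -> dict[str, MirnaRecord]:
        out: dict[str, MirnaRecord] = {}
        for r in self.relations:
            out.setdefault(r.mirna.id, r.mirna)
        return out

    @property
    def unique_sms(self) -> dict[str, SmRecord]:
        out: dict[str, SmRecord] = {}
        for r in self.relations:
            out.setdefault(r.sm.id, r.sm)
        return out

    def label_counts(self) -> dict[Label, int]:
        counts = {lab: 0 for lab in Label}
        for r in self.relations:
            counts[r.label] += 1
        return counts

    def subset(self, keys: Iterable[tuple[str, str]]) -> "RelationSet":
        wanted = set(keys)
        return RelationSet([r for r in self.relations if r.key in wanted])

    def without(self, keys: Iterable[tuple[str, str]]) -> "RelationSet":
        banned = set(keys)
        return RelationSet([r for r in self.relations if r.key not in banned])
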