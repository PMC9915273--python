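"""Pairwise similarity measures and fully-connected similarity networks.

miRNA--miRNA similarity is the fraction of identical aligned positions in
an optimal global alignment (uracil read as thymine/canonical U first);
compound--compound similarity is the Tanimoto coefficient of 1024-bit
Morgan fingerprints.  Networks are complete weighted graphs over one
entity kind, with thresholded neighbor queries (compounds: > 0.6;
miRNAs: > 0.8, looser because ~20-nt sequences produce many high
identities).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from rdkit.DataStructs import TanimotoSimilarity

from .features import morgan_fingerprint
from .types import MirnaRecord, SmRecord


class NetworkKind(enum.Enum):
    MIRNA = "mirna"
    SM = "sm"


@dataclass(frozen=True)
class SimilarityThresholds:
    """Similarity cutoffs above which two entities count as similar."""

    sm_tanimoto: float = 0.6
    mirna_identity: float = 0.8

    def __post_init__(self) -> None:
        for name, v in (("sm_tanimoto", self.sm_tanimoto), ("mirna_identity", self.mirna_identity)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")

    def for_kind(self, kind: NetworkKind) -> float:
        return self.sm_tanimoto if kind is NetworkKind.SM else self.mirna_identity


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring for nucleotide identity computation."""

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -0.5
    gap_extend: float = -0.1


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner(AlignmentScoring())


def sequence_identity(
    a: MirnaRecord,
    b: MirnaRecord,
    scoring: AlignmentScoring | None = None,
) -> float:
    """Global-alignment identity between two miRNA sequences, in [0, 1].

    Both sequences are mapped to a DNA alphabet (U -> T) before alignment;
    identity is identical aligned positions over the alignment length.
    """
    aligner = _DEFAULT_ALIGNER if scoring is None else _make_aligner(scoring)
    sa = a.sequence.upper().replace("U", "T")
    sb = b.sequence.upper().replace("U", "T")
    if sb < sa:
        # co-optimal alignments can differ by argument order; fixing a
        # canonical order keeps the measure symmetric
        sa, sb = sb, sa
    aln = aligner.align(sa, sb)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def tanimoto(a: SmRecord, b: SmRecord) -> float:
    """Tanimoto coefficient of the two compounds' Morgan fingerprints.

    |A and B| / |A or B|; degenerate all-zero fingerprints compare as 1.
    """
    fa = morgan_fingerprint(a)
    fb = morgan_fingerprint(b)
    if fa.GetNumOnBits() == 0 and fb.GetNumOnBits() == 0:
        return 1.0
    return TanimotoSimilarity(fa, fb)


class SimilarityNetwork:
    """A complete weighted graph over miRNAs or compounds.

    Nodes are ordered lexicographically by id; the n(n-1)/2 pairwise
    weights are stored symmetrically.  Self-similarity is defined as 1 and
    not counted as an edge.
    """

    def __init__(self, kind: NetworkKind, entities: Sequence[MirnaRecord] | Sequence[SmRecord]):
        ids = [e.id for e in entities]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate entity ids: {dupes}")
        if len(ids) < 2:
            raise ValueError("a similarity network needs at least 2 entities")
        self.kind = kind
        self.entities = {e.id: e for e in entities}
        self.nodes = sorted(ids)
        self._weights: dict[frozenset[str], float] = {}

    @property
    def n_edges(self) -> int:
        return len(self._weights)

    def _measure(self, a, b) -> float:
        if self.kind is NetworkKind.MIRNA:
            return sequence_identity(a, b)
        return tanimoto(a, b)

    def build(self) -> "SimilarityNetwork":
        """Compute all pairwise weights (n(n-1)/2 evaluations)."""
        if self.kind is NetworkKind.SM:
            # fingerprints cached once; Tanimoto over cached bit vectors
            fps = {i: morgan_fingerprint(self.entities[i]) for i in self.nodes}
            for ix, i in enumerate(self.nodes):
                for j in self.nodes[ix + 1 :]:
                    fi, fj = fps[i], fps[j]
                    if fi.GetNumOnBits() == 0 and fj.GetNumOnBits() == 0:
                        w = 1.0
                    else:
                        w = TanimotoSimilarity(fi, fj)
                    self._weights[frozenset((i, j))] = w
        else:
            for ix, i in enumerate(self.nodes):
                for j in self.nodes[ix + 1 :]:
                    self._weights[frozenset((i, j))] = sequence_identity(
                        self.entities[i], self.entities[j]
                    )
        return self

    def weight(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        try:
            return self._weights[frozenset((a, b))]
        except KeyError:
            raise KeyError(f"no edge between {a!r} and {b!r}; was build() called?")

    def similarity_to(self, query) -> dict[str, float]:
        """Similarity of an (possibly external) entity to every node."""
        expected = MirnaRecord if self.kind is NetworkKind.MIRNA else SmRecord
        if not isinstance(query, expected):
            raise TypeError(
                f"query of type {type(query).__name__} does not match "
                f"network kind {self.kind.value}"
            )
        if query.id in self.entities:
            return {n: self.weight(query.id, n) for n in self.nodes}
        return {n: self._measure(query, self.entities[n]) for n in self.nodes}

    def similar_neighbors(
        self, query, thresholds: SimilarityThresholds | None = None
    ) -> list[tuple[str, float]]:
        """Nodes strictly above the kind-appropriate similarity threshold.

        Sorted by descending similarity, ties broken lexicographically by id.
        The query itself (by id) is excluded.
        """
        thresholds = thresholds or SimilarityThresholds()
        cutoff = thresholds.for_kind(self.kind)
        sims = self.similarity_to(query)
        hits = [(n, s) for n, s in sims.items() if s > cutoff and n != query.id]
        return sorted(hits, key=lambda kv: (-kv[1], kv[0]))

    # --- serialization ---------------------------------------------------

    def to_files(self, edges_path: str | Path, header_path: str | Path) -> None:
        """Write a TSV edge list plus a JSON header."""
        with open(edges_path, "w") as fh:
            fh.write("id_a\tid_b\tweight\n")
            for ix, i in enumerate(self.nodes):
                for j in self.nodes[ix + 1 :]:
                    fh.write(f"{i}\t{j}\t{self.weight(i, j):.6g}\n")
        Path(header_path).write_text(
            json.dumps(
                {
                    "kind": self.kind.value,
                    "n_nodes": len(self.nodes),
                    "n_edges": self.n_edges,
                    "measure": "identity" if self.kind is NetworkKind.MIRNA else "tanimoto",
                }
            )
        )


def build_complete_network(
    entities: Iterable[MirnaRecord] | Iterable[SmRecord],
    kind: NetworkKind,
) -> SimilarityNetwork:
    """Build and fully populate a similarity network of the given kind."""
    return SimilarityNetwork(kind, list(entities)).build()
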