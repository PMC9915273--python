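"""Similarity-network inference for relations with a novel compound or miRNA.

When a query pair contains an entity the trained models never saw, its
regulation type can still be inferred from the training relations alone:
find training compounds similar to the query compound (Tanimoto > 0.6),
collect the training UP and DOWN relations of those candidates, return a
class immediately on a perfect miRNA match, and otherwise compare the mean
identity of the query miRNA to each class's collected miRNAs.  The mirror
procedure (thresholds swapped, miRNA candidates first) handles novel
miRNAs.  The approach abstains (NO_CALL) rather than guess when no
candidate, no subnetwork, or a tie blocks a decision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .similarity import (
    NetworkKind,
    SimilarityNetwork,
    SimilarityThresholds,
)
from .types import Label, MirnaRecord, RelationSet, SmRecord


class NovelSide(enum.Enum):
    SM = "sm"
    MIRNA = "mirna"


class Call(enum.Enum):
    UP = "up"
    DOWN = "down"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class QueryRelation:
    sm: SmRecord
    mirna: MirnaRecord
    novel_side: NovelSide


@dataclass
class InferenceResult:
    """Call plus the complete evidence chain behind it."""

    call: Call
    #: training entities similar to the novel query entity, with similarity
    candidates: list[tuple[str, float]] = field(default_factory=list)
    #: per-class perfect-match partner entity ids
    perfect_matches: dict[str, list[str]] = field(default_factory=dict)
    #: per-class mean similarity of the query partner to collected entities
    subnetwork_means: dict[str, float] = field(default_factory=dict)
    reason: str = ""

    def as_dict(self) -> dict:
        return {
            "call": self.call.value,
            "candidates": self.candidates,
            "perfect_matches": self.perfect_matches,
            "subnetwork_means": self.subnetwork_means,
            "reason": self.reason,
        }


def infer_regulation(
    query: QueryRelation,
    train_up: RelationSet,
    train_down: RelationSet,
    sm_net: SimilarityNetwork,
    mir_net: SimilarityNetwork,
    thresholds: SimilarityThresholds | None = None,
) -> InferenceResult:
    """Assign UP/DOWN (or abstain) to a query with one novel entity.

    ``sm_net`` and ``mir_net`` must cover the training compounds and
    miRNAs respectively; similarities to the novel query entity are
    computed on the fly.
    """
    thresholds = thresholds or SimilarityThresholds()
    if sm_net.kind is not NetworkKind.SM or mir_net.kind is not NetworkKind.MIRNA:
        raise ValueError("networks passed in the wrong order or of wrong kind")

    if query.novel_side is NovelSide.SM:
        novel_entity, partner = query.sm, query.mirna
        candidate_net, partner_net = sm_net, mir_net
        anchor_of = lambda rel: rel.sm.id          # entity matched to candidates
        partner_of = lambda rel: rel.mirna         # entity compared in subnetworks
    else:
        novel_entity, partner = query.mirna, query.sm
        candidate_net, partner_net = mir_net, sm_net
        anchor_of = lambda rel: rel.mirna.id
        partner_of = lambda rel: rel.sm

    if partner.id not in partner_net.entities:
        raise ValueError(
            f"non-novel entity {partner.id!r} is absent from the training network"
        )

    candidates = candidate_net.similar_neighbors(novel_entity, thresholds)
    # the query entity itself may sit in the network despite the novel flag;
    # a self-candidate (similarity 1) behaves as an ordinary candidate
    if novel_entity.id in candidate_net.entities:
        candidates = sorted(
            candidates + [(novel_entity.id, 1.0)], key=lambda kv: (-kv[1], kv[0])
        )
    result = InferenceResult(call=Call.NO_CALL, candidates=candidates)
    if not candidates:
        result.reason = "no training entity above the candidate threshold"
        return result
    candidate_ids = {c for c, _ in candidates}

    picked: dict[Label, list] = {}
    perfect: dict[Label, list[str]] = {}
    for label, train in ((Label.UP, train_up), (Label.DOWN, train_down)):
        rels = [r for r in train if anchor_of(r) in candidate_ids]
        picked[label] = rels
        perfect[label] = sorted(
            {partner_of(r).id for r in rels if partner_of(r).id == partner.id}
        )
    result.perfect_matches = {lab.value: ids for lab, ids in perfect.items() if ids}

    if perfect[Label.UP] and perfect[Label.DOWN]:
        result.reason = "perfect match in both classes"
        return result
    for label in (Label.UP, Label.DOWN):
        if perfect[label]:
            result.call = Call.UP if label is Label.UP else Call.DOWN
            result.reason = "perfect match"
            return result

    means: dict[Label, float] = {}
    for label, rels in picked.items():
        partner_ids = sorted({partner_of(r).id for r in rels})
        if partner_ids:
            sims = partner_net.similarity_to(partner)
            means[label] = sum(sims[p] for p in partner_ids) / len(partner_ids)
    result.subnetwork_means = {lab.value: m for lab, m in means.items()}
    if not means:
        result.reason = "no relations of either class among the candidates"
        return result
    if len(means) == 1:
        label = next(iter(means))
        result.call = Call.UP if label is Label.UP else Call.DOWN
        result.reason = "single-class subnetwork"
        return result
    if means[Label.UP] == means[Label.DOWN]:
        result.reason = "subnetwork means tie"
        return result
    winner = Label.UP if means[Label.UP] > means[Label.DOWN] else Label.DOWN
    result.call = Call.UP if winner is Label.UP else Call.DOWN
    result.reason = "higher subnetwork mean"
    return result
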