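"""Guilt-by-association relation augmentation and the seven-way data split.

To enlarge the labeled corpus, unlabeled (compound, miRNA) pairs are
screened against the known relations of each class separately: a candidate
pair receives class support when some known relation of that class has
both a sufficiently similar compound (Tanimoto > 0.6) and a sufficiently
similar miRNA (identity > 0.8).  Running the screen once per class keeps
non-associated pairs out; candidates supported by both classes are dropped
as ambiguous.

The split machinery carves an experimentally-labeled corpus plus the
augmented relations into seven disjoint sets: Train, Test, TestSim (the
held-out augmented relations), TestRptMIR / TestRptSM (relations whose
miRNA / compound recurs in training), and TestUniqMIR / TestUniqSM
(relations whose miRNA / compound never appears in training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import (
    NetworkKind,
    SimilarityNetwork,
    SimilarityThresholds,
    build_complete_network,
)
from .types import Label, MirnaRecord, RelationRecord, RelationSet, SmRecord


@dataclass
class DedupReport:
    n_exact_duplicates: int = 0
    n_conflicting_pairs: int = 0
    conflicts: list[tuple[str, str]] = field(default_factory=list)


def dedup_relations(raw: list[RelationRecord]) -> tuple[RelationSet, DedupReport]:
    """Collapse exact duplicates and drop label-conflicting pairs.

    Identical (sm, mirna, label) triples collapse to one record.  A pair
    carrying both an UP and a DOWN record is contradictory and removed
    entirely from both classes.
    """
    report = DedupReport()
    by_pair: dict[tuple[str, str], dict[Label, RelationRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in raw:
        if r.key not in by_pair:
            by_pair[r.key] = {}
            order.append(r.key)
        if r.label in by_pair[r.key]:
            report.n_exact_duplicates += 1
        else:
            by_pair[r.key][r.label] = r
    kept: list[RelationRecord] = []
    for key in order:
        labels = by_pair[key]
        directed = {lab for lab in labels if lab in (Label.UP, Label.DOWN)}
        if len(directed) == 2:
            report.n_conflicting_pairs += 1
            report.conflicts.append(key)
            continue
        # at most one directed label now; prefer it over UNKNOWN duplicates
        lab = next(iter(directed)) if directed else next(iter(labels))
        kept.append(labels[lab])
    return RelationSet(kept), report


@dataclass
class GbaConfig:
    """Knobs of the guilt-by-association screen."""

    thresholds: SimilarityThresholds = field(default_factory=SimilarityThresholds)
    #: minimum number of supporting known relations required per candidate
    min_anchors: int = 1


def _class_support(
    candidate_sm: str,
    candidate_mir: str,
    known: RelationSet,
    sm_net: SimilarityNetwork,
    mir_net: SimilarityNetwork,
    thresholds: SimilarityThresholds,
) -> int:
    """Count known relations anchoring the candidate above both thresholds."""
    n = 0
    for rel in known:
        sm_sim = sm_net.weight(candidate_sm, rel.sm.id)
        mir_sim = mir_net.weight(candidate_mir, rel.mirna.id)
        if sm_sim > thresholds.sm_tanimoto and mir_sim > thresholds.mirna_identity:
            n += 1
    return n


def infer_gba_relations(
    known_up: RelationSet,
    known_down: RelationSet,
    config: GbaConfig | None = None,
) -> tuple[RelationSet, RelationSet]:
    """Screen unlabeled pairs for potential UP and DOWN relations.

    The screen runs independently per class over that class's own
    similarity networks; the candidate space of a class is the full grid of
    the class's unique compounds x unique miRNAs minus its known pairs.
    Candidates supported by both classes are dropped.  Self-similarity
    (candidate entity identical to an anchor entity) counts as 1.
    """
    config = config or GbaConfig()
    if len(known_up) == 0 or len(known_down) == 0:
        raise ValueError("both known relation sets must be non-empty")

    # no candidate may duplicate an experimentally known pair of either class
    all_known = known_up.keys() | known_down.keys()
    supported: dict[Label, set[tuple[str, str]]] = {}
    entities: dict[Label, tuple[dict[str, SmRecord], dict[str, MirnaRecord]]] = {}
    for label, known in ((Label.UP, known_up), (Label.DOWN, known_down)):
        sms = known.unique_sms
        mirs = known.unique_mirnas
        entities[label] = (sms, mirs)
        sm_net = (
            build_complete_network(list(sms.values()), NetworkKind.SM)
            if len(sms) >= 2
            else None
        )
        mir_net = (
            build_complete_network(list(mirs.values()), NetworkKind.MIRNA)
            if len(mirs) >= 2
            else None
        )
        hits: set[tuple[str, str]] = set()
        for sm_id in sorted(sms):
            for mir_id in sorted(mirs):
                if (sm_id, mir_id) in all_known:
                    continue
                if sm_net is None or mir_net is None:
                    continue
                n_anchors = _class_support(
                    sm_id, mir_id, known, sm_net, mir_net, config.thresholds
                )
                if n_anchors >= config.min_anchors:
                    hits.add((sm_id, mir_id))
        supported[label] = hits

    dual = supported[Label.UP] & supported[Label.DOWN]
    out: dict[Label, RelationSet] = {}
    for label in (Label.UP, Label.DOWN):
        sms, mirs = entities[label]
        rels = [
            RelationRecord(sm=sms[s], mirna=mirs[m], label=label)
            for (s, m) in sorted(supported[label] - dual)
        ]
        out[label] = RelationSet(rels)
    return out[Label.UP], out[Label.DOWN]


@dataclass(frozen=True)
class SplitConfig:
    """Sizes and ratios of the seven-way split.

    Defaults follow the corpus-scale protocol: 20 unique miRNAs and 20
    unique compounds reserved per class for the novel-entity test sets,
    30 recurring-entity relations per pick, a 9:1 train:test split of the
    core, and a 4:1 split of the augmented relations.
    """

    n_uniq_mirnas_per_class: int = 20
    n_uniq_sms_per_class: int = 20
    n_rpt_per_pick: int = 30
    test_fraction: float = 0.1
    gba_test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1 or not 0 < self.gba_test_fraction < 1:
            raise ValueError("test fractions must lie in (0, 1)")


@dataclass
class DatasetBundle:
    """The seven pairwise-disjoint relation sets produced by build_splits."""

    train: RelationSet
    test: RelationSet
    test_sim: RelationSet
    test_rpt_mir: RelationSet
    test_rpt_sm: RelationSet
    test_uniq_mir: RelationSet
    test_uniq_sm: RelationSet
    #: (set name, (sm_id, mirna_id)) pairs removed post hoc as train overlaps
    removal_log: list[tuple[str, tuple[str, str]]] = field(default_factory=list)

    def members(self) -> dict[str, RelationSet]:
        return {
            "train": self.train,
            "test": self.test,
            "test_sim": self.test_sim,
            "test_rpt_mir": self.test_rpt_mir,
            "test_rpt_sm": self.test_rpt_sm,
            "test_uniq_mir": self.test_uniq_mir,
            "test_uniq_sm": self.test_uniq_sm,
        }


def _split_by_class(rs: RelationSet) -> dict[Label, list[RelationRecord]]:
    out: dict[Label, list[RelationRecord]] = {Label.UP: [], Label.DOWN: []}
    for r in rs:
        if r.label not in out:
            raise ValueError(f"relation {r.key} lacks an UP/DOWN label")
        out[r.label].append(r)
    return out


def _extract_recurring(
    pool: list[RelationRecord],
    n: int,
    entity_of,
    rng: np.random.Generator,
    what: str,
) -> tuple[list[RelationRecord], list[RelationRecord]]:
    """n relations whose entity recurs in the remaining pool."""
    counts: dict[str, int] = {}
    for r in pool:
        counts[entity_of(r)] = counts.get(entity_of(r), 0) + 1
    eligible = [i for i, r in enumerate(pool) if counts[entity_of(pool[i])] >= 2]
    if len(eligible) < n:
        raise ValueError(
            f"cannot pick {n} relations with recurring {what}; "
            f"only {len(eligible)} eligible"
        )
    picked = set(rng.choice(eligible, size=n, replace=False).tolist())
    taken = [pool[i] for i in sorted(picked)]
    rest = [pool[i] for i in range(len(pool)) if i not in picked]
    return taken, rest


def _random_split(
    pool: list[RelationRecord], test_fraction: float, rng: np.random.Generator
) -> tuple[list[RelationRecord], list[RelationRecord]]:
    n_test = int(round(len(pool) * test_fraction))
    idx = rng.permutation(len(pool))
    test_idx = set(idx[:n_test].tolist())
    train = [pool[i] for i in range(len(pool)) if i not in test_idx]
    test = [pool[i] for i in sorted(test_idx)]
    return train, test


def build_splits(
    experimental: RelationSet,
    gba_up: RelationSet,
    gba_down: RelationSet,
    config: SplitConfig | None = None,
) -> DatasetBundle:
    """Carve the corpus into the seven-way dataset bundle.

    Per class: (1) reserve all relations of n randomly chosen unique
    miRNAs (novel-miRNA pool) and (2) of n unique compounds (novel-compound
    pool); (3) from the remainder pick n recurring-miRNA and recurring-
    compound relations; (4) split the rest train:test; (5) split the
    augmented relations, training part joining Train and test part forming
    TestSim; (6) finally remove from every test set any pair present in
    Train, logging removals.  One seed drives all draws in this order.
    """
    config = config or SplitConfig()
    rng = np.random.default_rng(config.seed)

    by_class = _split_by_class(experimental)
    parts: dict[str, list[RelationRecord]] = {
        k: [] for k in ("uniq_mir", "uniq_sm", "rpt_mir", "rpt_sm", "train", "test")
    }
    # novel-entity reservation: entities are chosen per class, but all their
    # relations leave both class pools, so a reserved entity can never
    # re-enter training through the other class
    for part, n_entities, entity_of, what in (
        ("uniq_mir", config.n_uniq_mirnas_per_class, lambda r: r.mirna.id, "miRNAs"),
        ("uniq_sm", config.n_uniq_sms_per_class, lambda r: r.sm.id, "compounds"),
    ):
        for label in (Label.UP, Label.DOWN):
            ids = sorted({entity_of(r) for r in by_class[label]})
            if len(ids) <= n_entities:
                raise ValueError(
                    f"cannot reserve {n_entities} unique {what} out of {len(ids)} "
                    f"in the {label.value} pool"
                )
            chosen = set(rng.choice(ids, size=n_entities, replace=False))
            for pool_label in (Label.UP, Label.DOWN):
                pool = by_class[pool_label]
                parts[part] += [r for r in pool if entity_of(r) in chosen]
                by_class[pool_label] = [r for r in pool if entity_of(r) not in chosen]
    for label in (Label.UP, Label.DOWN):
        pool = by_class[label]
        taken, pool = _extract_recurring(
            pool, config.n_rpt_per_pick, lambda r: r.mirna.id, rng, "miRNAs"
        )
        parts["rpt_mir"] += taken
        taken, pool = _extract_recurring(
            pool, config.n_rpt_per_pick, lambda r: r.sm.id, rng, "compounds"
        )
        parts["rpt_sm"] += taken
        train, test = _random_split(pool, config.test_fraction, rng)
        parts["train"] += train
        parts["test"] += test

    gba_train: list[RelationRecord] = []
    gba_test: list[RelationRecord] = []
    for gba_set in (gba_up, gba_down):
        tr, te = _random_split(list(gba_set), config.gba_test_fraction, rng)
        gba_train += tr
        gba_test += te

    train_set = RelationSet(parts["train"] + gba_train)
    members = {
        "test": RelationSet(parts["test"]),
        "test_sim": RelationSet(gba_test),
        "test_rpt_mir": RelationSet(parts["rpt_mir"]),
        "test_rpt_sm": RelationSet(parts["rpt_sm"]),
        "test_uniq_mir": RelationSet(parts["uniq_mir"]),
        "test_uniq_sm": RelationSet(parts["uniq_sm"]),
    }
    removal_log: list[tuple[str, tuple[str, str]]] = []
    train_keys = train_set.keys()
    for name, rs in members.items():
        overlap = rs.keys() & train_keys
        if overlap:
            removal_log += [(name, key) for key in sorted(overlap)]
            members[name] = rs.without(overlap)
    return DatasetBundle(train=train_set, removal_log=removal_log, **members)


def pool_sizes(*subsets: RelationSet) -> int:
    """Total relation count over disjoint subsets (duplicates rejected)."""
    seen: set[tuple[str, str]] = set()
    total = 0
    for rs in subsets:
        for r in rs:
            if r.key in seen:
                raise ValueError(f"pair {r.key} appears in two subsets")
            seen.add(r.key)
            total += 1
    return total
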