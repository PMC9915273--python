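"""Similarity-network fallback inference for novel compounds/miRNAs."""

import numpy as np
import pytest

from smireg.fixtures import generate_clustered_relations
from smireg.netinfer import Call, NovelSide, QueryRelation, infer_regulation
from smireg.similarity import (
    NetworkKind,
    SimilarityThresholds,
    build_complete_network,
    sequence_identity,
    tanimoto,
)
from smireg.types import Label, MirnaRecord, RelationSet, SmRecord

from conftest import make_relation


def build_nets(train_up, train_down):
    both = RelationSet(list(train_up) + list(train_down))
    sm_net = build_complete_network(both.unique_sms.values(), NetworkKind.SM)
    mir_net = build_complete_network(both.unique_mirnas.values(), NetworkKind.MIRNA)
    return sm_net, mir_net


def brute_force_infer(query, train_up, train_down, thresholds):
    """Independent re-statement of the five-step decision rule."""
    if query.novel_side is NovelSide.SM:
        novel, partner = query.sm, query.mirna
        sim_novel = lambda rel_entity: tanimoto(novel, rel_entity)
        sim_partner = lambda e: (
            1.0 if e.id == partner.id else sequence_identity(partner, e)
        )
        anchor_of, partner_of = (lambda r: r.sm), (lambda r: r.mirna)
        cutoff = thresholds.sm_tanimoto
    else:
        novel, partner = query.mirna, query.sm
        sim_novel = lambda rel_entity: sequence_identity(novel, rel_entity)
        sim_partner = lambda e: 1.0 if e.id == partner.id else tanimoto(partner, e)
        anchor_of, partner_of = (lambda r: r.mirna), (lambda r: r.sm)
        cutoff = thresholds.mirna_identity

    # step 1: candidate anchors above threshold (self counts as 1.0)
    train_all = list(train_up) + list(train_down)
    anchor_entities = {}
    for r in train_all:
        anchor_entities[anchor_of(r).id] = anchor_of(r)
    candidates = {
        e_id
        for e_id, e in anchor_entities.items()
        if (1.0 if e_id == novel.id else sim_novel(e)) > cutoff
    }
    if not candidates:
        return Call.NO_CALL
    # step 2: relations whose anchor is a candidate
    picked = {
        Label.UP: [r for r in train_up if anchor_of(r).id in candidates],
        Label.DOWN: [r for r in train_down if anchor_of(r).id in candidates],
    }
    # step 3: perfect partner match
    perfect = {
        lab: any(partner_of(r).id == partner.id for r in rels)
        for lab, rels in picked.items()
    }
    if perfect[Label.UP] and perfect[Label.DOWN]:
        return Call.NO_CALL
    if perfect[Label.UP]:
        return Call.UP
    if perfect[Label.DOWN]:
        return Call.DOWN
    # steps 4-5: subnetwork means over unique partner entities
    means = {}
    for lab, rels in picked.items():
        partners = {partner_of(r).id: partner_of(r) for r in rels}
        if partners:
            means[lab] = float(np.mean([sim_partner(e) for e in partners.values()]))
    if not means:
        return Call.NO_CALL
    if len(means) == 1:
        return Call.UP if Label.UP in means else Call.DOWN
    if means[Label.UP] == means[Label.DOWN]:
        return Call.NO_CALL
    return Call.UP if means[Label.UP] > means[Label.DOWN] else Call.DOWN


@pytest.fixture(scope="module")
def cluster_world():
    train_up, train_down = generate_clustered_relations(n_per_class=10, seed=21)
    sm_net, mir_net = build_nets(train_up, train_down)
    return train_up, train_down, sm_net, mir_net


class TestDecisionRule:
    def test_perfect_match_returns_that_class(self, cluster_world):
        train_up, train_down, sm_net, mir_net = cluster_world
        known = train_up.relations[0]
        # novel compound very similar to the known compound, same miRNA
        query = QueryRelation(
            sm=SmRecord(id="novel-sm", smiles=known.sm.smiles + "C"),
            mirna=known.mirna,
            novel_side=NovelSide.SM,
        )
        result = infer_regulation(query, train_up, train_down, sm_net, mir_net)
        assert result.call is Call.UP
        assert result.reason == "perfect match"
        assert result.perfect_matches["up"] == [known.mirna.id]

    def test_no_candidate_above_threshold_abstains(self, cluster_world):
        train_up, train_down, sm_net, mir_net = cluster_world
        query = QueryRelation(
            sm=SmRecord(id="novel-sm", smiles="BrC(Br)(Br)Br"),  # unlike any anchor
            mirna=train_up.relations[0].mirna,
            novel_side=NovelSide.SM,
        )
        result = infer_regulation(query, train_up, train_down, sm_net, mir_net)
        assert result.call is Call.NO_CALL
        assert result.candidates == []

    def test_subnetwork_means_decide_without_perfect_match(self):
        # candidate compound anchors one UP and one DOWN relation; the query
        # miRNA is nearly identical to the UP partner and unlike the DOWN one
        seq_up = "ACGUACGUACGUACGUACGU"
        seq_down = "GGGGGUUUUUCCCCCAAAAA"
        train_up = RelationSet([
            make_relation("c1", "c1ccccc1CCCCCC", "m-up", seq_up, Label.UP),
            # dissimilar compound, never a candidate; its miRNA sits close
            # to the UP partner and serves as the query partner below
            make_relation("c-far", "ClC(Cl)(Cl)Cl", "m-near", seq_up[:-1] + "A", Label.UP),
        ])
        train_down = RelationSet([
            make_relation("c1", "c1ccccc1CCCCCC", "m-down", seq_down, Label.DOWN),
        ])
        sm_net, mir_net = build_nets(train_up, train_down)
        query = QueryRelation(
            sm=SmRecord(id="q-sm", smiles="c1ccccc1CCCCCCC"),
            mirna=MirnaRecord(id="m-near", sequence=seq_up[:-1] + "A"),
            novel_side=NovelSide.SM,
        )
        result = infer_regulation(query, train_up, train_down, sm_net, mir_net)
        assert result.call is Call.UP
        assert result.subnetwork_means["up"] > result.subnetwork_means["down"]

    def test_novel_mirna_side_mirrors_the_procedure(self, cluster_world):
        train_up, train_down, sm_net, mir_net = cluster_world
        known = train_down.relations[0]
        seq = known.mirna.sequence
        query = QueryRelation(
            sm=known.sm,
            mirna=MirnaRecord(id="novel-mir", sequence=seq[:-1] + ("A" if seq[-1] != "A" else "C")),
            novel_side=NovelSide.MIRNA,
        )
        result = infer_regulation(query, train_up, train_down, sm_net, mir_net)
        assert result.call is Call.DOWN

    def test_partner_absent_from_training_is_an_error(self, cluster_world):
        train_up, train_down, sm_net, mir_net = cluster_world
        query = QueryRelation(
            sm=SmRecord(id="novel-sm", smiles="CCO"),
            mirna=MirnaRecord(id="not-in-train", sequence="ACGUACGU"),
            novel_side=NovelSide.SM,
        )
        with pytest.raises(ValueError, match="not-in-train"):
            infer_regulation(query, train_up, train_down, sm_net, mir_net)


class TestOracleEquivalence:
    def test_matches_exhaustive_oracle_on_small_training_sets(self):
        thresholds = SimilarityThresholds()
        rng = np.random.default_rng(5)
        train_up, train_down = generate_clustered_relations(n_per_class=8, seed=5)
        sm_net, mir_net = build_nets(train_up, train_down)
        all_rels = list(train_up) + list(train_down)
        nts = "ACGU"
        for trial in range(30):
            base = all_rels[int(rng.integers(len(all_rels)))]
            if trial % 2 == 0:
                seq = list(base.mirna.sequence)
                for pos in rng.choice(len(seq), size=int(rng.integers(0, 8)), replace=False):
                    seq[pos] = nts[int(rng.integers(4))]
                query = QueryRelation(
                    sm=base.sm,
                    mirna=MirnaRecord(id=f"q{trial}", sequence="".join(seq)),
                    novel_side=NovelSide.MIRNA,
                )
            else:
                extra = "C" * int(rng.integers(0, 6))
                query = QueryRelation(
                    sm=SmRecord(id=f"q{trial}", smiles=base.sm.smiles + extra),
                    mirna=base.mirna,
                    novel_side=NovelSide.SM,
                )
            got = infer_regulation(query, train_up, train_down, sm_net, mir_net, thresholds)
            expected = brute_force_infer(query, train_up, train_down, thresholds)
            assert got.call is expected, f"trial {trial}"

    def test_irrelevant_training_relations_do_not_change_the_result(self):
        train_up, train_down = generate_clustered_relations(n_per_class=6, seed=9)
        # an isolated DOWN relation dissimilar to everything
        extra = make_relation("far-c", "BrC(Br)(Br)Br", "far-m", "UUUUUUUUAAAAAAAA", Label.DOWN)
        train_down_ext = RelationSet(list(train_down) + [extra])
        query = QueryRelation(
            sm=SmRecord(id="q", smiles=train_up.relations[0].sm.smiles + "C"),
            mirna=train_up.relations[1].mirna,
            novel_side=NovelSide.SM,
        )
        base_call = infer_regulation(
            query, train_up, train_down, *build_nets(train_up, train_down)
        ).call
        ext_call = infer_regulation(
            query, train_up, train_down_ext, *build_nets(train_up, train_down_ext)
        ).call
        assert base_call is ext_call

    def test_raising_thresholds_never_revokes_an_abstention(self):
        train_up, train_down = generate_clustered_relations(n_per_class=6, seed=2)
        sm_net, mir_net = build_nets(train_up, train_down)
        loose = SimilarityThresholds(0.5, 0.7)
        tight = SimilarityThresholds(0.8, 0.95)
        rng = np.random.default_rng(3)
        nts = "ACGU"
        for trial in range(20):
            base = (list(train_up) + list(train_down))[int(rng.integers(12))]
            seq = list(base.mirna.sequence)
            for pos in rng.choice(len(seq), size=int(rng.integers(0, 10)), replace=False):
                seq[pos] = nts[int(rng.integers(4))]
            query = QueryRelation(
                sm=base.sm,
                mirna=MirnaRecord(id=f"q{trial}", sequence="".join(seq)),
                novel_side=NovelSide.MIRNA,
            )
            loose_call = infer_regulation(
                query, train_up, train_down, sm_net, mir_net, loose
            ).call
            tight_call = infer_regulation(
                query, train_up, train_down, sm_net, mir_net, tight
            ).call
            if loose_call is Call.NO_CALL and not infer_regulation(
                query, train_up, train_down, sm_net, mir_net, loose
            ).candidates:
                assert tight_call is Call.NO_CALL


class TestPlantedClusters:
    def test_recovers_cluster_membership_with_high_accuracy_and_call_rate(self):
        train_up, train_down = generate_clustered_relations(n_per_class=12, seed=33)
        sm_net, mir_net = build_nets(train_up, train_down)
        rng = np.random.default_rng(33)
        nts = "ACGU"
        n_called = n_correct = n_total = 0
        for label, pool in ((Label.UP, train_up), (Label.DOWN, train_down)):
            for i in range(20):
                base = pool.relations[int(rng.integers(len(pool)))]
                if i % 2 == 0:
                    seq = list(base.mirna.sequence)
                    for pos in rng.choice(len(seq), size=2, replace=False):
                        seq[pos] = nts[int(rng.integers(4))]
                    query = QueryRelation(
                        sm=base.sm,
                        mirna=MirnaRecord(id=f"q-{label.value}-{i}", sequence="".join(seq)),
                        novel_side=NovelSide.MIRNA,
                    )
                else:
                    query = QueryRelation(
                        sm=SmRecord(
                            id=f"q-{label.value}-{i}",
                            smiles=base.sm.smiles + "C" * int(rng.integers(1, 3)),
                        ),
                        mirna=base.mirna,
                        novel_side=NovelSide.SM,
                    )
                result = infer_regulation(query, train_up, train_down, sm_net, mir_net)
                n_total += 1
                if result.call is not Call.NO_CALL:
                    n_called += 1
                    if result.call.value == label.value:
                        n_correct += 1
        assert n_called / n_total >= 0.8
        assert n_correct / n_called >= 0.9
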