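"""Deduplication, guilt-by-association screening, and the seven-way split."""

import numpy as np
import pytest

from smireg.fixtures import FixtureConfig, generate_clustered_relations, generate_fixture_relations
from smireg.gba import (
    GbaConfig,
    SplitConfig,
    build_splits,
    dedup_relations,
    infer_gba_relations,
    pool_sizes,
)
from smireg.similarity import (
    NetworkKind,
    SimilarityThresholds,
    build_complete_network,
    sequence_identity,
    tanimoto,
)
from smireg.types import Label, MirnaRecord, RelationRecord, RelationSet, SmRecord

from conftest import make_relation


class TestDedup:
    def test_exact_duplicates_collapse(self):
        r = make_relation("c1", "CCO", "m1", "ACGU", Label.UP)
        out, report = dedup_relations([r, r])
        assert len(out) == 1 and report.n_exact_duplicates == 1

    def test_conflicting_pair_removed_entirely(self):
        up = make_relation("c1", "CCO", "m1", "ACGU", Label.UP)
        down = make_relation("c1", "CCO", "m1", "ACGU", Label.DOWN)
        other = make_relation("c2", "CCN", "m2", "AAGG", Label.DOWN)
        out, report = dedup_relations([up, down, other])
        assert [r.key for r in out] == [("c2", "m2")]
        assert report.n_conflicting_pairs == 1
        assert report.conflicts == [("c1", "m1")]

    def test_empty_input_gives_empty_output(self):
        out, report = dedup_relations([])
        assert len(out) == 0 and report.n_conflicting_pairs == 0


def brute_force_gba(known_up, known_down, thresholds):
    """Exhaustive candidate enumeration, independent of the implementation."""
    supported = {}
    all_known = known_up.keys() | known_down.keys()
    for label, known in ((Label.UP, known_up), (Label.DOWN, known_down)):
        sms = known.unique_sms
        mirs = known.unique_mirnas
        hits = set()
        for s_id, s in sms.items():
            for m_id, m in mirs.items():
                if (s_id, m_id) in all_known:
                    continue
                for rel in known:
                    t = 1.0 if rel.sm.id == s_id else tanimoto(rel.sm, s)
                    i = 1.0 if rel.mirna.id == m_id else sequence_identity(rel.mirna, m)
                    if t > thresholds.sm_tanimoto and i > thresholds.mirna_identity:
                        hits.add((s_id, m_id))
                        break
        supported[label] = hits
    dual = supported[Label.UP] & supported[Label.DOWN]
    return supported[Label.UP] - dual, supported[Label.DOWN] - dual


class TestGbaInference:
    def test_matches_exhaustive_oracle_on_clustered_fixture(self):
        up, down = generate_clustered_relations(n_per_class=8, seed=4)
        got_up, got_down = infer_gba_relations(up, down)
        exp_up, exp_down = brute_force_gba(up, down, SimilarityThresholds())
        assert got_up.keys() == exp_up
        assert got_down.keys() == exp_down
        # the clustered construction guarantees some augmentation happens
        assert len(got_up) > 0 and len(got_down) > 0

    def test_inferred_relations_are_never_known_and_keep_their_class(self):
        up, down = generate_clustered_relations(n_per_class=6, seed=1)
        got_up, got_down = infer_gba_relations(up, down)
        assert not (got_up.keys() & up.keys())
        assert not (got_down.keys() & down.keys())
        assert all(r.label is Label.UP for r in got_up)
        assert all(r.label is Label.DOWN for r in got_down)

    def test_candidates_below_threshold_are_not_inferred(self):
        # two dissimilar UP relations cannot anchor anything; candidate
        # space exists but neither cross pair clears both thresholds
        up = RelationSet([
            make_relation("c1", "c1ccccc1CCCC", "m1", "ACGUACGUACGUACGUACGU", Label.UP),
            make_relation("c2", "C1CCNCC1NCCN", "m2", "GGUUCCAAGGUUCCAAGGUU", Label.UP),
        ])
        down = RelationSet([
            make_relation("c3", "CC(=O)OC", "m3", "UUUUAAAAUUUUAAAAUUUU", Label.DOWN),
            make_relation("c4", "c1ccncc1O", "m4", "CCCCGGGGCCCCGGGGCCCC", Label.DOWN),
        ])
        got_up, got_down = infer_gba_relations(up, down)
        exp_up, exp_down = brute_force_gba(up, down, SimilarityThresholds())
        assert got_up.keys() == exp_up == set()
        assert got_down.keys() == exp_down == set()

    def test_dual_supported_candidates_are_dropped(self):
        # c1 and m2 occur in both classes, so the unknown pair (c1, m2) sits
        # in both candidate grids; with one similar scaffold and one miRNA
        # family it is anchored by both classes and must be excluded, while
        # one-sided candidates like (c2, m1) are still inferred
        seq = "ACGUACGUACGUACGUACGU"
        up = RelationSet([
            make_relation("c1", "c1ccccc1CC", "m1", seq, Label.UP),
            make_relation("c2", "c1ccccc1CCC", "m2", seq[:-1] + "A", Label.UP),
        ])
        down = RelationSet([
            make_relation("c1", "c1ccccc1CC", "m4", seq[:-2] + "AA", Label.DOWN),
            make_relation("c3", "c1ccccc1CCCC", "m2", seq[:-1] + "A", Label.DOWN),
        ])
        got_up, got_down = infer_gba_relations(up, down)
        exp_up, exp_down = brute_force_gba(up, down, SimilarityThresholds())
        assert got_up.keys() == exp_up
        assert got_down.keys() == exp_down
        assert ("c1", "m2") not in got_up.keys()
        assert ("c1", "m2") not in got_down.keys()
        assert ("c2", "m1") in got_up.keys()

    def test_empty_known_set_rejected(self):
        up, _ = generate_clustered_relations(n_per_class=3, seed=0)
        with pytest.raises(ValueError):
            infer_gba_relations(up, RelationSet([]))


def _sized_relation_set(n, prefix, label):
    """n distinct relations built on a tiny entity pool (ids only matter)."""
    rels = []
    n_sms = int(np.ceil(np.sqrt(n)))
    n_mirs = int(np.ceil(n / n_sms))
    k = 0
    for i in range(n_sms):
        for j in range(n_mirs):
            if k >= n:
                break
            rels.append(
                RelationRecord(
                    sm=SmRecord(id=f"{prefix}-c{i}", smiles="CCO"),
                    mirna=MirnaRecord(id=f"{prefix}-m{j}", sequence="ACGUACGU"),
                    label=label,
                )
            )
            k += 1
    return RelationSet(rels)


class TestSplits:
    def test_corpus_scale_pool_arithmetic(self):
        # pooling the four training subsets and the four test subsets at
        # the corpus-scale sizes (9:1 splits of 1575 and 1214 experimental
        # relations plus 4:1 splits of 405 and 250 augmented relations)
        # reproduces the corpus totals
        train_parts = [
            _sized_relation_set(n, f"tr{i}", Label.UP)
            for i, n in enumerate([1417, 1092, 324, 200])
        ]
        test_parts = [
            _sized_relation_set(n, f"te{i}", Label.DOWN)
            for i, n in enumerate([158, 122, 81, 50])
        ]
        assert pool_sizes(*train_parts) == 3033
        assert pool_sizes(*test_parts) == 411

    @pytest.fixture(scope="class")
    @staticmethod
    def bundle_inputs():
        experimental = generate_fixture_relations(
            FixtureConfig(n_mirnas=40, n_sms=25, n_relations=550, noise_rate=0.0, seed=13)
        )
        gba_up, gba_down = generate_clustered_relations(n_per_class=12, seed=13)
        config = SplitConfig(
            n_uniq_mirnas_per_class=4, n_uniq_sms_per_class=4, n_rpt_per_pick=10, seed=3
        )
        return experimental, gba_up, gba_down, config

    def test_bundle_members_are_pairwise_disjoint(self, bundle_inputs):
        experimental, gba_up, gba_down, config = bundle_inputs
        bundle = build_splits(experimental, gba_up, gba_down, config)
        members = bundle.members()
        names = list(members)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                assert not (members[a].keys() & members[b].keys()), (a, b)

    def test_novel_mirnas_never_seen_in_training(self, bundle_inputs):
        experimental, gba_up, gba_down, config = bundle_inputs
        bundle = build_splits(experimental, gba_up, gba_down, config)
        train_mirnas = set(bundle.train.unique_mirnas)
        assert not (set(bundle.test_uniq_mir.unique_mirnas) & train_mirnas)
        train_sms = set(bundle.train.unique_sms)
        assert not (set(bundle.test_uniq_sm.unique_sms) & train_sms)

    def test_same_seed_reproduces_the_bundle(self, bundle_inputs):
        experimental, gba_up, gba_down, config = bundle_inputs
        b1 = build_splits(experimental, gba_up, gba_down, config)
        b2 = build_splits(experimental, gba_up, gba_down, config)
        for name in b1.members():
            assert b1.members()[name].keys() == b2.members()[name].keys()

    def test_infeasible_extraction_names_the_failure(self, bundle_inputs):
        experimental, gba_up, gba_down, _ = bundle_inputs
        config = SplitConfig(n_uniq_mirnas_per_class=1000, seed=0)
        with pytest.raises(ValueError, match="miRNA"):
            build_splits(experimental, gba_up, gba_down, config)
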