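"""Augment scarce labels by guilt-by-association, then build the
seven-way dataset split.

An unlabeled (compound, miRNA) pair inherits a class when some known
relation of that class has both a similar compound (Tanimoto > 0.6) and a
similar miRNA (identity > 0.8); the screen runs once per class and drops
candidates supported by both (ambiguous).  The split then produces
pairwise-disjoint Train / Test / TestSim / TestRptMIR / TestRptSM /
TestUniqMIR / TestUniqSM sets.
"""

from smireg.fixtures import FixtureConfig, generate_clustered_relations, generate_fixture_relations
from smireg.gba import SplitConfig, build_splits, infer_gba_relations

known_up, known_down = generate_clustered_relations(n_per_class=10, seed=42)
potential_up, potential_down = infer_gba_relations(known_up, known_down)
print(f"known relations: {len(known_up)} UP, {len(known_down)} DOWN")
print(f"guilt-by-association inferred: {len(potential_up)} potential UP, "
      f"{len(potential_down)} potential DOWN (new pairs, never known ones)")

experimental = generate_fixture_relations(
    FixtureConfig(n_mirnas=40, n_sms=25, n_relations=550, noise_rate=0.05, seed=42)
)
bundle = build_splits(
    experimental, potential_up, potential_down,
    SplitConfig(n_uniq_mirnas_per_class=4, n_uniq_sms_per_class=4,
                n_rpt_per_pick=10, seed=0),
)
print("split sizes (pairwise disjoint):")
for name, member in bundle.members().items():
    print(f"  {name:13s} {len(member):4d}")
print(f"post-hoc overlap removals: {len(bundle.removal_log)}")
print("TestUniq* hold entities the models never see in Train; TestRpt* hold "
      "new pairs of already-seen entities; TestSim holds held-out augmented pairs.")
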