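"""Infer regulation for relations with a novel compound or miRNA.

When an entity never appeared in training, the neural models see an
out-of-distribution input; the similarity-network fallback instead looks
for training compounds similar to the query compound, transfers a class on
a perfect miRNA match, and otherwise compares mean miRNA identity to each
class's matched partners.  It abstains (NO_CALL) rather than guess.
"""

from smireg.fixtures import generate_clustered_relations
from smireg.netinfer import NovelSide, QueryRelation, infer_regulation
from smireg.similarity import NetworkKind, build_complete_network
from smireg.types import MirnaRecord, RelationSet, SmRecord

train_up, train_down = generate_clustered_relations(n_per_class=10, seed=1)
both = RelationSet(list(train_up) + list(train_down))
sm_net = build_complete_network(both.unique_sms.values(), NetworkKind.SM)
mir_net = build_complete_network(both.unique_mirnas.values(), NetworkKind.MIRNA)

anchor = train_up.relations[0]
queries = {
    "novel compound, near the UP cluster": QueryRelation(
        sm=SmRecord(id="novel-sm", smiles=anchor.sm.smiles + "CC"),
        mirna=anchor.mirna,
        novel_side=NovelSide.SM,
    ),
    "novel compound, unlike any training compound": QueryRelation(
        sm=SmRecord(id="alien-sm", smiles="BrC(Br)(Br)Br"),
        mirna=anchor.mirna,
        novel_side=NovelSide.SM,
    ),
}
for label, query in queries.items():
    result = infer_regulation(query, train_up, train_down, sm_net, mir_net)
    print(f"{label}:")
    print(f"  call={result.call.value}  reason={result.reason}")
    print(f"  candidates={len(result.candidates)}  "
          f"subnetwork means={result.subnetwork_means or '-'}")
print("NO_CALL is an explicit abstention: no training compound was similar "
      "enough to anchor an inference.")
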