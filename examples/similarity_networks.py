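"""Build complete similarity networks and query thresholded neighbors.

miRNA--miRNA edges carry global-alignment sequence identity (U read as T);
compound--compound edges carry the Tanimoto coefficient of 1024-bit Morgan
fingerprints.  Two compounds count as similar above 0.6, two miRNAs above
0.8 (stricter for compounds because short sequences reach high identities
easily).
"""

import numpy as np

from smireg.fixtures import FixtureConfig, generate_mirnas, generate_sms
from smireg.similarity import (
    NetworkKind,
    SimilarityThresholds,
    build_complete_network,
)
from smireg.types import MirnaRecord

rng = np.random.default_rng(0)
config = FixtureConfig(n_mirnas=30, n_sms=20, seed=0)
mirnas = generate_mirnas(config, rng)
sms = generate_sms(config, rng)

mir_net = build_complete_network(mirnas, NetworkKind.MIRNA)
sm_net = build_complete_network(sms, NetworkKind.SM)
print(f"miRNA network: {len(mir_net.nodes)} nodes, {mir_net.n_edges} edges "
      f"(= n(n-1)/2)")
print(f"compound network: {len(sm_net.nodes)} nodes, {sm_net.n_edges} edges")

# a query similar to the first miRNA: two point substitutions
seq = list(mirnas[0].sequence)
seq[3] = "A" if seq[3] != "A" else "C"
seq[10] = "G" if seq[10] != "G" else "U"
query = MirnaRecord(id="query", sequence="".join(seq))
hits = mir_net.similar_neighbors(query, SimilarityThresholds())
print(f"query vs {mirnas[0].id}: neighbors above identity 0.8 -> "
      f"{[(n, round(s, 3)) for n, s in hits[:3]]}")
print("(an empty list would mean no training miRNA is similar enough to transfer labels from)")
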