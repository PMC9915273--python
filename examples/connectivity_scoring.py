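"""Score compound--disease connectivity from a regulation-probability matrix.

A disease signature is a pair of miRNA sets (up- and downregulated in the
disease).  Each compound's profile (upregulation probabilities over the
miRNA universe) is centered to [-1, 1] and ranked; weighted
Kolmogorov-Smirnov enrichment of the two sets combines into a score in
[-1, 1].  Negative = the compound reverses the disease signature (a
therapeutic candidate); positive = it mimics it.
"""

from smireg.connectivity import (
    DiseaseSignature,
    build_sm_mirna_matrix,
    connectivity_map,
)

disease_up = [f"mir-up-{i}" for i in range(5)]      # raised in the disease
disease_down = [f"mir-down-{i}" for i in range(5)]  # suppressed in the disease
background = [f"mir-bg-{i}" for i in range(20)]
signature = DiseaseSignature("carcinoma-like", frozenset(disease_up), frozenset(disease_down))

predictions = []
for m in disease_up:
    predictions += [("reverser", m, 0.05), ("mimic", m, 0.95), ("inert", m, 0.5)]
for m in disease_down:
    predictions += [("reverser", m, 0.95), ("mimic", m, 0.05), ("inert", m, 0.5)]
for m in background:
    predictions += [("reverser", m, 0.5), ("mimic", m, 0.5), ("inert", m, 0.5)]

matrix = build_sm_mirna_matrix(predictions)
table = connectivity_map(matrix, [signature])
print(table.round(3))
print("\nthe reverser suppresses the disease-raised miRNAs and raises the "
      "suppressed ones -> negative score (drug candidate); the mimic "
      "reproduces the disease profile -> positive score.")
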