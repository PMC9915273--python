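# Methods

`smireg` predicts the direction of a small molecule's regulatory effect on
a miRNA's expression (upregulation vs downregulation) and builds the
surrounding workflow: feature encoding, similarity-based label
augmentation, model training and ensembling, a similarity-network fallback
for novel entities, and compound–disease connectivity scoring. This note
records the model choices, conventions, and their rationale.

## Pair representation

A relation is a (compound, miRNA) pair. The miRNA sequence (RNA alphabet,
T tolerated and read as U) is encoded as a 360-vector of six blocks, in
this fixed order:

| block  | length | content |
|--------|--------|---------|
| NAC    | 4      | mononucleotide frequencies, count/L |
| DNC    | 16     | dinucleotide frequencies, count/(L−1) |
| TNC    | 64     | trinucleotide frequencies, count/(L−2) |
| QNC    | 256    | tetranucleotide frequencies, count/(L−3) |
| CTSNAP | 16     | t-spaced pair frequencies, count/(L−t+1), default t=3 |
| aveANF | 4      | average accumulated nucleotide frequency |

k-mer entries are ordered lexicographically over A<C<G<U. CTSNAP counts
the nucleotide pairs at the two ends of every length-t window; the
denominator L−t+1 is the window count, so t=2 degenerates to DNC. Exactly
one t is used (the 360 total forces a single 16-vector); t=3 is the
default because it is the smallest non-degenerate choice. aveANF averages,
over the occurrences of each nucleotide, the prefix density of that
nucleotide at the occurrence position — a scalar blend of composition and
position; absent nucleotides map to 0.

The compound is encoded as a 1036-vector: a 1024-bit Morgan fingerprint
(radius 2 — the standard ECFP4-equivalent choice), its on-bit density, six
structural counts (rings, heavy atoms, N+O, NH+OH, aliphatic carbocycles,
heteroatoms), the maximum and minimum atomic EState indices, one
EState-weighted van-der-Waals surface-area aggregate (the sum over the ten
standard VSA_EState bins — the 1036 arithmetic admits exactly one such
scalar), LogP, and molar refractivity. All descriptors come from RDKit.

The pair vector is the miRNA block followed by the compound block
(1396 features). Image-style models consume the first 1369 entries as a
37×37 single-channel matrix (row-major); sequence models consume the same
entries as 37 timesteps of 37 features. The trailing 27 entries (the tail
of the compound descriptor block) are dropped by both reshapes; 1396 does
not fit a 37×37 grid and truncation keeps the two input views consistent.

## Similarity measures and networks

miRNA–miRNA similarity is the identity fraction of an optimal global
alignment: U is mapped to T, the alignment is computed with Biopython's
`PairwiseAligner` (match 1, mismatch 0, gap open −0.5, gap extend −0.1 —
configurable), and identity = identical aligned columns / alignment
length. When co-optimal alignments exist the aligner's choice can depend
on argument order, so the pair is put in a canonical (lexicographic)
order first; the measure is then exactly symmetric. Compound–compound
similarity is the Tanimoto coefficient of the Morgan fingerprints; two
all-zero fingerprints compare as 1 (degenerate, flagged in the docstring).

Similarity networks are complete weighted graphs over one entity kind with
n(n−1)/2 edges. Thresholded neighbor queries use strict inequality:
compounds similar above 0.6, miRNAs above 0.8. The miRNA cutoff is the
looser-scale one because ~20-nt sequences produce many high identities.

## Guilt-by-association augmentation

To enlarge a scarce labeled corpus, the screen runs once per class (UP,
DOWN) over that class's own similarity networks. The candidate space of a
class is the grid of its unique compounds × unique miRNAs, minus every
pair experimentally known in either class (excluding only the class's own
pairs would let the screen re-label a known DOWN pair as potential UP).
A candidate is supported when at least one known relation of the class has
both entity similarities above threshold (`min_anchors` is configurable,
default 1; entity identity counts as similarity 1). Candidates supported
by both classes are ambiguous and dropped. One-sided novelty suffices —
a candidate may share its compound or its miRNA with an anchor relation.

## Dataset construction

The seven-way split mirrors a standard generalization protocol:

1. Per class, reserve all relations of n randomly chosen unique miRNAs →
   TestUniqMIR, then of n unique compounds → TestUniqSM. The chosen
   entities' relations leave **both** class pools, so a reserved entity
   can never re-enter Train through the other class.
2. Per class, pick n relations whose miRNA recurs in the remaining pool →
   TestRptMIR, likewise for compounds → TestRptSM.
3. Split the remainder 9:1 into the Train and Test cores.
4. Split the augmented relations 4:1; the large part joins Train, the
   held-out part is TestSim.
5. Remove from every test set any pair present in Train (post-hoc, logged).

One integer seed drives all draws in this fixed order, so the whole bundle
is reproducible. Pairs experimentally labeled both UP and DOWN are dropped
during deduplication (a contradictory label serves neither class).

## Classifiers

Twelve architectures are trained on the pair representation: nine
image-style (AlexNet, CNN, ConvMixer64, DSConv, LSTMCNN, MobileNetV2,
ResNet18, ResNet50, SCAResNet18) on the 37×37 matrix and three
sequence-style (RNN, BiRNN, Seq2Seq) on the 37-step view. All end in a
2-logit softmax head; the score is the probability of upregulation.

The models run on the package's own NumPy training engine (`smireg.nn`):
explicit forward/backward layers (im2col convolutions, depthwise
convolutions, max pooling, batch normalization, LSTM and convolutional
LSTM recurrences, channel/spatial attention), float32 tensors, Adam
optimization of two-class cross-entropy. Every layer's backward pass is
verified against central-difference gradients in the test suite's
development history; correctness is enforced end-to-end by the
learnability tests.

Stated structural counts are honored; unstated details are fixed as the
following conventions (37×37 inputs cannot take stock ImageNet strides, so
downsampling is capped to keep maps ≥ 2×2):

| architecture | convention |
|---|---|
| CNN | 3 × [conv 32@3×3 + BN + ReLU + maxpool 2]; dense 128; head |
| AlexNet | conv 96@11×11 stride 2, then 256@5×5, 384@3×3, 384@3×3, 256@3×3 (BN+ReLU each); pools after conv 1, 2, 5; FC 256/128/2 |
| ConvMixer64 | patch-embedding conv 64@4×4 stride 4; 2 blocks (residual depthwise 3×3 + pointwise 1×1, GELU+BN); global average pool |
| DSConv | depthwise (depth-multiplier 32) + pool, separable (depthwise 3×3 + pointwise 32); twice; dense 128 |
| LSTMCNN | 3 convolutional-LSTM layers scanning matrix rows as timesteps, 32 filters of width-3 1-D convolutions, each followed by 2× pooling over the (time, width) map |
| MobileNetV2 | stem 8; inverted residual blocks (expansion 2) 16→16→24→24→32→32 with stride 2 at width changes; 1×1 conv to 64; GAP |
| ResNet18 | stride-2 stem conv 16; 4 stages × 2 basic blocks, widths 16/32/48/64; GAP (1 + 16 convolutional layers + head) |
| ResNet50 | stride-2 stem conv 16; bottleneck stages 3/4/6/3, widths 8/12/16/24 (output 4×); GAP (1 + 48 + head) |
| SCAResNet18 | ResNet18 with a channel-attention (shared-MLP gate over average+max pooled descriptors) and spatial-attention (conv gate over channel mean/max maps) module after each stage |
| RNN | LSTM 256 → LSTM 256 → dense 256 → head |
| BiRNN | LSTM 256 → LSTM 256 → bidirectional LSTM 256 (concat) → head |
| Seq2Seq | encoder LSTM 256 / LSTM 256 / BiLSTM 256; decoder the same three layers reversed; dense 256 → head |

Training: Adam, learning rate 1e-3, batch size 100, two-class
cross-entropy. LSTM forget-gate biases initialize to 1 (the standard
open-gate initialization; without it the recurrent stacks optimize far too
slowly on 37-step inputs). Input features are standardized per feature
with training-set statistics stored on the model handle (the raw vector
mixes binary bits, compositions in [0,1], and unbounded descriptors).
Early stopping selects the epoch with the best validation AUC and restores
its parameters **and** batch-norm running statistics; the validation split
is carved from the training data (default 10%) rather than from any test
set, to avoid selection leakage. 5-fold cross-validation is available as
an assessment mode (`crossval_auc`); the deliverable model is trained once.

Determinism: one seed controls initialization and batch shuffling;
single-threaded NumPy is bit-deterministic, so identical seeds reproduce
identical histories.

Ensembles average member upregulation probabilities. The "top" ensemble is
selected greedily on validation AUC: start from the best single member,
repeatedly add the member that most improves the averaged ensemble, stop
when no addition improves (ties between candidates break lexicographically
by name).

## Similarity-network fallback

For a query pair whose compound (or miRNA) is novel, the fallback: (1)
collects training compounds with Tanimoto > 0.6 to the query compound
(identical entities count 1.0); no candidate → NO_CALL; (2) picks the
training UP and DOWN relations of those candidates; (3) if a picked
relation's miRNA equals the query miRNA, returns that class (a perfect
match in both classes → NO_CALL, defensively — upstream deduplication
should preclude it); (4) otherwise averages the identity of the query
miRNA to each class's picked miRNAs (unique entities, unweighted — the
averaging is over similarity scores, not anchored-relation multiplicity);
both classes empty → NO_CALL; (5) the strictly higher mean wins; an exact
tie → NO_CALL. The mirror procedure handles novel miRNAs (identity
threshold 0.8). Every decision carries its evidence chain (candidates,
matches, subnetwork means) for auditability.

## Connectivity scoring

The compound × miRNA matrix holds upregulation probabilities (duplicates
averaged; unobserved cells imputed at the neutral 0.5 and counted, keeping
all compounds comparable over one universe). For a disease signature (two
disjoint miRNA sets), the compound profile is centered to 2·p_up − 1 and
ranked descending (ties broken by miRNA id, tie count reported). Each set
gets a weighted Kolmogorov–Smirnov enrichment statistic: hits advance the
running sum by |weight|^p (p = 1) normalized over hit weights, misses
retreat by 1/(N − set size); the statistic is the extremum of the running
sum, signed. The connectivity score is (ES_up − ES_down)/2 when the two
statistics disagree in sign and 0 otherwise — the established convention
of this score family — clipped to [−1, 1]. Negative means the compound's
profile opposes the disease signature (reversal, the therapeutic
direction); positive means mimicry. Centering makes the score exactly
antisymmetric under p → 1−p.

## Synthetic data

The generator emulates a curated regulation table: miRNA sequences drawn
uniformly over ACGU at lengths 18–25 nt (the mature-miRNA range), SMILES
assembled from a valid-fragment vocabulary (alkyl chains, benzene,
pyridine, cyclohexane, naphthalene, piperidine, polar terminals) so every
molecule parses, and labels planted by a deterministic, feature-detectable
rule — UP iff (GC fraction > corpus median) XOR (fingerprint density >
corpus median) — then flipped independently at the configured noise rate
(default 0). A second generator plants two similarity clusters (one per
class, few-mutation sequence variants and decorated scaffolds) for the
augmentation and fallback-inference tests.

What the fixtures do **not** emulate: real miRNA sequence statistics
(seed-region conservation, family structure), real chemical space
(drug-like property distributions, scaffold diversity), and any real
biological coupling between compound structure and miRNA regulation. A
passing suite therefore shows the machinery is wired correctly and can
recover a signal of this feature-level kind — not that the models reach
any particular accuracy on real regulation corpora, which would require
the external databases this package deliberately does not download.

## Test problem sizes

The suite's heavier checks run at sizes chosen to keep a full run on one
CPU comfortable: ten architectures train on a 400-pair noise-free fixture
(300 train / 100 validation) with training cut off once the loss-halving
criterion is met (ResNet50 capped at 10 epochs as a smoke test); CNN and
LSTMCNN — the two flagship models — are assessed on a 2000-pair fixture
(1600 train / 400 held out) for both loss reduction and held-out ranking;
corpus-scale network assembly runs the real alignment path over 1104- and
867-entity sets. The same code paths scale to larger corpora linearly in
pairs (networks quadratically in entities).

## Known limitations

- The NumPy engine is CPU-only and unbatched across devices; training at
  real-corpus scale (~3000 pairs, hundreds of epochs) is feasible but slow.
- Alignment scoring behind published identity values is not recoverable
  exactly; only thresholded behavior is contractual, and the scoring is
  exposed as configuration.
- The weighted-KS connectivity formula is a reconstruction of the standard
  two-set convention (the primary sources delegate it to external code).
- Fallback inference abstains on ties and dual perfect matches rather than
  guessing; its accuracy claims hold on called queries only.
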