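# smireg

**Predicting small-molecule-mediated regulation of miRNA expression.**

miRNAs sit at the center of many disease pathways, and a growing class of
therapeutic strategies works by nudging their expression with small
molecules. Knowing *whether a compound and a miRNA interact* is only half
the question — the actionable half is the **direction**: does the compound
up- or downregulate the miRNA? `smireg` is a library for that direction
question. It provides, end to end:

- **Pair encoding** — a compound–miRNA pair becomes a fixed 1396-length
  vector: 360 miRNA features (k-mer compositions NAC/DNC/TNC/QNC, the
  t-spaced pair composition CTSNAP, and the positional aveANF statistic)
  concatenated with 1036 compound features (1024-bit Morgan fingerprint,
  its density, structural counts, EState extremes, an EState-weighted
  surface-area term, LogP, molar refractivity). The vector reshapes to a
  37×37 matrix for image-style models or 37 timesteps of 37 features for
  sequence models.
- **Similarity networks** — complete graphs of global-alignment sequence
  identity (miRNA–miRNA) and Morgan-fingerprint Tanimoto similarity
  (compound–compound), with thresholded neighbor queries (> 0.8 and > 0.6).
- **Guilt-by-association augmentation** — unlabeled pairs inherit a class
  when a known relation of that class has both entities similar above
  threshold; the screen runs once per class and drops dual-supported
  candidates. A seeded seven-way split (Train / Test / TestSim /
  TestRptMIR / TestRptSM / TestUniqMIR / TestUniqSM) separates seen-pair,
  seen-entity and novel-entity generalization.
- **Twelve neural classifiers** — AlexNet, CNN, ConvMixer64, DSConv,
  LSTMCNN, MobileNetV2, ResNet18, ResNet50, SCAResNet18 on the matrix
  view; RNN, BiRNN, Seq2Seq on the sequence view — trained with Adam
  (lr 1e-3, batch 100) and early stopping on validation AUC, plus
  probability-averaging ensembles (all members, or greedy top selection).
  Models run on the package's own NumPy training engine (`smireg.nn`).
- **Similarity-network fallback** — for pairs with a novel compound or
  miRNA, a transparent inference rule over the training relations that
  returns UP, DOWN, or an explicit NO_CALL with a full evidence chain.
- **Connectivity scoring** — compound profiles (upregulation
  probabilities over a miRNA universe) scored against disease miRNA
  signatures with a weighted Kolmogorov–Smirnov statistic in [−1, 1];
  negative scores mark signature-reversing (therapeutic-candidate)
  compounds.
- **Metric suite** — ACC, bACC, precision, recall, F1, MCC, Jaccard at
  the strict 0.5 threshold, and rank-based AUC / step-interpolated AUCPR.

A seeded synthetic-data module generates chemically valid, label-planted
relation tables so the whole pipeline is testable without downloading any
external database. See `docs/methods.md` for the full model description
and conventions.

## Worked example

`examples/train_and_evaluate.py` generates 600 synthetic relations (5%
label noise), trains the CNN on 450 of them, and evaluates on the rest:

```text
trained CNN for 30 epochs; best validation AUC 0.917 at epoch 28
  acc       0.847
  bacc      0.844
  precision 0.864
  recall    0.803
  f1        0.832
  mcc       0.693
  jaccard   0.713
  auc       0.917
  aucpr     0.908
```

AUC/AUCPR are threshold-free ranking measures; the rest apply the strict
p_up > 0.5 call rule. Values near 1 mean the model recovered the planted
regulation rule from the encoded features despite the label noise. The
other scripts in `examples/` each demonstrate one capability the same
way: `encode_features.py` (pair geometry), `similarity_networks.py`
(networks and neighbor queries), `gba_augmentation.py` (augmentation and
the seven-way split), `network_inference.py` (novel-entity fallback with
evidence chains), `connectivity_scoring.py` (signature reversal vs
mimicry).

A thin CLI mirrors the library for shell use — `smireg fixtures | encode |
simnet | augment | split | train | predict | evaluate | infer-net |
connect` (see `smireg --help`).

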