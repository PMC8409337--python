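# methylfusion

Prediction of arginine methylation sites from protein sequence windows
with a dual-branch neural network that fuses a spatial (convolutional)
and a sequential (recurrent) view of the same peptide.

## The problem

Protein arginine methylation is a post-translational modification that
regulates chromatin state and gene expression; mapping methylation
sites *in vivo* (mass spectrometry, Western blotting, ChIP) is slow and
expensive. A practical alternative is sequence-based classification:
given a 19-residue peptide window with the candidate arginine (R) at
the centre, predict whether that arginine is methylated. This package
is aimed at computational biologists who want a complete, reproducible
window-classification pipeline — data model, models, training protocol,
class-imbalance handling, evaluation — that runs on a laptop CPU with
no framework dependencies (the neural network layers, backpropagation
and the Adam optimizer are implemented in NumPy and verified by
finite-difference gradient checks).

## The model

A window `x ∈ {0,…,20}^19` (20 standard residues + `X`) is embedded
per-residue into 21 dimensions, then read by two branches:

* **Sequential branch** — two stacked LSTM layers of 64 units (dropout
  0.5 after each); the final time-step's hidden state feeds a linear
  32-unit latent layer: `z_seq ∈ ℝ^32`.
* **Spatial branch** — the embedded window, viewed as a 1-channel
  19 × 21 image, passes through four convolution blocks of 64 channels
  (conv → 2D batch-norm → ReLU → dropout 0.5), with identity residual
  connections around blocks 2–4; the flattened maps feed a linear
  32-unit latent layer: `z_sp ∈ ℝ^32`.

The two latents are **fused by summation**, `z = z_seq + z_sp`, and a
2-unit head with softmax gives `P(methylated | x)`. Single-branch
ablation variants (CNN-only, LSTM-only) and a baseline multi-layer
perceptron (embedding → 399 → 2; 160,841 parameters) are built from
the same configuration. Training is Adam (lr 0.001) on two-class
cross-entropy; the checkpoint with the best validation Matthews
correlation coefficient (MCC) is kept. Evaluation reports Acc, F1,
Sens, Spec, MCC and ROC-AUC; because curated site data is naturally
~5:1 negative:positive, the package supports both balanced
(undersampled) and imbalanced training regimes.

## Worked example

Generate a synthetic benchmark (planted 4-position motif, strength
0.9), train the fusion model briefly, and evaluate:

```bash
methylfusion generate --seed 3 --out data/
methylfusion train --manifest data/manifest.yaml --model ssmfn_merged \
    --seed 0 --epochs 10 --out model.npz
methylfusion evaluate --checkpoint model.npz --manifest data/manifest.yaml --split test
```

which prints:

```
saved best checkpoint (epoch 2, val MCC 0.9967) to model.npz
Acc     F1      Sens    Spec    MCC     AUC
1.0000  1.0000  1.0000  1.0000  1.0000  1.0000
```

i.e. with the default strong signal the model recovers the planted
motif completely: every held-out true site is found (sensitivity 1.0),
no background window is called positive (specificity 1.0), and the
ranking is perfect (AUC 1.0). Weaker signals give graded performance —
the power curve in `scripts/acceptance.py` traces AUC from ≈0.5 at
strength 0 to ≈1.0 at strength 0.9. `methylfusion predict` then scores
new windows from a plain-text or FASTA file, one probability per line.

The library API mirrors the CLI: `synthetic.generate` →
`peptide_data.balance_dataset` → `training.train` →
`evaluation.evaluate`, with `experiments.run_experiment` /
`run_ablation` orchestrating full variant × evaluation-set × seed
grids.

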