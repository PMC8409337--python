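# Methods

## Task and data model

The unit of prediction is a 19-residue peptide window whose centre
(position 10, 1-based) is arginine, the candidate methylation site.
Windows are strings over a fixed 21-symbol alphabet: the 20 standard
amino-acid one-letter codes in alphabetical order, plus `X` (index 20)
for unknown or nonstandard residues. `X` is the read-time fallback for
any out-of-alphabet character (selenocysteine, pyrrolysine, `B`/`Z`
ambiguity codes); input is uppercased before validation. The fixed
alphabetical ordering makes integer encodings and checkpoints portable
across runs and machines. Positions are stored 0-based internally and
reported 1-based in messages.

Datasets are ordered, fully labelled window collections tagged with a
split (train/validation/test) and a balance flag. Duplicate windows
*within* a class are kept — deduplication would silently change split
sizes — but the same sequence labelled both positive and negative is
rejected as a contradiction. On disk a dataset is one plain-text file
per class per split (one window per line; negatives may be spread over
several files, as public window collections often ship them), bound
together by a small YAML manifest; FASTA is accepted with one 19-mer
per record.

Curated methylation data is naturally imbalanced, roughly 5:1
negative:positive. `balance_dataset` implements the standard remedy:
uniform random undersampling of the majority class, without
replacement, to the minority count, driven by an explicit seed. The
minority class is conserved exactly and kept order-stable.

## Architectures

All models share an embedding layer with one 21-dimensional vector per
alphabet symbol (vocabulary and embedding width both 21, so the
flattened window is 21 × 19 = 399 features).

**Fusion network.** The embedding output is consumed by two branches:

* *Sequential branch*: 2 unidirectional LSTM layers, 64 units each,
  inter-layer dropout 0.5 applied to layer outputs (not to the
  recurrent transitions); the last time-step of the second layer feeds
  a linear 32-unit latent layer.
* *Spatial branch*: the embedded window is a 1-channel image of
  height 19 (positions) × width 21 (embedding features). Block 1
  convolves with a 3 × 21 kernel spanning the full feature axis —
  the standard way a 2D convolution reads a sequence of embeddings,
  since offsets along the embedding axis carry no spatial meaning —
  yielding 64 × 19 × 1 maps. Blocks 2–4 use 3 × 1 kernels, stride 1,
  height padding 1, no pooling, so shapes are preserved throughout.
  Each block is convolution → 2D batch normalisation → ReLU → dropout
  0.5 (the conventional ordering). Identity residual connections wrap
  blocks 2–4; block 1 changes the channel count (1 → 64), which rules
  out an identity skip there and no projection shortcut is introduced.
  The flattened 64 × 19 maps feed a linear 32-unit latent layer.

The two 32-unit latents are linear (fusion happens pre-activation) and
are fused by exact element-wise summation; a 2-unit head emits raw
class scores, normalised to probabilities by softmax at evaluation
time. Summation fusion lets gradients from one branch shape the other
through the shared embedding, in contrast to ensembling two separate
models. Ablation variants reuse the identical embedding and branch
wiring with the surviving branch's latent feeding the head directly.

**Baseline perceptron.** Embedding → flatten (399) → 399-unit hidden
layer with ReLU → 2-unit head; 160,841 parameters
(441 + 159,600 + 800).

## Numerical core

No deep-learning framework is used: layers (embedding, dense, LSTM,
2D convolution via im2col, 2D batch-norm, inverted dropout) implement
explicit forward/backward passes in float32 NumPy, with Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Every backward pass is verified
against central finite differences in float64 in the test suite, layer
by layer and end-to-end through each full model. Batch-norm keeps
exponential running statistics (momentum 0.1, unbiased variance) so
eval-mode inference is a deterministic function of weights and input.
LSTM forget-gate biases start at 1; dense/LSTM weights use Glorot
initialisation, convolutions He initialisation.

## Training protocol

Two-class cross-entropy, Adam at learning rate 0.001, mini-batches of
64 reshuffled each epoch. The published schedule of 500 epochs is the
configuration default; benchmarks in this package pass explicit
shorter schedules (their sizes below). Each epoch logs the training
loss and a full validation metric report. Both the final-epoch weights
and the weights at the epoch with the best validation MCC are kept
(ties resolve to the earlier epoch); **all experiment and benchmark
paths evaluate the best-MCC checkpoint**, and result provenance
records this. MCC steers selection because it is the most informative
single confusion-matrix summary under class imbalance. No class
weighting, learning-rate schedule, weight decay or gradient clipping
is applied; imbalance is handled purely through dataset composition.

All randomness — initialisation, shuffling, dropout, balancing,
generation — descends from explicit integer seeds through
`numpy.random.SeedSequence`, so (data, config, seed) reproduce every
reported number bit-for-bit.

## Evaluation

Threshold metrics derive from TP/TN/FP/FN at the 0.5 probability
threshold (equivalently score argmax, positive on ties). Two F1 forms
are available and every report records which was used: the
conventional 2TP/(2TP+FP+FN) (the default) and the threat-score form
TP/(TP+FP+FN) that part of the site-prediction literature prints under
the name "F1". AUC is the Mann–Whitney statistic with tied scores
counting one half, identical to trapezoidal ROC integration; the test
suite checks it against exhaustive pair counting and against
scikit-learn. MCC returns 0 when a marginal vanishes (degenerate
predictors occur early in training); other metrics with empty
denominators are reported as not-applicable rather than fabricated
zeros.

## Synthetic benchmark generator

The generator emulates the *structure* of curated window data —
geometry, centre-R constraint, split layout, class ratio — not
methylation biology; no attempt is made to match real residue
composition or motif content. Windows are drawn i.i.d. from a
background distribution over the 20 standard residues (uniform by
default, configurable), the centre fixed to R. Class signal is planted
at 4 non-centre positions (default 3, 7, 12, 16): each class has a
fixed, distinct preferred residue per position, derived
deterministically from the seed, and a background draw is replaced by
it with probability `signal_strength`. At strength 0 the classes share
one distribution exactly. Generated strings are globally unique, so
splits are disjoint and no cross-class contradiction can arise; `X` is
never generated. A per-position categorical replacement was chosen
over a full position-weight matrix because it exposes a single
interpretable strength knob.

Two knobs extend the symmetric default:

* `signal_mode="positive_only"` plants the motif only in positives,
  leaving negatives as pure background — the realistic picture for
  enzyme-recognition motifs;
* `carrier_fraction` is the fraction of positive windows carrying the
  motif at all. Real methylation positives are heterogeneous (several
  methyltransferase families and motifs), so a single-motif generator
  with carrier fraction < 1 models the recognisable subpopulation;
  non-carriers are irreducibly indistinguishable from background,
  capping attainable sensitivity near the carrier fraction.

Because the generator is i.i.d. and single-motif, passing benchmarks
demonstrates that the pipeline recovers plantable signal and respects
its null — not that the models attain any particular accuracy on real
proteomes, whose homology structure, composition bias and motif
diversity the generator deliberately omits.

## Benchmarks and their problem sizes

* **Memorisation sanity**: the fusion model must reach training
  accuracy 1.0 on 8 strongly separable windows within 200 epochs.
* **Separability**: 2,000+2,000 training, 100+100 steering, 500+500
  held-out windows, strength 0.9, 30 epochs; held-out AUC is the
  headline number. The null control permutes the labels of *all three
  splits* before training and evaluation: the full-permutation null
  concentrates at AUC 0.5 by the CLT. (Permuting only training labels
  yields a heavy-tailed statistic — the network amplifies the chance
  label–motif imbalance left by the permutation, which correlates,
  with either sign, with intact test labels.)
* **Power curve**: median held-out AUC over 3 seeds at strengths 0,
  0.3, 0.6, 0.9, run at 300+300 training windows and 10 epochs so the
  curve sits away from the AUC ceiling where ordering is informative.
* **Distribution shift**: data from a 5:1 pool with
  `positive_only` signal, carrier fraction 0.7, strength 0.9; training
  on the balanced (1,000+1,000) subset, evaluation on the imbalanced
  validation split (400 positives, 2,000 negatives), 15 epochs,
  3 seeds. With a heterogeneous positive class the balanced-trained
  classifier shows high specificity and low sensitivity on the natural
  distribution — sensitivity is capped by the carrier fraction while
  background negatives remain easy to reject — reproducing the
  qualitative asymmetry reported for window classifiers evaluated on
  naturally imbalanced sets.

## Known limitations

* Convolution kernel geometry, batch size, loss and selection rule are
  not published for the original design; this package's choices
  (3 × 21 then 3 × 1 kernels, batch 64, cross-entropy, best-MCC
  selection) are documented defaults, all configurable.
* The NumPy core targets desk-scale problems (10³–10⁴ windows); there
  is no GPU path, and very deep schedules (the 500-epoch default on
  full-size data) take hours on one core.
* The generator cannot stand in for curated proteome data; see above.
* Training-mode batch-norm statistics make train-mode forward passes
  batch-composition-dependent (as usual); only eval mode is
  deterministic per-sample.
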