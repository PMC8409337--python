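"""Training protocol: Adam + cross-entropy over shuffled mini-batches.

The published protocol is Adam at learning rate 0.001 for 500 epochs.
The loss is two-class cross-entropy on the 2-neuron head.  Each epoch
logs the mean training loss and a full validation metric report; both
the final-epoch weights and the weights at the epoch with the best
validation MCC (ties broken toward the earlier epoch) are kept.  MCC
steers selection because it is the most informative single number on
class-imbalanced data.

Every source of randomness (weight initialisation, epoch shuffling,
dropout masks) descends deterministically from explicit integer seeds,
so a run is exactly reproducible from (data, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _rng
from .architectures import _Model, ModelConfig, load_checkpoint
from .evaluation import MetricReport, report_from_scores
from .nn import Adam, softmax, softmax_cross_entropy
from .peptide_data import ALPHABET, PeptideWindow, WindowDataset, encode

logger = logging.getLogger(__name__)


def set_global_seed(seed: int) -> None:
    """Seed the shared generator driving model construction defaults."""
    _rng.set_global_seed(seed)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_metrics: MetricReport


@dataclass
class TrainRun:
    """Everything produced by one training run."""

    config: ModelConfig
    seed: int
    history: list[EpochRecord]
    best_epoch: int
    best_state: dict[str, np.ndarray]
    final_state: dict[str, np.ndarray]

    @property
    def best_val_mcc(self) -> float:
        return self.history[self.best_epoch - 1].val_metrics.mcc

    @property
    def loss_history(self) -> list[float]:
        return [r.train_loss for r in self.history]


def _check_disjoint(train_set: WindowDataset, val_set: WindowDataset) -> None:
    overlap = {w.residues for w in train_set} & {w.residues for w in val_set}
    if overlap:
        raise ValueError(
            f"validation set shares {len(overlap)} window(s) with the training set"
        )


def train(
    model: _Model,
    train_set: WindowDataset,
    val_set: WindowDataset,
    config: ModelConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    log_file: str | Path | None = None,
) -> TrainRun:
    """Optimise ``model`` in place; return history and checkpoints.

    ``epochs`` overrides ``config.epochs`` (the published default of
    500 is rarely what a desk-scale run wants).  The input datasets are
    never mutated.
    """
    config = config or model.config
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    _check_disjoint(train_set, val_set)
    n_epochs = config.epochs if epochs is None else epochs

    train_batch = encode(train_set.windows)
    val_batch = encode(val_set.windows)

    root = np.random.SeedSequence(seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in root.spawn(2))

    optimizer = Adam(lr=config.learning_rate)
    n = len(train_batch)
    history: list[EpochRecord] = []
    best_epoch, best_mcc, best_state = 0, -np.inf, None
    log_fh = open(log_file, "w") if log_file else None

    try:
        for epoch in range(1, n_epochs + 1):
            perm = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = perm[start : start + config.batch_size]
                model.zero_grad()
                scores = model.forward(
                    train_batch.indices[idx], training=True, rng=dropout_rng
                )
                loss, dscores = softmax_cross_entropy(scores, train_batch.labels[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch starting at {start}"
                    )
                model.backward(dscores)
                optimizer.step(model.parameters(), model.gradients())
                epoch_loss += loss * len(idx)
            epoch_loss /= n

            val_scores = model.forward(val_batch.indices, training=False)
            val_probs = softmax(val_scores)[:, 1]
            val_metrics = report_from_scores(val_batch.labels, val_probs)
            history.append(EpochRecord(epoch, epoch_loss, val_metrics))
            if val_metrics.mcc > best_mcc:  # strict: ties keep the earlier epoch
                best_mcc = val_metrics.mcc
                best_epoch = epoch
                best_state = model.state_dict()
            line = (
                f"epoch={epoch} loss={epoch_loss:.6f} "
                f"val_acc={val_metrics.accuracy:.4f} val_mcc={val_metrics.mcc:.4f}"
            )
            logger.info(line)
            if log_fh:
                import json

                json.dump({"epoch": epoch, "loss": epoch_loss, **val_metrics.to_dict()}, log_fh)
                log_fh.write("\n")
    finally:
        if log_fh:
            log_fh.close()

    return TrainRun(
        config=config,
        seed=seed,
        history=history,
        best_epoch=best_epoch,
        best_state=best_state,
        final_state=model.state_dict(),
    )


def predict(
    model_or_checkpoint: _Model | str | Path,
    windows: list[PeptideWindow],
    alphabet=ALPHABET,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window positive-class probability and hard 0/1 label.

    Accepts a built model or a checkpoint path.  Predictions run in
    eval mode (deterministic); the hard label is 1 iff the normalised
    positive-class probability is at least 0.5.
    """
    if isinstance(model_or_checkpoint, (str, Path)):
        model, ckpt_alphabet = load_checkpoint(model_or_checkpoint)
        if ckpt_alphabet != alphabet:
            raise ValueError("checkpoint alphabet does not match the current alphabet")
    else:
        model = model_or_checkpoint
    batch = encode(windows, alphabet)
    scores = model.forward(batch.indices, training=False)
    probs = softmax(scores)[:, 1]
    return probs, (probs >= 0.5).astype(np.int64)
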