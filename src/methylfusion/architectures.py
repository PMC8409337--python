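"""Model architectures for arginine-methylation site prediction.

Three model families are built here:

* **SSMFN** (spatial & sequential methylation fusion network): a shared
  residue embedding feeds two branches — a 2-layer LSTM that reads the
  window as a sequence, and a 4-block residual CNN that reads it as a
  2D position × feature map.  Each branch ends in a linear 32-unit
  latent layer; the two latents are fused by element-wise summation and
  a 2-unit head scores methylated vs not.
* **Single-branch ablations** of SSMFN (CNN-only, LSTM-only): the same
  embedding and branch, with the branch latent feeding the head
  directly.
* **SMLP**: the baseline perceptron — embedding, flatten to
  21 × 19 = 399 features, a 399-unit hidden layer, a 2-unit head.

Convolution geometry.  The embedded window is a 1-channel image of
height 19 (positions) × width 21 (embedding features).  The first block
convolves with a 3 × 21 kernel spanning the full feature axis — the
standard way a 2D convolution reads a sequence-of-embeddings, since
offsets along the embedding axis carry no spatial meaning — producing
64 × 19 × 1 maps.  Blocks 2–4 use 3 × 1 kernels, stride 1, height
padding 1, no pooling, so shapes are preserved and identity residual
connections around blocks 2–4 type-check.  Block 1 changes the channel
count (1 → 64), which rules out an identity skip there.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from ._rng import get_rng
from .peptide_data import ALPHABET, EncodedBatch, ResidueAlphabet

VARIANTS = ("merged", "cnn_only", "lstm_only")
MODEL_KINDS = ("ssmfn_merged", "ssmfn_cnn_only", "ssmfn_lstm_only", "smlp")


@dataclass
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    Defaults are the published settings of the fusion network: Adam at
    learning rate 0.001 for 500 epochs; a 21-symbol embedding of
    dimension 21 over 19-residue windows (21 × 19 = 399 flattened
    features); two 64-unit LSTM layers, each followed by dropout 0.5;
    four 64-channel convolution blocks with ReLU, 2D batch
    normalisation and dropout 0.5; 32-unit branch latents; a 2-neuron
    output head.  Batch size and kernel geometry are not published and
    are this package's choices.
    """

    vocab_size: int = 21
    window_length: int = 19
    embedding_dim: int = 21
    lstm_hidden: int = 64
    lstm_layers: int = 2
    dropout_rate: float = 0.5
    cnn_channels: int = 64
    cnn_blocks: int = 4
    #: kernel height applies to every block; the width applies to blocks
    #: 2+ (block 1 always spans the full embedding axis).
    conv_kernel: tuple[int, int] = (3, 1)
    latent_dim: int = 32
    output_dim: int = 2
    learning_rate: float = 0.001
    epochs: int = 500
    optimizer_name: str = "Adam"
    batch_size: int = 64

    def validate(self) -> None:
        counts = {
            "vocab_size": self.vocab_size,
            "window_length": self.window_length,
            "embedding_dim": self.embedding_dim,
            "lstm_hidden": self.lstm_hidden,
            "lstm_layers": self.lstm_layers,
            "cnn_channels": self.cnn_channels,
            "cnn_blocks": self.cnn_blocks,
            "latent_dim": self.latent_dim,
            "output_dim": self.output_dim,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        kh, kw = self.conv_kernel
        if kh % 2 != 1 or kh <= 0 or kw <= 0:
            raise ValueError("conv kernel height must be a positive odd number")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_kernel"] = list(self.conv_kernel)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "conv_kernel" in d:
            d["conv_kernel"] = tuple(d["conv_kernel"])
        return cls(**d)


def fuse(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fuse two branch latents by element-wise summation."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"latent shape mismatch: {a.shape} vs {b.shape}")
    return a + b


class _Model:
    """Shared bookkeeping: named layers, parameter access, state dicts."""

    kind: str
    config: ModelConfig

    def __init__(self):
        self._layers: list[tuple[str, nn.Layer]] = []

    def _add(self, name: str, layer: nn.Layer) -> nn.Layer:
        self._layers.append((name, layer))
        return layer

    def named_layers(self):
        return list(self._layers)

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": p for ln, layer in self._layers for pn, p in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": g for ln, layer in self._layers for pn, g in layer.grads.items()}

    def zero_grad(self) -> None:
        for _, layer in self._layers:
            layer.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.copy() for k, v in self.parameters().items()}
        for ln, layer in self._layers:
            for bn, b in layer.buffers.items():
                state[f"buffer.{ln}.{bn}"] = b.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        loaded = set()
        for key, value in state.items():
            scope, name = key.split(".", 1)
            if scope == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in state")
                np.copyto(params[name], value)
                loaded.add(key)
            elif scope == "buffer":
                ln, bn = name.rsplit(".", 1)
                layer = dict(self._layers)[ln]
                np.copyto(layer.buffers[bn], value)
                loaded.add(key)
        missing = {f"param.{k}" for k in params} - loaded
        if missing:
            raise KeyError(f"state is missing parameters: {sorted(missing)[:5]}")

    def forward(self, indices, *, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dscores: np.ndarray) -> None:
        raise NotImplementedError


class SSMFN(_Model):
    """Fusion network or one of its single-branch ablation variants."""

    def __init__(self, config: ModelConfig, variant: str = "merged", rng=None):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
        config.validate()
        rng = get_rng(rng)
        self.config = config
        self.variant = variant
        self.kind = f"ssmfn_{variant}"
        self.has_lstm = variant in ("merged", "lstm_only")
        self.has_cnn = variant in ("merged", "cnn_only")
        c = config

        self.embedding = self._add("embedding", nn.Embedding(c.vocab_size, c.embedding_dim, rng))

        if self.has_lstm:
            self.lstms = []
            self.lstm_drops = []
            in_size = c.embedding_dim
            for i in range(c.lstm_layers):
                self.lstms.append(self._add(f"lstm{i}", nn.LSTM(in_size, c.lstm_hidden, rng)))
                self.lstm_drops.append(self._add(f"lstm_drop{i}", nn.Dropout(c.dropout_rate)))
                in_size = c.lstm_hidden
            self.lstm_latent = self._add("lstm_latent", nn.Dense(c.lstm_hidden, c.latent_dim, rng))

        if self.has_cnn:
            kh, kw = c.conv_kernel
            self.convs, self.bns, self.relus, self.cnn_drops = [], [], [], []
            for i in range(c.cnn_blocks):
                if i == 0:
                    conv = nn.Conv2d(1, c.cnn_channels, (kh, c.embedding_dim), ((kh - 1) // 2, 0), rng)
                else:
                    conv = nn.Conv2d(
                        c.cnn_channels, c.cnn_channels, (kh, kw), ((kh - 1) // 2, (kw - 1) // 2), rng
                    )
                self.convs.append(self._add(f"conv{i}", conv))
                self.bns.append(self._add(f"bn{i}", nn.BatchNorm2d(c.cnn_channels)))
                self.relus.append(self._add(f"relu{i}", nn.ReLU()))
                self.cnn_drops.append(self._add(f"cnn_drop{i}", nn.Dropout(c.dropout_rate)))
            flat = c.cnn_channels * c.window_length
            self.cnn_latent = self._add("cnn_latent", nn.Dense(flat, c.latent_dim, rng))

        if self.has_lstm and self.has_cnn:
            if self.lstm_latent.params["W"].shape[1] != self.cnn_latent.params["W"].shape[1]:
                raise ValueError("branch latent dimensions differ; fusion requires equality")
        self.head = self._add("head", nn.Dense(c.latent_dim, c.output_dim, rng))

    # -- forward / backward ------------------------------------------------

    def _lstm_forward(self, emb, training, rng):
        h = emb
        for lstm, drop in zip(self.lstms, self.lstm_drops):
            h = drop.forward(lstm.forward(h), training=training, rng=rng)
        # sequence summary = final time-step of the last layer
        return self.lstm_latent.forward(h[:, -1])

    def _cnn_forward(self, emb, training, rng):
        x = emb[:, None, :, :]  # (N, 1, 19, D)
        for i in range(self.config.cnn_blocks):
            y = self.convs[i].forward(x, training=training)
            y = self.bns[i].forward(y, training=training)
            y = self.relus[i].forward(y)
            y = self.cnn_drops[i].forward(y, training=training, rng=rng)
            x = y if i == 0 else x + y  # identity residual once channels match
        self._cnn_out_shape = x.shape
        return self.cnn_latent.forward(x.reshape(x.shape[0], -1))

    def forward(self, indices, *, training=False, rng=None):
        emb = self.embedding.forward(indices)
        if self.variant == "merged":
            latent = fuse(
                self._lstm_forward(emb, training, rng), self._cnn_forward(emb, training, rng)
            )
        elif self.variant == "lstm_only":
            latent = self._lstm_forward(emb, training, rng)
        else:
            latent = self._cnn_forward(emb, training, rng)
        return self.head.forward(latent)

    def _lstm_backward(self, dlatent, emb_shape):
        dlast = self.lstm_latent.backward(dlatent)
        n, t, _ = emb_shape
        dh = np.zeros((n, t, self.config.lstm_hidden), dtype=dlast.dtype)
        dh[:, -1] = dlast
        for lstm, drop in zip(reversed(self.lstms), reversed(self.lstm_drops)):
            dh = lstm.backward(drop.backward(dh))
        return dh

    def _cnn_backward(self, dlatent):
        dflat = self.cnn_latent.backward(dlatent)
        dx = dflat.reshape(self._cnn_out_shape)
        for i in reversed(range(self.config.cnn_blocks)):
            dy = self.cnn_drops[i].backward(dx)
            dy = self.relus[i].backward(dy)
            dy = self.bns[i].backward(dy)
            dy = self.convs[i].backward(dy)
            dx = dy if i == 0 else dx + dy  # gradient also flows through the skip
        return dx[:, 0]  # drop the channel axis back to (N, 19, D)

    def backward(self, dscores):
        dlatent = self.head.backward(dscores)
        demb = None
        if self.has_lstm:
            demb = self._lstm_backward(dlatent, self.embedding._idx.shape + (self.config.embedding_dim,))
        if self.has_cnn:
            dc = self._cnn_backward(dlatent)
            demb = dc if demb is None else demb + dc
        self.embedding.backward(demb)


class SMLP(_Model):
    """Baseline multi-layer perceptron: embedding → 399 → 2."""

    kind = "smlp"

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        config.validate()
        rng = get_rng(rng)
        self.config = config
        c = config
        flat = c.embedding_dim * c.window_length
        self.embedding = self._add("embedding", nn.Embedding(c.vocab_size, c.embedding_dim, rng))
        self.hidden = self._add("hidden", nn.Dense(flat, flat, rng))
        self.relu = self._add("relu", nn.ReLU())
        self.head = self._add("head", nn.Dense(flat, c.output_dim, rng))

    def forward(self, indices, *, training=False, rng=None):
        emb = self.embedding.forward(indices)
        self._emb_shape = emb.shape
        h = self.relu.forward(self.hidden.forward(emb.reshape(emb.shape[0], -1)))
        return self.head.forward(h)

    def backward(self, dscores):
        dh = self.relu.backward(self.head.backward(dscores))
        dflat = self.hidden.backward(dh)
        self.embedding.backward(dflat.reshape(self._emb_shape))


def build_ssmfn(config: ModelConfig | None = None, variant: str = "merged", rng=None) -> SSMFN:
    """Construct the fusion network or a single-branch ablation variant."""
    return SSMFN(config or ModelConfig(), variant=variant, rng=rng)


def build_smlp(config: ModelConfig | None = None, rng=None) -> SMLP:
    """Construct the baseline perceptron."""
    return SMLP(config or ModelConfig(), rng=rng)


def build_model(kind: str, config: ModelConfig | None = None, rng=None) -> _Model:
    """Build any model by its kind tag (``ssmfn_*`` or ``smlp``)."""
    if kind == "smlp":
        return build_smlp(config, rng=rng)
    if kind.startswith("ssmfn_") and kind[len("ssmfn_"):] in VARIANTS:
        return build_ssmfn(config, variant=kind[len("ssmfn_"):], rng=rng)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def count_parameters(model: _Model) -> int:
    """Total number of trainable scalar weights."""
    return int(sum(p.size for p in model.parameters().values()))


def forward(model: _Model, batch, mode: str = "eval", rng=None) -> np.ndarray:
    """Run a forward pass and return the raw (n × 2) score matrix.

    ``mode='eval'`` disables dropout and uses batch-norm running
    statistics, so the output is a deterministic function of (weights,
    input).  Class probabilities follow by softmax-normalising the two
    scores.
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    indices = batch.indices if isinstance(batch, EncodedBatch) else np.asarray(batch)
    training = mode == "train"
    if training and rng is None:
        rng = get_rng()
    scores = model.forward(indices, training=training, rng=rng)
    if not np.isfinite(scores).all():
        raise FloatingPointError("non-finite scores in forward pass")
    return scores


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(model: _Model, path: str | Path, alphabet: ResidueAlphabet = ALPHABET) -> None:
    """Write a self-describing checkpoint (weights + config + alphabet)."""
    meta = {
        "kind": model.kind,
        "config": model.config.to_dict(),
        "alphabet": alphabet.symbols,
    }
    meta_arr = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), __meta__=meta_arr, **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[_Model, ResidueAlphabet]:
    """Rebuild a model (and its alphabet) from :func:`save_checkpoint` output."""
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = ModelConfig.from_dict(meta["config"])
    model = build_model(meta["kind"], config, rng=0)
    model.load_state_dict(state)
    return model, ResidueAlphabet(meta["alphabet"])
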