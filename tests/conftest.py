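import numpy as np
import pytest

from methylfusion.architectures import ModelConfig
from methylfusion.peptide_data import CENTER_INDEX, WINDOW_LENGTH, PeptideWindow, WindowDataset

STANDARD = "ACDEFGHIKLMNPQRSTVWY"


def make_window(residues_or_rng, label=None):
    """Build a valid window from a full string or randomly from an rng."""
    if isinstance(residues_or_rng, str):
        return PeptideWindow(residues=residues_or_rng, label=label)
    rng = residues_or_rng
    chars = [STANDARD[i] for i in rng.integers(0, 20, WINDOW_LENGTH)]
    chars[CENTER_INDEX] = "R"
    return PeptideWindow(residues="".join(chars), label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Reduced architecture for fast unit tests (same wiring, fewer units)."""
    return ModelConfig(
        embedding_dim=8,
        lstm_hidden=8,
        lstm_layers=2,
        cnn_channels=8,
        cnn_blocks=2,
        latent_dim=4,
        batch_size=4,
        epochs=5,
    )


def separable_toy_dataset(n_per_class=4, split="train"):
    """Strongly separable toy windows: positives are A-rich, negatives Y-rich."""
    windows = []
    for i in range(n_per_class):
        pos = list("A" * WINDOW_LENGTH)
        neg = list("Y" * WINDOW_LENGTH)
        pos[CENTER_INDEX] = neg[CENTER_INDEX] = "R"
        # vary one off-centre residue so windows are distinct
        pos[i] = "C"
        neg[i] = "D"
        windows.append(PeptideWindow("".join(pos), label=1))
        windows.append(PeptideWindow("".join(neg), label=0))
    return WindowDataset(windows=windows, split=split, balanced=True)


@pytest.fixture
def toy_train():
    return separable_toy_dataset(4, "train")


@pytest.fixture
def toy_val():
    ds = separable_toy_dataset(4, "validation")
    # shift the varied position so validation windows differ from training
    windows = []
    for w in ds.windows:
        chars = list(w.residues)
        base = "A" if w.label == 1 else "Y"
        idx = next(i for i, c in enumerate(chars) if c in "CD")
        chars[idx] = base
        chars[idx + 12] = "C" if w.label == 1 else "D"
        windows.append(PeptideWindow("".join(chars), label=w.label))
    return WindowDataset(windows=windows, split="validation", balanced=True)
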