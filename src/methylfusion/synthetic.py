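"""Synthetic 19-mer benchmark data with planted position-specific signal.

The generator emulates the *structure* of curated methylation window
data — fixed 19-residue windows with a centre arginine, disjoint
positive/negative sets per split, a configurable negative:positive
ratio (5:1 in the natural training distribution, 1:1 after balancing) —
not its biology.  Class signal is planted at a few non-centre
positions: each class gets a fixed preferred residue per signal
position (derived deterministically from the seed), and a background
draw at such a position is replaced by the preferred residue with
probability ``signal_strength``.  At strength 0 the two classes are
drawn from the identical distribution, giving an exact null.

Two optional knobs extend the symmetric default:

* ``signal_mode='positive_only'`` plants the motif only in positive
  windows, leaving negatives as pure background — the realistic
  picture for enzyme recognition motifs.
* ``carrier_fraction`` is the fraction of windows of a signalled class
  that carry the motif at all.  Real methylation positives are
  heterogeneous (several methyltransferase families, several motifs),
  so a single-motif generator with carrier_fraction < 1 models the
  recognisable subpopulation; non-carrier positives are irreducibly
  indistinguishable from background, capping attainable sensitivity at
  roughly the carrier fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .peptide_data import (
    ALPHABET,
    CENTER_INDEX,
    WINDOW_LENGTH,
    PeptideWindow,
    WindowDataset,
    write_windows,
)

#: Index of arginine in the shared alphabet.
_R_INDEX = ALPHABET.index_of("R")
#: Number of standard residues (signal and background never emit 'X').
_N_STANDARD = 20

SIGNAL_MODES = ("contrastive", "positive_only")
SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark dataset (counts are per class)."""

    n_positive: int = 2000
    n_negative: int = 2000
    signal_positions: tuple[int, ...] = (3, 7, 12, 16)
    signal_strength: float = 0.9
    background_frequencies: tuple[float, ...] | None = None
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    signal_mode: str = "contrastive"
    carrier_fraction: float = 1.0

    def validate(self) -> None:
        problems = []
        if self.n_positive <= 0 or self.n_negative <= 0:
            problems.append("class counts must be positive")
        if CENTER_INDEX in self.signal_positions:
            problems.append(f"signal_positions must not include the centre ({CENTER_INDEX})")
        if len(set(self.signal_positions)) != len(self.signal_positions):
            problems.append("signal_positions must be distinct")
        if any(not 0 <= p < WINDOW_LENGTH for p in self.signal_positions):
            problems.append(f"signal_positions must lie in [0, {WINDOW_LENGTH})")
        if not 0.0 <= self.signal_strength <= 1.0:
            problems.append("signal_strength must be in [0, 1]")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            problems.append("carrier_fraction must be in [0, 1]")
        if self.signal_mode not in SIGNAL_MODES:
            problems.append(f"signal_mode must be one of {SIGNAL_MODES}")
        fr = self.split_fractions
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            problems.append("split_fractions must be three positive numbers summing to 1")
        if self.background_frequencies is not None:
            bg = np.asarray(self.background_frequencies, dtype=float)
            if bg.shape != (_N_STANDARD,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
                problems.append(
                    f"background_frequencies must be {_N_STANDARD} non-negative "
                    "numbers summing to 1"
                )
        if problems:
            raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    def split_counts(self, n: int) -> tuple[int, int, int]:
        """Per-split counts for one class of size ``n`` (rounded fractions)."""
        n_train = round(self.split_fractions[0] * n)
        n_val = round(self.split_fractions[1] * n)
        n_test = n - n_train - n_val
        if min(n_train, n_val, n_test) <= 0:
            raise ValueError(f"split of {n} windows leaves an empty split")
        return n_train, n_val, n_test


def preferred_residues(spec: SyntheticSpec) -> dict[int, dict[int, str]]:
    """Class-specific preferred residue per signal position.

    Derived deterministically from the seed; the two classes always get
    *distinct* residues at each signal position.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    table: dict[int, dict[int, str]] = {0: {}, 1: {}}
    for pos in sorted(spec.signal_positions):
        pos_res, neg_res = rng.choice(_N_STANDARD, size=2, replace=False)
        table[1][pos] = ALPHABET.symbol_of(int(pos_res))
        table[0][pos] = ALPHABET.symbol_of(int(neg_res))
    return table


def _background(spec: SyntheticSpec):
    if spec.background_frequencies is None:
        return np.full(_N_STANDARD, 1.0 / _N_STANDARD)
    return np.asarray(spec.background_frequencies, dtype=float)


def _plant_matrix(
    idx: np.ndarray, label: int, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised planting over an (n, 19) index matrix (in place)."""
    if spec.signal_mode == "positive_only" and label == 0:
        return idx
    prefs = preferred_residues(spec)[label]
    n = idx.shape[0]
    carriers = rng.random(n) < spec.carrier_fraction
    for pos in sorted(spec.signal_positions):
        replace = carriers & (rng.random(n) < spec.signal_strength)
        idx[replace, pos] = ALPHABET.index_of(prefs[pos])
    return idx


def plant_signal(
    residues: str, class_label: int, spec: SyntheticSpec, rng: np.random.Generator
) -> PeptideWindow:
    """Plant class signal into one background-sampled window."""
    spec.validate()
    idx = np.array([[ALPHABET.index_of(c) for c in residues]], dtype=np.int64)
    idx = _plant_matrix(idx, class_label, spec, rng)
    return PeptideWindow(
        residues="".join(ALPHABET.symbol_of(int(i)) for i in idx[0]), label=class_label
    )


def _sample_class(
    n: int, label: int, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    bg = _background(spec)
    idx = rng.choice(_N_STANDARD, size=(n, WINDOW_LENGTH), p=bg)
    idx[:, CENTER_INDEX] = _R_INDEX
    return _plant_matrix(idx, label, spec, rng)


def generate(spec: SyntheticSpec) -> dict[str, WindowDataset]:
    """Generate train/validation/test datasets from ``spec``.

    Identical seeds give identical datasets.  All residue strings are
    globally unique (duplicates are resampled), so splits are disjoint
    and no window is labelled both positive and negative.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])

    per_class: dict[int, np.ndarray] = {}
    seen: set[str] = set()
    for label, n in ((1, spec.n_positive), (0, spec.n_negative)):
        idx = _sample_class(n, label, spec, rng)
        # resample any window colliding with an already drawn one; the
        # sequence space is ~20^14 so this loop essentially never runs
        while True:
            dup_rows = []
            fresh: set[str] = set()
            for i, row in enumerate(idx):
                s = "".join(ALPHABET.symbol_of(int(v)) for v in row)
                if s in seen or s in fresh:
                    dup_rows.append(i)
                else:
                    fresh.add(s)
            if not dup_rows:
                seen |= fresh
                break
            idx[dup_rows] = _sample_class(len(dup_rows), label, spec, rng)
        per_class[label] = idx

    datasets: dict[str, WindowDataset] = {}
    pos_counts = spec.split_counts(spec.n_positive)
    neg_counts = spec.split_counts(spec.n_negative)
    for s, split in enumerate(SPLITS):
        windows: list[PeptideWindow] = []
        for label, counts in ((1, pos_counts), (0, neg_counts)):
            start = sum(counts[:s])
            block = per_class[label][start : start + counts[s]]
            for row in block:
                windows.append(
                    PeptideWindow(
                        residues="".join(ALPHABET.symbol_of(int(i)) for i in row),
                        label=label,
                    )
                )
        datasets[split] = WindowDataset(
            windows=windows, split=split, balanced=pos_counts[s] == neg_counts[s]
        )
    return datasets


def imbalance_profile(spec: SyntheticSpec) -> dict[str, float]:
    """Negative:positive ratio per split (and overall)."""
    spec.validate()
    if spec.n_positive == 0:
        raise ValueError("ratio undefined with zero positives")
    pos_counts = spec.split_counts(spec.n_positive)
    neg_counts = spec.split_counts(spec.n_negative)
    profile = {
        split: neg_counts[i] / pos_counts[i] for i, split in enumerate(SPLITS)
    }
    profile["overall"] = spec.n_negative / spec.n_positive
    return profile


def write_supplementary_layout(
    datasets: dict[str, WindowDataset],
    outdir: str | Path,
    n_negative_train_files: int = 5,
) -> Path:
    """Write the six-file plain-text layout plus a loadable manifest.

    Training negatives are split round-robin across
    ``n_negative_train_files`` files (mirroring data releases that ship
    negatives as multiple files); every other class/split is one file.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format": "plain", "splits": {}}
    for split, ds in datasets.items():
        positives = [w for w in ds if w.label == 1]
        negatives = [w for w in ds if w.label == 0]
        pos_name = f"{split}_positive.txt"
        write_windows(outdir / pos_name, positives)
        neg_names = []
        if split == "train" and n_negative_train_files > 1:
            k = n_negative_train_files
            for j in range(k):
                name = f"{split}_negative_{j + 1}.txt"
                write_windows(outdir / name, negatives[j::k])
                neg_names.append(name)
        else:
            name = f"{split}_negative.txt"
            write_windows(outdir / name, negatives)
            neg_names.append(name)
        manifest["splits"][split] = {"positive": [pos_name], "negative": neg_names}
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def write_tsv(dataset: WindowDataset, path: str | Path) -> None:
    """Single-file labelled TSV: ``sequence<TAB>label`` per line."""
    Path(path).write_text("".join(f"{w.residues}\t{w.label}\n" for w in dataset))
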