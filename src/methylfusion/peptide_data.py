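"""Peptide-window data model and I/O.

The unit of data is a 19-residue peptide window centred on an arginine
(R), the candidate methylation site.  Windows are stored as plain
uppercase strings over a 21-symbol alphabet: the 20 standard amino-acid
one-letter codes plus ``X`` for unknown/nonstandard residues.

Datasets are ordered, labelled collections of windows tagged with a
split (train / validation / test) and a balance flag.  On disk a dataset
is a handful of plain-text files (one window per line) or FASTA files
(one 19-mer per record), grouped by class — mirroring the common
supplementary-data layout of one positive file plus several negative
files per split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 19
#: 0-based index of the centre residue ("10th" in 1-based reporting).
CENTER_INDEX = 9

_STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_RESIDUE = "X"


class ResidueAlphabet:
    """Fixed, ordered 21-symbol residue alphabet.

    The 20 standard residues come first in alphabetical order; ``X``
    (unknown/nonstandard) is last with index 20.  The ordering is frozen
    so that integer encodings and model checkpoints are portable.
    """

    def __init__(self, symbols: str = _STANDARD_RESIDUES + UNKNOWN_RESIDUE):
        symbols = str(symbols)
        if len(symbols) != 21 or len(set(symbols)) != 21:
            raise ValueError("alphabet must contain exactly 21 distinct symbols")
        if not all(s.isalpha() and s.isupper() for s in symbols):
            raise ValueError("alphabet symbols must be uppercase letters")
        missing = set(_STANDARD_RESIDUES) - set(symbols)
        if missing:
            raise ValueError(f"missing standard residues: {sorted(missing)}")
        self.symbols: str = symbols
        self._index = {s: i for i, s in enumerate(symbols)}

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def index_of(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"residue {symbol!r} is not in the alphabet") from None

    def symbol_of(self, index: int) -> str:
        return self.symbols[index]

    def __eq__(self, other) -> bool:
        return isinstance(other, ResidueAlphabet) and other.symbols == self.symbols

    def __repr__(self) -> str:
        return f"ResidueAlphabet({self.symbols!r})"


#: Module-level default alphabet; every component shares this instance.
ALPHABET = ResidueAlphabet()


@dataclass(frozen=True)
class PeptideWindow:
    """One 19-residue window with the candidate arginine at the centre."""

    residues: str
    label: int | None = None
    source_id: str | None = None

    def __post_init__(self):
        violations = validate_window(self.residues)
        if violations:
            raise ValueError(
                f"invalid peptide window {self.residues!r}: " + "; ".join(violations)
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def validate_window(residues: str, alphabet: ResidueAlphabet = ALPHABET) -> list[str]:
    """Check the three window invariants; return the violated ones.

    Returns an empty list when the window is valid.  Violations are
    reported by name so callers can decide whether to raise:

    * ``wrong length`` — not exactly 19 characters;
    * ``center not arginine`` — position 10 (1-based) is not ``R``;
    * ``invalid residue`` — a character outside the 21-symbol alphabet.
    """
    violations: list[str] = []
    if len(residues) != WINDOW_LENGTH:
        violations.append(f"wrong length: expected {WINDOW_LENGTH}, got {len(residues)}")
        return violations
    if residues[CENTER_INDEX] != "R":
        violations.append(
            f"center not arginine: position {CENTER_INDEX + 1} is {residues[CENTER_INDEX]!r}"
        )
    bad = sorted({c for c in residues if c not in alphabet})
    if bad:
        violations.append(f"invalid residue: {bad}")
    return violations


@dataclass
class WindowDataset:
    """Ordered, fully labelled window collection for one split."""

    windows: list[PeptideWindow]
    split: str
    balanced: bool = False

    VALID_SPLITS = ("train", "validation", "test")

    def __post_init__(self):
        if self.split not in self.VALID_SPLITS:
            raise ValueError(f"split must be one of {self.VALID_SPLITS}, got {self.split!r}")
        for w in self.windows:
            if w.label is None:
                raise ValueError("all windows in a dataset must be labelled")
        if self.balanced and self.n_positive != self.n_negative:
            raise ValueError(
                f"balanced flag set but counts differ: "
                f"{self.n_positive} positive vs {self.n_negative} negative"
            )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def n_positive(self) -> int:
        return sum(1 for w in self.windows if w.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for w in self.windows if w.label == 0)

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=np.int64)


@dataclass(frozen=True)
class EncodedBatch:
    """Integer-encoded windows ready for the embedding layer.

    ``indices`` has shape (n_windows, 19) with entries in [0, 20];
    decoding through the alphabet reproduces the residue strings exactly.
    """

    indices: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if self.indices.ndim != 2 or self.indices.shape[1] != WINDOW_LENGTH:
            raise ValueError(f"indices must have shape (n, {WINDOW_LENGTH})")
        if self.labels.shape != (self.indices.shape[0],):
            raise ValueError("labels length must match number of windows")

    def __len__(self) -> int:
        return self.indices.shape[0]


def encode(
    windows: Sequence[PeptideWindow], alphabet: ResidueAlphabet = ALPHABET
) -> EncodedBatch:
    """Map windows to an integer index matrix (one row per window)."""
    n = len(windows)
    indices = np.empty((n, WINDOW_LENGTH), dtype=np.int64)
    labels = np.empty(n, dtype=np.int64)
    for i, w in enumerate(windows):
        indices[i] = [alphabet.index_of(c) for c in w.residues]
        labels[i] = -1 if w.label is None else w.label
    return EncodedBatch(indices=indices, labels=labels)


def decode(indices: np.ndarray, alphabet: ResidueAlphabet = ALPHABET) -> list[str]:
    """Inverse of :func:`encode` on the residue strings."""
    return ["".join(alphabet.symbol_of(int(i)) for i in row) for row in np.atleast_2d(indices)]


class WindowFormatError(ValueError):
    """A window in an input file failed length/centre validation."""


class ClassContradictionError(ValueError):
    """The same residue string appears with both labels."""


def _clean_sequence(raw: str, where: str) -> tuple[str, int]:
    """Uppercase and map out-of-alphabet characters to ``X``.

    Returns the cleaned sequence and the number of substituted residues.
    """
    seq = raw.strip().upper()
    n_mapped = 0
    if any(c not in ALPHABET for c in seq):
        cleaned = []
        for c in seq:
            if c in ALPHABET:
                cleaned.append(c)
            else:
                cleaned.append(UNKNOWN_RESIDUE)
                n_mapped += 1
        seq = "".join(cleaned)
        logger.warning("%s: mapped %d out-of-alphabet residue(s) to 'X'", where, n_mapped)
    return seq, n_mapped


def read_windows(
    path: str | Path, format: str = "plain", label: int | None = None
) -> list[PeptideWindow]:
    """Read one file of 19-mer windows, all carrying ``label``.

    ``plain`` is one window per line (blank lines ignored); ``fasta`` is
    one window per record, with the record id kept as ``source_id``.
    Lowercase input is uppercased; characters outside the alphabet are
    mapped to ``X`` with a logged warning.  Any window failing
    length/centre validation raises :class:`WindowFormatError` naming
    the offending line or record.
    """
    path = Path(path)
    windows: list[PeptideWindow] = []
    if format == "plain":
        entries: Iterable[tuple[str, str, str | None]] = (
            (line, f"{path.name}:line {i}", None)
            for i, line in enumerate(path.read_text().splitlines(), start=1)
            if line.strip()
        )
    elif format == "fasta":
        from Bio import SeqIO

        entries = (
            (str(rec.seq), f"{path.name}:record {i}", rec.id)
            for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1)
        )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'plain' or 'fasta')")

    for raw, where, source_id in entries:
        seq, _ = _clean_sequence(raw, where)
        violations = validate_window(seq)
        if violations:
            raise WindowFormatError(f"{where}: " + "; ".join(violations))
        windows.append(PeptideWindow(residues=seq, label=label, source_id=source_id))
    return windows


def write_windows(
    path: str | Path, windows: Sequence[PeptideWindow], format: str = "plain"
) -> None:
    """Write windows to disk; inverse of :func:`read_windows`."""
    path = Path(path)
    if format == "plain":
        path.write_text("".join(w.residues + "\n" for w in windows))
    elif format == "fasta":
        with path.open("w") as fh:
            for i, w in enumerate(windows):
                fh.write(f">{w.source_id or f'window_{i}'}\n{w.residues}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def assemble_dataset(
    positive_files: Sequence[str | Path],
    negative_files: Sequence[str | Path],
    split: str,
    format: str = "plain",
) -> WindowDataset:
    """Concatenate per-class window files into one labelled dataset.

    Positives come first, then negatives, each in file order.  The
    balanced flag is set iff class counts are equal.  A residue string
    appearing in both classes is a labelling contradiction and raises
    :class:`ClassContradictionError`.
    """
    if not positive_files or not negative_files:
        raise ValueError("need at least one file per class")
    positives: list[PeptideWindow] = []
    for f in positive_files:
        positives.extend(read_windows(f, format=format, label=1))
    negatives: list[PeptideWindow] = []
    for f in negative_files:
        negatives.extend(read_windows(f, format=format, label=0))

    overlap = {w.residues for w in positives} & {w.residues for w in negatives}
    if overlap:
        shown = sorted(overlap)[:10]
        raise ClassContradictionError(
            f"{len(overlap)} window(s) labelled both positive and negative, e.g. {shown}"
        )
    logger.info(
        "assembled %s split: %d positive + %d negative windows",
        split, len(positives), len(negatives),
    )
    return WindowDataset(
        windows=positives + negatives,
        split=split,
        balanced=len(positives) == len(negatives),
    )


def balance_dataset(dataset: WindowDataset, seed: int) -> WindowDataset:
    """Down-sample the majority class to the minority count.

    Sampling is uniform without replacement, driven entirely by
    ``seed``; the minority class is kept whole and the original window
    order is preserved.  An already balanced dataset is returned
    unchanged.
    """
    n_pos, n_neg = dataset.n_positive, dataset.n_negative
    if n_pos == n_neg:
        logger.info("dataset already balanced (%d per class); returning unchanged", n_pos)
        return dataset
    majority_label = 0 if n_neg > n_pos else 1
    n_keep = min(n_pos, n_neg)

    majority_idx = [i for i, w in enumerate(dataset.windows) if w.label == majority_label]
    rng = np.random.default_rng(seed)
    kept = set(rng.choice(len(majority_idx), size=n_keep, replace=False).tolist())
    kept_idx = {majority_idx[j] for j in kept}

    windows = [
        w
        for i, w in enumerate(dataset.windows)
        if w.label != majority_label or i in kept_idx
    ]
    return WindowDataset(windows=windows, split=dataset.split, balanced=True)


def load_manifest(path: str | Path) -> dict[str, WindowDataset]:
    """Load a dataset manifest (YAML) into per-split datasets.

    Manifest layout::

        format: plain            # or fasta
        splits:
          train:
            positive: [pos_train.txt]
            negative: [neg_train_1.txt, neg_train_2.txt]
          validation: {...}
          test: {...}

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    fmt = doc.get("format", "plain")
    base = path.parent
    datasets: dict[str, WindowDataset] = {}
    for split, files in doc["splits"].items():
        datasets[split] = assemble_dataset(
            [base / f for f in files["positive"]],
            [base / f for f in files["negative"]],
            split=split,
            format=fmt,
        )
    return datasets
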