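"""Process-wide random generator shared by model construction and training."""

from __future__ import annotations

import numpy as np

_GLOBAL: np.random.Generator = np.random.default_rng(0)


def set_global_seed(seed: int) -> np.random.Generator:
    """Reset the shared generator; returns it for convenience."""
    global _GLOBAL
    _GLOBAL = np.random.default_rng(seed)
    return _GLOBAL


def get_rng(rng: np.random.Generator | int | None = None) -> np.random.Generator:
    """Resolve an rng argument: None → shared generator, int → fresh seed."""
    if rng is None:
        return _GLOBAL
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng
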