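"""Softmax and two-class cross-entropy with analytic gradient."""

from __future__ import annotations

import numpy as np


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-shift for numerical stability."""
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``labels`` under softmax(scores).

    Returns ``(loss, dscores)`` where ``dscores`` is the gradient of the
    mean loss with respect to the raw scores.
    """
    n = scores.shape[0]
    p = softmax(scores)
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dscores = p.copy()
    dscores[np.arange(n), labels] -= 1.0
    return loss, dscores / n
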