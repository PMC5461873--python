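"""Numerical primitives shared across the package.

All probability vectors are plain one-dimensional numpy arrays in linear
space; logarithms are taken at use sites with a fixed floor so that the
log of an impossible state is a large negative number (-16 nats) rather
than -inf.  This keeps prediction errors bounded when likelihood tensors
contain exact zeros.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

#: additive floor inside logarithms: log(p + EPS_LOG)
EPS_LOG = float(np.exp(-16.0))


def log_stable(x) -> np.ndarray:
    """Elementwise log with an exp(-16) floor (bounded for zeros)."""
    return np.log(np.asarray(x, dtype=float) + EPS_LOG)


def softmax(v, axis: int = -1) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    m = np.max(v, axis=axis, keepdims=True)
    e = np.exp(v - m)
    return e / np.sum(e, axis=axis, keepdims=True)


def normalize(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    s = p.sum()
    if s <= 0:
        raise ValueError("cannot normalize a non-positive vector")
    return p / s


def entropy_nats(p) -> float:
    """Shannon entropy in nats; exact at zeros (0 log 0 = 0)."""
    p = np.asarray(p, dtype=float)
    return float(-xlogy(p, p).sum())


def one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def project(table: np.ndarray, beliefs) -> np.ndarray:
    """Generalised dot product: contract every state axis of ``table``
    (axes 1..N; axis 0 is the outcome axis) with one belief vector per
    factor, returning a vector over axis 0."""
    out = np.asarray(table, dtype=float)
    for b in reversed(list(beliefs)):
        out = out @ np.asarray(b, dtype=float)
    return out


def marginal_over_factor(table: np.ndarray, weight, beliefs, keep: int) -> np.ndarray:
    """Marginal message of a likelihood-style tensor to one factor.

    Contracts axis 0 with ``weight`` (an outcome vector, possibly
    probabilistic) and every other state axis with the corresponding
    belief vector, leaving a vector over the states of factor ``keep``.
    """
    out = np.tensordot(np.asarray(weight, dtype=float), np.asarray(table, dtype=float), axes=(0, 0))
    for ax in reversed(range(len(beliefs))):
        if ax == keep:
            continue
        out = np.tensordot(out, np.asarray(beliefs[ax], dtype=float), axes=(ax, 0))
    return out
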