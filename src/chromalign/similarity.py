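"""Pairwise mass-spectral similarity with a Gaussian retention-time penalty.

The similarity between two peaks p = (m_p, i_p, t_p) and q = (m_q, i_q, t_q)
is

    f(p, q) = s(i_p, i_q) * exp(-(t_p - t_q)^2 / (2 D^2))

where s is a spectral similarity (cosine by default) and D is the expected
retention-time tolerance in seconds.  The Gaussian factor ranges from 1 at
perfect RT correspondence toward 0 for large RT differences and acts as a
soft elution-order prior.  A threshold T on the penalty lets callers skip
the (comparatively costly) spectral term altogether for hopeless pairs:
such pairs yield the :data:`BELOW_THRESHOLD` sentinel so downstream code
can count how much of the search space was pruned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "BELOW_THRESHOLD",
    "SIMILARITY_KINDS",
    "SimilarityConfig",
    "rt_penalty",
    "spectral_similarity",
    "peak_similarity",
    "pairwise_matrix",
    "prepare_vectors",
]

SIMILARITY_KINDS = ("cosine", "dot", "euclidean", "linCorr", "rankCorr")


class _BelowThreshold:
    """Sentinel for a peak pair pruned by the RT-penalty threshold."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "BELOW_THRESHOLD"


BELOW_THRESHOLD = _BelowThreshold()


@dataclass(frozen=True)
class SimilarityConfig:
    """Configuration of the peak/scan similarity function.

    kind : one of cosine, dot, euclidean (negated distance), linCorr
        (Pearson), rankCorr (Spearman)
    use_rt_penalty : apply the Gaussian RT factor
    D : RT tolerance width in seconds (must be > 0 when the penalty is on)
    T : threshold in [0, 1] on the penalty below which a pair is pruned
    """

    kind: str = "cosine"
    use_rt_penalty: bool = True
    D: float = 2.5
    T: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if self.use_rt_penalty and self.D <= 0:
            raise ValueError("D must be positive when the RT penalty is used")
        if not 0.0 <= self.T <= 1.0:
            raise ValueError("T must lie in [0, 1]")


def rt_penalty(t_p: float, t_q: float, D: float):
    """Gaussian retention-time penalty exp(-(t_p - t_q)^2 / (2 D^2)).

    Symmetric in its first two arguments; equals 1 iff t_p == t_q and
    decays monotonically in |t_p - t_q|.  Accepts arrays broadcast over
    t_p/t_q.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    dt = np.subtract(t_p, t_q)
    return np.exp(-(dt * dt) / (2.0 * D * D))


def spectral_similarity(u, v, kind: str = "cosine") -> float:
    """Similarity between two equal-length intensity vectors.

    Degenerate inputs (all-zero vectors for cosine, constant vectors for
    the correlation kinds) yield 0: a noise-free flat spectrum carries no
    information, and 0 keeps NaNs out of downstream argmax computations.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if kind == "dot":
        return float(u @ v)
    if kind == "euclidean":
        return -float(np.linalg.norm(u - v))
    if kind == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return 0.0
        return float(u @ v / (nu * nv))
    if kind == "linCorr":
        return _centered_cosine(u - u.mean(), v - v.mean())
    if kind == "rankCorr":
        ru = rankdata(u) - (u.size + 1) / 2.0
        rv = rankdata(v) - (v.size + 1) / 2.0
        return _centered_cosine(ru, rv)
    raise ValueError(f"unknown similarity kind {kind!r}")


def _centered_cosine(cu: np.ndarray, cv: np.ndarray) -> float:
    nu, nv = np.linalg.norm(cu), np.linalg.norm(cv)
    if nu == 0 or nv == 0:
        return 0.0
    return float(cu @ cv / (nu * nv))


class SimilarityCounter:
    """Counts spectral-similarity evaluations and pruned pairs."""

    def __init__(self) -> None:
        self.evaluated = 0
        self.pruned = 0


def peak_similarity(p, q, cfg: SimilarityConfig, counter: SimilarityCounter | None = None):
    """f(p, q): spectral similarity times the Gaussian RT penalty.

    When the penalty falls below ``cfg.T`` the spectral term is never
    evaluated and :data:`BELOW_THRESHOLD` is returned.
    """
    if cfg.use_rt_penalty:
        pen = float(rt_penalty(p.rt, q.rt, cfg.D))
        if pen < cfg.T:
            if counter is not None:
                counter.pruned += 1
            return BELOW_THRESHOLD
        if counter is not None:
            counter.evaluated += 1
        return spectral_similarity(p.intensities, q.intensities, cfg.kind) * pen
    if counter is not None:
        counter.evaluated += 1
    return spectral_similarity(p.intensities, q.intensities, cfg.kind)


# ---------------------------------------------------------------------------
# Vectorized helpers for the inner loops of BIPACE and DTW
# ---------------------------------------------------------------------------

def prepare_vectors(X: np.ndarray, kind: str) -> np.ndarray:
    """Pre-transform a stack of spectra (rows) so that pairwise similarity
    of the given kind reduces to a plain dot product, where possible.

    cosine -> rows scaled to unit norm (zero rows stay zero);
    linCorr -> rows centered then unit-normalized;
    rankCorr -> rows rank-transformed, centered, unit-normalized;
    dot / euclidean -> returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    if kind == "dot" or kind == "euclidean":
        return X
    if kind == "linCorr":
        X = X - X.mean(axis=1, keepdims=True)
    elif kind == "rankCorr":
        X = rankdata(X, axis=1).astype(float)
        X = X - X.mean(axis=1, keepdims=True)
    elif kind != "cosine":
        raise ValueError(f"unknown similarity kind {kind!r}")
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, X / np.where(norms == 0, 1.0, norms), 0.0)
    return out


def pairwise_matrix(U: np.ndarray, V: np.ndarray, kind: str) -> np.ndarray:
    """All-pairs spectral similarities between the rows of U and V.

    ``U`` and ``V`` must already have been passed through
    :func:`prepare_vectors` with the same ``kind``.
    """
    if kind == "euclidean":
        uu = np.sum(U * U, axis=1)[:, None]
        vv = np.sum(V * V, axis=1)[None, :]
        sq = np.maximum(uu + vv - 2.0 * (U @ V.T), 0.0)
        return -np.sqrt(sq)
    return U @ V.T
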