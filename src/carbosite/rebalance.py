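"""Two-way rebalancing core: optimal sampling scale and undersamplers.

With m minority (positive) and M majority (negative) samples, the two
classes meet at a common size s chosen to minimise the sum of the
oversampling ratio s/m and the undersampling ratio M/s; the minimiser
is s = sqrt(m * M), rounded to the nearest integer.

Negative selection is attention-based and runs in two stages. A
sample's attention diagonal — its row-softmax-normalised cosine
self-similarity — is low when the sample resembles many others
(representative) and high when it is an outlier. Stage 1 keeps the
ceil((s + M) / 2) negatives with the *smallest* diagonals among the
negatives alone (most representative). Stage 2 recomputes attention
over the kept negatives pooled with all positives and keeps the s
negatives with the *largest* diagonals — those least similar to the
pool, hence least positive-like. Both stages are deterministic; ties
break toward the lower original index.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .containers import FeatureMatrix

__all__ = [
    "AttentionMatrix",
    "RebalancePlan",
    "optimal_scale",
    "attention_scores",
    "attention_undersample",
    "random_undersample",
    "smote_oversample",
]


def _rows(data) -> np.ndarray:
    X = data.X if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array of sample rows")
    return X


@dataclass
class AttentionMatrix:
    """Row-stochastic attention values; entry (i, j) in [0, 1], rows sum to 1."""

    A: np.ndarray

    @property
    def diag(self) -> np.ndarray:
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError("diagonal only defined for square attention")
        return np.diag(self.A)


@dataclass
class RebalancePlan:
    """Outcome of planning one two-way rebalance.

    Indices are 0-based positions into the negative-class rows.
    """

    m: int
    M: int
    s: int
    stage1_keep: list[int]
    final_keep: list[int]
    n_synthesize: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RebalancePlan":
        with open(path) as fh:
            return cls(**json.load(fh))


def optimal_scale(m: int, M: int) -> int:
    """Common class size minimising s/m + M/s: round(sqrt(m*M)), clamped to [m, M]."""
    if m <= 0 or M <= 0:
        raise ValueError(f"class counts must be positive, got m={m}, M={M}")
    if m > M:
        raise ValueError(f"expected m <= M, got m={m}, M={M}")
    s = math.floor(math.sqrt(m * M) + 0.5)  # nearest int, half away from zero
    return min(max(s, m), M)


def attention_scores(queries, keys) -> AttentionMatrix:
    """Softmax-normalised cosine similarities between query and key rows."""
    Q, K = _rows(queries), _rows(keys)
    if Q.shape[1] != K.shape[1]:
        raise ValueError(f"dimension mismatch: {Q.shape[1]} vs {K.shape[1]}")
    for name, X in (("query", Q), ("key", K)):
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            i = int(np.argmax(norms == 0))
            raise ValueError(f"{name} row {i} has zero norm; cosine undefined")
    cos = (Q / np.linalg.norm(Q, axis=1, keepdims=True)) @ (
        K / np.linalg.norm(K, axis=1, keepdims=True)
    ).T
    z = cos - cos.max(axis=1, keepdims=True)
    e = np.exp(z)
    return AttentionMatrix(A=e / e.sum(axis=1, keepdims=True))


def _bottom_k(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest values, ties toward the lower index."""
    order = np.lexsort((np.arange(values.size), values))
    return np.sort(order[:k])


def attention_undersample(neg, pos, s: int) -> RebalancePlan:
    """Two-stage attention selection of s negatives (see module docstring)."""
    Xn, Xp = _rows(neg), _rows(pos)
    M, m = Xn.shape[0], Xp.shape[0]
    if Xn.shape[1] != Xp.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: negatives {Xn.shape[1]}, positives {Xp.shape[1]}"
        )
    if not 1 <= s <= M:
        raise ValueError(f"s must be in [1, {M}], got {s}")

    # Stage 1: most representative negatives (smallest self-attention).
    d1 = attention_scores(Xn, Xn).diag
    k1 = math.ceil((s + M) / 2)
    stage1 = _bottom_k(d1, k1)

    # Stage 2: among kept negatives pooled with positives, keep the s
    # with the largest self-attention (least positive-like).
    pool = np.vstack([Xn[stage1], Xp])
    d2 = attention_scores(pool, pool).diag[: stage1.size]
    top = _bottom_k(-d2, s)  # ties still resolve toward the lower index
    final = np.sort(stage1[top])

    return RebalancePlan(
        m=m,
        M=M,
        s=s,
        stage1_keep=stage1.tolist(),
        final_keep=final.tolist(),
        n_synthesize=max(0, s - m),
    )


def random_undersample(neg, s: int, seed: int) -> np.ndarray:
    """Uniform sample of s negative indices without replacement."""
    Xn = _rows(neg)
    if not 1 <= s <= Xn.shape[0]:
        raise ValueError(f"s must be in [1, {Xn.shape[0]}], got {s}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(Xn.shape[0], size=s, replace=False))


def smote_oversample(pos, n_new: int, k_neighbors: int = 5, seed: int = 0) -> np.ndarray:
    """Standard SMOTE interpolation: each synthetic point sits on the segment
    between a minority sample and one of its k nearest minority neighbours."""
    Xp = _rows(pos)
    n = Xp.shape[0]
    if n_new < 0:
        raise ValueError("n_new must be non-negative")
    if k_neighbors < 1 or n <= k_neighbors:
        raise ValueError(
            f"need more than k_neighbors={k_neighbors} positives, got {n}"
        )
    if n_new == 0:
        return np.empty((0, Xp.shape[1]))
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xp)
    _, idx = nn.kneighbors(Xp)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n, size=n_new)
    nbr = idx[base, rng.integers(1, k_neighbors + 1, size=n_new)]
    gap = rng.uniform(size=(n_new, 1))
    return Xp[base] + gap * (Xp[nbr] - Xp[base])
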