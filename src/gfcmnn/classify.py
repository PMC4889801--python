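"""Similarity-based decision rule over network outputs.

A trained network emits one activation per category.  The decision rule
treats the (clipped) output vector as a fuzzy set over the categories and
scores it against each candidate category's one-hot target pattern with the
fuzzy Jaccard index |A ∩ B| / |A ∪ B|, taking min/max as the fuzzy
intersection/union and the sum of memberships as the cardinality.  The
predicted category is the argmax similarity, with the lowest index winning
ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, InvalidParamsError

__all__ = [
    "SimilarityProfile",
    "AccuracyReport",
    "fuzzy_jaccard",
    "category_similarities",
    "accuracy",
]


@dataclass
class SimilarityProfile:
    """Per-category similarities in [0,1] and the argmax category (1-based)."""

    similarities: np.ndarray
    predicted: int


@dataclass
class AccuracyReport:
    """True/wrong counts and the accuracy percentage 100 * T / (T + N)."""

    T: int
    N: int

    @property
    def acc(self) -> float:
        return accuracy(self.T, self.N)


def fuzzy_jaccard(A, B) -> float:
    """Fuzzy Jaccard similarity: sum of minima over sum of maxima.

    Inputs are clipped to [0, 1] first.  Two all-zero vectors compare as
    identical (similarity 1, the empty-set convention).
    """
    A = np.clip(np.asarray(A, dtype=float), 0.0, 1.0)
    B = np.clip(np.asarray(B, dtype=float), 0.0, 1.0)
    if A.shape != B.shape:
        raise DimensionError(f"shape mismatch: {A.shape} vs {B.shape}")
    denom = float(np.sum(np.maximum(A, B)))
    if denom == 0.0:
        return 1.0
    return float(np.sum(np.minimum(A, B))) / denom


def category_similarities(O, n_o: int) -> SimilarityProfile:
    """Similarity of a network output vector to each one-hot category pattern.

    The candidate category c's target set is the indicator at c; the tested
    set is the output clipped to [0, 1].  Prediction is the smallest index
    attaining the maximum similarity.
    """
    O = np.asarray(O, dtype=float)
    if O.shape != (n_o,):
        raise DimensionError(f"output length {O.shape} != ({n_o},)")
    B = np.clip(O, 0.0, 1.0)
    total = float(B.sum())
    sims = np.empty(n_o)
    for c in range(n_o):
        # one-hot A: min-sum = B_c, max-sum = 1 + total - B_c
        sims[c] = B[c] / (1.0 + total - B[c])
    predicted = int(np.argmax(sims)) + 1
    return SimilarityProfile(similarities=sims, predicted=predicted)


def accuracy(T: int, N: int) -> float:
    """Classification accuracy 100 * T / (T + N) as a percentage."""
    if T < 0 or N < 0:
        raise InvalidParamsError("counts must be nonnegative")
    if T + N == 0:
        raise InvalidParamsError("empty evaluation: T + N must be >= 1")
    return 100.0 * T / (T + N)
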