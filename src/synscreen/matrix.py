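"""Symmetric interaction-score matrices with observation masks.

The central in-memory container of the package: a symmetric ``n x n``
matrix of pairwise interaction scores together with a boolean mask
marking which entries have actually been measured.  The diagonal
(self-interaction) is never part of the screenable set, and only the
strict upper triangle counts as distinct pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class InteractionMatrix:
    """Partially observed symmetric matrix of pairwise interaction scores.

    Parameters
    ----------
    values
        ``(n, n)`` float array of interaction scores.  Entries outside
        the observed set may hold any placeholder (conventionally NaN
        or 0); they are ignored wherever ``mask`` is False.
    mask
        ``(n, n)`` boolean array; True marks observed (measured) entries.
        Must be symmetric with a False diagonal.
    target_ids
        Ordered labels for the n targets (drugs or genes).
    """

    values: np.ndarray
    mask: np.ndarray
    target_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("values and mask must be square and of equal shape")
        if not self.target_ids:
            self.target_ids = [f"t{i}" for i in range(n)]
        if len(self.target_ids) != n:
            raise ValueError("target_ids length does not match matrix size")
        if len(set(self.target_ids)) != n:
            raise ValueError("duplicate target ids")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("observation mask must be symmetric")
        if np.any(np.diag(self.mask)):
            raise ValueError("diagonal entries cannot be observed (self-pairs are not screened)")
        obs = self.values[self.mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError("observed entries must be finite")
        v = np.where(self.mask, self.values, 0.0)
        if not np.allclose(v, v.T, atol=1e-9, rtol=0.0):
            raise ValueError("observed values must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of screenable pairs, n(n-1)/2."""
        return self.n * (self.n - 1) // 2

    @property
    def n_observed_pairs(self) -> int:
        return int(np.count_nonzero(np.triu(self.mask, k=1)))

    def observed_pairs(self) -> np.ndarray:
        """(m, 2) array of observed (i, j) index pairs with i < j."""
        i, j = np.nonzero(np.triu(self.mask, k=1))
        return np.column_stack([i, j])

    def untested_pairs(self) -> np.ndarray:
        """(m, 2) array of unobserved (i, j) index pairs with i < j."""
        i, j = np.nonzero(np.triu(~self.mask, k=1))
        return np.column_stack([i, j])

    def zero_filled(self) -> np.ndarray:
        """Dense copy with unobserved entries (and diagonal) set to 0."""
        return np.where(self.mask, self.values, 0.0)

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(
            self.values.copy(), self.mask.copy(), list(self.target_ids)
        )


def from_pairs(
    n: int,
    pairs: np.ndarray,
    scores: np.ndarray,
    target_ids: list[str] | None = None,
) -> InteractionMatrix:
    """Build an InteractionMatrix from a list of measured (i, j) pairs."""
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for (i, j), s in zip(np.asarray(pairs, dtype=int), np.asarray(scores, dtype=float)):
        if i == j:
            raise ValueError("self-pairs cannot be measured")
        values[i, j] = values[j, i] = s
        mask[i, j] = mask[j, i] = True
    return InteractionMatrix(values, mask, target_ids or [])
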