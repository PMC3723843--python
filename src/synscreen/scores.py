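"""Interaction scores and synergy calling.

The interaction score of a target pair is the Bliss deviation
``xi_ij = w_ij - w_i * w_j`` between the measured combination phenotype
and the product of single-perturbation phenotypes expected under
independence.  Negative scores indicate synergy.  Synergies are called
by thresholding the score distribution a number of standard deviations
below its mean.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import InteractionMatrix

__all__ = ["bliss_score", "sd_threshold", "call_synergies", "DegenerateScoresWarning"]


class DegenerateScoresWarning(UserWarning):
    """Raised when a score collection has zero spread."""


def bliss_score(w_i, w_j, w_ij):
    """Bliss interaction score ``w_ij - w_i * w_j``.

    Parameters are relative phenotypes (e.g. viability ratios) after
    single and pairwise perturbation; all must be finite and
    non-negative.  Accepts scalars or broadcastable arrays.  Under Bliss
    independence the score is 0; negative values indicate synergy.
    """
    w_i = np.asarray(w_i, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    w_ij = np.asarray(w_ij, dtype=float)
    for w in (w_i, w_j, w_ij):
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("phenotype ratios must be finite and non-negative")
    out = w_ij - w_i * w_j
    return float(out) if out.ndim == 0 else out


def sd_threshold(scores, c: float = 3.0) -> float:
    """Synergy-calling threshold ``mean(scores) - c * sd(scores)``.

    ``c`` is typically chosen by inspecting a QQ plot of the scores
    against a normal distribution; c = 3 is a common choice for dense
    genetic-interaction data, c = 1.5 for small drug panels.  A score is
    called synergistic when it falls strictly below the threshold.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    scores = scores[np.isfinite(scores)]
    if scores.size < 2:
        raise ValueError("need at least 2 finite scores to set a threshold")
    if c <= 0:
        raise ValueError("c must be positive")
    sd = scores.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(scores.mean())):
        sd = 0.0
    if sd == 0.0:
        warnings.warn(
            "score collection has zero spread; threshold degenerates to the constant",
            DegenerateScoresWarning,
        )
    return float(scores.mean() - c * sd)


def call_synergies(M: InteractionMatrix, threshold: float) -> np.ndarray:
    """Boolean synergy mask: True where an observed score < threshold.

    Strict inequality; unobserved entries and the diagonal are False.
    The result is symmetric for the (symmetric) input.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = np.zeros_like(M.mask)
    out[M.mask] = M.values[M.mask] < threshold
    return out
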