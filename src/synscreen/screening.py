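"""Adaptive screening protocols.

Four screening modes over a system of n targets (n(n-1)/2 candidate
pairs):

* ``brute`` — uniform random order, the baseline with efficiency
  eta = 1;
* ``oracle`` — tests the true synergies first, the eta = 1/prevalence
  upper bound;
* ``algorithm1`` — propensity-based sampling only: repeatedly
  re-estimate per-target propensities from the synergies found so far
  and draw the next batch with probability proportional to
  pi_i * pi_j;
* ``algorithm2`` — the full protocol: propensity batches alternate
  with prediction-driven batches, in which the observed scores are
  completed by cyclic projections and the most synergistic predicted
  untested pairs are tested greedily.  After each prediction batch its
  hit rate is compared with that of the preceding propensity batch;
  prediction mode continues while it is strictly winning, otherwise
  the screen falls back to propensity sampling.

The measurement "oracle" is a score provider callable: in simulation it
looks up the ground-truth matrix, in a retrospective screen it replays
recorded measurements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import propensity as prop
from .completion import CompletionConfig, SimilarityMatrix, pocs_complete
from .matrix import InteractionMatrix
from .metrics import (
    EfficiencyEstimate,
    ScreenTrace,
    TraceRecord,
    discovery_curve,
    estimate_eta,
)
from .simdata import SyntheticSystem

__all__ = ["ScreenConfig", "ScreenState", "hit_rate", "propensity_batch",
           "prediction_batch", "run_screen"]

logger = logging.getLogger(__name__)

F_CHECKPOINTS = (0.05, 0.1, 0.2, 0.3, 0.5)


@dataclass
class ScreenConfig:
    """Tuning parameters of a screen.

    Batch sizes are fractions of all pairs (default 1% each for the
    propensity and prediction batches); ``f_max`` stops the screen once
    that fraction of pairs has been tested.  ``rank_extreme_abs``
    switches the prediction-batch ranking from most-negative (most
    synergistic) to largest absolute predicted score.
    """

    mode: str = "algorithm2"
    batch_fraction_propensity: float = 0.01
    batch_fraction_prediction: float = 0.01
    prior_a: float = 0.5
    prior_b: float | None = None  # None -> number of targets
    f_max: float = 0.5
    seed: int = 0
    completion: CompletionConfig = field(default_factory=CompletionConfig)
    rank_extreme_abs: bool = False
    cv_lambdas: bool = False  # cross-validate (lambda2, lambda3) at the first prediction batch

    def __post_init__(self):
        if self.mode not in ("algorithm1", "algorithm2", "brute", "oracle"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for frac in (self.batch_fraction_propensity, self.batch_fraction_prediction):
            if not 0 < frac <= 1:
                raise ValueError("batch fractions must be in (0, 1]")
        if not 0 < self.f_max <= 1:
            raise ValueError("f_max must be in (0, 1]")


@dataclass
class ScreenState:
    """Mutable state of a running screen."""

    measured: InteractionMatrix
    propensities: prop.PropensityState
    trace: ScreenTrace
    threshold: float
    h_prop: float = float("nan")
    h_pred: float = float("nan")
    exhausted: bool = False
    _cached_lambdas: tuple[float, float] | None = None


def hit_rate(records) -> float:
    """Synergies per experiment within a batch window."""
    records = list(records)
    if not records:
        raise ValueError("empty window")
    return sum(r.synergy for r in records) / len(records)


def _test_pairs(state: ScreenState, pairs: np.ndarray, mode: str, score_provider) -> list[TraceRecord]:
    """Measure a batch of pairs, updating matrix and trace."""
    records = []
    for i, j in pairs:
        score = float(score_provider(int(i), int(j)))
        synergy = bool(score < state.threshold)
        state.measured.values[i, j] = state.measured.values[j, i] = score
        state.measured.mask[i, j] = state.measured.mask[j, i] = True
        rec = TraceRecord(len(state.trace), mode, int(i), int(j), score, synergy)
        state.trace.append(rec)
        records.append(rec)
    return records


def propensity_batch(
    state: ScreenState,
    config: ScreenConfig,
    score_provider,
    rng: np.random.Generator,
    mode: str = "propensity",
) -> list[TraceRecord]:
    """One propensity-sampling batch (estimate pi, draw, measure).

    With no prior findings the propensities are the (uniform) prior
    mean, so the first batch is a uniform random draw.  Returns the
    batch's trace records; a no-op (with ``state.exhausted`` set) when
    no untested pairs remain.
    """
    untested = state.measured.untested_pairs()
    if len(untested) == 0:
        state.exhausted = True
        return []
    n_a = max(1, int(round(config.batch_fraction_propensity * state.trace.total_pairs)))
    k = min(n_a, len(untested))
    probs = prop.pair_probabilities(state.propensities, untested)
    batch = prop.sample_pairs(untested, probs, k, rng)
    records = _test_pairs(state, batch, mode, score_provider)
    state.propensities = prop.update_state(
        state.propensities, batch, np.array([r.synergy for r in records])
    )
    state.h_prop = hit_rate(records)
    return records


def prediction_batch(
    state: ScreenState,
    Q: SimilarityMatrix | None,
    config: ScreenConfig,
    score_provider,
    rng: np.random.Generator,
) -> list[TraceRecord]:
    """One prediction-driven batch: complete the matrix, test the
    most extreme predicted untested pairs.

    Ranking is by most negative predicted score (most synergistic)
    unless ``config.rank_extreme_abs``.  On completion failure the
    batch falls back to propensity sampling with a logged warning.
    """
    untested = state.measured.untested_pairs()
    if len(untested) == 0:
        state.exhausted = True
        return []
    n_b = max(1, int(round(config.batch_fraction_prediction * state.trace.total_pairs)))
    k = min(n_b, len(untested))
    try:
        cfg = config.completion
        if Q is None and cfg.lambda3 > 0:
            cfg = replace(cfg, lambda3=0.0)
        if config.cv_lambdas and state._cached_lambdas is None:
            from .completion import cross_validate
            state._cached_lambdas = cross_validate(state.measured, Q, cfg, rng)
        if state._cached_lambdas is not None:
            lam2, lam3 = state._cached_lambdas
            cfg = replace(cfg, lambda2=lam2, lambda3=lam3)
        result = pocs_complete(state.measured, Q, cfg)
    except Exception as exc:  # completion failure -> propensity fallback
        logger.warning("matrix completion failed (%s); falling back to propensity", exc)
        warnings.warn(f"matrix completion failed ({exc}); propensity fallback")
        return propensity_batch(state, config, score_provider, rng)
    pred = result.M_hat[untested[:, 0], untested[:, 1]]
    key = -np.abs(pred) if config.rank_extreme_abs else pred
    order = np.argsort(key, kind="stable")
    batch = untested[order[:k]]
    records = _test_pairs(state, batch, "prediction", score_provider)
    # prediction findings also feed the propensity counts
    state.propensities = prop.update_state(
        state.propensities, batch, np.array([r.synergy for r in records])
    )
    state.h_pred = hit_rate(records)
    return records


def _brute_trace(config, rng, state, score_provider):
    order = rng.permutation(state.measured.untested_pairs())
    stop = int(np.ceil(config.f_max * state.trace.total_pairs))
    _test_pairs(state, order[:stop], "brute", score_provider)


def _oracle_trace(system: SyntheticSystem, config, rng, state, score_provider):
    pairs = state.measured.untested_pairs()
    true_syn = system.synergy_mask()[pairs[:, 0], pairs[:, 1]]
    syn_pairs = rng.permutation(pairs[true_syn])
    rest = rng.permutation(pairs[~true_syn])
    order = np.vstack([syn_pairs, rest]) if len(rest) else syn_pairs
    stop = int(np.ceil(config.f_max * state.trace.total_pairs))
    _test_pairs(state, order[:stop], "oracle", score_provider)


def run_screen(
    config: ScreenConfig,
    system: SyntheticSystem,
    Q: SimilarityMatrix | None = None,
) -> tuple[ScreenTrace, EfficiencyEstimate]:
    """Run a full simulated screen and estimate its efficiency.

    The ground-truth matrix of ``system`` serves as the measurement
    provider and its calibrated threshold as the synergy call.  The
    adaptive modes start with a propensity batch (completion needs
    observed entries); algorithm2 then alternates batches per the
    hit-rate rule: prediction mode is entered/kept only while its last
    batch's hit rate strictly exceeds the last propensity batch's.
    The screen stops at ``f >= f_max`` or exhaustion.  Fully
    deterministic given ``config.seed``.
    """
    n = system.n
    if system.n_synergies < 1:
        raise ValueError("system contains no synergies")
    rng = np.random.default_rng(config.seed)
    b = config.prior_b if config.prior_b is not None else float(n)
    state = ScreenState(
        measured=InteractionMatrix(
            np.zeros((n, n)), np.zeros((n, n), dtype=bool), list(system.target_ids)
        ),
        propensities=prop.PropensityState.cold(n, config.prior_a, b),
        trace=ScreenTrace(
            total_pairs=system.n_pairs,
            total_synergies=system.n_synergies,
            target_ids=list(system.target_ids),
        ),
        threshold=system.threshold,
    )

    def score_provider(i: int, j: int) -> float:
        return system.M_true[i, j]

    if config.mode == "brute":
        _brute_trace(config, rng, state, score_provider)
    elif config.mode == "oracle":
        _oracle_trace(system, config, rng, state, score_provider)
    else:
        in_prediction = False
        while state.trace.fraction_tested < config.f_max and not state.exhausted:
            if config.mode == "algorithm1" or not in_prediction:
                records = propensity_batch(state, config, score_provider, rng)
            else:
                records = prediction_batch(state, Q, config, score_provider, rng)
            if not records:
                break
            logger.info(
                "batch mode=%s hit_rate=%.3f f=%.3f F=%.3f",
                records[0].mode,
                hit_rate(records),
                state.trace.fraction_tested,
                state.trace.n_synergies_found / state.trace.total_synergies,
            )
            if config.mode == "algorithm2":
                if not in_prediction:
                    # after a propensity batch, always try a prediction cycle
                    in_prediction = True
                else:
                    # stay in prediction only while strictly out-hitting
                    # the last propensity batch; ties revert
                    in_prediction = state.h_pred > state.h_prop

    curve = discovery_curve(state.trace)
    est = estimate_eta(curve)
    return state.trace, est
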