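"""Beta-binomial propensity model for per-target interaction frequency.

Some targets ("hubs") take part in disproportionately many synergies.
Each target i is assigned a propensity pi_i, the probability that a
randomly chosen pair involving i is synergistic.  With a conjugate
Beta(a, b) prior and s_i synergies observed in n_i tested pairs, the
posterior-mean estimate is

    pi_i = (s_i + a) / (n_i + a + b).

Untested pairs are then sampled with probability proportional to
pi_i * pi_j, biasing the screen toward likely hubs while it is running.
The prior shapes (a, b) can be fixed by a rule of thumb (a small,
b near the number of targets, i.e. few targets are hubs) or estimated
from per-target counts by empirical Bayes (marginal beta-binomial
maximum likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PropensityState",
    "posterior_propensity",
    "pair_probabilities",
    "sample_pairs",
    "update_state",
    "fit_beta_binomial",
]


def posterior_propensity(s, n, a: float, b: float):
    """Posterior-mean propensity (s + a) / (n + a + b).

    ``s`` synergies found among ``n`` tested pairs for a target; (a, b)
    are the beta prior shapes.  Vectorises over s, n.
    """
    s = np.asarray(s, dtype=float)
    n = np.asarray(n, dtype=float)
    if a <= 0 or b <= 0:
        raise ValueError("prior shapes must be positive")
    if np.any(s < 0) or np.any(s > n):
        raise ValueError("need 0 <= s <= n")
    out = (s + a) / (n + a + b)
    return float(out) if out.ndim == 0 else out


@dataclass
class PropensityState:
    """Running per-target synergy counts and posterior propensities."""

    s: np.ndarray  # synergies found per target
    n: np.ndarray  # pairs tested per target
    a: float
    b: float

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if self.s.shape != self.n.shape:
            raise ValueError("s and n must have equal length")
        if np.any(self.s < 0) or np.any(self.s > self.n):
            raise ValueError("need 0 <= s_i <= n_i")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior shapes must be positive")

    @classmethod
    def cold(cls, n_targets: int, a: float = 0.5, b: float | None = None) -> "PropensityState":
        """Fresh state with no tests.  Default prior: a = 0.5, b = n_targets.

        This prior encodes the belief that few targets are interaction
        hubs (prior mean propensity a / (a + b) is small); a flat
        Beta(1, 1) prior instead expects roughly half of all pairs to
        interact and adapts poorly early in a screen.
        """
        if b is None:
            b = float(n_targets)
        return cls(np.zeros(n_targets, dtype=int), np.zeros(n_targets, dtype=int), a, b)

    @property
    def pi(self) -> np.ndarray:
        return posterior_propensity(self.s, self.n, self.a, self.b)


def pair_probabilities(state: PropensityState, untested: np.ndarray) -> np.ndarray:
    """Sampling probabilities proportional to pi_i * pi_j over untested pairs.

    ``untested`` is an (m, 2) array of (i, j) pairs with i < j.  Returns
    probabilities normalised to sum to 1 over those pairs.
    """
    untested = np.asarray(untested, dtype=int)
    if untested.size == 0:
        raise ValueError("no untested pairs")
    pi = state.pi
    w = pi[untested[:, 0]] * pi[untested[:, 1]]
    return w / w.sum()


def sample_pairs(
    untested: np.ndarray,
    probs: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw k distinct pairs without replacement, weighted by ``probs``.

    Successive sampling (draw, remove, renormalise) is implemented via
    Gumbel keys: pair order = argsort of log(weight) + Gumbel noise,
    which is distributionally identical and vectorised.
    """
    untested = np.asarray(untested, dtype=int)
    probs = np.asarray(probs, dtype=float)
    m = len(untested)
    if not 1 <= k <= m:
        raise ValueError(f"batch size {k} not in [1, {m}]")
    if probs.shape != (m,):
        raise ValueError("probs must match the untested pair list")
    with np.errstate(divide="ignore"):
        keys = np.log(probs) + rng.gumbel(size=m)
    order = np.argsort(-keys, kind="stable")
    return untested[order[:k]]


def update_state(
    state: PropensityState,
    pairs: np.ndarray,
    synergy: np.ndarray,
) -> PropensityState:
    """Record newly tested pairs: increment n (and s where synergistic)
    for both endpoints of each pair.  Returns a new state."""
    pairs = np.asarray(pairs, dtype=int)
    synergy = np.asarray(synergy, dtype=bool)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(synergy) != len(pairs):
        raise ValueError("pairs must be (m, 2) with a synergy flag per pair")
    seen = set()
    for i, j in pairs:
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"pair {key} listed twice")
        seen.add(key)
    s = state.s.copy()
    n = state.n.copy()
    for (i, j), hit in zip(pairs, synergy):
        n[i] += 1
        n[j] += 1
        if hit:
            s[i] += 1
            s[j] += 1
    return PropensityState(s, n, state.a, state.b)


def fit_beta_binomial(
    s: np.ndarray,
    n: np.ndarray,
    tol: float = 1e-8,
) -> tuple[float, float, bool]:
    """Empirical-Bayes fit of the beta prior shapes (a, b).

    Maximises the product of beta-binomial marginal likelihoods of the
    per-target synergy counts s_i given n_i.  Optimisation is in
    (log a, log b) with multiple starting points to avoid boundary
    traps.  Returns (a, b, converged); if every s_i is 0 the likelihood
    is maximised on the a -> 0 boundary and converged is False.
    """
    s = np.asarray(s, dtype=int)
    n = np.asarray(n, dtype=int)
    if np.any(s > n) or np.any(s < 0):
        raise ValueError("need 0 <= s_i <= n_i")
    use = n > 0
    if use.sum() < 2:
        raise ValueError("need at least 2 targets with tested pairs")
    s, n = s[use], n[use]

    def nll(log_ab):
        a, b = np.exp(log_ab)
        return -np.sum(stats.betabinom.logpmf(s, n, a, b))

    # moment-based start plus fixed alternatives
    rho = max(s.sum() / n.sum(), 1e-6)
    starts = [
        np.log([rho * len(n), (1 - rho) * len(n)]),
        np.log([0.5, float(len(n))]),
        np.log([1.0, 1.0]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": tol, "fatol": tol, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    converged = bool(best.success) and s.sum() > 0
    return float(a), float(b), converged
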