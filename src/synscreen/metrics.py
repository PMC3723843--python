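"""Screening-efficiency metrics: discovery curves and the efficiency eta.

A screen is summarised by the curve F(f): the fraction F of all
synergistic pairs discovered after testing a fraction f of all pairs.
Systematic (brute-force) screening gives E[F(f)] = f.  A screening
strategy that enriches for synergies by a constant factor eta in its
fractional discovery rate dF/df satisfies

    F(f) = 1 - (1 - f) ** eta,

so eta = 1 is brute force and the best achievable ("oracle") value is
1 / prevalence, reached by testing only true synergies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraceRecord",
    "ScreenTrace",
    "EfficiencyEstimate",
    "discovery_curve",
    "estimate_eta",
    "eta_from_point",
    "oracle_eta",
]

MODES = ("propensity", "prediction", "brute", "oracle")


@dataclass(frozen=True)
class TraceRecord:
    """One tested pair in a screen."""

    step: int
    mode: str
    i: int
    j: int
    score: float
    synergy: bool

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown search mode {self.mode!r}")
        if not self.i < self.j:
            raise ValueError("pair must be ordered i < j")


@dataclass
class ScreenTrace:
    """Ordered record of every pair tested during a screen.

    ``total_pairs`` is n(n-1)/2 for the screened system and
    ``total_synergies`` the ground-truth synergy count (known in
    simulation or retrospective screens).  When the ground truth is
    unknown, ``total_synergies`` may be set to the number of synergies
    found and ``ground_truth_known`` flagged False; discovery fractions
    are then relative to the discovered set and F(f) is not an absolute
    discovery curve.
    """

    total_pairs: int
    total_synergies: int
    records: list[TraceRecord] = field(default_factory=list)
    ground_truth_known: bool = True
    target_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._seen: set[tuple[int, int]] = set()
        for r in self.records:
            self._check_new(r)

    def _check_new(self, r: TraceRecord) -> None:
        key = (r.i, r.j)
        if key in self._seen:
            raise ValueError(f"pair {key} tested twice")
        if len(self._seen) >= self.total_pairs:
            raise ValueError("trace longer than the number of screenable pairs")
        self._seen.add(key)

    def append(self, record: TraceRecord) -> None:
        self._check_new(record)
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_synergies_found(self) -> int:
        return sum(r.synergy for r in self.records)

    @property
    def fraction_tested(self) -> float:
        return len(self.records) / self.total_pairs


@dataclass
class EfficiencyEstimate:
    """Fitted screening efficiency eta with the curve it came from."""

    eta: float
    curve: np.ndarray  # (m, 2) array of (f, F) points
    residual: float


def discovery_curve(trace: ScreenTrace) -> np.ndarray:
    """Per-step (f, F) discovery curve of a screen.

    f is the cumulative fraction of pairs tested, F the cumulative
    fraction of synergies discovered.  Both are non-decreasing; the
    curve starts after the first tested pair.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if trace.total_synergies <= 0:
        raise ValueError("zero total synergies: discovery fraction undefined")
    hits = np.cumsum([r.synergy for r in trace.records])
    steps = np.arange(1, len(trace) + 1)
    f = steps / trace.total_pairs
    F = hits / trace.total_synergies
    return np.column_stack([f, F])


def estimate_eta(curve: np.ndarray) -> EfficiencyEstimate:
    """Fit eta in F(f) = 1 - (1-f)**eta by least squares.

    Linearised as log(1-F) = eta * log(1-f), a line through the origin;
    points with F = 1 (log undefined) or f in {0, 1} are excluded.  If
    every usable point has F = 0 the screen found nothing and eta = 0 is
    returned with a warning.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2:
        raise ValueError("curve must be an (m, 2) array of (f, F) points")
    f, F = curve[:, 0], curve[:, 1]
    if np.any((f < 0) | (f > 1)) or np.any((F < 0) | (F > 1)):
        raise ValueError("f and F must lie in [0, 1]")
    keep = (f > 0) & (f < 1) & (F < 1)
    x = np.log1p(-f[keep])
    y = np.log1p(-F[keep])
    if x.size == 0 or np.all(y == 0.0):
        warnings.warn("no synergies discovered on the usable curve; eta = 0")
        return EfficiencyEstimate(0.0, curve, float("nan"))
    eta = float(np.dot(x, y) / np.dot(x, x))
    residual = float(np.sqrt(np.mean((y - eta * x) ** 2)))
    return EfficiencyEstimate(eta, curve, residual)


def eta_from_point(f: float, F: float) -> float:
    """eta from a single (f, F) checkpoint: log(1-F) / log(1-f).

    Useful for statements like "finds 75% of synergies by testing 20%".
    """
    if not (0 < f < 1) or not (0 <= F < 1):
        raise ValueError("need 0 < f < 1 and 0 <= F < 1")
    return float(np.log1p(-F) / np.log1p(-f))


def oracle_eta(prevalence: float) -> float:
    """Upper bound on eta: 1 / prevalence of synergistic pairs."""
    if not (0 < prevalence <= 1):
        raise ValueError("prevalence must be in (0, 1]")
    return 1.0 / prevalence
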