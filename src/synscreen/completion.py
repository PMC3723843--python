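"""Interaction-score matrix completion by cyclical convex-set projections.

The unknown symmetric score matrix M is assumed to lie in the
intersection of three convex sets in the space of symmetric matrices:

* C1 — matrices consistent with the measured entries D on the observed
  index set Omega (data fidelity);
* C2 — matrices of small nuclear norm, a convex surrogate for the
  modular / block-low-rank structure typical of interaction networks;
* C3 — matrices consistent with an external functional-similarity
  kernel Q (bistochastic, zero diagonal): row i of M should be close to
  the Q-weighted average of its functionally similar rows, i.e.
  ``(I - Q) M`` should be small.

A feasible point is found by cycling the three (penalised, proximal)
projections from a zero start until the relative Frobenius change per
cycle falls below a tolerance.  Each set is parameterised by a penalty
lambda rather than a set radius; the two forms give the same solution
path.  With the similarity set dropped (lambda3 = 0) and a hard data
constraint (lambda1 -> inf) the iteration reduces exactly to the
SoftImpute algorithm of Mazumder et al.

The per-step proximal maps are::

    data fidelity   X_ij = (M_ij + lambda1 * D_ij) / (1 + lambda1)  on Omega,
                    X_ij = M_ij                                     off Omega
    modularity      X = soft-threshold of the singular values of M by lambda2
    similarity      X = (I + lambda3 * (I - Q)^T (I - Q))^{-1} M, symmetrised
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse, stats

from .matrix import InteractionMatrix

__all__ = [
    "SimilarityMatrix",
    "CompletionConfig",
    "CompletionResult",
    "project_data",
    "svd_soft_threshold",
    "project_similarity",
    "pocs_complete",
    "cross_validate",
    "bistochastic_scale",
    "similarity_from_groups",
    "explained_fraction",
]


# ---------------------------------------------------------------------------
# similarity kernels


@dataclass
class SimilarityMatrix:
    """Bistochastic, symmetric, zero-diagonal functional-similarity kernel.

    Entry Q_ij weights how informative target j's interaction profile is
    for target i; rows and columns sum to 1 so Q acts as an averaging
    (kernel interpolation) operator on score matrices.
    """

    Q: np.ndarray

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        if np.any(Q < 0):
            raise ValueError("Q must be non-negative")
        if np.any(np.diag(Q) != 0):
            raise ValueError("Q must have a zero diagonal")
        if not np.allclose(Q, Q.T, atol=1e-8):
            raise ValueError("Q must be symmetric")
        if np.max(np.abs(Q.sum(axis=1) - 1)) > 1e-6:
            raise ValueError("Q rows must sum to 1 (bistochastic)")
        self.Q = Q

    @property
    def n(self) -> int:
        return self.Q.shape[0]


def bistochastic_scale(W: np.ndarray, tol: float = 1e-8, max_sweeps: int = 1000) -> SimilarityMatrix:
    """Scale a symmetric non-negative weight matrix to be bistochastic.

    Symmetric Sinkhorn-Knopp: find d > 0 with diag(d) W diag(d) doubly
    stochastic, iterating d <- d / sqrt(row sums).  Symmetry and the
    zero diagonal are preserved exactly.
    """
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("weights must have a zero diagonal")
    if np.any(W.sum(axis=1) == 0):
        raise ValueError("zero row: a target with no similarity support")
    d = np.ones(W.shape[0])
    for _ in range(max_sweeps):
        r = (W * np.outer(d, d)).sum(axis=1)
        if np.max(np.abs(r - 1)) < tol:
            break
        d /= np.sqrt(r)
    else:
        warnings.warn("bistochastic scaling hit the sweep cap before tolerance")
    return SimilarityMatrix(W * np.outer(d, d))


def similarity_from_groups(labels) -> SimilarityMatrix:
    """Similarity kernel from categorical group labels.

    Weight 1 within a group, 0 between groups, then bistochastic
    scaling.  Every group needs at least 2 members (a singleton has no
    similar neighbour and would give a zero row).
    """
    labels = np.asarray(labels)
    n = len(labels)
    W = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(W, 0.0)
    if np.any(W.sum(axis=1) == 0):
        raise ValueError("singleton group: every group needs >= 2 members")
    return bistochastic_scale(W)


def explained_fraction(M: np.ndarray, Q: SimilarityMatrix) -> float:
    """How much of M's structure the kernel Q explains, in [0, 1].

    Defined as ``max(0, 1 - ||M - QM||_F^2 / ||M||_F^2)``: 1 when M is a
    fixed point of the kernel average (QM = M), 0 when Q carries no
    information about M.  (Q's zero diagonal rules out the trivial
    identity solution.)
    """
    M = np.asarray(M, dtype=float)
    denom = np.linalg.norm(M) ** 2
    if denom == 0:
        raise ValueError("zero matrix: explained fraction undefined")
    resid = np.linalg.norm(M - Q.Q @ M) ** 2
    return max(0.0, 1.0 - resid / denom)


# ---------------------------------------------------------------------------
# the three proximal projections


def project_data(M: np.ndarray, D: InteractionMatrix, lambda1: float) -> np.ndarray:
    """Pull the current iterate toward the measured entries (set C1).

    Proximal map of ``lambda1/2 * ||P_Omega(X - D)||_F^2``: observed
    entries move to the convex combination (M + lambda1*D)/(1 + lambda1),
    unobserved entries are untouched.  lambda1 -> inf clamps observed
    entries to the data (hard constraint).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != D.values.shape:
        raise ValueError("shape mismatch between iterate and data")
    if lambda1 < 0:
        raise ValueError("lambda1 must be non-negative")
    X = M.copy()
    X[D.mask] = (M[D.mask] + lambda1 * D.values[D.mask]) / (1.0 + lambda1)
    return X


def svd_soft_threshold(M: np.ndarray, lambda2: float, rank_cap: int | None = None) -> np.ndarray:
    """Soft-threshold the singular values of M by lambda2 (set C2).

    The proximal map of the nuclear norm: singular values shrink by
    lambda2 and clip at zero, which promotes low rank / modularity.
    For symmetric input the SVD is taken through the eigendecomposition
    (singular values are |eigenvalues|), keeping the output exactly
    symmetric; for large matrices only the leading eigenpairs with
    |eigenvalue| > lambda2 are computed.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite input")
    if lambda2 < 0:
        raise ValueError("lambda2 must be non-negative")
    n = M.shape[0]
    symmetric = np.allclose(M, M.T, atol=1e-12)
    if symmetric and n > 500 and lambda2 > 0:
        return _truncated_eig_soft_threshold(M, lambda2, rank_cap or n - 1)
    if symmetric:
        e, V = np.linalg.eigh(M)
        shrunk = np.sign(e) * np.maximum(np.abs(e) - lambda2, 0.0)
        return (V * shrunk) @ V.T
    U, sv, Vt = np.linalg.svd(M, full_matrices=False)
    return (U * np.maximum(sv - lambda2, 0.0)) @ Vt


def _truncated_eig_soft_threshold(M: np.ndarray, lam: float, rank_cap: int) -> np.ndarray:
    """Adaptive truncated route: grow the computed rank until the
    smallest |eigenvalue| retrieved falls below the threshold."""
    k = min(20, rank_cap)
    while True:
        e, V = sparse.linalg.eigsh(M, k=k, which="LM")
        if np.min(np.abs(e)) < lam or k >= rank_cap:
            break
        k = min(2 * k, rank_cap)
    shrunk = np.sign(e) * np.maximum(np.abs(e) - lam, 0.0)
    return (V * shrunk) @ V.T


def project_similarity(
    M: np.ndarray,
    Q: SimilarityMatrix,
    lambda3: float,
    solver=None,
    symmetrized_residual: bool = False,
) -> np.ndarray:
    """Pull the iterate toward consistency with the similarity kernel (set C3).

    Proximal map of ``lambda3/2 * ||(I - Q) X||_F^2``:
    ``X = (I + lambda3 (I-Q)^T (I-Q))^{-1} M``, then symmetrised.  The
    system matrix is I plus a PSD term, hence always well conditioned;
    its Cholesky factor can be passed as ``solver`` to amortise the cost
    across iterations (each application is then just triangular solves).

    ``symmetrized_residual`` switches to penalising
    ``||X - (QX + XQ)/2||_F^2`` instead, whose proximal map is the
    Sylvester-type solve with the symmetrised operator; the default
    left-application residual is the kernel-interpolation reading.
    """
    M = np.asarray(M, dtype=float)
    if lambda3 < 0:
        raise ValueError("lambda3 must be non-negative")
    if lambda3 == 0:
        return M.copy()
    if solver is None:
        solver = make_similarity_solver(Q, lambda3, symmetrized_residual)
    X = solver(M)
    return 0.5 * (X + X.T)


def make_similarity_solver(Q: SimilarityMatrix, lambda3: float,
                           symmetrized_residual: bool = False):
    """Prefactorised linear solver for the similarity proximal map."""
    n = Q.n
    I = np.eye(n)
    B = I - Q.Q if not symmetrized_residual else I - 0.5 * (Q.Q + Q.Q.T)
    A = I + lambda3 * (B.T @ B)
    c, low = linalg.cho_factor(A)
    return lambda M: linalg.cho_solve((c, low), M)


# ---------------------------------------------------------------------------
# the cyclic projection loop


@dataclass
class CompletionConfig:
    """Penalties and numerical controls for the completion solver.

    lambda1 (data fidelity) defaults to 10 and rarely needs changing;
    values near 0 should be avoided as they treat the measurements as
    non-informative.  lambda2 (nuclear norm) and lambda3 (similarity)
    are data-dependent and normally chosen by cross-validation; the
    lambda2 grid is specified as fractions of the largest singular
    value of the zero-filled data.
    """

    lambda1: float = 10.0
    lambda2: float | None = None
    lambda3: float = 0.0
    tol: float = 1e-4
    max_iter: int = 500
    cv_folds: int = 5
    cv_holdout_fraction: float = 0.2
    lambda2_grid_fractions: tuple[float, ...] = tuple(np.geomspace(0.01, 0.5, 8).round(6))
    lambda3_grid: tuple[float, ...] = tuple(np.geomspace(0.01, 100.0, 7).round(6))
    svd_rank_cap: int | None = None
    c3_symmetrized_residual: bool = False

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda3 < 0:
            raise ValueError("penalties must be non-negative")
        if self.lambda1 < 0.5:
            warnings.warn("lambda1 near zero treats the measurements as non-informative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class CompletionResult:
    """Completed matrix plus convergence diagnostics."""

    M_hat: np.ndarray
    iterations: int
    converged: bool
    limit_cycle: bool
    rel_changes: list[float] = field(default_factory=list)
    lambda2: float | None = None
    lambda3: float | None = None


def default_lambda2(D: InteractionMatrix, fraction: float = 0.1) -> float:
    """lambda2 as a fraction of the top singular value of the
    zero-filled data; a serviceable default when skipping CV."""
    sv_max = np.linalg.norm(D.zero_filled(), ord=2)
    return float(fraction * sv_max)


def pocs_complete(
    D: InteractionMatrix,
    Q: SimilarityMatrix | None = None,
    config: CompletionConfig | None = None,
    M0: np.ndarray | None = None,
) -> CompletionResult:
    """Complete a partially observed score matrix by cyclic projections.

    Starting from the zero matrix (or ``M0``), each cycle applies the
    data-fidelity, nuclear-norm and similarity proximal maps in that
    order, until the relative Frobenius change of the iterate falls
    below ``config.tol``.  If the penalised sets fail to intersect the
    iteration settles into a limit cycle; this is detected (iterates
    repeat while the change series stops decreasing) and the average of
    the last cycle's three step outputs is returned with
    ``limit_cycle=True`` as a point close to all three sets.
    """
    config = config or CompletionConfig()
    if D.n_observed_pairs == 0:
        raise ValueError("no observed entries to complete from")
    lam2 = config.lambda2 if config.lambda2 is not None else default_lambda2(D)
    lam3 = config.lambda3 if Q is not None else 0.0
    if config.lambda3 > 0 and Q is None:
        raise ValueError("similarity penalty requires a similarity matrix Q")
    solver = (
        make_similarity_solver(Q, lam3, config.c3_symmetrized_residual)
        if (Q is not None and lam3 > 0)
        else None
    )
    n = D.n
    M = np.zeros((n, n)) if M0 is None else np.array(M0, dtype=float)

    rel_changes: list[float] = []
    converged = False
    limit_cycle = False
    prev_prev = None
    stall = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        M1 = project_data(M, D, config.lambda1)
        M2 = svd_soft_threshold(M1, lam2, config.svd_rank_cap)
        M3 = (
            project_similarity(M2, Q, lam3, solver=solver)
            if solver is not None
            else M2
        )
        denom = np.linalg.norm(M)
        step = np.linalg.norm(M3 - M)
        rel = step / denom if denom > 0 else np.inf
        rel_changes.append(rel)
        if rel < config.tol:
            M = M3
            converged = True
            break
        # limit-cycle check: iterate revisits the one from two cycles ago
        # while the relative change has stopped decreasing
        if prev_prev is not None and np.max(np.abs(M3 - prev_prev)) < 1e-6:
            if len(rel_changes) >= 2 and rel >= rel_changes[-2] - 1e-15:
                stall += 1
            else:
                stall = 0
            if stall >= 3:
                M = (M1 + M2 + M3) / 3.0
                limit_cycle = True
                break
        prev_prev = M
        M = M3
    return CompletionResult(
        M_hat=0.5 * (M + M.T),
        iterations=it,
        converged=converged,
        limit_cycle=limit_cycle,
        rel_changes=rel_changes,
        lambda2=lam2,
        lambda3=lam3,
    )


# ---------------------------------------------------------------------------
# penalty selection


def cross_validate(
    D: InteractionMatrix,
    Q: SimilarityMatrix | None,
    config: CompletionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Choose (lambda2, lambda3) by k-fold cross-validation on observed entries.

    A fraction of the observed pairs is held out per fold; for every
    grid point the matrix is completed from the remainder and scored by
    the Pearson correlation between held-out measurements and
    predictions, averaged over folds.  Ties are broken toward larger
    lambda2 (stronger shrinkage), then larger lambda3.  Without Q the
    lambda3 grid collapses to {0}.
    """
    config = config or CompletionConfig()
    rng = rng or np.random.default_rng()
    obs = D.observed_pairs()
    m = len(obs)
    folds = config.cv_folds
    hold = max(1, int(round(config.cv_holdout_fraction * m)))
    if m - hold < 2:
        raise ValueError("too few observed entries for cross-validation")
    sv_max = np.linalg.norm(D.zero_filled(), ord=2)
    lam2_grid = [f * sv_max for f in config.lambda2_grid_fractions]
    lam3_grid = list(config.lambda3_grid) if Q is not None else [0.0]

    fold_sets = [rng.choice(m, size=hold, replace=False) for _ in range(folds)]
    scores = np.full((len(lam2_grid), len(lam3_grid)), -np.inf)
    for i2, lam2 in enumerate(lam2_grid):
        for i3, lam3 in enumerate(lam3_grid):
            rs = []
            for held in fold_sets:
                held_pairs = obs[held]
                mask = D.mask.copy()
                mask[held_pairs[:, 0], held_pairs[:, 1]] = False
                mask[held_pairs[:, 1], held_pairs[:, 0]] = False
                D_train = InteractionMatrix(D.values, mask, list(D.target_ids))
                cfg = CompletionConfig(
                    lambda1=config.lambda1, lambda2=lam2, lambda3=lam3,
                    tol=config.tol, max_iter=config.max_iter,
                    svd_rank_cap=config.svd_rank_cap,
                    c3_symmetrized_residual=config.c3_symmetrized_residual,
                )
                res = pocs_complete(D_train, Q if lam3 > 0 else None, cfg)
                truth = D.values[held_pairs[:, 0], held_pairs[:, 1]]
                pred = res.M_hat[held_pairs[:, 0], held_pairs[:, 1]]
                if np.std(truth) == 0:
                    warnings.warn("degenerate CV fold (constant held-out values); skipped")
                    continue
                if np.std(pred) == 0:
                    # full shrinkage: no predictive power, not an error
                    rs.append(0.0)
                else:
                    rs.append(stats.pearsonr(truth, pred).statistic)
            if rs:
                scores[i2, i3] = float(np.mean(rs))
    # argmax with ties toward larger lambda2, then larger lambda3
    best = np.max(scores)
    cand = np.argwhere(scores >= best - 1e-12)
    i2, i3 = max(cand, key=lambda c: (c[0], c[1]))
    return float(lam2_grid[i2]), float(lam3_grid[i3])
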