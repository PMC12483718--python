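"""Regression-based factor score exploration (RFE).

RFE jointly estimates loadings ``A``, uniqueness square roots ``psi``,
regression coefficients ``B`` and the score block ``Z = [F U]`` by
alternating least squares on

    L(A, Psi, B, Z) = ||X - F A' - U Psi||^2 + alpha ||Y - F B'||^2

subject to ``(1/n) Z'Z = I``.  The regression term against the external
criteria ``Y`` removes the rotational freedom of the score block that plain
matrix-decomposition factor analysis leaves open, so the fitted ``F`` is
unique (up to the usual orthogonal rotation of the whole solution) whenever
the rank conditions checked by :func:`check_identification` hold — in
particular ``q >= r`` with a full-column-rank ``B``.

Each update is the exact conditional minimizer:

* scores: a ten Berge orthogonal-Procrustes step on the augmented block
  ``[X, sqrt(alpha) Y]`` (see :func:`build_blocks`, :func:`update_scores`);
* uniquenesses: ``psi_j = (1/n) u_j' x_j`` (:func:`update_psi`);
* coefficients: ``A = (1/n) X'F`` and ``B = (1/n) Y'F``
  (:func:`update_coefficients`).

The loss is therefore non-increasing by construction; an observed increase
raises :class:`~facscore.model_core.InternalConsistencyError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .model_core import (AlgoConfig, ConfigurationError, DataBundle,
                         FactorParams, InternalConsistencyError, ScoreSet,
                         check_constraint, mdfa_loss, rfe_loss)

#: default grid scanned by the semi-automatic alpha heuristic
ALPHA_GRID = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0)

#: relative floor below which a singular value counts as zero
_RANK_TOL = 1e-10


@dataclass
class FitResult:
    """Outcome of a multi-start alternating-least-squares fit."""

    params: FactorParams
    scores: ScoreSet
    loss_path: np.ndarray
    start_losses: np.ndarray
    best_loss: float
    local_solution_proportion: float
    alpha: float | None
    converged: bool
    n_iter: int
    method: str = "rfe"
    rank_deficient: bool = False
    max_constraint_dev: float = 0.0

    def __post_init__(self) -> None:
        self.loss_path = np.asarray(self.loss_path, dtype=float)
        self.start_losses = np.asarray(self.start_losses, dtype=float)


@dataclass
class IdentificationReport:
    """Diagnostic rank conditions for the uniqueness of the fitted scores."""

    unique: bool
    q: int
    r: int
    rank_X: int
    rank_Y: int | None
    rank_A: int
    rank_B: int | None
    rank_weight_block: int
    rank_product: int
    projection_residual: float
    notes: list = field(default_factory=list)


def build_blocks(data: DataBundle, params: FactorParams,
                 alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Augmented data block ``G = [X, sqrt(alpha) Y]`` and weight block ``W``.

    ``W`` stacks ``[A, Psi]`` over ``[sqrt(alpha) B, 0]`` so that the whole
    objective collapses to a single Frobenius discrepancy:

        ||X - F A' - U Psi||^2 + alpha ||Y - F B'||^2 = ||G - Z W'||^2.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if data.Y is None:
        raise ConfigurationError("build_blocks requires external criteria Y")
    if params.B is None:
        raise ConfigurationError("build_blocks requires coefficients B")
    p, q, r = data.p, data.q, params.r
    sa = np.sqrt(alpha)
    G = np.hstack([data.X, sa * data.Y])
    W = np.zeros((p + q, r + p))
    W[:p, :r] = params.A
    W[:p, r:] = np.diag(params.psi)
    W[p:, :r] = sa * params.B
    return G, W


def update_scores(G: np.ndarray, W: np.ndarray, n: int,
                  r: int) -> tuple[ScoreSet, bool]:
    """Constrained score update ``Z = sqrt(n) P Q'`` from the SVD ``G W = P L Q'``.

    Among all ``Z`` with ``(1/n) Z'Z = I`` this maximizes ``tr(W'G'Z)``
    (orthogonal-Procrustes / ten Berge argument), hence minimizes
    ``||G - Z W'||^2``.  Returns the scores and a full-rank flag; when
    ``G W`` is column-rank deficient the maximizer is not unique and the
    caller should flag the fit.
    """
    M = G @ W
    P, s, Qt = scipy.linalg.svd(M, full_matrices=False)
    full_rank = bool(s[-1] > _RANK_TOL * max(s[0], 1.0))
    Z = np.sqrt(n) * (P @ Qt)
    return ScoreSet(F=Z[:, :r], U=Z[:, r:]), full_rank


def update_psi(data: DataBundle, scores: ScoreSet) -> np.ndarray:
    """Optimal uniqueness square roots ``psi_j = (1/n) u_j' x_j``.

    Valid when the score constraint holds (so the columns of ``U`` are
    scaled-orthonormal).  Tiny negative values are numerical noise and are
    clamped to zero; a genuinely negative value cannot occur at a valid
    iterate and raises.
    """
    n = data.n
    psi = np.einsum("ij,ij->j", scores.U, data.X) / n
    floor = -1e-10 * max(1.0, float(np.max(np.abs(data.X))))
    if np.any(psi < floor):
        raise InternalConsistencyError(
            "negative uniqueness encountered; the score constraint was "
            "violated upstream")
    return np.maximum(psi, 0.0)


def update_coefficients(data: DataBundle,
                        scores: ScoreSet) -> tuple[np.ndarray, np.ndarray | None]:
    """Optimal ``A = (1/n) X'F`` and ``B = (1/n) Y'F`` given ``F'F = n I``."""
    n = data.n
    A = data.X.T @ scores.F / n
    B = data.Y.T @ scores.F / n if data.Y is not None else None
    return A, B


def _init_params(data: DataBundle, r: int, rng: np.random.Generator,
                 with_b: bool) -> FactorParams:
    """Principal-component loadings plus uniform jitter; psi from column spread."""
    n = data.n
    _, s, Vt = scipy.linalg.svd(data.X, full_matrices=False)
    A0 = Vt[:r].T * (s[:r] / np.sqrt(n))
    A0 = A0 + rng.uniform(-0.1, 0.1, size=A0.shape)
    psi0 = 0.5 * data.X.std(axis=0)
    B0 = np.zeros((data.q, r)) if with_b else None
    return FactorParams(A=A0, psi=psi0, B=B0)


def _single_start(data: DataBundle, r: int, config: AlgoConfig,
                  rng: np.random.Generator, use_y: bool) -> dict:
    params = _init_params(data, r, rng, with_b=use_y)
    alpha = config.alpha
    if use_y:
        norm_g2 = float(np.sum(data.X ** 2) + alpha * np.sum(data.Y ** 2))
    else:
        norm_g2 = float(np.sum(data.X ** 2))
    norm_g2 = max(norm_g2, 1e-12)

    prev = np.inf
    loss_path: list[float] = []
    converged = False
    rank_deficient = False
    max_dev = 0.0
    scores = None
    increase_tol = 1e-9 * max(1.0, norm_g2 * np.finfo(float).eps / 1e-9)

    for _ in range(config.max_iter):
        if use_y:
            G, W = build_blocks(data, params, alpha)
        else:
            G = data.X
            W = np.hstack([params.A, np.diag(params.psi)])
        # the flag reflects the final iterate: early iterates (B still zero)
        # are legitimately deficient without bearing on the solution
        scores, full_rank = update_scores(G, W, data.n, r)
        rank_deficient = not full_rank
        _, dev = check_constraint(scores, data.n)
        max_dev = max(max_dev, dev)

        psi = update_psi(data, scores)
        A, B = update_coefficients(data, scores)
        params = FactorParams(A=A, psi=psi, B=B if use_y else None)

        loss = rfe_loss(data, params, scores, alpha) if use_y \
            else mdfa_loss(data, params, scores)
        loss_path.append(loss)
        if loss > prev + max(1e-9, increase_tol):
            raise InternalConsistencyError(
                f"loss increased from {prev!r} to {loss!r}; every update is an "
                "exact conditional minimizer so this indicates a numerical bug")
        if prev - loss < config.tol * norm_g2:
            converged = True
            break
        prev = loss

    return {
        "params": params,
        "scores": scores,
        "loss_path": np.asarray(loss_path),
        "loss": loss_path[-1],
        "converged": converged,
        "rank_deficient": rank_deficient,
        "max_constraint_dev": max_dev,
    }


def _fit_als(data: DataBundle, r: int, config: AlgoConfig,
             use_y: bool, method: str) -> FitResult:
    """Multi-start driver shared by the plain and regression-penalized fits."""
    from .scoring_metrics import local_solution_proportion

    runs = []
    for i in range(config.n_starts):
        rng = np.random.default_rng(config.seed + i)
        runs.append(_single_start(data, r, config, rng, use_y=use_y))
    start_losses = np.array([run["loss"] for run in runs])
    best = runs[int(np.argmin(start_losses))]
    prop = local_solution_proportion(start_losses,
                                     config.local_solution_threshold)
    return FitResult(
        params=best["params"],
        scores=best["scores"],
        loss_path=best["loss_path"],
        start_losses=start_losses,
        best_loss=float(start_losses.min()),
        local_solution_proportion=prop,
        alpha=config.alpha if use_y else None,
        converged=best["converged"],
        n_iter=len(best["loss_path"]),
        method=method,
        rank_deficient=best["rank_deficient"],
        max_constraint_dev=best["max_constraint_dev"],
    )


def fit_rfe(data: DataBundle, r: int, config: AlgoConfig | None = None) -> FitResult:
    """Fit RFE by multi-start alternating least squares.

    Requires external criteria ``Y``; ``q >= r`` is recommended for unique
    scores (a warning is issued otherwise).  The best of ``config.n_starts``
    random starts is returned, together with the converged loss of every
    start and the proportion of local solutions among them.
    """
    config = config or AlgoConfig()
    if data.Y is None:
        raise ConfigurationError(
            "fit_rfe requires external criteria Y; use fit_mdfa for plain "
            "factor analysis")
    if r < 1:
        raise ValueError("r must be >= 1")
    if r >= data.p:
        raise ValueError(f"r must be smaller than the number of variables p={data.p}")
    if data.p >= data.n or data.q > data.n:
        raise ValueError("degenerate dimensions: need n > p and n >= q")
    data.require_headroom(r)
    if data.q < r:
        warnings.warn(
            f"q={data.q} external criteria < r={r} factors: the fitted factor "
            "scores are not guaranteed to be unique", stacklevel=2)
    return _fit_als(data, r, config, use_y=True, method="rfe")


def check_identification(data: DataBundle, params: FactorParams,
                         scores: ScoreSet, alpha: float = 1.0,
                         tol: float = 1e-8) -> IdentificationReport:
    """Verify the rank conditions for score uniqueness and the observed-space
    location of the fitted scores.

    The report checks that the weight block ``[A, Psi; sqrt(alpha) B, 0]``
    and the product block ``G W`` have full column rank ``r + p`` (the SVD
    score update is then unique), that ``q >= r`` with full-rank ``B``, and
    that the fitted ``F`` lies in the column space of ``[X, Y]`` — the
    projection residual ``||F - P_[X,Y] F|| / ||F||`` is reported and should
    vanish for an identified fit.
    """
    notes: list[str] = []
    r, p, q = params.r, data.p, data.q
    rank_X = int(np.linalg.matrix_rank(data.X))
    rank_A = int(np.linalg.matrix_rank(params.A))
    rank_Y = rank_B = None
    basis_cols = data.X
    if data.Y is not None and params.B is not None:
        rank_Y = int(np.linalg.matrix_rank(data.Y))
        rank_B = int(np.linalg.matrix_rank(params.B))
        basis_cols = np.hstack([data.X, data.Y])
        G, W = build_blocks(data, params, alpha)
        M = G @ W
    else:
        W = np.hstack([params.A, np.diag(params.psi)])
        M = data.X @ W
    rank_W = int(np.linalg.matrix_rank(W))
    rank_M = int(np.linalg.matrix_rank(M))

    Qb, _ = scipy.linalg.qr(basis_cols, mode="economic")
    resid = scores.F - Qb @ (Qb.T @ scores.F)
    proj_resid = float(np.linalg.norm(resid) / max(np.linalg.norm(scores.F), 1e-300))

    unique = True
    if data.Y is None or params.B is None:
        unique = False
        notes.append("no external criteria: scores are not uniquely determined "
                     "(plain MDFA indeterminacy)")
    else:
        if q < r:
            unique = False
            notes.append(f"q={q} < r={r}: too few external criteria")
        if rank_B is not None and rank_B < r:
            unique = False
            notes.append("B is column-rank deficient")
        if rank_Y is not None and rank_Y < q:
            unique = False
            notes.append("Y has linearly dependent columns")
    if rank_W < r + p:
        unique = False
        notes.append("weight block [A, Psi; sqrt(alpha) B, 0] is rank deficient: "
                     "its loading and uniqueness columns are not independent")
    if rank_M < r + p:
        unique = False
        notes.append("product block G W is column-rank deficient: the SVD score "
                     "update is not unique")
    if rank_X < p:
        notes.append("X is column-rank deficient")

    return IdentificationReport(
        unique=unique, q=q, r=r, rank_X=rank_X, rank_Y=rank_Y, rank_A=rank_A,
        rank_B=rank_B, rank_weight_block=rank_W, rank_product=rank_M,
        projection_residual=proj_resid, notes=notes)


def select_alpha(data: DataBundle, r: int, config: AlgoConfig | None = None,
                 grid: tuple[float, ...] = ALPHA_GRID,
                 rmsea_tol: float = 0.05) -> tuple[float, FitResult]:
    """Grid heuristic for the tuning weight.

    Scans the grid in increasing order and returns the smallest ``alpha``
    whose fitted loadings stay within ``rmsea_tol`` (root-mean-square
    deviation after orthogonal alignment) of the plain MDFA loadings, i.e.
    the smallest weight that pins the scores without distorting the
    factor-analytic solution.  Falls back to the smallest grid value with a
    warning when none qualifies.
    """
    from .mdfa import fit_mdfa
    from .rotation import align_for_rmsea
    from .scoring_metrics import rmsea

    config = config or AlgoConfig()
    reference = fit_mdfa(data, r, config).params.A
    fallback: tuple[float, FitResult] | None = None
    for a in sorted(grid):
        cfg = AlgoConfig(alpha=a, n_starts=config.n_starts, tol=config.tol,
                         max_iter=config.max_iter, seed=config.seed,
                         local_solution_threshold=config.local_solution_threshold)
        fit = fit_rfe(data, r, cfg)
        aligned = align_for_rmsea(fit.params.A, reference, mode="procrustes")
        if fallback is None:
            fallback = (a, fit)
        if rmsea(aligned, reference) < rmsea_tol:
            return a, fit
    warnings.warn(
        "no grid value kept the loadings within the requested distance of the "
        "plain MDFA fit; returning the smallest alpha", stacklevel=2)
    assert fallback is not None
    return fallback
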