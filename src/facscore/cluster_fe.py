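"""Clustering-based factor exploration (CFE) and the two-stage CCFE baseline.

CFE replaces the regression penalty of RFE by a K-means objective,

    ||X - F A' - U Psi||^2 + alpha ||F - M C'||^2,

jointly estimating the factor model, a binary membership matrix ``M`` and
centroids ``C`` while the score constraint ``(1/n) Z'Z = I`` is kept.  The
score update reuses the RFE machinery with the external-criteria block
replaced by the current cluster reconstruction ``M C'`` and its coefficient
block fixed to the identity.

CCFE is the earlier two-stage approach: fit plain MDFA first, then choose
the *free* part of the scores (see :class:`facscore.mdfa.ScoreDecomposition`)
to agree with a K-means structure as well as possible.  Because the free
rotation is optimized against the clustering objective alone, CCFE carves
tight clusters even when the underlying scores have none; CFE's penalty is
weighed against the factor-analytic fit and resists that artefact.  The
within-cluster variance and centroid separation computed by
:func:`cluster_stats` quantify the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.cluster import kmeans_plusplus

from .model_core import (AlgoConfig, DataBundle, FactorParams,
                         InternalConsistencyError, ScoreSet, check_constraint,
                         mdfa_loss)
from .mdfa import decompose_scores, fit_mdfa
from .rfe import FitResult, _init_params, update_coefficients, update_psi, update_scores


@dataclass
class ClusterModel:
    """Binary membership matrix ``M`` (n x k, row sums 1) and centroids ``C``."""

    M: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        self.C = np.asarray(self.C, dtype=float)
        if self.M.ndim != 2 or self.C.ndim != 2:
            raise ValueError("M and C must be 2-D")
        if self.M.shape[1] != self.C.shape[0]:
            raise ValueError("M's columns must match C's rows (k clusters)")
        if not np.array_equal(np.unique(self.M), np.array([0, 1])) \
                and not np.array_equal(np.unique(self.M), np.array([1])):
            raise ValueError("M must be binary")
        if not np.all(self.M.sum(axis=1) == 1):
            raise ValueError("every row of M must sum to 1")

    @property
    def k(self) -> int:
        return self.M.shape[1]

    @property
    def labels(self) -> np.ndarray:
        """Zero-based cluster index per observation."""
        return np.argmax(self.M, axis=1)


@dataclass
class ClusterStats:
    """Within-cluster variances and pairwise centroid distances."""

    within: np.ndarray
    centroid_distances: np.ndarray
    min_within: float
    max_between: float


def _sq_dists(F: np.ndarray, C: np.ndarray) -> np.ndarray:
    diff = F[:, None, :] - C[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _assign(F: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels; equidistant ties go to the lowest index.

    Empty clusters are re-seeded at the point farthest from its assigned
    centroid, which never increases the K-means objective.
    """
    k = C.shape[0]
    for _ in range(k + 1):
        d2 = _sq_dists(F, C)
        labels = np.argmin(d2, axis=1)
        empty = [g for g in range(k) if not np.any(labels == g)]
        if not empty:
            return labels
        far = int(np.argmax(d2[np.arange(len(labels)), labels]))
        C = C.copy()
        C[empty[0]] = F[far]
    raise InternalConsistencyError("could not resolve empty clusters")


def _membership(labels: np.ndarray, k: int) -> np.ndarray:
    M = np.zeros((labels.shape[0], k), dtype=int)
    M[np.arange(labels.shape[0]), labels] = 1
    return M


def _centroids(F: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    C = np.empty((k, F.shape[1]))
    for g in range(k):
        C[g] = F[labels == g].mean(axis=0)
    return C


def _init_centroids(F: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    seed = int(rng.integers(0, 2**31 - 1))
    centers, _ = kmeans_plusplus(F, n_clusters=k, random_state=seed)
    return centers


def _cfe_loss(data: DataBundle, params: FactorParams, scores: ScoreSet,
              labels: np.ndarray, C: np.ndarray, alpha: float) -> float:
    pen = float(np.sum((scores.F - C[labels]) ** 2))
    return mdfa_loss(data, params, scores) + alpha * pen


def fit_cfe(data: DataBundle, r: int, k: int,
            config: AlgoConfig | None = None) -> tuple[FitResult, ClusterModel]:
    """Joint factor-and-cluster fit by alternating minimization.

    Every substep (constrained score update, uniqueness and loading updates,
    K-means assignment and centroid updates) is an exact conditional
    minimizer, so the total loss is non-increasing.  The best of
    ``config.n_starts`` random starts is returned.
    """
    config = config or AlgoConfig()
    if not 2 <= k < data.n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={data.n}")
    if r < 1 or r >= data.p:
        raise ValueError(f"need 1 <= r < p, got r={r}, p={data.p}")
    data.require_headroom(r)
    alpha = config.alpha
    n = data.n
    norm_g2 = max(float(np.sum(data.X ** 2)), 1e-12)

    runs = []
    for i in range(config.n_starts):
        rng = np.random.default_rng(config.seed + i)
        params = _init_params(data, r, rng, with_b=False)
        # bootstrap scores from a plain (penalty-free) update, then seed clusters
        scores, _ = update_scores(
            data.X, np.hstack([params.A, np.diag(params.psi)]), n, r)
        C = _init_centroids(scores.F, k, rng)
        labels = _assign(scores.F, C)
        C = _centroids(scores.F, labels, k)

        prev = np.inf
        loss_path: list[float] = []
        converged = False
        rank_deficient = False
        max_dev = 0.0
        sa = np.sqrt(alpha)
        for _ in range(config.max_iter):
            G = np.hstack([data.X, sa * C[labels]])
            W = np.zeros((data.p + r, r + data.p))
            W[:data.p, :r] = params.A
            W[:data.p, r:] = np.diag(params.psi)
            W[data.p:, :r] = sa * np.eye(r)
            scores, full_rank = update_scores(G, W, n, r)
            rank_deficient = rank_deficient or not full_rank
            _, dev = check_constraint(scores, n)
            max_dev = max(max_dev, dev)

            psi = update_psi(data, scores)
            A, _ = update_coefficients(data, scores)
            params = FactorParams(A=A, psi=psi)

            labels = _assign(scores.F, C)
            C = _centroids(scores.F, labels, k)

            loss = _cfe_loss(data, params, scores, labels, C, alpha)
            loss_path.append(loss)
            if loss > prev + 1e-9 * max(1.0, prev):
                raise InternalConsistencyError(
                    f"CFE loss increased from {prev!r} to {loss!r}")
            if prev - loss < config.tol * norm_g2:
                converged = True
                break
            prev = loss
        runs.append({"params": params, "scores": scores, "labels": labels,
                     "C": C, "loss": loss_path[-1],
                     "loss_path": np.asarray(loss_path), "converged": converged,
                     "rank_deficient": rank_deficient, "max_dev": max_dev})

    from .scoring_metrics import local_solution_proportion

    start_losses = np.array([run["loss"] for run in runs])
    best = runs[int(np.argmin(start_losses))]
    result = FitResult(
        params=best["params"], scores=best["scores"],
        loss_path=best["loss_path"], start_losses=start_losses,
        best_loss=float(start_losses.min()),
        local_solution_proportion=local_solution_proportion(
            start_losses, config.local_solution_threshold),
        alpha=alpha, converged=best["converged"],
        n_iter=len(best["loss_path"]), method="cfe",
        rank_deficient=best["rank_deficient"],
        max_constraint_dev=best["max_dev"])
    model = ClusterModel(M=_membership(best["labels"], k), C=best["C"])
    return result, model


def fit_ccfe(data: DataBundle, r: int, k: int,
             config: AlgoConfig | None = None) -> tuple[FitResult, ClusterModel]:
    """Two-stage baseline: plain MDFA, then cluster the free score component.

    Stage 1 fits MDFA and splits the optimal scores into the determinate
    part and the free component — an n x r column-orthonormal block
    orthogonal to col(X) that the factor-analytic loss leaves completely
    undetermined.  Stage 2 alternates K-means steps on ``F`` with an exact
    Procrustes update of the *entire* free block minimizing
    ``||F - M C'||^2`` over the indeterminacy class; the full score set
    keeps the orthonormality constraint exactly throughout.  Because the
    free block is chosen against the clustering objective alone, this
    baseline carves tight clusters even out of structureless scores.
    ``loss_path`` and the start losses of the returned result refer to the
    stage-2 clustering objective; the factor parameters are those of the
    stage-1 MDFA fit.
    """
    config = config or AlgoConfig()
    if not 2 <= k < data.n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={data.n}")
    stage1 = fit_mdfa(data, r, config)
    dec = decompose_scores(data, stage1.params,
                           rng=np.random.default_rng(config.seed))
    n = data.n
    Jf = dec._Jf
    root_n = np.sqrt(n)
    Qx, _ = scipy.linalg.qr(data.X, mode="economic")
    scale = max(float(np.sum(dec.F_det ** 2)) + n * r, 1e-12)

    def free_block_update(labels: np.ndarray, C: np.ndarray,
                          P2: np.ndarray) -> np.ndarray:
        # maximize tr(P2' (M C' - F_det) Jf') over orthonormal P2 _|_ col(X)
        K = (C[labels] - dec.F_det) @ Jf.T
        K -= Qx @ (Qx.T @ K)
        Us, s, Vts = scipy.linalg.svd(K, full_matrices=False)
        if s[-1] <= 1e-12 * max(s[0], 1.0):
            return P2  # degenerate target: keep the current basis
        return Us @ Vts

    runs = []
    for i in range(config.n_starts):
        rng = np.random.default_rng(config.seed + i)
        T0, _ = scipy.linalg.qr(rng.standard_normal((r, r)))
        P2 = dec.basis_perp @ T0
        F = dec.F_det + root_n * P2 @ Jf
        C = _init_centroids(F, k, rng)
        labels = _assign(F, C)
        C = _centroids(F, labels, k)

        prev = np.inf
        path: list[float] = []
        converged = False
        for _ in range(config.max_iter):
            P2 = free_block_update(labels, C, P2)
            F = dec.F_det + root_n * P2 @ Jf

            labels = _assign(F, C)
            C = _centroids(F, labels, k)

            obj = float(np.sum((F - C[labels]) ** 2))
            path.append(obj)
            if obj > prev + 1e-9 * max(1.0, prev):
                raise InternalConsistencyError(
                    f"CCFE stage-2 objective increased from {prev!r} to {obj!r}")
            if prev - obj < config.tol * scale:
                converged = True
                break
            prev = obj
        runs.append({"P2": P2, "labels": labels, "C": C, "obj": path[-1],
                     "path": np.asarray(path), "converged": converged})

    from .scoring_metrics import local_solution_proportion

    objs = np.array([run["obj"] for run in runs])
    best = runs[int(np.argmin(objs))]
    scores = dec.score_with_basis(best["P2"])
    _, dev = check_constraint(scores, n)
    result = FitResult(
        params=stage1.params, scores=scores, loss_path=best["path"],
        start_losses=objs, best_loss=float(objs.min()),
        local_solution_proportion=local_solution_proportion(
            objs, config.local_solution_threshold),
        alpha=None, converged=best["converged"], n_iter=len(best["path"]),
        method="ccfe", rank_deficient=stage1.rank_deficient,
        max_constraint_dev=max(stage1.max_constraint_dev, dev))
    model = ClusterModel(M=_membership(best["labels"], k), C=best["C"])
    return result, model


def cluster_stats(F: np.ndarray, model: ClusterModel) -> ClusterStats:
    """Within-cluster variances and centroid separations of clustered scores.

    The within-cluster variance of cluster ``g`` is the mean squared
    Euclidean distance of its members to centroid ``g``; centroid
    separations are plain Euclidean distances between centroid rows.
    """
    F = np.asarray(F, dtype=float)
    labels = model.labels
    k = model.k
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):
        raise ValueError("within-cluster variance is undefined for an empty cluster")
    within = np.empty(k)
    for g in range(k):
        diff = F[labels == g] - model.C[g]
        within[g] = float(np.mean(np.sum(diff * diff, axis=1)))
    diffc = model.C[:, None, :] - model.C[None, :, :]
    dists = np.sqrt(np.einsum("ijk,ijk->ij", diffc, diffc))
    iu = np.triu_indices(k, 1)
    return ClusterStats(within=within, centroid_distances=dists,
                        min_within=float(within.min()),
                        max_between=float(dists[iu].max()))
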