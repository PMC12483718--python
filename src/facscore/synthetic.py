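"""Synthetic data generators used by the tests and the simulation study.

Three designs are provided:

* :func:`generate_dataset` — the Monte Carlo recovery design: exactly
  orthonormal true scores, perfect-simple-structure loadings with uniform
  nonzero magnitudes and random signs, dense regression coefficients for the
  external criteria, and Gaussian error rescaled so the explained-variance
  proportion ``rho`` is hit exactly;
* :func:`generate_nocluster_demo` — a small cluster-free benchmark
  (continuous scores, fixed simple-structure loadings, uniform residuals)
  for demonstrating that a clustering penalty does not invent structure;
* :func:`generate_clustered_demo` — a planted-cluster variant for testing
  membership recovery.

All generators return exactly constraint-satisfying true score blocks and
column-centered data, and are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .cluster_fe import ClusterModel
from .model_core import DataBundle, FactorParams, ScoreSet

#: the three explained-variance levels of the recovery study
RHO_GRID = (0.5, 0.7, 0.9)


@dataclass
class SimulationDesign:
    """Conditions of one cell of the Monte Carlo recovery study.

    Defaults: n=200 observations, p=12 variables, r=3 factors, q=3 external
    criteria, nonzero loadings Uniform(0.5, 1.0) with random signs, true
    uniqueness square roots 0.5 for every variable, explained variance 0.9.
    """

    n: int = 200
    p: int = 12
    q: int = 3
    r: int = 3
    rho: float = 0.9
    loading_low: float = 0.5
    loading_high: float = 1.0
    psi_true: np.ndarray | None = None
    seed: int = 0
    cluster_spec: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")
        if self.n <= self.p + self.r:
            raise ValueError("need n > p + r")
        if self.psi_true is None:
            self.psi_true = np.full(self.p, 0.5)
        else:
            self.psi_true = np.asarray(self.psi_true, dtype=float).ravel()
            if self.psi_true.shape[0] != self.p or np.any(self.psi_true < 0):
                raise ValueError("psi_true must be a nonnegative length-p vector")


@dataclass
class TruthBundle:
    """True parameters and scores underlying a generated dataset."""

    scores: ScoreSet
    params: FactorParams
    clusters: ClusterModel | None = None


def generate_true_scores(n: int, r: int, p: int,
                         seed: int | np.random.Generator = 0) -> ScoreSet:
    """Exactly constraint-satisfying true scores.

    An n x (r+p) block of Uniform(0, 1) draws is column-standardized; its
    left singular vectors, scaled by sqrt(n), give a score block with
    ``(1/n) Z'Z = I`` exactly and mean-zero columns.
    """
    if n <= p + r:
        raise ValueError("need n > p + r")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    raw = rng.uniform(0.0, 1.0, size=(n, r + p))
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    K, _, _ = scipy.linalg.svd(raw, full_matrices=False)
    Z = np.sqrt(n) * K
    return ScoreSet(F=Z[:, :r], U=Z[:, r:])


def simple_structure_loadings(p: int, r: int, low: float = 0.5,
                              high: float = 1.0,
                              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Perfect-cluster loading pattern: each variable loads on one factor.

    Variables are split into r consecutive blocks (the last block absorbs
    the remainder when p is not divisible by r); nonzero entries are drawn
    from Uniform(low, high) with random signs.
    """
    if r > p:
        raise ValueError("need r <= p")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    A = np.zeros((p, r))
    block = p // r
    for j in range(p):
        A[j, min(j // block, r - 1)] = 1.0
    mags = rng.uniform(low, high, size=p)
    signs = rng.choice([-1.0, 1.0], size=p)
    return A * (mags * signs)[:, None]


def scale_error_to_rho(model_part: np.ndarray, raw_error: np.ndarray,
                       rho: float) -> np.ndarray:
    """Rescale an error matrix so the explained-variance ratio equals rho.

    Returns ``c * raw_error`` with ``c`` chosen so that
    ``||model||^2 / (||model||^2 + ||c * error||^2) = rho`` exactly;
    ``rho = 1`` gives the zero matrix.
    """
    if model_part.shape != raw_error.shape:
        raise ValueError("model part and error must have the same shape")
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    if rho == 1.0:
        return np.zeros_like(raw_error)
    err_norm = float(np.linalg.norm(raw_error))
    if err_norm == 0:
        raise ValueError("raw error matrix must be nonzero")
    c = float(np.linalg.norm(model_part)) / err_norm * np.sqrt((1 - rho) / rho)
    return c * raw_error


def generate_dataset(design: SimulationDesign) -> tuple[DataBundle, TruthBundle]:
    """One replication of the recovery design.

    ``X = F A' + U Psi + E_x`` and ``Y = F B' + E_y`` with standard-normal
    raw errors rescaled to the design's ``rho``; both outputs are
    column-centered afterwards.  ``B`` is dense Uniform(loading_low,
    loading_high) with random signs.
    """
    rng = np.random.default_rng(design.seed)
    scores = generate_true_scores(design.n, design.r, design.p, rng)
    A = simple_structure_loadings(design.p, design.r, design.loading_low,
                                  design.loading_high, rng)
    B = rng.uniform(design.loading_low, design.loading_high,
                    size=(design.q, design.r)) \
        * rng.choice([-1.0, 1.0], size=(design.q, design.r))
    psi = np.asarray(design.psi_true, dtype=float)

    model_x = scores.F @ A.T + scores.U * psi
    ex = scale_error_to_rho(model_x, rng.standard_normal(model_x.shape), design.rho)
    X = model_x + ex
    model_y = scores.F @ B.T
    ey = scale_error_to_rho(model_y, rng.standard_normal(model_y.shape), design.rho)
    Y = model_y + ey

    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    data = DataBundle(X=X, Y=Y)
    truth = TruthBundle(scores=scores, params=FactorParams(A=A, psi=psi, B=B))
    return data, truth


#: fixed loadings of the cluster-free demonstration: six variables, two
#: factors, perfect simple structure with loadings 0.8
DEMO_LOADING = 0.8
#: fixed uniqueness square roots of the demonstration variables
DEMO_PSI = 0.6


def generate_nocluster_demo(n: int = 200,
                            seed: int = 0) -> tuple[DataBundle, ScoreSet]:
    """Cluster-free demonstration data: continuous scores, no planted groups.

    Six variables load 0.8 on one of two factors each; uniqueness square
    roots are 0.6; residuals are Uniform(-1, 1).  Returns the centered data
    and the true scores (which exhibit no cluster structure by
    construction).
    """
    rng = np.random.default_rng(seed)
    p, r = 6, 2
    scores = generate_true_scores(n, r, p, rng)
    A = np.zeros((p, r))
    A[:3, 0] = DEMO_LOADING
    A[3:, 1] = DEMO_LOADING
    psi = np.full(p, DEMO_PSI)
    X = scores.F @ A.T + scores.U * psi + rng.uniform(-1.0, 1.0, size=(n, p))
    X = X - X.mean(axis=0)
    return DataBundle(X=X), scores


def generate_clustered_demo(n: int, r: int = 2, k: int = 3,
                            separation: float = 8.0, seed: int = 0, *,
                            p: int = 6, rho: float = 0.9
                            ) -> tuple[DataBundle, TruthBundle]:
    """Planted-cluster scores pushed through the same data construction.

    Cluster centroids sit at simplex vertices with pairwise distance
    ``separation`` (in units of the unit within-cluster standard deviation);
    members scatter around them with standard-normal noise.  The raw scores
    are then symmetrically orthonormalized toward the scaled-orthonormality
    constraint — the closest exactly-valid score block — which preserves the
    planted structure whenever the clusters are well separated.
    ``separation = 0`` collapses to the cluster-free case.
    """
    if k < 2:
        raise ValueError("need k >= 2")
    if n <= p + r:
        raise ValueError("need n > p + r")
    rng = np.random.default_rng(seed)

    # simplex vertices in R^r with pairwise distance `separation`
    verts = _simplex_vertices(k, r, rng)
    d = float(np.linalg.norm(verts[0] - verts[1]))
    centers = verts * (separation / d) if d > 0 and separation > 0 \
        else np.zeros((k, r))
    labels = rng.integers(0, k, size=n)
    # guarantee non-empty planted clusters
    labels[:k] = np.arange(k)
    raw_f = centers[labels] + rng.standard_normal((n, r))
    raw_u = rng.standard_normal((n, p))
    raw = np.hstack([raw_f, raw_u])
    raw = raw - raw.mean(axis=0)

    # symmetric (closest-matrix) orthonormalization toward (1/n) Z'Z = I
    Uo, _, Vt = scipy.linalg.svd(raw, full_matrices=False)
    Z = np.sqrt(n) * (Uo @ Vt)
    scores = ScoreSet(F=Z[:, :r], U=Z[:, r:])

    A = _fixed_simple(p, r)
    psi = np.full(p, DEMO_PSI)
    model = scores.F @ A.T + scores.U * psi
    X = model + scale_error_to_rho(model, rng.standard_normal(model.shape), rho)
    X = X - X.mean(axis=0)

    M = np.zeros((n, k), dtype=int)
    M[np.arange(n), labels] = 1
    C = np.vstack([scores.F[labels == g].mean(axis=0) for g in range(k)])
    truth = TruthBundle(scores=scores, params=FactorParams(A=A, psi=psi),
                        clusters=ClusterModel(M=M, C=C))
    return DataBundle(X=X), truth


def _fixed_simple(p: int, r: int) -> np.ndarray:
    A = np.zeros((p, r))
    block = p // r
    for j in range(p):
        A[j, min(j // block, r - 1)] = DEMO_LOADING
    return A


def _simplex_vertices(k: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """k centroid positions in R^r with equal pairwise distances when possible.

    A regular simplex with k vertices needs k-1 dimensions; when r is too
    small, random unit directions are used instead (pairwise distances then
    vary, but remain of comparable magnitude).
    """
    if k - 1 <= r:
        E = np.eye(k) - 1.0 / k  # centered; pairwise distance sqrt(2)
        _, _, Vt = scipy.linalg.svd(E)
        pts = E @ Vt[: k - 1].T  # k x (k-1), still regular
        if k - 1 < r:
            pts = np.hstack([pts, np.zeros((k, r - (k - 1)))])
        return pts
    pts = rng.standard_normal((k, r))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts
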