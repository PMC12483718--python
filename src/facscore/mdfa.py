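"""Plain matrix-decomposition factor analysis and score indeterminacy.

The plain fit minimizes ``||X - F A' - U Psi||^2`` under ``(1/n) Z'Z = I``
with no external criteria.  At the optimum the score block is *not* unique:
writing the SVD of the product block ``X [A, Psi] = P L Q'``, exactly ``r``
singular values vanish (for full-column-rank ``X``), so the left singular
vectors paired with them can be replaced by any orthonormal set orthogonal
to the determined part.  :func:`decompose_scores` materializes this split:
the common scores decompose as

    F(T) = F_det + sqrt(n) * basis_perp @ T @ Jf

with ``F_det`` a linear combination of the columns of ``X``, ``basis_perp``
an orthonormal basis orthogonal to the column space of ``X``, ``Jf`` a fixed
mixing block from the SVD's null space, and ``T`` an arbitrary orthogonal
r x r matrix.  Every choice of ``T`` attains the same loss — this is factor
score indeterminacy made explicit, and it is the degree of freedom that the
regression (RFE) and clustering (CFE/CCFE) penalties pin down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model_core import (AlgoConfig, DataBundle, FactorParams,
                         InternalConsistencyError, ScoreSet, mdfa_loss)
from .rfe import FitResult, _fit_als, _RANK_TOL


@dataclass
class ScoreDecomposition:
    """Split of the optimal MDFA scores into determinate and free parts.

    Attributes
    ----------
    F_det, U_det
        Uniquely determined parts of the common and unique scores; both are
        linear combinations of the columns of ``X``.
    basis_perp
        n x r orthonormal basis of a subspace orthogonal to col(X); the free
        part of the scores lives here.
    singulars
        The p singular values of ``X`` itself.
    Q_det, Q_free
        Right singular blocks of ``X [A, Psi]``: determined directions
        ((r+p) x p) and null directions ((r+p) x r).
    """

    F_det: np.ndarray
    U_det: np.ndarray
    basis_perp: np.ndarray
    singulars: np.ndarray
    Q_det: np.ndarray
    Q_free: np.ndarray
    n: int
    r: int

    @property
    def _Jf(self) -> np.ndarray:
        # r x r mixing block: first r rows of the null right-vectors, transposed
        return self.Q_free[: self.r, :].T

    @property
    def _Ju(self) -> np.ndarray:
        return self.Q_free[self.r:, :].T

    def common_scores(self, T: np.ndarray) -> np.ndarray:
        """Common scores ``F(T)`` for an orthogonal r x r ``T``."""
        return self.F_det + np.sqrt(self.n) * self.basis_perp @ T @ self._Jf

    def score_with_basis(self, P2: np.ndarray) -> ScoreSet:
        """The score set for an arbitrary free basis ``P2``.

        The full indeterminacy class of the optimal scores is obtained by
        replacing ``basis_perp`` with *any* n x r column-orthonormal block
        orthogonal to col(X); ``score_variant`` walks the subfamily reachable
        from the stored basis by an r x r rotation, this method walks the
        whole class.  No orthogonality checks are performed beyond shape;
        callers are expected to supply a valid basis.
        """
        P2 = np.asarray(P2, dtype=float)
        if P2.shape != self.basis_perp.shape:
            raise ValueError(f"P2 must have shape {self.basis_perp.shape}")
        root_n = np.sqrt(self.n)
        F = self.F_det + root_n * P2 @ self._Jf
        U = self.U_det + root_n * P2 @ self._Ju
        return ScoreSet(F=F, U=U)

    def score_variant(self, T: np.ndarray) -> ScoreSet:
        """The full score set (F, U) for an orthogonal r x r ``T``.

        Every variant satisfies the scaled orthonormality constraint exactly
        and attains the same MDFA loss.
        """
        T = np.asarray(T, dtype=float)
        if T.shape != (self.r, self.r):
            raise ValueError(f"T must be {self.r} x {self.r}, got {T.shape}")
        if not np.allclose(T.T @ T, np.eye(self.r), atol=1e-8):
            raise ValueError("T must be orthogonal")
        F = self.common_scores(T)
        U = self.U_det + np.sqrt(self.n) * self.basis_perp @ T @ self._Ju
        return ScoreSet(F=F, U=U)


def fit_mdfa(data: DataBundle, r: int, config: AlgoConfig | None = None) -> FitResult:
    """Fit plain MDFA from the best of ``config.n_starts`` random starts.

    The score update is the same ten Berge SVD step as in RFE with the
    external-criteria block absent; because the product block ``X [A, Psi]``
    is column-rank deficient by construction, the returned scores are one
    arbitrary member of the optimal family (see :func:`decompose_scores`).
    """
    config = config or AlgoConfig()
    if r < 1:
        raise ValueError("r must be >= 1")
    if r >= data.p:
        raise ValueError(f"r must be smaller than the number of variables p={data.p}")
    data.require_headroom(r)
    sv = scipy.linalg.svdvals(data.X)
    if sv[-1] <= _RANK_TOL * max(sv[0], 1.0):
        warnings.warn(
            "X is column-rank deficient; the MDFA fit proceeds but the "
            "determinate/free score decomposition is ill-defined", stacklevel=2)
    return _fit_als(data, r, config, use_y=False, method="mdfa")


def decompose_scores(data: DataBundle, params: FactorParams,
                     rng: np.random.Generator | None = None,
                     verify: bool = True) -> ScoreDecomposition:
    """Split the optimal scores for fitted ``params`` into determinate and
    free parts.

    Requires ``X`` to have full column rank ``p`` (otherwise the determined
    part is itself ambiguous and a :class:`ValueError` is raised).  The
    free-part basis is built by projecting a random Gaussian block out of
    col(X) and orthonormalizing, so pass ``rng`` for reproducibility; any
    valid basis spans the same indeterminacy class.

    When ``verify`` is true the MDFA loss is evaluated at two random
    orthogonal ``T`` and compared against ``T = I`` as a self-check of the
    indeterminacy statement.
    """
    rng = rng or np.random.default_rng(0)
    n, p, r = data.n, data.p, params.r
    sx = scipy.linalg.svdvals(data.X)
    if sx[-1] <= _RANK_TOL * max(sx[0], 1.0):
        raise ValueError(
            "decompose_scores requires X with full column rank p: the split "
            "into determinate and free score parts is otherwise ill-defined")

    W = np.hstack([params.A, np.diag(params.psi)])
    M = data.X @ W
    P, s, Qt = scipy.linalg.svd(M, full_matrices=False)
    # generically rank(X W) = p, leaving exactly r null directions
    if s[p - 1] <= _RANK_TOL * max(s[0], 1.0):
        warnings.warn(
            "product block X [A, Psi] has fewer than p positive singular "
            "values; the determinate part may be under-determined", stacklevel=2)
    Q = Qt.T
    P1, Q1 = P[:, :p], Q[:, :p]
    Q2 = Q[:, p:]
    F_det = np.sqrt(n) * P1 @ Q1[:r, :].T
    U_det = np.sqrt(n) * P1 @ Q1[r:, :].T

    # orthonormal basis orthogonal to col(X): project Gaussians, orthonormalize
    Qx, _ = scipy.linalg.qr(data.X, mode="economic")
    for _ in range(5):
        raw = rng.standard_normal((n, r))
        raw -= Qx @ (Qx.T @ raw)
        basis, Rtri = scipy.linalg.qr(raw, mode="economic")
        if np.min(np.abs(np.diag(Rtri))) > 1e-8:
            break
    else:  # pragma: no cover - probability zero
        raise InternalConsistencyError("could not build a basis orthogonal to col(X)")

    dec = ScoreDecomposition(F_det=F_det, U_det=U_det, basis_perp=basis,
                             singulars=sx, Q_det=Q1, Q_free=Q2, n=n, r=r)

    if verify:
        base = mdfa_loss(data, params, dec.score_variant(np.eye(r)))
        for _ in range(2):
            T, _ = scipy.linalg.qr(rng.standard_normal((r, r)))
            other = mdfa_loss(data, params, dec.score_variant(T))
            if abs(other - base) > 1e-8 * max(1.0, base):
                raise InternalConsistencyError(
                    "loss is not invariant over the free score rotation; "
                    "the decomposition is inconsistent")
    return dec
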