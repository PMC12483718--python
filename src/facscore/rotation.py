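"""Post-fit rotation and alignment utilities.

The fitted loss is invariant under a joint transformation of the common
block — loadings, regression coefficients and common scores — by a
nonsingular r x r matrix, so any fitted solution is one member of an orbit.
This module provides

* :func:`geomin_rotate` — oblique geomin rotation by gradient projection,
  the standard choice for interpreting loadings with row-wise simple
  structure; scores and coefficients are counter-transformed so the model
  reconstruction ``F A'`` is preserved exactly;
* :func:`procrustes_align` — orthogonal Procrustes alignment of one score
  matrix onto another, used when comparing score solutions;
* :func:`align_for_rmsea` — resolution of column order and sign (or a full
  orthogonal rotation) before computing recovery errors against a known
  truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import linear_sum_assignment


@dataclass
class RotationResult:
    """An oblique rotation ``T`` with transformed quantities.

    Conventions: rotated loadings ``A_rot = A (T')^{-1}``, factor
    correlations ``Phi = T'T`` (unit diagonal because the columns of ``T``
    are normalized), counter-rotated scores ``F_rot = F T`` so that
    ``F_rot A_rot' = F A'`` holds exactly.  ``B`` transforms like ``A``.
    """

    T: np.ndarray
    A_rot: np.ndarray
    Phi: np.ndarray
    criterion_value: float
    converged: bool
    n_iter: int
    B_rot: np.ndarray | None = None
    F_rot: np.ndarray | None = None


def geomin_criterion(L: np.ndarray, epsilon: float = 0.01) -> float:
    """Geomin complexity: sum over rows of the geometric mean of a_jl^2 + eps."""
    L2 = L * L + epsilon
    return float(np.sum(np.exp(np.mean(np.log(L2), axis=1))))


def _geomin_value_grad(L: np.ndarray, epsilon: float) -> tuple[float, np.ndarray]:
    r = L.shape[1]
    L2 = L * L + epsilon
    pro = np.exp(np.mean(np.log(L2), axis=1))
    f = float(np.sum(pro))
    Gq = (2.0 / r) * (L / L2) * pro[:, None]
    return f, Gq


def _gpa_oblique(A: np.ndarray, T0: np.ndarray, epsilon: float,
                 max_iter: int, tol: float) -> tuple[np.ndarray, float, bool, int]:
    """Oblique gradient-projection rotation of ``A`` starting from ``T0``.

    Standard gradient-projection algorithm: steepest descent on the rotation
    criterion over matrices ``T`` with unit-norm columns, with step halving.
    """
    T = T0.copy()
    L = A @ np.linalg.inv(T).T
    f, Gq = _geomin_value_grad(L, epsilon)
    G = -(L.T @ Gq @ np.linalg.inv(T)).T
    al = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Gp = G - T * np.sum(T * G, axis=0)[None, :]  # project onto the manifold
        s = float(np.linalg.norm(Gp))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(20):
            Xt = T - al * Gp
            Tt = Xt / np.sqrt(np.sum(Xt * Xt, axis=0))[None, :]
            Lt = A @ np.linalg.inv(Tt).T
            ft, Gqt = _geomin_value_grad(Lt, epsilon)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, L, f = Tt, Lt, ft
        G = -(L.T @ Gqt @ np.linalg.inv(T)).T
    return T, f, converged, it


def geomin_rotate(A: np.ndarray, epsilon: float = 0.01, n_starts: int = 30,
                  F: np.ndarray | None = None, B: np.ndarray | None = None,
                  max_iter: int = 1000, tol: float = 1e-5,
                  seed: int = 0) -> RotationResult:
    """Oblique geomin rotation of a loading matrix, best of random starts.

    The first start is the identity; the rest are random unit-column
    matrices.  Pass ``F`` and/or ``B`` to receive the consistently
    counter-transformed scores and coefficients.
    """
    A = np.asarray(A, dtype=float)
    r = A.shape[1]
    if r < 2:
        raise ValueError("rotation requires at least two factors")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, bool, int] | None = None
    for i in range(max(1, n_starts)):
        if i == 0:
            T0 = np.eye(r)
        else:
            T0 = rng.standard_normal((r, r))
            T0 /= np.sqrt(np.sum(T0 * T0, axis=0))[None, :]
        try:
            cand = _gpa_oblique(A, T0, epsilon, max_iter, tol)
        except np.linalg.LinAlgError:
            continue  # singular interim T; discard this start
        if best is None or cand[1] < best[1]:
            best = cand
    assert best is not None
    T, f, converged, it = best
    if not converged:
        warnings.warn("geomin rotation did not fully converge; returning the "
                      "best iterate", stacklevel=2)
    Tinv_t = np.linalg.inv(T).T
    return RotationResult(
        T=T, A_rot=A @ Tinv_t, Phi=T.T @ T, criterion_value=f,
        converged=converged, n_iter=it,
        B_rot=None if B is None else np.asarray(B, dtype=float) @ Tinv_t,
        F_rot=None if F is None else np.asarray(F, dtype=float) @ T)


def procrustes_align(F_source: np.ndarray,
                     F_target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal Procrustes: ``T = argmin ||F_source T - F_target||`` over
    orthogonal ``T``; returns ``(T, F_source @ T)``."""
    F_source = np.asarray(F_source, dtype=float)
    F_target = np.asarray(F_target, dtype=float)
    if F_source.shape != F_target.shape:
        raise ValueError("score matrices must have identical shapes")
    M = F_source.T @ F_target
    U, s, Vt = scipy.linalg.svd(M)
    if s[-1] <= 1e-12 * max(s[0], 1.0):
        warnings.warn("rank-deficient cross-product: the aligning rotation is "
                      "not unique", stacklevel=2)
    T = U @ Vt
    return T, F_source @ T


def _perm_sign_align(M_est: np.ndarray, M_true: np.ndarray) -> np.ndarray:
    """Optimal column permutation and signs minimizing the squared error.

    Because the squared error separates over target columns, the optimum
    over all permutation/sign combinations is found exactly: each potential
    pairing gets its best sign, and the pairing itself is solved as a linear
    assignment problem.
    """
    cross = M_est.T @ M_true
    ne = np.sum(M_est * M_est, axis=0)
    nt = np.sum(M_true * M_true, axis=0)
    cost = ne[:, None] + nt[None, :] - 2.0 * np.abs(cross)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty_like(rows)
    perm[cols] = rows
    signs = np.sign(cross[perm, np.arange(len(perm))])
    signs[signs == 0] = 1.0
    return M_est[:, perm] * signs[None, :]


def align_for_rmsea(M_est: np.ndarray, M_true: np.ndarray,
                    mode: str = "permutation_sign") -> np.ndarray:
    """Align an estimated matrix to its truth before computing recovery error.

    ``permutation_sign`` resolves column order and sign only (appropriate
    when the estimate is already in the truth's rotation); ``procrustes``
    applies the best orthogonal rotation (appropriate when the fitting loss
    is rotation-invariant, so the estimate sits at an arbitrary point of its
    orbit).
    """
    M_est = np.asarray(M_est, dtype=float)
    M_true = np.asarray(M_true, dtype=float)
    if M_est.shape != M_true.shape:
        raise ValueError("matrices must have identical shapes")
    if mode == "permutation_sign":
        return _perm_sign_align(M_est, M_true)
    if mode == "procrustes":
        _, aligned = procrustes_align(M_est, M_true)
        return aligned
    raise ValueError(f"unknown alignment mode: {mode!r}")
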