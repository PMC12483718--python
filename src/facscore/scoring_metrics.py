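"""Evaluation statistics: recovery error, local-solution frequency, post-hoc
scores, score comparisons and individual residuals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .model_core import DataBundle, FactorParams, ScoreSet


@dataclass
class RecoveryReport:
    """Recovery errors of the five parameter matrices of one fitted replication."""

    rmsea_A: float
    rmsea_F: float
    rmsea_U: float
    rmsea_B: float
    rmsea_uniqueness: float
    local_solution_proportion: float


def rmsea(M_hat: np.ndarray, M_true: np.ndarray) -> float:
    """Root mean squared element-wise deviation between two equal-shape arrays.

    Column order, sign and rotation are *not* resolved here; apply
    :func:`facscore.rotation.align_for_rmsea` first when the estimate's
    orientation is arbitrary.
    """
    M_hat = np.asarray(M_hat, dtype=float)
    M_true = np.asarray(M_true, dtype=float)
    if M_hat.shape != M_true.shape:
        raise ValueError(f"shape mismatch: {M_hat.shape} vs {M_true.shape}")
    d = M_hat - M_true
    return float(np.sqrt(np.mean(d * d)))


def local_solution_proportion(start_losses, threshold: float = 1e-4) -> float:
    """Fraction of multi-start losses exceeding the best by a relative margin.

    A start with converged loss ``f_j`` counts as a local solution when
    ``(f_j - f_min) / f_min > threshold``; for a zero best loss any strictly
    larger ``f_j`` beyond the absolute threshold counts.
    """
    losses = np.asarray(start_losses, dtype=float)
    if losses.size == 0:
        raise ValueError("start_losses must be non-empty")
    fmin = float(losses.min())
    denom = fmin if fmin > 0 else 1.0
    return float(np.mean((losses - fmin) / denom > threshold))


def bartlett_scores(X: np.ndarray, A: np.ndarray, psi: np.ndarray,
                    Phi: np.ndarray | None = None) -> np.ndarray:
    """Bartlett's weighted-least-squares factor scores.

    Per observation this solves the generalized least-squares problem
    ``min_f (x - A f)' Psi^{-2} (x - A f)``, giving

        F_hat = X Psi^{-2} A (A' Psi^{-2} A)^{-1},

    a linear map of ``X`` alone.  ``Phi`` (the factor correlation matrix of
    an oblique solution) is accepted and validated for interface parity with
    rotated loadings, but the weighted-least-squares estimator itself does
    not depend on it.  A vanishing uniqueness makes the weights singular and
    raises, naming the offending variable.
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(A, dtype=float)
    psi = np.asarray(psi, dtype=float).ravel()
    if psi.shape[0] != A.shape[0]:
        raise ValueError("psi must have one entry per variable")
    scale = max(float(np.max(psi)), 1.0)
    bad = np.where(psi <= 1e-8 * scale)[0]
    if bad.size:
        raise ValueError(
            f"uniqueness square root is (near) zero for variable index "
            f"{int(bad[0])}; Bartlett weights are singular for this variable")
    if Phi is not None:
        Phi = np.asarray(Phi, dtype=float)
        r = A.shape[1]
        if Phi.shape != (r, r) or not np.allclose(Phi, Phi.T, atol=1e-8) \
                or not np.allclose(np.diag(Phi), 1.0, atol=1e-6):
            raise ValueError("Phi must be a symmetric correlation matrix with "
                             "unit diagonal")
    WA = A / (psi ** 2)[:, None]
    return X @ WA @ np.linalg.inv(A.T @ WA)


def score_correlations(F1: np.ndarray, F2: np.ndarray,
                       align: bool = False) -> np.ndarray:
    """Pearson correlation per matched column pair of two score matrices.

    With ``align=True`` the columns of ``F1`` are first matched to ``F2`` by
    the permutation/sign search used for recovery errors.
    """
    F1 = np.asarray(F1, dtype=float)
    F2 = np.asarray(F2, dtype=float)
    if F1.shape != F2.shape:
        raise ValueError("score matrices must have identical shapes")
    if align:
        from .rotation import align_for_rmsea
        F1 = align_for_rmsea(F1, F2, mode="permutation_sign")
    c1 = F1 - F1.mean(axis=0)
    c2 = F2 - F2.mean(axis=0)
    s1 = np.sqrt(np.sum(c1 * c1, axis=0))
    s2 = np.sqrt(np.sum(c2 * c2, axis=0))
    if np.any(s1 == 0) or np.any(s2 == 0):
        raise ValueError("zero-variance column: correlation undefined")
    return np.sum(c1 * c2, axis=0) / (s1 * s2)


def cohens_d_ci(scores_group1, scores_group2,
                level: float = 0.95) -> tuple[float, float, float]:
    """Pooled-SD standardized mean difference with a large-sample CI.

    ``d = (mean1 - mean2) / s_pooled`` with the usual pooled standard
    deviation; the confidence interval is the normal approximation
    ``d +- z * SE`` with ``SE = sqrt((n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)))``.
    """
    g1 = np.asarray(scores_group1, dtype=float).ravel()
    g2 = np.asarray(scores_group2, dtype=float).ravel()
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least two observations")
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled standard deviation is zero")
    d = float((g1.mean() - g2.mean()) / np.sqrt(sp2))
    se = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2)))
    z = norm.ppf(0.5 + level / 2.0)
    return d, float(d - z * se), float(d + z * se)


def individual_residuals(data: DataBundle, params: FactorParams,
                         scores: ScoreSet) -> np.ndarray:
    """Euclidean norm of each observation's model residual.

    Because the fitted scores are unique, the row-wise residual
    ``x_i - A f_i - Psi u_i`` is well defined; its norm measures how poorly
    observation ``i`` complies with the factor model.  The squared values
    sum to the factor-analytic part of the loss.
    """
    resid = data.X - scores.F @ params.A.T - scores.U * params.psi
    return np.sqrt(np.sum(resid * resid, axis=1))
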