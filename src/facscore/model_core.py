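"""Core containers and loss functions for matrix-decomposition factor analysis.

The factor-analysis model fitted throughout this package decomposes a
column-centered data matrix ``X`` (n observations x p variables) as

    X  ~=  F A' + U Psi

where ``F`` (n x r) holds common factor scores, ``U`` (n x p) unique factor
scores, ``A`` (p x r) factor loadings and ``Psi`` a nonnegative diagonal
matrix of the square roots of the uniquenesses.  The joint score block
``Z = [F U]`` is constrained to be column-orthonormal after scaling:
``(1/n) Z'Z = I``.  The regression-penalized variant adds external criteria
``Y`` (n x q) with coefficients ``B`` (q x r) and a tuning weight ``alpha``.

Everything downstream (the plain MDFA fit, RFE, CFE, CCFE) manipulates the
types defined here and reports the loss functions evaluated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: columns of X and Y must be mean-zero within this tolerance
CENTER_TOL = 1e-8
#: tolerance on the scaled orthonormality constraint (1/n) Z'Z = I
CONSTRAINT_TOL = 1e-6


class ConfigurationError(ValueError):
    """A method was invoked with inputs it is not defined for."""


class InternalConsistencyError(RuntimeError):
    """A mathematical guarantee of the algorithm was violated numerically."""


def _as_float_matrix(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite entries; "
                         "drop incomplete rows before constructing a DataBundle")
    return arr


@dataclass
class DataBundle:
    """Column-centered observed data ``X`` plus optional external criteria ``Y``.

    Centering is the caller's responsibility (the readers in
    :mod:`facscore.cli_io` do it); construction fails on non-centered input
    rather than silently recentering.
    """

    X: np.ndarray
    Y: np.ndarray | None = None
    row_ids: list | None = None
    var_names_x: list | None = None
    var_names_y: list | None = None

    def __post_init__(self) -> None:
        self.X = _as_float_matrix(self.X, "X")
        self._check_centered(self.X, "X")
        if self.Y is not None:
            self.Y = _as_float_matrix(self.Y, "Y")
            if self.Y.shape[0] != self.X.shape[0]:
                raise ValueError(
                    f"X and Y must have the same number of rows: "
                    f"{self.X.shape[0]} vs {self.Y.shape[0]}")
            self._check_centered(self.Y, "Y")
        if self.row_ids is not None and len(self.row_ids) != self.X.shape[0]:
            raise ValueError("row_ids length does not match the number of rows")
        if self.var_names_x is not None and len(self.var_names_x) != self.X.shape[1]:
            raise ValueError("var_names_x length does not match X's columns")
        if self.Y is not None and self.var_names_y is not None \
                and len(self.var_names_y) != self.Y.shape[1]:
            raise ValueError("var_names_y length does not match Y's columns")

    @staticmethod
    def _check_centered(mat: np.ndarray, name: str) -> None:
        dev = np.max(np.abs(mat.mean(axis=0))) if mat.size else 0.0
        if dev > CENTER_TOL:
            raise ValueError(
                f"columns of {name} must be mean-centered "
                f"(max |column mean| = {dev:.3g} > {CENTER_TOL:g})")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return 0 if self.Y is None else self.Y.shape[1]

    def require_headroom(self, r: int) -> None:
        """Enforce n > p + r, needed for the orthonormal score block to exist."""
        if self.n <= self.p + r:
            raise ValueError(
                f"need n > p + r for an n x (r+p) column-orthonormal score "
                f"block; got n={self.n}, p={self.p}, r={r}")


@dataclass
class FactorParams:
    """Loadings ``A`` (p x r), uniqueness square roots ``psi`` (length p),
    and optional regression coefficients ``B`` (q x r)."""

    A: np.ndarray
    psi: np.ndarray
    B: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = _as_float_matrix(self.A, "A")
        self.psi = np.asarray(self.psi, dtype=float).ravel()
        if self.psi.shape[0] != self.A.shape[0]:
            raise ValueError("psi length must equal the number of variables p")
        if np.any(self.psi < -1e-10):
            raise ValueError("psi entries (uniqueness square roots) must be >= 0")
        self.psi = np.maximum(self.psi, 0.0)
        if self.B is not None:
            self.B = _as_float_matrix(self.B, "B")
            if self.B.shape[1] != self.A.shape[1]:
                raise ValueError("B must have the same number of columns (r) as A")

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def r(self) -> int:
        return self.A.shape[1]

    @property
    def Psi(self) -> np.ndarray:
        """The diagonal p x p matrix of uniqueness square roots."""
        return np.diag(self.psi)


@dataclass
class ScoreSet:
    """Common scores ``F`` (n x r) and unique scores ``U`` (n x p)."""

    F: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.F = _as_float_matrix(self.F, "F")
        self.U = _as_float_matrix(self.U, "U")
        if self.F.shape[0] != self.U.shape[0]:
            raise ValueError(
                f"F and U must have the same number of rows: "
                f"{self.F.shape[0]} vs {self.U.shape[0]}")

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def r(self) -> int:
        return self.F.shape[1]

    @property
    def Z(self) -> np.ndarray:
        """The joint score block [F U], shape n x (r+p)."""
        return np.hstack([self.F, self.U])


@dataclass
class AlgoConfig:
    """Settings shared by all alternating-least-squares fitters.

    alpha
        Positive tuning weight on the penalty term (regression or K-means).
        A small value keeps the factor-analytic part dominant.
    n_starts
        Number of random initializations; the best converged loss wins.
    tol
        Convergence threshold on the per-iteration loss decrease, relative
        to the squared norm of the (augmented) data block.
    local_solution_threshold
        A start counts as a local solution when its converged loss exceeds
        the best one by more than this relative margin.
    """

    alpha: float = 0.01
    n_starts: int = 20
    tol: float = 1e-7
    max_iter: int = 1000
    seed: int = 0
    local_solution_threshold: float = 1e-4

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_starts < 1 or self.max_iter < 1:
            raise ValueError("n_starts and max_iter must be positive integers")


def check_constraint(scores: ScoreSet, n: int | None = None,
                     tol: float = CONSTRAINT_TOL) -> tuple[bool, float]:
    """Check the scaled orthonormality constraint (1/n) Z'Z = I.

    Returns ``(ok, max_deviation)`` where the deviation is the largest
    absolute entry of (1/n) Z'Z - I.
    """
    Z = scores.Z
    if n is None:
        n = Z.shape[0]
    gram = Z.T @ Z / n
    dev = float(np.max(np.abs(gram - np.eye(gram.shape[0]))))
    return dev <= tol, dev


def mdfa_loss(data: DataBundle, params: FactorParams, scores: ScoreSet) -> float:
    """Squared Frobenius norm ``||X - F A' - U Psi||^2``."""
    _check_shapes(data, params, scores)
    resid = data.X - scores.F @ params.A.T - scores.U * params.psi
    return float(np.sum(resid * resid))


def rfe_loss(data: DataBundle, params: FactorParams, scores: ScoreSet,
             alpha: float) -> float:
    """``||X - F A' - U Psi||^2 + alpha ||Y - F B'||^2``.

    ``alpha = 0`` is accepted for diagnostic evaluation (the value then
    equals :func:`mdfa_loss`); estimation itself requires ``alpha > 0``.
    """
    if data.Y is None:
        raise ConfigurationError(
            "rfe_loss requires external criteria Y; use mdfa_loss for plain "
            "factor analysis without external variables")
    if params.B is None:
        raise ConfigurationError("rfe_loss requires regression coefficients B")
    resid_y = data.Y - scores.F @ params.B.T
    return mdfa_loss(data, params, scores) + alpha * float(np.sum(resid_y * resid_y))


def penalized_form_loss(data: DataBundle, params: FactorParams, scores: ScoreSet,
                        alpha: float) -> float:
    """The regression term re-expressed as penalties on ``B``.

    Under the score constraint (``F'F = n I``) the regression term expands to
    an L2 penalty on ``B`` minus a factor-criterion covariance term plus the
    constant ``alpha ||Y||^2``:

        ||Y - F B'||^2 = ||Y||^2 + n ||B||^2 - 2 tr(B F'Y)

    The returned value omits the constant, so

        rfe_loss == penalized_form_loss + alpha * ||Y||^2

    whenever the constraint holds.  Used as an algebraic cross-check.
    """
    if data.Y is None:
        raise ConfigurationError("penalized_form_loss requires external criteria Y")
    if params.B is None:
        raise ConfigurationError("penalized_form_loss requires coefficients B")
    n = data.n
    cross = float(np.sum(data.Y * (scores.F @ params.B.T)))
    penalty = alpha * (n * float(np.sum(params.B * params.B)) - 2.0 * cross)
    return mdfa_loss(data, params, scores) + penalty


def penalized_form_constant(data: DataBundle, alpha: float) -> float:
    """The constant ``alpha ||Y||^2`` dropped by :func:`penalized_form_loss`."""
    if data.Y is None:
        raise ConfigurationError("no external criteria Y present")
    return alpha * float(np.sum(data.Y * data.Y))


def _check_shapes(data: DataBundle, params: FactorParams, scores: ScoreSet) -> None:
    if params.p != data.p:
        raise ValueError(f"loadings have p={params.p} rows but X has p={data.p} columns")
    if scores.F.shape != (data.n, params.r):
        raise ValueError(
            f"F has shape {scores.F.shape}, expected {(data.n, params.r)}")
    if scores.U.shape != (data.n, data.p):
        raise ValueError(
            f"U has shape {scores.U.shape}, expected {(data.n, data.p)}")
    if params.B is not None and data.Y is not None \
            and params.B.shape[0] != data.q:
        raise ValueError(
            f"B has {params.B.shape[0]} rows but Y has q={data.q} columns")
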