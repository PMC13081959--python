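"""Rayleigh-quotient contrastive PCA core.

Contrastive PCA finds directions ``v`` that maximize variance in a *target*
dataset relative to a *background* dataset by maximizing the Rayleigh
quotient

.. math::

    R(v) = \\frac{v^\\top \\Sigma_T v}{v^\\top \\Sigma_B v},

whose stationary points are the generalized eigenvectors of the pair
``(Sigma_T, Sigma_B)``.  The corresponding eigenvalues are target-to-
background variance ratios, which makes them directly interpretable: a
direction with eigenvalue 4 carries four times as much variance in the
target as in the background.

This module provides the covariance and projection primitives shared by the
spatial (kernel-weighted) and functional (basis-coefficient) extensions, and
the generalized symmetric eigensolver itself.  The solver whitens with a
Cholesky factor of the (regularized) background covariance, which guarantees
real eigenvalues and background-orthonormal eigenvectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import (
    DegenerateDirectionError,
    InvalidInputError,
    SingularBackgroundError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CenteredMatrix",
    "CovarianceMatrix",
    "ContrastiveDecomposition",
    "center_columns",
    "sample_covariance",
    "generalized_eigensolve",
    "rayleigh_quotient",
    "project",
]

#: Relative tolerance used when checking symmetry of covariance inputs.
SYMMETRY_RTOL = 1e-8


@dataclass
class CenteredMatrix:
    """An observations x features matrix with explicit centering state.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_obs, n_features)``.
    centered
        Whether every column has zero mean.
    feature_ids, obs_ids
        Identifier lists aligned with the matrix axes.
    column_means
        Means subtracted during centering (``None`` if never centered).
    """

    values: np.ndarray
    centered: bool
    feature_ids: list[str] = field(default_factory=list)
    obs_ids: list[str] = field(default_factory=list)
    column_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("values must be a 2-D matrix")
        n, p = self.values.shape
        if not self.feature_ids:
            self.feature_ids = [f"f{j}" for j in range(p)]
        if not self.obs_ids:
            self.obs_ids = [f"o{i}" for i in range(n)]
        if len(self.feature_ids) != p:
            raise InvalidInputError(
                f"feature_ids length {len(self.feature_ids)} != {p} columns"
            )
        if len(self.obs_ids) != n:
            raise InvalidInputError(
                f"obs_ids length {len(self.obs_ids)} != {n} rows"
            )

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class CovarianceMatrix:
    """A p x p covariance estimate with its divisor and provenance tag.

    ``kind`` is one of ``plain`` (ordinary sample covariance),
    ``kernel_weighted`` (spatially weighted; may be indefinite if the kernel
    was truncated) and ``coefficient_space`` (Gram-whitened functional
    coefficient covariance).
    """

    values: np.ndarray
    divisor: int
    kind: str = "plain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidInputError("covariance must be square")
        _check_symmetric(self.values, name=f"{self.kind} covariance")

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class ContrastiveDecomposition:
    """Top-k generalized eigenpairs of a target/background covariance pair.

    ``eigenvalues`` are sorted descending; ``eigenvectors`` columns satisfy
    ``v_i^T (Sigma_B + eps I) v_j = delta_ij`` (background-orthonormality)
    and the Rayleigh quotient of column ``i`` equals ``eigenvalues[i]``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    regularization: float
    n_components: int

    @property
    def p(self) -> int:
        return self.eigenvectors.shape[0]


def _check_symmetric(values: np.ndarray, name: str = "matrix") -> None:
    scale = np.max(np.abs(values)) if values.size else 0.0
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if scale > 0 and asym > SYMMETRY_RTOL * scale:
        raise InvalidInputError(
            f"{name} is asymmetric beyond tolerance "
            f"(max |A - A^T| = {asym:.3e}, scale {scale:.3e})"
        )


def _as_cov_array(sigma: CovarianceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(sigma, CovarianceMatrix):
        return sigma.values
    arr = np.asarray(sigma, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InvalidInputError("covariance must be a square matrix")
    _check_symmetric(arr)
    return arr


def center_columns(
    M: np.ndarray,
    feature_ids: list[str] | None = None,
    obs_ids: list[str] | None = None,
) -> CenteredMatrix:
    """Subtract column means, retaining them as metadata.

    Raises
    ------
    InvalidInputError
        If the matrix has fewer than two rows or contains non-finite
        entries.
    """
    arr = np.asarray(M, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError("input must be a 2-D matrix")
    if arr.shape[0] < 2:
        raise InvalidInputError(
            f"need at least 2 observations to center, got {arr.shape[0]}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("input contains non-finite entries")
    means = arr.mean(axis=0)
    return CenteredMatrix(
        values=arr - means,
        centered=True,
        feature_ids=feature_ids or [],
        obs_ids=obs_ids or [],
        column_means=means,
    )


def sample_covariance(
    M: CenteredMatrix, *, center_if_needed: bool = False
) -> CovarianceMatrix:
    """Plain sample covariance ``M^T M / (n - 1)`` of a centered matrix.

    The ``(n - 1)`` divisor is used everywhere in this package so that
    generalized eigenvalues remain interpretable as variance ratios.
    """
    if not M.centered:
        if not center_if_needed:
            raise InvalidInputError(
                "matrix is not centered; pass center_if_needed=True or call "
                "center_columns first"
            )
        M = center_columns(M.values, M.feature_ids, M.obs_ids)
    n = M.n_obs
    if n < 2:
        raise InvalidInputError("need at least 2 observations")
    S = M.values.T @ M.values / (n - 1)
    S = (S + S.T) / 2.0
    return CovarianceMatrix(values=S, divisor=n - 1, kind="plain")


def default_regularization(sigma_B: np.ndarray) -> float:
    """Default ridge added to the background diagonal.

    ``1e-8 * trace(Sigma_B) / p`` — proportional to the mean background
    variance, so it is scale-equivariant and negligible for well-conditioned
    backgrounds while making rank-deficient ones solvable.
    """
    p = sigma_B.shape[0]
    return 1e-8 * float(np.trace(sigma_B)) / p


def generalized_eigensolve(
    sigma_T: CovarianceMatrix | np.ndarray,
    sigma_B: CovarianceMatrix | np.ndarray,
    k: int | None = None,
    eps: float | None = None,
) -> ContrastiveDecomposition:
    """Top-k generalized eigenpairs of ``(Sigma_T, Sigma_B + eps I)``.

    The problem is solved by whitening: factor ``Sigma_B + eps I = L L^T``
    (Cholesky), solve the ordinary symmetric eigenproblem of
    ``L^{-1} Sigma_T L^{-T}``, and back-transform ``v = L^{-T} u``.  This
    guarantees real eigenvalues and ``Sigma_B``-orthonormal eigenvectors.

    Parameters
    ----------
    sigma_T, sigma_B
        Target and background covariance matrices of identical dimension.
    k
        Number of components to retain (defaults to ``min(10, p)``).
    eps
        Nonnegative ridge added to the background diagonal; defaults to
        ``1e-8 * trace(Sigma_B)/p``.

    Raises
    ------
    SingularBackgroundError
        If ``Sigma_B + eps I`` is not positive definite; the message names
        its smallest eigenvalue.
    InvalidInputError
        On dimension mismatch, ``k > p``, or asymmetric input.
    """
    T = _as_cov_array(sigma_T)
    B = _as_cov_array(sigma_B)
    if T.shape != B.shape:
        raise InvalidInputError(
            f"covariance dimensions differ: {T.shape} vs {B.shape}"
        )
    p = T.shape[0]
    if k is None:
        k = min(10, p)
    if k < 1 or k > p:
        raise InvalidInputError(f"k={k} must be in [1, p={p}]")
    if eps is None:
        eps = default_regularization(B)
    if eps < 0:
        raise InvalidInputError("eps must be nonnegative")

    B_reg = B + eps * np.eye(p)
    try:
        L = linalg.cholesky(B_reg, lower=True)
    except linalg.LinAlgError:
        smallest = float(np.linalg.eigvalsh(B_reg)[0])
        raise SingularBackgroundError(
            "background covariance (after eps regularization) is not "
            f"positive definite; smallest eigenvalue = {smallest:.6e}"
        ) from None

    # M = L^{-1} Sigma_T L^{-T}, symmetrized against round-off
    half = linalg.solve_triangular(L, T, lower=True)
    M = linalg.solve_triangular(L, half.T, lower=True).T
    M = (M + M.T) / 2.0
    evals, U = linalg.eigh(M)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    U = U[:, order]
    V = linalg.solve_triangular(L, U, lower=True, trans="T")

    # sign convention: make each eigenvector's largest-magnitude entry positive
    for j in range(V.shape[1]):
        idx = int(np.argmax(np.abs(V[:, j])))
        if V[idx, j] < 0:
            V[:, j] = -V[:, j]

    if evals.size and evals[-1] < 0:
        n_neg = int(np.sum(evals < 0))
        logger.warning(
            "%d negative generalized eigenvalue(s) retained (target "
            "covariance indefinite, e.g. after kernel truncation)", n_neg
        )
        warnings.warn(
            f"{n_neg} negative generalized eigenvalue(s) retained",
            RuntimeWarning,
            stacklevel=2,
        )

    return ContrastiveDecomposition(
        eigenvalues=evals,
        eigenvectors=V,
        regularization=float(eps),
        n_components=k,
    )


def rayleigh_quotient(
    v: np.ndarray,
    sigma_T: CovarianceMatrix | np.ndarray,
    sigma_B: CovarianceMatrix | np.ndarray,
) -> float:
    """Evaluate ``v^T Sigma_T v / v^T Sigma_B v`` (scale-invariant in v)."""
    T = _as_cov_array(sigma_T)
    B = _as_cov_array(sigma_B)
    v = np.asarray(v, dtype=float).ravel()
    if v.size != T.shape[0] or T.shape != B.shape:
        raise InvalidInputError("dimension mismatch between v and covariances")
    if not np.any(v):
        raise InvalidInputError("v must be nonzero")
    denom = float(v @ B @ v)
    if denom <= 0:
        raise DegenerateDirectionError(
            f"v^T Sigma_B v = {denom:.6e} is not positive"
        )
    return float(v @ T @ v) / denom


def project(
    M: CenteredMatrix | np.ndarray, decomposition: ContrastiveDecomposition
) -> np.ndarray:
    """Project observations onto the contrastive directions.

    Returns an ``(n, k)`` score matrix; column ``i`` is the GE-(i+1) score of
    every observation.
    """
    values = M.values if isinstance(M, CenteredMatrix) else np.asarray(M, float)
    if values.ndim != 2 or values.shape[1] != decomposition.p:
        raise InvalidInputError(
            f"feature dimension {values.shape[-1]} does not match "
            f"decomposition dimension {decomposition.p}"
        )
    return values @ decomposition.eigenvectors
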