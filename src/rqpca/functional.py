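"""Contrastive functional PCA in basis-coefficient space (f-rhoPCA).

Two groups of noisy curves — a *target* process X(t) and a *background*
process Y(t) on a common interval — are each represented in a finite basis
``B(t) = (b_1(t), ..., b_D(t))``; each sample i becomes a coefficient row
``a_i`` via ordinary least squares.  The contrastive objective, maximizing
the Rayleigh quotient of the covariance *operators*

.. math::

    \\operatorname*{argmax}_\\phi
    \\frac{\\langle C_X \\phi, \\phi\\rangle}{\\langle C_Y \\phi, \\phi\\rangle},

restricted to the span of the basis with ``phi = f^T B(t)``, becomes a
finite-dimensional generalized eigenproblem.  Because the basis functions
need not be orthogonal, the Gram matrix ``G_kl = \\int b_k b_l`` enters:
the quotient in coefficients is ``f^T G Sigma_X G f / f^T G Sigma_Y G f``,
so the substitution ``w = G^{1/2} f`` whitens it into the symmetric pair
``(G^{1/2} Sigma_X G^{1/2}, G^{1/2} Sigma_Y G^{1/2})``.  Eigenfunctions are
reconstructed with basis coefficients ``f = G^{-1/2} w``, which makes the
basis route agree with the discrete-grid route and makes the integral
projection score ``theta_i = \\int X_i(t) v(t) dt = a_i^T G f`` satisfy the
identity "variance ratio of scores on component 1 = lambda_1".

Coefficient rows are centered per group (the operator formulation subtracts
the group mean function) before covariances are formed, and the (n-1)
divisor keeps eigenvalues interpretable as variance ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .core import (
    CenteredMatrix,
    CovarianceMatrix,
    center_columns,
    generalized_eigensolve,
)
from .exceptions import (
    AccuracyError,
    AlignmentError,
    DegenerateDirectionError,
    InvalidInputError,
    NotPSDError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BasisSystem",
    "FunctionalSampleSet",
    "EigenfunctionSet",
    "GriddedEigenfunctionSet",
    "ScoreSet",
    "make_basis",
    "gram_matrix",
    "sqrt_psd",
    "fit_samples",
    "qc_filter",
    "QCReport",
    "f_rho_pca",
    "f_rho_pca_discrete",
    "score_samples",
    "score_variance_ratio",
]


# ---------------------------------------------------------------------------
# basis systems
# ---------------------------------------------------------------------------

@dataclass
class BasisSystem:
    """D linearly independent functions on a closed interval with their Gram
    matrix ``G_kl = int b_k(t) b_l(t) dt``.

    Supported kinds: ``bspline`` (order-`order` splines on uniform interior
    knots with full end-knot multiplicity), ``fourier`` (orthonormal
    constant + sin/cos pairs on the full period, G = I), ``monomial``
    (``1, t, t^2, ...``).
    """

    kind: str
    D: int
    domain: tuple[float, float]
    order: int | None = None
    knots: np.ndarray | None = None
    gram: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions at ``t``; returns ``(len(t), D)``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        t0, t1 = self.domain
        if self.kind == "monomial":
            return np.vander(t, self.D, increasing=True)
        if self.kind == "fourier":
            return _fourier_design(t, self.D, t0, t1)
        if self.kind == "bspline":
            spl = BSpline(self.knots, np.eye(self.D), self.order - 1)
            return spl(t)
        raise InvalidInputError(f"unknown basis kind {self.kind!r}")


def _fourier_design(t: np.ndarray, D: int, t0: float, t1: float) -> np.ndarray:
    T = t1 - t0
    out = np.empty((t.size, D))
    out[:, 0] = 1.0 / np.sqrt(T)
    amp = np.sqrt(2.0 / T)
    for j in range(1, D):
        m = (j + 1) // 2
        arg = 2.0 * np.pi * m * (t - t0) / T
        out[:, j] = amp * (np.sin(arg) if j % 2 == 1 else np.cos(arg))
    return out


def make_basis(
    kind: str,
    D: int,
    domain: tuple[float, float],
    order: int = 4,
) -> BasisSystem:
    """Construct a basis system with its Gram matrix precomputed.

    For B-splines the knot vector places ``D - order`` uniform interior
    knots on the domain with full multiplicity at both ends (so with
    ``D = order`` there are no interior knots and the basis is the Bernstein
    basis of degree ``order - 1``).
    """
    t0, t1 = float(domain[0]), float(domain[1])
    if not t1 > t0:
        raise InvalidInputError("domain must be a nondegenerate interval")
    if D < 1:
        raise InvalidInputError("D must be >= 1")
    knots = None
    if kind == "bspline":
        if D < order:
            raise InvalidInputError(
                f"bspline requires D >= order, got D={D}, order={order}"
            )
        interior = np.linspace(t0, t1, D - order + 2)[1:-1]
        knots = np.concatenate([[t0] * order, interior, [t1] * order])
        basis = BasisSystem(kind=kind, D=D, domain=(t0, t1), order=order,
                            knots=knots)
    elif kind in ("fourier", "monomial"):
        basis = BasisSystem(kind=kind, D=D, domain=(t0, t1))
    else:
        raise InvalidInputError(f"unknown basis kind {kind!r}")
    basis.gram = gram_matrix(basis)
    _check_gram_pd(basis.gram)
    return basis


def _check_gram_pd(G: np.ndarray) -> None:
    ev = np.linalg.eigvalsh(G)
    if ev[0] <= 1e-12 * ev[-1]:
        raise InvalidInputError(
            "basis functions are numerically linearly dependent "
            f"(Gram eigenvalue ratio {ev[0] / ev[-1]:.3e})"
        )


def gram_matrix(basis: BasisSystem) -> np.ndarray:
    """Gram matrix of a basis system.

    Analytic for monomial and Fourier systems; for B-splines, fixed-order
    Gauss-Legendre quadrature per knot span (exact for piecewise
    polynomials), verified by doubling the quadrature order.
    """
    t0, t1 = basis.domain
    D = basis.D
    if basis.kind == "monomial":
        k, l = np.meshgrid(np.arange(D), np.arange(D), indexing="ij")
        e = k + l + 1
        return (t1**e - t0**e) / e
    if basis.kind == "fourier":
        return np.eye(D)
    if basis.kind == "bspline":
        G1 = _quadrature_gram(basis, n_nodes=basis.order + 1)
        G2 = _quadrature_gram(basis, n_nodes=2 * (basis.order + 1))
        scale = max(np.max(np.abs(G2)), 1e-300)
        if np.max(np.abs(G1 - G2)) > 1e-8 * scale:
            raise AccuracyError(
                "B-spline Gram quadrature did not converge on order doubling"
            )
        return (G2 + G2.T) / 2.0
    raise InvalidInputError(f"unknown basis kind {basis.kind!r}")


def _quadrature_gram(basis: BasisSystem, n_nodes: int) -> np.ndarray:
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    spans = np.unique(basis.knots)
    G = np.zeros((basis.D, basis.D))
    for a, b in zip(spans[:-1], spans[1:]):
        mid, half = (a + b) / 2.0, (b - a) / 2.0
        t = mid + half * nodes
        Bt = basis.evaluate(t)
        G += half * (Bt.T * weights) @ Bt
    return G


def sqrt_psd(G: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition.

    Eigenvalues below zero (within ``-1e-10`` of the largest, relatively)
    are clipped to 0; a substantially negative eigenvalue raises.
    """
    G = np.asarray(G, dtype=float)
    ev, U = np.linalg.eigh((G + G.T) / 2.0)
    if ev[-1] > 0 and ev[0] < -1e-10 * ev[-1]:
        raise NotPSDError(
            f"matrix has substantially negative eigenvalue {ev[0]:.3e}"
        )
    ev = np.clip(ev, 0.0, None)
    return (U * np.sqrt(ev)) @ U.T


# ---------------------------------------------------------------------------
# sample fitting and QC
# ---------------------------------------------------------------------------

@dataclass
class FunctionalSampleSet:
    """Basis-coefficient representation of one group of fitted curves.

    ``coefficients`` has one row per successfully fitted sample;
    ``r_squared`` holds the per-sample goodness of fit (1 - RSS/TSS, TSS
    about the sample's own mean; defined as 0 for constant trajectories).
    Unfittable samples (fewer than D usable points) are excluded and
    recorded in ``unfittable`` as ``(sample_id, reason)`` pairs.
    """

    coefficients: np.ndarray
    basis: BasisSystem
    r_squared: np.ndarray
    group: str
    sample_ids: list[str]
    unfittable: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.coefficients.shape[0]

    @property
    def mean_coefficients(self) -> np.ndarray:
        """Empirical group mean in coefficient space (stand-in for the mean
        function of the process)."""
        return self.coefficients.mean(axis=0)

    def subset(self, keep: np.ndarray) -> "FunctionalSampleSet":
        keep = np.asarray(keep)
        return FunctionalSampleSet(
            coefficients=self.coefficients[keep],
            basis=self.basis,
            r_squared=self.r_squared[keep],
            group=self.group,
            sample_ids=[self.sample_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.sample_ids[i] for i in keep],
            unfittable=list(self.unfittable),
        )


def fit_samples(
    times: list[np.ndarray],
    values: list[np.ndarray],
    basis: BasisSystem,
    sample_ids: list[str] | None = None,
    group: str = "target",
) -> FunctionalSampleSet:
    """Least-squares fit of each sample's measurements to the basis.

    Samples may have different (irregular) time grids.  Points outside the
    basis domain are ignored; a sample with fewer than D distinct usable
    time points is flagged unfittable and excluded (not a hard failure).
    """
    if len(times) != len(values):
        raise InvalidInputError("times and values must have equal length")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(times))]
    t0, t1 = basis.domain
    coeffs, r2s, kept_ids, unfittable = [], [], [], []
    for sid, t, y in zip(sample_ids, times, values):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = (t >= t0) & (t <= t1) & np.isfinite(t) & np.isfinite(y)
        t, y = t[inside], y[inside]
        if np.unique(t).size < basis.D:
            unfittable.append(
                (sid, f"{np.unique(t).size} distinct usable points < D={basis.D}")
            )
            continue
        Bt = basis.evaluate(t)
        a, *_ = np.linalg.lstsq(Bt, y, rcond=None)
        resid = y - Bt @ a
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 0.0 if tss == 0.0 else 1.0 - float(np.sum(resid**2)) / tss
        coeffs.append(a)
        r2s.append(r2)
        kept_ids.append(sid)
    return FunctionalSampleSet(
        coefficients=np.array(coeffs).reshape(len(coeffs), basis.D),
        basis=basis,
        r_squared=np.asarray(r2s, dtype=float),
        group=group,
        sample_ids=kept_ids,
        unfittable=unfittable,
    )


@dataclass
class QCReport:
    """Outcome of the R-squared / group-size quality filter."""

    passed: bool
    dropped: list[tuple[str, str, str]]  # (sample_id, group, reason)
    n_target_kept: int
    n_background_kept: int


def qc_filter(
    target: FunctionalSampleSet,
    background: FunctionalSampleSet,
    r2_min: float = 0.5,
    min_per_group: int = 7,
) -> tuple[FunctionalSampleSet, FunctionalSampleSet, QCReport]:
    """Drop poorly fitted trajectories and apply the group-size rule.

    A sample is kept iff its R-squared is at least ``r2_min`` (inclusive).
    The unit of analysis passes QC only if both groups retain at least
    ``min_per_group`` samples; empty results are valid and reported.
    """
    if target.basis is not background.basis:
        raise AlignmentError("target and background must share the basis")
    dropped: list[tuple[str, str, str]] = []
    out = []
    for s in (target, background):
        keep = s.r_squared >= r2_min
        for i in np.flatnonzero(~keep):
            dropped.append(
                (s.sample_ids[i], s.group,
                 f"R2={s.r_squared[i]:.4f} < {r2_min}")
            )
        for sid, reason in s.unfittable:
            dropped.append((sid, s.group, f"unfittable: {reason}"))
        out.append(s.subset(keep))
    report = QCReport(
        passed=out[0].n >= min_per_group and out[1].n >= min_per_group,
        dropped=dropped,
        n_target_kept=out[0].n,
        n_background_kept=out[1].n,
    )
    return out[0], out[1], report


# ---------------------------------------------------------------------------
# the contrastive eigenproblem
# ---------------------------------------------------------------------------

@dataclass
class EigenfunctionSet:
    """Contrastive eigenfunctions in basis representation.

    ``w_vectors`` are the solutions of the whitened eigenproblem;
    ``coefficient_vectors`` are the basis coefficients of the
    eigenfunctions, related by ``coefficient_vectors = G^{-1/2} w``, so that
    ``v_k(t) = coefficient_vectors[:, k] . B(t)``.
    """

    coefficient_vectors: np.ndarray  # D x k
    w_vectors: np.ndarray  # D x k
    eigenvalues: np.ndarray
    basis: BasisSystem
    regularization: float = 0.0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Eigenfunction values on a grid; returns ``(len(t), k)``."""
        return self.basis.evaluate(t) @ self.coefficient_vectors


def _group_covariance(
    samples: FunctionalSampleSet, G_half: np.ndarray, center: bool
) -> CovarianceMatrix:
    A = samples.coefficients
    n = A.shape[0]
    if n < 2:
        raise InvalidInputError(
            f"group {samples.group!r} needs >= 2 samples, has {n}"
        )
    if center:
        A = A - A.mean(axis=0)
    C = G_half @ (A.T @ A) @ G_half / (n - 1)
    C = (C + C.T) / 2.0
    return CovarianceMatrix(values=C, divisor=n - 1, kind="coefficient_space")


def f_rho_pca(
    target: FunctionalSampleSet,
    background: FunctionalSampleSet,
    k: int | None = None,
    eps: float | None = None,
    center: bool = True,
) -> EigenfunctionSet:
    """Contrastive functional PCA in coefficient space.

    Centers each group's coefficient rows about its own mean, forms the
    Gram-whitened coefficient covariances
    ``G^{1/2} A^T A G^{1/2} / (n-1)`` for each group, solves the
    generalized eigenproblem, and reconstructs eigenfunction basis
    coefficients ``f = G^{-1/2} w``.
    """
    if target.basis is not background.basis:
        raise AlignmentError("target and background must share the basis")
    basis = target.basis
    G_half = sqrt_psd(basis.gram)
    C_X = _group_covariance(target, G_half, center)
    C_Y = _group_covariance(background, G_half, center)
    dec = generalized_eigensolve(C_X, C_Y, k=k, eps=eps)
    W = dec.eigenvectors
    G_half_inv = np.linalg.inv(G_half)
    F = G_half_inv @ W
    return EigenfunctionSet(
        coefficient_vectors=F,
        w_vectors=W,
        eigenvalues=dec.eigenvalues,
        basis=basis,
        regularization=dec.regularization,
    )


@dataclass
class GriddedEigenfunctionSet:
    """Eigenfunctions of the discrete-domain objective, defined on a grid
    with linear interpolation between grid points."""

    grid: np.ndarray
    values: np.ndarray  # p x k
    eigenvalues: np.ndarray
    regularization: float

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, self.values.shape[1]))
        for j in range(self.values.shape[1]):
            out[:, j] = np.interp(t, self.grid, self.values[:, j])
        return out


def f_rho_pca_discrete(
    target: CenteredMatrix | np.ndarray,
    background: CenteredMatrix | np.ndarray,
    grid: np.ndarray,
    k: int | None = None,
    eps: float | None = None,
) -> GriddedEigenfunctionSet:
    """Contrastive PCA of curves measured on a common discrete grid.

    Both matrices are samples x time-points on the same ordered grid; plain
    covariances over samples are contrasted and the eigenvectors are
    returned as gridded functions (linear interpolation between points).
    """
    grid = np.asarray(grid, dtype=float)
    X = target.values if isinstance(target, CenteredMatrix) else np.asarray(target, float)
    Y = background.values if isinstance(background, CenteredMatrix) else np.asarray(background, float)
    if X.shape[1] != grid.size or Y.shape[1] != grid.size:
        raise InvalidInputError(
            f"grid length {grid.size} does not match matrices "
            f"({X.shape[1]}, {Y.shape[1]} time points)"
        )
    Xc = center_columns(X)
    Yc = center_columns(Y)
    S_X = Xc.values.T @ Xc.values / (Xc.n_obs - 1)
    S_Y = Yc.values.T @ Yc.values / (Yc.n_obs - 1)
    dec = generalized_eigensolve((S_X + S_X.T) / 2, (S_Y + S_Y.T) / 2,
                                 k=k, eps=eps)
    return GriddedEigenfunctionSet(
        grid=grid,
        values=dec.eigenvectors,
        eigenvalues=dec.eigenvalues,
        regularization=dec.regularization,
    )


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

@dataclass
class ScoreSet:
    """Integral projections of fitted curves onto eigenfunctions."""

    scores: np.ndarray  # n x k
    group: str
    sample_ids: list[str]


def score_samples(
    samples: FunctionalSampleSet,
    efs: EigenfunctionSet,
    center: bool = True,
) -> ScoreSet:
    """Project fitted curves onto eigenfunctions.

    The score is the integral projection
    ``theta_ik = int X_i(t) v_k(t) dt``, computed exactly in coefficient
    space as ``a_i^T G f_k``.  By default coefficients are centered about
    the sample set's own mean, matching the covariance convention, so the
    variance ratio of component-1 scores between the fitting groups equals
    the top eigenvalue when ``eps = 0``.
    """
    if samples.basis is not efs.basis:
        raise AlignmentError("samples and eigenfunctions must share the basis")
    A = samples.coefficients
    if center:
        A = A - A.mean(axis=0)
    theta = A @ samples.basis.gram @ efs.coefficient_vectors
    return ScoreSet(scores=theta, group=samples.group,
                    sample_ids=list(samples.sample_ids))


def score_variance_ratio(
    target_scores: ScoreSet,
    background_scores: ScoreSet,
    component: int = 0,
) -> float:
    """Target-to-background variance ratio of scores on one component.

    Sample variances use the (n-1) divisor.  This is the statistic used to
    rank genes by how much more a temporal mode varies in the target group
    (e.g. booster dose) than in the background group (e.g. primer dose).
    """
    ts = target_scores.scores[:, component]
    bs = background_scores.scores[:, component]
    if ts.size < 2 or bs.size < 2:
        raise InvalidInputError("each group needs >= 2 samples")
    vb = float(np.var(bs, ddof=1))
    if vb <= 0:
        raise DegenerateDirectionError("background score variance is zero")
    return float(np.var(ts, ddof=1)) / vb
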