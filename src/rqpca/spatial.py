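"""Kernel-weighted contrastive PCA for spatially registered data (k-rhoPCA).

A spatially resolved expression matrix (Visium spots, Visium HD bins, or any
observations with coordinates) is contrasted against a non-spatial
background such as dissociated scRNA-seq.  The target covariance is replaced
by its kernel-weighted counterpart

.. math::

    \\hat\\Sigma^K = \\frac{1}{n-1} X^\\top K X,

where ``K_ij = exp(-||s_i - s_j||^2 / 2h^2)`` is a Gaussian kernel over
spatial locations.  The kernel up-weights covariance between nearby
observations, so the generalized eigenvectors of
``(Sigma_T^K, Sigma_B)`` pick out gene programs that vary *smoothly in
space* in the target while carrying little variance in the background.

The default bandwidth follows the median heuristic (square root of the
median pairwise distance).  For large datasets the kernel may be truncated
at a radius, chosen either directly or so that each observation keeps a
target mean number of spatial neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import pdist, squareform

from .core import (
    CenteredMatrix,
    ContrastiveDecomposition,
    CovarianceMatrix,
    generalized_eigensolve,
    project,
    sample_covariance,
)
from .exceptions import AlignmentError, InvalidInputError, ZeroSpreadError

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialCoordinates",
    "SpatialKernel",
    "KRhoPCAResult",
    "median_bandwidth",
    "gaussian_kernel",
    "radius_for_mean_neighbors",
    "mean_neighbor_count",
    "kernel_weighted_covariance",
    "k_rho_pca",
]


@dataclass
class SpatialCoordinates:
    """Locations ``s_i`` of n observations in an m-dimensional domain."""

    points: np.ndarray
    obs_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim == 1:
            self.points = self.points[:, None]
        if self.points.ndim != 2:
            raise InvalidInputError("points must be an n x m matrix")
        if self.points.shape[0] < 2:
            raise InvalidInputError("need at least 2 locations")
        if not np.all(np.isfinite(self.points)):
            raise InvalidInputError("coordinates contain non-finite values")
        if self.obs_ids is None:
            self.obs_ids = [f"o{i}" for i in range(self.points.shape[0])]
        if len(self.obs_ids) != self.points.shape[0]:
            raise InvalidInputError("obs_ids length does not match points")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise InvalidInputError("obs_ids must be unique")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class SpatialKernel:
    """Symmetric nonnegative n x n spatial weight matrix.

    ``weights`` is dense for untruncated kernels and ``scipy.sparse`` CSR
    when a truncation radius was applied.  Gaussian kernels have unit
    diagonal and entries in [0, 1].
    """

    weights: np.ndarray | sparse.spmatrix
    bandwidth: float
    radius: float | None = None
    kernel_kind: str = "gaussian"

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def toarray(self) -> np.ndarray:
        if sparse.issparse(self.weights):
            return self.weights.toarray()
        return np.asarray(self.weights)


def median_bandwidth(coords: SpatialCoordinates) -> float:
    """Median-heuristic bandwidth: sqrt of the median pairwise distance.

    The median is taken over all unordered distinct pairs of (unsquared)
    Euclidean distances; an even-length list uses the midpoint of the two
    middle values.
    """
    d = pdist(coords.points)
    med = float(np.median(d))
    if med <= 0:
        raise ZeroSpreadError("all spatial locations coincide")
    return float(np.sqrt(med))


def gaussian_kernel(
    coords: SpatialCoordinates,
    h: float,
    radius: float | None = None,
) -> SpatialKernel:
    """Gaussian kernel ``K_ij = exp(-||s_i - s_j||^2 / (2 h^2))``.

    If ``radius`` is given, entries with distance strictly greater than
    ``radius`` are zeroed (the diagonal is always kept) and the result is
    stored sparse.  Truncation can make downstream kernel-weighted
    covariances indefinite; this is tolerated (see :mod:`rqpca.core`).
    """
    if h <= 0:
        raise InvalidInputError(f"bandwidth h must be positive, got {h}")
    D = squareform(pdist(coords.points))
    K = np.exp(-(D**2) / (2.0 * h * h))
    if radius is not None:
        if radius <= 0:
            raise InvalidInputError("radius must be positive")
        K[D > radius] = 0.0
        np.fill_diagonal(K, 1.0)
        return SpatialKernel(
            weights=sparse.csr_matrix(K), bandwidth=float(h),
            radius=float(radius),
        )
    return SpatialKernel(weights=K, bandwidth=float(h), radius=None)


def radius_for_mean_neighbors(
    coords: SpatialCoordinates, target_mean: float
) -> float:
    """Smallest radius giving a mean of ``target_mean`` neighbors per point.

    Neighbor counting excludes self and uses a closed boundary (distance
    ``<= r`` counts).  The mean neighbor count at radius r equals
    ``2 * #{pairs with d <= r} / n``, a step function jumping at sorted
    pairwise distances, so the smallest feasible radius is the
    ``ceil(target_mean * n / 2)``-th smallest pairwise distance.
    """
    n = coords.n
    if not 0 < target_mean < n:
        raise InvalidInputError(
            f"target_mean must be in (0, n={n}), got {target_mean}"
        )
    d = np.sort(pdist(coords.points))
    needed_pairs = int(np.ceil(target_mean * n / 2.0 - 1e-12))
    needed_pairs = min(needed_pairs, d.size)
    return float(d[needed_pairs - 1])


def mean_neighbor_count(coords: SpatialCoordinates, radius: float) -> float:
    """Mean over points of the number of other points within ``radius``.

    Self is excluded; the boundary is closed (distance ``<= radius``).
    """
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    d = pdist(coords.points)
    return float(2.0 * np.sum(d <= radius) / coords.n)


def kernel_weighted_covariance(
    M: CenteredMatrix, K: SpatialKernel
) -> CovarianceMatrix:
    """Kernel-weighted sample covariance ``X^T K X / (n - 1)``.

    The product is evaluated as ``X^T (K X)`` so a sparse truncated kernel
    is never densified, and the result is exactly symmetrized as
    ``(S + S^T)/2`` to absorb floating-point asymmetry.
    """
    if not M.centered:
        raise InvalidInputError("expression matrix must be centered")
    n = M.n_obs
    if K.n != n:
        raise AlignmentError(
            f"kernel dimension {K.n} does not match {n} observations"
        )
    X = M.values
    S = X.T @ (K.weights @ X) / (n - 1)
    S = np.asarray(S)
    S = (S + S.T) / 2.0
    return CovarianceMatrix(values=S, divisor=n - 1, kind="kernel_weighted")


@dataclass
class KRhoPCAResult:
    """Everything a k-rhoPCA run resolves: decomposition, scores, kernel."""

    decomposition: ContrastiveDecomposition
    scores: np.ndarray
    bandwidth: float
    radius: float | None
    kernel: SpatialKernel


def k_rho_pca(
    target: CenteredMatrix,
    coords: SpatialCoordinates,
    background: CenteredMatrix,
    k: int | None = None,
    h: float | None = None,
    radius: float | None = None,
    mean_neighbors: float | None = None,
    eps: float | None = None,
) -> KRhoPCAResult:
    """Full kernel-weighted contrastive decomposition of a spatial target.

    Composes the pipeline: median-heuristic bandwidth (when ``h`` is not
    given) -> Gaussian kernel (optionally truncated at ``radius``, or at the
    radius giving ``mean_neighbors`` average spatial neighbors) ->
    kernel-weighted target covariance vs. plain background covariance ->
    generalized eigensolve -> projection of the target onto the contrastive
    directions.

    ``target`` and ``background`` must share an identical ordered feature
    list; ``coords`` must align with the target's observations.
    """
    if target.feature_ids != background.feature_ids:
        raise AlignmentError(
            "target and background feature lists differ "
            f"(target has {len(target.feature_ids)}, background "
            f"{len(background.feature_ids)}; first mismatch: "
            f"{_first_mismatch(target.feature_ids, background.feature_ids)})"
        )
    if coords.n != target.n_obs:
        raise AlignmentError(
            f"{coords.n} coordinates for {target.n_obs} target observations"
        )
    if coords.obs_ids != target.obs_ids:
        missing = [i for i in target.obs_ids if i not in set(coords.obs_ids)]
        raise AlignmentError(
            f"coordinate obs_ids do not match target obs_ids; "
            f"{len(missing)} target ids missing: {missing[:5]}"
        )
    if radius is not None and mean_neighbors is not None:
        raise InvalidInputError("pass radius or mean_neighbors, not both")

    if h is None:
        h = median_bandwidth(coords)
    if mean_neighbors is not None:
        radius = radius_for_mean_neighbors(coords, mean_neighbors)
    kernel = gaussian_kernel(coords, h=h, radius=radius)

    sigma_T = kernel_weighted_covariance(target, kernel)
    sigma_B = sample_covariance(background)
    decomposition = generalized_eigensolve(sigma_T, sigma_B, k=k, eps=eps)
    scores = project(target, decomposition)
    if radius is not None:
        min_eig = float(np.linalg.eigvalsh(sigma_T.values)[0])
        if min_eig < 0:
            logger.info(
                "truncated kernel made the target covariance indefinite "
                "(min eigenvalue %.3e)", min_eig,
            )
    return KRhoPCAResult(
        decomposition=decomposition,
        scores=scores,
        bandwidth=float(h),
        radius=None if radius is None else float(radius),
        kernel=kernel,
    )


def _first_mismatch(a: list[str], b: list[str]) -> str:
    for x, y in zip(a, b):
        if x != y:
            return f"{x!r} vs {y!r}"
    return "length mismatch"
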