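"""Synthetic datasets with planted contrastive structure.

The generators emulate the two study designs the package targets:

* :func:`make_spatial_dataset` — a spatially registered target (grid of
  spots) carrying one smooth spatial expression mode along a known gene
  loading ``u*``, on top of non-spatial modes shared with a dissociated
  background; the background lacks the spatial mode entirely.  This mimics a
  tumor section profiled spatially with matched non-spatial scRNA-seq of
  adjacent tissue.

* :func:`make_functional_dataset` — two groups of noisy expression
  trajectories on a two-week, 11-time-point design (days 0-9 and 14,
  mirroring a primer/booster vaccination time course).  Both groups share
  smooth background modes; one extra smooth mode ``v*`` is drawn with a
  larger score standard deviation in the target group, planting a known
  target-to-background variance ratio.

All scores and noise are Gaussian, which keeps planted variance ratios
analytic; seeds are explicit everywhere and outputs are reproducible
byte-for-byte given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .functional import BasisSystem, make_basis
from .functional import sqrt_psd as _sqrtm_psd
from .spatial import SpatialCoordinates

__all__ = [
    "SpatialScenario",
    "FunctionalScenario",
    "SpatialDataset",
    "FunctionalDataset",
    "make_spatial_dataset",
    "make_functional_dataset",
]


@dataclass
class SpatialScenario:
    """Parameters of the planted spatial contrast.

    The spatial field is a one-period, mean-zero sinusoidal stripe along the
    grid's long axis with the given amplitude; shared (non-spatial) loadings
    appear with unit score standard deviation in both target and background.
    """

    grid_shape: tuple[int, int] = (20, 20)
    p: int = 30
    n_shared: int = 3
    field_amplitude: float = 2.0
    shared_sd: float = 1.0
    noise_sd: float = 0.5
    n_background: int = 2000
    seed: int = 0


@dataclass
class SpatialDataset:
    target_values: np.ndarray
    coords: SpatialCoordinates
    background_values: np.ndarray
    feature_ids: list[str]
    truth: dict = field(default_factory=dict)


def _random_unit(rng: np.random.Generator, p: int) -> np.ndarray:
    v = rng.standard_normal(p)
    return v / np.linalg.norm(v)


def make_spatial_dataset(scenario: SpatialScenario) -> SpatialDataset:
    """Generate a spatial target, its coordinates, and a matched background.

    Target row at location s: ``field(s) * u_star + sum_j z_j w_j + noise``;
    background rows carry only the shared modes plus noise.  The truth
    record stores ``u_star``, the field values, and the shared loadings for
    recovery tests.
    """
    rng = np.random.default_rng(scenario.seed)
    rows, cols = scenario.grid_shape
    n = rows * cols
    p = scenario.p

    # orthonormal loading set: distinct gene programs, the spatial one first
    raw = rng.standard_normal((p, scenario.n_shared + 1))
    q, _ = np.linalg.qr(raw)
    u_star = q[:, 0] * np.sign(q[np.argmax(np.abs(q[:, 0])), 0])
    shared = q[:, 1:].T

    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    points = np.column_stack([jj.ravel(), ii.ravel()]).astype(float)
    long_axis = 0 if cols >= rows else 1
    extent = cols if cols >= rows else rows
    # one full period across the long axis; sums to zero over the grid
    field_vals = scenario.field_amplitude * np.sin(
        2.0 * np.pi * points[:, long_axis] / extent
    )

    z_t = rng.normal(0.0, scenario.shared_sd, size=(n, scenario.n_shared))
    target = (
        field_vals[:, None] * u_star[None, :]
        + z_t @ shared
        + rng.normal(0.0, scenario.noise_sd, size=(n, p))
    )
    z_b = rng.normal(
        0.0, scenario.shared_sd, size=(scenario.n_background, scenario.n_shared)
    )
    background = z_b @ shared + rng.normal(
        0.0, scenario.noise_sd, size=(scenario.n_background, p)
    )

    obs_ids = [f"spot{i:05d}" for i in range(n)]
    feature_ids = [f"gene{j:04d}" for j in range(p)]
    return SpatialDataset(
        target_values=target,
        coords=SpatialCoordinates(points=points, obs_ids=obs_ids),
        background_values=background,
        feature_ids=feature_ids,
        truth={
            "u_star": u_star,
            "field_values": field_vals,
            "shared_loadings": shared,
        },
    )


#: Measurement days of the emulated two-dose vaccination time course.
DEFAULT_TIME_GRID = tuple(float(t) for t in list(range(10)) + [14])


@dataclass
class FunctionalScenario:
    """Parameters of the planted functional contrast.

    The planted mode ``v*`` is drawn at ``target_extra_sd`` in the target
    group and ``background_sd`` in the background; the default is a
    target-only mode (``background_sd = 0``) at signal-to-noise ratio 3
    against the unit-scale smooth curve noise.  Setting ``background_sd``
    positive plants a known target-to-background score-variance ratio
    ``(target_extra_sd / background_sd)^2`` instead.  Modes are drawn in the
    basis's coefficient space and G-orthonormalized, so each has unit L2
    norm on the domain.

    Besides the structured modes, every curve in both groups carries smooth
    sample-to-sample fluctuations with isotropic covariance in the whitened
    coefficient space (``curve_noise_sd``): the functional analogue of white
    noise in L2.  This keeps the background process non-degenerate in every
    direction, as the positive-definiteness requirement on the background
    covariance operator demands.
    """

    domain: tuple[float, float] = (0.0, 14.0)
    D: int = 5
    order: int = 4
    basis_kind: str = "bspline"
    n_target: int = 50
    n_background: int = 50
    n_shared: int = 2
    shared_sd: float = 1.0
    target_extra_sd: float = 3.0
    background_sd: float = 0.0
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    time_jitter: float = 0.0
    curve_noise_sd: float = 1.0
    measurement_noise_sd: float = 0.3
    mean_level: float = 1.0
    seed: int = 0


@dataclass
class FunctionalDataset:
    target_times: list[np.ndarray]
    target_values: list[np.ndarray]
    background_times: list[np.ndarray]
    background_values: list[np.ndarray]
    basis: BasisSystem
    truth: dict = field(default_factory=dict)


def _g_orthonormal_modes(
    rng: np.random.Generator, basis: BasisSystem, n_modes: int
) -> np.ndarray:
    """Random coefficient vectors, Gram-Schmidt-orthonormalized in the
    G-inner product (each mode has unit L2 norm; distinct modes are
    L2-orthogonal, as fPCA modes of variation are)."""
    G = basis.gram
    modes = []
    for _ in range(n_modes):
        c = rng.standard_normal(basis.D)
        for m in modes:
            c = c - (m @ G @ c) * m
        c = c / np.sqrt(c @ G @ c)
        modes.append(c)
    return np.array(modes)


def make_functional_dataset(scenario: FunctionalScenario) -> FunctionalDataset:
    """Generate target and background curve measurements with one planted
    target-enriched temporal mode.

    Each curve is ``mean + sum_j z_ij mode_j(t) + z*_i v*(t)`` with mode
    scores drawn at the group's stated standard deviations (the planted mode
    at ``target_extra_sd`` in the target, ``background_sd`` in the
    background); measurements add i.i.d. Gaussian noise at the sampled time
    points.  The truth record stores the planted coefficients and all drawn
    scores.
    """
    rng = np.random.default_rng(scenario.seed)
    basis = make_basis(
        scenario.basis_kind, scenario.D, scenario.domain, order=scenario.order
    )
    modes = _g_orthonormal_modes(rng, basis, scenario.n_shared + 1)
    shared, v_star = modes[:-1], modes[-1]
    # whitened-isotropic smooth fluctuations: coef ~ N(0, sd^2 G^{-1})
    G_half_inv = np.linalg.inv(_sqrtm_psd(basis.gram))

    def _draw_group(n: int, planted_sd: float):
        times, values, scores, coefs = [], [], [], []
        for _ in range(n):
            t = np.asarray(scenario.time_grid, dtype=float)
            if scenario.time_jitter > 0:
                t = t + rng.uniform(
                    -scenario.time_jitter, scenario.time_jitter, size=t.size
                )
                t = np.clip(np.sort(t), *scenario.domain)
            z_shared = rng.normal(0.0, scenario.shared_sd, scenario.n_shared)
            z_star = rng.normal(0.0, planted_sd)
            coef = (
                z_shared @ shared
                + z_star * v_star
                + G_half_inv
                @ rng.normal(0.0, scenario.curve_noise_sd, basis.D)
            )
            Bt = basis.evaluate(t)
            y = (
                scenario.mean_level
                + Bt @ coef
                + rng.normal(0.0, scenario.measurement_noise_sd, t.size)
            )
            times.append(t)
            values.append(y)
            scores.append(np.concatenate([z_shared, [z_star]]))
            coefs.append(coef)
        return times, values, np.array(scores), np.array(coefs)

    t_times, t_values, t_scores, t_coefs = _draw_group(
        scenario.n_target, scenario.target_extra_sd
    )
    b_times, b_values, b_scores, b_coefs = _draw_group(
        scenario.n_background, scenario.background_sd
    )
    pop_cov_bg = (
        scenario.shared_sd**2 * shared.T @ shared
        + scenario.background_sd**2 * np.outer(v_star, v_star)
        + scenario.curve_noise_sd**2 * np.linalg.inv(basis.gram)
    )
    return FunctionalDataset(
        target_times=t_times,
        target_values=t_values,
        background_times=b_times,
        background_values=b_values,
        basis=basis,
        truth={
            "v_star_coefficients": v_star,
            "shared_coefficients": shared,
            "target_scores": t_scores,
            "background_scores": b_scores,
            "target_coefficients": t_coefs,
            "background_coefficients": b_coefs,
            "background_population_covariance": pop_cov_bg,
            "planted_variance_ratio": (
                scenario.target_extra_sd / scenario.background_sd
            )
            ** 2
            if scenario.background_sd > 0
            else np.inf,
        },
    )
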