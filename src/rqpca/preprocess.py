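"""Count-matrix filtering and normalization.

Implements the standard steps that precede a contrastive decomposition:
observation/feature filters for spot- or bin-level count matrices
(minimum counts, expression prevalence, mitochondrial fraction), depth
normalization with log transform, DESeq2-style median-of-ratios size
factors for bulk RNA-seq, pre-dose (day 0) scaling of longitudinal
trajectories, and highly-variable-gene selection on the background dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, InvalidInputError

__all__ = [
    "CountMatrix",
    "FilterReport",
    "filter_counts",
    "depth_normalize_log",
    "median_of_ratios_size_factors",
    "day0_normalize",
    "select_hvg",
]

#: Default identifier prefix marking mitochondrial features.
MITO_PREFIX = "MT-"


@dataclass
class CountMatrix:
    """Nonnegative integer counts, observations x features.

    ``mito_mask`` marks features counted as mitochondrial for the
    mitochondrial-fraction filter; if not given it is derived from
    ``feature_ids`` by prefix (default ``"MT-"``, case-insensitive).
    """

    counts: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    obs_ids: list[str] = field(default_factory=list)
    mito_mask: np.ndarray | None = None
    mito_prefix: str = MITO_PREFIX

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InvalidInputError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        n, p = self.counts.shape
        if not self.feature_ids:
            self.feature_ids = [f"g{j}" for j in range(p)]
        if not self.obs_ids:
            self.obs_ids = [f"c{i}" for i in range(n)]
        if len(self.feature_ids) != p or len(self.obs_ids) != n:
            raise InvalidInputError("id lists do not match matrix dimensions")
        if self.mito_mask is None:
            pref = self.mito_prefix.lower()
            self.mito_mask = np.array(
                [fid.lower().startswith(pref) for fid in self.feature_ids]
            )
        else:
            self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
            if self.mito_mask.size != p:
                raise InvalidInputError("mito_mask does not align with features")

    @property
    def n_obs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]


@dataclass
class FilterReport:
    """How many observations/features each filter rule removed."""

    obs_low_counts: int = 0
    obs_high_counts: int = 0
    obs_high_mito: int = 0
    features_low_prevalence: int = 0


def filter_counts(
    M: CountMatrix,
    min_obs_counts: int = 0,
    max_obs_counts: int | None = None,
    min_feature_obs: int = 0,
    max_mito_frac: float | None = None,
) -> tuple[CountMatrix, FilterReport]:
    """Apply observation filters, then the feature-prevalence filter.

    All inequalities are strict, mirroring the usual phrasing of these
    rules: observations with *fewer than* ``min_obs_counts`` total counts,
    *more than* ``max_obs_counts`` total counts, or *greater than*
    ``max_mito_frac`` mitochondrial fraction are removed; features expressed
    (count > 0) in *fewer than* ``min_feature_obs`` of the surviving
    observations are removed.  Applying the same thresholds twice removes
    nothing further.
    """
    if min_obs_counts < 0 or min_feature_obs < 0:
        raise InvalidInputError("thresholds must be nonnegative")
    report = FilterReport()
    totals = M.counts.sum(axis=1)
    keep_obs = np.ones(M.n_obs, dtype=bool)

    low = totals < min_obs_counts
    report.obs_low_counts = int(low.sum())
    keep_obs &= ~low
    if max_obs_counts is not None:
        high = totals > max_obs_counts
        report.obs_high_counts = int((high & keep_obs).sum())
        keep_obs &= ~high
    if max_mito_frac is not None:
        mito = M.counts[:, M.mito_mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        high_mito = frac > max_mito_frac
        report.obs_high_mito = int((high_mito & keep_obs).sum())
        keep_obs &= ~high_mito

    if not keep_obs.any():
        raise EmptyResultError("all observations removed by filters")

    surviving = M.counts[keep_obs]
    prevalence = (surviving > 0).sum(axis=0)
    keep_feat = prevalence >= min_feature_obs
    report.features_low_prevalence = int((~keep_feat).sum())

    out = CountMatrix(
        counts=surviving[:, keep_feat],
        feature_ids=[f for f, k in zip(M.feature_ids, keep_feat) if k],
        obs_ids=[o for o, k in zip(M.obs_ids, keep_obs) if k],
        mito_mask=M.mito_mask[keep_feat],
        mito_prefix=M.mito_prefix,
    )
    return out, report


def depth_normalize_log(
    M: CountMatrix | np.ndarray, scale: float = 1e4
) -> np.ndarray:
    """Depth-normalize and log-transform: ``log(1 + scale * count / total)``.

    Every observation must have a positive total (run :func:`filter_counts`
    first).  The result is invariant to uniform scaling of an observation's
    counts.
    """
    counts = M.counts if isinstance(M, CountMatrix) else np.asarray(M)
    totals = counts.sum(axis=1, dtype=float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = (
            [M.obs_ids[i] for i in zero[:5]]
            if isinstance(M, CountMatrix)
            else list(zero[:5])
        )
        raise InvalidInputError(
            f"{zero.size} observation(s) with zero total counts: {ids}"
        )
    return np.log1p(scale * counts / totals[:, None])


def median_of_ratios_size_factors(M: CountMatrix | np.ndarray) -> np.ndarray:
    """DESeq2-style median-of-ratios size factors, one per observation.

    The per-feature reference is the geometric mean of counts over
    observations, restricted to features with no zero anywhere; each
    observation's size factor is the median over those reference features of
    count / reference.  Dividing counts by the size factors equalizes
    sequencing depth without letting a few highly expressed features
    dominate, which a simple total-count factor would.
    """
    counts = (M.counts if isinstance(M, CountMatrix) else np.asarray(M)).astype(float)
    all_nonzero = np.all(counts > 0, axis=0)
    if not all_nonzero.any():
        raise InvalidInputError(
            "no feature has nonzero counts in every observation; consider "
            "adding a pseudocount before computing size factors"
        )
    log_ratios = np.log(counts[:, all_nonzero]) - np.mean(
        np.log(counts[:, all_nonzero]), axis=0
    )
    # median taken in log space, as DESeq2 does (for an even number of
    # reference features this is the geometric mean of the middle ratios)
    return np.exp(np.median(log_ratios, axis=1))


def day0_normalize(
    trajectories: pd.DataFrame,
    sample_col: str = "sample_id",
    time_col: str = "time",
    value_col: str = "value",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Scale each trajectory by its pre-dose (t = 0) value.

    Every value in a trajectory is divided by that trajectory's measurement
    at time 0, so the t = 0 value becomes 1.  Trajectories with a missing or
    zero day-0 value are excluded and reported as ``(sample_id, reason)``.
    """
    excluded: list[tuple[str, str]] = []
    parts = []
    for sid, grp in trajectories.groupby(sample_col, sort=False):
        at0 = grp.loc[grp[time_col] == 0, value_col]
        if at0.empty:
            excluded.append((str(sid), "no day-0 measurement"))
            continue
        baseline = float(at0.iloc[0])
        if baseline == 0:
            excluded.append((str(sid), "day-0 value is zero"))
            continue
        out = grp.copy()
        out[value_col] = out[value_col] / baseline
        parts.append(out)
    result = (
        pd.concat(parts, ignore_index=True)
        if parts
        else trajectories.iloc[0:0].copy()
    )
    return result, excluded


def select_hvg(
    background: CountMatrix | np.ndarray,
    n_top: int,
    already_normalized: bool = False,
) -> list[int]:
    """Indices of the ``n_top`` most variable features of the background.

    Features are ranked by the variance of depth-normalized log values
    (counts are normalized first unless ``already_normalized``).  Both the
    target and background should then be subset to the returned features.
    Ties are broken by feature order for determinism.
    """
    values = (
        np.asarray(background)
        if already_normalized
        else depth_normalize_log(background)
    )
    if n_top > values.shape[1]:
        raise InvalidInputError(
            f"n_top={n_top} exceeds {values.shape[1]} features"
        )
    variances = values.var(axis=0, ddof=1)
    order = np.argsort(-variances, kind="stable")
    return sorted(order[:n_top].tolist())
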