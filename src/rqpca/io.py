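"""Readers and writers for the on-disk formats the pipelines touch.

Expression matrices come either as a CellRanger-style Matrix Market triplet
directory (``matrix.mtx`` stored features x observations, plus
``features.tsv`` and ``barcodes.tsv``; gzipped variants accepted) or as
dense delimited text with a header row and an id column.  Both are
normalized to observations x features on read.  Spatial coordinates and
long-format functional measurements are delimited tables; coordinates are
aligned to expression observation ids by id, never by row order.
"""

from __future__ import annotations

import csv
import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import AlignmentError, ConfigError, ParseError
from .preprocess import CountMatrix
from .spatial import SpatialCoordinates

__all__ = [
    "read_expression",
    "write_expression_mtx",
    "write_expression_dense",
    "read_coords",
    "write_coords",
    "read_long_functional",
    "write_long_functional",
]


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise ParseError(f"missing {stem}[.gz] in {directory}")


def _read_tsv_ids(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_expression(
    path: str | Path, dialect: str = "auto"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an expression matrix as (values, feature_ids, obs_ids).

    ``dialect`` is ``mtx_triplet`` (a directory), ``dense_delimited`` (a
    delimited file with header row and leading id column, rows =
    observations), or ``auto`` (directory -> triplet, file -> dense).
    Matrix Market triplets are features x observations on disk and are
    transposed on read.  Use :func:`to_count_matrix` for integer counts.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "mtx_triplet" if path.is_dir() else "dense_delimited"
    if dialect == "mtx_triplet":
        mtx = _find(path, "matrix.mtx")
        try:
            mat = spio.mmread(str(mtx))
        except Exception as exc:
            raise ParseError(f"cannot parse {mtx}: {exc}") from exc
        mat = sparse.csr_matrix(mat).toarray() if sparse.issparse(mat) else np.asarray(mat)
        feature_ids = _read_tsv_ids(_find(path, "features.tsv"))
        obs_ids = _read_tsv_ids(_find(path, "barcodes.tsv"))
        if mat.shape != (len(feature_ids), len(obs_ids)):
            raise ParseError(
                f"matrix is {mat.shape} but features.tsv has "
                f"{len(feature_ids)} rows and barcodes.tsv {len(obs_ids)}"
            )
        return mat.T.astype(float), feature_ids, obs_ids
    if dialect == "dense_delimited":
        df = _read_delimited(path, index_col=0)
        return (
            df.to_numpy(dtype=float),
            [str(c) for c in df.columns],
            [str(i) for i in df.index],
        )
    raise ParseError(f"unknown dialect {dialect!r}")


def to_count_matrix(
    values: np.ndarray, feature_ids: list[str], obs_ids: list[str]
) -> CountMatrix:
    """Interpret read values as integer counts (validates integrality)."""
    if not np.allclose(values, np.round(values)):
        raise ParseError("expression values are not integer counts")
    return CountMatrix(
        counts=np.round(values).astype(np.int64),
        feature_ids=feature_ids,
        obs_ids=obs_ids,
    )


def _read_delimited(path: Path, index_col: int | None = None) -> pd.DataFrame:
    path = Path(path)
    with open(path, "rt", newline="") as fh:
        sample = fh.read(8192)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        sep = ","
    try:
        return pd.read_csv(path, sep=sep, index_col=index_col)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def write_expression_mtx(
    directory: str | Path,
    values: np.ndarray,
    feature_ids: list[str],
    obs_ids: list[str],
) -> None:
    """Write a CellRanger-style triplet directory (features x observations)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / "matrix.mtx"),
                 sparse.coo_matrix(np.asarray(values).T))
    (directory / "features.tsv").write_text(
        "".join(f"{f}\t{f}\tGene Expression\n" for f in feature_ids)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in obs_ids)
    )


def write_expression_dense(
    path: str | Path,
    values: np.ndarray,
    feature_ids: list[str],
    obs_ids: list[str],
) -> None:
    pd.DataFrame(values, index=obs_ids, columns=feature_ids).to_csv(path)


def read_coords(
    path: str | Path, obs_ids: list[str] | None = None
) -> SpatialCoordinates:
    """Read a coordinates table with columns id, x, y[, ...].

    When ``obs_ids`` is given the rows are aligned to that order by id;
    unmatched or duplicate ids raise with the offending ids listed.
    """
    df = _read_delimited(Path(path))
    if df.shape[1] < 3:
        raise ParseError("coordinates table needs id, x, y columns")
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ParseError(f"duplicate coordinate ids: {dup[:5]}")
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    if obs_ids is not None:
        missing = [i for i in obs_ids if i not in df.index]
        if missing:
            raise AlignmentError(
                f"{len(missing)} observation id(s) missing from coordinates: "
                f"{missing[:5]}"
            )
        df = df.loc[obs_ids]
    return SpatialCoordinates(
        points=df.iloc[:, :2].to_numpy(dtype=float),
        obs_ids=[str(i) for i in df.index],
    )


def write_coords(path: str | Path, coords: SpatialCoordinates) -> None:
    pd.DataFrame(
        {
            "obs_id": coords.obs_ids,
            "x": coords.points[:, 0],
            "y": coords.points[:, 1] if coords.points.shape[1] > 1 else 0.0,
        }
    ).to_csv(path, index=False)


def read_long_functional(
    path: str | Path,
    target_label: str,
    background_label: str,
    feature_col: str = "feature",
) -> pd.DataFrame:
    """Read long-format measurements (sample_id, group, time, value).

    An optional ``feature`` column allows several units of analysis (genes)
    in one file; a constant feature is assumed when absent.  Times are
    sorted ascending within each sample; duplicate (feature, sample, time)
    rows and group labels other than the two designated ones are errors.
    """
    df = _read_delimited(Path(path))
    required = {"sample_id", "group", "time", "value"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"long-format file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if feature_col not in df.columns:
        df = df.copy()
        df[feature_col] = "feature_1"
    labels = set(df["group"].astype(str).unique())
    allowed = {target_label, background_label}
    unknown = labels - allowed
    if unknown:
        raise ConfigError(
            f"unknown group label(s) {sorted(unknown)}; expected {sorted(allowed)}"
        )
    dup = df.duplicated(subset=[feature_col, "sample_id", "time"])
    if dup.any():
        rows = df.loc[dup, [feature_col, "sample_id", "time"]].head(5)
        raise ParseError(
            f"duplicate (feature, sample, time) rows, e.g.\n{rows}"
        )
    return df.sort_values(
        [feature_col, "group", "sample_id", "time"]
    ).reset_index(drop=True)


def group_series(
    df: pd.DataFrame, label: str, feature: str | None = None,
    feature_col: str = "feature",
) -> tuple[list[str], list[np.ndarray], list[np.ndarray]]:
    """Extract per-sample (ids, times, values) for one group label."""
    sub = df[df["group"].astype(str) == label]
    if feature is not None:
        sub = sub[sub[feature_col].astype(str) == feature]
    ids, times, values = [], [], []
    for sid, grp in sub.groupby("sample_id", sort=True):
        grp = grp.sort_values("time")
        ids.append(str(sid))
        times.append(grp["time"].to_numpy(dtype=float))
        values.append(grp["value"].to_numpy(dtype=float))
    return ids, times, values


def write_long_functional(
    path: str | Path,
    ids: list[str],
    times: list[np.ndarray],
    values: list[np.ndarray],
    group: str,
    feature: str = "feature_1",
    append: bool = False,
) -> None:
    frames = [
        pd.DataFrame(
            {
                "feature": feature,
                "sample_id": sid,
                "group": group,
                "time": t,
                "value": v,
            }
        )
        for sid, t, v in zip(ids, times, values)
    ]
    df = pd.concat(frames, ignore_index=True)
    mode = "a" if append and Path(path).exists() else "w"
    df.to_csv(path, index=False, mode=mode, header=(mode == "w"))
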