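"""Pearson functional-connectivity networks and their tabular formats.

A subject's resting-state signal is summarised as a ``T x m`` matrix of
regional time-series (one column per atlas region, 1-based AAL indexing by
convention).  The functional network is the ``m x m`` matrix of pairwise
Pearson correlations with a zero diagonal; its upper triangle, flattened in
row-major order, is the per-subject feature vector consumed by the edge
selection and classification stages (``M = m(m-1)/2`` features).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "EdgeVector",
    "pearson_network",
    "threshold_network",
    "vectorize_edges",
    "devectorize_edges",
    "build_design",
    "edge_pairs",
    "n_edges",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_manifest",
    "read_connectivity_csv",
    "write_connectivity_csv",
    "write_edge_table",
    "PATIENT",
    "CONTROL",
]

PATIENT = "patient"
CONTROL = "control"

_SYM_ATOL = 1e-10


@dataclass
class RoiTimeSeries:
    """One subject's ``T x m`` regional signal matrix."""

    subject_id: str
    data: np.ndarray
    region_ids: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a 2-D (T x m) array")
        T, m = self.data.shape
        if T < 3:
            raise ValueError(f"need at least 3 timepoints, got {T}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time-series of {self.subject_id!r}")
        if self.region_ids is None:
            self.region_ids = list(range(1, m + 1))
        else:
            self.region_ids = [int(r) for r in self.region_ids]
        if len(self.region_ids) != m:
            raise ValueError("region_ids length does not match number of columns")
        if len(set(self.region_ids)) != m:
            raise ValueError("region_ids must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric ``m x m`` Pearson network, zero diagonal, entries in [-1, 1]."""

    values: np.ndarray
    region_ids: Sequence[int] | None = None
    threshold_applied: float | None = None

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        if not np.allclose(V, V.T, atol=_SYM_ATOL):
            raise ValueError("connectivity matrix must be symmetric")
        V = (V + V.T) / 2.0
        np.fill_diagonal(V, 0.0)
        off = np.abs(V[~np.eye(V.shape[0], dtype=bool)])
        if off.size and off.max() > 1.0 + 1e-9:
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.values = np.clip(V, -1.0, 1.0)
        np.fill_diagonal(self.values, 0.0)
        m = V.shape[0]
        if self.region_ids is None:
            self.region_ids = list(range(1, m + 1))
        else:
            self.region_ids = [int(r) for r in self.region_ids]
        if len(self.region_ids) != m:
            raise ValueError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Row-major upper-triangle flattening of a connectivity matrix.

    Edge ``k`` corresponds to the region-index pair ``edge_pairs(m)[k]``; the
    order for m=3 is (1,2), (1,3), (2,3).
    """

    features: np.ndarray
    region_ids: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float).ravel()
        m = len(self.region_ids)
        if m and self.features.size != n_edges(m):
            raise ValueError(
                f"feature length {self.features.size} inconsistent with m={m}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("edge features must be finite")

    @property
    def n_features(self) -> int:
        return self.features.size


def n_edges(m: int) -> int:
    """Number of distinct region pairs, M = m(m-1)/2."""
    return m * (m - 1) // 2


def edge_pairs(m: int, region_ids: Sequence[int] | None = None) -> np.ndarray:
    """Ordered (i, j) pairs (i < j) for the upper triangle, row-major.

    Returns a ``(M, 2)`` integer array of region ids (1-based by default).
    """
    rows, cols = np.triu_indices(m, k=1)
    ids = np.asarray(region_ids if region_ids is not None else range(1, m + 1))
    return np.column_stack([ids[rows], ids[cols]])


def pearson_network(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Sample Pearson correlation between every pair of regional time-series.

    Raises if any region's signal is constant (the correlation would be
    undefined); the error names the offending region ids.
    """
    X = ts.data
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        ids = [ts.region_ids[i] for i in bad]
        raise ValueError(f"constant time-series for region id(s) {ids}")
    C = np.corrcoef(X, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 0.0)
    return ConnectivityMatrix(C, region_ids=ts.region_ids)


def threshold_network(C: ConnectivityMatrix, tau: float) -> ConnectivityMatrix:
    """Zero out edges with |r| below ``tau``; survivors keep sign and value.

    Magnitude thresholding deliberately preserves strong negative
    correlations.  tau=0 leaves the fully connected network unchanged.
    """
    tau = float(tau)
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {tau}")
    V = C.values.copy()
    V[np.abs(V) < tau] = 0.0
    return ConnectivityMatrix(V, region_ids=C.region_ids, threshold_applied=tau)


def vectorize_edges(C: ConnectivityMatrix) -> EdgeVector:
    """Flatten the upper triangle into the length-M feature vector."""
    m = C.n_regions
    rows, cols = np.triu_indices(m, k=1)
    return EdgeVector(C.values[rows, cols], region_ids=C.region_ids)


def devectorize_edges(v: EdgeVector) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_edges` (exact round trip)."""
    M = v.n_features
    m = int(round((1 + np.sqrt(1 + 8 * M)) / 2))
    if n_edges(m) != M:
        raise ValueError(f"feature length {M} is not m(m-1)/2 for any integer m")
    V = np.zeros((m, m))
    rows, cols = np.triu_indices(m, k=1)
    V[rows, cols] = v.features
    V += V.T
    ids = v.region_ids if len(v.region_ids) == m else None
    return ConnectivityMatrix(V, region_ids=ids)


def build_design(
    subjects: Sequence[tuple[str, RoiTimeSeries, str]],
    tau: float = 0.0,
    fisher_z: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str], list[int]]:
    """Stack thresholded edge vectors into the regression design.

    Returns ``(X, y, subject_ids, region_ids)`` where row j of ``X`` is
    subject j's edge vector and ``y`` encodes patient=+1, control=-1 (a
    zero-mean target suits the intercept-free linear model).  ``fisher_z``
    optionally applies arctanh to the retained correlations (off by default).
    """
    if not subjects:
        raise ValueError("no subjects supplied")
    labels = [lab for _, _, lab in subjects]
    for lab in labels:
        if lab not in (PATIENT, CONTROL):
            raise ValueError(f"unknown label {lab!r}; expected 'patient' or 'control'")
    if len(set(labels)) < 2:
        raise ValueError("design requires at least one subject per class")
    region_ids = None
    rows = []
    for sid, ts, _ in subjects:
        C = threshold_network(pearson_network(ts), tau)
        if region_ids is None:
            region_ids = list(C.region_ids)
        elif list(C.region_ids) != region_ids:
            raise ValueError(f"subject {sid!r} has inconsistent regions")
        rows.append(vectorize_edges(C).features)
    X = np.vstack(rows)
    if fisher_z:
        X = np.arctanh(np.clip(X, -0.999999, 0.999999))
    y = np.array([1.0 if lab == PATIENT else -1.0 for lab in labels])
    return X, y, [sid for sid, _, _ in subjects], region_ids


# ---------------------------------------------------------------------------
# tabular I/O


def write_timeseries_tsv(ts: RoiTimeSeries, path: str | os.PathLike) -> None:
    df = pd.DataFrame(ts.data, columns=[str(r) for r in ts.region_ids])
    df.to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path: str | os.PathLike, subject_id: str | None = None) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    region_ids = [int(c) for c in df.columns]
    sid = subject_id if subject_id is not None else os.path.splitext(os.path.basename(path))[0]
    return RoiTimeSeries(sid, df.to_numpy(dtype=float), region_ids)


def read_manifest(path: str | os.PathLike) -> list[tuple[str, RoiTimeSeries, str]]:
    """Load a cohort from a ``subject_id,file,label`` manifest.

    File paths are resolved relative to the manifest's directory.  Returns a
    list of ``(subject_id, RoiTimeSeries, label)`` in manifest order.
    """
    base = os.path.dirname(os.path.abspath(path))
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"unreadable manifest {path}: {exc}") from exc
    required = {"subject_id", "file", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns {sorted(required)}")
    subjects = []
    for i, row in df.iterrows():
        lab = str(row["label"])
        if lab not in (PATIENT, CONTROL):
            raise ValueError(f"manifest line {i + 2}: unknown label {lab!r}")
        fpath = os.path.join(base, str(row["file"]))
        ts = read_timeseries_tsv(fpath, subject_id=str(row["subject_id"]))
        subjects.append((str(row["subject_id"]), ts, lab))
    return subjects


def write_connectivity_csv(C: ConnectivityMatrix, path: str | os.PathLike) -> None:
    """m x m grid with region ids as header row and index column."""
    ids = [str(r) for r in C.region_ids]
    pd.DataFrame(C.values, index=ids, columns=ids).to_csv(path)


def read_connectivity_csv(path: str | os.PathLike) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(df.to_numpy(dtype=float), region_ids=[int(c) for c in df.columns])


def write_edge_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
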