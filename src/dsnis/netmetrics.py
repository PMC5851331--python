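"""Group-level topological metrics of weighted functional networks.

Five summaries of a (thresholded) connectivity matrix, computed on absolute
edge weights throughout (negative correlations would make the geometric
triangle mean undefined):

- strength: per node, the sum of |w_ij| over the other nodes; per subject,
  the mean node strength.
- diversity: per node, the population variance of its m-1 edge weights
  (heterogeneity of a region's connectivity profile); per subject, the mean.
- clustering: weighted clustering coefficient via the geometric triangle
  form, C_i = sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3} / (k_i (k_i - 1)) with
  w' = |w| / max |w| and k_i the node degree among surviving edges; nodes
  with fewer than two neighbours score 0.
- overlap score: for a group of subjects, |edges present in every subject| /
  |edges present in any subject| after binarising at the threshold.
- weighted overlap score: sum over union edges of the across-subject minimum
  |w| divided by the sum of the across-subject maximum |w|.

The two overlap scores are single group-level values in [0, 1]; the other
three are per-subject scalars reported as group mean +- SD.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix

__all__ = [
    "strength",
    "diversity",
    "clustering",
    "overlap_score",
    "weighted_overlap_score",
    "group_report",
]


def _abs_weights(C: ConnectivityMatrix) -> np.ndarray:
    return np.abs(C.values)


def strength(C: ConnectivityMatrix) -> tuple[np.ndarray, float]:
    """Node strengths and their mean over nodes."""
    W = _abs_weights(C)
    node = W.sum(axis=1)
    return node, float(node.mean())


def diversity(C: ConnectivityMatrix) -> tuple[np.ndarray, float]:
    """Per-node population variance of the m-1 edge weights, and its mean."""
    W = _abs_weights(C)
    m = W.shape[0]
    if m < 3:
        raise ValueError("diversity needs at least 3 regions (variance of >=2 weights)")
    mask = ~np.eye(m, dtype=bool)
    rows = W[mask].reshape(m, m - 1)
    node = rows.var(axis=1)  # population variance (ddof=0)
    return node, float(node.mean())


def clustering(C: ConnectivityMatrix) -> tuple[np.ndarray, float]:
    """Geometric weighted clustering coefficient per node, and its mean."""
    W = _abs_weights(C)
    m = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        warnings.warn("all-zero network: clustering coefficient is 0 everywhere")
        return np.zeros(m), 0.0
    Wn = np.cbrt(W / wmax)
    cycles = np.diagonal(Wn @ Wn @ Wn)  # sum over ordered (j, h) triangle pairs
    k = (W > 0).sum(axis=1)
    node = np.zeros(m)
    ok = k >= 2
    node[ok] = cycles[ok] / (k[ok] * (k[ok] - 1))
    return node, float(node.mean())


def _presence(C: ConnectivityMatrix, tau: float) -> np.ndarray:
    V = np.abs(C.values)
    return (V >= tau) & (V > 0)


def overlap_score(group: Sequence[ConnectivityMatrix], tau: float = 0.0) -> float:
    """|edges shared by all subjects| / |edges present in any subject|."""
    if len(group) < 2:
        raise ValueError("overlap needs at least 2 subjects")
    masks = [_presence(C, tau) for C in group]
    inter = np.logical_and.reduce(masks)
    union = np.logical_or.reduce(masks)
    n_union = union.sum()
    if n_union == 0:
        warnings.warn("no edge survives in any subject; overlap defined as 0")
        return 0.0
    return float(inter.sum() / n_union)


def weighted_overlap_score(group: Sequence[ConnectivityMatrix], tau: float = 0.0) -> float:
    """sum_e min_s |w_es| / sum_e max_s |w_es| over edges surviving anywhere."""
    if len(group) < 2:
        raise ValueError("overlap needs at least 2 subjects")
    stack = np.stack([np.where(_presence(C, tau), np.abs(C.values), 0.0) for C in group])
    mx = stack.max(axis=0)
    denom = mx.sum()
    if denom == 0:
        warnings.warn("no edge survives in any subject; weighted overlap defined as 0")
        return 0.0
    return float(stack.min(axis=0).sum() / denom)


_SUBJECT_METRICS = {
    "connectivity_strength": strength,
    "connectivity_diversity": diversity,
    "clustering_coefficient": clustering,
}


def group_report(
    groups: Mapping[str, Sequence[ConnectivityMatrix]], tau: float = 0.0
) -> pd.DataFrame:
    """Per-group topology table (metric rows, mean/sd columns per group).

    Subject-level metrics are summarised as mean +- SD across the group's
    subjects; the two overlap scores are single group-level values (their sd
    column is NaN).
    """
    if len(groups) < 2:
        raise ValueError("group report needs at least two groups")
    records: dict[str, dict[str, float]] = {}
    for gname, nets in groups.items():
        if not nets:
            raise ValueError(f"group {gname!r} is empty")
        col: dict[str, float] = {}
        for mname, fn in _SUBJECT_METRICS.items():
            vals = np.array([fn(C)[1] for C in nets])
            col[f"{mname}_mean"] = float(vals.mean())
            col[f"{mname}_sd"] = float(vals.std())
        col["overlap_score_mean"] = overlap_score(nets, tau) if len(nets) > 1 else 1.0
        col["overlap_score_sd"] = np.nan
        col["weighted_overlap_score_mean"] = (
            weighted_overlap_score(nets, tau) if len(nets) > 1 else 1.0
        )
        col["weighted_overlap_score_sd"] = np.nan
        records[gname] = col
    metrics = [
        "connectivity_strength",
        "connectivity_diversity",
        "clustering_coefficient",
        "overlap_score",
        "weighted_overlap_score",
    ]
    rows = []
    for mname in metrics:
        row: dict[str, object] = {"metric": mname, "threshold": tau}
        for gname, col in records.items():
            row[f"{gname}_mean"] = col[f"{mname}_mean"]
            row[f"{gname}_sd"] = col[f"{mname}_sd"]
        rows.append(row)
    return pd.DataFrame(rows)
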