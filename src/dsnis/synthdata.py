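"""Synthetic two-group cohorts with planted differential connectivity.

The clinical cohort behind the original study (24 patients, 21 matched
controls, 180-volume resting-state scans) is not publicly deposited, so this
module generates surrogate cohorts in which the ground truth is known: each
subject's regional time-series is drawn from a zero-mean multivariate normal
whose correlation structure is an equicorrelation background, raised by a
known effect size ``delta`` on a planted set of "signal" edges in the patient
group only.  Inter-subject heterogeneity is modelled as additive Gaussian
noise on the off-diagonal correlations followed by projection back to a
positive-definite matrix.

Everything is deterministic under the spec's master seed: per-subject random
streams are spawned from a single :class:`numpy.random.SeedSequence`.

The defaults mirror the original study's scale (m=90 AAL regions, T=170
usable volumes, 24 patients / 21 controls); the distributional choices are
stand-ins — no BOLD hemodynamics, drift, or motion is simulated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectome import (
    CONTROL,
    PATIENT,
    RoiTimeSeries,
    write_timeseries_tsv,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "build_group_covariance",
    "generate_cohort",
    "write_fixture",
    "read_truth_edges",
    "default_signal_edges",
]

_MIN_EIG = 1e-6
_CORR_CAP = 0.99


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-edge cohort.

    ``signal_edges`` are 1-based region pairs (i, j) with i < j whose
    population correlation in the patient group is
    ``clip(base_correlation + effect_size, -0.99, 0.99)``; everywhere else
    (and everywhere for controls) it is ``base_correlation``.
    """

    n_patients: int = 24
    n_controls: int = 21
    n_regions: int = 90
    n_timepoints: int = 170
    signal_edges: tuple[tuple[int, int], ...] = ()
    base_correlation: float = 0.2
    effect_size: float = 0.5
    subject_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_patients + self.n_controls == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if abs(self.base_correlation) >= 1.0:
            raise ValueError("|base_correlation| must be < 1")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be non-negative")
        edges = tuple((int(i), int(j)) for i, j in self.signal_edges)
        for i, j in edges:
            if not (1 <= i < j <= self.n_regions):
                raise ValueError(f"signal edge ({i}, {j}) outside the upper triangle")
        if len(set(edges)) != len(edges):
            raise ValueError("signal edges must be distinct")
        object.__setattr__(self, "signal_edges", edges)

    @property
    def patient_signal_correlation(self) -> float:
        return float(np.clip(self.base_correlation + self.effect_size, -_CORR_CAP, _CORR_CAP))


@dataclass
class SyntheticCohort:
    subjects: list[tuple[str, RoiTimeSeries, str]]
    truth_edges: tuple[tuple[int, int], ...]
    spec: SyntheticSpec = field(repr=False)

    def __post_init__(self) -> None:
        expected = self.spec.n_patients + self.spec.n_controls
        if len(self.subjects) != expected:
            raise ValueError("subject count does not match spec group sizes")


def default_signal_edges(
    spec_m: int, n_edges: int, seed: int = 0
) -> tuple[tuple[int, int], ...]:
    """Draw ``n_edges`` distinct random region pairs (1-based, i < j)."""
    rng = np.random.default_rng(seed)
    rows, cols = np.triu_indices(spec_m, k=1)
    pick = rng.choice(rows.size, size=n_edges, replace=False)
    return tuple(sorted((int(rows[k]) + 1, int(cols[k]) + 1) for k in pick))


def _project_pd(S: np.ndarray, min_eig: float = _MIN_EIG) -> np.ndarray:
    """Clip the spectrum from below so the smallest eigenvalue is >= min_eig."""
    S = (S + S.T) / 2.0
    w, U = np.linalg.eigh(S)
    if w[0] >= min_eig:
        return S
    w = np.maximum(w, min_eig)
    return (U * w) @ U.T


def build_group_covariance(spec: SyntheticSpec, group: str) -> np.ndarray:
    """Population covariance (= correlation) matrix for one diagnosis group.

    Equicorrelation background with the planted patient-group bumps; projected
    to the nearest positive-definite matrix only if the raw construction is
    indefinite.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"unknown group {group!r}")
    m = spec.n_regions
    rho = spec.base_correlation
    S = np.full((m, m), rho)
    np.fill_diagonal(S, 1.0)
    if group == PATIENT:
        r_sig = spec.patient_signal_correlation
        for i, j in spec.signal_edges:
            S[i - 1, j - 1] = S[j - 1, i - 1] = r_sig
    return _project_pd(S)


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw the full two-group cohort; bit-identical for the same spec+seed."""
    groups = [(PATIENT, spec.n_patients), (CONTROL, spec.n_controls)]
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_patients + spec.n_controls)
    subjects: list[tuple[str, RoiTimeSeries, str]] = []
    region_ids = list(range(1, spec.n_regions + 1))
    k = 0
    for label, count in groups:
        S_group = build_group_covariance(spec, label)
        for _ in range(count):
            rng = np.random.default_rng(streams[k])
            S = S_group
            if spec.subject_noise_sd > 0:
                m = spec.n_regions
                E = np.zeros((m, m))
                iu = np.triu_indices(m, k=1)
                E[iu] = rng.normal(0.0, spec.subject_noise_sd, size=iu[0].size)
                E += E.T
                S = _project_pd(S_group + E)
            w, U = np.linalg.eigh(S)
            L = U * np.sqrt(np.maximum(w, 0.0))
            data = rng.standard_normal((spec.n_timepoints, spec.n_regions)) @ L.T
            sid = f"sub-{k + 1:03d}"
            subjects.append((sid, RoiTimeSeries(sid, data, region_ids), label))
            k += 1
    return SyntheticCohort(subjects, spec.signal_edges, spec)


def write_fixture(cohort: SyntheticCohort, directory: str | os.PathLike) -> str:
    """Write per-subject TSV time-series, a CSV manifest, and the truth edges.

    Returns the manifest path.  The layout round-trips through
    :func:`dsnis.connectome.read_manifest`.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for sid, ts, label in cohort.subjects:
        fname = f"{sid}.tsv"
        try:
            write_timeseries_tsv(ts, os.path.join(directory, fname))
        except OSError as exc:
            raise OSError(f"failed writing {os.path.join(directory, fname)}: {exc}") from exc
        rows.append({"subject_id": sid, "file": fname, "label": label})
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows, columns=["subject_id", "file", "label"]).to_csv(manifest, index=False)
    truth = os.path.join(directory, "truth_edges.tsv")
    with open(truth, "w") as fh:
        fh.write("i\tj\n")
        for i, j in cohort.truth_edges:
            fh.write(f"{i}\t{j}\n")
    return manifest


def read_truth_edges(path: str | os.PathLike) -> tuple[tuple[int, int], ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple((int(i), int(j)) for i, j in zip(df["i"], df["j"]))
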