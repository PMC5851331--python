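"""Kernel discriminant analysis with a nearest-neighbour decision rule.

Samples z_i (DSNIS feature vectors) are mapped implicitly into a reproducing
kernel Hilbert space; the discriminant direction w = sum_i alpha_i phi(z_i)
is found by maximising the kernelised Rayleigh quotient

    alpha_opt = argmax (alpha' K W K alpha) / (alpha' K K alpha)

where K is the Gram matrix and W the block class-indicator matrix
(W_ij = 1/n_c when i and j share a class of size n_c, else 0; W is a
symmetric idempotent projection).  The quotient is solved in the stable
subspace spanned by the eigencomponents of K above a relative cutoff, which
handles singular K K (duplicate samples, rank-deficient kernels) exactly as
an eigendecomposition of K.  Projections of new samples are
sum_i alpha_i f(z, z_i); classification assigns the label of the nearest
training projection (k = 1), ties broken by the smallest training index.

Degeneracy note: when K has full rank the maximal quotient value 1 is
attained on a c-dimensional eigenspace that always contains the useless
direction projecting every sample to the same constant.  The retained c-1
discriminants are chosen inside that maximal eigenspace orthogonal to the
constant projection — a deterministic tie-break among equally optimal
solutions, not a modification of the objective.  An optional ``center``
flag instead double-centres K and uses the centred between-class projector
(classic kernel Fisher discriminant behaviour).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances, linear_kernel, polynomial_kernel, rbf_kernel

__all__ = [
    "KernelSpec",
    "KdaModel",
    "gram",
    "indicator_matrix",
    "fit",
    "project",
    "predict",
    "model_to_json",
    "model_from_json",
]

_EIG_RTOL = 1e-10
_DEGEN_TOL = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    rbf: f(u, v) = exp(-gamma ||u - v||^2); gamma=None means the median
    heuristic, gamma = 1 / (2 sigma^2) with sigma the median pairwise
    training distance, resolved at fit time.
    linear: f(u, v) = u'v.
    polynomial: f(u, v) = (gamma u'v + coef0)^degree.
    """

    family: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "linear", "polynomial"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _resolve_gamma(spec: KernelSpec, Z: np.ndarray) -> float | None:
    if spec.family == "linear":
        return None
    if spec.gamma is not None:
        return spec.gamma
    if spec.family == "polynomial":
        return 1.0 / max(Z.shape[1], 1)
    d = euclidean_distances(Z)
    med = np.median(d[np.triu_indices_from(d, k=1)]) if Z.shape[0] > 1 else 0.0
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


def _kernel(Z1: np.ndarray, Z2: np.ndarray, spec: KernelSpec, gamma: float | None) -> np.ndarray:
    if spec.family == "linear":
        return linear_kernel(Z1, Z2)
    if spec.family == "rbf":
        return rbf_kernel(Z1, Z2, gamma=gamma)
    return polynomial_kernel(Z1, Z2, degree=spec.degree, gamma=gamma, coef0=spec.coef0)


def gram(Z: np.ndarray, spec: KernelSpec | None = None) -> np.ndarray:
    """Training Gram matrix K_ij = f(z_i, z_j); validated symmetric PSD."""
    spec = spec or KernelSpec()
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite feature values")
    K = _kernel(Z, Z, spec, _resolve_gamma(spec, Z))
    K = (K + K.T) / 2.0
    w_min = np.linalg.eigvalsh(K)[0]
    scale = max(1.0, float(np.abs(K).max()))
    if w_min < -1e-10 * scale:
        raise ValueError(f"kernel Gram matrix is not PSD (min eigenvalue {w_min:.3e})")
    return K


def indicator_matrix(labels: Sequence) -> np.ndarray:
    """Block class-indicator matrix W of the between-class quotient.

    W_ij = 1/n_c when samples i and j are both in the class of size n_c,
    else 0.  W is symmetric, idempotent, and every row sums to 1.
    """
    labels = np.asarray(labels)
    classes, inv = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("indicator matrix requires at least two classes")
    n = labels.size
    W = np.zeros((n, n))
    for c in range(classes.size):
        members = np.flatnonzero(inv == c)
        W[np.ix_(members, members)] = 1.0 / members.size
    return W


@dataclass
class KdaModel:
    Z: np.ndarray = field(repr=False)
    labels: np.ndarray
    spec: KernelSpec
    gamma: float | None
    alpha: np.ndarray = field(repr=False)          # n x q expansion coefficients
    eigenvalues: np.ndarray                        # attained quotient per discriminant
    projections: np.ndarray = field(repr=False)    # n x q training projections
    centered: bool = False
    stabilization: dict = field(default_factory=dict)
    # centring statistics (populated when centered=True)
    _k_col_means: np.ndarray | None = field(default=None, repr=False)
    _k_grand_mean: float = 0.0

    @property
    def n_discriminants(self) -> int:
        return self.alpha.shape[1]


def _select_discriminants(
    mu: np.ndarray, V: np.ndarray, U_r: np.ndarray, n: int, needed: int, deflate_constant: bool
) -> np.ndarray:
    """Pick `needed` eigenvectors of the reduced problem, largest quotient
    first; inside a degenerate maximal eigenspace, directions orthogonal to
    the constant projection are preferred (deterministic tie-break)."""
    order = np.argsort(mu)[::-1]
    mu, V = mu[order], V[:, order]
    top = mu[0]
    deg = np.flatnonzero(mu >= top - _DEGEN_TOL * max(1.0, abs(top)))
    if deflate_constant and deg.size > needed:
        B = V[:, deg]                                   # basis of the maximal eigenspace
        u = U_r.T @ (np.ones(n) / np.sqrt(n))           # constant projection in reduced coords
        cvec = B.T @ u
        nc = np.linalg.norm(cvec)
        if nc > 1e-10:
            # orthonormal complement of cvec inside the eigenspace
            Q = np.linalg.qr(
                np.column_stack([cvec / nc, np.eye(deg.size)]), mode="complete"
            )[0][:, 1:deg.size]
            candidates = B @ Q
            rest = V[:, deg.size:]
            V = np.column_stack([candidates, rest])
    return V[:, :needed]


def fit(
    Z: np.ndarray,
    labels: Sequence,
    spec: KernelSpec | None = None,
    center: bool = False,
    eig_rtol: float = _EIG_RTOL,
) -> KdaModel:
    """Fit the kernel discriminant by the stabilised generalized eigenproblem.

    K is eigendecomposed; components with eigenvalue above
    ``eig_rtol * lambda_max`` span the stable subspace in which the quotient
    reduces to a plain symmetric eigenproblem on U' W U.  The top c-1
    eigenvectors become the discriminants, normalised so alpha' K K alpha = 1.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    n = Z.shape[0]
    classes = np.unique(labels)
    c = classes.size
    if c < 2:
        raise ValueError("need at least two classes")
    if n < c:
        raise ValueError("need at least as many samples as classes")
    spec = spec or KernelSpec()
    gamma = _resolve_gamma(spec, Z)
    K = _kernel(Z, Z, spec, gamma)
    K = (K + K.T) / 2.0
    W = indicator_matrix(labels)

    k_col_means = None
    grand = 0.0
    if center:
        k_col_means = K.mean(axis=0)
        grand = float(K.mean())
        H = np.eye(n) - np.full((n, n), 1.0 / n)
        K = H @ K @ H
        W = W - np.full((n, n), 1.0 / n)   # centred between-class projector

    lam, U = np.linalg.eigh(K)
    lam_max = lam[-1]
    if lam_max <= 0:
        raise ValueError("kernel Gram matrix is zero or negative definite")
    keep = lam > eig_rtol * lam_max
    U_r, lam_r = U[:, keep], lam[keep]
    r = int(keep.sum())

    needed = c - 1
    if r < needed:
        warnings.warn(
            f"only {r} stable kernel eigencomponents; reducing discriminants from {needed} to {r}"
        )
        needed = r

    A = U_r.T @ W @ U_r
    A = (A + A.T) / 2.0
    mu, V = np.linalg.eigh(A)
    theta = _select_discriminants(mu, V, U_r, n, needed, deflate_constant=not center)
    attained = np.einsum("ij,ij->j", theta, A @ theta)

    alpha = U_r @ (theta / lam_r[:, None])
    proj = U_r @ theta                      # = K @ alpha on the stable subspace
    return KdaModel(
        Z=Z,
        labels=labels,
        spec=spec,
        gamma=gamma,
        alpha=alpha,
        eigenvalues=attained,
        projections=proj,
        centered=center,
        stabilization={"rank": r, "eig_rtol": eig_rtol, "n": n},
        _k_col_means=k_col_means,
        _k_grand_mean=grand,
    )


def project(model: KdaModel, z: np.ndarray) -> np.ndarray:
    """Projection(s) of new sample(s): sum_i alpha_i f(z, z_i) per
    discriminant.  A single 1-D sample returns a length-(c-1) vector."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    Zq = np.atleast_2d(z)
    if Zq.shape[1] != model.Z.shape[1]:
        raise ValueError(
            f"query dimension {Zq.shape[1]} != training dimension {model.Z.shape[1]}"
        )
    Kq = _kernel(Zq, model.Z, model.spec, model.gamma)
    if model.centered:
        # out-of-sample double-centring against the training kernel
        Kq = (
            Kq
            - Kq.mean(axis=1, keepdims=True)
            - model._k_col_means[None, :]
            + model._k_grand_mean
        )
    P = Kq @ model.alpha
    return P[0] if single else P


def predict(model: KdaModel, z: np.ndarray):
    """Nearest-neighbour label in the discriminant space (k = 1).

    Ties in distance are broken by the smallest training index.  A single
    sample returns a scalar label, a 2-D batch an array of labels.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    P = np.atleast_2d(project(model, z))
    out = []
    for p in P:
        d = np.linalg.norm(model.projections - p[None, :], axis=1)
        dmin = d.min()
        winner = int(np.flatnonzero(d <= dmin + 1e-12 * (1.0 + dmin))[0])
        out.append(model.labels[winner])
    out = np.asarray(out)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# serialization (self-describing JSON archive for separate fit/predict runs)


def model_to_json(model: KdaModel) -> str:
    payload = {
        "Z": model.Z.tolist(),
        "labels": model.labels.tolist(),
        "spec": {
            "family": model.spec.family,
            "gamma": model.spec.gamma,
            "degree": model.spec.degree,
            "coef0": model.spec.coef0,
        },
        "gamma": model.gamma,
        "alpha": model.alpha.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "projections": model.projections.tolist(),
        "centered": model.centered,
        "stabilization": model.stabilization,
        "k_col_means": None if model._k_col_means is None else model._k_col_means.tolist(),
        "k_grand_mean": model._k_grand_mean,
    }
    return json.dumps(payload)


def model_from_json(text: str) -> KdaModel:
    d = json.loads(text)
    return KdaModel(
        Z=np.asarray(d["Z"], float),
        labels=np.asarray(d["labels"]),
        spec=KernelSpec(**d["spec"]),
        gamma=d["gamma"],
        alpha=np.asarray(d["alpha"], float),
        eigenvalues=np.asarray(d["eigenvalues"], float),
        projections=np.asarray(d["projections"], float),
        centered=d["centered"],
        stabilization=d["stabilization"],
        _k_col_means=None if d["k_col_means"] is None else np.asarray(d["k_col_means"], float),
        _k_grand_mean=d["k_grand_mean"],
    )
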