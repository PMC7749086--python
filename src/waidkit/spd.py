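"""Geometry of symmetric positive-definite (SPD) matrices.

SPD matrices do not form a vector space, so descriptor similarity is
computed with dedicated measures:

* LERM, the log-Euclidean Riemannian metric
  ``||Log(D1) - Log(D2)||_F`` — a true geodesic distance obtained by
  embedding SPD matrices into the (flat) space of symmetric matrices via
  the principal matrix logarithm;
* JBLD, the Jensen-Bregman LogDet divergence
  ``[log|D1/2 + D2/2| - 1/2 log|D1 D2|]^(1/2)`` — cheaper (Cholesky
  log-determinants, no eigendecomposition), symmetric and affine
  invariant, but not a metric and not guaranteed to induce a Mercer
  kernel.

Both are exposed as scalar operations, batched pairwise Gram matrices,
and RBF kernels ``exp(-gamma * dist^2)`` built from them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimilarityGram",
    "validate_spd",
    "matrix_log",
    "matrix_exp",
    "logdet_cholesky",
    "lerm_distance",
    "jbld_divergence",
    "pairwise_gram",
    "rbf_from_gram",
]

#: relative symmetry tolerance and absolute eigenvalue floor for SPD checks
SYMMETRY_RTOL = 1e-8
EIG_FLOOR = 1e-12

MEASURES = ("lerm", "jbld")


@dataclass(frozen=True)
class SimilarityGram:
    """Pairwise distance/divergence matrix: zero diagonal, symmetric, >= 0."""

    values: np.ndarray
    measure: str


def validate_spd(D: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Check symmetry and strict positive definiteness; return the array.

    Matrices failing the check are rejected, never silently repaired.
    """
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be square, got shape {D.shape}")
    scale = np.abs(D).max()
    if scale == 0 or np.abs(D - D.T).max() > SYMMETRY_RTOL * scale:
        raise ValueError(f"{name} is not symmetric within tolerance")
    lam_min = float(np.linalg.eigvalsh(D)[0])
    if lam_min <= EIG_FLOOR:
        raise ValueError(
            f"{name} is not positive definite: smallest eigenvalue {lam_min:.3e}"
        )
    return D


def matrix_log(D: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm ``U diag(log lam) U^T`` of an SPD matrix."""
    D = validate_spd(D)
    lam, U = np.linalg.eigh(D)
    L = (U * np.log(lam)) @ U.T
    return (L + L.T) / 2.0

def matrix_exp(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (inverse of matrix_log)."""
    S = np.asarray(S, dtype=np.float64)
    lam, U = np.linalg.eigh((S + S.T) / 2.0)
    E = (U * np.exp(lam)) @ U.T
    return (E + E.T) / 2.0


def logdet_cholesky(D: np.ndarray) -> float:
    """log-determinant of an SPD matrix via its Cholesky factor:
    ``2 * sum(log diag(L))`` for ``D = L L^T``."""
    try:
        L = np.linalg.cholesky(np.asarray(D, dtype=np.float64))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"matrix is not positive definite: {exc}") from exc
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def _check_pair(D1: np.ndarray, D2: np.ndarray) -> None:
    if np.shape(D1) != np.shape(D2):
        raise ValueError(
            f"dimension mismatch: {np.shape(D1)} vs {np.shape(D2)}"
        )


def lerm_distance(D1: np.ndarray, D2: np.ndarray) -> float:
    """Log-Euclidean distance ``||Log(D1) - Log(D2)||_F``."""
    _check_pair(D1, D2)
    return float(np.linalg.norm(matrix_log(D1) - matrix_log(D2), "fro"))


def jbld_divergence(D1: np.ndarray, D2: np.ndarray) -> float:
    """Jensen-Bregman LogDet divergence (square-root form).

    Log-determinants are computed from Cholesky factors. The radicand is
    nonnegative in exact arithmetic; values in [-1e-10, 0] are clamped to
    0, anything lower raises.
    """
    _check_pair(D1, D2)
    D1 = validate_spd(D1, "D1")
    D2 = validate_spd(D2, "D2")
    radicand = logdet_cholesky((D1 + D2) / 2.0) - 0.5 * (
        logdet_cholesky(D1) + logdet_cholesky(D2)
    )
    if radicand < -1e-10:
        raise ValueError(f"JBLD radicand {radicand:.3e} below numerical tolerance")
    return float(np.sqrt(max(radicand, 0.0)))


def pairwise_gram(descriptors: list[np.ndarray], measure: str = "lerm") -> SimilarityGram:
    """Symmetric pairwise distance matrix under the chosen measure.

    For LERM the n matrix logarithms are computed once and distances come
    from Frobenius norms of their differences (n log-evals, not n^2).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    if len(descriptors) == 0:
        raise ValueError("need at least one descriptor")
    dims = {np.shape(D) for D in descriptors}
    if len(dims) != 1:
        raise ValueError(f"descriptors have mixed shapes: {sorted(dims)}")
    n = len(descriptors)
    G = np.zeros((n, n))
    if measure == "lerm":
        logs = np.stack([matrix_log(D) for D in descriptors])
        flat = logs.reshape(n, -1)
        sq = np.sum(flat**2, axis=1)
        G = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
        np.fill_diagonal(G, 0.0)
        G = np.sqrt(np.maximum(G, 0.0))
    else:
        mats = [validate_spd(D, f"descriptor {i}") for i, D in enumerate(descriptors)]
        half_logdets = np.array([0.5 * logdet_cholesky(D) for D in mats])
        for i in range(n):
            for j in range(i + 1, n):
                rad = (
                    logdet_cholesky((mats[i] + mats[j]) / 2.0)
                    - half_logdets[i]
                    - half_logdets[j]
                )
                if rad < -1e-10:
                    raise ValueError(
                        f"JBLD radicand {rad:.3e} below tolerance for pair ({i},{j})"
                    )
                G[i, j] = G[j, i] = np.sqrt(max(rad, 0.0))
    G = (G + G.T) / 2.0
    return SimilarityGram(values=G, measure=measure)


def rbf_from_gram(gram: SimilarityGram, gamma: float = 2.5e-4) -> np.ndarray:
    """RBF kernel ``K = exp(-gamma * dist^2)`` from a distance Gram matrix.

    The LERM version is a genuine Mercer kernel (Gaussian on the
    log-embedded matrices). JBLD distances can yield an indefinite K; if
    eigenvalues fall below -1e-8, a warning is emitted and the negative
    part of the spectrum is clipped to 0 so downstream kernel machines
    receive a PSD matrix.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    K = np.exp(-gamma * gram.values**2)
    lam_min = float(np.linalg.eigvalsh(K)[0])
    if lam_min < -1e-8:
        warnings.warn(
            f"indefinite RBF kernel from {gram.measure} distances "
            f"(min eigenvalue {lam_min:.3e}); clipping negative spectrum",
            RuntimeWarning,
            stacklevel=2,
        )
        lam, U = np.linalg.eigh(K)
        K = (U * np.maximum(lam, 0.0)) @ U.T
        K = (K + K.T) / 2.0
    return K
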