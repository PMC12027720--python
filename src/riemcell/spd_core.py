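"""Primitives of SPD-manifold geometry.

Symmetric positive definite (SPD) matrices form a Riemannian manifold; this
module provides the exact operations everything else is built on: projection
of an arbitrary square matrix onto the SPD cone, matrix log/exp between the
manifold and its tangent space at the identity, an isometric half-vectorization
of symmetric matrices, the Stein (Jensen–Bregman LogDet) divergence, Cholesky
factorization, and regularized patch covariance descriptors.

All functions accept either a bare ``numpy`` array or one of the light wrapper
dataclasses below and return wrappers, so the geometric invariants travel with
the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_EPS = 1e-6

__all__ = [
    "SPDMatrix",
    "TangentSymm",
    "TangentVector",
    "CholeskyFactor",
    "project_to_spd",
    "spd_log",
    "spd_exp",
    "tangent_vectorize",
    "tangent_unvectorize",
    "stein_divergence",
    "cholesky_factor",
    "patch_covariance",
    "expm_sym",
    "expm_sym_vjp",
    "logm_sym",
]


def _values(x) -> np.ndarray:
    """Unwrap a dataclass carrying ``.values`` or pass an array through."""
    return np.asarray(getattr(x, "values", x), dtype=float)


def _check_square_finite(M: np.ndarray, name: str = "matrix") -> None:
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite entries")


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


@dataclass(frozen=True)
class SPDMatrix:
    """A symmetric positive definite matrix with an eigenvalue floor ``eps``."""

    values: np.ndarray
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        _check_square_finite(v, "SPDMatrix.values")
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TangentSymm:
    """Symmetric matrix: an element of the tangent space at the identity."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        _check_square_finite(v, "TangentSymm.values")
        if not np.allclose(v, v.T, rtol=1e-10, atol=1e-10):
            raise ValueError("TangentSymm must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TangentVector:
    """Half-vectorized symmetric matrix of length d(d+1)/2."""

    values: np.ndarray
    dim: int = field(default=0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        d = self.dim or _dim_from_veclen(v.size)
        if v.size != d * (d + 1) // 2:
            raise ValueError(f"vector length {v.size} inconsistent with d={d}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "dim", d)


@dataclass(frozen=True)
class CholeskyFactor:
    """Lower-triangular factor L with positive diagonal, L Lᵀ = A."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        _check_square_finite(v, "CholeskyFactor.values")
        if not np.allclose(v, np.tril(v)):
            raise ValueError("CholeskyFactor must be lower-triangular")
        if np.any(np.diag(v) <= 0):
            raise ValueError("CholeskyFactor diagonal must be positive")
        object.__setattr__(self, "values", v)


def _dim_from_veclen(n: int) -> int:
    # n = d(d+1)/2  =>  d = (sqrt(8n+1)-1)/2
    d = int(round((np.sqrt(8 * n + 1) - 1) / 2))
    if d * (d + 1) // 2 != n:
        raise ValueError(f"{n} is not a triangular number")
    return d


def project_to_spd(M, eps: float = DEFAULT_EPS) -> SPDMatrix:
    """Symmetrize then clamp eigenvalues: A = ½(M+Mᵀ) = QΛQᵀ, Λ ← max(Λ, εI).

    Idempotent; a symmetric input with eigmin ≥ eps is returned unchanged
    (up to the eigendecomposition round-trip).
    """
    M = _values(M)
    _check_square_finite(M)
    if eps <= 0:
        raise ValueError("eps must be positive")
    A = _sym(M)
    lam, Q = np.linalg.eigh(A)
    if lam.min() >= eps:
        return SPDMatrix(A, eps=eps)
    lam = np.maximum(lam, eps)
    return SPDMatrix(_sym((Q * lam) @ Q.T), eps=eps)


def logm_sym(A: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD array via eigendecomposition."""
    lam, Q = np.linalg.eigh(A)
    if lam.min() <= 0:
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return _sym((Q * np.log(lam)) @ Q.T)


def expm_sym(Y: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric array via eigendecomposition."""
    lam, Q = np.linalg.eigh(Y)
    if lam.max() > 700.0:  # exp would overflow float64
        raise OverflowError("matrix exponential overflow: eigenvalue > 700")
    return _sym((Q * np.exp(lam)) @ Q.T)


def expm_sym_vjp(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Vector-Jacobian product of ``expm_sym`` at symmetric Y.

    For Y = V diag(γ) Vᵀ the Fréchet derivative in direction H is
    V ((Vᵀ H V) ∘ K) Vᵀ with K_ij the divided difference of exp between
    γ_i and γ_j; the adjoint has the same form applied to G.
    """
    lam, V = np.linalg.eigh(_sym(Y))
    e = np.exp(lam)
    den = lam[:, None] - lam[None, :]
    num = e[:, None] - e[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(np.abs(den) > 1e-12, num / den, np.exp(0.5 * (lam[:, None] + lam[None, :])))
    Gs = _sym(G)
    return _sym(V @ ((V.T @ Gs @ V) * K) @ V.T)


def spd_log(A) -> TangentSymm:
    """Log map at the identity: SPD manifold → tangent space."""
    Av = _values(A)
    _check_square_finite(Av)
    return TangentSymm(logm_sym(Av))


def spd_exp(Y) -> SPDMatrix:
    """Exp map at the identity: tangent space → SPD manifold. Inverse of spd_log."""
    Yv = _sym(_values(Y))
    _check_square_finite(Yv)
    return SPDMatrix(expm_sym(Yv), eps=0.0)


def tangent_vectorize(Y) -> TangentVector:
    """Flatten the upper triangle row-major, off-diagonals scaled by √2.

    The scaling makes the map a linear isometry: ⟨vec Y₁, vec Y₂⟩ = tr(Y₁Y₂).
    """
    Yv = _values(Y)
    _check_square_finite(Yv)
    d = Yv.shape[0]
    iu, ju = np.triu_indices(d)
    scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return TangentVector(Yv[iu, ju] * scale, dim=d)


def tangent_unvectorize(z, dim: int | None = None) -> TangentSymm:
    """Exact inverse of :func:`tangent_vectorize`."""
    zv = np.asarray(getattr(z, "values", z), dtype=float).ravel()
    d = dim or getattr(z, "dim", 0) or _dim_from_veclen(zv.size)
    if zv.size != d * (d + 1) // 2:
        raise ValueError(f"length {zv.size} does not match d={d}")
    iu, ju = np.triu_indices(d)
    scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
    Y = np.zeros((d, d))
    Y[iu, ju] = zv / scale
    Y = Y + np.triu(Y, 1).T
    return TangentSymm(Y)


def _chol_logdet(A: np.ndarray) -> float:
    L = np.linalg.cholesky(A)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def stein_divergence(A, B) -> float:
    """Stein (Jensen–Bregman LogDet) divergence between SPD matrices.

    S(A, B) = log det((A+B)/2) − ½ log det A − ½ log det B.
    Symmetric, nonnegative, zero iff A = B, invariant under congruence
    A ↦ MAMᵀ. Computed through Cholesky-based log-determinants.
    """
    Av, Bv = _values(A), _values(B)
    if Av.shape != Bv.shape:
        raise ValueError(f"dimension mismatch: {Av.shape} vs {Bv.shape}")
    s = _chol_logdet(0.5 * (Av + Bv)) - 0.5 * _chol_logdet(Av) - 0.5 * _chol_logdet(Bv)
    return max(s, 0.0)  # clip tiny negative round-off


def cholesky_factor(A) -> CholeskyFactor:
    Av = _values(A)
    _check_square_finite(Av)
    try:
        L = np.linalg.cholesky(Av)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("input is not positive definite") from exc
    return CholeskyFactor(L)


def patch_covariance(X, eps: float = DEFAULT_EPS) -> SPDMatrix:
    """Regularized sample covariance of a d × n feature-by-pixel matrix.

    Rows are features, columns are pixels; the per-feature mean is subtracted,
    Cov = (X−X̄)(X−X̄)ᵀ/(n−1) + εI, and the result is passed through
    :func:`project_to_spd`.
    """
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim != 2:
        raise ValueError("X must be a 2-D feature-by-pixel matrix")
    d, n = Xv.shape
    if n < 2:
        raise ValueError("need at least 2 pixels for a sample covariance")
    Xc = Xv - Xv.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / (n - 1) + eps * np.eye(d)
    return project_to_spd(C, eps=eps)
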