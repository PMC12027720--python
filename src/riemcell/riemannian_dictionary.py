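"""Riemannian dictionary learning on SPD patch descriptors.

A dictionary of K tangent-space atoms Z_k and an amortized linear encoder W
are learned jointly by full-batch gradient descent on a Stein-divergence
reconstruction loss with an L1 sparsity penalty on the weights and a spatial
smoothness penalty between 4-neighbour patches.

The pipeline per descriptor A:
    z = vec(log A)  →  ω = W z + b  →  Y = Σ_k ω_k Z_k  →  Â = exp(Y)
and the loss
    L = (1/N) Σ_i S(A_i, Â_i) + α · mean_i ‖ω_i‖₁ + β · mean_pairs ‖Δω‖²

Gradients of the Stein term are analytic: ∂S/∂Â = ½M⁻¹ − ½Â⁻¹ with
M = (A+Â)/2, pulled back through the symmetric matrix exponential via its
eigendecomposition-based Fréchet adjoint (``spd_core.expm_sym_vjp``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.cluster import KMeans

from .patch_features import PatchGrid
from .spd_core import (
    SPDMatrix,
    logm_sym,
    spd_exp,
    tangent_unvectorize,
    tangent_vectorize,
)

__all__ = [
    "DictionaryModel",
    "WeightField",
    "init_dictionary",
    "encode_weights",
    "reconstruct_spd",
    "encode_field",
    "dictionary_loss",
    "fit_dictionary",
    "save_model",
    "load_model",
]

DEFAULT_K = 8
DEFAULT_ALPHA = 1e-3
DEFAULT_BETA = 1e-3
DEFAULT_LR = 1e-2
DEFAULT_EPOCHS = 500


@dataclass
class DictionaryModel:
    atoms: np.ndarray  # K × d × d symmetric tangent atoms Z_k
    encoder_weights: np.ndarray  # K × d(d+1)/2
    encoder_bias: np.ndarray  # K
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    eps: float = 1e-6

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=float)
        self.encoder_weights = np.asarray(self.encoder_weights, dtype=float)
        self.encoder_bias = np.asarray(self.encoder_bias, dtype=float)
        K, d, d2 = self.atoms.shape
        if d != d2 or K < 1:
            raise ValueError("atoms must be K×d×d with K >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.encoder_weights.shape != (K, d * (d + 1) // 2):
            raise ValueError("encoder_weights must be K × d(d+1)/2")
        if self.encoder_bias.shape != (K,):
            raise ValueError("encoder_bias must have length K")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def dim(self) -> int:
        return self.atoms.shape[1]


@dataclass
class WeightField:
    weights: np.ndarray  # rows × cols × K
    grid: PatchGrid = field(repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 3 or w.shape[:2] != self.grid.grid_dims:
            raise ValueError(
                f"weights shape {w.shape} inconsistent with grid {self.grid.grid_dims}"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        self.weights = w

    @property
    def flat(self) -> np.ndarray:
        return self.weights.reshape(-1, self.weights.shape[-1])


def _tangent_vectors(covs) -> np.ndarray:
    return np.stack([tangent_vectorize(logm_sym(np.asarray(c.values))).values for c in covs])


def init_dictionary(covs: list[SPDMatrix], K: int, seed: int, alpha: float = DEFAULT_ALPHA,
                    beta: float = DEFAULT_BETA, eps: float = 1e-6) -> DictionaryModel:
    """Initialize atoms from K-Means++ centroids of the tangent vectors.

    The encoder (W, b) starts as the least-squares affine map from tangent
    vectors to one-hot centroid assignments, so the initial weights already
    roughly select the nearest atom.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(covs):
        raise ValueError(f"K={K} exceeds the number of descriptors ({len(covs)})")
    Z = _tangent_vectors(covs)  # N × p
    d = covs[0].values.shape[0]
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(Z)
    atoms = np.stack([tangent_unvectorize(c, dim=d).values for c in km.cluster_centers_])
    onehot = np.eye(K)[labels]  # N × K
    design = np.hstack([Z, np.ones((Z.shape[0], 1))])  # affine least squares
    coef, *_ = np.linalg.lstsq(design, onehot, rcond=None)
    W = coef[:-1].T  # K × p
    b = coef[-1]
    return DictionaryModel(atoms=atoms, encoder_weights=W, encoder_bias=b,
                           alpha=alpha, beta=beta, eps=eps)


def encode_weights(model: DictionaryModel, A) -> np.ndarray:
    """ω = W · vec(log A) + b (unconstrained reals)."""
    z = tangent_vectorize(logm_sym(np.asarray(getattr(A, "values", A), dtype=float))).values
    if z.size != model.encoder_weights.shape[1]:
        raise ValueError("descriptor dimension does not match the model")
    return model.encoder_weights @ z + model.encoder_bias


def encode_field(model: DictionaryModel, covs: list[SPDMatrix], grid: PatchGrid) -> WeightField:
    """Encode every patch descriptor and shape the weights on the patch grid."""
    W = np.stack([encode_weights(model, c) for c in covs])
    rows, cols = grid.grid_dims
    return WeightField(weights=W.reshape(rows, cols, model.n_atoms), grid=grid)


def reconstruct_spd(model: DictionaryModel, omega) -> SPDMatrix:
    """Â = exp(Σ_k ω_k Z_k) — always a valid SPD matrix."""
    w = np.asarray(omega, dtype=float).ravel()
    if w.size != model.n_atoms:
        raise ValueError(f"expected {model.n_atoms} weights, got {w.size}")
    Y = np.tensordot(w, model.atoms, axes=(0, 0))
    return spd_exp(Y)


def _neighbor_pairs(rows: int, cols: int) -> np.ndarray:
    """Index pairs of 4-neighbour patches on a rows × cols grid (right + down)."""
    idx = np.arange(rows * cols).reshape(rows, cols)
    pairs = []
    if cols > 1:
        pairs.append(np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1))
    if rows > 1:
        pairs.append(np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1))
    return np.concatenate(pairs) if pairs else np.empty((0, 2), dtype=int)


def _stein_batch(A: np.ndarray, Y: np.ndarray, want_grad: bool):
    """Batched S(A_i, exp(Y_i)) over stacked (N,d,d) arrays.

    Returns (per-item divergences, gradients w.r.t. Y or None). Raises
    ``OverflowError`` if any exp would overflow and ``LinAlgError`` on a
    non-PD intermediate — both are caught by the line search.
    """
    lam, V = np.linalg.eigh(0.5 * (Y + np.swapaxes(Y, -1, -2)))
    if lam.max() > 700.0:
        raise OverflowError("matrix exponential overflow")
    e = np.exp(lam)
    Ahat = np.einsum("nij,nj,nkj->nik", V, e, V)
    M = 0.5 * (A + Ahat)
    Lm = np.linalg.cholesky(M)
    logdet_m = 2.0 * np.log(np.diagonal(Lm, axis1=-2, axis2=-1)).sum(axis=-1)
    logdet_a = 2.0 * np.log(
        np.diagonal(np.linalg.cholesky(A), axis1=-2, axis2=-1)
    ).sum(axis=-1)
    logdet_h = lam.sum(axis=-1)
    s = np.maximum(logdet_m - 0.5 * logdet_a - 0.5 * logdet_h, 0.0)
    if not want_grad:
        return s, None
    Minv = np.linalg.inv(M)
    Hinv = np.einsum("nij,nj,nkj->nik", V, 1.0 / e, V)
    G = 0.5 * Minv - 0.5 * Hinv  # dS/dÂ
    # pull back through the symmetric matrix exponential (divided differences)
    den = lam[..., :, None] - lam[..., None, :]
    num = e[..., :, None] - e[..., None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(
            np.abs(den) > 1e-12,
            num / den,
            np.exp(0.5 * (lam[..., :, None] + lam[..., None, :])),
        )
    inner = np.einsum("nji,njk,nkl->nil", V, 0.5 * (G + np.swapaxes(G, -1, -2)), V)
    dY = np.einsum("nij,njk,nlk->nil", V, inner * K, V)
    return s, 0.5 * (dY + np.swapaxes(dY, -1, -2))


def dictionary_loss(
    model: DictionaryModel, covs: list[SPDMatrix], field_: WeightField
) -> tuple[float, dict[str, float]]:
    """Total loss and its parts {stein, l1, smooth} for a given weight field."""
    W = field_.flat
    if W.shape[0] != len(covs):
        raise ValueError("weight field size does not match descriptor count")
    A = np.stack([np.asarray(c.values, dtype=float) for c in covs])
    Y = np.einsum("nk,kab->nab", W, model.atoms)
    s, _ = _stein_batch(A, Y, want_grad=False)
    stein = float(s.mean())
    l1 = model.alpha * float(np.abs(W).sum(axis=1).mean())
    pairs = _neighbor_pairs(*field_.grid.grid_dims)
    if len(pairs):
        diffs = W[pairs[:, 0]] - W[pairs[:, 1]]
        smooth = model.beta * float((diffs**2).sum() / len(pairs))
    else:
        smooth = 0.0
    parts = {"stein": stein, "l1": l1, "smooth": smooth}
    return stein + l1 + smooth, parts


def _loss_and_grads(model: DictionaryModel, A_list: list[np.ndarray], Zvecs: np.ndarray,
                    pairs: np.ndarray):
    """Full-batch loss and analytic gradients with respect to W, b, atoms."""
    N, K = Zvecs.shape[0], model.n_atoms
    omega = Zvecs @ model.encoder_weights.T + model.encoder_bias  # N × K
    A = A_list if isinstance(A_list, np.ndarray) else np.stack(A_list)
    Y = np.einsum("nk,kab->nab", omega, model.atoms)
    s, dY = _stein_batch(A, Y, want_grad=True)
    stein = float(s.mean())
    dY = dY / N
    dOmega = np.einsum("kab,nab->nk", model.atoms, dY)
    dAtoms = np.einsum("nk,nab->kab", omega, dY)

    l1 = model.alpha * float(np.abs(omega).sum(axis=1).mean())
    dOmega += model.alpha * np.sign(omega) / N

    smooth = 0.0
    if len(pairs):
        diffs = omega[pairs[:, 0]] - omega[pairs[:, 1]]
        smooth = model.beta * float((diffs**2).sum() / len(pairs))
        g = 2.0 * model.beta * diffs / len(pairs)
        np.add.at(dOmega, pairs[:, 0], g)
        np.add.at(dOmega, pairs[:, 1], -g)

    dW = dOmega.T @ Zvecs
    db = dOmega.sum(axis=0)
    total = stein + l1 + smooth
    return total, {"stein": stein, "l1": l1, "smooth": smooth}, dW, db, dAtoms


def fit_dictionary(
    model: DictionaryModel,
    covs: list[SPDMatrix],
    grid: PatchGrid,
    epochs: int = DEFAULT_EPOCHS,
    lr: float = DEFAULT_LR,
    seed: int = 0,
) -> tuple[DictionaryModel, list[float]]:
    """Full-batch gradient descent with backtracking line search over W, b, Z_k.

    Each epoch takes one descent step: the step size starts from ``lr``, is
    halved while the candidate loss does not decrease (the matrix exponential
    makes the landscape sharply curved, so a fixed step diverges), and is
    allowed to grow back by 1.25× after successful epochs. Atoms are
    re-symmetrized ½(Z+Zᵀ) after every step. Fully deterministic (``seed`` is
    accepted for interface symmetry). Raises ``FloatingPointError`` with the
    offending epoch on a non-finite loss.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if lr <= 0:
        raise ValueError("lr must be positive")
    A_stack = np.stack([np.asarray(c.values, dtype=float) for c in covs])
    A_list = A_stack
    Zvecs = _tangent_vectors(covs)
    pairs = _neighbor_pairs(*grid.grid_dims)
    m = replace(model)

    def step(model_, eta, dW, db, dAtoms):
        newA = model_.atoms - eta * dAtoms
        return DictionaryModel(
            atoms=0.5 * (newA + newA.transpose(0, 2, 1)),
            encoder_weights=model_.encoder_weights - eta * dW,
            encoder_bias=model_.encoder_bias - eta * db,
            alpha=model_.alpha,
            beta=model_.beta,
            eps=model_.eps,
        )

    def try_loss(model_):
        try:
            omega = Zvecs @ model_.encoder_weights.T + model_.encoder_bias
            Y = np.einsum("nk,kab->nab", omega, model_.atoms)
            si, _ = _stein_batch(A_stack, Y, want_grad=False)
            s = float(si.mean())
            l1 = model_.alpha * float(np.abs(omega).sum(axis=1).mean())
            sm = 0.0
            if len(pairs):
                diffs = omega[pairs[:, 0]] - omega[pairs[:, 1]]
                sm = model_.beta * float((diffs**2).sum() / len(pairs))
            return s + l1 + sm
        except (np.linalg.LinAlgError, OverflowError):
            return np.inf

    history: list[float] = []
    eta = lr
    for epoch in range(epochs):
        total, _, dW, db, dAtoms = _loss_and_grads(m, A_list, Zvecs, pairs)
        if not np.isfinite(total):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history.append(total)
        candidate = step(m, eta, dW, db, dAtoms)
        new_loss = try_loss(candidate)
        tries = 0
        while new_loss >= total and tries < 30:
            eta *= 0.5
            candidate = step(m, eta, dW, db, dAtoms)
            new_loss = try_loss(candidate)
            tries += 1
        if new_loss < total:
            m = candidate
            eta = min(eta * 1.25, lr)
        # else: stuck at a stationary point; keep the current model
    return m, history


def save_model(model: DictionaryModel, prefix: str) -> dict[str, str]:
    """Serialize to ``<prefix>.json`` (config) + ``<prefix>.npz`` (arrays)."""
    paths = {"config": f"{prefix}.json", "arrays": f"{prefix}.npz"}
    np.savez(paths["arrays"], atoms=model.atoms, encoder_weights=model.encoder_weights,
             encoder_bias=model.encoder_bias)
    with open(paths["config"], "w") as fh:
        json.dump({"K": model.n_atoms, "dim": model.dim, "alpha": model.alpha,
                   "beta": model.beta, "eps": model.eps}, fh, indent=2)
    return paths


def load_model(prefix: str) -> DictionaryModel:
    with open(f"{prefix}.json") as fh:
        cfg = json.load(fh)
    arrs = np.load(f"{prefix}.npz")
    return DictionaryModel(atoms=arrs["atoms"], encoder_weights=arrs["encoder_weights"],
                           encoder_bias=arrs["encoder_bias"], alpha=cfg["alpha"],
                           beta=cfg["beta"], eps=cfg["eps"])
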