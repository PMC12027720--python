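"""Convolutional autoencoder over masked cell crops.

Three variants share a five-stage strided conv encoder (kernel 4, stride 2,
padding 1, channels doubling to ``feature_depth``) that maps a 128×128 crop to
a 4×4 feature map, a two-layer shape MLP embedding the source bounding-box
size, and a mirrored transposed-conv decoder:

* ``AE``    — deterministic latent, no attention;
* ``MHAAE`` — masked multi-head cross-attention in the bottleneck between the
  image-feature tokens and the shape embedding (queries = tokens + shape,
  keys/values = tokens, letterbox token positions masked out);
* ``VAE``   — MHAAE plus a reparameterized latent with a KLD penalty.

The bottleneck is spatial: a 1×1 convolution reduces the feature map to a
``latent_dim``-deep 4×4 latent map, which the decoder consumes concatenated
with the spatially broadcast shape embedding through channel batch
normalization. The deliverable embedding is the global average pool of that
same latent map, L2-normalized — on the reconstruction path, so it is trained
by the loss (MAE + (1 − SSIM)). The VAE samples a reparameterized vector from
the pooled features and re-expands it to the 4×4 map.

Everything runs on the package's small numpy autograd engine; training is Adam
with the configured learning rate and per-epoch exponential decay, with
rotation/flip augmentation and 3×3 Gaussian blur input noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, box_mean_valid, concat, conv2d, conv_transpose2d, matmul
from .crops import CROP_SIZE, CellCrop

__all__ = ["EncoderConfig", "AutoencoderModel", "train_autoencoder", "embed_cells", "LatentVector"]

VARIANTS = ("AE", "MHAAE", "VAE")
ATTN_HEADS = 4


@dataclass
class EncoderConfig:
    feature_depth: int = 256
    kernel: int = 4
    stride: int = 2
    padding: int = 1
    latent_dim: int = 256
    variant: str = "AE"
    loss_terms: tuple[str, ...] = ("MAE", "SSIM")
    kld_weight: float = 0.001
    lr: float = 1e-4
    batch: int = 128
    lr_decay: float = 0.95
    epochs: int = 50
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.batch < 1:
            raise ValueError("batch must be >= 1")
        unknown = set(self.loss_terms) - {"MAE", "SSIM"}
        if unknown:
            raise ValueError(f"unknown loss terms {sorted(unknown)}")

    @property
    def channels(self) -> tuple[int, ...]:
        fd = self.feature_depth
        return (max(1, fd // 16), max(1, fd // 8), max(1, fd // 4), max(1, fd // 2), fd)


@dataclass
class LatentVector:
    """256-d (latent_dim) embedding, unit Euclidean norm."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        n = np.linalg.norm(v)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"latent vector must be unit norm, got {n}")
        self.values = v


def _kaiming(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class AutoencoderModel:
    """Parameter container plus forward pass for all variants."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel
        ch = config.channels
        fd = config.feature_depth
        ld = config.latent_dim
        p: dict[str, Tensor] = {}
        cin = 1
        for i, cout in enumerate(ch):
            p[f"enc{i}_w"] = Tensor(_kaiming(rng, (cout, cin, k, k), cin * k * k), True)
            p[f"enc{i}_b"] = Tensor(np.zeros(cout, dtype=np.float32), True)
            cin = cout
        # shape MLP: (h, w)/128 → 64 → fd, layer-normalized
        p["smlp1_w"] = Tensor(_kaiming(rng, (2, 64), 2), True)
        p["smlp1_b"] = Tensor(np.zeros(64, dtype=np.float32), True)
        p["smlp2_w"] = Tensor(_kaiming(rng, (64, fd), 64), True)
        p["smlp2_b"] = Tensor(np.zeros(fd, dtype=np.float32), True)
        p["sln_g"] = Tensor(np.ones(fd, dtype=np.float32), True)
        p["sln_b"] = Tensor(np.zeros(fd, dtype=np.float32), True)
        if config.variant in ("MHAAE", "VAE"):
            for name in ("q", "k", "v", "o"):
                p[f"attn_{name}_w"] = Tensor(_kaiming(rng, (fd, fd), fd), True)
                p[f"attn_{name}_b"] = Tensor(np.zeros(fd, dtype=np.float32), True)
        p["lat_w"] = Tensor(_kaiming(rng, (ld, fd, 1, 1), fd), True)
        p["lat_b"] = Tensor(np.zeros(ld, dtype=np.float32), True)
        if config.variant == "VAE":
            p["mu_w"] = Tensor(_kaiming(rng, (ld, ld), ld), True)
            p["mu_b"] = Tensor(np.zeros(ld, dtype=np.float32), True)
            p["lv_w"] = Tensor((rng.standard_normal((ld, ld)) * 0.01).astype(np.float32), True)
            p["lv_b"] = Tensor(np.zeros(ld, dtype=np.float32), True)
        p["bn_g"] = Tensor(np.ones(ld + fd, dtype=np.float32), True)
        p["bn_b"] = Tensor(np.zeros(ld + fd, dtype=np.float32), True)
        p["dec_in_w"] = Tensor(_kaiming(rng, (fd, ld + fd, 1, 1), ld + fd), True)
        p["dec_in_b"] = Tensor(np.zeros(fd, dtype=np.float32), True)
        if config.variant == "VAE":
            p["vae_fc_w"] = Tensor(_kaiming(rng, (ld, ld * 16), ld), True)
            p["vae_fc_b"] = Tensor(np.zeros(ld * 16, dtype=np.float32), True)
        rev = (fd,) + tuple(reversed(ch[:-1])) + (1,)
        for i in range(len(rev) - 1):
            cin_t, cout_t = rev[i], rev[i + 1]
            p[f"dec{i}_w"] = Tensor(_kaiming(rng, (cin_t, cout_t, k, k), cin_t * k * k), True)
            p[f"dec{i}_b"] = Tensor(np.zeros(cout_t, dtype=np.float32), True)
        self.params = p
        self.bn_mean = np.zeros(ld + fd, dtype=np.float32)
        self.bn_var = np.ones(ld + fd, dtype=np.float32)
        self.grid = CROP_SIZE // (config.stride ** len(ch))  # bottleneck side (4)

    # -- building blocks ------------------------------------------------------

    def _shape_embed(self, shapes: np.ndarray) -> Tensor:
        p = self.params
        s = Tensor((shapes / float(CROP_SIZE)).astype(np.float32))
        h = (matmul(s, p["smlp1_w"]) + p["smlp1_b"]).relu()
        h = matmul(h, p["smlp2_w"]) + p["smlp2_b"]
        mu = h.mean(axis=1, keepdims=True)
        var = ((h - mu) ** 2).mean(axis=1, keepdims=True)
        return p["sln_g"] * ((h - mu) / (var + 1e-5).sqrt()) + p["sln_b"]

    def _attention(self, tokens: Tensor, shape_emb: Tensor, valid: np.ndarray) -> Tensor:
        """Masked multi-head cross-attention; residual over the tokens."""
        p = self.params
        B, L, D = tokens.shape
        H = ATTN_HEADS
        dh = D // H
        q_in = tokens + shape_emb.reshape(B, 1, D)

        def proj(t, name):
            flat = matmul(t.reshape(B * L, D), p[f"attn_{name}_w"]) + p[f"attn_{name}_b"]
            return flat.reshape(B, L, H, dh).transpose(0, 2, 1, 3)  # B,H,L,dh

        q, kk, v = proj(q_in, "q"), proj(tokens, "k"), proj(tokens, "v")
        scores = matmul(q, kk.transpose(0, 1, 3, 2)) * np.float32(1.0 / np.sqrt(dh))
        bias = np.where(valid, 0.0, -1e9).astype(np.float32)[:, None, None, :]  # B,1,1,L
        scores = scores + Tensor(bias)
        smax = scores.data.max(axis=-1, keepdims=True)  # detached stabilizer
        e = (scores - Tensor(smax)).exp()
        att = e / e.sum(axis=-1, keepdims=True)
        out = matmul(att, v).transpose(0, 2, 1, 3).reshape(B * L, D)
        out = (matmul(out, p["attn_o_w"]) + p["attn_o_b"]).reshape(B, L, D)
        return tokens + out

    def encode(self, x: Tensor, shapes: np.ndarray, masks: np.ndarray):
        """Returns (pooled latent features before normalization, shape embedding)."""
        cfg = self.config
        p = self.params
        h = x
        for i in range(len(cfg.channels)):
            h = conv2d(h, p[f"enc{i}_w"], p[f"enc{i}_b"], stride=cfg.stride,
                       padding=cfg.padding).relu()
        s = self._shape_embed(shapes)
        g = self.grid
        if cfg.variant in ("MHAAE", "VAE"):
            B = h.shape[0]
            tokens = h.reshape(B, cfg.feature_depth, g * g).transpose(0, 2, 1)
            valid = self._token_mask(masks)
            tokens = self._attention(tokens, s, valid)
            h = tokens.transpose(0, 2, 1).reshape(B, cfg.feature_depth, g, g)
        lat_map = conv2d(h, p["lat_w"], p["lat_b"])  # 1×1 reduction, stays 4×4
        pooled = lat_map.mean(axis=(2, 3))  # global average pool → B × latent_dim
        return pooled, s, lat_map

    def _token_mask(self, masks: np.ndarray) -> np.ndarray:
        """Downsample padding masks to the bottleneck grid: valid if any true pixel."""
        B = masks.shape[0]
        g = self.grid
        block = CROP_SIZE // g
        m = masks.reshape(B, g, block, g, block).any(axis=(2, 4))
        m = m.reshape(B, g * g)
        m[~m.any(axis=1)] = True  # never mask out every key position
        return m

    def forward(self, x: Tensor, shapes: np.ndarray, masks: np.ndarray,
                train: bool, rng: np.random.Generator | None = None):
        """Full pass; returns (reconstruction, z_normalized, mu, logvar)."""
        cfg = self.config
        p = self.params
        pooled, s, lat_map = self.encode(x, shapes, masks)
        B = x.shape[0]
        g = self.grid
        mu = logvar = None
        if cfg.variant == "VAE":
            mu = matmul(pooled, p["mu_w"].transpose(1, 0)) + p["mu_b"]
            logvar = matmul(pooled, p["lv_w"].transpose(1, 0)) + p["lv_b"]
            if train:
                if rng is None:
                    raise ValueError("VAE training requires an rng")
                noise = Tensor(rng.standard_normal(mu.shape).astype(np.float32))
                z_sample = mu + (logvar * 0.5).exp() * noise
            else:
                z_sample = mu
            dec_map = (matmul(z_sample, p["vae_fc_w"]) + p["vae_fc_b"]).reshape(
                B, cfg.latent_dim, g, g
            )
        else:
            dec_map = lat_map
        # normalized embedding (the deliverable latent; mu for the VAE)
        z_raw = mu if cfg.variant == "VAE" else pooled
        norm = ((z_raw**2).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        z = z_raw / norm
        # spatial bottleneck: latent map ⊕ broadcast shape embedding, batch-normed
        s_map = s.reshape(B, cfg.feature_depth, 1, 1) + Tensor(
            np.zeros((B, cfg.feature_depth, g, g), dtype=np.float32)
        )
        cat = concat([dec_map, s_map], axis=1)  # B × (ld+fd) × g × g
        if train:
            bmu = cat.mean(axis=(0, 2, 3), keepdims=True)
            bvar = ((cat - bmu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.bn_mean = 0.9 * self.bn_mean + 0.1 * bmu.data.ravel()
            self.bn_var = 0.9 * self.bn_var + 0.1 * bvar.data.ravel()
            cat = (cat - bmu) / (bvar + 1e-5).sqrt()
        else:
            cat = (cat - Tensor(self.bn_mean[None, :, None, None])) / Tensor(
                np.sqrt(self.bn_var[None, :, None, None] + 1e-5)
            )
        cat = p["bn_g"].reshape(1, -1, 1, 1) * cat + p["bn_b"].reshape(1, -1, 1, 1)
        h = conv2d(cat, p["dec_in_w"], p["dec_in_b"]).relu()
        n_dec = len(cfg.channels)
        for i in range(n_dec):
            h = conv_transpose2d(h, p[f"dec{i}_w"], p[f"dec{i}_b"], stride=cfg.stride,
                                 padding=cfg.padding)
            if i < n_dec - 1:
                h = h.relu()
        # final layer is linear: a tanh head saturates at the −1 background and
        # collapses the reconstruction to a constant (dead gradients)
        return h, z, mu, logvar

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    # -- serialization --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrs = {k: v.data for k, v in self.params.items()}
        arrs["__bn_mean"] = self.bn_mean
        arrs["__bn_var"] = self.bn_var
        return arrs

    def load_state_arrays(self, arrs) -> None:
        for k, t in self.params.items():
            t.data = np.asarray(arrs[k], dtype=np.float32)
        self.bn_mean = np.asarray(arrs["__bn_mean"], dtype=np.float32)
        self.bn_var = np.asarray(arrs["__bn_var"], dtype=np.float32)


# -- losses --------------------------------------------------------------------

_SSIM_WIN = 7


def ssim_mean(x: Tensor, y: Tensor) -> Tensor:
    """Differentiable mean SSIM on [0,1] images (uniform 7×7 window)."""
    c1, c2 = 0.01**2, 0.03**2
    mx = box_mean_valid(x, _SSIM_WIN)
    my = box_mean_valid(y, _SSIM_WIN)
    sxx = box_mean_valid(x * x, _SSIM_WIN) - mx * mx
    syy = box_mean_valid(y * y, _SSIM_WIN) - my * my
    sxy = box_mean_valid(x * y, _SSIM_WIN) - mx * my
    num = (mx * my * 2.0 + c1) * (sxy * 2.0 + c2)
    den = (mx * mx + my * my + c1) * (sxx + syy + c2)
    return (num / den).mean()


def _loss(recon: Tensor, target: Tensor, mu, logvar, cfg: EncoderConfig):
    parts: dict[str, float] = {}
    total = None
    if "MAE" in cfg.loss_terms:
        mae = (recon - target).abs().mean()
        parts["mae"] = float(mae.data)
        total = mae
    if "SSIM" in cfg.loss_terms:
        s = ssim_mean((recon + 1.0) * 0.5, (target + 1.0) * 0.5)
        dssim = 1.0 - s
        parts["ssim"] = float(s.data)
        total = dssim if total is None else total + dssim
    if cfg.variant == "VAE":
        kld = ((mu**2 + logvar.exp() - logvar - 1.0) * 0.5).mean()
        parts["kld"] = float(kld.data)
        total = total + kld * cfg.kld_weight
    if total is None:
        raise ValueError("loss_terms must include at least one of MAE/SSIM")
    return total, parts


# -- training ------------------------------------------------------------------

_BLUR_K = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0


def _blur3(batch: np.ndarray) -> np.ndarray:
    """3×3 Gaussian blur of a (B,1,H,W) batch, reflective borders."""
    from scipy.ndimage import convolve1d

    out = convolve1d(batch, [0.25, 0.5, 0.25], axis=2, mode="reflect")
    return convolve1d(out, [0.25, 0.5, 0.25], axis=3, mode="reflect")


def _augment(px: np.ndarray, mask: np.ndarray, shapes: np.ndarray, rng) -> tuple:
    """Random 90° rotations and flips, keeping masks and (h, w) consistent."""
    B = px.shape[0]
    ks = rng.integers(0, 4, size=B)
    flips = rng.integers(0, 2, size=B)
    px = px.copy()
    mask = mask.copy()
    shapes = shapes.copy()
    for i in range(B):
        if ks[i]:
            px[i, 0] = np.rot90(px[i, 0], ks[i])
            mask[i] = np.rot90(mask[i], ks[i])
            if ks[i] % 2 == 1:
                shapes[i] = shapes[i, ::-1]
        if flips[i]:
            px[i, 0] = px[i, 0][:, ::-1]
            mask[i] = mask[i][:, ::-1]
    return np.ascontiguousarray(px), np.ascontiguousarray(mask), shapes


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def _crop_arrays(crops: list[CellCrop]):
    px = np.stack([c.pixels for c in crops]).astype(np.float32)[:, None, :, :]
    masks = np.stack([c.padding_mask for c in crops])
    shapes = np.array([c.orig_size for c in crops], dtype=np.float32)
    return px, masks, shapes


def train_autoencoder(
    crops: list[CellCrop], config: EncoderConfig
) -> tuple[AutoencoderModel, list[float]]:
    """Train on synthetic or real crops; returns (model, per-epoch mean loss).

    Adam at ``config.lr`` with exponential per-epoch decay ``config.lr_decay``;
    rotation/flip augmentation plus 3×3 Gaussian blur applied to the encoder
    input (the target stays unblurred). Deterministic per ``config.seed``.
    Raises ``FloatingPointError`` with the epoch index on a non-finite loss.
    """
    if not crops:
        raise ValueError("need at least one crop")
    model = AutoencoderModel(config)
    rng = np.random.default_rng(config.seed + 1)
    px, masks, shapes = _crop_arrays(crops)
    n = len(crops)
    opt = _Adam(model.params, config.lr)
    history: list[float] = []
    for epoch in range(config.epochs):
        opt.lr = config.lr * config.lr_decay**epoch
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch):
            idx = order[start : start + config.batch]
            bp, bm, bs = px[idx], masks[idx], shapes[idx]
            if config.augment:
                bp, bm, bs = _augment(bp, bm, bs, rng)
            x_in = Tensor(_blur3(bp).astype(np.float32))
            target = Tensor(bp)
            recon, _, mu, logvar = model.forward(x_in, bs, bm, train=True, rng=rng)
            loss, _ = _loss(recon, target, mu, logvar, config)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    return model, history


def embed_cells(model: AutoencoderModel, crops: list[CellCrop],
                batch: int | None = None) -> list[LatentVector]:
    """L2-normalized latent vector per crop (deterministic given the model)."""
    px, masks, shapes = _crop_arrays(crops)
    bsz = batch or model.config.batch
    out: list[LatentVector] = []
    for start in range(0, len(crops), bsz):
        sl = slice(start, start + bsz)
        pooled, _, _ = model.encode(Tensor(px[sl]), shapes[sl], masks[sl])
        z = pooled
        if model.config.variant == "VAE":
            p = model.params
            z = matmul(pooled, p["mu_w"].transpose(1, 0)) + p["mu_b"]
        vals = z.data.astype(float)
        vals = vals / np.maximum(np.linalg.norm(vals, axis=1, keepdims=True), 1e-12)
        out.extend(LatentVector(v) for v in vals)
    return out


def reconstruct(model: AutoencoderModel, crops: list[CellCrop]) -> np.ndarray:
    """Eval-mode reconstructions (B×128×128, in [−1, 1])."""
    px, masks, shapes = _crop_arrays(crops)
    recon, *_ = model.forward(Tensor(px), shapes, masks, train=False)
    return recon.data[:, 0]
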