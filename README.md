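# riemcell

Unsupervised analysis of grayscale (phase-contrast-like) microscopy images,
in two independent arms:

1. **SPD / Riemannian segmentation** — images are split into patches, each
   patch is summarized by a regularized covariance descriptor of per-pixel
   features (an SPD matrix). A dictionary of tangent-space atoms plus an
   amortized linear encoder is learned by minimizing a Stein-divergence
   reconstruction loss with L1 and spatial-smoothness penalties. K-Means over
   the learned patch weights, soft assignment, and patch folding yield
   per-pixel, per-class probability maps and label maps.
2. **Latent morphology** — per-cell instance masks are cut into masked,
   normalized 128×128 crops; a convolutional autoencoder (optionally with a
   masked multi-head cross-attention bottleneck between image features and a
   shape-vector MLP, or a variational latent) produces L2-normalized 256-d
   embeddings; Barnes–Hut t-SNE with a cosine metric projects them to 2-D,
   HDBSCAN clusters them, and per-cluster area statistics (mean ± SEM) are
   reported.

A `synthetic_data` module generates deterministic textured scenes with
ground-truth instance masks, round-vs-elongated cell-crop populations, and
random SPD fixtures, so the whole pipeline runs and is tested without any
external data. The autoencoder runs on a small built-in numpy autograd engine
(no GPU or deep-learning framework required); everything is deterministic per
seed on CPU.

## Layout

| Module | Role |
| --- | --- |
| `riemcell.spd_core` | SPD projection, log/exp maps, isometric vectorization, Stein divergence, Cholesky, patch covariance |
| `riemcell.patch_features` | feature stacks, patch unfold/fold, covariance grids |
| `riemcell.riemannian_dictionary` | tangent-space dictionary + linear encoder, loss, analytic-gradient fitting |
| `riemcell.segmentation_maps` | K-Means on weight fields, soft assignments, probability/label maps |
| `riemcell.latent_embedding` | crops, autoencoder (AE / MHAAE / VAE), embeddings, t-SNE, HDBSCAN, area stats |
| `riemcell.synthetic_data` | deterministic scenes, crop populations, random SPD matrices |
| `riemcell.cli` | `riemcell` command-line interface |

## CLI

Every stage takes `--seed` (split into per-stage seeds via
`SHA-256(f"{seed}:{stage}")`) and an optional `--config` YAML whose keys
mirror `riemcell.cli.RunConfig`; unknown keys are rejected. Every artifact
embeds the hash of the resolved configuration.

```bash
# segmentation arm
riemcell simulate-scene --width 128 --height 128 --cells 6 --classes 2 \
    --seed 0 --out-prefix scene
riemcell fit-dictionary --image scene_image.tif --out-model dict --seed 0
riemcell segment --image scene_image.tif --model dict --classes 3 \
    --out-prefix seg --seed 0

# latent arm
riemcell crop --image scene_image.tif --labels scene_labels.tif --out crops.npz
riemcell train-ae --crops crops.npz --out-model ae --seed 0
riemcell embed --crops crops.npz --model ae --out latents.csv --seed 0
riemcell tsne --latents latents.csv --out points.csv --seed 0
riemcell cluster --points points.csv --crops crops.npz --out labels.csv --seed 0
```

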