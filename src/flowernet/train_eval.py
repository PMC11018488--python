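"""Training loop and counting metrics.

Training follows the patch strategy: every training image is divided
into a 3×3 grid of blocks, labels (density map + dilated mask) are built
at the network's output stride for each block, and Adam descends the
combined multitask loss over shuffled mini-batches of blocks.  Weights
start i.i.d. uniform on [−scale, scale] with zero biases.  Testing uses
complete images: each test image passes through mask-gated prediction
and the per-image (labeled, predicted) counts yield MAE and RMSE

    MAE  = mean |z_i − ẑ_i|,      RMSE = sqrt(mean (z_i − ẑ_i)²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses as L
from .data_io import (DatasetManifest, ImageRecord, PointAnnotationSet,
                      load_entry, split_into_patches)
from .labelgen import make_targets
from .model import (FlowerNet, FlowerNetConfig, normalize_image, predict_count)
from .nn import Adam

Scene = tuple[ImageRecord, PointAnnotationSet]


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 4
    seed: int = 0
    alpha: float = 8.0
    sigma: float = 4.0
    dilation: int = 3
    patch_grid: tuple[int, int] = (3, 3)
    init_scale: float = 0.05
    shuffle: bool = True

    def __post_init__(self):
        for name in ("epochs", "learning_rate", "batch_size", "sigma",
                     "init_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MetricsReport:
    mae: float
    rmse: float
    per_image: list[tuple[float, float]] = field(default_factory=list)


def compute_mae_rmse(pairs: list[tuple[float, float]]) -> tuple[float, float]:
    """MAE and RMSE over (labeled, predicted) count pairs."""
    if not pairs:
        raise ValueError("need at least one (labeled, predicted) pair")
    diff = np.array([z - zh for z, zh in pairs], dtype=np.float64)
    return float(np.abs(diff).mean()), float(np.sqrt(np.square(diff).mean()))


def init_weights_uniform(model: FlowerNet, scale: float = 0.05,
                         seed: int = 0) -> FlowerNet:
    """Uniform weight init on [−scale, scale]; biases zero; seeded."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    for name, p in model.parameters():
        if name.endswith(".bias"):
            p.value[...] = 0.0
        else:
            p.value[...] = rng.uniform(-scale, scale,
                                       size=p.value.shape).astype(np.float32)
    return model


def _resolve_scenes(data, root: str | Path = ".") -> list[Scene]:
    if isinstance(data, DatasetManifest):
        return [(img, ann) for img, ann, _ in
                (load_entry(e, root) for e in data.subset("train"))]
    return list(data)


def _build_samples(scenes: list[Scene], cfg: TrainConfig, stride: int):
    """Patch every scene and build stride-resolution targets."""
    samples = []
    for img, ann in scenes:
        for p_img, p_ann in split_into_patches(img, ann, cfg.patch_grid):
            density, mask = make_targets(p_ann, p_img.shape, sigma=cfg.sigma,
                                         dilation=cfg.dilation, stride=stride)
            samples.append((normalize_image(p_img)[0],
                            density.values.astype(np.float32)[None],
                            mask.values.astype(np.float32)[None]))
    return samples


def train_model(data, train_cfg: TrainConfig | None = None,
                net_cfg: FlowerNetConfig | None = None,
                loss_cfg: L.LossConfig | None = None,
                root: str | Path = ".", model: FlowerNet | None = None,
                ) -> tuple[FlowerNet, list[dict]]:
    """Train FlowerNet on 3×3 patches of the training scenes.

    ``data`` is a DatasetManifest (its train split is loaded from disk)
    or an in-memory list of (ImageRecord, PointAnnotationSet) scenes.
    Returns the trained model and a per-epoch log of loss terms.
    """
    cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or L.LossConfig(alpha=cfg.alpha)
    scenes = _resolve_scenes(data, root)
    if not scenes:
        raise ValueError("empty training set")

    if model is None:
        model = FlowerNet(net_cfg or FlowerNetConfig())
        init_weights_uniform(model, cfg.init_scale, cfg.seed)
    stride = model.config.output_stride
    samples = _build_samples(scenes, cfg, stride)

    # group sample indices by patch shape so batches stack cleanly
    by_shape: dict[tuple, list[int]] = {}
    for i, (x, _, _) in enumerate(samples):
        by_shape.setdefault(x.shape, []).append(i)

    params = [p for _, p in model.parameters()]
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    log: list[dict] = []
    has_mask = model.mask_branch is not None

    for epoch in range(cfg.epochs):
        batches = []
        for idxs in by_shape.values():
            order = rng.permutation(idxs) if cfg.shuffle else np.array(idxs)
            batches += [order[i:i + cfg.batch_size]
                        for i in range(0, len(order), cfg.batch_size)]
        sums = np.zeros(3)
        for batch in batches:
            x = np.stack([samples[i][0] for i in batch])
            gt_d = np.stack([samples[i][1] for i in batch])
            gt_m = np.stack([samples[i][2] for i in batch])
            mask_prob, density = model.forward(x)
            lm = (L.mask_loss(mask_prob, gt_m, loss_cfg.mask_loss_form)
                  if has_mask else 0.0)
            lr_ = L.regression_loss(density, gt_d)
            opt.zero_grad()
            dmask = (L.mask_loss_grad(mask_prob, gt_m, loss_cfg.mask_loss_form)
                     if has_mask else None)
            ddens = loss_cfg.alpha * L.regression_loss_grad(density, gt_d)
            model.backward(dmask, ddens)
            opt.step()
            sums += (lm, lr_, L.combined_loss(lm, lr_, loss_cfg.alpha))
        n = len(batches)
        log.append({"epoch": epoch + 1, "L_mask": sums[0] / n,
                    "L_regression": sums[1] / n, "L": sums[2] / n})
    return model, log


def evaluate_model(model: FlowerNet, data, root: str | Path = ".",
                   ) -> MetricsReport:
    """Full-image evaluation: MAE/RMSE over (labeled, predicted) counts."""
    if isinstance(data, DatasetManifest):
        scenes = [(img, ann) for img, ann, _ in
                  (load_entry(e, root) for e in data.subset("test"))]
    else:
        scenes = list(data)
    if not scenes:
        raise ValueError("empty test set")
    pairs = []
    for img, ann in scenes:
        _, _, count = predict_count(model, img)
        pairs.append((float(len(ann)), count))
    mae, rmse = compute_mae_rmse(pairs)
    return MetricsReport(mae, rmse, pairs)
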