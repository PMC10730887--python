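"""Multi-task loss, augmentation, dataset splitting and the fit loop.

The loss combines the four head outputs against their encoded labels:

    L = (1/(m n)) * [ alpha*SSE_heat + beta*SSE_jgs + SSE_depth ]
      + (gamma/(l k)) * SSE_offset(masked)

with m, n the heatmap grid height/width, l, k the input height/width, and
the offset squared errors accumulated only on positive-sample cells.
Defaults alpha=16, beta=4, gamma=2 reflect the primacy of the heatmap task;
depth is weighted 1. The depth SSE runs over the full-resolution grid but
is normalized by the heatmap cell count m*n — a deliberate constant rescale
kept for fidelity to the loss as published.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .codec import DEFAULT_CODEC, CodecConfig, LabelBundle, decode_keypoints
from .network import NetworkOutputs, PoseNet
from .nn import Adam, Tensor
from .skeleton import DEFAULT_SKELETON, KeypointSet


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 16.0  # heatmap
    beta: float = 4.0    # JGS
    gamma: float = 2.0   # offset
    # depth weight is fixed at 1

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    weight_decay: float = 1e-6
    lr_pretrain: float = 5e-4   # halved once after 50 epochs
    lr_finetune: float = 1e-4   # halved every 50 epochs
    phase: str = "pretrain"     # "pretrain" | "finetune"
    freeze_backbone_fraction: float = 0.75  # finetune: stem + first 2 stages
    seed: int = 0

    def __post_init__(self):
        if self.lr_pretrain <= 0 or self.lr_finetune <= 0:
            raise ValueError("learning rates must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.phase not in ("pretrain", "finetune"):
            raise ValueError("phase must be 'pretrain' or 'finetune'")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index under the phase schedule."""
        if self.phase == "pretrain":
            return self.lr_pretrain * (0.5 if epoch >= 50 else 1.0)
        return self.lr_finetune * 0.5 ** (epoch // 50)


@dataclass(frozen=True)
class AugmentConfig:
    occlusion_prob: float = 0.5
    occlusion_frac: tuple = (0.10, 0.25)  # rectangle side / image side
    rotation_deg: float = 10.0            # uniform in [-r, +r]
    mirror_prob: float = 0.5

    def __post_init__(self):
        if not (0 <= self.occlusion_prob <= 1 and 0 <= self.mirror_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.rotation_deg <= 10:
            raise ValueError("rotation range must lie within [0, 10] degrees")


def multitask_loss(pred: NetworkOutputs, labels, w: LossWeights = LossWeights()
                   ) -> Tensor:
    """Weighted multi-task MSE (see module docstring). Returns a scalar
    Tensor; call ``.item()`` for the value, ``.backward()`` for gradients.

    ``labels`` is a :class:`LabelBundle` or a sequence of them (a batch).
    """
    if isinstance(labels, LabelBundle):
        labels = [labels]
    heat = np.stack([lb.heatmap for lb in labels])
    jgs = np.stack([lb.jgs for lb in labels])
    depth = np.stack([lb.depth for lb in labels])[:, None]
    off = np.stack([lb.offsets for lb in labels])
    mask = np.stack([lb.offset_mask for lb in labels])
    mask2 = np.repeat(mask, 2, axis=1).astype(np.float32)

    for p, t, name in ((pred.heatmap, heat, "heatmap"), (pred.jgs, jgs, "jgs"),
                       (pred.depth, depth, "depth"), (pred.offsets, off, "offsets")):
        if tuple(p.shape) != t.shape:
            raise ValueError(f"{name}: prediction shape {tuple(p.shape)} != "
                             f"label shape {t.shape}")
    n = heat.shape[0]
    m_, n_ = heat.shape[2], heat.shape[3]
    l_, k_ = depth.shape[2], depth.shape[3]

    sse_h = (pred.heatmap - Tensor(heat)).square().sum()
    sse_g = (pred.jgs - Tensor(jgs)).square().sum()
    sse_d = (pred.depth - Tensor(depth)).square().sum()
    sse_o = ((pred.offsets - Tensor(off)) * Tensor(mask2)).square().sum()
    dense = (w.alpha * sse_h + w.beta * sse_g + sse_d) * (1.0 / (m_ * n_ * n))
    return dense + sse_o * (w.gamma / (l_ * k_ * n))


def grayscale_depth_proxy(image: np.ndarray) -> np.ndarray:
    """Luminance of an RGB image rescaled to [0, 1].

    Used as the depth target when pretraining on RGB-only data. Accepts
    (H, W, 3) uint8 or float (float assumed already in [0, 1]).
    """
    img = np.asarray(image)
    if img.dtype.kind in "ui":
        img = img.astype(np.float32) / 255.0
    return (0.299 * img[..., 0] + 0.587 * img[..., 1]
            + 0.114 * img[..., 2]).astype(np.float32)


def split_dataset(n_items: int, ratio_train: int = 4, ratio_val: int = 1,
                  seed: int = 0):
    """Seeded random partition into (train_idx, val_idx).

    Validation gets the ceiling share ``ceil(n * rv / (rt + rv))`` —
    e.g. 3588 items at 4:1 give (2870, 718).
    """
    if ratio_train <= 0 or ratio_val <= 0:
        raise ValueError("ratios must be positive")
    if n_items < ratio_train + ratio_val:
        raise ValueError("too few items for the requested split")
    n_val = math.ceil(n_items * ratio_val / (ratio_train + ratio_val))
    perm = np.random.default_rng(seed).permutation(n_items)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _rotate_plane(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate an (H, W[, C]) image about its centre; bilinear, zero fill.

    Convention (shared with keypoint rotation below): a feature at p moves
    to c + R(p - c) with R the standard rotation of the (x, y) plane —
    y down, so positive angles appear clockwise on screen.
    """
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.radians(angle_deg)
    cos, sin = np.cos(th), np.sin(th)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # inverse map: output pixel q samples input at c + R(-th)(q - c)
    dx, dy = xx - cx, yy - cy
    sx = cx + cos * dx + sin * dy
    sy = cy - sin * dx + cos * dy
    coords = np.stack([sy, sx])
    if img.ndim == 2:
        return ndimage.map_coordinates(img, coords, order=1, mode="constant")
    return np.stack([ndimage.map_coordinates(img[..., c], coords, order=1,
                                             mode="constant")
                     for c in range(img.shape[2])], axis=-1)


def _rotate_points(coords: np.ndarray, angle_deg: float, h: int, w: int):
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = np.radians(angle_deg)
    cos, sin = np.cos(th), np.sin(th)
    d = coords - [cx, cy]
    return np.stack([cx + cos * d[:, 0] - sin * d[:, 1],
                     cy + sin * d[:, 0] + cos * d[:, 1]], axis=1)


def augment_sample(image: np.ndarray, depth: np.ndarray,
                   keypoints: KeypointSet, cfg: AugmentConfig = AugmentConfig(),
                   rng_seed: int = 0, skeleton=DEFAULT_SKELETON):
    """Random occlusion + rotation + mirroring, label-consistent and
    deterministic given ``rng_seed``.

    image is (H, W, 3) float, depth (H, W). Occlusion paints a mean-colour
    rectangle and leaves labels untouched; rotation transforms image,
    depth and keypoints coherently about the image centre (points leaving
    the frame are flagged invisible); mirroring flips horizontally and
    permutes left/right joints.
    """
    rng = np.random.default_rng(rng_seed)
    image = np.array(image, dtype=np.float32, copy=True)
    depth = np.array(depth, dtype=np.float32, copy=True)
    h, w = image.shape[:2]
    coords = keypoints.coords.copy()
    visible = keypoints.visible.copy()

    if rng.random() < cfg.occlusion_prob:
        frac = rng.uniform(*cfg.occlusion_frac)
        ow, oh = int(frac * w), int(frac * h)
        x0 = rng.integers(0, max(1, w - ow))
        y0 = rng.integers(0, max(1, h - oh))
        image[y0:y0 + oh, x0:x0 + ow] = image.mean(axis=(0, 1))

    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    if angle != 0.0:
        image = _rotate_plane(image, angle)
        depth = _rotate_plane(depth, angle)
        coords = _rotate_points(coords, angle, h, w)
        inb = ((coords[:, 0] >= 0) & (coords[:, 0] < w)
               & (coords[:, 1] >= 0) & (coords[:, 1] < h))
        visible &= inb

    if rng.random() < cfg.mirror_prob:
        image = image[:, ::-1].copy()
        depth = depth[:, ::-1].copy()
        kp = KeypointSet(coords, visible).mirrored(w, skeleton)
        coords, visible = kp.coords, kp.visible

    return image, depth, KeypointSet(coords, visible)


def freeze_backbone(model: PoseNet, fraction: float) -> int:
    """Freeze the first ``fraction`` of backbone stages; returns how many."""
    stages = model.backbone_stages()
    n_freeze = int(fraction * len(stages))
    for st in stages[:n_freeze]:
        for p in st.parameters():
            p.requires_grad = False
    return n_freeze


def fit(model: PoseNet, dataset, train_cfg: TrainConfig = TrainConfig(),
        loss_weights: LossWeights = LossWeights(), callback=None) -> dict:
    """Train the model on (image, LabelBundle) pairs.

    ``dataset`` is a sequence of tuples (image (3,H,W) float32 in [0,1],
    :class:`LabelBundle`). Runs Adam with the phase's halving schedule,
    optionally freezing backbone stages in the finetune phase. Records
    per-epoch mean loss; stops early if ``callback(epoch, model, history)``
    returns True. Deterministic given the config seed.
    """
    data = list(dataset)
    if not data:
        raise ValueError("empty dataset")
    if train_cfg.phase == "finetune":
        freeze_backbone(model, train_cfg.freeze_backbone_fraction)
    opt = Adam(model.parameters(), lr=train_cfg.lr_at(0),
               weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    history = {"loss": [], "lr": []}
    for epoch in range(train_cfg.epochs):
        opt.lr = train_cfg.lr_at(epoch)
        order = rng.permutation(len(data))
        losses = []
        for start in range(0, len(data), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            images = np.stack([data[i][0] for i in idx])
            bundles = [data[i][1] for i in idx]
            opt.zero_grad()
            pred = model(images)
            loss = multitask_loss(pred, bundles, loss_weights)
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(opt.lr)
        if callback is not None and callback(epoch, model, history):
            break
    return history


def predict_keypoints(model: PoseNet, images,
                      cfg: CodecConfig = DEFAULT_CODEC):
    """Forward images (N,3,H,W) and decode per-frame keypoints."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    out = model(images)
    return [decode_keypoints(out.heatmap.data[i], out.offsets.data[i], cfg)
            for i in range(images.shape[0])]
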