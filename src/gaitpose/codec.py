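"""Label codec: keypoints <-> training-target grids.

Four target grids are produced per frame, all but depth at 1/stride of the
input resolution (stride 4 by default):

* **heatmap** — one channel per joint; a Gaussian bump
  ``exp(-d^2 / (2 sigma^2))`` centred on the joint's anchor cell.
* **offsets** — two channels per joint (even = x, odd = y) storing the
  normalized sub-stride residual ``(x - stride*x_h) / stride`` on every
  positive cell, where ``x_h = floor(x / stride)`` is the anchor.
* **offset_mask** — the positive-sample support: cells within squared grid
  distance ``d_th`` of the anchor.
* **jgs** — one binary channel per limb segment marking cells lying on the
  segment within half-width ``delta``.

The Gaussian exponent uses the squared-distance / (2 sigma^2) convention.
With sigma = 6 every cell at squared distance <= 36 has value
>= exp(-1/2) = 0.6065 > 0.6, so the 0.6 heat threshold and the d_th = 36
disc define the same positive set on the integer lattice
(-2 sigma^2 ln 0.6 = 36.77).

Decoding reads the argmax cell of each heatmap channel (ties: first in
row-major order) and adds the offset stored there; because the Gaussian is
centred on the *anchor* cell this round-trips exactly for quarter-pixel
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .skeleton import DEFAULT_SKELETON, KeypointSet, SkeletonDefinition


@dataclass(frozen=True)
class CodecConfig:
    sigma: float = 6.0          # Gaussian width, grid pixels
    d_th: float = 36.0          # positive-sample radius, squared grid pixels
    heat_threshold: float = 0.6  # decode visibility / positive-sample cut
    stride: int = 4             # input -> grid downscale factor
    delta: float = 8.0          # limb-mask half-width, input pixels

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.d_th < 0:
            raise ValueError("d_th must be >= 0")
        if not 0 < self.heat_threshold < 1:
            raise ValueError("heat_threshold must lie in (0, 1)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


DEFAULT_CODEC = CodecConfig()


@dataclass
class LabelBundle:
    """All training targets for one frame."""

    heatmap: np.ndarray      # (J, Hg, Wg) in [0, 1]
    offsets: np.ndarray      # (2J, Hg, Wg); channel 2k = x, 2k+1 = y
    offset_mask: np.ndarray  # (J, Hg, Wg) bool
    jgs: np.ndarray          # (E, Hg, Wg) in {0, 1}
    depth: np.ndarray        # (H, W) in [0, 1]

    def save(self, path) -> None:
        np.savez_compressed(
            path, heatmap=self.heatmap, offsets=self.offsets,
            offset_mask=self.offset_mask, jgs=self.jgs, depth=self.depth)

    @classmethod
    def load(cls, path) -> "LabelBundle":
        with np.load(path) as z:
            return cls(**{k: z[k] for k in
                          ("heatmap", "offsets", "offset_mask", "jgs", "depth")})


def _check_grid(grid_h: int, grid_w: int) -> None:
    if grid_h < 1 or grid_w < 1:
        raise ValueError(f"grid dims must be >= 1, got {grid_h}x{grid_w}")


def _anchors(keypoints: KeypointSet, cfg: CodecConfig) -> np.ndarray:
    """Integer grid anchor cell floor(p / stride) per joint, shape (J, 2)."""
    return np.floor(keypoints.coords / cfg.stride).astype(int)


def encode_heatmap(keypoints: KeypointSet, grid_h: int, grid_w: int,
                   cfg: CodecConfig = DEFAULT_CODEC) -> np.ndarray:
    """Per-joint Gaussian heatmap on the (grid_h, grid_w) lattice."""
    _check_grid(grid_h, grid_w)
    anchors = _anchors(keypoints, cfg)
    gy, gx = np.mgrid[0:grid_h, 0:grid_w]
    out = np.zeros((len(anchors), grid_h, grid_w), dtype=np.float32)
    for k, ((ax, ay), vis) in enumerate(zip(anchors, keypoints.visible)):
        if not vis:
            continue
        d2 = (gx - ax) ** 2 + (gy - ay) ** 2
        out[k] = np.exp(-d2 / (2.0 * cfg.sigma ** 2))
    return out


def positive_sample_mask(keypoints: KeypointSet, grid_h: int, grid_w: int,
                         cfg: CodecConfig = DEFAULT_CODEC) -> np.ndarray:
    """Boolean (J, grid_h, grid_w) grid: squared distance to anchor <= d_th."""
    _check_grid(grid_h, grid_w)
    anchors = _anchors(keypoints, cfg)
    gy, gx = np.mgrid[0:grid_h, 0:grid_w]
    out = np.zeros((len(anchors), grid_h, grid_w), dtype=bool)
    for k, ((ax, ay), vis) in enumerate(zip(anchors, keypoints.visible)):
        if not vis:
            continue
        out[k] = (gx - ax) ** 2 + (gy - ay) ** 2 <= cfg.d_th
    return out


def encode_offsets(keypoints: KeypointSet, grid_h: int, grid_w: int,
                   cfg: CodecConfig = DEFAULT_CODEC):
    """Offset grids + positive mask.

    Returns ``(offsets, mask)`` where offsets has shape (2J, grid_h, grid_w);
    on masked cells channel 2k holds ``(x - stride*floor(x/stride))/stride``
    (a value in [0, 1)) and channel 2k+1 the y analogue; zero elsewhere.
    """
    _check_grid(grid_h, grid_w)
    mask = positive_sample_mask(keypoints, grid_h, grid_w, cfg)
    anchors = _anchors(keypoints, cfg)
    s = float(cfg.stride)
    off = np.zeros((2 * len(anchors), grid_h, grid_w), dtype=np.float32)
    rel = (keypoints.coords - anchors * s) / s  # (J, 2) in [0, 1)
    for k in range(len(anchors)):
        off[2 * k][mask[k]] = rel[k, 0]
        off[2 * k + 1][mask[k]] = rel[k, 1]
    return off, mask


def encode_jgs(keypoints: KeypointSet, skeleton: SkeletonDefinition = DEFAULT_SKELETON,
               grid_h: int = 128, grid_w: int = 128,
               cfg: CodecConfig = DEFAULT_CODEC) -> np.ndarray:
    """Binary limb-segment ("trunk") masks, one channel per skeleton edge.

    A grid cell c is marked for edge (i, j) iff the scalar projection of
    (c - p_j) onto the unit edge direction lies within [0, |p_i - p_j|] and
    its perpendicular distance to the edge line is <= delta / stride.
    Edges with an invisible endpoint yield an all-zero channel; coincident
    endpoints yield an all-zero channel and a warning.
    """
    _check_grid(grid_h, grid_w)
    pts = keypoints.coords / cfg.stride          # continuous grid coords
    half_w = cfg.delta / cfg.stride
    gy, gx = np.mgrid[0:grid_h, 0:grid_w]
    out = np.zeros((skeleton.n_edges, grid_h, grid_w), dtype=np.float32)
    for e, (i, j) in enumerate(skeleton.edge_indices()):
        if not (keypoints.visible[i] and keypoints.visible[j]):
            continue
        pi, pj = pts[i], pts[j]
        seg = pi - pj
        length = float(np.hypot(*seg))
        if length == 0.0:
            warnings.warn(
                f"degenerate edge {skeleton.edges[e]}: coincident endpoints",
                stacklevel=2)
            continue
        v = seg / length
        rx, ry = gx - pj[0], gy - pj[1]
        t = rx * v[0] + ry * v[1]                 # along-trunk coordinate
        perp = np.abs(rx * v[1] - ry * v[0])      # distance to edge line
        out[e] = ((t >= 0) & (t <= length) & (perp <= half_w)).astype(np.float32)
    return out


def decode_keypoints(heatmap: np.ndarray, offsets: np.ndarray,
                     cfg: CodecConfig = DEFAULT_CODEC) -> KeypointSet:
    """Recover pixel keypoints from heatmap + offset grids.

    Per joint: anchor = row-major-first argmax cell of its heatmap channel;
    pixel = stride * (anchor + offset at anchor). Joints whose peak value is
    below ``heat_threshold`` are flagged invisible (coordinates still
    reported).
    """
    heatmap = np.asarray(heatmap)
    offsets = np.asarray(offsets)
    if heatmap.ndim != 3 or offsets.ndim != 3 or heatmap.shape[1:] != offsets.shape[1:]:
        raise ValueError("heatmap and offsets must be (C,H,W) with equal H,W")
    n_j = heatmap.shape[0]
    if offsets.shape[0] != 2 * n_j:
        raise ValueError(
            f"offset channels ({offsets.shape[0]}) must be twice heatmap "
            f"channels ({n_j})")
    coords = np.zeros((n_j, 2), dtype=float)
    visible = np.zeros(n_j, dtype=bool)
    s = float(cfg.stride)
    for k in range(n_j):
        flat = int(np.argmax(heatmap[k]))
        ay, ax = divmod(flat, heatmap.shape[2])
        ox = float(offsets[2 * k, ay, ax])
        oy = float(offsets[2 * k + 1, ay, ax])
        coords[k] = (s * (ax + ox), s * (ay + oy))
        visible[k] = heatmap[k, ay, ax] >= cfg.heat_threshold
    return KeypointSet(coords, visible)


def encode_bundle(keypoints: KeypointSet, depth: np.ndarray,
                  skeleton: SkeletonDefinition = DEFAULT_SKELETON,
                  cfg: CodecConfig = DEFAULT_CODEC) -> LabelBundle:
    """Encode all four targets for one frame. depth is the (H, W) target."""
    depth = np.asarray(depth, dtype=np.float32)
    h, w = depth.shape
    gh, gw = h // cfg.stride, w // cfg.stride
    heat = encode_heatmap(keypoints, gh, gw, cfg)
    off, mask = encode_offsets(keypoints, gh, gw, cfg)
    jgs = encode_jgs(keypoints, skeleton, gh, gw, cfg)
    return LabelBundle(heat, off, mask, jgs, depth)
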