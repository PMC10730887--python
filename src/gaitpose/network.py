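"""The pose network: Focus stem, SE-ResNeXt backbone, FPN, four heads.

Input is an RGB image (N, 3, S, S). The backbone applies a lossless
space-to-depth "Focus" slice (1/2) followed by three strided stages
(1/4, 1/8, 1/16 — four downsamplings in total); an FPN fuses the three
stage outputs top-down with lateral 1x1 connections back to 1/4 resolution
(two upsamplings). Four heads emit:

* ``heatmap``  (J,  S/4, S/4), sigmoid-squashed,
* ``offsets``  (2J, S/4, S/4), linear,
* ``jgs``      (E,  S/4, S/4), linear — limb-guidance channels used only
  as training supervision,
* ``depth``    (1,  S,   S),   sigmoid-squashed relative depth, likewise
  supervision-only.

Channel widths scale with ``width_multiplier``; the Full (1.0) and Lite
(0.5) presets differ roughly 4x in parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Conv2d, Module, SEResNeXtBlock, Sequential, Tensor


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 512
    base_width: int = 48          # stem width at multiplier 1.0
    width_multiplier: float = 1.0
    n_joints: int = 8
    n_edges: int = 8
    cardinality: int = 8
    se_reduction: int = 8
    blocks_per_stage: tuple = (2, 3, 4)
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")

    def _ch(self, mult: float) -> int:
        c = int(round(self.base_width * mult * self.width_multiplier))
        return max(self.cardinality, c - c % self.cardinality)

    @property
    def stage_widths(self) -> tuple:
        return (self._ch(1), self._ch(2), self._ch(4), self._ch(8))

    @property
    def fpn_width(self) -> int:
        return self._ch(2)


FULL = ModelConfig(width_multiplier=1.0)
LITE = ModelConfig(width_multiplier=0.5)


@dataclass
class NetworkOutputs:
    depth: Tensor    # (N, 1, S, S)
    heatmap: Tensor  # (N, J, S/4, S/4)
    offsets: Tensor  # (N, 2J, S/4, S/4)
    jgs: Tensor      # (N, E, S/4, S/4)

    def numpy(self) -> "NetworkOutputs":
        return NetworkOutputs(*[Tensor(t.data.copy()) for t in
                                (self.depth, self.heatmap, self.offsets,
                                 self.jgs)])


def focus_rearrange(image: np.ndarray) -> np.ndarray:
    """Lossless space-to-depth slice: (C, H, W) -> (4C, H/2, W/2).

    Stacks the four pixel-parity sub-grids (even/even, even/odd, odd/even,
    odd/odd rows/cols) along the channel axis. The inverse rearrangement
    (:func:`focus_inverse`) reconstructs the input exactly.
    """
    image = np.asarray(image)
    c, h, w = image.shape
    if h % 2 or w % 2:
        raise ValueError("focus_rearrange needs even H and W")
    return np.concatenate([image[:, 0::2, 0::2], image[:, 0::2, 1::2],
                           image[:, 1::2, 0::2], image[:, 1::2, 1::2]], axis=0)


def focus_inverse(stacked: np.ndarray) -> np.ndarray:
    """Inverse of :func:`focus_rearrange`."""
    c4, h2, w2 = stacked.shape
    if c4 % 4:
        raise ValueError("channel count must be a multiple of 4")
    c = c4 // 4
    out = np.empty((c, 2 * h2, 2 * w2), dtype=stacked.dtype)
    out[:, 0::2, 0::2] = stacked[0 * c:1 * c]
    out[:, 0::2, 1::2] = stacked[1 * c:2 * c]
    out[:, 1::2, 0::2] = stacked[2 * c:3 * c]
    out[:, 1::2, 1::2] = stacked[3 * c:4 * c]
    return out


class _Head(Module):
    def __init__(self, cin, hidden, cout, squash, rng):
        self.conv = Conv2d(cin, hidden, k=3, rng=rng)
        self.out = Conv2d(hidden, cout, k=1, rng=rng)
        self.squash = squash

    def forward(self, x):
        y = self.out(self.conv(x).relu())
        return y.sigmoid() if self.squash else y


class _DepthHead(Module):
    """1/4-resolution features -> full-resolution relative-depth map."""

    def __init__(self, cin, rng):
        c1, c2 = max(8, cin // 2), max(8, cin // 4)
        self.conv1 = Conv2d(cin, c1, k=3, rng=rng)
        self.conv2 = Conv2d(c1, c2, k=3, rng=rng)
        self.out = Conv2d(c2, 1, k=1, rng=rng)

    def forward(self, x):
        y = self.conv1(x).relu().upsample2()
        y = self.conv2(y).relu().upsample2()
        return self.out(y).sigmoid()


class PoseNet(Module):
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c0, c1, c2, c3 = cfg.stage_widths
        f = cfg.fpn_width

        def stage(cin, cout, n_blocks):
            mods = [Conv2d(cin, cout, k=3, stride=2, rng=rng)]
            mods.extend(SEResNeXtBlock(cout, cfg.cardinality,
                                       cfg.se_reduction, rng)
                        for _ in range(n_blocks))
            return Sequential(*mods)

        self.stem = Conv2d(12, c0, k=3, rng=rng)        # after Focus slice
        self.stage1 = stage(c0, c1, cfg.blocks_per_stage[0])  # 1/4
        self.stage2 = stage(c1, c2, cfg.blocks_per_stage[1])  # 1/8
        self.stage3 = stage(c2, c3, cfg.blocks_per_stage[2])  # 1/16
        self.lat1 = Conv2d(c1, f, k=1, rng=rng)
        self.lat2 = Conv2d(c2, f, k=1, rng=rng)
        self.lat3 = Conv2d(c3, f, k=1, rng=rng)
        self.smooth = Conv2d(f, f, k=3, rng=rng)
        h = max(8, f // 2)
        self.head_heat = _Head(f, h, cfg.n_joints, squash=True, rng=rng)
        self.head_off = _Head(f, h, 2 * cfg.n_joints, squash=False, rng=rng)
        self.head_jgs = _Head(f, h, cfg.n_edges, squash=False, rng=rng)
        self.head_depth = _DepthHead(f, rng=rng)

    def forward(self, x) -> NetworkOutputs:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("input H and W must be divisible by 16")
        y = x.space_to_depth()                 # 1/2
        y = self.stem(y).relu()
        s1 = self.stage1(y)                    # 1/4
        s2 = self.stage2(s1)                   # 1/8
        s3 = self.stage3(s2)                   # 1/16
        p3 = self.lat3(s3)
        p2 = self.lat2(s2) + p3.upsample2()    # 1/8  (first upsampling)
        p1 = self.lat1(s1) + p2.upsample2()    # 1/4  (second upsampling)
        fused = self.smooth(p1).relu()
        return NetworkOutputs(
            depth=self.head_depth(fused),
            heatmap=self.head_heat(fused),
            offsets=self.head_off(fused),
            jgs=self.head_jgs(fused),
        )

    def backbone_stages(self):
        """Stem-to-deep ordering used for partial freezing."""
        return [self.stem, self.stage1, self.stage2, self.stage3]


def build_model(cfg: ModelConfig) -> PoseNet:
    """Construct the network; all parameters are finite by construction."""
    model = PoseNet(cfg)
    for p in model.parameters():
        if not np.all(np.isfinite(p.data)):
            raise RuntimeError("non-finite parameter after initialization")
    return model


def count_parameters(model: Module) -> int:
    """Total trainable scalar parameter count."""
    return int(sum(p.data.size for p in model.parameters()))
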