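"""Dataset manifests, image loading, and geometry-preserving resizing."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .codec import DEFAULT_CODEC, CodecConfig, encode_bundle
from .skeleton import DEFAULT_SKELETON, KeypointSet
from .training import grayscale_depth_proxy


class DatasetError(ValueError):
    pass


@dataclass
class DatasetManifest:
    root: str
    image_size: int
    entries: list              # dicts: rgb, depth (opt), keypoints, visible
    skeleton_tag: str = "sagittal-8"
    fps: float = None

    def __len__(self):
        return len(self.entries)

    def keypoints(self, i: int) -> KeypointSet:
        e = self.entries[i]
        return KeypointSet.from_flat(e["keypoints"], e.get("visible"))

    def load_rgb(self, i: int) -> np.ndarray:
        """(H, W, 3) float32 in [0, 1]."""
        path = os.path.join(self.root, self.entries[i]["rgb"])
        return np.asarray(Image.open(path).convert("RGB"),
                          dtype=np.float32) / 255.0

    def load_depth(self, i: int) -> np.ndarray:
        """(H, W) float32 in [0, 1], or None if the entry has no depth."""
        name = self.entries[i].get("depth")
        if not name:
            return None
        arr = np.asarray(Image.open(os.path.join(self.root, name)),
                         dtype=np.float32)
        peak = 65535.0 if arr.max() > 255 else max(arr.max(), 1.0)
        return arr / peak

    def save(self, out_dir=None) -> str:
        """Write annotations.json (images are referenced, not copied)."""
        out_dir = out_dir or self.root
        os.makedirs(out_dir, exist_ok=True)
        payload = {"image_size": self.image_size, "skeleton": self.skeleton_tag,
                   "fps": self.fps, "entries": self.entries}
        path = os.path.join(out_dir, "annotations.json")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return path


def load_dataset(root) -> DatasetManifest:
    """Load and validate ``annotations.json`` in ``root``.

    Every referenced file must exist and every keypoint tuple must have
    exactly 16 values; violations raise :class:`DatasetError` naming the
    offending entry.
    """
    path = os.path.join(root, "annotations.json")
    if not os.path.exists(path):
        raise DatasetError(f"no annotations.json under {root}")
    with open(path) as fh:
        raw = json.load(fh)
    entries = raw.get("entries", [])
    for n, e in enumerate(entries):
        kp = e.get("keypoints", [])
        if len(kp) != 16:
            raise DatasetError(
                f"entry {n} ({e.get('rgb', '?')}): keypoints has "
                f"{len(kp)} values, expected 16")
        for key in ("rgb", "depth"):
            name = e.get(key)
            if name and not os.path.exists(os.path.join(root, name)):
                raise DatasetError(f"entry {n}: missing file {name}")
    return DatasetManifest(root=str(root), image_size=raw.get("image_size"),
                           entries=entries,
                           skeleton_tag=raw.get("skeleton", "sagittal-8"),
                           fps=raw.get("fps"))


def pad_and_scale(image: np.ndarray, target: int, keypoints: KeypointSet = None,
                  depth: np.ndarray = None, pad_value=None):
    """Pad to square (symmetric borders, mean-colour fill) then scale to
    ``target`` x ``target``; keypoints are transformed consistently.

    Returns (image, keypoints, depth, transform) where transform is
    (pad_x, pad_y, scale): new = (old + pad) * scale.
    """
    h, w = image.shape[:2]
    side = max(h, w)
    pad_x, pad_y = (side - w) // 2, (side - h) // 2
    if pad_value is None:
        pad_value = image.mean(axis=(0, 1))
    sq = np.empty((side, side) + image.shape[2:], dtype=image.dtype)
    sq[...] = pad_value
    sq[pad_y:pad_y + h, pad_x:pad_x + w] = image
    scale = target / side

    def _resize(arr, mode):
        img = Image.fromarray(arr) if arr.dtype != np.float32 else \
            Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8))
        out = np.asarray(img.resize((target, target), Image.BILINEAR),
                         dtype=np.float32)
        return out / 255.0 if arr.dtype == np.float32 else out

    image_out = _resize(sq, None)
    depth_out = None
    if depth is not None:
        dsq = np.zeros((side, side), dtype=np.float32)
        dsq[pad_y:pad_y + h, pad_x:pad_x + w] = depth
        depth_out = _resize(dsq, None)
    kp_out = None
    if keypoints is not None:
        coords = (keypoints.coords + [pad_x, pad_y]) * scale
        kp_out = KeypointSet(coords, keypoints.visible.copy())
    return image_out, kp_out, depth_out, (pad_x, pad_y, scale)


def to_training_set(manifest: DatasetManifest, input_size: int,
                    cfg: CodecConfig = DEFAULT_CODEC,
                    skeleton=DEFAULT_SKELETON, indices=None):
    """Materialize (image (3,S,S), LabelBundle) training pairs.

    Frames without a depth image fall back to the grayscale luminance
    proxy as the depth target.
    """
    pairs = []
    for i in indices if indices is not None else range(len(manifest)):
        rgb = manifest.load_rgb(i)
        depth = manifest.load_depth(i)
        kp = manifest.keypoints(i)
        rgb, kp, depth, _ = pad_and_scale(rgb, input_size, kp, depth)
        if depth is None:
            depth = grayscale_depth_proxy(rgb)
        bundle = encode_bundle(kp, depth, skeleton, cfg)
        pairs.append((rgb.transpose(2, 0, 1).astype(np.float32), bundle))
    return pairs
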