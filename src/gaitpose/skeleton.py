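"""Sagittal-view skeleton model: 8 joints, 8 limb segments, left/right mirror pairs.

Coordinates throughout the package are 0-based image coordinates: x grows
rightward, y grows downward. A frame's annotation is stored as a flat
16-tuple ``(x1, y1, ..., x8, y8)`` with joints in :data:`JOINT_NAMES` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Joint identifiers in canonical order: shoulders, hips, knees, ankles,
#: left before right.
JOINT_NAMES = ("LS", "RS", "LH", "RH", "LK", "RK", "LA", "RA")

#: Limb segments ("trunks") connecting the joints. Order matters: each edge
#: owns one guidance-mask channel.
EDGES = (
    ("LS", "RS"),
    ("LH", "RH"),
    ("LS", "LH"),
    ("RS", "RH"),
    ("LH", "LK"),
    ("RH", "RK"),
    ("LK", "LA"),
    ("RK", "RA"),
)

MIRROR_PAIRS = (("LS", "RS"), ("LH", "RH"), ("LK", "RK"), ("LA", "RA"))


@dataclass(frozen=True)
class SkeletonDefinition:
    """The joint/edge graph of the detected figure.

    Invariants (checked on construction): exactly 8 joints and 8 edges,
    every edge endpoint is a declared joint, and the mirror map is an
    involution covering all joints.
    """

    joint_names: tuple = JOINT_NAMES
    edges: tuple = EDGES
    mirror_pairs: tuple = MIRROR_PAIRS

    def __post_init__(self):
        if len(self.joint_names) != 8:
            raise ValueError("skeleton must declare exactly 8 joints")
        if len(self.edges) != 8:
            raise ValueError("skeleton must declare exactly 8 edges")
        names = set(self.joint_names)
        for a, b in self.edges:
            if a not in names or b not in names:
                raise ValueError(f"edge ({a},{b}) references undeclared joint")
        mm = self.mirror_map
        if set(mm) != names or any(mm[mm[j]] != j for j in names):
            raise ValueError("mirror_map must be an involution over all joints")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mirror_map(self) -> dict:
        m = {}
        for a, b in self.mirror_pairs:
            m[a] = b
            m[b] = a
        return m

    def index(self, name: str) -> int:
        return self.joint_names.index(name)

    def edge_indices(self) -> list:
        """Edges as (i, j) integer joint indices."""
        return [(self.index(a), self.index(b)) for a, b in self.edges]

    def mirror_permutation(self) -> np.ndarray:
        """Joint-index permutation swapping left and right."""
        mm = self.mirror_map
        return np.array([self.index(mm[n]) for n in self.joint_names])


DEFAULT_SKELETON = SkeletonDefinition()


@dataclass
class KeypointSet:
    """One frame's 8 joint pixel coordinates plus visibility flags."""

    coords: np.ndarray  # (8, 2) float, columns (x, y), input-image pixels
    visible: np.ndarray = None  # (8,) bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(8, 2)
        if self.visible is None:
            self.visible = np.ones(8, dtype=bool)
        self.visible = np.asarray(self.visible, dtype=bool).reshape(8)

    @classmethod
    def from_flat(cls, flat, visible=None) -> "KeypointSet":
        """Build from the 16-tuple annotation layout (x then y per joint)."""
        flat = np.asarray(flat, dtype=float).reshape(-1)
        if flat.size != 16:
            raise ValueError(f"expected a 16-tuple, got {flat.size} values")
        return cls(flat.reshape(8, 2), visible)

    def to_flat(self) -> list:
        return [float(v) for v in self.coords.reshape(-1)]

    def in_bounds(self, width: int, height: int) -> np.ndarray:
        x, y = self.coords[:, 0], self.coords[:, 1]
        return (x >= 0) & (x < width) & (y >= 0) & (y < height)

    def mirrored(self, width: int, skeleton: SkeletonDefinition = DEFAULT_SKELETON) -> "KeypointSet":
        """Horizontal flip: x -> width-1-x and left/right joints swapped."""
        perm = skeleton.mirror_permutation()
        coords = self.coords[perm].copy()
        coords[:, 0] = (width - 1) - coords[:, 0]
        return KeypointSet(coords, self.visible[perm].copy())
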