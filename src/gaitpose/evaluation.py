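"""Keypoint accuracy (PCKs) and joint-angle curve similarity.

PCKs normalizes each prediction error by the *smaller side of the ground
truth keypoints' bounding box* (rather than head size), which suits a
walking figure whose head is not annotated: a joint counts as correct when
||pred - truth|| / min(x-range, y-range) <= epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .skeleton import KeypointSet


@dataclass(frozen=True)
class PCKConfig:
    epsilons: tuple = (0.1, 0.08)

    def __post_init__(self):
        if any(e <= 0 for e in self.epsilons):
            raise ValueError("epsilon thresholds must be > 0")


def _normalizer(truth: KeypointSet) -> float:
    c = truth.coords[truth.visible]
    if c.shape[0] < 2:
        return 0.0
    return float(min(np.ptp(c[:, 0]), np.ptp(c[:, 1])))


def pcks(pred, truth, eps: float = 0.1, per_joint: bool = False):
    """Percentage of correct keypoints at threshold eps.

    pred/truth are equal-length sequences of :class:`KeypointSet`. Joints
    invisible in the truth are excluded; samples with a degenerate (zero)
    bounding box are skipped with a warning. Returns the mean over joints
    then samples, in [0, 1]; with per_joint=True additionally returns the
    per-joint correct fraction over all counted samples.
    """
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have equal length")
    sample_scores = []
    joint_hits = np.zeros(8)
    joint_counts = np.zeros(8)
    for n, (p, t) in enumerate(zip(pred, truth)):
        dn = _normalizer(t)
        if dn == 0.0:
            warnings.warn(f"sample {n}: degenerate keypoint bbox, skipped",
                          stacklevel=2)
            continue
        vis = t.visible
        if not vis.any():
            warnings.warn(f"sample {n}: no visible joints, skipped",
                          stacklevel=2)
            continue
        d = np.linalg.norm(p.coords - t.coords, axis=1) / dn
        ok = (d <= eps) & vis
        sample_scores.append(ok[vis].mean())
        joint_hits += ok & vis
        joint_counts += vis
    if not sample_scores:
        raise ValueError("no scorable samples")
    total = float(np.mean(sample_scores))
    if per_joint:
        with np.errstate(invalid="ignore"):
            pj = np.where(joint_counts > 0, joint_hits / np.maximum(joint_counts, 1), np.nan)
        return total, pj
    return total


def curve_similarity(y_g, y_t) -> float:
    """sqrt(sum of squared pointwise differences) / F for equal-length series.

    0 for identical curves; smaller is more similar. Note this is
    sqrt(SSE)/F, not an RMSE.
    """
    y_g = np.asarray(y_g, dtype=float)
    y_t = np.asarray(y_t, dtype=float)
    if y_g.shape != y_t.shape or y_g.ndim != 1 or y_g.size < 1:
        raise ValueError("series must be equal-length 1-D with F >= 1")
    f = y_g.size
    return float(np.sqrt(np.sum((y_g - y_t) ** 2)) / f)
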