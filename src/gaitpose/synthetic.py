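"""Synthetic sagittal-view walker: closed-form gait kinematics plus a
stick-figure renderer with aligned relative-depth maps.

The generator emulates a treadmill-style recording: the pelvis stays fixed
in front of the camera while thigh and calf angles follow smooth periodic
pulses whose amplitudes stay inside normal-walking ranges of motion
(hip flexion/extension -10..40 deg, knee flexion 0..67 deg). Every
downstream quantity (joint pixel positions, angles, events, stride length,
phase symmetry) has a closed-form ground truth, so the whole pipeline is
testable without real recordings.

Kinematic conventions match the analysis module: camera axis perpendicular
to the sagittal plane, image y down, walking direction +x, thigh/calf
angles measured from vertical-down with forward positive.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .skeleton import DEFAULT_SKELETON, KeypointSet
from .gait import CameraIntrinsics


@dataclass
class WalkerParams:
    # body geometry (m)
    thigh_l: float = 0.42
    thigh_r: float = 0.42
    calf_l: float = 0.40
    calf_r: float = 0.40
    torso: float = 0.50          # hip-to-shoulder
    hip_half_depth: float = 0.12  # left/right hip offset along the camera axis
    side_offset_m: float = 0.015  # small forward offset separating the sides
    far_side_shade: float = 0.55  # brightness of far-side (right) limbs

    # gait kinematics
    hip_min_deg: float = -8.0    # thigh-from-vertical extremes, within -10..40
    hip_max_deg: float = 35.0
    knee_swing_deg: float = 60.0  # peak swing flexion, within 0..67
    knee_stance_deg: float = 6.0  # small stance-phase flexion
    cycle_time_s: float = 1.2
    stance_fraction: float = 0.62
    phase_offset_rad: float = np.pi  # left-right phase shift
    asymmetry: float = 1.0       # multiplies the right leg's stance fraction

    # camera / rendering
    fps: float = 60.0
    subject_z: float = 3.0       # distance camera -> sagittal plane, m
    image_size: int = 512
    focal_px: float = None       # defaults to image_size (≈53 deg FOV)
    limb_width_px: float = None  # defaults to image_size / 64
    background: float = 0.08     # background gray level
    noise_std: float = 0.0       # additive RGB noise
    occluder: tuple = None       # (x0, y0, w, h) rectangle, pixels
    occluded_joints: tuple = ()  # joints inside the occluder to flag invisible
    seed: int = 0

    def __post_init__(self):
        if self.cycle_time_s <= 0:
            raise ValueError("cycle_time_s must be > 0")
        if not 0.05 <= self.stance_fraction <= 0.95:
            raise ValueError("stance_fraction must lie in [0.05, 0.95]")
        if self.fps <= 0 or self.subject_z <= 0:
            raise ValueError("fps and subject_z must be > 0")
        if self.focal_px is None:
            self.focal_px = float(self.image_size)
        if self.limb_width_px is None:
            self.limb_width_px = max(2.0, self.image_size / 64)

    @property
    def camera(self) -> CameraIntrinsics:
        return CameraIntrinsics(self.focal_px, self.focal_px)

    def stance_fraction_of(self, side: str) -> float:
        f = self.stance_fraction * (self.asymmetry if side == "R" else 1.0)
        return float(np.clip(f, 0.05, 0.95))


@dataclass
class GaitTrajectory:
    """Ground-truth kinematics: angles in degrees, positions in metres."""

    t: np.ndarray            # (n,) seconds
    hip_l: np.ndarray        # thigh-from-vertical, signed
    hip_r: np.ndarray
    knee_l: np.ndarray       # flexion, >= 0
    knee_r: np.ndarray
    positions: np.ndarray    # (n, 8, 3) camera coords in skeleton order
    params: WalkerParams = None


def _thigh_angle(phase: np.ndarray, f_st: float, lo: float, hi: float) -> np.ndarray:
    """Half-cosine stance retraction then swing advance; C1-smooth, periodic.

    Heel strike at phase 0 with the thigh at its forward extreme.
    """
    phase = np.mod(phase, 1.0)
    amp = hi - lo
    stance = lo + amp * (1 + np.cos(np.pi * phase / f_st)) / 2
    swing = lo + amp * (1 - np.cos(np.pi * (phase - f_st) / (1 - f_st))) / 2
    return np.where(phase < f_st, stance, swing)


def _knee_angle(phase: np.ndarray, f_st: float, k_st: float, k_sw: float) -> np.ndarray:
    """Small stance flexion bump plus a large swing flexion bump, in [0, k_sw]."""
    phase = np.mod(phase, 1.0)
    stance = k_st * np.sin(np.pi * phase / f_st) ** 2
    swing = k_sw * np.sin(np.pi * (phase - f_st) / (1 - f_st)) ** 2
    return np.where(phase < f_st, stance, swing)


def simulate_gait(params: WalkerParams, n_frames: int = None,
                  duration_s: float = None) -> GaitTrajectory:
    """Closed-form walker kinematics -> per-frame angles and 3-D positions.

    Right heel strike at t = 0; the left leg runs ``phase_offset_rad``
    ahead (pi = half a cycle). With asymmetry = 1 the two legs' angle
    series are identical up to that shift.
    """
    if n_frames is None:
        duration_s = 5 * params.cycle_time_s if duration_s is None else duration_s
        n_frames = int(round(duration_s * params.fps))
    t = np.arange(n_frames) / params.fps
    base = t / params.cycle_time_s
    ph_r = base
    ph_l = base + params.phase_offset_rad / (2 * np.pi)

    f_l, f_r = params.stance_fraction_of("L"), params.stance_fraction_of("R")
    hip_l = _thigh_angle(ph_l, f_l, params.hip_min_deg, params.hip_max_deg)
    hip_r = _thigh_angle(ph_r, f_r, params.hip_min_deg, params.hip_max_deg)
    knee_l = _knee_angle(ph_l, f_l, params.knee_stance_deg, params.knee_swing_deg)
    knee_r = _knee_angle(ph_r, f_r, params.knee_stance_deg, params.knee_swing_deg)

    pos = np.zeros((n_frames, 8, 3))
    sk = DEFAULT_SKELETON
    r = np.radians
    for side, hip, knee, thigh, calf, dz in (
            ("L", hip_l, knee_l, params.thigh_l, params.calf_l, -params.hip_half_depth),
            ("R", hip_r, knee_r, params.thigh_r, params.calf_r, +params.hip_half_depth)):
        z = params.subject_z + dz
        hip_xy = np.array([-params.side_offset_m if side == "L"
                           else params.side_offset_m, 0.0])
        phi = hip - knee  # calf-from-vertical; flexion bends the calf back
        kx = hip_xy[0] + thigh * np.sin(r(hip))
        ky = hip_xy[1] + thigh * np.cos(r(hip))
        ax = kx + calf * np.sin(r(phi))
        ay = ky + calf * np.cos(r(phi))
        for name, x, y in ((f"{side}S", np.full(n_frames, hip_xy[0]),
                            np.full(n_frames, hip_xy[1] - params.torso)),
                           (f"{side}H", np.full(n_frames, hip_xy[0]),
                            np.full(n_frames, hip_xy[1])),
                           (f"{side}K", kx, ky),
                           (f"{side}A", ax, ay)):
            j = sk.index(name)
            pos[:, j, 0] = x
            pos[:, j, 1] = y
            pos[:, j, 2] = z
    return GaitTrajectory(t, hip_l, hip_r, knee_l, knee_r, pos, params)


def project_points(points: np.ndarray, params: WalkerParams) -> np.ndarray:
    """Pinhole projection of (..., 3) camera coords to pixel (..., 2)."""
    c = params.image_size / 2.0
    x = params.focal_px * points[..., 0] / points[..., 2] + c
    y = params.focal_px * points[..., 1] / points[..., 2] + c
    return np.stack([x, y], axis=-1)


def _draw_segment(canvas: np.ndarray, zbuf: np.ndarray, p0, p1, z0, z1,
                  width: float, value: float) -> None:
    """Rasterize a thick segment with soft (anti-aliased) edges.

    canvas gets ``value`` inside the segment; zbuf records the interpolated
    camera depth of covered pixels (nearest wins).
    """
    h, w = canvas.shape
    x0, y0 = p0
    x1, y1 = p1
    lo_x = max(0, int(np.floor(min(x0, x1) - width - 1)))
    hi_x = min(w, int(np.ceil(max(x0, x1) + width + 2)))
    lo_y = max(0, int(np.floor(min(y0, y1) - width - 1)))
    hi_y = min(h, int(np.ceil(max(y0, y1) + width + 2)))
    if lo_x >= hi_x or lo_y >= hi_y:
        return
    gy, gx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    if L2 == 0:
        tproj = np.zeros_like(gx, dtype=float)
    else:
        tproj = np.clip(((gx - x0) * dx + (gy - y0) * dy) / L2, 0.0, 1.0)
    cx = x0 + tproj * dx
    cy = y0 + tproj * dy
    dist = np.hypot(gx - cx, gy - cy)
    alpha = np.clip(width / 2 + 0.5 - dist, 0.0, 1.0)  # 1px soft edge
    zseg = z0 + tproj * (z1 - z0)
    sub_c = canvas[lo_y:hi_y, lo_x:hi_x]
    sub_z = zbuf[lo_y:hi_y, lo_x:hi_x]
    hit = alpha > 0
    # painter compositing: segments are drawn far-to-near, so later (nearer)
    # strokes cover earlier ones
    sub_c[hit] = alpha[hit] * value + (1 - alpha[hit]) * sub_c[hit]
    nearer = hit & ((sub_z == 0) | (zseg < sub_z))
    sub_z[nearer] = zseg[nearer]


def render_frames(traj: GaitTrajectory, params: WalkerParams = None):
    """Render a trajectory to (rgb_frames, depth_maps, keypoint_sets).

    rgb frames are (H, W, 3) float in [0, 1]; depth maps are (H, W) with
    background 0 and drawn limbs at relative depth in (0, 1], nearer =
    larger. The camera views the subject's left side, so right-side limbs
    are both occluded by and drawn darker than left-side ones (the shading
    cue real sagittal footage provides). Keypoint labels are the projected
    ground truth regardless of occlusion; joints projecting outside the
    frame are flagged invisible, as are joints listed in
    ``params.occluded_joints``.
    """
    params = params or traj.params
    rng = np.random.default_rng(params.seed)
    sk = DEFAULT_SKELETON
    n = traj.positions.shape[0]
    size = params.image_size
    pix = project_points(traj.positions, params)

    z_all = traj.positions[..., 2]
    z_near, z_far = float(z_all.min()), float(z_all.max())
    z_span = max(z_far - z_near, 1e-6)

    frames = np.zeros((n, size, size, 3), dtype=np.float32)
    depths = np.zeros((n, size, size), dtype=np.float32)
    kp_sets = []
    edge_idx = sk.edge_indices()
    # draw far-to-near so near-side limbs occlude far-side ones
    def _edge_z(e):
        i, j = edge_idx[e]
        return -(traj.positions[0, i, 2] + traj.positions[0, j, 2])

    draw_order = sorted(range(len(edge_idx)), key=_edge_z)
    shades = []
    for (i, j) in edge_idx:
        names = {sk.joint_names[i][0], sk.joint_names[j][0]}
        if names == {"R"}:
            shades.append(params.far_side_shade)
        elif names == {"L"}:
            shades.append(1.0)
        else:  # cross-body connections
            shades.append(0.5 * (1.0 + params.far_side_shade))
    for f in range(n):
        canvas = np.zeros((size, size), dtype=np.float32)
        zbuf = np.zeros((size, size), dtype=np.float32)
        for e in draw_order:
            i, j = edge_idx[e]
            _draw_segment(canvas, zbuf, pix[f, i], pix[f, j],
                          traj.positions[f, i, 2], traj.positions[f, j, 2],
                          params.limb_width_px, shades[e])
        rgb = params.background + (1.0 - params.background) * canvas
        rgb = np.repeat(rgb[:, :, None], 3, axis=2)
        if params.occluder is not None:
            x0, y0, ww, hh = [int(v) for v in params.occluder]
            rgb[y0:y0 + hh, x0:x0 + ww] = 0.5
        if params.noise_std > 0:
            rgb = rgb + rng.normal(0, params.noise_std, rgb.shape)
        frames[f] = np.clip(rgb, 0, 1)

        drawn = zbuf > 0
        rel = np.zeros_like(zbuf)
        # nearer limbs brighter; background stays exactly 0
        rel[drawn] = 0.2 + 0.8 * (z_far - zbuf[drawn]) / z_span
        depths[f] = rel

        vis = (pix[f, :, 0] >= 0) & (pix[f, :, 0] < size) \
            & (pix[f, :, 1] >= 0) & (pix[f, :, 1] < size)
        for name in params.occluded_joints:
            vis[sk.index(name)] = False
        kp_sets.append(KeypointSet(pix[f].copy(), vis))
    return frames, depths, kp_sets


def generate_dataset(n_frames: int, params: WalkerParams, out_dir) -> dict:
    """Write paired RGB/depth PNGs plus an ``annotations.json`` manifest.

    The manifest stores each frame's keypoints as the flat 16-tuple
    (x1, y1, ..., x8, y8) with visibility flags; fully reproducible from
    ``params.seed``. Returns the manifest dict.
    """
    from PIL import Image

    os.makedirs(out_dir, exist_ok=True)
    entries = []
    if n_frames > 0:
        traj = simulate_gait(params, n_frames=n_frames)
        frames, depths, kps = render_frames(traj, params)
        for f in range(n_frames):
            rgb_name = f"frame_{f:05d}.png"
            dep_name = f"depth_{f:05d}.png"
            Image.fromarray((frames[f] * 255).astype(np.uint8)).save(
                os.path.join(out_dir, rgb_name))
            d16 = (depths[f] * 65535).astype(np.uint16)
            Image.fromarray(d16).save(os.path.join(out_dir, dep_name))
            entries.append({
                "rgb": rgb_name,
                "depth": dep_name,
                "keypoints": [round(float(v), 4) for v in kps[f].to_flat()],
                "visible": [bool(v) for v in kps[f].visible],
            })
    manifest = {
        "image_size": params.image_size,
        "skeleton": "sagittal-8",
        "fps": params.fps,
        "entries": entries,
    }
    with open(os.path.join(out_dir, "annotations.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
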