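"""Closed-form gait analysis from per-frame keypoints.

Given a sagittal-view keypoint series, camera focal lengths and the
subject's leg-segment lengths, this module computes:

* hip and knee joint-angle series (pinhole back-projection; depth cancels),
* gait events (heel strikes / toe-offs) per leg,
* stride length from segment angles and leg lengths,
* spatiotemporal parameters (stride cycle, stride speed),
* the phase symmetry index D_ps.

Angle conventions (camera axis perpendicular to the sagittal plane, image
y pointing down): the hip angle is the angle between the thigh (hip->knee)
and the vertical-down direction, positive when the knee is *forward* of the
hip in the walking direction; the knee angle is the flexion angle between
thigh and calf, in [0, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .skeleton import DEFAULT_SKELETON, KeypointSet


class UndefinedAngleError(ValueError):
    """Raised when an angle is requested for coincident joints."""


class InsufficientDataError(ValueError):
    """Raised when fewer than one full gait cycle is observed."""


@dataclass(frozen=True)
class CameraIntrinsics:
    f_x: float  # pixels
    f_y: float  # pixels

    def __post_init__(self):
        if self.f_x <= 0 or self.f_y <= 0:
            raise ValueError("focal lengths must be > 0")


@dataclass(frozen=True)
class LegLengths:
    """Thigh/calf lengths in metres; unprimed = left, primed = right."""

    l1: float
    l2: float
    l1p: float
    l2p: float

    def __post_init__(self):
        if min(self.l1, self.l2, self.l1p, self.l2p) <= 0:
            raise ValueError("leg segment lengths must be > 0")


@dataclass(frozen=True)
class NormativeConstants:
    """Healthy-gait normative timing used by the phase symmetry index."""

    T0: float = 1.2    # mean healthy gait cycle, s
    T_T: float = 0.62  # stance share of the cycle
    T_W: float = 0.38  # swing share of the cycle

    def __post_init__(self):
        if abs(self.T_T + self.T_W - 1.0) > 1e-9:
            raise ValueError("stance and swing shares must sum to 1")


@dataclass
class AngleSeries:
    """Per-frame joint angles in degrees with timestamps in seconds."""

    t: np.ndarray
    hip_l: np.ndarray
    hip_r: np.ndarray
    knee_l: np.ndarray
    knee_r: np.ndarray


@dataclass
class GaitEvents:
    """Detected events per leg; all times in seconds."""

    heel_strikes_l: np.ndarray
    heel_strikes_r: np.ndarray
    toe_offs_l: np.ndarray
    toe_offs_r: np.ndarray

    def stance_intervals(self, side: str) -> list:
        hs = self.heel_strikes_l if side == "L" else self.heel_strikes_r
        to = self.toe_offs_l if side == "L" else self.toe_offs_r
        out = []
        for h in hs:
            later = to[to > h]
            if later.size:
                out.append((float(h), float(later[0])))
        return out

    def cycle_times(self, side: str) -> np.ndarray:
        hs = self.heel_strikes_l if side == "L" else self.heel_strikes_r
        return np.diff(hs)

    def mean_durations(self):
        """(ST_L, ST_R, SW_L, SW_R, T) averaged over detected cycles."""
        st_l = np.mean([b - a for a, b in self.stance_intervals("L")])
        st_r = np.mean([b - a for a, b in self.stance_intervals("R")])
        cyc = np.concatenate([self.cycle_times("L"), self.cycle_times("R")])
        if cyc.size == 0:
            raise InsufficientDataError("no complete gait cycle detected")
        t = float(np.mean(cyc))
        return float(st_l), float(st_r), t - float(st_l), t - float(st_r), t


@dataclass
class GaitReport:
    stride_length_m: float
    cycle_time_s: float
    speed_m_s: float
    phase_symmetry: float
    angles: AngleSeries = None
    events: GaitEvents = None
    short_cycle_flag: bool = False  # True when measured T < T0

    def to_dict(self) -> dict:
        return {
            "stride_length_m": self.stride_length_m,
            "cycle_time_s": self.cycle_time_s,
            "speed_m_s": self.speed_m_s,
            "phase_symmetry": self.phase_symmetry,
            "short_cycle_flag": self.short_cycle_flag,
        }


def pixel_to_camera(p, z: float, cam: CameraIntrinsics) -> np.ndarray:
    """Back-project pixel (x, y) at depth z (m) to camera coordinates."""
    if z <= 0:
        raise ValueError("depth z must be > 0")
    x, y = float(p[0]), float(p[1])
    return np.array([z * x / cam.f_x, z * y / cam.f_y, z])


def _signed_vertical_angle(p1, p2, cam: CameraIntrinsics,
                           walking_sign: float) -> float:
    """Signed angle (deg) of segment p1->p2 from vertical-down.

    Depth cancels in the back-projection, leaving the intrinsic-rescaled
    pixel form arccos(f_x*dy / sqrt(f_y^2 dx^2 + f_x^2 dy^2)); the sign is
    positive when p2 is forward of p1 in the walking direction.
    """
    dx = float(p2[0] - p1[0])
    dy = float(p2[1] - p1[1])
    if dx == 0.0 and dy == 0.0:
        raise UndefinedAngleError("coincident joints: angle undefined")
    mag = np.degrees(np.arccos(
        np.clip(cam.f_x * dy / np.hypot(cam.f_y * dx, cam.f_x * dy), -1, 1)))
    sign = 1.0 if dx * walking_sign > 0 else (-1.0 if dx * walking_sign < 0 else 0.0)
    return float(sign * mag) if mag != 0.0 else 0.0


def hip_angle(hip_px, knee_px, cam: CameraIntrinsics,
              walking_sign: float = 1.0) -> float:
    """Signed thigh-from-vertical angle in degrees.

    walking_sign is +1 when the subject walks toward +x in the image
    (camera on the subject's left), -1 for the opposite direction.
    """
    return _signed_vertical_angle(hip_px, knee_px, cam, walking_sign)


def knee_angle(hip_px, knee_px, ankle_px, cam: CameraIntrinsics) -> float:
    """Knee flexion angle in degrees, range [0, 180].

    arccos of the normalized dot product of the thigh vector (hip->knee)
    and calf vector (knee->ankle) after intrinsic rescaling; equivalent to
    back-projecting at any common depth and measuring the 3-D angle.
    """
    a = np.array([(knee_px[0] - hip_px[0]) / cam.f_x,
                  (knee_px[1] - hip_px[1]) / cam.f_y])
    b = np.array([(ankle_px[0] - knee_px[0]) / cam.f_x,
                  (ankle_px[1] - knee_px[1]) / cam.f_y])
    na, nb = np.hypot(*a), np.hypot(*b)
    if na == 0 or nb == 0:
        raise UndefinedAngleError("zero-length leg segment: angle undefined")
    return float(np.degrees(np.arccos(np.clip(a @ b / (na * nb), -1, 1))))


def segment_angles_from_keypoints(hip_px, knee_px, ankle_px,
                                  cam: CameraIntrinsics,
                                  walking_sign: float = 1.0):
    """(theta, phi): signed thigh- and calf-from-vertical angles, degrees."""
    theta = _signed_vertical_angle(hip_px, knee_px, cam, walking_sign)
    phi = _signed_vertical_angle(knee_px, ankle_px, cam, walking_sign)
    return theta, phi


def _smooth(x: np.ndarray, win: int) -> np.ndarray:
    win = max(1, int(win)) | 1  # odd
    if win == 1 or x.size < win:
        return x
    kernel = np.ones(win) / win
    pad = win // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def detect_gait_events(ankle_x_l: np.ndarray, ankle_x_r: np.ndarray,
                       fps: float, walking_sign: float = 1.0,
                       min_separation_s: float = 0.4,
                       smooth_s: float = 0.1) -> GaitEvents:
    """Heel strikes and toe-offs from ankle forward-displacement series.

    The inputs are each ankle's x-pixel trajectory *relative to the hip*
    (forward displacement). Heel strike = local maximum of the smoothed
    forward displacement; toe-off = local minimum; minimum peak separation
    ``min_separation_s`` suppresses jitter. Deterministic.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    ankle_x_l = np.asarray(ankle_x_l, dtype=float) * walking_sign
    ankle_x_r = np.asarray(ankle_x_r, dtype=float) * walking_sign
    n = ankle_x_l.size
    if n != ankle_x_r.size:
        raise ValueError("left/right series must have equal length")
    if n < 2 * fps:
        raise InsufficientDataError("need at least 2 s of frames")
    dist = max(1, int(round(min_separation_s * fps)))
    win = int(round(smooth_s * fps))

    def _events(x):
        xs = _smooth(x, win)
        if np.ptp(xs) < 1e-9:
            return np.array([]), np.array([])
        # keep extrema in the outer 40% bands of the smoothed range:
        # robust to near-boundary peaks that prominence measures would drop
        hi = xs.min() + 0.6 * np.ptp(xs)
        lo = xs.max() - 0.6 * np.ptp(xs)
        hs, _ = find_peaks(xs, distance=dist, height=hi)
        to, _ = find_peaks(-xs, distance=dist, height=-lo)
        return hs / fps, to / fps

    hs_l, to_l = _events(ankle_x_l)
    hs_r, to_r = _events(ankle_x_r)
    ev = GaitEvents(hs_l, hs_r, to_l, to_r)
    if min(hs_l.size, hs_r.size) < 2:
        raise InsufficientDataError("fewer than one full gait cycle detected")
    return ev


def stride_length(theta: float, phi: float, theta_p: float, phi_p: float,
                  legs: LegLengths) -> float:
    """Forward distance between the feet from segment angles (degrees).

    (l1' sin theta' + l2' sin phi') - (l1 sin theta + l2 sin phi), with
    unprimed = left leg, primed = right leg; positive when the right foot
    is forward of the left.
    """
    r = np.radians
    return float((legs.l1p * np.sin(r(theta_p)) + legs.l2p * np.sin(r(phi_p)))
                 - (legs.l1 * np.sin(r(theta)) + legs.l2 * np.sin(r(phi))))


def phase_symmetry_index(st_l: float, st_r: float, sw_l: float, sw_r: float,
                         t: float, k: NormativeConstants = NormativeConstants()
                         ) -> float:
    """D_ps = sqrt(T0/T) * (T_T * min/max stance + T_W * min/max swing).

    1.0 for perfectly symmetric gait at the normative cycle time; no
    clamping is applied, so T < T0 can push the value above 1 (callers flag
    such recordings).
    """
    vals = (st_l, st_r, sw_l, sw_r, t)
    if min(vals) <= 0:
        raise ValueError("all durations must be > 0")
    return float(np.sqrt(k.T0 / t)
                 * (k.T_T * min(st_l, st_r) / max(st_l, st_r)
                    + k.T_W * min(sw_l, sw_r) / max(sw_l, sw_r)))


def phase_symmetry(events: GaitEvents,
                   k: NormativeConstants = NormativeConstants()) -> float:
    """Phase symmetry index from detected events (cycle-averaged durations)."""
    st_l, st_r, sw_l, sw_r, t = events.mean_durations()
    return phase_symmetry_index(st_l, st_r, sw_l, sw_r, t, k)


def angle_series(keypoint_sets, fps: float, cam: CameraIntrinsics,
                 walking_sign: float = 1.0,
                 skeleton=DEFAULT_SKELETON) -> AngleSeries:
    """Hip/knee angle series for both legs from per-frame keypoints."""
    idx = {n: skeleton.index(n) for n in ("LH", "RH", "LK", "RK", "LA", "RA")}
    t, hl, hr, kl, kr = [], [], [], [], []
    for f, kp in enumerate(keypoint_sets):
        c = kp.coords
        t.append(f / fps)
        hl.append(hip_angle(c[idx["LH"]], c[idx["LK"]], cam, walking_sign))
        hr.append(hip_angle(c[idx["RH"]], c[idx["RK"]], cam, walking_sign))
        kl.append(knee_angle(c[idx["LH"]], c[idx["LK"]], c[idx["LA"]], cam))
        kr.append(knee_angle(c[idx["RH"]], c[idx["RK"]], c[idx["RA"]], cam))
    return AngleSeries(np.array(t), np.array(hl), np.array(hr),
                       np.array(kl), np.array(kr))


def gait_report(keypoint_sets, cam: CameraIntrinsics, legs: LegLengths,
                fps: float, k: NormativeConstants = NormativeConstants(),
                walking_sign: float = 1.0,
                skeleton=DEFAULT_SKELETON) -> GaitReport:
    """Full gait analysis chain: angles -> events -> stride/cycle/speed/D_ps.

    Stride length is the segment-angle formula evaluated at every detected heel
    strike (leading minus trailing foot, so non-negative by construction)
    and averaged over cycles; speed = mean stride length / mean cycle time.
    """
    series = angle_series(keypoint_sets, fps, cam, walking_sign, skeleton)
    idx = {n: skeleton.index(n) for n in ("LH", "RH", "LA", "RA")}
    ax_l = np.array([kp.coords[idx["LA"], 0] - kp.coords[idx["LH"], 0]
                     for kp in keypoint_sets])
    ax_r = np.array([kp.coords[idx["RA"], 0] - kp.coords[idx["RH"], 0]
                     for kp in keypoint_sets])
    events = detect_gait_events(ax_l, ax_r, fps, walking_sign)

    seg = []
    for f, kp in enumerate(keypoint_sets):
        c = kp.coords
        th_l, ph_l = segment_angles_from_keypoints(
            c[skeleton.index("LH")], c[skeleton.index("LK")],
            c[skeleton.index("LA")], cam, walking_sign)
        th_r, ph_r = segment_angles_from_keypoints(
            c[skeleton.index("RH")], c[skeleton.index("RK")],
            c[skeleton.index("RA")], cam, walking_sign)
        seg.append((th_l, ph_l, th_r, ph_r))
    seg = np.array(seg)

    strides = []
    for hs, leading in ((events.heel_strikes_l, "L"),
                        (events.heel_strikes_r, "R")):
        for t_hs in hs:
            f = int(round(t_hs * fps))
            if f >= len(seg):
                continue
            th_l, ph_l, th_r, ph_r = seg[f]
            d = stride_length(th_l, ph_l, th_r, ph_r, legs)
            strides.append(-d if leading == "L" else d)
    if not strides:
        raise InsufficientDataError("no heel strikes within the recording")
    d_sl = float(np.mean(strides))

    st_l, st_r, sw_l, sw_r, t_cycle = events.mean_durations()
    d_ps = phase_symmetry_index(st_l, st_r, sw_l, sw_r, t_cycle, k)
    return GaitReport(
        stride_length_m=d_sl,
        cycle_time_s=t_cycle,
        speed_m_s=d_sl / t_cycle,
        phase_symmetry=d_ps,
        angles=series,
        events=events,
        short_cycle_flag=t_cycle < k.T0,
    )
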