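"""Geometric simulator of webcam landmark-tracking sessions.

Replaces the camera + landmark-tracking CNN stage with a forward model so
the whole gaze pipeline can run without video: a rigid 3D face with
spherical eyeballs fixates a calibration dot sweeping the screen in a
serpentine raster; 13 facial points (4 pupil-rim corners per eye, 4 eye
corners, one upper-lip/philtrum point) are projected through a pinhole
camera into a webcam frame, perturbed with isotropic Gaussian noise, and
emitted with per-point likelihood scores. Blink frames get pupil
likelihoods below the downstream filter threshold.

Coordinate conventions (all lengths in mm unless stated):

* Camera frame: origin at the camera pinhole, x rightward, y downward,
  z into the scene. Projection: ``u = f*X/Z + cx``, ``v = f*Y/Z + cy``.
* Screen plane: z = 0 (camera mounted at the screen), top-center of the
  panel offset from the camera by ``screen_top_center_mm``.
* Head-local frame: axes parallel to the camera frame at identity pose,
  origin between the eyes; the face surface points toward negative local z
  (toward the camera).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dlc_io import COORDS, RAW_LANDMARKS
from .geometry import ScreenGeometry

__all__ = [
    "HeadPose",
    "FaceModel",
    "CameraModel",
    "SimulationConfig",
    "generate_calibration_path",
    "gaze_direction",
    "simulate_frame",
    "simulate_session",
]

PUPIL_LANDMARKS = tuple(n for n in RAW_LANDMARKS if "pupil" in n)


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass(frozen=True)
class HeadPose:
    """Rigid head placement in camera coordinates.

    Rotations are intrinsic and composed yaw (about y, down axis), then
    pitch (about x), then roll (about z): ``R = R_yaw @ R_pitch @ R_roll``.
    """

    position_mm: tuple[float, float, float] = (0.0, 0.0, 500.0)
    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    roll_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.position_mm[2] <= 0:
            raise ValueError("head must sit in front of the camera (positive depth)")

    @property
    def rotation(self) -> np.ndarray:
        return _rot_y(self.yaw_deg) @ _rot_x(self.pitch_deg) @ _rot_z(self.roll_deg)

    def to_world(self, local_points: np.ndarray) -> np.ndarray:
        return np.asarray(self.position_mm) + local_points @ self.rotation.T


@dataclass(frozen=True)
class FaceModel:
    """Rigid 3D landmark anchors (head-local mm) plus eyeball parameters.

    The default face is bilaterally symmetric about the head-local x = 0
    midline, with a 63 mm interpupillary distance and 12 mm eyeball radius
    (standard adult anthropometric values). ``pupil_rim_radius_mm`` is the
    radius of the square of pupil-rim corner points around the pupil axis.
    """

    eye_center_left: tuple[float, float, float] = (-31.5, 0.0, 0.0)
    eye_center_right: tuple[float, float, float] = (31.5, 0.0, 0.0)
    lateral_corner_left: tuple[float, float, float] = (-49.5, 2.0, -5.0)
    lateral_corner_right: tuple[float, float, float] = (49.5, 2.0, -5.0)
    medial_corner_left: tuple[float, float, float] = (-14.0, 2.0, -5.0)
    medial_corner_right: tuple[float, float, float] = (14.0, 2.0, -5.0)
    lip_philtrum: tuple[float, float, float] = (0.0, 52.0, -10.0)
    eyeball_radius_mm: float = 12.0
    pupil_rim_radius_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.eyeball_radius_mm <= 0 or self.pupil_rim_radius_mm <= 0:
            raise ValueError("eyeball and pupil-rim radii must be positive")
        if self.pupil_rim_radius_mm >= self.eyeball_radius_mm:
            raise ValueError("pupil rim must be smaller than the eyeball")

    @property
    def static_landmarks(self) -> dict[str, np.ndarray]:
        """Landmarks rigid in the head frame (everything but the pupils)."""
        return {
            "left_lateral_corner": np.asarray(self.lateral_corner_left),
            "left_medial_corner": np.asarray(self.medial_corner_left),
            "right_medial_corner": np.asarray(self.medial_corner_right),
            "right_lateral_corner": np.asarray(self.lateral_corner_right),
            "lip_philtrum": np.asarray(self.lip_philtrum),
        }


@dataclass(frozen=True)
class CameraModel:
    """Pinhole webcam plus the rigid placement of the screen plane.

    The default focal length (1400 px) matches a consumer webcam's 1080p
    horizontal field of view; the frame is a 600x500 px crop around the
    face. The screen lies in the z = 0 plane with its top-center 50 mm
    above the camera (webcam mounted on the top bezel).
    """

    focal_length_px: float = 1400.0
    principal_point: tuple[float, float] = (300.0, 250.0)
    frame_width_px: int = 600
    frame_height_px: int = 500
    screen_top_center_mm: tuple[float, float, float] = (0.0, -50.0, 0.0)

    def project(self, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project (N, 3) camera-frame points to (N, 2) frame pixels.

        Returns (pixels, in_front) where ``in_front`` flags positive depth.
        """
        pts = np.atleast_2d(points_mm)
        z = pts[:, 2]
        in_front = z > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.focal_length_px * pts[:, 0] / z + self.principal_point[0]
            v = self.focal_length_px * pts[:, 1] / z + self.principal_point[1]
        return np.column_stack([u, v]), in_front

    def screen_point_mm(self, target_px, geom: ScreenGeometry) -> np.ndarray:
        """3D camera-frame location of a screen pixel (x, y)."""
        sx, sy = float(target_px[0]), float(target_px[1])
        top = np.asarray(self.screen_top_center_mm)
        return top + np.array(
            [(sx - geom.width_px / 2.0) * geom.mm_per_px_x, sy * geom.mm_per_px_y, 0.0]
        )


def _default_poses() -> tuple[HeadPose, ...]:
    return (
        HeadPose(yaw_deg=-20.0),
        HeadPose(yaw_deg=0.0),
        HeadPose(yaw_deg=20.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Noise, blink and timing parameters of a simulated session.

    ``blink_likelihood_range`` must sit strictly below the preprocessing
    likelihood threshold (0.7) so blinks are removable; normal frames draw
    likelihoods near 1.
    """

    noise_sd_px: float = 1.0
    blink_probability: float = 0.027
    blink_likelihood_range: tuple[float, float] = (0.0, 0.7)
    normal_likelihood_range: tuple[float, float] = (0.95, 1.0)
    fps: float = 30.0
    seed: int = 0
    poses: tuple[HeadPose, ...] = field(default_factory=_default_poses)

    def __post_init__(self) -> None:
        if self.noise_sd_px < 0:
            raise ValueError("noise_sd_px must be >= 0")
        if not 0.0 <= self.blink_probability <= 1.0:
            raise ValueError("blink_probability must lie in [0, 1]")
        lo, hi = self.normal_likelihood_range
        if not (0.9 <= lo <= hi <= 1.0):
            raise ValueError("normal likelihoods must lie in [0.9, 1.0]")
        blo, bhi = self.blink_likelihood_range
        if not (0.0 <= blo <= bhi <= 0.7):
            raise ValueError("blink likelihoods must lie in [0, 0.7]")


def generate_calibration_path(
    geom: ScreenGeometry,
    n_lines: int = 5,
    fps: float = 30.0,
    slow_factor: float = 0.4,
    fast_factor: float = 1.6,
    base_speed_px_s: float = 300.0,
    margin_px: float = 50.0,
) -> pd.DataFrame:
    """Serpentine raster trace of the calibration dot, sampled at ``fps``.

    The dot sweeps ``n_lines`` horizontal lines in alternating directions,
    joined by downward vertical increments. Along each horizontal line the
    speed is modulated as ``base * (slow + (fast - slow) * sin^2(pi*u))``
    with ``u`` the fractional position along the line, so the dot slows
    near direction changes and speeds up mid-line; vertical increments run
    at the slow speed. With defaults the session lasts about one minute.

    Returns a DataFrame with columns ``frame``, ``x``, ``y`` (screen px).
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if slow_factor <= 0 or fast_factor <= 0 or base_speed_px_s <= 0:
        raise ValueError("speed factors must be positive")
    if fps <= 0:
        raise ValueError("fps must be positive")
    x_lo, x_hi = margin_px, geom.width_px - margin_px
    y_lo, y_hi = margin_px, geom.height_px - margin_px
    if x_hi <= x_lo or y_hi <= y_lo:
        raise ValueError("margin leaves no traversal span on this screen")

    y_lines = np.linspace(y_lo, y_hi, n_lines)
    # Segment list: (start, end, kind); kinds modulate speed differently.
    segments: list[tuple[np.ndarray, np.ndarray, str]] = []
    for i, y in enumerate(y_lines):
        left_to_right = i % 2 == 0
        start = np.array([x_lo if left_to_right else x_hi, y])
        end = np.array([x_hi if left_to_right else x_lo, y])
        segments.append((start, end, "horizontal"))
        if i + 1 < n_lines:
            nxt = np.array([end[0], y_lines[i + 1]])
            segments.append((end, nxt, "vertical"))

    dt = 1.0 / fps
    rows = []
    frame = 0
    for start, end, kind in segments:
        length = float(np.linalg.norm(end - start))
        direction = (end - start) / length
        s = 0.0
        while s < length:
            pos = start + s * direction
            rows.append((frame, pos[0], pos[1]))
            frame += 1
            u = s / length
            if kind == "horizontal":
                mult = slow_factor + (fast_factor - slow_factor) * np.sin(np.pi * u) ** 2
            else:
                mult = slow_factor
            s += base_speed_px_s * mult * dt
    rows.append((frame, segments[-1][1][0], segments[-1][1][1]))
    return pd.DataFrame(rows, columns=["frame", "x", "y"]).astype(
        {"frame": int, "x": float, "y": float}
    )


def gaze_direction(eyeball_center_mm, target_mm) -> np.ndarray:
    """Unit vector from the eyeball center toward a 3D fixation target."""
    center = np.asarray(eyeball_center_mm, dtype=float)
    target = np.asarray(target_mm, dtype=float)
    vec = target - center
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise ValueError("fixation target coincides with the eyeball center")
    return vec / norm


def _pupil_corners(center_mm: np.ndarray, axis: np.ndarray, radius: float, rim: float) -> np.ndarray:
    """Four pupil-rim corner points whose 3D centroid is the pupil center.

    The pupil center is the intersection of the gaze axis with the eyeball
    sphere; the corners form a square of radius ``rim`` in the tangent
    plane there, so averaging them recovers the pupil center exactly.
    """
    pupil = center_mm + radius * axis
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    angles = np.radians([45.0, 135.0, 225.0, 315.0])
    return pupil + rim * (np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2))


def simulate_frame(
    target_px,
    pose: HeadPose,
    face: FaceModel,
    cam: CameraModel,
    geom: ScreenGeometry,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, tuple[float, float, float]], bool]:
    """Simulate one frame: landmark pixels + likelihoods for one gaze target.

    Each eyeball is rotated so its pupil axis points at the 3D screen
    target ("look-at" kinematics; no ocular torsion or corneal refraction),
    all 13 landmark points are projected through the pinhole camera,
    isotropic Gaussian noise of ``cfg.noise_sd_px`` is added, and a blink
    is drawn with ``cfg.blink_probability`` (blinks assign sub-threshold
    likelihoods to the pupil points only — blinks occlude pupils, not the
    mouth). Returns (observation, valid); ``valid`` is False when any
    landmark falls behind the camera.
    """
    target_3d = cam.screen_point_mm(target_px, geom)

    names: list[str] = []
    points: list[np.ndarray] = []
    for side, eye_local in (("left", face.eye_center_left), ("right", face.eye_center_right)):
        eye_world = pose.to_world(np.asarray(eye_local))
        axis = gaze_direction(eye_world, target_3d)
        corners = _pupil_corners(eye_world, axis, face.eyeball_radius_mm, face.pupil_rim_radius_mm)
        for k in range(4):
            names.append(f"{side}_pupil_corner_{k + 1}")
            points.append(corners[k])
    for name, local in face.static_landmarks.items():
        names.append(name)
        points.append(pose.to_world(local))

    pixels, in_front = cam.project(np.vstack(points))
    valid = bool(np.all(in_front))
    if cfg.noise_sd_px > 0:
        pixels = pixels + rng.normal(0.0, cfg.noise_sd_px, size=pixels.shape)

    blink = rng.random() < cfg.blink_probability
    lo, hi = cfg.normal_likelihood_range
    likelihood = dict(zip(names, rng.uniform(lo, hi, size=len(names))))
    if blink:
        blo, bhi = cfg.blink_likelihood_range
        for name in PUPIL_LANDMARKS:
            likelihood[name] = rng.uniform(blo, bhi)
    if not valid:
        likelihood = {name: 0.0 for name in names}

    obs = {
        name: (float(px[0]), float(px[1]), float(likelihood[name]))
        for name, px in zip(names, pixels)
    }
    return obs, valid


def simulate_session(
    path: pd.DataFrame,
    face: FaceModel,
    cam: CameraModel,
    geom: ScreenGeometry,
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the calibration path once per head pose and concatenate.

    Returns ``(landmarks, targets)``: a landmark table with
    ``(bodyparts, coords)`` columns and a row-aligned ground-truth table
    with columns ``target_x_px``, ``target_y_px`` and a ``pose`` label,
    both indexed by a continuous frame counter across poses. All
    randomness flows from ``cfg.seed``.
    """
    if len(path) == 0:
        raise ValueError("calibration path is empty")
    if len(cfg.poses) == 0:
        raise ValueError("at least one head pose is required")
    rng = np.random.default_rng(cfg.seed)

    records = np.empty((len(path) * len(cfg.poses), 3 * len(RAW_LANDMARKS)))
    truth_rows = []
    i = 0
    path_xy = path[["x", "y"]].to_numpy()
    for pose_id, pose in enumerate(cfg.poses):
        for target in path_xy:
            obs, _valid = simulate_frame(target, pose, face, cam, geom, cfg, rng)
            records[i] = [v for name in RAW_LANDMARKS for v in obs[name]]
            truth_rows.append((target[0], target[1], pose_id))
            i += 1

    index = pd.Index(range(i), name="frame")
    columns = pd.MultiIndex.from_product(
        [RAW_LANDMARKS, COORDS], names=["bodyparts", "coords"]
    )
    landmarks = pd.DataFrame(records, index=index, columns=columns)
    targets = pd.DataFrame(
        truth_rows, index=index, columns=["target_x_px", "target_y_px", "pose"]
    ).astype({"pose": int})
    return landmarks, targets
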