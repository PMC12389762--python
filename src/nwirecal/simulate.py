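"""Synthetic tracked-ultrasound calibration datasets with known truth.

The simulator stands in for a water-tank acquisition: a tracked probe is
swept over a layered N-wire phantom while B-mode frames and 6-DoF sensor
poses are recorded. It emulates

* blob-like wire cross-sections under a Gaussian point-spread function,
* multiplicative speckle (gamma-distributed, fully-developed
  approximation),
* elongated bright echo artifacts and isolated bright distractors,
* bounded pixel-localization jitter of the rendered blob centres,
* electromagnetic pose noise on the recorded (not true) poses,
* probe pitch/yaw and moderate translations around a nominal scanning
  pose held roughly perpendicular to the wires.

Everything is seeded; regenerating with the same seed reproduces the
dataset bit for bit. Truth features are never touched by image noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import ConfigurationError, DegenerateGeometryError
from .detect import CandidatePoint
from .filtering import FrameDetection, Triplet
from .geometry import (
    CalibrationState,
    PhantomGeometry,
    PoseParams6,
    RigidTransform,
    default_phantom,
    matrix_to_pose,
    pose_to_matrix,
)

__all__ = [
    "NoiseConfig",
    "TruthFeature",
    "SyntheticFrame",
    "SyntheticDataset",
    "default_truth_state",
    "nominal_chain",
    "generate_poses",
    "project_wires",
    "render_frame",
    "make_dataset",
    "truth_detection",
    "DEFAULT_IMAGE_SIZE",
    "DEFAULT_ROT_RANGE_DEG",
    "DEFAULT_TRANS_RANGE_MM",
]

DEFAULT_IMAGE_SIZE = (512, 512)  # (height, width) px
# Scanning-protocol ranges around the nominal pose: (pitch, yaw, roll) deg
# and (lateral, axial, elevational) mm, with rotations pivoting about the
# probe face (image centre). Roll and the elevational components are kept
# small so the wires stay near-horizontal and the cut stays near mid-wire
# — the same near-perpendicular protocol the structural filtering
# thresholds presuppose.
DEFAULT_ROT_RANGE_DEG = (0.8, 0.5, 1.0)
DEFAULT_TRANS_RANGE_MM = (5.0, 5.0, 0.1)

# Vertical clearances (px): clutter keeps 38 px from the wire rows (just
# beyond the 30 px centre-refinement radius, so no bright off-structure
# pixel can enter a feature's refinement window) and 30 px from other
# clutter; at >= 30 px any cross-structure pair already exceeds the
# collinearity slope bound.
_TRUTH_CLEARANCE_PX = 38.0
_CLUTTER_SEP_PX = 30.0


@dataclass(frozen=True)
class NoiseConfig:
    """Noise and clutter levels of the rendered acquisition.

    ``pose_trans_sigma`` (mm) / ``pose_rot_sigma`` (deg) perturb the
    recorded poses (defaults below the tracker's 1 mm spec);
    ``pixel_jitter_sigma`` (px) displaces rendered blob centres
    (truncated at 2 sigma); ``speckle_strength`` scales a mean-one
    gamma-distributed multiplicative field; ``psf_sigma_px`` is the blob
    scale (2.5 px ~ 0.3 mm wires blurred by a clinical PSF at
    0.1 mm/px).
    """

    pose_trans_sigma: float = 0.2
    pose_rot_sigma: float = 0.1
    pixel_jitter_sigma: float = 1.0
    speckle_strength: float = 0.3
    n_artifacts: int = 2
    n_distractors: int = 4
    psf_sigma_px: float = 2.5
    background: float = 20.0
    blob_peak: float = 230.0
    n_structured_rows: int = 0

    def __post_init__(self) -> None:
        sigmas = (
            self.pose_trans_sigma,
            self.pose_rot_sigma,
            self.pixel_jitter_sigma,
            self.speckle_strength,
            self.psf_sigma_px,
        )
        if min(sigmas) < 0:
            raise ValueError("noise sigmas must be non-negative")
        if min(self.n_artifacts, self.n_distractors, self.n_structured_rows) < 0:
            raise ValueError("clutter counts must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseConfig":
        return cls(
            pose_trans_sigma=0.0,
            pose_rot_sigma=0.0,
            pixel_jitter_sigma=0.0,
            speckle_strength=0.0,
            n_artifacts=0,
            n_distractors=0,
        )


class TruthFeature(NamedTuple):
    """Ground-truth wire crossing: layer, label (A/B/C) and real-valued
    pixel position."""

    layer_index: int
    label: str
    u: float
    v: float


@dataclass(frozen=True)
class SyntheticFrame:
    frame_index: int
    image: np.ndarray
    pose_recorded: RigidTransform
    pose_true: RigidTransform
    truth_features: tuple[TruthFeature, ...]
    psf_sigma_px: float


@dataclass(frozen=True)
class SyntheticDataset:
    frames: tuple[SyntheticFrame, ...]
    truth_state: CalibrationState
    phantom: PhantomGeometry
    seed: int

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def recorded_poses(self) -> dict[int, RigidTransform]:
        return {f.frame_index: f.pose_recorded for f in self.frames}

    def true_poses(self) -> dict[int, RigidTransform]:
        return {f.frame_index: f.pose_true for f in self.frames}


# Nominal image->phantom chain: image u runs along the phantom wire-
# spacing axis (x_P), image depth v runs down the layer stack (-z_P),
# the image normal points along the wires (y_P). The nominal cut plane
# passes mid-wire through the default phantom, centred in a 512x512
# image at 0.1 mm/px.
_R_CHAIN = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
_T_CHAIN = np.array([-13.1, 12.5, 15.6])


def nominal_chain() -> RigidTransform:
    """The nominal combined transform T_WP * T_RW * T_UR (image metric
    frame -> phantom) when the probe sits in its reference pose."""
    return RigidTransform(_R_CHAIN, _T_CHAIN)


def default_truth_state(sx: float = 0.1, sy: float = 0.1) -> CalibrationState:
    """A realistic ground-truth calibration: the sensor is mounted a few
    centimetres from the image origin with a few degrees of misalignment,
    and T_WP closes the chain so the nominal pose views the phantom
    mid-wire."""
    t_ur = PoseParams6(np.array([0.05, -0.03, 0.04]), np.array([12.0, -8.0, 35.0]))
    ur = pose_to_matrix(t_ur)
    wp = nominal_chain() @ ur.inverse()
    return CalibrationState(t_ur, matrix_to_pose(wp), sx, sy)


def _broadcast3(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a scalar or length-3 sequence")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr


def _sample_pose(
    rng,
    rot_range_deg,
    trans_range_mm,
    nominal: RigidTransform,
    pivot: np.ndarray | None = None,
) -> RigidTransform:
    rot = np.deg2rad(rng.uniform(-rot_range_deg, rot_range_deg))
    trans = rng.uniform(-trans_range_mm, trans_range_mm)
    r = Rotation.from_euler("xyz", rot).as_matrix()
    if pivot is None:
        perturb = RigidTransform(r, trans)
    else:
        # rotate about the pivot (the probe face), then translate
        perturb = RigidTransform(r, pivot - r @ pivot + trans)
    return nominal @ perturb


def generate_poses(
    n: int,
    rot_range_deg=DEFAULT_ROT_RANGE_DEG,
    trans_range_mm=DEFAULT_TRANS_RANGE_MM,
    seed: int = 0,
    nominal: RigidTransform | None = None,
    pivot=None,
) -> list[RigidTransform]:
    """Sample ``n`` sensor poses uniformly within per-axis rotation and
    translation ranges around the nominal scanning pose (deterministic
    per seed). Rotations pivot about ``pivot`` (sensor-frame point, mm)
    when given — the operator tilts the probe about its face, not about
    the sensor mounted on its shaft."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rot_range = _broadcast3(rot_range_deg, "rot_range_deg")
    trans_range = _broadcast3(trans_range_mm, "trans_range_mm")
    nominal = nominal or RigidTransform.identity()
    rng = np.random.default_rng(seed)
    pivot = None if pivot is None else np.asarray(pivot, dtype=float)
    return [_sample_pose(rng, rot_range, trans_range, nominal, pivot) for _ in range(n)]


def project_wires(
    state: CalibrationState,
    pose: RigidTransform,
    phantom: PhantomGeometry,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
) -> list[TruthFeature]:
    """Analytic wire crossings of the image plane.

    Wire endpoints are mapped into the metric image frame with the
    inverse of ``T_WP * T_RW * T_UR``; each segment's crossing of the
    plane ``z_U = 0`` is found by linear interpolation and converted to
    pixels. Only crossings inside the image are returned. A wire lying
    in the plane raises :class:`DegenerateGeometryError`; a wire
    parallel to but off the plane simply yields no feature.
    """
    h, w = image_size
    chain = state.t_wp_transform @ pose @ state.t_ur_transform
    inv = chain.inverse()
    feats: list[TruthFeature] = []
    for layer in phantom.layers:
        for label, p0, p1 in layer.wires():
            q0, q1 = inv.apply(p0), inv.apply(p1)
            dz = q1[2] - q0[2]
            if abs(dz) < 1e-12:
                if abs(q0[2]) < 1e-9:
                    raise DegenerateGeometryError(
                        f"wire {label} of layer {layer.layer_index} lies in the image plane"
                    )
                continue
            t = -q0[2] / dz
            if not (0.0 <= t <= 1.0):
                continue
            q = q0 + t * (q1 - q0)
            u, v = q[0] / state.sx, q[1] / state.sy
            if 0.0 <= u <= w - 1 and 0.0 <= v <= h - 1:
                feats.append(TruthFeature(layer.layer_index, label, float(u), float(v)))
    return feats


def _add_blob(img: np.ndarray, u: float, v: float, amplitude: float, sigma: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma)) + 1
    c0, c1 = max(int(u) - r, 0), min(int(u) + r + 1, w)
    r0, r1 = max(int(v) - r, 0), min(int(v) + r + 1, h)
    if c0 >= c1 or r0 >= r1:
        return
    uu, vv = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    img[r0:r1, c0:c1] += amplitude * np.exp(-((uu - u) ** 2 + (vv - v) ** 2) / (2 * sigma**2))


def _add_bar(img: np.ndarray, p0: np.ndarray, p1: np.ndarray, amplitude: float, width_sigma: float) -> None:
    h, w = img.shape
    lo = np.floor(np.minimum(p0, p1)).astype(int) - 4
    hi = np.ceil(np.maximum(p0, p1)).astype(int) + 5
    c0, c1 = max(lo[0], 0), min(hi[0], w)
    r0, r1 = max(lo[1], 0), min(hi[1], h)
    if c0 >= c1 or r0 >= r1:
        return
    uu, vv = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    d = p1 - p0
    length = np.linalg.norm(d)
    t = ((uu - p0[0]) * d[0] + (vv - p0[1]) * d[1]) / length**2
    t = np.clip(t, 0.0, 1.0)
    px, py = p0[0] + t * d[0], p0[1] + t * d[1]
    dist2 = (uu - px) ** 2 + (vv - py) ** 2
    img[r0:r1, c0:c1] += amplitude * np.exp(-dist2 / (2 * width_sigma**2))


def _interval_clear(lo: float, hi: float, occupied: list[tuple[float, float]], sep: float) -> bool:
    return all(lo - sep > o_hi or hi + sep < o_lo for o_lo, o_hi in occupied)


def render_frame(
    truth_features: Sequence[TruthFeature],
    image_size: tuple[int, int],
    noise: NoiseConfig,
    seed: int = 0,
) -> np.ndarray:
    """Render one 8-bit frame from the truth features.

    Wire crossings become isotropic Gaussian blobs (peak ~230 over a
    dim background) at the truth positions plus bounded localization
    jitter; bright elongated bars (echo artifacts) and isolated blobs
    (distractors) are placed with a minimum vertical clearance from the
    wire rows, as off-structure specular reflectors; an optional
    *structured* distractor row mimics a false wire layer with regular
    spacing (used for ablation experiments). Multiplicative speckle is
    applied last, then quantization. Deterministic per seed.
    """
    h, w = image_size
    rng = np.random.default_rng(seed)
    img = np.full((h, w), noise.background, dtype=float)
    amp = noise.blob_peak - noise.background

    feats = list(truth_features)
    if noise.pixel_jitter_sigma > 0:
        jit = rng.normal(0.0, noise.pixel_jitter_sigma, size=(len(feats), 2))
        clip = 2.0 * noise.pixel_jitter_sigma
        jit = np.clip(jit, -clip, clip)
    else:
        jit = np.zeros((len(feats), 2))
    for f, (du, dv) in zip(feats, jit):
        _add_blob(img, f.u + du, f.v + dv, amp, noise.psf_sigma_px)

    truth_vs = [f.v for f in feats]
    truth_bands = [(v - _TRUTH_CLEARANCE_PX + _CLUTTER_SEP_PX,
                    v + _TRUTH_CLEARANCE_PX - _CLUTTER_SEP_PX) for v in truth_vs]
    occupied = list(truth_bands)

    for _ in range(noise.n_structured_rows):
        if feats:
            v_top = min(truth_vs)
            v_row = v_top - 40.0 if v_top - 40.0 > 8.0 else max(truth_vs) + 40.0
            u_mid = float(np.median([f.u for f in feats]))
        else:
            v_row, u_mid = h / 2.0, w / 2.0
        spacing = 125.0
        for k in (-1, 0, 1):
            u = min(max(u_mid + k * spacing, 8.0), w - 9.0)
            _add_blob(img, u, v_row, 255.0 - noise.background, noise.psf_sigma_px)
        occupied.append((v_row, v_row))

    for _ in range(noise.n_artifacts):
        for _attempt in range(200):
            length = rng.uniform(60.0, 140.0)
            ang = rng.uniform(0.0, np.pi)
            cu = rng.uniform(20.0, w - 20.0)
            cv = rng.uniform(10.0, h - 10.0)
            d = 0.5 * length * np.array([np.cos(ang), np.sin(ang)])
            p0, p1 = np.array([cu, cv]) - d, np.array([cu, cv]) + d
            lo, hi = min(p0[1], p1[1]), max(p0[1], p1[1])
            if _interval_clear(lo, hi, occupied, _CLUTTER_SEP_PX):
                _add_bar(img, p0, p1, 180.0, 1.2)
                occupied.append((lo, hi))
                break

    for _ in range(noise.n_distractors):
        for _attempt in range(300):
            u = rng.uniform(15.0, w - 15.0)
            v = rng.uniform(15.0, h - 15.0)
            if _interval_clear(v, v, occupied, _CLUTTER_SEP_PX):
                _add_blob(img, u, v, amp, noise.psf_sigma_px)
                occupied.append((v, v))
                break

    if noise.speckle_strength > 0:
        g = rng.gamma(4.0, 0.25, size=img.shape)  # mean 1, unit-shape speckle
        img = img * (1.0 + noise.speckle_strength * (g - 1.0))

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _perturb_pose(pose: RigidTransform, noise: NoiseConfig, rng) -> RigidTransform:
    if noise.pose_rot_sigma == 0 and noise.pose_trans_sigma == 0:
        return pose
    axis = rng.normal(size=3)
    axis /= max(np.linalg.norm(axis), 1e-12)
    angle = np.deg2rad(rng.normal(0.0, noise.pose_rot_sigma))
    dr = Rotation.from_rotvec(angle * axis).as_matrix()
    dt = rng.normal(0.0, noise.pose_trans_sigma, size=3)
    return pose @ RigidTransform(dr, dt)


def _layers_complete(feats: Sequence[TruthFeature], phantom: PhantomGeometry) -> bool:
    per_layer: dict[int, set[str]] = {}
    for f in feats:
        per_layer.setdefault(f.layer_index, set()).add(f.label)
    return all(per_layer.get(lay.layer_index, set()) == {"A", "B", "C"} for lay in phantom.layers)


def make_dataset(
    truth_state: CalibrationState | None = None,
    phantom: PhantomGeometry | None = None,
    n_frames: int = 30,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    rot_range_deg=DEFAULT_ROT_RANGE_DEG,
    trans_range_mm=DEFAULT_TRANS_RANGE_MM,
    psf_choices: Sequence[float] | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic calibration dataset.

    Poses are sampled around the nominal scanning pose; frames in which
    any layer projects fewer than three crossings are regenerated with a
    fresh pose (up to 100 retries each). Recorded poses are the true
    poses perturbed by tracker noise; pixel jitter affects only the
    rendered images, never the truth features. ``psf_choices`` draws the
    per-frame PSF scale from a set (emulating varied imaging depth).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    truth_state = truth_state or default_truth_state()
    phantom = phantom or default_phantom()
    noise = noise or NoiseConfig()
    rot_range = _broadcast3(rot_range_deg, "rot_range_deg")
    trans_range = _broadcast3(trans_range_mm, "trans_range_mm")
    rng = np.random.default_rng(seed)
    nominal = RigidTransform.identity()
    h, w = image_size
    centre_metric = np.array([0.5 * (w - 1) * truth_state.sx, 0.5 * (h - 1) * truth_state.sy, 0.0])
    pivot = truth_state.t_ur_transform.apply(centre_metric)

    frames: list[SyntheticFrame] = []
    for i in range(n_frames):
        for _attempt in range(100):
            pose = _sample_pose(rng, rot_range, trans_range, nominal, pivot)
            feats = project_wires(truth_state, pose, phantom, image_size)
            if _layers_complete(feats, phantom):
                break
        else:
            raise ConfigurationError(
                "could not place the phantom fully in view after 100 retries; "
                "check the truth state, phantom and pose ranges"
            )
        psf = noise.psf_sigma_px if psf_choices is None else float(rng.choice(psf_choices))
        frame_noise = replace(noise, psf_sigma_px=psf)
        img = render_frame(feats, image_size, frame_noise, seed=int(rng.integers(2**31)))
        recorded = _perturb_pose(pose, noise, rng)
        frames.append(
            SyntheticFrame(
                frame_index=i,
                image=img,
                pose_recorded=recorded,
                pose_true=pose,
                truth_features=tuple(feats),
                psf_sigma_px=psf,
            )
        )
    return SyntheticDataset(tuple(frames), truth_state, phantom, seed)


def truth_detection(frame: SyntheticFrame, n_layers: int = 3) -> FrameDetection:
    """Build a :class:`FrameDetection` directly from a frame's truth
    features — the noiseless oracle used by closure tests and by the
    noiseless-recovery acceptance check (it bypasses pixel quantization
    entirely)."""
    triplets = []
    by_layer: dict[int, dict[str, TruthFeature]] = {}
    for f in frame.truth_features:
        by_layer.setdefault(f.layer_index, {})[f.label] = f
    for layer_index in sorted(by_layer):
        feats = by_layer[layer_index]
        if set(feats) != {"A", "B", "C"}:
            continue
        pts = [
            CandidatePoint(u=feats[lab].u, v=feats[lab].v, response=1.0, scale=1.0)
            for lab in ("A", "B", "C")
        ]
        pts.sort(key=lambda p: (p.u, p.v))
        triplets.append(Triplet(tuple(pts), slope=0.0, layer_index=layer_index))
    return FrameDetection(frame.frame_index, tuple(triplets), k_main=0.0)
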