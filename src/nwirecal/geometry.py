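"""Rigid-transform algebra and the N-wire phantom geometric model.

Coordinate chain
----------------
Four frames are involved in freehand-ultrasound probe calibration:

* ``U`` — the ultrasound image plane (2D pixels lifted to mm via the pixel
  scales ``sx``, ``sy``; the image lies in the plane ``z_U = 0``),
* ``R`` — the tracking sensor rigidly mounted on the probe,
* ``W`` — the world frame of the tracking system,
* ``P`` — the N-wire phantom frame.

``T_AB`` maps points from frame A to frame B. ``T_RW`` (sensor pose) is
measured by the tracker; ``T_UR`` (the calibration matrix) and ``T_WP``
are the unknowns, together with the pixel scales — 14 free parameters.

Conventions
-----------
* Euler angles: intrinsic Z-Y-X (yaw, pitch, roll), radians.
* Pixels: origin at the top-left corner, ``u`` rightward along columns,
  ``v`` downward along rows, 0-based.
* Transforms are stored as rotation matrix + translation vector; 4x4
  homogeneous matrices appear only at I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import AlphaRangeError, DegenerateGeometryError

__all__ = [
    "RigidTransform",
    "PoseParams6",
    "CalibrationState",
    "NWireLayer",
    "PhantomGeometry",
    "Correspondence",
    "pose_to_matrix",
    "matrix_to_pose",
    "compose",
    "image_point_to_metric",
    "alpha_from_triplet",
    "middle_point_phantom",
    "default_phantom",
]

_EULER_SEQ = "ZYX"  # intrinsic yaw-pitch-roll


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {np.shape(x)}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    return v


@dataclass(frozen=True)
class RigidTransform:
    """A rigid-body transform ``x -> R x + t`` (rotation dimensionless,
    translation in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = _as_vec3(self.translation, "translation")
        if r.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {r.shape}")
        if not np.all(np.isfinite(r)):
            raise ValueError("rotation must be finite")
        defect = np.abs(r.T @ r - np.eye(3)).max()
        if defect > 1e-6:
            raise ValueError(f"rotation is not orthogonal (defect {defect:.2e})")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation has determinant -1 (reflection, not rigid)")
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 homogeneous matrix, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        """Apply to one point (3,) or a stack of points (..., 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Composition ``(t1 o t2)(x) = t1(t2(x))``."""
    return t1 @ t2


@dataclass(frozen=True)
class PoseParams6:
    """6-DoF pose: intrinsic Z-Y-X Euler angles (rad) + translation (mm)."""

    angles: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        a = _as_vec3(self.angles, "angles")
        t = _as_vec3(self.translation, "translation")
        a.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "translation", t)

    @classmethod
    def zero(cls) -> "PoseParams6":
        return cls(np.zeros(3), np.zeros(3))


def pose_to_matrix(p: PoseParams6) -> RigidTransform:
    """Rotation from intrinsic Z-Y-X Euler angles, then translation."""
    rot = Rotation.from_euler(_EULER_SEQ, p.angles).as_matrix()
    return RigidTransform(rot, p.translation)


def matrix_to_pose(t: RigidTransform) -> PoseParams6:
    """Inverse of :func:`pose_to_matrix`.

    At gimbal lock (pitch = +-pi/2) the third angle is set to 0; the
    returned pose still reproduces the input matrix.
    """
    with warnings.catch_warnings():
        # scipy warns when it applies exactly the convention we document
        warnings.filterwarnings("ignore", message=".*[Gg]imbal lock.*")
        angles = Rotation.from_matrix(t.rotation).as_euler(_EULER_SEQ)
    return PoseParams6(angles, t.translation)


@dataclass(frozen=True)
class CalibrationState:
    """The 14 unknowns of the calibration problem: the image-to-sensor
    transform ``T_UR``, the world-to-phantom transform ``T_WP`` and the
    pixel scales ``sx``, ``sy`` (mm/pixel)."""

    t_ur: PoseParams6
    t_wp: PoseParams6
    sx: float
    sy: float

    def __post_init__(self) -> None:
        if not (self.sx > 0 and self.sy > 0):
            raise ValueError("pixel scales sx, sy must be positive")

    @property
    def t_ur_transform(self) -> RigidTransform:
        return pose_to_matrix(self.t_ur)

    @property
    def t_wp_transform(self) -> RigidTransform:
        return pose_to_matrix(self.t_wp)

    def as_vector(self) -> np.ndarray:
        """Flatten to the 14-vector (ur angles, ur trans, wp angles,
        wp trans, sx, sy)."""
        return np.concatenate(
            [
                self.t_ur.angles,
                self.t_ur.translation,
                self.t_wp.angles,
                self.t_wp.translation,
                [self.sx, self.sy],
            ]
        )

    @classmethod
    def from_vector(cls, v) -> "CalibrationState":
        v = np.asarray(v, dtype=float).reshape(-1)
        if v.shape != (14,):
            raise ValueError(f"expected 14 parameters, got {v.shape}")
        return cls(
            PoseParams6(v[0:3], v[3:6]),
            PoseParams6(v[6:9], v[9:12]),
            float(v[12]),
            float(v[13]),
        )


def image_point_to_metric(u, v, sx: float, sy: float) -> np.ndarray:
    """Lift pixel coordinates to the metric image frame: (sx*u, sy*v, 0).

    Accepts scalars or equal-length arrays; homogeneous lifting is the
    caller's concern.
    """
    if not (sx > 0 and sy > 0):
        raise ValueError("pixel scales must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    out = np.stack([sx * u, sy * v, np.zeros_like(u)], axis=-1)
    return out


@dataclass(frozen=True)
class NWireLayer:
    """One layer of the N-wire phantom.

    Vertices (mm, phantom frame): ``a`` is the anchor, ``b`` is displaced
    from ``a`` along the wire-spacing axis, ``c`` along the wire-length
    axis, ``d`` is the opposite corner. The two side wires run a->c and
    b->d; the diagonal wire runs a->d.
    """

    layer_index: int
    z: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = _as_vec3(getattr(self, name), name)
            v.setflags(write=False)
            object.__setattr__(self, name, v)
        ab = self.b - self.a
        ac = self.c - self.a
        if np.linalg.norm(ab) <= 0 or np.linalg.norm(ac) <= 0:
            raise ValueError("layer vertices must be distinct along both axes")
        if np.abs(self.d - (self.a + ab + ac)).max() > 1e-6:
            raise ValueError("vertex d must equal a + (b-a) + (c-a)")
        # parallelogram identity above already forces coplanarity, but keep
        # the explicit check for loaders that relax it later
        n = np.cross(ab, ac)
        if abs(np.dot(self.d - self.a, n)) / max(np.linalg.norm(n), 1e-12) > 1e-6:
            raise ValueError("layer vertices are not coplanar")

    @property
    def wire_spacing(self) -> float:
        return float(np.linalg.norm(self.b - self.a))

    @property
    def wire_length(self) -> float:
        return float(np.linalg.norm(self.c - self.a))

    def wires(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """The three wire segments with their feature labels: the a->c
        side wire images as point A, the diagonal a->d as B and the b->d
        side wire as C."""
        return [("A", self.a, self.c), ("B", self.a, self.d), ("C", self.b, self.d)]


@dataclass(frozen=True)
class PhantomGeometry:
    """Ordered stack of N-wire layers (top to bottom in the image)."""

    layers: tuple[NWireLayer, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        if not layers:
            raise ValueError("phantom needs at least one layer")
        zs = np.array([lay.z for lay in layers])
        dz = np.diff(zs)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("layer z values must be strictly monotone")
        object.__setattr__(self, "layers", layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, index: int) -> NWireLayer:
        for lay in self.layers:
            if lay.layer_index == index:
                return lay
        raise KeyError(f"no layer with index {index}")


def default_phantom(
    n_layers: int = 3,
    layer_spacing: float = 10.0,
    wire_spacing: float = 25.0,
    wire_length: float = 25.0,
    top_z: float = 0.0,
) -> PhantomGeometry:
    """The default 3-layer phantom: 10 mm between layers, 25 mm between
    the parallel wires (the open-source N-wire layout), symmetric 25 mm
    wire length."""
    layers = []
    for i in range(n_layers):
        z = top_z - i * layer_spacing
        a = np.array([0.0, 0.0, z])
        b = a + np.array([wire_spacing, 0.0, 0.0])
        c = a + np.array([0.0, wire_length, 0.0])
        d = a + np.array([wire_spacing, wire_length, 0.0])
        layers.append(NWireLayer(i, z, a, b, c, d))
    return PhantomGeometry(tuple(layers))


def alpha_from_triplet(a_px, b_px, c_px, tol: float = 0.05) -> float:
    """Distance ratio ``alpha = |B-A| / |C-A|`` of an image triplet.

    The ratio locates the diagonal-wire crossing B along the phantom
    diagonal by similar triangles. Values outside ``[-tol, 1+tol]``
    (default tol 0.05, allowing slightly oblique insonification) raise
    :class:`AlphaRangeError`; coincident A and C raise
    :class:`DegenerateGeometryError`.
    """
    a = np.asarray(a_px, dtype=float)
    b = np.asarray(b_px, dtype=float)
    c = np.asarray(c_px, dtype=float)
    denom = float(np.linalg.norm(c - a))
    if denom < 1e-12:
        raise DegenerateGeometryError("triplet endpoints A and C coincide")
    alpha = float(np.linalg.norm(b - a)) / denom
    if not (-tol <= alpha <= 1.0 + tol):
        raise AlphaRangeError(
            f"alpha {alpha:.4f} outside [{-tol}, {1 + tol}]: mislabeled triplet"
        )
    return alpha


def middle_point_phantom(alpha: float, layer: NWireLayer) -> np.ndarray:
    """Phantom-frame position of the diagonal crossing B: ``a + alpha*(d-a)``.

    In the layer's local axes this satisfies x = alpha*|a-b| and
    y = alpha*|a-c|; the z coordinate is the (known, fixed) layer height.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return layer.a + alpha * (layer.d - layer.a)


@dataclass(frozen=True)
class Correspondence:
    """One (image point, phantom point, pose) triple consumed by the
    solver and by every error metric.

    ``pixel`` is the detected B point in pixels, ``x_p`` the phantom-frame
    position reconstructed from ``alpha``, ``pose`` the recorded sensor
    pose ``T_RW`` for the frame.
    """

    frame_index: int
    layer_index: int
    pixel: np.ndarray
    alpha: float
    x_p: np.ndarray
    pose: RigidTransform

    def __post_init__(self) -> None:
        px = np.asarray(self.pixel, dtype=float).reshape(2)
        xp = _as_vec3(self.x_p, "x_p")
        px.setflags(write=False)
        xp.setflags(write=False)
        object.__setattr__(self, "pixel", px)
        object.__setattr__(self, "x_p", xp)
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("correspondence alpha must lie in [0, 1]")
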