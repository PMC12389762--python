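"""File formats and configuration.

* pose tables: CSV (``frame,r00..r22,tx,ty,tz``, sensor->world) or JSON
  lists of 4x4 row-major matrices; rotations with small orthogonality
  defects (< 1e-4) are projected to the nearest rotation,
* image sequences: a directory of PNG/TIFF frames (lexicographic order)
  or a single MetaImage (.mha/.mhd) stack,
* phantom geometry: YAML/JSON with per-layer vertices a, b, c, d (mm),
* calibration results: JSON with full-precision matrices,
* run configuration: YAML mapping onto the parameter dataclasses, with
  unknown keys rejected explicitly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .detect import DetectionParams
from .exceptions import FormatError
from .filtering import FilterParams
from .geometry import NWireLayer, PhantomGeometry, RigidTransform
from .simulate import NoiseConfig
from .solver import CalibrationResult, CalibrationState, RansacParams
from .geometry import matrix_to_pose

__all__ = [
    "read_pose_table",
    "write_pose_table",
    "read_image_sequence",
    "load_phantom",
    "save_phantom",
    "write_calibration",
    "read_calibration",
    "RunConfig",
]

_POSE_COLUMNS = ["frame"] + [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz"]


def _nearest_rotation(r: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(r)
    return u @ vt


def _validate_pose_matrix(r: np.ndarray, t: np.ndarray, where: str) -> RigidTransform:
    defect = np.abs(r.T @ r - np.eye(3)).max()
    if defect > 1e-4:
        raise FormatError(f"{where}: rotation violates orthogonality (defect {defect:.2e})")
    if np.linalg.det(r) < 0:
        raise FormatError(f"{where}: rotation has determinant -1 (reflection)")
    return RigidTransform(_nearest_rotation(r), t)


def read_pose_table(path) -> list[tuple[int, RigidTransform]]:
    """Read per-frame sensor->world poses from CSV or JSON.

    Frame indices must be unique; the list is returned sorted by frame
    index. Rows with a non-rigid matrix raise :class:`FormatError`
    naming the offending row.
    """
    path = Path(path)
    out: list[tuple[int, RigidTransform]] = []
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for i, entry in enumerate(data):
            m = np.asarray(entry, dtype=float)
            if m.shape != (4, 4):
                raise FormatError(f"pose entry {i}: expected a 4x4 matrix, got {m.shape}")
            out.append((i, _validate_pose_matrix(m[:3, :3], m[:3, 3], f"pose entry {i}")))
    else:
        df = pd.read_csv(path)
        missing = [c for c in _POSE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"pose table missing columns: {missing}")
        for _, row in df.iterrows():
            idx = int(row["frame"])
            r = np.array([[row[f"r{i}{j}"] for j in range(3)] for i in range(3)], dtype=float)
            t = np.array([row["tx"], row["ty"], row["tz"]], dtype=float)
            out.append((idx, _validate_pose_matrix(r, t, f"frame {idx}")))
    indices = [i for i, _ in out]
    if len(set(indices)) != len(indices):
        raise FormatError("duplicate frame indices in pose table")
    return sorted(out, key=lambda x: x[0])


def write_pose_table(poses: dict[int, RigidTransform] | list[RigidTransform], path) -> None:
    if not isinstance(poses, dict):
        poses = dict(enumerate(poses))
    rows = []
    for idx in sorted(poses):
        p = poses[idx]
        row = {"frame": idx}
        for i in range(3):
            for j in range(3):
                row[f"r{i}{j}"] = p.rotation[i, j]
        row["tx"], row["ty"], row["tz"] = p.translation
        rows.append(row)
    pd.DataFrame(rows, columns=_POSE_COLUMNS).to_csv(path, index=False)


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = (0.2989 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2])
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def read_image_sequence(path) -> list[np.ndarray]:
    """Load frames from a directory of PNG/TIFF files (name order) or a
    MetaImage volume; frames are returned as 8-bit grayscale arrays of
    identical shape."""
    path = Path(path)
    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not files:
            raise FormatError(f"no PNG/TIFF frames found in {path}")
        for f in files:
            try:
                frames.append(_to_gray(np.asarray(iio.imread(f))))
            except (OSError, ValueError) as exc:
                raise FormatError(f"cannot read image {f}: {exc}") from exc
    elif path.suffix.lower() in {".mha", ".mhd"}:
        import SimpleITK as sitk

        vol = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
        if vol.ndim == 2:
            vol = vol[None]
        frames = [_to_gray(sl) for sl in vol]
    else:
        raise FormatError(f"unsupported image input: {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"frames have mixed dimensions: {sorted(shapes)}")
    return frames


def load_phantom(path) -> PhantomGeometry:
    """Load an N-wire phantom description (YAML or JSON) of the form
    ``layers: [{z: 0, a: [..], b: [..], c: [..], d: [..]}, ...]``."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "layers" not in data:
        raise FormatError("phantom file must contain a 'layers' list")
    layers = []
    for i, entry in enumerate(data["layers"]):
        try:
            layers.append(
                NWireLayer(
                    layer_index=int(entry.get("layer_index", i)),
                    z=float(entry["z"]),
                    a=np.asarray(entry["a"], dtype=float),
                    b=np.asarray(entry["b"], dtype=float),
                    c=np.asarray(entry["c"], dtype=float),
                    d=np.asarray(entry["d"], dtype=float),
                )
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"phantom layer {i}: {exc}") from exc
    return PhantomGeometry(tuple(layers))


def save_phantom(phantom: PhantomGeometry, path) -> None:
    data = {
        "layers": [
            {
                "layer_index": lay.layer_index,
                "z": lay.z,
                "a": lay.a.tolist(),
                "b": lay.b.tolist(),
                "c": lay.c.tolist(),
                "d": lay.d.tolist(),
            }
            for lay in phantom.layers
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


_CALIB_REQUIRED = {"t_ur", "t_wp", "sx", "sy", "mean_error", "max_error", "inlier_mask", "residuals"}


def write_calibration(result: CalibrationResult, path) -> None:
    """Serialise a calibration result to JSON (matrices row-major, full
    float precision)."""
    s = result.state
    from .geometry import pose_to_matrix

    data = {
        "schema_version": 1,
        "t_ur": pose_to_matrix(s.t_ur).as_matrix().tolist(),
        "t_wp": pose_to_matrix(s.t_wp).as_matrix().tolist(),
        # pose parameters are the primary record: they reconstruct the
        # matrices bit for bit (matrix -> Euler loses the last ulp)
        "t_ur_pose": {"angles": s.t_ur.angles.tolist(), "translation": s.t_ur.translation.tolist()},
        "t_wp_pose": {"angles": s.t_wp.angles.tolist(), "translation": s.t_wp.translation.tolist()},
        "sx": s.sx,
        "sy": s.sy,
        "mean_error": result.mean_error,
        "max_error": result.max_error,
        "n_inliers": result.n_inliers,
        "inlier_mask": np.asarray(result.inlier_mask, dtype=bool).tolist(),
        "residuals": np.asarray(result.residuals, dtype=float).tolist(),
        "n_lm_evaluations": result.n_lm_evaluations,
        "method": result.method,
        "converged": result.converged,
    }
    Path(path).write_text(json.dumps(data))


def read_calibration(path) -> CalibrationResult:
    """Read a calibration result back; missing required fields raise
    :class:`FormatError` naming the field, unknown extra keys are
    accepted with a warning."""
    data = json.loads(Path(path).read_text())
    for field_name in sorted(_CALIB_REQUIRED):
        if field_name not in data:
            raise FormatError(f"calibration file missing field '{field_name}'")
    known = _CALIB_REQUIRED | {
        "schema_version",
        "n_inliers",
        "n_lm_evaluations",
        "method",
        "converged",
        "t_ur_pose",
        "t_wp_pose",
    }
    extra = set(data) - known
    if extra:
        warnings.warn(f"calibration file has unrecognised keys {sorted(extra)}; ignoring")
    if "t_ur_pose" in data and "t_wp_pose" in data:
        from .geometry import PoseParams6

        ur_pose = PoseParams6(
            np.asarray(data["t_ur_pose"]["angles"], float),
            np.asarray(data["t_ur_pose"]["translation"], float),
        )
        wp_pose = PoseParams6(
            np.asarray(data["t_wp_pose"]["angles"], float),
            np.asarray(data["t_wp_pose"]["translation"], float),
        )
    else:  # legacy files carry only the matrices
        ur_pose = matrix_to_pose(RigidTransform.from_matrix(np.asarray(data["t_ur"], float)))
        wp_pose = matrix_to_pose(RigidTransform.from_matrix(np.asarray(data["t_wp"], float)))
    state = CalibrationState(ur_pose, wp_pose, float(data["sx"]), float(data["sy"]))
    return CalibrationResult(
        state=state,
        inlier_mask=np.asarray(data["inlier_mask"], dtype=bool),
        residuals=np.asarray(data["residuals"], dtype=float),
        mean_error=float(data["mean_error"]),
        max_error=float(data["max_error"]),
        n_lm_evaluations=int(data.get("n_lm_evaluations", 0)),
        converged=bool(data.get("converged", True)),
        method=str(data.get("method", "ransac+lm")),
    )


_SECTION_TYPES = {
    "detection": DetectionParams,
    "filtering": FilterParams,
    "ransac": RansacParams,
    "simulator": NoiseConfig,
}


@dataclasses.dataclass
class RunConfig:
    """Aggregate run configuration: one section per parameter dataclass
    plus the phantom path, seed and verbosity. Round-trips losslessly
    through YAML; unknown keys are rejected with an explicit error."""

    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    filtering: FilterParams = dataclasses.field(default_factory=FilterParams)
    ransac: RansacParams = dataclasses.field(default_factory=RansacParams)
    simulator: NoiseConfig = dataclasses.field(default_factory=NoiseConfig)
    phantom_path: str | None = None
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError("run config must be a mapping")
        top_known = set(_SECTION_TYPES) | {"phantom_path", "seed", "verbosity"}
        unknown = set(raw) - top_known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for section, typ in _SECTION_TYPES.items():
            entries = raw.get(section, {}) or {}
            field_names = {f.name for f in dataclasses.fields(typ)}
            bad = set(entries) - field_names
            if bad:
                raise FormatError(f"unknown keys in '{section}': {sorted(bad)}")
            for name in ("se_angles", "scales"):
                if name in entries and isinstance(entries[name], list):
                    entries[name] = tuple(entries[name])
            kwargs[section] = typ(**entries)
        return cls(
            phantom_path=raw.get("phantom_path"),
            seed=int(raw.get("seed", 0)),
            verbosity=str(raw.get("verbosity", "info")),
            **kwargs,
        )

    def to_yaml(self, path) -> None:
        data: dict = {}
        for section, typ in _SECTION_TYPES.items():
            d = dataclasses.asdict(getattr(self, section))
            for k, v in list(d.items()):
                if isinstance(v, tuple):
                    d[k] = list(v)
            data[section] = d
        data["phantom_path"] = self.phantom_path
        data["seed"] = self.seed
        data["verbosity"] = self.verbosity
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
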