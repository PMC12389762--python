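"""The 14-parameter calibration estimate: Levenberg-Marquardt nonlinear
least squares wrapped in a RANSAC outlier-rejection loop.

Each correspondence contributes the 3-vector residual

    r_i = X_iP - T_WP * T_RW * T_UR * (sx*u_i, sy*v_i, 0)

with the frame's own recorded pose T_RW; the unknowns are the two 6-DoF
transforms plus the pixel scales (parameterized internally through their
logarithms so positivity is structural). RANSAC repeatedly fits minimal
correspondence subsets, scores inliers by the Euclidean residual against
``eps_inlier`` (mm, phantom frame) and refines the largest inlier set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .exceptions import (
    AlphaRangeError,
    DegenerateGeometryError,
    FormatError,
    IllConditionedWarning,
    InitializationFailureError,
    RobustFailureError,
    UnderdeterminedError,
)
from .filtering import FrameDetection
from .geometry import (
    CalibrationState,
    Correspondence,
    PhantomGeometry,
    PoseParams6,
    RigidTransform,
    alpha_from_triplet,
    matrix_to_pose,
    middle_point_phantom,
    pose_to_matrix,
)

__all__ = [
    "RansacParams",
    "CalibrationResult",
    "build_correspondences",
    "residual_vector",
    "initial_state",
    "solve_lm",
    "solve_lm_result",
    "solve_ransac_lm",
    "check_pose_diversity",
]

logger = logging.getLogger(__name__)

MIN_CORRESPONDENCES = 5  # >= 15 scalar equations for 14 unknowns


@dataclass(frozen=True)
class RansacParams:
    """RANSAC loop settings: 3000 iterations, minimal subsets of 10
    correspondences, inlier threshold 0.5 mm. The loop stops early when
    the inlier ratio reaches ``inlier_stop_ratio`` or when the best
    inlier set has not improved for ``max_stall_iterations`` draws (the
    inlier set has converged)."""

    n_iterations: int = 3000
    subset_size: int = 10
    eps_inlier: float = 0.5
    inlier_stop_ratio: float = 0.9
    seed: int = 0
    max_stall_iterations: int = 150

    def __post_init__(self) -> None:
        if self.subset_size < MIN_CORRESPONDENCES:
            raise ValueError(f"subset_size must be >= {MIN_CORRESPONDENCES}")
        if self.eps_inlier <= 0:
            raise ValueError("eps_inlier must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    """Estimate plus diagnostics.

    ``residuals`` holds the per-correspondence Euclidean errors (mm)
    under the final state; ``mean_error``/``max_error`` summarise the
    inlier residuals; ``n_lm_evaluations`` counts residual-function
    evaluations across all L-M solves.
    """

    state: CalibrationState
    inlier_mask: np.ndarray
    residuals: np.ndarray
    mean_error: float
    max_error: float
    n_lm_evaluations: int
    converged: bool = True
    method: str = "ransac+lm"

    @property
    def n_inliers(self) -> int:
        return int(np.count_nonzero(self.inlier_mask))

    def summary(self) -> str:
        s = self.state
        ur = pose_to_matrix(s.t_ur)
        lines = [
            "N-wire probe calibration results",
            "=" * 48,
            f"method:            {self.method}",
            f"correspondences:   {len(self.residuals)}",
            f"inliers:           {self.n_inliers}",
            f"mean error (mm):   {self.mean_error:.4f}",
            f"max error (mm):    {self.max_error:.4f}",
            f"pixel scale sx:    {s.sx:.5f} mm/px",
            f"pixel scale sy:    {s.sy:.5f} mm/px",
            "T_UR Euler ZYX (deg): "
            + np.array2string(np.rad2deg(s.t_ur.angles), precision=3),
            "T_UR translation (mm): "
            + np.array2string(ur.translation, precision=3),
            f"L-M evaluations:   {self.n_lm_evaluations}",
        ]
        return "\n".join(lines)


def build_correspondences(
    detections: list[FrameDetection],
    poses: dict[int, RigidTransform] | list[RigidTransform],
    phantom: PhantomGeometry,
) -> list[Correspondence]:
    """Turn per-frame detections into solver correspondences.

    For each detected layer triplet: alpha from the labeled A/B/C
    pixels, the phantom-frame B position from alpha, and one
    correspondence carrying the B pixel and the frame's recorded pose.
    Triplets failing the alpha range check are dropped (counted in the
    log); a detection without a pose raises :class:`FormatError`.

    Frames that detected fewer rows than the phantom has layers are
    skipped entirely: row order alone cannot identify *which* layers
    remain, and a mislabeled layer would inject a gross (layer-spacing
    sized) error.
    """
    if isinstance(poses, dict):
        pose_map = poses
    else:
        pose_map = dict(enumerate(poses))
    out: list[Correspondence] = []
    n_dropped = 0
    n_incomplete = 0
    for det in detections:
        if det.n_layers_detected < phantom.n_layers:
            if det.n_layers_detected:
                n_incomplete += 1
            continue
        if det.frame_index not in pose_map:
            raise FormatError(f"no pose recorded for frame {det.frame_index}")
        pose = pose_map[det.frame_index]
        pts = {}
        for layer_index, label, u, v in det.labeled_points():
            pts.setdefault(layer_index, {})[label] = np.array([u, v])
        for layer_index, labeled in pts.items():
            try:
                alpha = alpha_from_triplet(labeled["A"], labeled["B"], labeled["C"])
            except (AlphaRangeError, DegenerateGeometryError):
                n_dropped += 1
                continue
            alpha = float(np.clip(alpha, 0.0, 1.0))
            layer = phantom.layer(layer_index)
            x_p = middle_point_phantom(alpha, layer)
            out.append(
                Correspondence(
                    frame_index=det.frame_index,
                    layer_index=layer_index,
                    pixel=labeled["B"],
                    alpha=alpha,
                    x_p=x_p,
                    pose=pose,
                )
            )
    if n_dropped:
        logger.info("dropped %d correspondences failing the alpha range check", n_dropped)
    if n_incomplete:
        logger.info("skipped %d frames with an incomplete layer stack", n_incomplete)
    return out


class _CorrArrays:
    """Stacked numpy views of a correspondence list for fast residuals."""

    def __init__(self, corrs: list[Correspondence]):
        self.n = len(corrs)
        self.uv = np.array([c.pixel for c in corrs], dtype=float).reshape(self.n, 2)
        self.x_p = np.array([c.x_p for c in corrs], dtype=float).reshape(self.n, 3)
        self.r_rw = np.array([c.pose.rotation for c in corrs], dtype=float).reshape(self.n, 3, 3)
        self.t_rw = np.array([c.pose.translation for c in corrs], dtype=float).reshape(self.n, 3)

    def subset(self, idx) -> "_CorrArrays":
        out = object.__new__(_CorrArrays)
        out.n = len(idx)
        out.uv = self.uv[idx]
        out.x_p = self.x_p[idx]
        out.r_rw = self.r_rw[idx]
        out.t_rw = self.t_rw[idx]
        return out


def _euler_zyx_matrix(a: np.ndarray) -> np.ndarray:
    """Intrinsic Z-Y-X rotation matrix (hot path; avoids object churn)."""
    cz, sz = np.cos(a[0]), np.sin(a[0])
    cy, sy = np.cos(a[1]), np.sin(a[1])
    cx, sx = np.cos(a[2]), np.sin(a[2])
    return np.array(
        [
            [cz * cy, cz * sy * sx - sz * cx, cz * sy * cx + sz * sx],
            [sz * cy, sz * sy * sx + cz * cx, sz * sy * cx - cz * sx],
            [-sy, cy * sx, cy * cx],
        ]
    )


def _components_from_params(arr: _CorrArrays, x: np.ndarray) -> np.ndarray:
    """Residual components straight from the 14-parameter vector."""
    r_ur = _euler_zyx_matrix(x[0:3])
    t_ur = x[3:6]
    r_wp = _euler_zyx_matrix(x[6:9])
    t_wp = x[9:12]
    sx, sy = np.exp(x[12]), np.exp(x[13])
    x_u = np.column_stack([arr.uv[:, 0] * sx, arr.uv[:, 1] * sy, np.zeros(arr.n)])
    x_r = x_u @ r_ur.T + t_ur
    x_w = np.einsum("nij,nj->ni", arr.r_rw, x_r) + arr.t_rw
    pred = x_w @ r_wp.T + t_wp
    return (arr.x_p - pred).ravel()


def _predict(arr: _CorrArrays, ur: RigidTransform, wp: RigidTransform, sx: float, sy: float) -> np.ndarray:
    x_u = np.column_stack([arr.uv[:, 0] * sx, arr.uv[:, 1] * sy, np.zeros(arr.n)])
    x_r = x_u @ ur.rotation.T + ur.translation
    x_w = np.einsum("nij,nj->ni", arr.r_rw, x_r) + arr.t_rw
    return x_w @ wp.rotation.T + wp.translation


def _components_from_state(arr: _CorrArrays, state: CalibrationState) -> np.ndarray:
    pred = _predict(arr, state.t_ur_transform, state.t_wp_transform, state.sx, state.sy)
    return (arr.x_p - pred).ravel()


def residual_vector(state: CalibrationState, corrs: list[Correspondence]) -> np.ndarray:
    """Per-correspondence Euclidean residuals (mm, phantom frame)."""
    if not corrs:
        return np.zeros(0)
    arr = _CorrArrays(corrs)
    comp = _components_from_state(arr, state).reshape(-1, 3)
    return np.linalg.norm(comp, axis=1)


def _pack(state: CalibrationState) -> np.ndarray:
    return np.concatenate(
        [
            state.t_ur.angles,
            state.t_ur.translation,
            state.t_wp.angles,
            state.t_wp.translation,
            [np.log(state.sx), np.log(state.sy)],
        ]
    )


def _unpack(x: np.ndarray) -> CalibrationState:
    return CalibrationState(
        PoseParams6(x[0:3], x[3:6]),
        PoseParams6(x[6:9], x[9:12]),
        float(np.exp(x[12])),
        float(np.exp(x[13])),
    )


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src points onto dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    h = (src - mu_s).T @ (dst - mu_d)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, mu_d - r @ mu_s)


def _procrustes_polish(
    arr: _CorrArrays, ur: RigidTransform, sx: float, sy: float, sweeps: int = 3
) -> tuple[RigidTransform, RigidTransform]:
    """Alternating closed-form rigid fits: with T_UR fixed, the optimal
    T_WP is a Kabsch fit of the world-frame image points onto the
    phantom points, and vice versa."""
    x_u = np.column_stack([arr.uv[:, 0] * sx, arr.uv[:, 1] * sy, np.zeros(arr.n)])
    wp = RigidTransform.identity()
    for _ in range(sweeps):
        x_r = x_u @ ur.rotation.T + ur.translation
        x_w = np.einsum("nij,nj->ni", arr.r_rw, x_r) + arr.t_rw
        wp = _kabsch(x_w, arr.x_p)
        # back out the sensor-frame targets and refit T_UR
        y_w = (arr.x_p - wp.translation) @ wp.rotation
        y_r = np.einsum("nji,nj->ni", arr.r_rw, y_w - arr.t_rw)
        ur = _kabsch(x_u, y_r)
    return ur, wp


def initial_state(
    corrs: list[Correspondence],
    phantom: PhantomGeometry | None = None,
    depth_hint: float | None = None,
    image_height: int | None = None,
    n_restarts: int = 50,
    seed: int = 0,
) -> CalibrationState:
    """Deterministic multi-restart initialization.

    Pixel scales are seeded from ``depth_hint / image_height`` when
    given, else 0.1 mm/px. Random T_UR guesses (identity first) within
    physically plausible ranges are polished by alternating Kabsch fits
    and scored by mean residual; the best becomes the L-M start.
    """
    if len(corrs) < MIN_CORRESPONDENCES:
        raise UnderdeterminedError(
            f"initialization needs >= {MIN_CORRESPONDENCES} correspondences"
        )
    if depth_hint is not None and image_height:
        sx0 = sy0 = float(depth_hint) / float(image_height)
    else:
        sx0 = sy0 = 0.1
    arr = _CorrArrays(corrs)
    rng = np.random.default_rng(seed)
    best_state, best_score = None, np.inf
    for k in range(max(n_restarts, 1)):
        if k == 0:
            ur0 = RigidTransform.identity()
        else:
            axis = rng.normal(size=3)
            axis /= max(np.linalg.norm(axis), 1e-12)
            angle = rng.uniform(0.0, 0.35)
            rot = Rotation.from_rotvec(angle * axis).as_matrix()
            ur0 = RigidTransform(rot, rng.uniform(-50.0, 50.0, size=3))
        ur, wp = _procrustes_polish(arr, ur0, sx0, sy0)
        state = CalibrationState(matrix_to_pose(ur), matrix_to_pose(wp), sx0, sy0)
        res = _components_from_state(arr, state).reshape(-1, 3)
        score = float(np.linalg.norm(res, axis=1).mean())
        if np.isfinite(score) and score < best_score:
            best_score, best_state = score, state
    if best_state is None:
        raise InitializationFailureError("no finite-residual initialization found")
    return best_state


def _solve_lm_arrays(
    arr: _CorrArrays,
    init: CalibrationState,
    loose: bool = False,
) -> tuple[CalibrationState, float, int, bool]:
    x0 = _pack(init)

    def fun(x):
        return _components_from_params(arr, x)

    tol = 1e-6 if loose else 1e-10
    max_iter = 50 if loose else 200
    res = least_squares(
        fun,
        x0,
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * (len(x0) + 1),
    )
    c0 = float(np.sum(fun(x0) ** 2))
    c1 = float(2.0 * res.cost)
    nfev = int(res.nfev) + 1
    if c1 > c0:  # never return a state worse than the initialization
        return init, c0, nfev, False
    return _unpack(res.x), c1, nfev, bool(res.status > 0)


def solve_lm(corrs: list[Correspondence], init: CalibrationState) -> CalibrationState:
    """Levenberg-Marquardt solve of the 14-parameter problem from the
    given initialization. Raises :class:`UnderdeterminedError` below 5
    correspondences; on non-convergence the best iterate is returned
    (and flagged in :func:`solve_lm_result`)."""
    if len(corrs) < MIN_CORRESPONDENCES:
        raise UnderdeterminedError(
            f"{len(corrs)} correspondences give {3 * len(corrs)} equations "
            "for 14 unknowns"
        )
    state, _, _, _ = _solve_lm_arrays(_CorrArrays(corrs), init)
    return state


def solve_lm_result(corrs: list[Correspondence], init: CalibrationState) -> CalibrationResult:
    """Plain L-M fit on all correspondences, packaged as a
    :class:`CalibrationResult` (every correspondence counted an inlier)."""
    if len(corrs) < MIN_CORRESPONDENCES:
        raise UnderdeterminedError(
            f"{len(corrs)} correspondences give {3 * len(corrs)} equations "
            "for 14 unknowns"
        )
    arr = _CorrArrays(corrs)
    state, _, nfev, converged = _solve_lm_arrays(arr, init)
    resid = np.linalg.norm(_components_from_state(arr, state).reshape(-1, 3), axis=1)
    mask = np.ones(len(corrs), dtype=bool)
    return CalibrationResult(
        state=state,
        inlier_mask=mask,
        residuals=resid,
        mean_error=float(resid.mean()),
        max_error=float(resid.max()),
        n_lm_evaluations=nfev,
        converged=converged,
        method="lm",
    )


def solve_ransac_lm(
    corrs: list[Correspondence],
    ransac: RansacParams | None = None,
    init: CalibrationState | None = None,
) -> CalibrationResult:
    """RANSAC-assisted L-M estimation.

    Each iteration draws ``subset_size`` correspondences without
    replacement, runs a capped L-M solve warm-started from ``init``,
    and counts inliers (residual < ``eps_inlier``) over the full set.
    The largest inlier set wins (earlier iteration on ties); a final
    tight L-M refinement on that set produces the returned state.
    """
    ransac = ransac or RansacParams()
    if len(corrs) < ransac.subset_size:
        raise ValueError(
            f"need at least subset_size={ransac.subset_size} correspondences, "
            f"got {len(corrs)}"
        )
    if init is None:
        init = initial_state(corrs, seed=ransac.seed)
    arr = _CorrArrays(corrs)
    rng = np.random.default_rng(ransac.seed)
    n = arr.n
    best_count, best_mask, best_state = -1, None, None
    total_nfev = 0
    stall = 0
    for _ in range(ransac.n_iterations):
        idx = rng.choice(n, size=ransac.subset_size, replace=False)
        state, _, nfev, _ = _solve_lm_arrays(arr.subset(idx), init, loose=True)
        total_nfev += nfev
        resid = np.linalg.norm(_components_from_state(arr, state).reshape(-1, 3), axis=1)
        mask = resid < ransac.eps_inlier
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask, best_state = count, mask, state
            stall = 0
        else:
            stall += 1
        if best_count >= ransac.inlier_stop_ratio * n:
            break
        if stall >= ransac.max_stall_iterations:
            break
    if best_count <= 0:
        raise RobustFailureError("RANSAC found no inliers")
    inlier_idx = np.nonzero(best_mask)[0]
    if best_count >= MIN_CORRESPONDENCES:
        final_state, _, nfev, converged = _solve_lm_arrays(arr.subset(inlier_idx), best_state)
        total_nfev += nfev
    else:
        final_state, converged = best_state, False
    resid = np.linalg.norm(_components_from_state(arr, final_state).reshape(-1, 3), axis=1)
    inlier_resid = resid[best_mask]
    return CalibrationResult(
        state=final_state,
        inlier_mask=best_mask,
        residuals=resid,
        mean_error=float(inlier_resid.mean()),
        max_error=float(inlier_resid.max()),
        n_lm_evaluations=total_nfev,
        converged=converged,
        method="ransac+lm",
    )


def check_pose_diversity(poses, min_spread_deg: float = 5.0) -> np.ndarray:
    """Per-axis rotational spread (deg) of a pose set, warning through
    :class:`IllConditionedWarning` when any axis spans less than
    ``min_spread_deg`` — the protocol of multi-axis rotations exists
    precisely to avoid poorly conditioned estimates."""
    poses = list(poses.values()) if isinstance(poses, dict) else list(poses)
    if not poses:
        return np.zeros(3)
    r0 = poses[0].rotation
    angles = np.array(
        [Rotation.from_matrix(r0.T @ p.rotation).as_rotvec(degrees=True) for p in poses]
    )
    spread = angles.max(axis=0) - angles.min(axis=0)
    if np.any(spread < min_spread_deg):
        warnings.warn(
            "pose set has rotational spread "
            f"{np.round(spread, 2)} deg (< {min_spread_deg} deg about some axis); "
            "the calibration may be ill-conditioned",
            IllConditionedWarning,
            stacklevel=2,
        )
    return spread
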