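"""Quantitative evaluation: detection rates, point-reconstruction error
and calibration reproducibility (CRE).

* recognition rate = N_detected / N_total, false detection rate =
  N_false / (N_false + N_detected), with greedy nearest-neighbour
  matching of detections to truth within a pixel tolerance;
* point reconstruction error e_i = || X_iP - T_WP T_RW T_UR X_iU ||
  summarised by its mean and max;
* CRE: the four image corners are mapped through each calibration
  session's own (sx, sy, T_UR) into the sensor frame; per corner the CR
  value is the mean distance of the mapped points to their centroid and
  CRE is the mean of the four CR values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CalibrationState, Correspondence, image_point_to_metric, pose_to_matrix
from .solver import CalibrationResult, residual_vector

__all__ = [
    "DetectionMetrics",
    "ErrorStats",
    "CREStats",
    "detection_metrics",
    "reconstruction_errors",
    "calibration_reproducibility",
]


@dataclass(frozen=True)
class DetectionMetrics:
    n_detected: int
    n_false: int
    n_total: int

    @property
    def recognition_rate(self) -> float:
        return self.n_detected / self.n_total

    @property
    def false_detection_rate(self) -> float:
        denom = self.n_false + self.n_detected
        if denom == 0:
            return 0.0
        return self.n_false / denom


@dataclass(frozen=True)
class ErrorStats:
    per_point: np.ndarray

    @property
    def n(self) -> int:
        return len(self.per_point)

    @property
    def valid(self) -> bool:
        return self.n > 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_point)) if self.valid else float("nan")

    @property
    def max(self) -> float:
        return float(np.max(self.per_point)) if self.valid else float("nan")


@dataclass(frozen=True)
class CREStats:
    per_corner: np.ndarray  # 4 CR values, mm

    @property
    def cre(self) -> float:
        return float(np.mean(self.per_corner))


def detection_metrics(detected_points, truth_points, match_tol: float = 5.0) -> DetectionMetrics:
    """Greedy nearest-neighbour matching of detections against truth.

    Pairs are matched in order of increasing distance; each truth point
    and each detection is used at most once, and only pairs closer than
    ``match_tol`` pixels count. Matched detections are correct
    (N_detected), unmatched detections are false positives.
    """
    truth = np.asarray(truth_points, dtype=float).reshape(-1, 2)
    if len(truth) == 0:
        raise ValueError("truth point set must be non-empty")
    det = np.asarray(detected_points, dtype=float).reshape(-1, 2)
    if len(det) == 0:
        return DetectionMetrics(0, 0, len(truth))
    d = np.linalg.norm(det[:, None, :] - truth[None, :, :], axis=2)
    pairs = [(d[i, j], i, j) for i in range(len(det)) for j in range(len(truth)) if d[i, j] <= match_tol]
    pairs.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    for _, i, j in pairs:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
    n_detected = len(used_det)
    return DetectionMetrics(n_detected, len(det) - n_detected, len(truth))


def reconstruction_errors(
    result: CalibrationResult,
    corrs: list[Correspondence],
    inliers_only: bool = False,
) -> ErrorStats:
    """Point-reconstruction errors of a calibration over a
    correspondence set (all points by default, RANSAC inliers only on
    request)."""
    errs = residual_vector(result.state, corrs)
    if inliers_only:
        errs = errs[np.asarray(result.inlier_mask, dtype=bool)]
    return ErrorStats(errs)


def calibration_reproducibility(
    states: list[CalibrationState],
    image_size: tuple[int, int],
) -> CREStats:
    """Calibration reproducibility error across repeated sessions.

    Each state maps the four image corners (scaled by its own sx, sy)
    through its own T_UR into the sensor frame; CR per corner is the
    mean distance to the centroid over sessions, CRE the mean CR.
    """
    if len(states) == 0:
        raise ValueError("need at least one calibration state")
    h, w = image_size
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    mapped = np.empty((len(states), 4, 3))
    for i, s in enumerate(states):
        ur = pose_to_matrix(s.t_ur)
        pts = image_point_to_metric(corners[:, 0], corners[:, 1], s.sx, s.sy)
        mapped[i] = ur.apply(pts)
    centroids = mapped.mean(axis=0)  # (4, 3)
    cr = np.linalg.norm(mapped - centroids[None], axis=2).mean(axis=0)
    return CREStats(cr)
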