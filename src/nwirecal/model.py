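"""Model-style front end for probe calibration.

:class:`ProbeCalibration` holds the data (correspondences built from
per-frame detections, recorded poses and the phantom geometry);
``fit()`` estimates the 14 calibration parameters and returns the
:class:`~nwirecal.solver.CalibrationResult` carrying the estimate,
per-point residuals, the inlier set and a ``summary()`` table.

Typical use::

    dataset = make_dataset(seed=1)
    model = ProbeCalibration.from_dataset(dataset)
    result = model.fit(method="ransac", seed=1)
    print(result.summary())
"""

from __future__ import annotations

import numpy as np

from .detect import DetectionParams
from .filtering import FilterParams, FrameDetection, detect_frame
from .geometry import CalibrationState, Correspondence, PhantomGeometry, RigidTransform, default_phantom
from .solver import (
    CalibrationResult,
    RansacParams,
    build_correspondences,
    check_pose_diversity,
    initial_state,
    residual_vector,
    solve_lm_result,
    solve_ransac_lm,
)

__all__ = ["ProbeCalibration"]


class ProbeCalibration:
    """The N-wire calibration model for one acquired dataset."""

    def __init__(self, correspondences: list[Correspondence], phantom: PhantomGeometry | None = None):
        self.correspondences = list(correspondences)
        self.phantom = phantom or default_phantom()

    @classmethod
    def from_detections(
        cls,
        detections: list[FrameDetection],
        poses: dict[int, RigidTransform] | list[RigidTransform],
        phantom: PhantomGeometry | None = None,
    ) -> "ProbeCalibration":
        phantom = phantom or default_phantom()
        corrs = build_correspondences(detections, poses, phantom)
        return cls(corrs, phantom)

    @classmethod
    def from_dataset(
        cls,
        dataset,
        det_params: DetectionParams | None = None,
        filt_params: FilterParams | None = None,
        use_truth_features: bool = False,
    ) -> "ProbeCalibration":
        """Run the detection pipeline over a :class:`SyntheticDataset`
        (or any object with ``frames`` carrying ``image``,
        ``pose_recorded`` and ``frame_index``) and build the model.

        ``use_truth_features`` bypasses the image pipeline and uses the
        simulator's exact wire crossings — the noiseless oracle.
        """
        from .simulate import truth_detection  # local import avoids a cycle

        phantom = dataset.phantom
        detections = []
        for frame in dataset.frames:
            if use_truth_features:
                detections.append(truth_detection(frame, phantom.n_layers))
            else:
                detections.append(
                    detect_frame(
                        frame.image,
                        det_params,
                        filt_params,
                        n_layers=phantom.n_layers,
                        frame_index=frame.frame_index,
                    )
                )
        return cls.from_detections(detections, dataset.recorded_poses(), phantom)

    @property
    def n_correspondences(self) -> int:
        return len(self.correspondences)

    def fit(
        self,
        method: str = "ransac",
        init: CalibrationState | None = None,
        ransac_params: RansacParams | None = None,
        seed: int = 0,
        n_restarts: int = 50,
    ) -> CalibrationResult:
        """Estimate the calibration.

        ``method``: "ransac" (RANSAC-assisted L-M, default) or "lm"
        (plain L-M on all correspondences). A multi-restart
        initialization is computed when ``init`` is not supplied.
        """
        check_pose_diversity([c.pose for c in self.correspondences])
        if init is None:
            init = initial_state(self.correspondences, self.phantom, seed=seed, n_restarts=n_restarts)
        if method == "lm":
            return solve_lm_result(self.correspondences, init)
        if method == "ransac":
            params = ransac_params or RansacParams(seed=seed)
            return solve_ransac_lm(self.correspondences, params, init)
        raise ValueError(f"unknown method {method!r}; use 'ransac' or 'lm'")

    def residuals(self, state: CalibrationState) -> np.ndarray:
        return residual_vector(state, self.correspondences)

    def plot_residuals(self, result: CalibrationResult, ax=None):
        """Bar plot of per-correspondence residuals, outliers highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = np.where(result.inlier_mask, "tab:blue", "tab:red")
        ax.bar(np.arange(len(result.residuals)), result.residuals, color=list(colors))
        ax.set_xlabel("correspondence")
        ax.set_ylabel("residual (mm)")
        ax.set_title("Point reconstruction residuals")
        return ax
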