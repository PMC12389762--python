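"""Correspondence building, residuals, initialization, L-M recovery and
RANSAC robustness."""

import dataclasses
import warnings

import numpy as np
import pytest

from nwirecal.exceptions import IllConditionedWarning, UnderdeterminedError
from nwirecal.geometry import CalibrationState, PoseParams6, pose_to_matrix
from nwirecal.model import ProbeCalibration
from nwirecal.simulate import truth_detection
from nwirecal.solver import (
    RansacParams,
    build_correspondences,
    check_pose_diversity,
    initial_state,
    residual_vector,
    solve_lm,
    solve_lm_result,
    solve_ransac_lm,
)


@pytest.fixture(scope="module")
def truth_corrs(noiseless_dataset):
    dets = [truth_detection(f) for f in noiseless_dataset.frames]
    return build_correspondences(dets, noiseless_dataset.recorded_poses(), noiseless_dataset.phantom)


def _perturbed(state, d_mm=2.0, d_rad=np.deg2rad(2.0), seed=0):
    rng = np.random.default_rng(seed)
    v = state.as_vector()
    v[0:3] += rng.uniform(-d_rad, d_rad, 3)
    v[3:6] += rng.uniform(-d_mm, d_mm, 3)
    v[6:9] += rng.uniform(-d_rad, d_rad, 3)
    v[9:12] += rng.uniform(-d_mm, d_mm, 3)
    return CalibrationState.from_vector(v)


def _corner_mapping_error(a: CalibrationState, b: CalibrationState, size=(512, 512)):
    from nwirecal.geometry import image_point_to_metric

    h, w = size
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    pa = pose_to_matrix(a.t_ur).apply(image_point_to_metric(corners[:, 0], corners[:, 1], a.sx, a.sy))
    pb = pose_to_matrix(b.t_ur).apply(image_point_to_metric(corners[:, 0], corners[:, 1], b.sx, b.sy))
    return np.linalg.norm(pa - pb, axis=1).max()


class TestBuildCorrespondences:
    def test_counts(self, truth_corrs):
        assert len(truth_corrs) == 90

    def test_empty_detections(self, phantom):
        assert build_correspondences([], {}, phantom) == []

    def test_mislabeled_triplet_dropped(self, noiseless_dataset):
        from nwirecal.detect import CandidatePoint
        from nwirecal.filtering import FrameDetection, Triplet

        ds = noiseless_dataset
        dets = [truth_detection(f) for f in ds.frames[:1]]
        # a triplet whose middle point is far off the A-C axis yields
        # alpha > 1.05 and must be dropped, not propagated
        pts = tuple(
            CandidatePoint(u=u, v=v, response=1.0, scale=1.0)
            for u, v in ((0.0, 100.0), (50.0, 300.0), (100.0, 100.0))
        )
        bad = Triplet(pts, 0.0, 0)
        broken = FrameDetection(0, (bad,) + dets[0].triplets[1:], 0.0)
        corrs = build_correspondences([broken], ds.recorded_poses(), ds.phantom)
        assert len(corrs) == 2  # the mislabeled layer is dropped

    def test_missing_pose_raises(self, noiseless_dataset):
        from nwirecal.exceptions import FormatError

        dets = [truth_detection(f) for f in noiseless_dataset.frames[:2]]
        with pytest.raises(FormatError):
            build_correspondences(dets, {0: noiseless_dataset.frames[0].pose_recorded},
                                  noiseless_dataset.phantom)


class TestResidualVector:
    def test_truth_state_residuals_vanish(self, noiseless_dataset, truth_corrs):
        res = residual_vector(noiseless_dataset.truth_state, truth_corrs)
        assert res.max() < 1e-6

    def test_pure_translation_offset_gives_unit_residuals(self, truth_corrs):
        """With all rotations identity, a 1 mm T_UR translation offset
        appears as exactly 1 mm in every residual."""
        base = CalibrationState(PoseParams6.zero(), PoseParams6.zero(), 0.1, 0.1)
        corrs = [
            dataclasses.replace(
                c,
                pose=dataclasses.replace(c.pose, rotation=np.eye(3)),
                x_p=np.zeros(3),
            )
            for c in truth_corrs[:10]
        ]
        # make the base state exact, then shift T_UR by (1, 0, 0)
        exact = [dataclasses.replace(c, x_p=residual_helper(base, c)) for c in corrs]
        shifted = CalibrationState(
            PoseParams6(np.zeros(3), np.array([1.0, 0.0, 0.0])), PoseParams6.zero(), 0.1, 0.1
        )
        res = residual_vector(shifted, exact)
        assert np.allclose(res, 1.0, atol=1e-9)

    def test_empty_list(self, truth_state):
        assert residual_vector(truth_state, []).size == 0


def residual_helper(state, corr):
    """Forward-map a correspondence's pixel through a state's chain."""
    from nwirecal.geometry import image_point_to_metric

    x_u = image_point_to_metric(corr.pixel[0], corr.pixel[1], state.sx, state.sy)
    chain = state.t_wp_transform @ corr.pose @ state.t_ur_transform
    return chain.apply(x_u)


class TestInitialState:
    def test_deterministic(self, truth_corrs):
        a = initial_state(truth_corrs, seed=5)
        b = initial_state(truth_corrs, seed=5)
        assert np.array_equal(a.as_vector(), b.as_vector())

    def test_close_to_basin_on_noiseless_data(self, truth_corrs):
        init = initial_state(truth_corrs, n_restarts=50, seed=0)
        assert residual_vector(init, truth_corrs).mean() < 50.0

    def test_too_few_correspondences(self, truth_corrs):
        with pytest.raises(UnderdeterminedError):
            initial_state(truth_corrs[:4])


class TestSolveLM:
    def test_recovers_truth_from_perturbed_init(self, noiseless_dataset, truth_corrs):
        init = _perturbed(noiseless_dataset.truth_state)
        est = solve_lm(truth_corrs, init)
        assert _corner_mapping_error(est, noiseless_dataset.truth_state) < 1e-3

    def test_optimal_init_unchanged(self, noiseless_dataset, truth_corrs):
        est = solve_lm(truth_corrs, noiseless_dataset.truth_state)
        assert _corner_mapping_error(est, noiseless_dataset.truth_state) < 1e-6

    def test_underdetermined(self, noiseless_dataset, truth_corrs):
        with pytest.raises(UnderdeterminedError):
            solve_lm(truth_corrs[:4], noiseless_dataset.truth_state)

    def test_objective_never_increases(self, truth_corrs):
        """The returned state never has a larger residual sum than its
        initialization."""
        for seed in range(5):
            init = _perturbed(initial_state(truth_corrs, seed=0), d_mm=20.0,
                              d_rad=0.3, seed=seed)
            est = solve_lm(truth_corrs, init)
            c_init = (residual_vector(init, truth_corrs) ** 2).sum()
            c_est = (residual_vector(est, truth_corrs) ** 2).sum()
            assert c_est <= c_init + 1e-9


class TestRansac:
    def test_outlier_free_matches_plain_lm(self, noiseless_dataset, truth_corrs):
        init = initial_state(truth_corrs, seed=0)
        res = solve_ransac_lm(truth_corrs, RansacParams(seed=0), init)
        assert res.inlier_mask.all()
        lm = solve_lm(truth_corrs, init)
        assert _corner_mapping_error(res.state, lm) < 1e-6

    def test_gross_outliers_excluded(self, truth_corrs, rng):
        corrs = list(truth_corrs)
        n = len(corrs)
        bad_idx = set(rng.choice(n, n // 5, replace=False).tolist())
        for i in bad_idx:
            corrs[i] = dataclasses.replace(corrs[i], x_p=corrs[i].x_p + np.array([50.0, 0, 0]))
        init = initial_state(corrs, seed=1)
        res = solve_ransac_lm(corrs, RansacParams(seed=1), init)
        assert not res.inlier_mask[sorted(bad_idx)].any()

    def test_deterministic(self, truth_corrs):
        init = initial_state(truth_corrs, seed=2)
        a = solve_ransac_lm(truth_corrs, RansacParams(seed=2), init)
        b = solve_ransac_lm(truth_corrs, RansacParams(seed=2), init)
        assert np.array_equal(a.inlier_mask, b.inlier_mask)
        assert np.array_equal(a.state.as_vector(), b.state.as_vector())

    def test_subset_size_guard(self, truth_corrs):
        with pytest.raises(ValueError):
            solve_ransac_lm(truth_corrs[:8], RansacParams(subset_size=10))

    def test_robustness_dominance(self, truth_corrs):
        """RANSAC+L-M never evaluates worse than L-M alone on data with
        gross contamination, across contamination fractions and seeds."""
        fast = RansacParams(n_iterations=400, max_stall_iterations=40)
        for frac in (0.05, 0.10, 0.15, 0.20):
            for seed in range(3):
                rng = np.random.default_rng(1000 * seed + int(frac * 100))
                corrs = list(truth_corrs)
                n = len(corrs)
                idx = rng.choice(n, max(int(round(frac * n)), 1), replace=False)
                for i in idx:
                    d = rng.normal(size=3)
                    d *= rng.uniform(3.0, 8.0) / np.linalg.norm(d)
                    corrs[i] = dataclasses.replace(corrs[i], x_p=corrs[i].x_p + d)
                clean = [c for j, c in enumerate(corrs) if j not in set(idx)]
                init = initial_state(corrs, seed=seed)
                lm = solve_lm_result(corrs, init)
                rr = solve_ransac_lm(corrs, dataclasses.replace(fast, seed=seed), init)
                e_lm = residual_vector(lm.state, clean).mean()
                e_rr = residual_vector(rr.state, clean).mean()
                assert e_rr <= e_lm + 1e-9


class TestModelFrontEnd:
    def test_noisy_pipeline_fit_summary(self, noisy_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IllConditionedWarning)
            model = ProbeCalibration.from_dataset(noisy_dataset)
            res = model.fit(method="ransac", seed=3,
                            ransac_params=RansacParams(seed=3, n_iterations=300,
                                                       max_stall_iterations=40))
        assert res.mean_error < 1.0
        text = res.summary()
        assert "mean error" in text and "inliers" in text

    def test_pose_diversity_warning(self, truth_corrs):
        identical = [truth_corrs[0].pose] * 10
        with pytest.warns(IllConditionedWarning):
            check_pose_diversity(identical)
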