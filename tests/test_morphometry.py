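"""Resampling, GPA, sliding, variance profiles and shape PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from billflex import morphometry as mo
from billflex import synthetic as sy

from conftest import hinge_landmark_index


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

class TestResample:
    def test_straight_segment_uniform_spacing(self):
        pts = np.array([[0.0, 0.0], [20.0, 0.0]])
        out = mo.resample_equidistant(pts, 21)
        np.testing.assert_allclose(out[:, 0], np.arange(21.0), atol=1e-12)
        np.testing.assert_allclose(out[:, 1], 0.0, atol=1e-12)

    def test_output_count_is_21(self, rng):
        pts = np.cumsum(rng.uniform(0.1, 1.0, size=(37, 2)), axis=0)
        assert mo.resample_equidistant(pts).shape == (21, 2)

    def test_semicircle_equal_chords(self):
        """Equidistant points on a dense semicircle have equal chords."""
        theta = np.linspace(0.0, np.pi, 4000)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        out = mo.resample_equidistant(pts, 21)
        chords = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.ptp(chords) / chords.mean() < 1e-6

    def test_endpoints_preserved_exactly(self, rng):
        pts = rng.normal(size=(50, 2)).cumsum(axis=0)
        out = mo.resample_equidistant(pts, 21)
        np.testing.assert_array_equal(out[0], pts[0])
        np.testing.assert_array_equal(out[-1], pts[-1])

    def test_zero_length_trace_rejected(self):
        with pytest.raises(mo.DegenerateTraceError):
            mo.resample_equidistant(np.zeros((5, 2)))


class TestExtractFrames:
    def test_exact_divisibility(self):
        np.testing.assert_array_equal(
            mo.extract_frames(101, 11), np.arange(0, 101, 10)
        )

    def test_identity_selection(self):
        np.testing.assert_array_equal(mo.extract_frames(11, 11), np.arange(11))

    @pytest.mark.parametrize("n_frames", [97, 53, 111, 12])
    def test_rounding_matches_brute_force(self, n_frames):
        idx = mo.extract_frames(n_frames, 11)
        expected = [int(np.floor(k * (n_frames - 1) / 10 + 0.5))
                    for k in range(11)]
        np.testing.assert_array_equal(idx, expected)
        assert idx[0] == 0 and idx[-1] == n_frames - 1
        assert np.all(np.diff(idx) > 0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            mo.extract_frames(10, 11)


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------

def _random_shapes(rng, m, k):
    return rng.normal(size=(m, k, 2))


def _similarity(shape, angle, scale, shift):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return scale * shape @ rot.T + shift


def _gpa_oracle(shapes, n_sweeps=2000, tol=1e-14):
    """Independent GPA: pairwise ordinary-Procrustes coordinate descent.

    Aligns unit-size shapes by repeatedly rotating each one onto the
    leave-one-out mean of the others until the total sum of squared
    deviations from the mean stops decreasing.
    """
    x = shapes - shapes.mean(axis=1, keepdims=True)
    x = x / np.sqrt((x ** 2).sum(axis=(1, 2)))[:, None, None]
    prev = np.inf
    for _ in range(n_sweeps):
        for i in range(x.shape[0]):
            target = (x.sum(axis=0) - x[i]) / (x.shape[0] - 1)
            h = x[i].T @ target
            u, _, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(u @ vt))
            r = u @ np.diag([1.0, d]) @ vt
            x[i] = x[i] @ r
        ss = ((x - x.mean(axis=0)) ** 2).sum()
        if prev - ss < tol:
            break
        prev = ss
    return ss


class TestGPA:
    def test_exact_superposition_of_transformed_copies(self, rng):
        shape = _random_shapes(rng, 1, 63)[0]
        other = _similarity(shape, np.deg2rad(30.0), 1.0, np.array([3.0, -2.0]))
        res = mo.gpa_align(np.stack([shape, other]))
        np.testing.assert_allclose(res.aligned[0], res.aligned[1], atol=1e-10)
        assert mo.total_procrustes_ss(res) < 1e-18

    def test_consensus_is_mean_of_aligned(self, rng):
        base = _random_shapes(rng, 1, 12)[0]
        shapes = base[None] + 0.1 * _random_shapes(rng, 8, 12)
        res = mo.gpa_align(shapes)
        mean = res.aligned.mean(axis=0)
        mean = mean / np.linalg.norm(mean - mean.mean(axis=0))
        np.testing.assert_allclose(res.consensus, mean, atol=1e-8)
        assert res.converged

    def test_aligned_shapes_centered_unit_size(self, rng):
        res = mo.gpa_align(_random_shapes(rng, 6, 20))
        np.testing.assert_allclose(res.aligned.mean(axis=1), 0.0, atol=1e-12)
        sizes = np.sqrt((res.aligned ** 2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-12)

    def test_residual_ss_matches_independent_oracle(self, rng):
        """GPA residual SS agrees with a pairwise-OPA descent oracle."""
        shapes = _random_shapes(rng, 10, 5)
        res = mo.gpa_align(shapes)
        ss = mo.total_procrustes_ss(res)
        ss_oracle = _gpa_oracle(shapes)
        assert ss == pytest.approx(ss_oracle, abs=1e-8)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-np.pi, np.pi),
        scale=st.floats(0.1, 10.0),
        tx=st.floats(-50.0, 50.0),
        ty=st.floats(-50.0, 50.0),
    )
    def test_invariant_under_similarity_transform(self, angle, scale, tx, ty):
        rng = np.random.default_rng(11)
        shapes = _random_shapes(rng, 5, 15)
        res_a = mo.gpa_align(shapes)
        shapes2 = shapes.copy()
        shapes2[2] = _similarity(shapes[2], angle, scale, np.array([tx, ty]))
        res_b = mo.gpa_align(shapes2)
        assert abs(mo.total_procrustes_ss(res_a)
                   - mo.total_procrustes_ss(res_b)) < 1e-8

    def test_degenerate_configuration_rejected(self):
        shapes = np.zeros((3, 63, 2))
        with pytest.raises(mo.DegenerateShapeError):
            mo.gpa_align(shapes)


# ---------------------------------------------------------------------------
# semi-landmark sliding
# ---------------------------------------------------------------------------

class TestSliding:
    def test_identical_shapes_noop(self, base_frame):
        shapes = np.stack([base_frame] * 4)
        res = mo.gpa_align(shapes)
        slid = mo.slide_semilandmarks(res)
        np.testing.assert_allclose(slid.aligned, res.aligned, atol=1e-10)

    def test_single_slidable_landmark_matches_tangent_projection(self):
        """One slidable point on a straight line: closed-form projection."""
        k = 21
        base = np.column_stack([np.linspace(0.0, 20.0, k), np.zeros(k)])
        specimen = base.copy()
        specimen[10] += np.array([0.7, 0.0])   # displaced along the line
        res = mo.gpa_align(np.stack([base, base, specimen]))
        slid = mo.slide_semilandmarks(res, slide_sets={"culmen": [10]},
                                      tol=0.0)
        # sliding along the tangent removes the purely tangential offset
        d_before = np.linalg.norm(res.aligned[2, 10] - res.consensus[10])
        d_after = np.linalg.norm(slid.aligned[2, 10] - slid.consensus[10])
        assert d_after < 1e-8
        assert d_after <= d_before

    def test_descent_property(self, template, rng):
        sc = sy.BendingScenario(tracking_noise_sd=0.05, seed=5)
        frames = sy.generate_lick_dataset(template, sc, 2)
        res = mo.gpa_align(frames)
        before = mo.total_procrustes_ss(res)
        slid = mo.slide_semilandmarks(res)
        after = mo.total_procrustes_ss(slid)
        assert after <= before + 1e-12

    def test_endpoint_in_slide_set_rejected(self, base_frame):
        res = mo.gpa_align(np.stack([base_frame] * 3))
        with pytest.raises(IndexError):
            mo.slide_semilandmarks(res, slide_sets={"culmen": [0, 5]})


# ---------------------------------------------------------------------------
# variance profiles
# ---------------------------------------------------------------------------

class TestVarianceProfile:
    def test_rigid_dataset_zero_variance(self, template):
        sc = sy.BendingScenario(tip_deflections_mm=(0.0,),
                                tracking_noise_sd=0.0)
        frames = sy.generate_lick_dataset(template, sc, 3)
        res = mo.gpa_align(frames)
        prof = mo.landmark_variance_profile(res, [f.cycle_id for f in frames])
        assert prof.mean_s2.max() < 1e-20

    def test_hinge_scenario_variance_concentrated_distally(self, template):
        """Culmen S^2 peaks distal of the hinge; proximal leakage < 5%.

        Single-line (culmen) deflection keeps the Procrustes leakage onto
        the static proximal landmarks below 5% of the maximum.
        """
        sc = sy.BendingScenario(hinge_positions=(0.65,),
                                tip_deflections_mm=(0.5,),
                                bend_lines=("culmen",),
                                tracking_noise_sd=0.0)
        frames = sy.generate_lick_dataset(template, sc, 3)
        res = mo.gpa_align(frames)
        prof = mo.landmark_variance_profile(res, [f.cycle_id for f in frames])
        s2 = prof.line_mean("culmen")
        hinge_idx = int(round(hinge_landmark_index(0.65)))
        assert np.argmax(s2) + 1 < hinge_idx          # distal of the hinge
        assert s2[hinge_idx:].max() < 0.05 * s2.max()  # proximal leakage

    def test_variance_scales_quadratically_with_amplitude(self, template):
        profs = {}
        for defl in (0.25, 0.5):
            sc = sy.BendingScenario(hinge_positions=(0.65,),
                                    tip_deflections_mm=(defl,),
                                    tracking_noise_sd=0.0)
            frames = sy.generate_lick_dataset(template, sc, 2)
            res = mo.gpa_align(frames)
            profs[defl] = mo.landmark_variance_profile(
                res, [f.cycle_id for f in frames]
            ).line_mean("culmen")
        moving = np.arange(0, 5)   # distal culmen landmarks
        ratio = profs[0.5][moving] / profs[0.25][moving]
        assert np.all(np.abs(ratio - 4.0) < 0.8)   # x4 within 20%

    def test_ci_bounds_bracket_mean(self, template):
        sc = sy.BendingScenario(tracking_noise_sd=0.03, seed=2)
        frames = sy.generate_lick_dataset(template, sc, 5)
        res = mo.gpa_align(frames)
        prof = mo.landmark_variance_profile(res, [f.cycle_id for f in frames])
        assert np.all(prof.ci_low <= prof.mean_s2)
        assert np.all(prof.mean_s2 <= prof.ci_high)
        assert np.all(prof.mean_s2 >= 0.0)

    def test_single_cycle_has_no_ci(self, template):
        sc = sy.BendingScenario(tracking_noise_sd=0.03)
        frames = sy.generate_lick_dataset(template, sc, 1)
        res = mo.gpa_align(frames)
        prof = mo.landmark_variance_profile(res, [f.cycle_id for f in frames])
        assert prof.ci_low is None and prof.ci_high is None

    def test_total_variance_partitions_over_landmarks(self, template):
        """Sum of per-landmark S^2 equals total aligned variance (1 cycle)."""
        sc = sy.BendingScenario(tracking_noise_sd=0.05, seed=9)
        frames = sy.generate_lick_dataset(template, sc, 1)
        res = mo.gpa_align(frames)
        prof = mo.landmark_variance_profile(res, [f.cycle_id for f in frames])
        total = res.flat().var(axis=0, ddof=1).sum()
        assert prof.mean_s2.sum() == pytest.approx(total, rel=1e-10)


# ---------------------------------------------------------------------------
# leakage experiment
# ---------------------------------------------------------------------------

class TestLeakage:
    def test_zero_ranges_returns_zero(self, base_frame):
        assert mo.leakage_fraction(base_frame, [3, 7], (0.0, 0.0)) == 0.0

    def test_invalid_index_sets_rejected(self, base_frame):
        with pytest.raises(ValueError):
            mo.leakage_fraction(base_frame, [], (0.1, 0.1))
        with pytest.raises(ValueError):
            mo.leakage_fraction(base_frame, np.arange(63), (0.1, 0.1))

    def test_invariant_to_global_rotation_of_base_frame(self, base_frame):
        f1 = mo.leakage_fraction(base_frame, [2, 10, 17], (0.05, 0.25),
                                 n_replicates=60, seed=4)
        rotated = _similarity(base_frame, np.deg2rad(73.0), 1.0,
                              np.array([5.0, 1.0]))
        f2 = mo.leakage_fraction(rotated, [2, 10, 17], (0.05, 0.25),
                                 n_replicates=60, seed=4)
        assert f1 == pytest.approx(f2, abs=1e-10)


# ---------------------------------------------------------------------------
# shape PCA
# ---------------------------------------------------------------------------

class TestShapePCA:
    def test_single_deformation_axis_gives_pc1_100(self, base_frame):
        shapes = []
        for a in np.linspace(-0.05, 0.05, 7):
            s = base_frame.copy()
            s[:5, 1] += a
            shapes.append(s)
        res = mo.gpa_align(np.stack(shapes))
        traj = mo.shape_pca(res)
        # the superimposition is mildly nonlinear, so allow a sliver of
        # higher-order variance beyond the single commanded axis
        assert traj.percent_variance[0] > 99.9

    def test_reconstruction_identity(self, template):
        sc = sy.BendingScenario(tracking_noise_sd=0.03, seed=6)
        frames = sy.generate_lick_dataset(template, sc, 2)
        res = mo.gpa_align(frames)
        traj = mo.shape_pca(res)
        recon = traj.center + traj.scores @ traj.loadings
        np.testing.assert_allclose(recon, res.flat(), atol=1e-10)

    def test_percent_variance_sums_to_100_and_axes_orthonormal(self, template):
        sc = sy.BendingScenario(tracking_noise_sd=0.03, seed=8)
        frames = sy.generate_lick_dataset(template, sc, 2)
        traj = mo.shape_pca(mo.gpa_align(frames))
        assert traj.percent_variance.sum() == pytest.approx(100.0)
        gram = traj.loadings @ traj.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_replicate_cycles_trace_overlapping_loops(self, template):
        """Replicate lick cycles overlap in PC1-PC2 morphospace."""
        from scipy.spatial.distance import directed_hausdorff

        sc = sy.BendingScenario(hinge_positions=(0.65,),
                                tip_deflections_mm=(0.5,),
                                tracking_noise_sd=0.02, seed=3)
        frames = sy.generate_lick_dataset(template, sc, 4)
        res = mo.gpa_align(frames)
        traj = mo.shape_pca(res)
        cycles = np.array([f.cycle_id for f in frames])
        loops = [traj.scores[cycles == c, :2] for c in np.unique(cycles)]
        lengths = [np.linalg.norm(np.diff(lp, axis=0), axis=1).sum()
                   for lp in loops]
        hds = []
        for i in range(len(loops)):
            for j in range(i + 1, len(loops)):
                hds.append(max(directed_hausdorff(loops[i], loops[j])[0],
                               directed_hausdorff(loops[j], loops[i])[0]))
        assert np.mean(hds) < np.mean(lengths)

    def test_wireframe_magnification(self, template):
        sc = sy.BendingScenario(tracking_noise_sd=0.03, seed=1)
        frames = sy.generate_lick_dataset(template, sc, 2)
        traj = mo.shape_pca(mo.gpa_align(frames))
        w = mo.deformation_wireframe(traj, axis=0, score=traj.scores[0, 0],
                                     magnification=7.0)
        assert w.shape == (63, 2)
        assert np.all(np.isfinite(w))


class TestHingeRecovery:
    def test_hinge_localized_within_1p5_landmarks(self, template):
        """Variance-profile kink localizes the true hinge (20 scenarios)."""
        rng = np.random.default_rng(7)
        errs = []
        for t in range(20):
            hf = rng.uniform(0.3, 0.8)
            sc = sy.BendingScenario(hinge_positions=(hf,),
                                    tip_deflections_mm=(0.5,),
                                    tracking_noise_sd=0.02, seed=100 + t)
            frames = sy.generate_lick_dataset(template, sc, 10)
            res = mo.gpa_align(frames)
            prof = mo.landmark_variance_profile(
                res, [f.cycle_id for f in frames]
            )
            est = mo.estimate_hinge_index(prof.line_mean("culmen"))
            errs.append(abs(est - hinge_landmark_index(hf)))
        assert max(errs) <= 1.5
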