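"""String operations: tangents, projected evolution, smoothing, reparametrization,
RMSD, and the full optimization loop on analytic landscapes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cvstring as cs
from cvstring.meanforce import MeanForceEstimate


def _line_path(R=5, direction=(1.0, 0.0)):
    d = np.asarray(direction) / np.linalg.norm(direction)
    return cs.StringPath(np.outer(np.linspace(0, 1, R), d))


class TestTangent:
    def test_collinear_path_tangent_is_line_direction(self):
        path = _line_path(7, (3.0, 4.0))
        for r in range(7):
            np.testing.assert_allclose(cs.path_tangent(path, r), [0.6, 0.8])

    def test_reversal_negates_tangents(self):
        rng = np.random.default_rng(0)
        imgs = np.cumsum(rng.uniform(0.1, 1.0, size=(6, 2)), axis=0)
        fwd = cs.StringPath(imgs)
        rev = cs.StringPath(imgs[::-1])
        for r in range(6):
            np.testing.assert_allclose(
                cs.path_tangent(fwd, r), -cs.path_tangent(rev, 5 - r), atol=1e-12
            )

    def test_circular_arc_tangent_orthogonal_to_radius(self):
        R = 41
        t = np.linspace(0, np.pi / 2, R)
        path = cs.StringPath(np.column_stack([np.cos(t), np.sin(t)]))
        dalpha = 1.0 / (R - 1)
        for r in range(1, R - 1):
            tang = cs.path_tangent(path, r)
            # O(dalpha^2) discretization error
            assert abs(np.dot(tang, path.images[r])) < 10 * dalpha**2

    def test_degenerate_tangent_reported(self):
        path = cs.StringPath(np.array([[0.0, 0], [0, 0], [1, 0]]), np.array([0, 0.5, 1.0]))
        with pytest.raises(ValueError, match="degenerate"):
            cs.path_tangent(path, 0)


class TestEvolveImage:
    def test_gradient_parallel_to_tangent_leaves_image_unchanged(self):
        est = MeanForceEstimate(np.array([2.0, 0.0]), np.eye(2), np.zeros(2))
        z = cs.evolve_image(np.array([0.5, 0.5]), est, np.array([1.0, 0.0]), 0.1)
        np.testing.assert_allclose(z, [0.5, 0.5], atol=1e-15)

    def test_orthogonal_gradient_full_step(self):
        est = MeanForceEstimate(np.array([0.0, 3.0]), np.eye(2), np.zeros(2))
        z = cs.evolve_image(np.zeros(2), est, np.array([1.0, 0.0]), 0.1)
        np.testing.assert_allclose(z, [0.0, -0.3])

    def test_metric_scaling_arithmetic(self):
        est = MeanForceEstimate(np.array([-1.0, 0.0]), np.diag([2.0, 1.0]), np.zeros(2))
        z = cs.evolve_image(np.zeros(2), est, np.array([0.0, 1.0]), 0.1)
        np.testing.assert_allclose(z, [0.2, 0.0])

    def test_non_finite_gradient_rejected(self):
        est = MeanForceEstimate(np.array([np.nan, 0.0]), np.eye(2), np.zeros(2))
        with pytest.raises(ValueError):
            cs.evolve_image(np.zeros(2), est, np.array([0.0, 1.0]), 0.1)


class TestSmoothing:
    def test_zero_smoothing_is_identity(self):
        rng = np.random.default_rng(1)
        path = cs.StringPath(np.sort(rng.uniform(size=(6, 1)), axis=0))
        np.testing.assert_array_equal(cs.smooth_path(path, 0.0).images, path.images)

    @given(s=st.floats(min_value=0.0, max_value=0.499))
    @settings(derandomize=True, max_examples=25)
    def test_straight_path_is_fixed_point(self, s):
        path = _line_path(9, (1.0, 2.0))
        np.testing.assert_allclose(cs.smooth_path(path, s).images, path.images, atol=1e-12)

    def test_zigzag_damped_by_formula(self):
        path = cs.StringPath(np.array([[0.0], [1.0], [0.0]]), np.array([0.0, 0.5, 1.0]))
        out = cs.smooth_path(path, 0.01)
        assert out.images[1, 0] == pytest.approx(0.99)

    def test_invalid_s_rejected(self):
        with pytest.raises(ValueError):
            cs.smooth_path(_line_path(), 0.5)


class TestReparametrize:
    def test_uniform_path_unchanged(self):
        path = _line_path(25)
        out = cs.reparametrize(path)
        np.testing.assert_allclose(out.images, path.images, atol=1e-12)

    def test_three_image_line_recentred(self):
        path = cs.StringPath(np.array([[0.0], [0.9], [1.0]]), np.array([0.0, 0.9, 1.0]))
        out = cs.reparametrize(path)
        assert out.images[1, 0] == pytest.approx(0.5, abs=1e-10)

    def test_25_images_give_24_equal_segments(self):
        rng = np.random.default_rng(2)
        imgs = np.cumsum(rng.uniform(0.1, 1.0, size=(25, 3)), axis=0)
        out = cs.reparametrize(cs.StringPath(imgs))
        assert out.delta_alpha == pytest.approx(1.0 / 24)
        seg = np.linalg.norm(np.diff(out.images, axis=0), axis=1)
        assert (seg.max() - seg.min()) / seg.mean() < 1e-8

    @given(seed=st.integers(0, 1000))
    @settings(derandomize=True, max_examples=20)
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        imgs = np.cumsum(rng.uniform(0.05, 1.0, size=(12, 2)), axis=0)
        once = cs.reparametrize(cs.StringPath(imgs))
        twice = cs.reparametrize(once)
        np.testing.assert_allclose(twice.images, once.images, atol=1e-10)

    def test_endpoints_preserved_exactly(self):
        rng = np.random.default_rng(3)
        imgs = np.cumsum(rng.uniform(0.1, 1.0, size=(9, 2)), axis=0)
        out = cs.reparametrize(cs.StringPath(imgs))
        np.testing.assert_array_equal(out.images[0], imgs[0])
        np.testing.assert_array_equal(out.images[-1], imgs[-1])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            cs.reparametrize(cs.StringPath(np.zeros((3, 2)), np.array([0, 0.5, 1.0])))


class TestPathRmsd:
    def test_identical_zero(self):
        p = _line_path(6)
        assert cs.path_rmsd(p, p) == 0.0

    def test_uniform_shift(self):
        p = _line_path(6)
        q = cs.StringPath(p.images + 0.3, p.alphas)
        assert cs.path_rmsd(p, q) == pytest.approx(0.3)

    def test_single_entry_formula(self):
        p = _line_path(5)
        imgs = p.images.copy()
        imgs[2, 1] += 0.7
        q = cs.StringPath(imgs, p.alphas)
        assert cs.path_rmsd(p, q) == pytest.approx(0.7 / np.sqrt(5 * 2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs.path_rmsd(_line_path(5), _line_path(6))


# transverse stiffness 50 so the bowed string relaxes within 100 cycles at the
# default descent step (relaxation rate c * descent_step per cycle)
@pytest.fixture(scope="module")
def double_well_t0():
    surf = cs.double_well(5.0, 50.0)
    sampler = cs.SamplerConfig(kT=0.0, timestep=1e-3, n_steps_total=300, n_steps_burnin=200)
    sched = cs.OptimizationSchedule(
        per_cycle_sampler=sampler, n_cycles=100, descent_step=0.001, smoothing=0.01
    )
    # start from a bowed path so the optimizer has real work to do
    t = np.linspace(0, 1, 25)
    imgs = np.column_stack([-1 + 2 * t, 0.5 * np.sin(np.pi * t)])
    init = cs.StringPath(imgs)
    return cs.optimize_string(init, surf, cs.identity_cvset(2), 200.0, sched, master_seed=0)


class TestOptimizeString:
    def test_converges_to_x_axis(self, double_well_t0):
        assert np.abs(double_well_t0.final_path.images[:, 1]).max() < 0.05

    def test_deterministic_at_zero_temperature(self, double_well_t0):
        surf = cs.double_well(5.0, 50.0)
        sampler = cs.SamplerConfig(kT=0.0, timestep=1e-3, n_steps_total=300, n_steps_burnin=200)
        sched = cs.OptimizationSchedule(
            per_cycle_sampler=sampler, n_cycles=100, descent_step=0.001, smoothing=0.01
        )
        t = np.linspace(0, 1, 25)
        init = cs.StringPath(np.column_stack([-1 + 2 * t, 0.5 * np.sin(np.pi * t)]))
        again = cs.optimize_string(init, surf, cs.identity_cvset(2), 200.0, sched, master_seed=0)
        np.testing.assert_array_equal(
            again.final_path.images, double_well_t0.final_path.images
        )

    def test_free_endpoints_reach_basin_minima(self, double_well_t0):
        surf = cs.double_well(5.0, 50.0)
        for z in (double_well_t0.final_path.images[0], double_well_t0.final_path.images[-1]):
            assert np.linalg.norm(surf.gradient(z)) < 0.2

    def test_rmsd_vs_final_non_increasing_after_transient(self, double_well_t0):
        r = double_well_t0.convergence.per_cycle_rmsd_vs_final
        tail = r[len(r) // 5 :]
        assert np.all(np.diff(tail) < 1e-6)

    def test_fixed_endpoints_never_move(self):
        surf = cs.double_well(5.0, 1.0)
        sampler = cs.SamplerConfig(kT=0.0, timestep=1e-3, n_steps_total=200, n_steps_burnin=100)
        sched = cs.OptimizationSchedule(
            per_cycle_sampler=sampler, n_cycles=5, descent_step=0.001,
            smoothing=0.01, endpoint_mode="fixed",
        )
        init = cs.linear_initial_path([-1.2, 0.3], [1.2, 0.3], 15)
        res = cs.optimize_string(init, surf, cs.identity_cvset(2), 100.0, sched, master_seed=0)
        for p in res.paths:
            np.testing.assert_array_equal(p.images[0], init.images[0])
            np.testing.assert_array_equal(p.images[-1], init.images[-1])

    def test_seeded_runs_reproduce_at_finite_temperature(self):
        surf = cs.double_well(5.0, 1.0)
        sampler = cs.SamplerConfig(kT=0.5, timestep=1e-3, n_steps_total=400)
        sched = cs.OptimizationSchedule(
            per_cycle_sampler=sampler, n_cycles=4, descent_step=0.001, smoothing=0.01
        )
        init = cs.linear_initial_path([-1.0, 0.0], [1.0, 0.0], 10)
        r1 = cs.optimize_string(init, surf, cs.identity_cvset(2), 100.0, sched, master_seed=42)
        r2 = cs.optimize_string(init, surf, cs.identity_cvset(2), 100.0, sched, master_seed=42)
        np.testing.assert_array_equal(r1.final_path.images, r2.final_path.images)
        r3 = cs.optimize_string(init, surf, cs.identity_cvset(2), 100.0, sched, master_seed=43)
        assert not np.array_equal(r1.final_path.images, r3.final_path.images)

    def test_stationarity_of_projected_force_at_convergence(self, double_well_t0):
        # on the converged string the projected driving force is negligible
        final = double_well_t0.final_path
        ests = double_well_t0.estimates[-1]
        for r in range(1, final.R - 1):
            tang = cs.path_tangent(final, r)
            f = ests[r].metric @ (-ests[r].gradient)
            f_perp = f - tang * np.dot(tang, f)
            assert np.linalg.norm(f_perp) < 0.5


def test_total_sampling_time_protocol_arithmetic():
    # 20 ps per image x 25 images x 100 cycles = 50 ns
    assert cs.total_sampling_time(20e-12, 25, 100) == pytest.approx(50e-9)


def test_image_seed_is_deterministic_and_distinct():
    a = np.random.default_rng(cs.image_seed(1, 2, 3)).integers(1 << 31)
    b = np.random.default_rng(cs.image_seed(1, 2, 3)).integers(1 << 31)
    c = np.random.default_rng(cs.image_seed(1, 2, 4)).integers(1 << 31)
    assert a == b
    assert a != c
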