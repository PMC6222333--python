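"""Free-energy integration, stationary-state classification, uncertainties, and
rate/barrier conversions."""

import numpy as np
import pytest

import cvstring as cs
from cvstring.meanforce import MeanForceEstimate


def _estimates(grads):
    return [
        MeanForceEstimate(np.atleast_1d(g), np.eye(len(np.atleast_1d(g))), 0 * np.atleast_1d(g), i)
        for i, g in enumerate(grads)
    ]


class TestIntegrateProfile:
    def test_zero_gradients_flat_profile(self):
        path = cs.linear_initial_path([0.0, 0.0], [1.0, 1.0], 10)
        prof = cs.integrate_profile(path, _estimates(np.zeros((10, 2))))
        np.testing.assert_allclose(prof.G, 0.0, atol=1e-14)

    def test_constant_gradient_along_straight_line(self):
        # straight path of length L with constant gradient g along it: dG = g*L
        L, g = 2.0, 1.5
        d = np.array([1.0, 0.0])
        path = cs.linear_initial_path([0, 0], L * d, 8)
        prof = cs.integrate_profile(path, _estimates([g * d] * 8))
        assert prof.G[-1] == pytest.approx(g * L, abs=1e-6)

    def test_analytic_double_well_spine_barrier(self):
        # exact spine gradients of the h=5 double well integrate to barrier 5
        h = 5.0
        x = np.linspace(-1, 1, 25)
        path = cs.StringPath(np.column_stack([x, np.zeros(25)]))
        grads = [np.array([4 * h * xi * (xi**2 - 1), 0.0]) for xi in x]
        prof = cs.integrate_profile(path, _estimates(grads), n_grid=75)
        # 75-point grid puts the sampled maximum ~half a grid step off the true peak
        assert prof.barrier == pytest.approx(5.0, abs=0.01)
        # grid refinement changes the barrier by < 0.1%
        prof2 = cs.integrate_profile(path, _estimates(grads), n_grid=150)
        assert abs(prof2.barrier - prof.barrier) / prof.barrier < 1e-3

    def test_additivity_over_alpha_segments(self):
        x = np.linspace(-1, 1, 25)
        path = cs.StringPath(np.column_stack([x, np.zeros(25)]))
        grads = [np.array([4 * 5 * xi * (xi**2 - 1), 0.0]) for xi in x]
        prof = cs.integrate_profile(path, _estimates(grads), n_grid=75)
        inc = np.diff(prof.G)
        assert prof.G[-1] == pytest.approx(np.sum(inc), abs=1e-10)

    def test_too_few_images_rejected(self):
        path = cs.linear_initial_path([0.0], [1.0], 3)
        with pytest.raises(ValueError):
            cs.integrate_profile(path, _estimates(np.zeros((3, 1))))

    def test_default_grid_has_75_inclusive_points(self):
        path = cs.linear_initial_path([0.0], [1.0], 8)
        prof = cs.integrate_profile(path, _estimates(np.zeros((8, 1))))
        assert len(prof.alpha_grid) == 75
        assert prof.alpha_grid[0] == 0.0 and prof.alpha_grid[-1] == 1.0


class TestStationaryStates:
    def _profile(self, G, stderr=None):
        grid = np.linspace(0, 1, len(G))
        return cs.FreeEnergyProfile(grid, np.asarray(G, dtype=float), stderr)

    def test_single_maximum(self):
        a = np.linspace(0, 1, 75)
        prof = self._profile(np.sin(np.pi * a))
        labels = [s.label for s in cs.locate_stationary_states(prof)]
        assert labels == ["RC", "TS1", "PC"]

    def test_monotone_profile_endpoints_only(self):
        prof = self._profile(np.linspace(0, -3, 75))
        labels = [s.label for s in cs.locate_stationary_states(prof)]
        assert labels == ["RC", "PC"]

    def test_two_barrier_labelling_in_order(self):
        a = np.linspace(0, 1, 201)
        G = 3 * np.exp(-((a - 0.25) ** 2) / 0.004) + 5 * np.exp(-((a - 0.7) ** 2) / 0.004)
        prof = self._profile(G - G[0])
        states = cs.locate_stationary_states(prof)
        assert [s.label for s in states] == ["RC", "TS1", "IM1", "TS2", "PC"]
        assert states[1].alpha == pytest.approx(0.25, abs=0.01)
        assert states[3].G == pytest.approx(5.0, abs=0.05)

    def test_noise_wiggles_suppressed_by_uncertainty(self):
        rng = np.random.default_rng(0)
        a = np.linspace(0, 1, 75)
        clean = 5 * np.sin(np.pi * a) ** 2
        noisy = clean + 0.05 * rng.standard_normal(75)
        noisy -= noisy[0]
        prof = self._profile(noisy, stderr=np.full(75, 0.2))
        labels = [s.label for s in cs.locate_stationary_states(prof)]
        assert labels == ["RC", "TS1", "PC"]

    def test_cv_values_interpolated_at_states(self):
        a = np.linspace(0, 1, 75)
        prof = self._profile(np.sin(np.pi * a))
        path = cs.linear_initial_path([0.0, 10.0], [1.0, 20.0], 25)
        states = cs.locate_stationary_states(prof, path)
        ts = states[1]
        np.testing.assert_allclose(ts.cv_values, [ts.alpha, 10 + 10 * ts.alpha], atol=1e-8)


class TestProfileUncertainty:
    def _flat(self, G):
        return cs.FreeEnergyProfile(np.linspace(0, 1, len(G)), G)

    def test_identical_profiles_zero_spread(self):
        p = self._flat(np.linspace(0, 0, 10))
        out = cs.profile_uncertainty([p, p, p])
        np.testing.assert_array_equal(out.stderr, 0.0)

    def test_two_point_sample_sd(self):
        g1 = np.zeros(10)
        g2 = np.zeros(10)
        g2[5] = 0.4
        out = cs.profile_uncertainty([self._flat(g1), self._flat(g2)])
        assert out.stderr[5] == pytest.approx(0.4 / np.sqrt(2))

    def test_recovers_injected_noise_scale(self):
        rng = np.random.default_rng(1)
        sigma = 0.3
        profs = []
        for _ in range(10):
            g = sigma * rng.standard_normal(50)
            g[0] = 0.0
            profs.append(self._flat(g))
        out = cs.profile_uncertainty(profs)
        # sampling distribution of the SD at n=10 is wide; 40% tolerance pointwise
        interior = out.stderr[1:]
        assert np.all(np.abs(interior - sigma) < 0.4 * sigma + 0.25 * sigma)
        assert np.median(np.abs(interior - sigma)) < 0.4 * sigma

    def test_mismatched_grids_rejected(self):
        p1 = self._flat(np.zeros(10))
        p2 = cs.FreeEnergyProfile(np.linspace(0, 1, 11), np.zeros(11))
        with pytest.raises(ValueError):
            cs.profile_uncertainty([p1, p2])


class TestKineticConversions:
    def test_prefactor_rate_gives_zero_barrier(self):
        from cvstring._constants import KB_OVER_H_PER_S_K

        T = 310.0
        assert cs.eyring_barrier(KB_OVER_H_PER_S_K * T, T) == pytest.approx(0.0, abs=1e-12)

    def test_catalyzed_rate_barrier(self):
        # k_cat = 0.2/s corresponds to ~18.6 kcal/mol near room temperature
        assert cs.eyring_barrier(0.2, 300.0) == pytest.approx(18.6, abs=0.3)

    def test_solution_rate_barrier(self):
        # k = 8e-8/s corresponds to ~27.4 kcal/mol near room temperature
        assert cs.eyring_barrier(8e-8, 300.0) == pytest.approx(27.4, abs=0.3)

    def test_eyring_round_trip(self):
        k = cs.eyring_rate(14.0, 298.15)
        assert cs.eyring_barrier(k, 298.15) == pytest.approx(14.0, rel=1e-12)

    def test_half_life_catalyzed(self):
        assert cs.first_order_half_life(0.2) == pytest.approx(3.5, abs=0.05)

    def test_half_life_solution_in_days(self):
        days = cs.first_order_half_life(8e-8) / cs.SECONDS_PER_DAY
        assert days == pytest.approx(100.0, rel=0.01)

    def test_doubling_rate_halves_half_life(self):
        assert cs.first_order_half_life(0.4) == pytest.approx(
            cs.first_order_half_life(0.2) / 2
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            cs.eyring_barrier(bad, 300.0)
        with pytest.raises(ValueError):
            cs.first_order_half_life(bad)
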