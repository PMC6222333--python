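"""Benchmark landscapes: exact gradients, closed forms, and the MEP oracle."""

import numpy as np
import pytest

import cvstring as cs
from cvstring.surfaces import finite_difference_hessian


def _fd_gradient_check(surface, n_points=100, seed=0, box=None):
    rng = np.random.default_rng(seed)
    lo = surface.domain[:, 0] if box is None else box[0]
    hi = surface.domain[:, 1] if box is None else box[1]
    x = rng.uniform(lo, hi, size=(n_points, surface.dimension))
    g = surface.gradient(x)
    h = 1e-6
    for j in range(surface.dimension):
        e = np.zeros(surface.dimension)
        e[j] = h
        fd = (surface.energy(x + e) - surface.energy(x - e)) / (2 * h)
        rel = np.abs(fd - g[:, j]) / np.maximum(1.0, np.abs(fd))
        assert rel.max() < 1e-6


@pytest.mark.parametrize(
    "factory",
    [
        cs.muller_brown,
        lambda: cs.double_well(5.0, 1.0),
        lambda: cs.quadratic_well(2.0, 3),
        lambda: cs.proton_relay_surface(6, cs.gac_like_profile()),
        lambda: cs.proton_relay_surface(4, cs.sac_like_profile()),
    ],
)
def test_gradient_consistent_with_finite_differences(factory):
    surf = factory()
    box = (np.maximum(surf.domain[:, 0], -3), np.minimum(surf.domain[:, 1], 3))
    _fd_gradient_check(surf, box=box)
    x = np.random.default_rng(1).uniform(box[0], box[1], size=(200, surf.dimension))
    assert np.all(np.isfinite(surf.energy(x)))


class TestDoubleWell:
    def test_closed_forms(self):
        dw = cs.double_well(5.0, 1.0)
        assert dw.energy([0.0, 0.0]) - dw.energy([1.0, 0.0]) == pytest.approx(5.0)
        assert dw.energy([-1.0, 0.0]) == pytest.approx(0.0)
        assert dw.energy([1.0, 0.0]) == pytest.approx(0.0)
        np.testing.assert_allclose(dw.gradient([0.0, 0.0]), 0.0, atol=1e-12)

    @pytest.mark.parametrize("h,c", [(0.0, 1.0), (-1.0, 1.0), (5.0, 0.0), (5.0, -2.0)])
    def test_rejects_non_positive_parameters(self, h, c):
        with pytest.raises(ValueError):
            cs.double_well(h, c)


class TestMullerBrown:
    def test_parameters_recorded(self, muller_brown_surface):
        p = muller_brown_surface.parameters
        assert p["A"] == [-200.0, -100.0, -170.0, 15.0]
        assert p["a"] == [-1.0, -1.0, -6.5, 0.7]

    def test_deeper_minimum_energy_and_stationarity(self, muller_brown_surface, mb_minima):
        # deepest basin located independently by dense grid scan + Newton polish
        mb = muller_brown_surface
        xs = np.linspace(-1.5, 1.2, 271)
        ys = np.linspace(-0.3, 2.0, 231)
        XX, YY = np.meshgrid(xs, ys, indexing="ij")
        E = mb.energy(np.stack([XX, YY], axis=-1))
        i, j = np.unravel_index(np.argmin(E), E.shape)
        xmin = cs.refine_minimum(mb, [xs[i], ys[j]])
        np.testing.assert_allclose(xmin, mb_minima[0], atol=1e-8)
        assert mb.energy(xmin) == pytest.approx(-146.6995172, abs=1e-4)
        for m in mb_minima:
            assert np.linalg.norm(mb.gradient(m)) < 1e-6

    def test_oracle_saddles_are_first_order(self, muller_brown_surface, mb_oracle):
        assert mb_oracle.saddle_points is not None
        assert len(mb_oracle.saddle_points) == 2
        for s in mb_oracle.saddle_points:
            eig = np.linalg.eigvalsh(finite_difference_hessian(muller_brown_surface, s))
            assert np.sum(eig < 0) == 1


class TestProtonRelay:
    def test_spine_extrema_reproduce_spec_exactly(self):
        values = [0.0, 9.1, -1.0, 14.0, -2.1, 12.0, -6.0, 10.0, -1.7]
        surf = cs.proton_relay_surface(6, values)
        t = surf.spine_nodes()
        np.testing.assert_allclose(surf.spine_profile(t), values, atol=1e-8)
        # dense evaluation: extrema only at the nodes, count and order preserved
        td = np.linspace(0.0, surf.spine_length, 4001)
        s = surf.spine_profile(td)
        interior_max = np.flatnonzero((s[1:-1] > s[:-2]) & (s[1:-1] > s[2:])) + 1
        interior_min = np.flatnonzero((s[1:-1] < s[:-2]) & (s[1:-1] < s[2:])) + 1
        assert len(interior_max) == 4
        assert len(interior_min) == 3

    def test_flat_spine_oracle_is_straight(self):
        surf = cs.proton_relay_surface(2, [0.0, 0.0, 0.0])
        ref = cs.brute_force_mep(surf, [0.0, 0.0], [surf.spine_length, 0.0], resolution=0.05)
        assert np.abs(ref.points[:, 1]).max() <= 0.05
        assert ref.saddle_indices == []

    def test_non_alternating_spec_rejected(self):
        with pytest.raises(ValueError):
            cs.proton_relay_surface(4, [0.0, 1.0, 2.0, 0.5])
        with pytest.raises(ValueError):
            cs.proton_relay_surface(4, [0.0, 1.0, 1.0, 2.0])

    def test_n_cv_bounds(self):
        with pytest.raises(ValueError):
            cs.proton_relay_surface(1, [0.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            cs.proton_relay_surface(7, [0.0, 1.0, 0.0])


class TestBruteForceMep:
    def test_double_well_path_is_x_axis(self):
        dw = cs.double_well(5.0, 1.0)
        ref = cs.brute_force_mep(dw, [-1.0, 0.0], [1.0, 0.0], resolution=0.02)
        assert np.abs(ref.points[:, 1]).max() < 0.02
        assert ref.energies.max() == pytest.approx(5.0, abs=1e-3)
        np.testing.assert_allclose(ref.saddle_points[0], [0.0, 0.0], atol=1e-8)

    def test_muller_brown_crosses_known_saddles(self, mb_oracle):
        # independently refined saddles of the standard parameter set
        np.testing.assert_allclose(
            mb_oracle.saddle_points[0], [-0.8220, 0.6243], atol=2e-4
        )
        np.testing.assert_allclose(
            mb_oracle.saddle_points[1], [0.2125, 0.2930], atol=2e-4
        )
        d0 = np.linalg.norm(mb_oracle.points - mb_oracle.saddle_points[0], axis=1).min()
        d1 = np.linalg.norm(mb_oracle.points - mb_oracle.saddle_points[1], axis=1).min()
        assert max(d0, d1) < 0.01 + mb_oracle.length / len(mb_oracle.points)

    def test_identical_endpoints_single_point(self, muller_brown_surface):
        ref = cs.brute_force_mep(muller_brown_surface, [0.0, 0.5], [0.0, 0.5])
        assert ref.points.shape == (1, 2)
        assert ref.length == 0.0

    def test_symmetry_under_endpoint_reversal(self):
        dw = cs.double_well(3.0, 2.0)
        fwd = cs.brute_force_mep(dw, [-1.0, 0.0], [1.0, 0.0], resolution=0.02)
        rev = cs.brute_force_mep(dw, [1.0, 0.0], [-1.0, 0.0], resolution=0.02)
        np.testing.assert_allclose(fwd.points, rev.points[::-1], atol=0.02)

    def test_endpoint_outside_domain_rejected(self, muller_brown_surface):
        with pytest.raises(ValueError):
            cs.brute_force_mep(muller_brown_surface, [-10.0, 0.0], [0.6, 0.0])

    def test_uniform_spacing(self, mb_oracle):
        seg = np.linalg.norm(np.diff(mb_oracle.points, axis=0), axis=1)
        assert (seg.max() - seg.min()) / seg.mean() < 1e-8


def test_surface_serialization_round_trip():
    from cvstring.surfaces import surface_from_dict

    for surf in [
        cs.muller_brown(),
        cs.double_well(2.5, 0.7),
        cs.proton_relay_surface(4, cs.sac_like_profile(), transverse=12.0),
    ]:
        clone = surface_from_dict(surf.to_dict())
        x = np.random.default_rng(0).uniform(-0.5, 0.5, size=(5, surf.dimension))
        np.testing.assert_array_equal(surf.energy(x), clone.energy(x))
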