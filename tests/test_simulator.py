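"""Triangular-weighted thick-slice synthesis and the index-based baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctsim import (
    AxialVolume,
    SimulationConfig,
    SliceGeometry,
    difference_map,
    simulate,
    simulate_direct_downsample,
    simulate_gaussian_average,
    simulate_proposed,
    simulate_simple_average,
    triangular_weight,
)

from conftest import make_ramp_volume, make_volume


class TestTriangularWeight:
    @pytest.mark.parametrize(
        "p,l,t,expected",
        [
            (3.0, 3.0, 2.0, 1.0),
            (0.0, 2.0, 2.0, 0.0),
            (1.5, 1.0, 2.0, 0.75),
            (5.0, 1.0, 2.0, 0.0),  # beyond support
        ],
    )
    def test_closed_form(self, p, l, t, expected):
        assert triangular_weight(p, l, t) == pytest.approx(expected, abs=1e-12)

    @given(
        p=st.floats(-100, 100),
        l=st.floats(-100, 100),
        t=st.floats(0.1, 50),
    )
    @settings(derandomize=True, max_examples=300)
    def test_properties(self, p, l, t):
        w = triangular_weight(p, l, t)
        assert 0.0 <= w <= 1.0
        assert w == triangular_weight(l, p, t)  # symmetric
        if abs(p - l) >= t:
            assert w == 0.0

    def test_vectorized(self):
        w = triangular_weight(np.array([0.0, 1.0, 2.0]), 1.0, 2.0)
        np.testing.assert_allclose(w, [0.5, 1.0, 0.5])

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            triangular_weight(0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            triangular_weight(0.0, 0.0, -1.0)


class TestSimulateProposed:
    def test_constant_volume_preserved(self):
        thin = make_volume([7.0, 7.0, 7.0], [0, 1, 2])
        out = simulate_proposed(thin, SliceGeometry(0.3, 1.7, 0.7, 2.0))
        np.testing.assert_allclose(out.voxels, 7.0)

    def test_unit_weight_selects_coincident_slice_exactly(self):
        thin = make_volume([0.0, 10.0, 20.0], [0, 1, 2])
        out = simulate_proposed(thin, SliceGeometry(1.0, 1.0, 1.0, 1.0))
        # t = spacing: neighbours get weight 0; output is the l=1 slice bit-for-bit
        assert np.array_equal(out.voxels[0], thin.voxels[1])
        assert out.positions.tolist() == [1.0]

    def test_hand_computed_weighted_sum(self):
        thin = make_volume([0.0, 10.0, 20.0], [0, 1, 2])
        out = simulate_proposed(thin, SliceGeometry(1.0, 1.0, 1.0, 2.0))
        # weights (0.5, 1, 0.5): (0*0.5 + 10*1 + 20*0.5) / 2 = 10
        np.testing.assert_allclose(out.voxels[0], 10.0, atol=1e-12)

    def test_output_grid_and_thickness(self):
        thin = make_volume(np.zeros(11), np.arange(11.0))
        geom = SliceGeometry(0.0, 10.0, 2.0, 3.0)
        out = simulate_proposed(thin, geom)
        np.testing.assert_allclose(out.positions, [0, 2, 4, 6, 8, 10])
        assert out.thickness == 3.0

    def test_linear_ramp_exactness(self):
        """Affine-in-z input with symmetric kernel support reproduces the
        ramp value at each target position."""
        positions = np.arange(-4.0, 13.0)
        thin = make_ramp_volume(positions, slope=13.5, intercept=-200.0)
        geom = SliceGeometry(0.0, 8.0, 2.0, 2.5)
        out = simulate_proposed(thin, geom)
        for k, p in enumerate(out.positions):
            np.testing.assert_allclose(out.voxels[k], -200.0 + 13.5 * p, atol=1e-9)

    def test_convex_envelope(self, rng):
        thin = AxialVolume(rng.normal(0, 300, (20, 8, 8)), np.arange(20.0), 1.0)
        geom = SliceGeometry(2.3, 16.9, 1.7, 2.6)
        out = simulate_proposed(thin, geom)
        w = triangular_weight(out.positions[:, None], thin.positions[None, :], 2.6)
        for k in range(out.n_slices):
            contrib = thin.voxels[w[k] > 0]
            assert np.all(out.voxels[k] >= contrib.min(axis=0) - 1e-9)
            assert np.all(out.voxels[k] <= contrib.max(axis=0) + 1e-9)

    def test_gap_in_thin_coverage_is_loud(self):
        thin = make_volume([1.0, 2.0], [0.0, 20.0])
        with pytest.raises(ValueError, match="10"):
            simulate_proposed(thin, SliceGeometry(0.0, 20.0, 10.0, 1.0))


class TestBaselines:
    def test_downsample_keeps_every_factorth_slice(self):
        thin = make_volume(np.arange(6.0), np.arange(6.0))
        out = simulate_direct_downsample(thin, 3)
        assert out.positions.tolist() == [0.0, 3.0]
        np.testing.assert_allclose(out.voxels[:, 0, 0], [0.0, 3.0])
        assert out.thickness == 3.0

    def test_downsample_factor_one_is_identity(self):
        thin = make_volume(np.arange(5.0), np.arange(5.0))
        out = simulate_direct_downsample(thin, 1)
        np.testing.assert_array_equal(out.voxels, thin.voxels)

    def test_downsample_odd_count(self):
        thin = make_volume(np.arange(5.0), np.arange(5.0))
        out = simulate_direct_downsample(thin, 2)
        assert out.positions.tolist() == [0.0, 2.0, 4.0]

    def test_simple_average_pairs(self):
        thin = make_volume([0.0, 2.0], [0.0, 1.0])
        out = simulate_simple_average(thin, 2)
        np.testing.assert_allclose(out.voxels[0], 1.0)
        assert out.positions.tolist() == [0.5]  # group-mean position, index-derived

    def test_simple_average_drops_remainder(self):
        thin = make_volume(np.arange(7.0), np.arange(7.0))
        out = simulate_simple_average(thin, 3)
        assert out.n_slices == 2
        np.testing.assert_allclose(out.voxels[:, 0, 0], [1.0, 4.0])

    def test_simple_average_too_few_slices(self):
        thin = make_volume([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="factor"):
            simulate_simple_average(thin, 3)

    def test_gaussian_constant_preserved(self):
        thin = make_volume(np.full(10, 42.0), np.arange(10.0))
        out = simulate_gaussian_average(thin, sigma=1.5, factor=2)
        np.testing.assert_allclose(out.voxels, 42.0, atol=1e-9)

    def test_gaussian_impulse_reproduces_kernel(self):
        n = 21
        vox = np.zeros((n, 4, 4))
        vox[10] = 1.0
        thin = AxialVolume(vox, np.arange(float(n)), 1.0)
        sigma = 1.5
        out = simulate_gaussian_average(thin, sigma=sigma, factor=1)
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        np.testing.assert_allclose(
            out.voxels[10 - radius : 10 + radius + 1, 0, 0], kernel, atol=1e-12
        )

    def test_gaussian_tiny_sigma_equals_downsample(self):
        thin = make_volume(np.arange(8.0), np.arange(8.0))
        out = simulate_gaussian_average(thin, sigma=1e-4, factor=2)
        ref = simulate_direct_downsample(thin, 2)
        np.testing.assert_allclose(out.voxels, ref.voxels, atol=1e-9)

    @pytest.mark.parametrize("bad", [0, -1, 1.5])
    def test_invalid_factor_rejected(self, bad):
        thin = make_volume([1.0, 2.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            simulate_direct_downsample(thin, bad)


class TestPositionCorrection:
    """The documented misplacement of index-based simulation, and its absence
    in the mm-based method."""

    def test_proposed_positions_are_physical(self):
        for n_thin in (10, 11):  # parity of the thin count must not matter
            thin = make_volume(np.zeros(n_thin), np.arange(float(n_thin)))
            geom = SliceGeometry(0.0, float(n_thin - 1), 2.0, 2.0)
            out = simulate_proposed(thin, geom)
            np.testing.assert_allclose(out.positions, np.arange(0.0, n_thin, 2.0))

    def test_simple_average_misplaces_slice_centres(self):
        thin = make_volume(np.zeros(10), np.arange(10.0))
        out = simulate_simple_average(thin, 2)
        true_grid = np.arange(0.0, 10.0, 2.0)
        # every simple-average centre sits half a thin spacing off the true grid
        assert np.min(np.abs(out.positions[:, None] - true_grid[None, :])) >= 0.5

    def test_index_methods_cannot_realize_non_integer_grids(self):
        thin = make_volume(np.zeros(13), np.arange(13.0))
        true_grid = set(np.arange(0.0, 12.1, 1.5))
        for out in (
            simulate_direct_downsample(thin, 2),
            simulate_gaussian_average(thin, 1.0, 2),
        ):
            assert not set(out.positions) <= true_grid
        out = simulate_proposed(thin, SliceGeometry(0.0, 12.0, 1.5, 3.0))
        assert set(out.positions) <= true_grid


class TestDifferenceMap:
    def test_identical_volumes_give_zero(self):
        a = make_volume([1.0, 2.0], [0.0, 1.0])
        d = difference_map(a, a)
        np.testing.assert_array_equal(d.voxels, 0.0)

    def test_constant_difference(self):
        a = make_volume([5.0, 5.0], [0.0, 1.0])
        b = make_volume([2.0, 2.0], [0.0, 1.0])
        np.testing.assert_allclose(difference_map(a, b).voxels, 3.0)

    def test_matches_elementwise_subtraction(self, rng):
        vox_a = rng.normal(size=(3, 5, 5))
        vox_b = rng.normal(size=(3, 5, 5))
        a = AxialVolume(vox_a, [0, 1, 2], 1.0)
        b = AxialVolume(vox_b, [0, 1, 2], 1.0)
        d = difference_map(a, b)
        for k in range(3):
            for r in range(5):
                for c in range(5):
                    assert d.voxels[k, r, c] == vox_a[k, r, c] - vox_b[k, r, c]

    def test_mismatched_geometry_rejected(self):
        a = make_volume([1.0, 2.0], [0.0, 1.0])
        b = make_volume([1.0, 2.0], [0.0, 2.0])
        with pytest.raises(ValueError, match="positions"):
            difference_map(a, b)
        c = make_volume([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="shape"):
            difference_map(a, c)


class TestSimulationConfig:
    def test_dispatch_matches_direct_calls(self):
        thin = make_volume(np.arange(8.0), np.arange(8.0))
        geom = SliceGeometry(0.0, 7.0, 2.0, 3.0)
        np.testing.assert_array_equal(
            simulate(thin, SimulationConfig("proposed", geom=geom)).voxels,
            simulate_proposed(thin, geom).voxels,
        )
        np.testing.assert_array_equal(
            simulate(thin, SimulationConfig("simple_average", factor=2)).voxels,
            simulate_simple_average(thin, 2).voxels,
        )

    def test_gaussian_default_sigma_is_half_factor(self):
        thin = make_volume(np.arange(8.0), np.arange(8.0))
        out = simulate(thin, SimulationConfig("gaussian_average", factor=4))
        ref = simulate_gaussian_average(thin, sigma=2.0, factor=4)
        np.testing.assert_array_equal(out.voxels, ref.voxels)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            SimulationConfig("bicubic")

    def test_proposed_requires_geometry(self):
        with pytest.raises(ValueError, match="SliceGeometry"):
            SimulationConfig("proposed")


def test_constant_preservation_all_methods():
    thin = make_volume(np.full(12, -75.0), np.arange(12.0))
    outs = [
        simulate_proposed(thin, SliceGeometry(0.0, 11.0, 2.0, 3.0)),
        simulate_direct_downsample(thin, 2),
        simulate_simple_average(thin, 2),
        simulate_gaussian_average(thin, 1.0, 2),
    ]
    for out in outs:
        np.testing.assert_allclose(out.voxels, -75.0, atol=1e-9)
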