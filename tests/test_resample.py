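"""Whole-volume resampling: flavor chains, metadata algebra, round-trip
identity under mean pooling, and the conservation audit."""

import numpy as np
import pytest

from ctcompat import (
    FlavorChain,
    HUVolume,
    InterpConfig,
    VoxelSpacing,
    apply_chain,
    conservation_audit,
    downsample_axis,
    upsample_axis,
    upsample_xy,
    upsample_z,
)
from ctcompat.resample import downsample_chain

from conftest import make_volume, random_volume

NO_CLAMP = InterpConfig(clamp_floor=None)


class TestFlavorChain:
    def test_parse_canonical(self):
        assert FlavorChain.parse("Z,XY,Z").tokens == ("Z", "XY", "Z")

    def test_parse_is_case_and_whitespace_tolerant(self):
        assert FlavorChain.parse("z, xy ,Z").tokens == ("Z", "XY", "Z")

    @pytest.mark.parametrize("bad", ["Q", "Z,,W", "", "ZX"])
    def test_rejects_unknown_tokens(self, bad):
        with pytest.raises(ValueError):
            FlavorChain.parse(bad)


class TestUpsampleAxis:
    def test_canonical_zprofile_middle_voxel(self, zprofile_volume):
        up, report = upsample_z(zprofile_volume)
        # middle parent -50 with neighbors 0/100: alpha = 25 -> (-75, -25)
        np.testing.assert_allclose(up.values[2:4, 0, 0], [-75.0, -25.0])
        assert report.max_delta == 0.0 and report.n_clamped == 0

    def test_edge_voxel_uses_replicate_padding(self, zprofile_volume):
        up, _ = upsample_z(zprofile_volume)
        # first parent 0 with padded neighbors (0, -50): alpha = -12.5
        np.testing.assert_allclose(up.values[0:2, 0, 0], [12.5, -12.5])

    def test_lower_child_sits_on_lower_index_side(self):
        # increasing profile: lower child must track the lower neighbor
        v = make_volume(np.arange(5, dtype=float).reshape(5, 1, 1) * 100)
        up, _ = upsample_z(v)
        assert up.values[2, 0, 0] < up.values[3, 0, 0]

    def test_uniform_volume_stays_uniform(self):
        v = make_volume(np.full((3, 4, 5), 77.0))
        up, report = upsample_axis(v, "y")
        assert up.values.shape == (3, 8, 5)
        np.testing.assert_array_equal(up.values, 77.0)
        assert report.max_delta == 0.0

    def test_spacing_halves_only_along_axis(self, ct_spacing):
        v = HUVolume(np.zeros((2, 2, 2)), ct_spacing)
        up, _ = upsample_axis(v, "x")
        assert up.spacing == VoxelSpacing(0.35, 0.7, 1.5)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError):
            upsample_axis(make_volume(np.zeros((2, 2, 2))), "t")

    def test_ramp_children_are_half_step_offsets(self):
        """On an exact ramp with slope s per voxel, interior children are
        parent -/+ s/2 (all reference modes coincide)."""
        s = 50.0
        ramp = np.arange(6, dtype=float) * s
        v = make_volume(ramp.reshape(6, 1, 1))
        for mode in ("linear", "spline"):
            up, _ = upsample_z(v, InterpConfig(reference_mode=mode, clamp_floor=None))
            interior = up.values[2:-2, 0, 0]
            # alpha = (next - prev)/4 = s/2, so children sit at parent -/+ s/2,
            # matching the 0/50/100 ramp where every method yields (25, 75)
            expected = np.ravel([(p - s / 2, p + s / 2) for p in ramp[1:-1]])
            np.testing.assert_allclose(interior, expected, atol=1e-9)

    def test_clamped_children_counted_and_delta_reported(self):
        v = make_volume(np.array([0.0, -1020.0, 3000.0]).reshape(3, 1, 1))
        up, report = upsample_z(v)  # default floor -1024
        assert report.n_clamped >= 1
        assert report.max_delta > 0
        assert up.values.min() >= -1024.0


class TestXYAndChains:
    def test_xy_doubles_both_inplane_dims(self, ct_spacing):
        v = HUVolume(np.random.default_rng(0).uniform(-100, 100, (2, 5, 4)), ct_spacing)
        up, _ = upsample_xy(v, NO_CLAMP)
        assert up.values.shape == (2, 10, 8)
        assert up.spacing == VoxelSpacing(0.35, 0.35, 1.5)

    def test_xy_parent_block_mean_is_parent(self):
        arr = np.zeros((1, 3, 3))
        arr[0, 1, 1] = 100.0
        up, _ = upsample_xy(make_volume(arr), NO_CLAMP)
        block = up.values[0, 2:4, 2:4]
        assert block.mean() == pytest.approx(100.0, abs=1e-9)

    def test_axis_order_passes_commute_and_conserve(self):
        """Each pass is a linear operator along its own axis, so the two
        in-plane orders commute (within rounding); both conserve."""
        rng = np.random.default_rng(3)
        v = random_volume(rng, (2, 6, 6))
        a, _ = upsample_xy(v, InterpConfig(clamp_floor=None, axis_order_xy="x_then_y"))
        b, _ = upsample_xy(v, InterpConfig(clamp_floor=None, axis_order_xy="y_then_x"))
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)
        for out in (a, b):
            pooled = downsample_axis(downsample_axis(out, "x"), "y")
            np.testing.assert_allclose(pooled.values, v.values, atol=1e-9)

    def test_chain_metadata_z_xy(self, ct_spacing):
        v = HUVolume(np.zeros((3, 8, 8)), ct_spacing)
        up, _ = apply_chain(v, "Z,XY", NO_CLAMP)
        assert up.values.shape == (6, 16, 16)
        assert up.spacing == VoxelSpacing(0.35, 0.35, 0.75)

    def test_chain_z_xy_z_quarters_slice_thickness(self, ct_spacing):
        v = HUVolume(np.zeros((2, 2, 2)), ct_spacing)
        up, _ = apply_chain(v, "Z,XY,Z", NO_CLAMP)
        assert up.spacing.dz == pytest.approx(1.5 / 4)

    def test_single_token_chain_equals_flavor(self):
        rng = np.random.default_rng(9)
        v = random_volume(rng, (4, 4, 4))
        a, _ = apply_chain(v, "Z", NO_CLAMP)
        b, _ = upsample_z(v, NO_CLAMP)
        np.testing.assert_array_equal(a.values, b.values)

    def test_bad_chain_fails_before_computation(self):
        with pytest.raises(ValueError):
            apply_chain(make_volume(np.zeros((2, 2, 2))), "Z,Q")


class TestDownsample:
    def test_pair_means(self):
        v = make_volume(np.array([-75.0, -25.0, 60.0, 40.0]).reshape(4, 1, 1))
        down = downsample_axis(v, "z")
        np.testing.assert_allclose(down.values[:, 0, 0], [-50.0, 50.0])
        assert down.spacing.dz == 2.0

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            downsample_axis(make_volume(np.zeros((3, 2, 2))), "z")


class TestRoundTrip:
    @pytest.mark.parametrize("flavors", ["Z", "XY", "Z,XY,Z"])
    @pytest.mark.parametrize("mode", ["linear", "spline"])
    def test_mean_pool_inverts_upsampling(self, flavors, mode):
        rng = np.random.default_rng(17)
        v = random_volume(rng, (6, 7, 5))
        cfg = InterpConfig(reference_mode=mode, clamp_floor=None)
        up, report = apply_chain(v, flavors, cfg)
        assert report.n_clamped == 0
        back = downsample_chain(up, flavors)
        assert np.abs(back.values - v.values).max() <= 1e-9
        assert back.spacing == v.spacing

    def test_affine_equivariance_linear_reference(self):
        rng = np.random.default_rng(23)
        v = random_volume(rng, (4, 5, 6), low=-500, high=500)
        a, b = 1.7, -120.0
        scaled = HUVolume(a * v.values + b, v.spacing)
        up_v, _ = apply_chain(v, "Z,XY", NO_CLAMP)
        up_s, _ = apply_chain(scaled, "Z,XY", NO_CLAMP)
        np.testing.assert_allclose(up_s.values, a * up_v.values + b, atol=1e-9)

    def test_locality_one_parent_neighborhood_per_pass(self):
        base = make_volume(np.zeros((9, 1, 1)))
        bumped = make_volume(np.zeros((9, 1, 1)))
        bumped.values[4, 0, 0] = 500.0
        up0, _ = upsample_z(base, NO_CLAMP)
        up1, _ = upsample_z(bumped, NO_CLAMP)
        changed = np.nonzero(up0.values[:, 0, 0] != up1.values[:, 0, 0])[0]
        # children of parents 3..5 only: output indices 6..11
        assert changed.min() >= 6 and changed.max() <= 11


class TestConservationAudit:
    def test_conserving_child_audits_clean(self):
        rng = np.random.default_rng(31)
        v = random_volume(rng, (4, 4, 4))
        up, _ = apply_chain(v, "Z,XY", NO_CLAMP)
        report = conservation_audit(v, up, "Z,XY")
        assert report.max_delta <= 1e-9
        assert report.n_clamped == 0

    def test_classical_linear_child_shows_known_defect(self):
        # parent -50 split by plain linear interpolation against 0 / 100
        parent = make_volume(np.array([[[-50.0]]]))
        child = make_volume(np.array([-25.0, 25.0]).reshape(2, 1, 1))
        report = conservation_audit(parent, child, "z")
        assert report.max_delta == pytest.approx(50.0)

    def test_classical_spline_child_shows_known_defect(self):
        parent = make_volume(np.array([[[0.0]]]))
        child = make_volume(np.array([-9.375, 40.625]).reshape(2, 1, 1))
        report = conservation_audit(parent, child, "z")
        assert report.max_delta == pytest.approx(15.625)

    def test_dimension_mismatch_rejected(self):
        parent = make_volume(np.zeros((2, 2, 2)))
        child = make_volume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            conservation_audit(parent, child, "z")
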