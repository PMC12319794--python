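"""Physiology assignment and cylinder dipole field synthesis."""

import numpy as np
import pytest

from vasim.field import (
    FieldParams,
    FrequencyFieldMap,
    HematocritScheme,
    OxygenationState,
    assign_physiology,
    build_field_basis,
    build_field_map,
    segment_field_offset,
    susceptibility_difference,
)
from vasim.network import ARTERY, MICROVESSEL, VEIN, VascularNetwork, classify_segments

from conftest import make_single_vein


class TestPhysiology:
    def test_microvessel_saturation_is_the_midpoint(self):
        ox = OxygenationState(so2_vein=0.62)
        assert ox.so2_micro == pytest.approx(0.785)
        assert ox.so2_vein <= ox.so2_micro <= ox.so2_artery

    def test_hematocrit_multipliers(self):
        hct = HematocritScheme(systemic=0.45)
        assert hct.for_compartment(ARTERY) == pytest.approx(0.405)
        assert hct.for_compartment(MICROVESSEL) == pytest.approx(0.315)
        assert hct.for_compartment(VEIN) == pytest.approx(0.54)

    def test_assignment_by_compartment(self, two_segment_net):
        net = assign_physiology(
            two_segment_net, OxygenationState(so2_vein=0.62), HematocritScheme()
        )
        assert net.so2[net.compartment == VEIN][0] == 0.62
        assert net.so2[net.compartment == MICROVESSEL][0] == pytest.approx(0.785)
        art = assign_physiology(
            classify_segments(two_segment_net), OxygenationState(0.62), HematocritScheme()
        )
        # every artery segment sits at 95 % saturation
        assert np.all(art.so2[art.compartment == ARTERY] == 0.95) or not np.any(
            art.compartment == ARTERY
        )

    def test_unlabeled_segment_rejected(self):
        net = VascularNetwork(
            np.zeros((1, 3)), np.array([[0.0, 0.0, 10.0]]), [1.0], [10.0]
        )
        with pytest.raises(ValueError, match="unlabeled"):
            assign_physiology(net, OxygenationState(0.62), HematocritScheme())

    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            OxygenationState(so2_vein=0.99)  # above arterial
        with pytest.raises(ValueError):
            HematocritScheme(systemic=0.9)  # vein hct would exceed 1


class TestSusceptibility:
    def test_fully_oxygenated_blood_vanishes(self):
        assert susceptibility_difference(1.0, 0.5, FieldParams()) == 0.0

    def test_reference_value(self):
        dchi = susceptibility_difference(0.6, 0.54, FieldParams())
        assert dchi == pytest.approx(7.492e-7, rel=1e-3)

    def test_linearity_in_deoxygenation(self):
        p = FieldParams()
        full = susceptibility_difference(0.6, 0.5, p)
        half = susceptibility_difference(0.8, 0.5, p)
        assert half == pytest.approx(full / 2.0)


class TestSegmentOffset:
    @pytest.fixture()
    def vein(self):
        seg = make_single_vein(radius=10.0, box=100.0).segments[0]
        return seg

    def test_reference_point(self, vein):
        # R=10, r=20, theta=0, psi=90 deg
        val = segment_field_offset(vein, [50.0, 50.0, 70.0])
        assert val == pytest.approx(175.3, rel=1e-3)

    def test_null_at_45_degrees(self, vein):
        d = 20.0 / np.sqrt(2.0)
        val = segment_field_offset(vein, [50.0 + d, 50.0, 50.0 + d])
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_null_for_axis_parallel_to_b0(self):
        net = make_single_vein(radius=10.0, box=100.0)
        net.p_start[0] = [50.0, 50.0, 0.0]
        net.p_end[0] = [50.0, 50.0, 100.0]
        assert segment_field_offset(net.segments[0], [80.0, 50.0, 50.0]) == 0.0

    def test_point_inside_vessel_rejected(self, vein):
        with pytest.raises(ValueError, match="inside"):
            segment_field_offset(vein, [50.0, 50.0, 55.0])

    def test_inverse_square_decay(self, vein):
        rs = np.array([15.0, 22.0, 33.0, 49.0, 70.0])
        vals = [abs(segment_field_offset(vein, [50.0, 50.0, 50.0 + r])) for r in rs]
        slope = np.polyfit(np.log(rs), np.log(vals), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.05)

    def test_hz_units_divide_by_two_pi(self, vein):
        rad = segment_field_offset(vein, [50.0, 50.0, 70.0], FieldParams())
        hz = segment_field_offset(
            vein, [50.0, 50.0, 70.0], FieldParams(frequency_units="hz")
        )
        assert hz == pytest.approx(rad / (2.0 * np.pi))


class TestFieldMap:
    def test_fully_oxygenated_network_gives_zero_field(self):
        net = make_single_vein(so2=1.0)
        fmap = build_field_map(net, grid_spacing=4.0)
        assert np.all(fmap.values == 0.0)

    def test_single_segment_matches_pointwise_oracle(self):
        net = make_single_vein(radius=5.0, box=80.0)
        fmap = build_field_map(net, grid_spacing=1.0, cutoff_rel=None, dtype=np.float64)
        seg = net.segments[0]
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            ijk = tuple(rng.integers(0, 81, 3))
            pt = np.array(ijk, float)
            s = (pt - seg.p_start) @ seg.axis
            if fmap.mask[ijk] or not 0.0 <= s <= 80.0:
                continue
            expected = segment_field_offset(seg, pt)
            if abs(expected) < 1e-9:
                continue
            assert fmap.values[ijk] == pytest.approx(expected, rel=1e-6)
            checked += 1

    def test_linearity_in_b0(self):
        net = make_single_vein()
        lo = build_field_map(net, FieldParams(b0=7.0), grid_spacing=4.0, dtype=np.float64)
        hi = build_field_map(net, FieldParams(b0=14.0), grid_spacing=4.0, dtype=np.float64)
        np.testing.assert_allclose(hi.values, 2.0 * lo.values, rtol=1e-12)

    def test_superposition_of_disjoint_segment_sets(self):
        box = np.array([[0.0, 0.0, 0.0], [80.0, 80.0, 80.0]])
        a = VascularNetwork(
            np.array([[20.0, 0.0, 20.0]]), np.array([[20.0, 80.0, 20.0]]),
            [3.0], [80.0], compartment=np.array([VEIN], dtype=np.int8), box=box,
        )
        b = VascularNetwork(
            np.array([[60.0, 0.0, 60.0]]), np.array([[60.0, 80.0, 60.0]]),
            [3.0], [80.0], compartment=np.array([MICROVESSEL], dtype=np.int8), box=box,
        )
        both = VascularNetwork(
            np.vstack([a.p_start, b.p_start]), np.vstack([a.p_end, b.p_end]),
            [3.0, 3.0], [80.0, 80.0],
            compartment=np.array([VEIN, MICROVESSEL], dtype=np.int8), box=box,
        )
        for net in (a, b, both):
            net.so2[:] = 0.6
            net.hct[:] = 0.5
        kw = dict(grid_spacing=2.0, dtype=np.float64)
        fa, fb, fab = (build_field_map(n, **kw) for n in (a, b, both))
        np.testing.assert_allclose(fab.values, fa.values + fb.values, atol=1e-9)

    def test_dipole_shell_average_vanishes(self):
        # the external cylinder dipole has zero angular mean over any shell
        net = make_single_vein(radius=5.0, box=200.0)
        seg = net.segments[0]
        thetas = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        for r in (20.0, 50.0):
            pts = np.column_stack(
                [100.0 + r * np.cos(thetas), np.full_like(thetas, 100.0),
                 100.0 + r * np.sin(thetas)]
            )
            vals = [segment_field_offset(seg, p) for p in pts]
            assert np.mean(vals) == pytest.approx(0.0, abs=1e-8)

    def test_mask_marks_interior(self):
        net = make_single_vein(radius=8.0, box=80.0)
        fmap = build_field_map(net, grid_spacing=2.0)
        assert fmap.mask[20, 20, 20] == 1  # on the axis
        assert fmap.mask[0, 0, 0] == 0
        # node counting at 2 um spacing under-fills the strict r < R disk
        expected = np.pi * 8.0**2 * 80.0 / 80.0**3
        assert fmap.mask.mean() == pytest.approx(expected, rel=0.2)

    def test_periodic_build_matches_on_wrap_faces(self):
        net = make_single_vein(radius=5.0, box=80.0)
        fmap = build_field_map(net, grid_spacing=2.0, periodic_xy=True, dtype=np.float64)
        # with in-plane images summed, opposite x-faces carry the same field
        np.testing.assert_allclose(
            fmap.values[0, :, :], fmap.values[-1, :, :], rtol=1e-6, atol=1e-3
        )

    def test_basis_combination_matches_direct_build(self, two_segment_net):
        ox, hct = OxygenationState(so2_vein=0.62), HematocritScheme()
        net = assign_physiology(two_segment_net, ox, hct)
        direct = build_field_map(net, grid_spacing=4.0, periodic_xy=True)
        basis = build_field_basis(net, grid_spacing=4.0, periodic_xy=True)
        combined = basis.combine(ox, hct)
        np.testing.assert_allclose(combined.values, direct.values, rtol=1e-4, atol=1e-3)
        np.testing.assert_array_equal(combined.mask, direct.mask)

    def test_hdf5_roundtrip(self, tmp_path):
        net = make_single_vein()
        fmap = build_field_map(net, grid_spacing=4.0)
        p = tmp_path / "field.h5"
        fmap.save(p)
        back = FrequencyFieldMap.load(p)
        np.testing.assert_array_equal(back.values, fmap.values)
        np.testing.assert_array_equal(back.mask, fmap.mask)
        assert back.params == fmap.params

    def test_invalid_spacing(self):
        with pytest.raises(ValueError, match="grid_spacing"):
            build_field_map(make_single_vein(), grid_spacing=0.0)
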