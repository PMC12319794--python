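"""Vascular network loading, labeling, laminar partition and CBV."""

import csv

import numpy as np
import pytest

from vasim.network import (
    ARTERY,
    MICROVESSEL,
    VEIN,
    VascularNetwork,
    VesselSegment,
    classify_segments,
    compute_cbv_profile,
    load_network,
    macrovessel_trunks,
    partition_laminae,
    relabel_artery_vein_ratio,
    save_network,
)


class TestSegmentValidation:
    def test_rejects_nonpositive_radius_and_length(self):
        with pytest.raises(ValueError, match="radius"):
            VesselSegment(0, [0, 0, 0], [0, 0, 10], radius=-1.0, length=10.0)
        with pytest.raises(ValueError, match="length"):
            VesselSegment(0, [0, 0, 0], [0, 0, 10], radius=1.0, length=0.0)

    def test_network_rejects_bad_rows(self):
        with pytest.raises(ValueError, match="non-positive radius"):
            VascularNetwork(
                np.zeros((1, 3)), np.array([[0.0, 0.0, 10.0]]), [0.0], [10.0]
            )


class TestDialect:
    def test_two_segment_fixture_roundtrip(self, two_segment_net, tmp_path):
        p = tmp_path / "net.csv"
        save_network(two_segment_net, p)
        net = load_network(p)
        assert len(net) == 2
        np.testing.assert_allclose(net.radius, [4.0, 12.0])
        np.testing.assert_allclose(net.p_start, two_segment_net.p_start)
        assert net.adjacency[0] == {1} and net.adjacency[1] == {0}
        # canonical write o load o write is byte-identical
        p2 = tmp_path / "net2.csv"
        save_network(net, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_malformed_and_invalid_records_name_the_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "id,x1,y1,z1,x2,y2,z2,radius_um,length_um\n"
            "0,0,0,0,0,0,10,2.0,10\n"
            "1,0,0,0,0,0,10,oops,10\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            load_network(p)
        p.write_text(
            "id,x1,y1,z1,x2,y2,z2,radius_um,length_um\n"
            "0,0,0,0,0,0,10,-2.0,10\n"
        )
        with pytest.raises(ValueError, match="non-positive radius"):
            load_network(p)

    def test_total_length_matches_line_by_line_sum(self, tmp_path):
        rng = np.random.default_rng(11)
        n = 500
        p0 = rng.uniform(0, 900, (n, 3))
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        length = rng.uniform(10, 80, n)
        net = VascularNetwork(
            p0, p0 + d * length[:, None], rng.uniform(1, 30, n), length,
            box=np.array([[-200.0, -200.0, -200.0], [1200.0, 1200.0, 1200.0]]),
        )
        p = tmp_path / "gen.csv"
        save_network(net, p)
        # independent line-by-line oracle using the csv module
        with open(p) as fh:
            total = sum(float(row["length_um"]) for row in csv.DictReader(fh))
        assert total == pytest.approx(load_network(p).length.sum(), rel=1e-12)


def _grid_net(radii, zs, adjacency=None, box_z=1600.0):
    """Vertical segments at given radii/depth starts, 100 um long."""
    n = len(radii)
    p0 = np.column_stack([np.full(n, 500.0), np.linspace(100, 900, n), zs])
    p1 = p0 + np.array([0.0, 0.0, 100.0])
    return VascularNetwork(
        p0, p1, np.asarray(radii, float), np.full(n, 100.0),
        adjacency=adjacency,
        box=np.array([[0.0, 0.0, 0.0], [1000.0, 1000.0, box_z]]),
    )


class TestClassification:
    @pytest.mark.parametrize(
        "radius,expected",
        [(3.0, MICROVESSEL), (8.0, ARTERY), (20.0, VEIN), (5.99, MICROVESSEL)],
    )
    def test_radius_rules_in_pial_band(self, radius, expected):
        net = classify_segments(_grid_net([radius], [0.0]))
        assert net.compartment[0] == expected

    def test_penetrating_inherits_connected_pial_label(self):
        # pial vein at the surface, connected 8 um segment at depth: the
        # radius alone says artery, the vessel path says vein
        net = _grid_net([20.0, 8.0], [0.0, 400.0], adjacency={0: {1}})
        out = classify_segments(net)
        assert out.compartment[0] == VEIN
        assert out.compartment[1] == VEIN

    def test_orphan_macrovessel_falls_back_to_radius(self, caplog):
        net = _grid_net([20.0, 8.0], [0.0, 400.0])  # no adjacency
        with caplog.at_level("WARNING"):
            out = classify_segments(net)
        assert out.compartment[1] == ARTERY
        assert any("no connected path" in r.message for r in caplog.records)

    def test_label_completeness(self):
        rng = np.random.default_rng(0)
        net = _grid_net(rng.uniform(1, 30, 20), rng.uniform(0, 1400, 20))
        out = relabel_artery_vein_ratio(classify_segments(net))
        assert not np.any(out.compartment == 0)


class TestRelabeling:
    def _trunk_net(self, n_trunks, radii=None):
        radii = radii if radii is not None else np.linspace(30, 8, n_trunks)
        return classify_segments(_grid_net(radii, np.zeros(n_trunks)))

    @pytest.mark.parametrize("n,expected_veins", [(4, 1), (8, 2), (6, 2), (5, 1), (10, 2)])
    def test_rounded_target_ratio(self, n, expected_veins):
        out = relabel_artery_vein_ratio(self._trunk_net(n), ratio=(3, 1), seed=0)
        trunks = macrovessel_trunks(out)
        idx = {int(s): i for i, s in enumerate(out.ids)}
        veins = sum(1 for t in trunks if out.compartment[idx[t[0]]] == VEIN)
        assert veins == expected_veins
        assert len(trunks) - veins == n - expected_veins

    def test_already_at_ratio_is_fixed_point(self):
        net = self._trunk_net(4, radii=[30.0, 10.0, 9.0, 8.0])  # 1 vein, 3 arteries
        out = relabel_artery_vein_ratio(net, seed=0)
        np.testing.assert_array_equal(out.compartment, net.compartment)

    def test_largest_trunks_become_veins(self):
        out = relabel_artery_vein_ratio(self._trunk_net(8), seed=0)
        order = np.argsort(-out.radius)
        assert set(out.compartment[order[:2]]) == {VEIN}

    def test_microvessels_untouched(self):
        net = classify_segments(_grid_net([3.0, 20.0, 9.0, 8.0, 7.0], np.zeros(5)))
        out = relabel_artery_vein_ratio(net)
        assert out.compartment[0] == MICROVESSEL


class TestLaminarPartition:
    def test_equal_division(self, two_segment_net):
        net = _grid_net([3.0], [0.0], box_z=1600.0)
        part = partition_laminae(net, 16)
        assert part.n_laminae == 16
        assert part.thickness == pytest.approx(100.0)
        np.testing.assert_allclose(np.diff(part.boundaries), 100.0)

    def test_boundary_point_goes_to_deeper_slab(self):
        part = partition_laminae(_grid_net([3.0], [0.0], box_z=1600.0), 16)
        assert part.lamina_of(np.array([100.0]))[0] == 1
        assert part.lamina_of(np.array([1600.0]))[0] == 15  # last slab closed

    def test_volume_conservation(self):
        part = partition_laminae(_grid_net([3.0], [0.0], box_z=1600.0), 16)
        assert 16 * part.lamina_volume == pytest.approx(1000.0 * 1000.0 * 1600.0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            partition_laminae(_grid_net([3.0], [0.0]), 0)


class TestCBV:
    def test_single_cylinder_fraction(self):
        # R=10, L=100 fully inside a 1 mm x 1 mm x 100 um slab
        net = _grid_net([10.0], [0.0], box_z=1600.0)
        net.compartment[:] = ARTERY
        part = partition_laminae(net, 16)
        cbv = compute_cbv_profile(net, part)
        assert cbv.artery[0] == pytest.approx(np.pi * 100 * 100 / 1e8)
        assert np.all(cbv.total[1:] == 0.0)

    def test_split_segment_conserves_volume(self):
        net = _grid_net([10.0], [50.0], box_z=1600.0)  # spans laminae 1 and 2
        net.compartment[:] = VEIN
        part = partition_laminae(net, 16)
        cbv = compute_cbv_profile(net, part)
        total = (cbv.vein * part.lamina_volume).sum()
        assert total == pytest.approx(np.pi * 100 * 100, rel=1e-12)
        assert cbv.vein[0] == pytest.approx(cbv.vein[1])

    def test_cbv_conservation_random_network(self):
        rng = np.random.default_rng(5)
        n = 200
        p0 = np.column_stack(
            [rng.uniform(0, 1000, n), rng.uniform(0, 1000, n), rng.uniform(0, 1500, n)]
        )
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        length = rng.uniform(20, 90, n)
        p1 = np.clip(p0 + d * length[:, None], 0.0, [1000, 1000, 1600])
        geo = np.linalg.norm(p1 - p0, axis=1)
        net = VascularNetwork(
            p0, p1, rng.uniform(2, 20, n), geo,
            compartment=rng.integers(1, 4, n).astype(np.int8),
            box=np.array([[0.0, 0.0, 0.0], [1000.0, 1000.0, 1600.0]]),
        )
        part = partition_laminae(net, 16)
        cbv = compute_cbv_profile(net, part)
        lhs = (cbv.total * part.lamina_volume).sum()
        assert lhs == pytest.approx(net.volume.sum(), rel=1e-9)

    def test_radius_scaling_scales_fractions_quadratically(self):
        net = _grid_net([4.0, 9.0], [120.0, 700.0], box_z=1600.0)
        net.compartment[:] = MICROVESSEL
        part = partition_laminae(net, 16)
        base = compute_cbv_profile(net, part).total
        net2 = net.copy()
        net2.radius *= 3.0
        scaled = compute_cbv_profile(net2, part).total
        np.testing.assert_allclose(scaled, 9.0 * base, rtol=1e-12)

    def test_unlabeled_network_rejected(self):
        net = _grid_net([4.0], [0.0])
        part = partition_laminae(net, 16)
        with pytest.raises(ValueError, match="labeled"):
            compute_cbv_profile(net, part)
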