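"""Shared fixtures: small networks, field maps and partitions.

Everything is generated programmatically; expensive Monte-Carlo fixtures
are session-scoped so the laminar acceptance checks share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from vasim.field import FrequencyFieldMap
from vasim.network import MICROVESSEL, VEIN, LaminarPartition, VascularNetwork


@pytest.fixture()
def two_segment_net() -> VascularNetwork:
    """A hand-written two-segment network inside a 100 um cube."""
    return VascularNetwork(
        p_start=np.array([[10.0, 10.0, 20.0], [50.0, 50.0, 10.0]]),
        p_end=np.array([[10.0, 90.0, 20.0], [50.0, 50.0, 90.0]]),
        radius=np.array([4.0, 12.0]),
        length=np.array([80.0, 80.0]),
        compartment=np.array([MICROVESSEL, VEIN], dtype=np.int8),
        adjacency={0: {1}},
        box=np.array([[0.0, 0.0, 0.0], [100.0, 100.0, 100.0]]),
        name="two_segment",
    )


@pytest.fixture()
def empty_field() -> FrequencyFieldMap:
    """Zero-susceptibility field on a 100 um cube (21^3 nodes, 5 um grid)."""
    shape = (21, 21, 21)
    return FrequencyFieldMap(
        origin=np.zeros(3),
        spacing=5.0,
        values=np.zeros(shape, dtype=np.float32),
        mask=np.zeros(shape, dtype=np.uint8),
        box=np.array([[0.0, 0.0, 0.0], [100.0, 100.0, 100.0]]),
    )


@pytest.fixture()
def part16() -> LaminarPartition:
    return LaminarPartition(boundaries=np.linspace(0.0, 100.0, 17), xy_area=1e4)


def uniform_field(value: float, box: float = 100.0, spacing: float = 5.0) -> FrequencyFieldMap:
    """Spatially constant offset field (global-phase identity tests)."""
    n = int(box / spacing) + 1
    return FrequencyFieldMap(
        origin=np.zeros(3),
        spacing=spacing,
        values=np.full((n, n, n), value, dtype=np.float32),
        mask=np.zeros((n, n, n), dtype=np.uint8),
        box=np.array([[0.0, 0.0, 0.0], [box, box, box]]),
    )


def random_static_field(seed: int, box: float = 100.0, spacing: float = 5.0) -> FrequencyFieldMap:
    """Frozen Gaussian offset field (spin-echo refocusing tests)."""
    rng = np.random.default_rng(seed)
    fmap = uniform_field(0.0, box, spacing)
    fmap.values = rng.normal(0.0, 300.0, fmap.values.shape).astype(np.float32)
    return fmap


def make_single_vein(
    radius: float = 5.0, box: float = 80.0, so2: float = 0.6, hct: float = 0.54
) -> VascularNetwork:
    """One vein along y through the box centre, physiology pre-assigned."""
    c = box / 2.0
    net = VascularNetwork(
        p_start=np.array([[c, 0.0, c]]),
        p_end=np.array([[c, box, c]]),
        radius=np.array([radius]),
        length=np.array([box]),
        compartment=np.array([VEIN], dtype=np.int8),
        box=np.array([[0.0, 0.0, 0.0], [box, box, box]]),
        name="single_vein",
    )
    net.so2[:] = so2
    net.hct[:] = hct
    return net
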