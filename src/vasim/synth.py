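"""Synthetic vascular inputs.

Two generators are provided:

* :func:`generate_cylinder_phantom` — mono-sized, randomly placed and
  oriented cylinders at a prescribed blood volume fraction.  This is the
  classic validation geometry for vessel-size-dependent GE/SE relaxometry.
* :func:`generate_cortical_network` — a cortical-like voxel (~1 mm^2 in
  plane, 1–1.75 mm deep) with pial macrovessels at a 3:1 artery:vein ratio,
  tapering penetrating trunks, and a quasi-uniform capillary bed, emulating
  the depth-dependent CBV statistics of two-photon vascular reconstructions:
  high CBV in the top ~250 um driven by pial vessels, total CBV of O(1–2 %).

Cylinders may overlap; volume-fraction accounting is the analytic
``sum(pi R^2 L) / V`` consistent with how baseline CBV is defined for the
vectorized source data, not a voxelized union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ARTERY, MICROVESSEL, VEIN, VascularNetwork


@dataclass(frozen=True)
class PhantomSpec:
    """Mono-sized random-cylinder phantom description."""

    cylinder_radius: float  # um
    target_volume_fraction: float
    box: float = 300.0  # um, cubic edge
    max_cylinders: int = 200_000
    max_length: float | None = None  # cap cylinder length (None: full chord)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_volume_fraction < 0.2:
            raise ValueError("target_volume_fraction must be in (0, 0.2)")
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder_radius must be positive")
        if self.box <= 2 * self.cylinder_radius:
            raise ValueError("box must exceed the cylinder diameter")
        if self.max_length is not None and self.max_length <= 0:
            raise ValueError("max_length must be positive")


def _clip_line_to_box(center: np.ndarray, direction: np.ndarray, size: float):
    """Chord of the infinite line through ``center`` inside the cube [0, size]^3."""
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        d = direction[ax]
        if abs(d) < 1e-12:
            continue
        a = (0.0 - center[ax]) / d
        b = (size - center[ax]) / d
        t0 = max(t0, min(a, b))
        t1 = min(t1, max(a, b))
    return center + t0 * direction, center + t1 * direction, t1 - t0


def generate_cylinder_phantom(spec: PhantomSpec) -> VascularNetwork:
    """Add random chords through the box until the volume fraction is met.

    Centers are uniform in the box, axis directions uniform on the sphere,
    and each cylinder spans the full chord of its line through the box.  The
    generator stops at the cylinder count whose cumulative analytic fraction
    is closest to the target (overlaps are not corrected).
    """
    rng = np.random.default_rng(spec.seed)
    box_volume = spec.box**3
    area = np.pi * spec.cylinder_radius**2
    p0, p1, lengths = [], [], []
    achieved = 0.0
    for _ in range(spec.max_cylinders):
        center = rng.uniform(0.0, spec.box, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        a, b, chord = _clip_line_to_box(center, d, spec.box)
        if chord <= 0:
            continue
        if spec.max_length is not None and chord > spec.max_length:
            # shrink symmetrically about the chord midpoint
            mid = 0.5 * (a + b)
            a = mid - 0.5 * spec.max_length * d
            b = mid + 0.5 * spec.max_length * d
            chord = spec.max_length
        frac = area * chord / box_volume
        if achieved >= spec.target_volume_fraction:
            break
        # keep the last cylinder only if it brings us closer to the target
        if achieved + frac > spec.target_volume_fraction:
            overshoot = achieved + frac - spec.target_volume_fraction
            undershoot = spec.target_volume_fraction - achieved
            if overshoot > undershoot and p0:
                break
        p0.append(a)
        p1.append(b)
        lengths.append(chord)
        achieved += frac
        if achieved >= spec.target_volume_fraction:
            break
    else:
        raise RuntimeError(
            f"target fraction {spec.target_volume_fraction} not reached within "
            f"{spec.max_cylinders} cylinders (achieved {achieved:.4g})"
        )
    n = len(p0)
    net = VascularNetwork(
        np.asarray(p0),
        np.asarray(p1),
        np.full(n, spec.cylinder_radius),
        np.asarray(lengths),
        compartment=np.full(n, VEIN, dtype=np.int8),
        box=np.array([[0.0, 0.0, 0.0], [spec.box, spec.box, spec.box]]),
        name=f"phantom_r{spec.cylinder_radius:g}",
    )
    return net


@dataclass(frozen=True)
class CortexSpec:
    """Synthetic cortical voxel description.

    Defaults follow the anatomy the laminar analysis assumes: ~1 mm^2 plane,
    1 mm cortical thickness (the lower end of the 1–1.75 mm range spanned by
    the source reconstructions), six pial arteries and two pial veins (3:1),
    capillary radii well below 6 um, and a total baseline CBV of ~1.5 %.
    """

    xy_extent: float = 1000.0  # um
    depth: float = 1000.0  # um
    n_pial_arteries: int = 6
    n_pial_veins: int = 2
    penetrating_spacing: float = 250.0  # um between penetrating trunks
    capillary_radius_mean: float = 3.0  # um
    capillary_radius_sd: float = 0.5
    capillary_length_range: tuple[float, float] = (50.0, 100.0)
    capillary_density_decay: float = 0.7  # relative density at depth vs top
    target_total_cbv: float = 0.015
    pial_enhancement: float = 1.0  # scales pial vessel radii
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pial_arteries != 3 * self.n_pial_veins:
            raise ValueError("pial artery:vein counts must be 3:1 by construction")
        if not 1000.0 - 1e-9 <= self.depth <= 1750.0 + 1e-9:
            raise ValueError("depth must lie in the 1000-1750 um range")
        if self.capillary_radius_mean >= 6.0:
            raise ValueError("capillary radii must stay below the 6 um threshold")
        if not 0.005 <= self.target_total_cbv <= 0.05:
            raise ValueError("target_total_cbv outside the plausible 0.5-5 % range")


class _Builder:
    def __init__(self, box: np.ndarray):
        self.p0: list[np.ndarray] = []
        self.p1: list[np.ndarray] = []
        self.radius: list[float] = []
        self.length: list[float] = []
        self.comp: list[int] = []
        self.adj: dict[int, set[int]] = {}
        self.box = box

    def add(self, a, b, r, comp, link_to: int | None = None) -> int:
        a = np.clip(np.asarray(a, float), self.box[0], self.box[1])
        b = np.clip(np.asarray(b, float), self.box[0], self.box[1])
        length = float(np.linalg.norm(b - a))
        if length <= 1e-6:
            return -1
        sid = len(self.radius)
        self.p0.append(a)
        self.p1.append(b)
        self.radius.append(float(r))
        self.length.append(length)
        self.comp.append(comp)
        self.adj.setdefault(sid, set())
        if link_to is not None and link_to >= 0:
            self.adj[sid].add(link_to)
            self.adj.setdefault(link_to, set()).add(sid)
        return sid

    def volume(self) -> float:
        return float(np.sum(np.pi * np.asarray(self.radius) ** 2 * np.asarray(self.length)))

    def network(self, name: str) -> VascularNetwork:
        return VascularNetwork(
            np.asarray(self.p0),
            np.asarray(self.p1),
            np.asarray(self.radius),
            np.asarray(self.length),
            compartment=np.asarray(self.comp, dtype=np.int8),
            adjacency=self.adj,
            box=self.box,
            name=name,
        )


def generate_cortical_network(spec: CortexSpec) -> VascularNetwork:
    """Build a labeled cortical-like network meeting the CBV constraints.

    Construction order: pial vessels (top ~10–40 um, spanning the full plane),
    penetrating trunks descending from them with tapering radius and small
    lateral jitter, then a capillary bed of short randomly oriented segments
    (mild preference for the depth axis) filling the microvessel CBV budget.
    The output satisfies, by construction: a 3:1 artery:vein trunk ratio,
    top-250-um CBV above the deeper average, and total CBV within 20 % of
    the target.
    """
    rng = np.random.default_rng(spec.seed)
    s, depth = spec.xy_extent, spec.depth
    box = np.array([[0.0, 0.0, 0.0], [s, s, depth]])
    b = _Builder(box)

    # --- pial macrovessels, alternating x- and y-oriented, stratified in-plane
    n_trunks = spec.n_pial_arteries + spec.n_pial_veins
    comps = [VEIN] * spec.n_pial_veins + [ARTERY] * spec.n_pial_arteries
    rng.shuffle(comps)
    offsets = (np.arange(n_trunks) + rng.uniform(0.2, 0.8, n_trunks)) / n_trunks * s
    pial_ids = []
    for k, comp in enumerate(comps):
        # pial veins are the dominant surface vessels and span the plane;
        # pial arteries are represented by shorter surface stubs so the top
        # lamina stays in the realistic few-percent CBV range
        z = rng.uniform(10.0, 40.0)
        if comp == VEIN:
            r = rng.uniform(11.0, 14.0) * spec.pial_enhancement
            if k % 2 == 0:
                a, c = [0.0, offsets[k], z], [s, offsets[k], z]
            else:
                a, c = [offsets[k], 0.0, z], [offsets[k], s, z]
        else:
            r = rng.uniform(6.5, 9.0) * spec.pial_enhancement
            stub = 250.0
            start = rng.uniform(0.0, s - stub)
            if k % 2 == 0:
                a, c = [start, offsets[k], z], [start + stub, offsets[k], z]
            else:
                a, c = [offsets[k], start, z], [offsets[k], start + stub, z]
        pial_ids.append((b.add(a, c, r, comp), comp, r))

    # --- penetrating trunks descending from the pial vessels, tapering
    n_pen_total = max(n_trunks, int(round((s / spec.penetrating_spacing) ** 2)))
    per_trunk = [n_pen_total // n_trunks + (1 if i < n_pen_total % n_trunks else 0)
                 for i in range(n_trunks)]
    seg_len = 100.0
    for (pid, comp, pial_r), n_pen in zip(pial_ids, per_trunk):
        for _ in range(n_pen):
            t = rng.uniform(0.1, 0.9)
            top = b.p0[pid] + t * (b.p1[pid] - b.p0[pid])
            bottom_z = rng.uniform(0.7, 1.0) * depth
            r_top = min(pial_r, rng.uniform(7.0, 9.0)) if comp == ARTERY else min(
                pial_r, rng.uniform(9.0, 12.0)
            )
            r_bot = rng.uniform(3.0, 4.5)
            n_seg = max(2, int(np.ceil((bottom_z - top[2]) / seg_len)))
            zs = np.linspace(top[2], bottom_z, n_seg + 1)
            radii = np.linspace(r_top, r_bot, n_seg)
            prev = pid
            pos = top.copy()
            for j in range(n_seg):
                jitter = rng.normal(0.0, 8.0, size=2)
                nxt = np.array([pos[0] + jitter[0], pos[1] + jitter[1], zs[j + 1]])
                sid = b.add(pos, nxt, radii[j], comp, link_to=prev)
                if sid >= 0:
                    prev = sid
                    pos = np.clip(nxt, box[0], box[1])

    macro_volume = b.volume()
    voxel_volume = s * s * depth
    micro_budget = spec.target_total_cbv * voxel_volume - macro_volume
    if micro_budget <= 0:
        raise RuntimeError(
            "macrovessels alone exceed the total CBV target "
            f"({macro_volume / voxel_volume:.3%} > {spec.target_total_cbv:.3%}); "
            "reduce pial_enhancement or raise target_total_cbv"
        )

    # --- capillary bed: short segments, depth-weighted density
    micro_volume = 0.0
    decay = spec.capillary_density_decay
    max_caps = 500_000
    for _ in range(max_caps):
        if micro_volume >= micro_budget:
            break
        # rejection-sample depth against the linear density profile
        z = rng.uniform(0.0, depth)
        if rng.uniform() > 1.0 + (decay - 1.0) * z / depth:
            continue
        center = np.array([rng.uniform(0, s), rng.uniform(0, s), z])
        d = rng.normal(size=3) * np.array([1.0, 1.0, 1.3])  # mild depth bias
        d /= np.linalg.norm(d)
        half = 0.5 * rng.uniform(*spec.capillary_length_range)
        r = float(np.clip(rng.normal(spec.capillary_radius_mean, spec.capillary_radius_sd),
                          1.5, 5.9))
        sid = b.add(center - half * d, center + half * d, r, MICROVESSEL)
        if sid >= 0:
            micro_volume += np.pi * r**2 * b.length[sid]
    else:
        raise RuntimeError("capillary packing failed to reach the microvessel CBV budget")

    net = b.network(name=f"cortex_seed{spec.seed}")

    total_cbv = net.volume.sum() / voxel_volume
    if abs(total_cbv - spec.target_total_cbv) > 0.2 * spec.target_total_cbv:
        raise RuntimeError(
            f"generated total CBV {total_cbv:.3%} deviates more than 20 % from "
            f"the {spec.target_total_cbv:.3%} target"
        )
    top = _mean_cbv_in_band(net, 0.0, 250.0)
    deep = _mean_cbv_in_band(net, 250.0, depth)
    if top <= deep:
        raise RuntimeError(
            f"top-250-um CBV ({top:.3%}) does not exceed the deeper mean ({deep:.3%})"
        )
    return net


def _mean_cbv_in_band(net: VascularNetwork, z0: float, z1: float) -> float:
    """Analytic CBV of the depth band [z0, z1), apportioning by z-overlap."""
    za = np.minimum(net.p_start[:, 2], net.p_end[:, 2])
    zb = np.maximum(net.p_start[:, 2], net.p_end[:, 2])
    span = zb - za
    overlap = np.clip(np.minimum(zb, z1) - np.maximum(za, z0), 0.0, None)
    frac = np.where(span > 0, overlap / np.where(span > 0, span, 1.0),
                    ((za >= z0) & (za < z1)).astype(float))
    ext = net.box[1] - net.box[0]
    band_volume = ext[0] * ext[1] * (z1 - z0)
    return float(np.sum(net.volume * frac) / band_volume)
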