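"""Susceptibility physiology and frequency-offset field synthesis.

Deoxygenated hemoglobin makes vessel blood paramagnetic relative to tissue;
each vessel segment therefore perturbs the main field.  The perturbation of
one segment is modeled as the external field of an infinite cylinder,
evaluated only over the segment's axial extent (end effects neglected):

    dw(r) = 1/2 * gamma * B0 * dchi * (R/r)^2 * cos(2 theta) * sin(psi)^2

with ``dchi = 4 pi * 0.276e-6 * Hct(R) * (1 - SO2)`` (SI, dimensionless),
``r`` the perpendicular distance to the segment axis, ``psi`` the angle
between the axis and B0 (along +z, normal to the pial surface), and
``theta`` the in-plane azimuth between the radial vector and the projection
of B0 onto the plane perpendicular to the axis.

Offsets are accumulated in angular units (rad/s) so that phase integrates
directly in radians; a Hz mode (divide by 2 pi) exists for sensitivity
analysis.  The total field over a voxel is the superposition of all
segments, sampled on a regular grid together with an inside-vessel mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from ._kernels import accumulate_field, accumulate_mask
from .network import ARTERY, MICROVESSEL, UNLABELED, VEIN, VascularNetwork

#: the 15 venous oxygen-saturation states swept by the laminar experiments
SO2_VEIN_LEVELS = tuple(np.round(np.arange(0.50, 0.93, 0.03), 2))

#: default cutoff radius in units of R: (R/r)^2 drops to 1e-3 of the wall value
DEFAULT_CUTOFF_REL = float(np.sqrt(1000.0))

_COMP_ORDER = {"artery": ARTERY, "vein": VEIN, "microvessel": MICROVESSEL}


@dataclass(frozen=True)
class OxygenationState:
    """Steady-state oxygen saturation per vascular compartment.

    Arteries sit at 95 %; the microvessel value is the midpoint between the
    arterial and the imposed venous saturation.
    """

    so2_vein: float
    so2_artery: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2_vein <= 1.0 or not 0.0 <= self.so2_artery <= 1.0:
            raise ValueError("saturations must lie in [0, 1]")
        if self.so2_vein > self.so2_artery:
            raise ValueError("venous saturation cannot exceed arterial")

    @property
    def so2_micro(self) -> float:
        return self.so2_artery - (self.so2_artery - self.so2_vein) / 2.0

    def for_compartment(self, code: int) -> float:
        if code == ARTERY:
            return self.so2_artery
        if code == VEIN:
            return self.so2_vein
        if code == MICROVESSEL:
            return self.so2_micro
        raise ValueError(f"no saturation defined for compartment code {code}")


@dataclass(frozen=True)
class HematocritScheme:
    """Vessel-size-dependent hematocrit from a systemic value.

    Arteries carry 0.90x, microvessels 0.70x and veins 1.20x the systemic
    hematocrit (the venous surplus models red-cell stalling in venules).
    """

    systemic: float = 0.45
    artery_factor: float = 0.90
    micro_factor: float = 0.70
    vein_factor: float = 1.20

    def __post_init__(self) -> None:
        for code in (ARTERY, VEIN, MICROVESSEL):
            h = self.for_compartment(code)
            if not 0.0 < h < 1.0:
                raise ValueError(f"hematocrit {h} outside (0, 1)")

    def for_compartment(self, code: int) -> float:
        if code == ARTERY:
            return self.artery_factor * self.systemic
        if code == VEIN:
            return self.vein_factor * self.systemic
        if code == MICROVESSEL:
            return self.micro_factor * self.systemic
        raise ValueError(f"no hematocrit defined for compartment code {code}")


HCT_SWEEP_LEVELS = tuple(np.round(np.arange(0.35, 0.5501, 0.025), 3))


@dataclass(frozen=True)
class FieldParams:
    """Field-synthesis constants: B0 [T], gamma [rad/(s T)], dchi prefactor."""

    b0: float = 7.0
    gamma: float = 267.5e6
    chi_do_coeff: float = 4.0 * np.pi * 0.276e-6
    frequency_units: str = "rad"  # "rad" (angular, default) or "hz"

    def __post_init__(self) -> None:
        if self.b0 <= 0 or self.gamma <= 0 or self.chi_do_coeff <= 0:
            raise ValueError("field parameters must be positive")
        if self.frequency_units not in ("rad", "hz"):
            raise ValueError("frequency_units must be 'rad' or 'hz'")

    @property
    def unit_scale(self) -> float:
        return 1.0 if self.frequency_units == "rad" else 1.0 / (2.0 * np.pi)


def assign_physiology(
    net: VascularNetwork, ox: OxygenationState, hct: HematocritScheme
) -> VascularNetwork:
    """Set every segment's SO2 and hematocrit from its compartment label."""
    if np.any(net.compartment == UNLABELED):
        raise ValueError("network contains unlabeled segments")
    out = net.copy()
    for code in (ARTERY, VEIN, MICROVESSEL):
        sel = out.compartment == code
        out.so2[sel] = ox.for_compartment(code)
        out.hct[sel] = hct.for_compartment(code)
    return out


def set_uniform_physiology(net: VascularNetwork, so2: float, hct: float) -> VascularNetwork:
    """Give every segment the same SO2/hematocrit (phantom studies)."""
    out = net.copy()
    out.so2[:] = so2
    out.hct[:] = hct
    return out


def susceptibility_difference(so2: float, hct_vessel: float, params: FieldParams) -> float:
    """Blood-vs-tissue susceptibility difference (SI, dimensionless)."""
    if not 0.0 <= so2 <= 1.0 or not 0.0 <= hct_vessel <= 1.0:
        raise ValueError("so2 and hematocrit must lie in [0, 1]")
    return params.chi_do_coeff * hct_vessel * (1.0 - so2)


def segment_field_offset(seg, point, params: FieldParams = FieldParams()) -> float:
    """Frequency offset of a single segment at an external point.

    Pure infinite-cylinder expression; the axial truncation applied during
    map synthesis is not imposed here.  Raises if the point lies on the
    segment axis or inside the vessel radius.
    """
    point = np.asarray(point, dtype=float)
    u = seg.axis
    d = point - seg.p_start
    s = d @ u
    v = d - s * u
    r2 = float(v @ v)
    if r2 < seg.radius**2:
        raise ValueError("field point inside the vessel (external field only)")
    sin2psi = 1.0 - u[2] ** 2
    if sin2psi < 1e-14:
        return 0.0
    bproj = np.array([-u[0] * u[2], -u[1] * u[2], sin2psi]) / np.sqrt(sin2psi)
    cos_t = (v @ bproj) / np.sqrt(r2)
    cos2t = 2.0 * cos_t**2 - 1.0
    dchi = susceptibility_difference(seg.so2, seg.hct, params)
    dw = 0.5 * params.gamma * params.b0 * dchi * (seg.radius**2 / r2) * cos2t * sin2psi
    return dw * params.unit_scale


@dataclass
class FrequencyFieldMap:
    """Sampled frequency-offset volume plus the inside-vessel mask.

    ``values[i, j, k]`` is the offset at ``origin + (i, j, k) * spacing``;
    values at masked (intravascular) nodes are never used by the walk.
    """

    origin: np.ndarray  # (3,), um
    spacing: float  # um
    values: np.ndarray  # (nx, ny, nz)
    mask: np.ndarray  # (nx, ny, nz) uint8
    box: np.ndarray  # (2, 3) physical bounds, um
    params: FieldParams = field(default_factory=FieldParams)

    @property
    def extent(self) -> np.ndarray:
        return self.box[1] - self.box[0]

    def extravascular_fraction(self) -> float:
        return 1.0 - float(self.mask.mean())

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at box coordinates (tests and spot checks)."""
        from scipy.interpolate import RegularGridInterpolator

        axes = [
            self.origin[a] + self.spacing * np.arange(self.values.shape[a]) for a in range(3)
        ]
        itp = RegularGridInterpolator(axes, self.values, bounds_error=False, fill_value=None)
        return itp(np.atleast_2d(points))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values, compression="gzip")
            f.create_dataset("mask", data=self.mask, compression="gzip")
            f["origin"] = self.origin
            f["box"] = self.box
            f.attrs["spacing"] = self.spacing
            f.attrs["b0"] = self.params.b0
            f.attrs["gamma"] = self.params.gamma
            f.attrs["chi_do_coeff"] = self.params.chi_do_coeff
            f.attrs["frequency_units"] = self.params.frequency_units

    @classmethod
    def load(cls, path) -> "FrequencyFieldMap":
        with h5py.File(path, "r") as f:
            params = FieldParams(
                b0=float(f.attrs["b0"]),
                gamma=float(f.attrs["gamma"]),
                chi_do_coeff=float(f.attrs["chi_do_coeff"]),
                frequency_units=str(f.attrs["frequency_units"]),
            )
            return cls(
                origin=f["origin"][:],
                spacing=float(f.attrs["spacing"]),
                values=f["values"][:],
                mask=f["mask"][:],
                box=f["box"][:],
                params=params,
            )


def _grid_shape(box: np.ndarray, spacing: float) -> tuple[int, int, int]:
    ext = box[1] - box[0]
    return tuple(int(np.ceil(e / spacing - 1e-9)) + 1 for e in ext)


def _segment_arrays(net: VascularNetwork, sel: np.ndarray):
    u = net.axis_unit[sel]
    return (
        np.ascontiguousarray(net.p_start[sel]),
        np.ascontiguousarray(u),
        np.ascontiguousarray(net.geometric_length[sel]),
        np.ascontiguousarray(net.radius[sel]),
    )


def _with_periodic_images(p0, u, L, R, dchi, box, cutoff_rel, cap_slack):
    """Replicate segments into the 8 neighbouring xy cells where they matter."""
    ext = box[1] - box[0]
    outs = [(p0, u, L, R, dchi)]
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            shift = np.array([sx * ext[0], sy * ext[1], 0.0])
            q0 = p0 + shift
            q1 = q0 + u * L[:, None]
            m = cutoff_rel * R + cap_slack * R
            lo = np.minimum(q0, q1) - m[:, None]
            hi = np.maximum(q0, q1) + m[:, None]
            keep = np.all(hi >= box[0], axis=1) & np.all(lo <= box[1], axis=1)
            if np.any(keep):
                outs.append((q0[keep], u[keep], L[keep], R[keep], dchi[keep]))
    return (
        np.concatenate([o[0] for o in outs]),
        np.concatenate([o[1] for o in outs]),
        np.concatenate([o[2] for o in outs]),
        np.concatenate([o[3] for o in outs]),
        np.concatenate([o[4] for o in outs]),
    )


def build_field_map(
    net: VascularNetwork,
    params: FieldParams = FieldParams(),
    grid_spacing: float = 1.0,
    periodic_xy: bool = False,
    cutoff_rel: float | None = DEFAULT_CUTOFF_REL,
    cap_slack: float = 1.0,
    dtype=np.float32,
    dchi: np.ndarray | None = None,
) -> FrequencyFieldMap:
    """Superpose per-segment dipole fields on a regular grid.

    Each segment contributes only where a point's axial projection falls
    within the segment (plus ``cap_slack`` radii at the caps) and within
    ``cutoff_rel * R`` of the axis (``cutoff_rel=None`` disables the cutoff
    for exact-summation oracle tests).  ``periodic_xy`` adds the in-plane
    periodic images of segments so the field is consistent with the wrapped
    random walk.  ``dchi`` overrides the per-segment susceptibility
    differences (otherwise computed from assigned SO2/hematocrit).
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if dchi is None:
        if np.any(np.isnan(net.so2)) or np.any(np.isnan(net.hct)):
            raise ValueError("assign physiology before building the field map")
        dchi = params.chi_do_coeff * net.hct * (1.0 - net.so2)
    dchi = np.asarray(dchi, dtype=float)
    box = net.box.copy()
    shape = _grid_shape(box, grid_spacing)
    values = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.uint8)
    sel = np.ones(len(net), dtype=bool)
    p0, u, L, R = _segment_arrays(net, sel)
    p0 = p0 - box[0]
    local_box = np.stack([np.zeros(3), box[1] - box[0]])
    cut = -1.0 if cutoff_rel is None else float(cutoff_rel)
    fp0, fu, fL, fR, fdchi = (p0, u, L, R, dchi)
    if periodic_xy:
        fp0, fu, fL, fR, fdchi = _with_periodic_images(
            p0, u, L, R, dchi, local_box, cut if cut > 0 else 1e6, cap_slack
        )
    origin = np.zeros(3)
    accumulate_field(
        values, origin, grid_spacing, fp0, fu, fL, fR, fdchi,
        params.gamma * params.b0, cut, cap_slack,
    )
    accumulate_mask(mask, origin, grid_spacing, fp0, fu, fL, fR)
    values *= params.unit_scale
    return FrequencyFieldMap(
        origin=box[0].copy(),
        spacing=grid_spacing,
        values=values.astype(dtype, copy=False),
        mask=mask,
        box=box,
        params=params,
    )


@dataclass
class FieldBasis:
    """Per-compartment unit fields enabling cheap SO2/hematocrit re-weighting.

    The dipole field is linear in each segment's ``dchi``, and within a
    compartment ``dchi = chi_do_coeff * Hct_c * (1 - SO2_c)`` is a common
    scalar.  Storing one field per compartment computed at unit
    ``Hct * (1 - SO2)`` lets any oxygenation/hematocrit state be synthesized
    as a weighted sum without re-summing segments.
    """

    fields: np.ndarray  # (3, nx, ny, nz) float32: artery, vein, microvessel
    mask: np.ndarray
    origin: np.ndarray
    spacing: float
    box: np.ndarray
    params: FieldParams

    ORDER = ("artery", "vein", "microvessel")

    def weights(self, ox: OxygenationState, hct: HematocritScheme) -> np.ndarray:
        return np.array(
            [
                hct.for_compartment(_COMP_ORDER[c]) * (1.0 - ox.for_compartment(_COMP_ORDER[c]))
                for c in self.ORDER
            ]
        )

    def combine(self, ox: OxygenationState, hct: HematocritScheme) -> FrequencyFieldMap:
        w = self.weights(ox, hct)
        values = np.tensordot(w, self.fields, axes=1).astype(np.float32)
        return FrequencyFieldMap(
            origin=self.origin.copy(),
            spacing=self.spacing,
            values=values,
            mask=self.mask,
            box=self.box.copy(),
            params=self.params,
        )


def build_field_basis(
    net: VascularNetwork,
    params: FieldParams = FieldParams(),
    grid_spacing: float = 3.0,
    periodic_xy: bool = True,
    cutoff_rel: float | None = DEFAULT_CUTOFF_REL,
    cap_slack: float = 1.0,
) -> FieldBasis:
    """Build the three per-compartment unit fields and the shared vessel mask."""
    if np.any(net.compartment == UNLABELED):
        raise ValueError("network contains unlabeled segments")
    box = net.box.copy()
    shape = _grid_shape(box, grid_spacing)
    fields = np.zeros((3,) + shape, dtype=np.float32)
    mask = np.zeros(shape, dtype=np.uint8)
    local_box = np.stack([np.zeros(3), box[1] - box[0]])
    cut = -1.0 if cutoff_rel is None else float(cutoff_rel)
    origin = np.zeros(3)
    for ci, comp in enumerate(FieldBasis.ORDER):
        sel = net.compartment == _COMP_ORDER[comp]
        if not np.any(sel):
            continue
        p0, u, L, R = _segment_arrays(net, sel)
        p0 = p0 - box[0]
        dchi = np.full(len(R), params.chi_do_coeff)
        if periodic_xy:
            p0, u, L, R, dchi = _with_periodic_images(
                p0, u, L, R, dchi, local_box, cut if cut > 0 else 1e6, cap_slack
            )
        vals = np.zeros(shape, dtype=np.float64)
        accumulate_field(
            vals, origin, grid_spacing, p0, u, L, R, dchi,
            params.gamma * params.b0, cut, cap_slack,
        )
        accumulate_mask(mask, origin, grid_spacing, p0, u, L, R)
        fields[ci] = (vals * params.unit_scale).astype(np.float32)
    return FieldBasis(
        fields=fields, mask=mask, origin=box[0].copy(), spacing=grid_spacing,
        box=box, params=params,
    )
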