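"""Vascular network graphs: loading, labeling, laminar partitioning, baseline CBV.

The voxel anatomy is a collection of straight cylindrical vessel segments
with endpoint coordinates (micrometres), a radius and a length, plus optional
segment-to-segment connectivity.  The coordinate convention throughout the
package is: ``z`` is cortical depth, ``z = 0`` at the pial surface, increasing
toward the white-matter boundary.  Laminae are indexed 1 (pial) to
``n_laminae`` (deep) as half-open slabs ``[z_i, z_{i+1})`` with the deepest
slab closed.

Segment volumes are always the analytic cylinder volume ``pi * R**2 * L``
using the stored length field; overlap between vessels is not corrected,
matching the usual definition of baseline CBV for vectorized vascular data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: compartment label codes used in the packed arrays
COMPARTMENTS = ("unlabeled", "artery", "vein", "microvessel")
UNLABELED, ARTERY, VEIN, MICROVESSEL = 0, 1, 2, 3
_CODE = {name: i for i, name in enumerate(COMPARTMENTS)}

#: default radius thresholds (micrometres) for compartment classification
CAPILLARY_MAX_RADIUS = 6.0
ARTERY_RADIUS_RANGE = (6.0, 11.0)
VEIN_RADIUS_RANGE = (11.0, 36.0)
#: default extent of the "near the pial surface" band used for label seeding
PIAL_BAND = 100.0

_COLUMNS = ["id", "x1", "y1", "z1", "x2", "y2", "z2", "radius_um", "length_um"]


@dataclass
class VesselSegment:
    """A single cylindrical vessel segment (convenience record view)."""

    id: int
    p_start: np.ndarray
    p_end: np.ndarray
    radius: float
    length: float
    compartment: str = "unlabeled"
    so2: float = np.nan
    hct: float = np.nan

    def __post_init__(self) -> None:
        self.p_start = np.asarray(self.p_start, dtype=float)
        self.p_end = np.asarray(self.p_end, dtype=float)
        if self.radius <= 0:
            raise ValueError(f"segment {self.id}: radius must be positive")
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: length must be positive")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"segment {self.id}: unknown compartment {self.compartment!r}")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the segment."""
        d = self.p_end - self.p_start
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError(f"segment {self.id}: degenerate endpoints")
        return d / n

    @property
    def volume(self) -> float:
        """Cylinder volume pi*R^2*L in um^3 (stored length is authoritative)."""
        return np.pi * self.radius**2 * self.length


class VascularNetwork:
    """Array-backed collection of vessel segments with connectivity.

    Parameters
    ----------
    p_start, p_end
        ``(n, 3)`` endpoint coordinates in micrometres.
    radius, length
        ``(n,)`` per-segment radius and length in micrometres.  The stored
        length is authoritative for volumes; a mismatch of more than 5 %
        against the endpoint distance is logged but not rejected (curved
        source vessels legitimately store arc length).
    compartment
        ``(n,)`` integer codes into :data:`COMPARTMENTS`, or omitted.
    adjacency
        mapping segment id -> set of neighbouring segment ids (symmetrized).
    box
        ``(2, 3)`` lower/upper corner; inferred from the coordinates if None.
    """

    def __init__(
        self,
        p_start: np.ndarray,
        p_end: np.ndarray,
        radius: np.ndarray,
        length: np.ndarray,
        compartment: np.ndarray | None = None,
        ids: np.ndarray | None = None,
        adjacency: dict[int, set[int]] | None = None,
        box: np.ndarray | None = None,
        name: str = "network",
    ):
        self.p_start = np.atleast_2d(np.asarray(p_start, dtype=float))
        self.p_end = np.atleast_2d(np.asarray(p_end, dtype=float))
        self.radius = np.asarray(radius, dtype=float).ravel()
        self.length = np.asarray(length, dtype=float).ravel()
        n = len(self.radius)
        if self.p_start.shape != (n, 3) or self.p_end.shape != (n, 3):
            raise ValueError("endpoint arrays must have shape (n, 3)")
        if np.any(self.radius <= 0):
            bad = int(np.flatnonzero(self.radius <= 0)[0])
            raise ValueError(f"non-positive radius at segment index {bad}")
        if np.any(self.length <= 0):
            bad = int(np.flatnonzero(self.length <= 0)[0])
            raise ValueError(f"non-positive length at segment index {bad}")
        self.ids = (
            np.arange(n, dtype=np.int64) if ids is None else np.asarray(ids, dtype=np.int64)
        )
        if compartment is None:
            self.compartment = np.zeros(n, dtype=np.int8)
        else:
            self.compartment = np.asarray(compartment, dtype=np.int8).copy()
        self.so2 = np.full(n, np.nan)
        self.hct = np.full(n, np.nan)
        self.adjacency: dict[int, set[int]] = {int(i): set() for i in self.ids}
        if adjacency:
            for a, nbrs in adjacency.items():
                for b in nbrs:
                    self.adjacency[int(a)].add(int(b))
                    self.adjacency[int(b)].add(int(a))
        if box is None:
            lo = np.minimum(self.p_start.min(axis=0), self.p_end.min(axis=0))
            hi = np.maximum(self.p_start.max(axis=0), self.p_end.max(axis=0))
            box = np.stack([lo, hi])
        self.box = np.asarray(box, dtype=float)
        self.name = name
        self._check_lengths()

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.radius)

    def _check_lengths(self) -> None:
        d = np.linalg.norm(self.p_end - self.p_start, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(d - self.length) / self.length
        n_bad = int(np.sum(rel > 0.05))
        if n_bad:
            logger.warning(
                "%d/%d segments have endpoint distance deviating >5%% from the "
                "stored length; stored length kept authoritative for volumes",
                n_bad,
                len(self),
            )

    @property
    def pial_z(self) -> float:
        return float(self.box[0, 2])

    @property
    def wm_z(self) -> float:
        return float(self.box[1, 2])

    @property
    def axis_unit(self) -> np.ndarray:
        """(n, 3) unit axis vectors from geometric endpoints."""
        d = self.p_end - self.p_start
        n = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.where(n == 0, 1.0, n)

    @property
    def geometric_length(self) -> np.ndarray:
        return np.linalg.norm(self.p_end - self.p_start, axis=1)

    @property
    def volume(self) -> np.ndarray:
        """Per-segment cylinder volume pi*R^2*L in um^3."""
        return np.pi * self.radius**2 * self.length

    def compartment_names(self) -> np.ndarray:
        return np.asarray(COMPARTMENTS)[self.compartment]

    @property
    def segments(self) -> list[VesselSegment]:
        names = self.compartment_names()
        return [
            VesselSegment(
                int(self.ids[i]),
                self.p_start[i],
                self.p_end[i],
                float(self.radius[i]),
                float(self.length[i]),
                str(names[i]),
                float(self.so2[i]),
                float(self.hct[i]),
            )
            for i in range(len(self))
        ]

    def copy(self) -> "VascularNetwork":
        out = VascularNetwork(
            self.p_start.copy(),
            self.p_end.copy(),
            self.radius.copy(),
            self.length.copy(),
            self.compartment.copy(),
            self.ids.copy(),
            {k: set(v) for k, v in self.adjacency.items()},
            self.box.copy(),
            self.name,
        )
        out.so2 = self.so2.copy()
        out.hct = self.hct.copy()
        return out

    def graph(self, mask: np.ndarray | None = None) -> nx.Graph:
        """Connectivity as an (optionally masked) networkx graph of segment ids."""
        g = nx.Graph()
        keep = set(self.ids[mask].tolist()) if mask is not None else set(self.ids.tolist())
        g.add_nodes_from(keep)
        for a, nbrs in self.adjacency.items():
            if a not in keep:
                continue
            for b in nbrs:
                if b in keep:
                    g.add_edge(a, b)
        return g

    def validate(self) -> None:
        """Raise if segment endpoints escape the bounding box (small slack)."""
        eps = 1e-6
        for p in (self.p_start, self.p_end):
            if np.any(p < self.box[0] - eps) or np.any(p > self.box[1] + eps):
                raise ValueError("segment endpoints outside the network box")


# ---------------------------------------------------------------------------
# on-disk dialect
# ---------------------------------------------------------------------------


def load_network(path, dialect: str = "csv") -> VascularNetwork:
    """Read a network from the columnar text dialect.

    The dialect is a comma- or tab-separated table with header columns
    ``id,x1,y1,z1,x2,y2,z2,radius_um,length_um`` plus optional
    ``compartment`` and ``neighbors`` (semicolon-separated ids).  Vectorized
    matrix-container source files (m-by-3 position block plus diameter and
    length column vectors) need a one-off conversion to this table; see the
    README for the column mapping.
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed network file {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in _COLUMNS:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(f"{path}: malformed value in column {col!r} at line {bad[0] + 2}")
        df[col] = pd.to_numeric(df[col])
    for col, what in (("radius_um", "radius"), ("length_um", "length")):
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValueError(f"{path}: non-positive {what} at line {bad[0] + 2}")
    comp = None
    if "compartment" in df.columns:
        names = df["compartment"].fillna("unlabeled").astype(str)
        unknown = set(names) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"{path}: unknown compartment labels {sorted(unknown)}")
        comp = np.array([_CODE[c] for c in names], dtype=np.int8)
    adjacency: dict[int, set[int]] = {}
    if "neighbors" in df.columns:
        for sid, cell in zip(df["id"], df["neighbors"].fillna("")):
            cell = str(cell).strip()
            if cell:
                adjacency[int(sid)] = {int(tok) for tok in cell.split(";") if tok}
    net = VascularNetwork(
        df[["x1", "y1", "z1"]].to_numpy(),
        df[["x2", "y2", "z2"]].to_numpy(),
        df["radius_um"].to_numpy(),
        df["length_um"].to_numpy(),
        compartment=comp,
        ids=df["id"].to_numpy(np.int64),
        adjacency=adjacency,
    )
    return net


def save_network(net: VascularNetwork, path) -> None:
    """Write the canonical comma-separated form (stable byte-for-byte)."""
    names = net.compartment_names()
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(_COLUMNS + ["compartment", "neighbors"]) + "\n")
        for i in range(len(net)):
            nbrs = ";".join(str(b) for b in sorted(net.adjacency.get(int(net.ids[i]), ())))
            vals = [
                str(int(net.ids[i])),
                *(format(v, ".10g") for v in net.p_start[i]),
                *(format(v, ".10g") for v in net.p_end[i]),
                format(net.radius[i], ".10g"),
                format(net.length[i], ".10g"),
                str(names[i]),
                nbrs,
            ]
            fh.write(",".join(vals) + "\n")


# ---------------------------------------------------------------------------
# classification and relabeling
# ---------------------------------------------------------------------------


def classify_segments(
    net: VascularNetwork,
    capillary_max_radius: float = CAPILLARY_MAX_RADIUS,
    artery_radius_range: tuple[float, float] = ARTERY_RADIUS_RANGE,
    vein_radius_range: tuple[float, float] = VEIN_RADIUS_RANGE,
    pial_band: float = PIAL_BAND,
) -> VascularNetwork:
    """Label every segment as microvessel, artery or vein.

    Segments with radius below ``capillary_max_radius`` are microvessels.
    Macrovessels lying in the pial band (top ``pial_band`` micrometres) are
    seeded by radius: arteries in ``artery_radius_range``, veins in
    ``vein_radius_range`` (and above).  Remaining (penetrating) macrovessels
    inherit the label of their nearest connected labeled segment following
    the vessel path; orphans with no connected seed fall back to their own
    radius and are logged.
    """
    out = net.copy()
    r = out.radius
    micro = r < capillary_max_radius
    out.compartment[micro] = MICROVESSEL

    macro = ~micro
    z_top = np.minimum(out.p_start[:, 2], out.p_end[:, 2])
    in_band = macro & (z_top <= out.pial_z + pial_band)
    by_radius = np.where(r >= vein_radius_range[0], VEIN, ARTERY).astype(np.int8)
    out.compartment[in_band] = by_radius[in_band]

    # propagate along the macrovessel connectivity from the pial seeds
    pending = macro & ~in_band
    if np.any(pending):
        g = out.graph(mask=macro)
        idx_of = {int(sid): i for i, sid in enumerate(out.ids)}
        seeds = [int(s) for s in out.ids[in_band]]
        if seeds:
            # multi-source BFS; each pending macrovessel takes the label of the
            # nearest seed along the vessel path, larger seed radius wins ties
            order = sorted(seeds, key=lambda s: -out.radius[idx_of[s]])
            dist = {s: 0 for s in order}
            label = {s: out.compartment[idx_of[s]] for s in order}
            frontier = list(order)
            while frontier:
                nxt = []
                for a in frontier:
                    for b in g.neighbors(a):
                        if b not in dist:
                            dist[b] = dist[a] + 1
                            label[b] = label[a]
                            nxt.append(b)
                frontier = nxt
            for sid in out.ids[pending]:
                sid = int(sid)
                if sid in label:
                    out.compartment[idx_of[sid]] = label[sid]
        orphan = pending & (out.compartment == UNLABELED)
        if np.any(orphan):
            logger.warning(
                "%d macrovessel segments have no connected path to a pial seed; "
                "falling back to their own radius range",
                int(orphan.sum()),
            )
            out.compartment[orphan] = by_radius[orphan]
    return out


def macrovessel_trunks(net: VascularNetwork) -> list[list[int]]:
    """Connected groups of macrovessel segment ids (pial vessel + its tree)."""
    macro = (net.compartment == ARTERY) | (net.compartment == VEIN)
    g = net.graph(mask=macro)
    return [sorted(c) for c in nx.connected_components(g)]


def relabel_artery_vein_ratio(
    net: VascularNetwork, ratio: tuple[int, int] = (3, 1), seed: int = 0
) -> VascularNetwork:
    """Reassign macrovessel trunk labels to approximate an artery:vein ratio.

    Trunks (connected macrovessel groups) are sorted by their maximum pial
    radius, descending; the largest ``max(1, round(n/(a+v)*v))`` trunks are
    relabeled vein (pial veins are the largest vessels in cortical data) and
    the remainder artery.  Ties in radius are broken deterministically by the
    given seed.  Microvessels are untouched; each trunk keeps a single label
    (the per-vessel label-discontinuity mode of split trunks is intentionally
    not applied).
    """
    a, v = ratio
    if a <= 0 or v <= 0:
        raise ValueError("ratio parts must be positive")
    out = net.copy()
    trunks = macrovessel_trunks(out)
    if not trunks:
        return out
    if len(trunks) < 4:
        logger.warning("only %d macrovessel trunks; best-effort %d:%d split", len(trunks), a, v)
    idx_of = {int(sid): i for i, sid in enumerate(out.ids)}
    rng = np.random.default_rng(seed)
    keyed = []
    for t in trunks:
        rows = [idx_of[s] for s in t]
        keyed.append((max(out.radius[rows]), rng.random(), t, rows))
    keyed.sort(key=lambda kv: (-kv[0], kv[1]))
    n_vein = max(1, round(len(trunks) * v / (a + v))) if len(trunks) > 1 else 1
    for rank, (_, _, _, rows) in enumerate(keyed):
        out.compartment[rows] = VEIN if rank < n_vein else ARTERY
    return out


# ---------------------------------------------------------------------------
# laminar partition and CBV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LaminarPartition:
    """Equal-thickness depth slabs between the pial surface and WM boundary."""

    boundaries: np.ndarray  # (n+1,) increasing z values, um
    xy_area: float  # um^2

    @property
    def n_laminae(self) -> int:
        return len(self.boundaries) - 1

    @property
    def thickness(self) -> float:
        return float(self.boundaries[1] - self.boundaries[0])

    @property
    def lamina_volume(self) -> float:
        """Volume of one slab in um^3 (all slabs are equal)."""
        return self.xy_area * self.thickness

    def lamina_of(self, z: np.ndarray) -> np.ndarray:
        """0-based lamina index; half-open slabs, deepest slab closed."""
        z = np.asarray(z, dtype=float)
        z0, z1 = self.boundaries[0], self.boundaries[-1]
        if np.any(z < z0) or np.any(z > z1):
            raise ValueError("depth outside the partitioned range")
        idx = np.floor((z - z0) / self.thickness).astype(np.int64)
        return np.minimum(idx, self.n_laminae - 1)

    def group_of(self, lamina: np.ndarray) -> np.ndarray:
        """Four-group laminar labels used for reporting (16 laminae only)."""
        if self.n_laminae != 16:
            raise ValueError("laminar grouping is defined for 16 laminae")
        names = np.asarray(["top", "top_middle", "middle_bottom", "bottom"])
        return names[np.asarray(lamina) // 4]


def partition_laminae(net: VascularNetwork, n: int = 16) -> LaminarPartition:
    """Split the cortical thickness into ``n`` equal slabs."""
    if n < 1:
        raise ValueError("number of laminae must be >= 1")
    if net.wm_z <= net.pial_z:
        raise ValueError("network has non-positive cortical thickness")
    boundaries = np.linspace(net.pial_z, net.wm_z, n + 1)
    ext = net.box[1] - net.box[0]
    return LaminarPartition(boundaries=boundaries, xy_area=float(ext[0] * ext[1]))


@dataclass
class CBVProfile:
    """Per-lamina blood volume fractions split by vascular compartment."""

    artery: np.ndarray
    vein: np.ndarray
    microvessel: np.ndarray
    partition: LaminarPartition = field(repr=False)

    @property
    def total(self) -> np.ndarray:
        return self.artery + self.vein + self.microvessel

    @property
    def macro(self) -> np.ndarray:
        return self.artery + self.vein

    def to_frame(self) -> pd.DataFrame:
        n = len(self.artery)
        return pd.DataFrame(
            {
                "lamina": np.arange(1, n + 1),
                "cbv_artery": self.artery,
                "cbv_vein": self.vein,
                "cbv_microvessel": self.microvessel,
                "cbv_total": self.total,
            }
        )


def compute_cbv_profile(net: VascularNetwork, part: LaminarPartition) -> CBVProfile:
    """Analytic cylinder-volume CBV per lamina and compartment.

    Segments crossing a slab boundary are apportioned linearly by the axial
    (z) length fraction falling inside each slab.  Purely horizontal segments
    belong entirely to the slab of their z coordinate.
    """
    if np.any(net.compartment == UNLABELED):
        raise ValueError("all segments must be labeled before computing CBV")
    n = part.n_laminae
    vols = np.zeros((n, 3))  # artery, vein, micro
    b = part.boundaries
    za = np.minimum(net.p_start[:, 2], net.p_end[:, 2])
    zb = np.maximum(net.p_start[:, 2], net.p_end[:, 2])
    seg_vol = net.volume
    comp_col = net.compartment - 1  # artery->0, vein->1, micro->2
    span = zb - za
    flat = span <= 0
    # horizontal segments: all volume into the slab containing their z
    if np.any(flat):
        lam = part.lamina_of(za[flat])
        np.add.at(vols, (lam, comp_col[flat]), seg_vol[flat])
    idx = np.flatnonzero(~flat)
    if idx.size:
        # overlap of [za, zb] with each slab, vectorized over slabs
        lo = np.maximum(za[idx, None], b[None, :-1])
        hi = np.minimum(zb[idx, None], b[None, 1:])
        frac = np.clip(hi - lo, 0.0, None) / span[idx, None]
        contrib = frac * seg_vol[idx, None]
        for c in range(3):
            sel = comp_col[idx] == c
            if np.any(sel):
                vols[:, c] += contrib[sel].sum(axis=0)
    slab_vol = part.lamina_volume
    return CBVProfile(
        artery=vols[:, 0] / slab_vol,
        vein=vols[:, 1] / slab_vol,
        microvessel=vols[:, 2] / slab_vol,
        partition=part,
    )
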