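"""Random-walk dephasing of extravascular spins through a frequency field.

Walkers diffuse with isotropic Gaussian steps (per-axis s.d.
``sqrt(2 D dt)``), are rejected and redrawn at vessel walls (impermeable
network), wrap periodically in x/y, and are invalidated and resimulated if
they touch the pial or white-matter face.  The per-lamina complex ensemble
phasor ``A(t) = <exp(-i phi(t))>`` is recorded on a subsampled time axis;
gradient-echo and spin-echo readings are produced in the same pass (the
trajectories are sequence-independent, only the phase bookkeeping differs:
spin-echo negates accumulated phase at TE/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import h5py
import numpy as np

from ._kernels import walk_states
from .field import FieldBasis, FrequencyFieldMap, HematocritScheme, OxygenationState
from .network import LaminarPartition

_MASK_INSIDE_LIMIT = 0.5  # abort if less than half the volume is extravascular


@dataclass(frozen=True)
class SequenceParams:
    """Pulse-sequence and walk settings for one simulation.

    ``te`` and ``dt`` in ms, ``d_coeff`` in um^2/ms.  ``n_spins`` defaults to
    a desk-scale 1e5 (the full-scale reference condition is 20 repetitions of
    5e7 spins).  ``store_every`` subsamples the recorded time axis; phase is
    always integrated at every ``dt``.
    """

    kind: str = "GE"  # "GE" or "SE"
    te: float = 27.0
    dt: float = 0.025
    d_coeff: float = 1.0
    n_spins: int = 100_000
    n_reps: int = 1
    seed: int = 0
    store_every: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("GE", "SE"):
            raise ValueError("kind must be 'GE' or 'SE'")
        if self.te <= 0 or self.dt <= 0:
            raise ValueError("te and dt must be positive")
        if self.d_coeff < 0:
            raise ValueError("d_coeff must be non-negative")
        steps = self.te / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("te must be an integer number of time steps")
        if self.kind == "SE":
            half = round(steps) / 2
            if abs(half - round(half)) > 1e-9:
                raise ValueError("SE needs an even number of steps (flip at TE/2)")
        if round(steps) % self.store_every:
            raise ValueError("te must fall on a stored sample (te/dt % store_every == 0)")

    @property
    def n_steps(self) -> int:
        return round(self.te / self.dt)

    @property
    def sigma(self) -> float:
        return float(np.sqrt(2.0 * self.d_coeff * self.dt))


@dataclass
class SpinEnsemble:
    """Initial walker positions (box-local um) and their lamina attribution."""

    positions: np.ndarray  # (n, 3)
    lamina: np.ndarray  # (n,) int64, 0-based, by initial depth
    n_laminae: int
    seed: int


@dataclass
class LaminarAttenuation:
    """Per-lamina complex attenuation A(t), per Monte-Carlo repetition.

    ``phasor`` has shape (n_reps, n_laminae, n_times) with ``times[0] = 0``
    and ``A(0) = 1``.  The magnitude |A| is the extravascular dephasing
    factor multiplying the intrinsic tissue decay in the signal model.
    """

    times: np.ndarray  # (n_times,), ms
    phasor: np.ndarray  # complex
    counts: np.ndarray  # (n_reps, n_laminae) walkers per lamina
    kind: str = "GE"

    @property
    def n_reps(self) -> int:
        return self.phasor.shape[0]

    @property
    def n_laminae(self) -> int:
        return self.phasor.shape[1]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.phasor)

    def mean_magnitude(self) -> np.ndarray:
        """|ensemble-mean phasor| pooled over repetitions, per lamina/time."""
        w = self.counts[:, :, None].astype(float)
        pooled = (self.phasor * w).sum(axis=0) / np.maximum(w.sum(axis=0), 1.0)
        return np.abs(pooled)

    def time_index(self, t: float) -> int:
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-6:
            raise ValueError(f"time {t} ms not on the stored axis")
        return idx

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f["times"] = self.times
            f.create_dataset("phasor", data=self.phasor, compression="gzip")
            f["counts"] = self.counts
            f.attrs["kind"] = self.kind

    @classmethod
    def load(cls, path) -> "LaminarAttenuation":
        with h5py.File(path, "r") as f:
            return cls(
                times=f["times"][:],
                phasor=f["phasor"][:],
                counts=f["counts"][:],
                kind=str(f.attrs["kind"]),
            )


def initialize_spins(
    fieldmap: FrequencyFieldMap | FieldBasis,
    part: LaminarPartition,
    n: int,
    seed: int,
) -> SpinEnsemble:
    """Uniform extravascular seeding by rejection sampling against the mask.

    Lamina attribution is by initial depth (walkers cross laminae later; the
    starting position is the unambiguous choice).
    """
    mask = fieldmap.mask
    if mask.mean() > _MASK_INSIDE_LIMIT:
        raise RuntimeError(
            f"vessel mask covers {mask.mean():.0%} of the volume; "
            "extravascular fraction below 50 % - mask suspect"
        )
    ext = fieldmap.box[1] - fieldmap.box[0]
    h = fieldmap.spacing
    rng = np.random.default_rng(seed)
    out = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(0.0, 1.0, size=(max(2 * (n - got), 1024), 3)) * ext
        idx = np.minimum((cand / h + 0.5).astype(np.int64), np.array(mask.shape) - 1)
        ok = mask[idx[:, 0], idx[:, 1], idx[:, 2]] == 0
        take = min(int(ok.sum()), n - got)
        out[got : got + take] = cand[ok][:take]
        got += take
    lam = part.lamina_of(out[:, 2] + fieldmap.box[0, 2])
    return SpinEnsemble(positions=out, lamina=lam, n_laminae=part.n_laminae, seed=seed)


def _run_walk(
    fields: np.ndarray,
    weights: np.ndarray,
    mask: np.ndarray,
    spacing: float,
    extent: np.ndarray,
    ens: SpinEnsemble,
    dt: float,
    sigma: float,
    n_steps: int,
    store_every: int,
    flip_step: int,
    seed: int,
    z_periodic: bool,
    wall_tries: int = 10,
    walker_retries: int = 100,
):
    sum_ge, sum_se, counts, n_failed = walk_states(
        np.ascontiguousarray(fields, dtype=np.float32),
        np.ascontiguousarray(weights, dtype=np.float64),
        mask,
        float(spacing),
        float(extent[0]),
        float(extent[1]),
        float(extent[2]),
        float(dt),
        float(sigma),
        int(n_steps),
        int(store_every),
        int(flip_step),
        np.ascontiguousarray(ens.positions[:, 0]),
        np.ascontiguousarray(ens.positions[:, 1]),
        np.ascontiguousarray(ens.positions[:, 2]),
        np.ascontiguousarray(ens.lamina, dtype=np.int64),
        int(ens.n_laminae),
        int(seed) % 2147483647,
        bool(z_periodic),
        int(wall_tries),
        int(walker_retries),
    )
    if n_failed:
        raise RuntimeError(
            f"{n_failed} walkers exhausted their retry budget at the pial/WM "
            "faces; the geometry leaves too little room near a boundary"
        )
    denom = np.maximum(counts, 1).astype(float)[:, None]
    a_ge = (sum_ge[..., 0] + 1j * sum_ge[..., 1]) / denom
    a_se = (sum_se[..., 0] + 1j * sum_se[..., 1]) / denom
    return a_ge, a_se, counts


def _prepend_t0(a_states: np.ndarray) -> np.ndarray:
    shape = a_states.shape[:-1] + (1,)
    return np.concatenate([np.ones(shape, dtype=a_states.dtype), a_states], axis=-1)


def simulate_dephasing(
    ens: SpinEnsemble,
    fieldmap: FrequencyFieldMap,
    seq: SequenceParams,
    z_periodic: bool = False,
) -> LaminarAttenuation:
    """Walk one ensemble through one field for one sequence.

    The ensemble is re-seeded per repetition (``seed + rep`` streams for the
    positions, independent walk streams per walker).  For SE the accumulated
    phases are negated at TE/2.
    """
    n_steps = seq.n_steps
    flip = n_steps // 2 if seq.kind == "SE" else 0
    weights = np.ones((1, 1))
    fields = fieldmap.values[None, ...]
    extent = fieldmap.box[1] - fieldmap.box[0]
    reps_phasor = []
    reps_counts = []
    for rep in range(seq.n_reps):
        e = ens if rep == 0 else _reseed(ens, fieldmap, seq.seed + 7919 * rep)
        a_ge, a_se, counts = _run_walk(
            fields, weights, fieldmap.mask, fieldmap.spacing, extent, e,
            seq.dt, seq.sigma, n_steps, seq.store_every, flip,
            seed=seq.seed + 104729 * rep, z_periodic=z_periodic,
        )
        reps_phasor.append((a_se if seq.kind == "SE" else a_ge)[0])
        reps_counts.append(counts)
    times = np.concatenate([[0.0], seq.dt * seq.store_every * np.arange(1, n_steps // seq.store_every + 1)])
    return LaminarAttenuation(
        times=times,
        phasor=_prepend_t0(np.stack(reps_phasor)),
        counts=np.stack(reps_counts),
        kind=seq.kind,
    )


def simulate_ge_se(
    ens: SpinEnsemble,
    fieldmap: FrequencyFieldMap,
    te_ge: float = 27.0,
    te_se: float = 50.0,
    dt: float = 0.025,
    d_coeff: float = 1.0,
    n_reps: int = 1,
    seed: int = 0,
    store_every: int = 8,
    z_periodic: bool = False,
) -> tuple[LaminarAttenuation, LaminarAttenuation]:
    """Both sequence readings from one set of trajectories.

    Trajectories are sequence-independent; the gradient-echo reading is the
    free-precession phasor truncated at ``te_ge`` and the spin-echo reading
    refocuses at ``te_se / 2``.
    """
    if te_se < te_ge:
        raise ValueError("te_se must be >= te_ge")
    n_steps = round(te_se / dt)
    if n_steps % 2 or n_steps % store_every or round(te_ge / dt) % store_every:
        raise ValueError("TEs must fall on stored samples and allow a TE/2 flip")
    weights = np.ones((1, 1))
    fields = fieldmap.values[None, ...]
    extent = fieldmap.box[1] - fieldmap.box[0]
    ge_reps, se_reps, counts_reps = [], [], []
    for rep in range(n_reps):
        e = ens if rep == 0 else _reseed(ens, fieldmap, ens.seed + 7919 * rep)
        a_ge, a_se, counts = _run_walk(
            fields, weights, fieldmap.mask, fieldmap.spacing, extent, e,
            dt, float(np.sqrt(2.0 * d_coeff * dt)), n_steps, store_every,
            n_steps // 2, seed=seed + 104729 * rep, z_periodic=z_periodic,
        )
        ge_reps.append(a_ge[0])
        se_reps.append(a_se[0])
        counts_reps.append(counts)
    times = np.concatenate([[0.0], dt * store_every * np.arange(1, n_steps // store_every + 1)])
    n_ge = round(te_ge / dt) // store_every
    att_ge = LaminarAttenuation(
        times=times[: n_ge + 1],
        phasor=_prepend_t0(np.stack(ge_reps))[..., : n_ge + 1],
        counts=np.stack(counts_reps),
        kind="GE",
    )
    att_se = LaminarAttenuation(
        times=times,
        phasor=_prepend_t0(np.stack(se_reps)),
        counts=np.stack(counts_reps),
        kind="SE",
    )
    return att_ge, att_se


def _reseed(ens: SpinEnsemble, fieldmap, seed: int) -> SpinEnsemble:
    from .network import LaminarPartition as _LP

    boundaries = np.linspace(
        fieldmap.box[0, 2], fieldmap.box[1, 2], ens.n_laminae + 1
    )
    ext = fieldmap.box[1] - fieldmap.box[0]
    part = _LP(boundaries=boundaries, xy_area=float(ext[0] * ext[1]))
    return initialize_spins(fieldmap, part, len(ens.lamina), seed)


@dataclass
class StateSweepResult:
    """GE and SE attenuations for every susceptibility state of a sweep."""

    times_ge: np.ndarray
    times_se: np.ndarray
    a_ge: np.ndarray  # (n_reps, n_states, n_lam, n_times_ge) complex
    a_se: np.ndarray
    counts: np.ndarray  # (n_reps, n_lam)

    def attenuation(self, state: int, kind: str) -> LaminarAttenuation:
        if kind == "GE":
            return LaminarAttenuation(self.times_ge, self.a_ge[:, state], self.counts, "GE")
        return LaminarAttenuation(self.times_se, self.a_se[:, state], self.counts, "SE")


def simulate_state_sweep(
    basis: FieldBasis,
    part: LaminarPartition,
    states: list[tuple[OxygenationState, HematocritScheme]],
    te_ge: float = 27.0,
    te_se: float = 50.0,
    dt: float = 0.025,
    d_coeff: float = 1.0,
    n_spins: int = 100_000,
    n_reps: int = 1,
    seed: int = 0,
    store_every: int = 8,
    z_periodic: bool = False,
) -> StateSweepResult:
    """One walk per repetition evaluates every oxygenation/hematocrit state.

    Trajectories depend only on the vessel mask, and the accrued phase is
    linear in the per-compartment basis phases, so a single pass yields the
    attenuation of every state and of both sequences: the spin-echo readout
    refocuses at ``te_se / 2``; the gradient-echo reading is the
    free-precession phasor, truncated at ``te_ge``.
    """
    if te_se < te_ge:
        raise ValueError("te_se must be >= te_ge (shared-trajectory pass)")
    n_steps = round(te_se / dt)
    if n_steps % 2 or n_steps % store_every or round(te_ge / dt) % store_every:
        raise ValueError("TEs must fall on stored samples and allow a TE/2 flip")
    weights = np.stack([basis.weights(ox, hct) for ox, hct in states])
    extent = basis.box[1] - basis.box[0]
    a_ge_reps, a_se_reps, counts_reps = [], [], []
    for rep in range(n_reps):
        ens = initialize_spins(basis, part, n_spins, seed + 7919 * rep)
        a_ge, a_se, counts = _run_walk(
            basis.fields, weights, basis.mask, basis.spacing, extent, ens,
            dt, float(np.sqrt(2.0 * d_coeff * dt)), n_steps, store_every,
            n_steps // 2, seed=seed + 104729 * rep, z_periodic=z_periodic,
        )
        a_ge_reps.append(a_ge)
        a_se_reps.append(a_se)
        counts_reps.append(counts)
    times = np.concatenate([[0.0], dt * store_every * np.arange(1, n_steps // store_every + 1)])
    n_ge = round(te_ge / dt) // store_every
    return StateSweepResult(
        times_ge=times[: n_ge + 1],
        times_se=times,
        a_ge=_prepend_t0(np.stack(a_ge_reps))[..., : n_ge + 1],
        a_se=_prepend_t0(np.stack(a_se_reps)),
        counts=np.stack(counts_reps),
    )
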