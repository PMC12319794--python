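"""Numba kernels: dipole-field accumulation on a grid and the random walk.

Everything here is deliberately scalar-loop, single-threaded and
counter-seeded per walker so that results are bit-reproducible and
independent of execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["accumulate_field", "accumulate_mask", "walk_states"]


@njit(cache=True, fastmath=True)
def accumulate_field(
    values,  # (nx, ny, nz) float, modified in place
    origin,  # (3,) grid origin, um
    h,  # grid spacing, um
    p0,  # (m, 3) segment start points
    axis,  # (m, 3) unit axis vectors
    length,  # (m,) geometric axial extents
    radius,  # (m,)
    dchi,  # (m,) susceptibility difference per segment (SI, dimensionless)
    gamma_b0,  # gamma * B0 [rad/s]
    cutoff_rel,  # skip contributions beyond cutoff_rel * R (<=0: no cutoff)
    cap_slack_rel,  # axial slack at the segment caps, in radii
):
    """Superpose the external infinite-cylinder dipole field of each segment.

    For a field point at perpendicular distance ``r`` from a segment axis,
    azimuth ``theta`` against the in-plane B0 projection and axis-to-B0 angle
    ``psi``, the angular frequency offset is

        dw = 0.5 * gamma * B0 * dchi * (R/r)^2 * cos(2 theta) * sin(psi)^2.

    Contributions are only evaluated where the point's axial projection falls
    within the segment extent (plus ``cap_slack_rel`` radii at the caps) and,
    if a cutoff is set, within ``cutoff_rel * R`` of the axis.  Points inside
    the segment (r < R) are skipped; the intravascular field is never used.
    B0 points along +z.
    """
    nx, ny, nz = values.shape
    for seg in range(p0.shape[0]):
        R = radius[seg]
        pref = 0.5 * gamma_b0 * dchi[seg] * R * R
        if pref == 0.0:
            continue
        ux, uy, uz = axis[seg, 0], axis[seg, 1], axis[seg, 2]
        L = length[seg]
        slack = cap_slack_rel * R
        cut = cutoff_rel * R if cutoff_rel > 0.0 else 1e30
        cut2 = cut * cut
        R2 = R * R
        sin2psi = 1.0 - uz * uz
        if sin2psi < 1e-14:
            continue
        # in-plane unit projection of B0 (z-hat minus its axial component)
        bnorm = np.sqrt(sin2psi)
        bx = -ux * uz / bnorm
        by = -uy * uz / bnorm
        bz = sin2psi / bnorm
        ax0, ay0, az0 = p0[seg, 0], p0[seg, 1], p0[seg, 2]
        ex, ey, ez = ax0 + ux * L, ay0 + uy * L, az0 + uz * L
        # axis-aligned bounding box of the truncated cylinder + cutoff margin
        # (clamped in float first: an uncapped cutoff must not overflow ints)
        margin = cut + slack
        i0 = int(np.floor(max(0.0, min(ax0, ex) - margin - origin[0]) / h))
        i1 = int(np.ceil(min((nx - 1) * h, max(ax0, ex) + margin - origin[0]) / h))
        j0 = int(np.floor(max(0.0, min(ay0, ey) - margin - origin[1]) / h))
        j1 = int(np.ceil(min((ny - 1) * h, max(ay0, ey) + margin - origin[1]) / h))
        k0 = int(np.floor(max(0.0, min(az0, ez) - margin - origin[2]) / h))
        k1 = int(np.ceil(min((nz - 1) * h, max(az0, ez) + margin - origin[2]) / h))
        i1 = min(i1, nx - 1)
        j1 = min(j1, ny - 1)
        k1 = min(k1, nz - 1)
        if i1 < i0 or j1 < j0 or k1 < k0:
            continue
        for i in range(i0, i1 + 1):
            dx0 = origin[0] + i * h - ax0
            for j in range(j0, j1 + 1):
                dy0 = origin[1] + j * h - ay0
                for k in range(k0, k1 + 1):
                    dz0 = origin[2] + k * h - az0
                    s = dx0 * ux + dy0 * uy + dz0 * uz
                    if s < -slack or s > L + slack:
                        continue
                    vx = dx0 - s * ux
                    vy = dy0 - s * uy
                    vz = dz0 - s * uz
                    r2 = vx * vx + vy * vy + vz * vz
                    if r2 > cut2 or r2 < R2:
                        continue
                    ct = (vx * bx + vy * by + vz * bz)
                    cos2t = 2.0 * ct * ct / r2 - 1.0
                    values[i, j, k] += pref / r2 * cos2t * sin2psi


@njit(cache=True)
def accumulate_mask(
    mask,  # (nx, ny, nz) uint8, modified in place
    origin,
    h,
    p0,
    axis,
    length,
    radius,
):
    """Mark grid nodes lying inside any vessel (r < R within the axial span)."""
    nx, ny, nz = mask.shape
    for seg in range(p0.shape[0]):
        R = radius[seg]
        R2 = R * R
        ux, uy, uz = axis[seg, 0], axis[seg, 1], axis[seg, 2]
        L = length[seg]
        ax0, ay0, az0 = p0[seg, 0], p0[seg, 1], p0[seg, 2]
        ex, ey, ez = ax0 + ux * L, ay0 + uy * L, az0 + uz * L
        i0 = max(0, int(np.floor((min(ax0, ex) - R - origin[0]) / h)))
        i1 = min(nx - 1, int(np.ceil((max(ax0, ex) + R - origin[0]) / h)))
        j0 = max(0, int(np.floor((min(ay0, ey) - R - origin[1]) / h)))
        j1 = min(ny - 1, int(np.ceil((max(ay0, ey) + R - origin[1]) / h)))
        k0 = max(0, int(np.floor((min(az0, ez) - R - origin[2]) / h)))
        k1 = min(nz - 1, int(np.ceil((max(az0, ez) + R - origin[2]) / h)))
        for i in range(i0, i1 + 1):
            dx0 = origin[0] + i * h - ax0
            for j in range(j0, j1 + 1):
                dy0 = origin[1] + j * h - ay0
                for k in range(k0, k1 + 1):
                    dz0 = origin[2] + k * h - az0
                    s = dx0 * ux + dy0 * uy + dz0 * uz
                    if s < 0.0 or s > L:
                        continue
                    vx = dx0 - s * ux
                    vy = dy0 - s * uy
                    vz = dz0 - s * uz
                    if vx * vx + vy * vy + vz * vz < R2:
                        mask[i, j, k] = 1


@njit(cache=True, fastmath=True, inline="always")
def _trilerp(values, h, x, y, z):
    nx, ny, nz = values.shape
    fx = x / h
    fy = y / h
    fz = z / h
    i = int(fx)
    j = int(fy)
    k = int(fz)
    if i > nx - 2:
        i = nx - 2
    if j > ny - 2:
        j = ny - 2
    if k > nz - 2:
        k = nz - 2
    if i < 0:
        i = 0
    if j < 0:
        j = 0
    if k < 0:
        k = 0
    tx = fx - i
    ty = fy - j
    tz = fz - k
    c00 = values[i, j, k] * (1 - tx) + values[i + 1, j, k] * tx
    c10 = values[i, j + 1, k] * (1 - tx) + values[i + 1, j + 1, k] * tx
    c01 = values[i, j, k + 1] * (1 - tx) + values[i + 1, j, k + 1] * tx
    c11 = values[i, j + 1, k + 1] * (1 - tx) + values[i + 1, j + 1, k + 1] * tx
    return (c00 * (1 - ty) + c10 * ty) * (1 - tz) + (c01 * (1 - ty) + c11 * ty) * tz


@njit(cache=True, inline="always")
def _inside_mask(mask, h, x, y, z):
    nx, ny, nz = mask.shape
    i = int(x / h + 0.5)
    j = int(y / h + 0.5)
    k = int(z / h + 0.5)
    if i > nx - 1:
        i = nx - 1
    if j > ny - 1:
        j = ny - 1
    if k > nz - 1:
        k = nz - 1
    return mask[i, j, k] != 0


@njit(cache=True, fastmath=True)
def walk_states(
    fields,
    weights,  # (n_states, n_basis) float64
    mask,
    h,
    lx,
    ly,
    lz,
    dt,
    sigma,
    n_steps,
    store_every,
    flip_step,
    x0,
    y0,
    z0,
    lam,
    n_lam,
    base_seed,
    z_periodic,
    wall_tries,
    walker_retries,
):
    """Random walk with phase accrual; returns per-lamina phasor sums.

    Each walker takes Gaussian steps (s.d. ``sigma`` per axis); steps landing
    inside a vessel are rejected and redrawn (impermeable walls); x/y exits
    wrap periodically preserving phase; touching the pial (z<=0) or WM
    (z>=lz) face invalidates the whole path and the walker is resimulated
    from its initial position with a fresh random stream (bounded retries).
    Phase accrues per basis field as ``phi_c += field_c(x) * dt`` (fields in
    rad/s, dt converted from ms to s); the per-state phase is the
    weight-combined sum over basis fields.  At every ``store_every``-th step
    the complex phasor exp(-i phi) is accumulated per (state, lamina): both
    the free-precession (gradient-echo) reading and the refocused (spin-echo)
    reading, where phases after ``flip_step`` are negated about the flip
    value; ``flip_step = 0`` disables refocusing.

    Returns ``(sum_ge, sum_se, counts, n_failed)`` with phasor sums of shape
    ``(n_states, n_lam, n_steps//store_every, 2)`` holding (cos, -sin)
    components, walker counts per lamina, and the number of walkers whose
    retry budget was exhausted.
    """
    n_states, n_basis = weights.shape
    n_store = n_steps // store_every
    sum_ge = np.zeros((n_states, n_lam, n_store, 2))
    sum_se = np.zeros((n_states, n_lam, n_store, 2))
    counts = np.zeros(n_lam, dtype=np.int64)
    n_failed = 0
    buf_ge = np.empty((n_states, n_store, 2))
    buf_se = np.empty((n_states, n_store, 2))
    phi = np.empty(n_basis)
    phi_flip = np.empty(n_basis)
    n_walkers = x0.shape[0]
    dt_s = dt * 1e-3  # fields are rad/s, time axis is ms
    for w in range(n_walkers):
        completed = False
        for retry in range(walker_retries):
            seed = (base_seed + 1009 * w + 665357 * retry) % 2147483647
            np.random.seed(seed)
            x = x0[w]
            y = y0[w]
            z = z0[w]
            if retry > 0:
                # the invalidated path is discarded and a fresh walker takes
                # its place: new extravascular start in the same lamina slab
                li = lam[w]
                zlo = li * lz / n_lam
                zhi = (li + 1) * lz / n_lam
                for _ in range(100):
                    cx = np.random.random() * lx
                    cy = np.random.random() * ly
                    cz = zlo + np.random.random() * (zhi - zlo)
                    if cz <= 0.0 or cz >= lz:
                        continue
                    if not _inside_mask(mask, h, cx, cy, cz):
                        x = cx
                        y = cy
                        z = cz
                        break
            for c in range(n_basis):
                phi[c] = 0.0
                phi_flip[c] = 0.0
            valid = True
            for step in range(1, n_steps + 1):
                if sigma > 0.0:
                    accepted = False
                    for _ in range(wall_tries):
                        nx_ = x + sigma * np.random.normal()
                        ny_ = y + sigma * np.random.normal()
                        nz_ = z + sigma * np.random.normal()
                        if nx_ < 0.0:
                            nx_ += lx
                        elif nx_ >= lx:
                            nx_ -= lx
                        if ny_ < 0.0:
                            ny_ += ly
                        elif ny_ >= ly:
                            ny_ -= ly
                        if z_periodic:
                            if nz_ < 0.0:
                                nz_ += lz
                            elif nz_ >= lz:
                                nz_ -= lz
                        elif nz_ <= 0.0 or nz_ >= lz:
                            valid = False
                            break
                        if not _inside_mask(mask, h, nx_, ny_, nz_):
                            x = nx_
                            y = ny_
                            z = nz_
                            accepted = True
                            break
                    if not valid:
                        break
                    # after wall_tries rejections the walker stays in place
                    _ = accepted
                for c in range(n_basis):
                    phi[c] += _trilerp(fields[c], h, x, y, z) * dt_s
                if step == flip_step:
                    for c in range(n_basis):
                        phi_flip[c] = phi[c]
                if step % store_every == 0:
                    idx = step // store_every - 1
                    for st in range(n_states):
                        p = 0.0
                        for c in range(n_basis):
                            p += weights[st, c] * phi[c]
                        buf_ge[st, idx, 0] = np.cos(p)
                        buf_ge[st, idx, 1] = -np.sin(p)
                        if flip_step > 0 and step >= flip_step:
                            ps = p
                            for c in range(n_basis):
                                ps -= 2.0 * weights[st, c] * phi_flip[c]
                            buf_se[st, idx, 0] = np.cos(ps)
                            buf_se[st, idx, 1] = -np.sin(ps)
                        else:
                            buf_se[st, idx, 0] = buf_ge[st, idx, 0]
                            buf_se[st, idx, 1] = buf_ge[st, idx, 1]
            if valid:
                li = lam[w]
                counts[li] += 1
                for st in range(n_states):
                    for idx in range(n_store):
                        sum_ge[st, li, idx, 0] += buf_ge[st, idx, 0]
                        sum_ge[st, li, idx, 1] += buf_ge[st, idx, 1]
                        sum_se[st, li, idx, 0] += buf_se[st, idx, 0]
                        sum_se[st, li, idx, 1] += buf_se[st, idx, 1]
                completed = True
                break
        if not completed:
            n_failed += 1
    return sum_ge, sum_se, counts, n_failed
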