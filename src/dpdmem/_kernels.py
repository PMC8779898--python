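"""Numba kernels shared by the reference engine and the cell-graph backend.

Both backends call the same per-pair arithmetic, the same counter-based pair
RNG and the same accumulation loops, so that in strict-order mode their
per-step forces agree bitwise; the backends differ only in how pairs are
discovered (cell-list sweep vs message exchange between cell vertices).

Non-bonded forms are the canonical soft-DPD ones: conservative
``a_ij (1 - r) r_hat`` for r < 1, dissipative ``-gamma (1-r)^2 (r_hat . v_ij)
r_hat`` and random ``sigma (1-r) zeta r_hat / sqrt(dt)`` with
``sigma^2 = 2 gamma kBT`` and ``zeta`` a symmetric zero-mean unit-variance
variate drawn per (pair, step).
"""

import numpy as np
from numba import njit

_SQRT3 = 1.7320508075688772
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53

_C0 = np.uint64(0x9E3779B97F4A7C15)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)
_C3 = np.uint64(0xD6E8FEB86659FD93)


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * _C1
    z = (z ^ (z >> np.uint64(27))) * _C2
    z = z ^ (z >> np.uint64(31))
    return z


@njit(cache=True, inline="always")
def _pair_unit(i, j, step, seed):
    """Symmetric counter-based variate, uniform on [-sqrt(3), sqrt(3)].

    Keyed on (min(i,j), max(i,j), step, seed) so the value is identical no
    matter which cell or backend evaluates the pair, with zero mean and unit
    variance over the stream.
    """
    if i > j:
        i, j = j, i
    h = _C0 ^ np.uint64(seed)
    h = _mix64(h + np.uint64(i) * _C1)
    h = _mix64(h + np.uint64(j) * _C2)
    h = _mix64(h + np.uint64(step) * _C3)
    u = np.float64(h >> np.uint64(11)) * _INV_2_53
    return (2.0 * u - 1.0) * _SQRT3


@njit(cache=True)
def pair_rng_stream(i, j, steps, seed):
    """Vector of variates for a fixed pair over an array of steps (test hook)."""
    out = np.empty(steps.shape[0])
    for s in range(steps.shape[0]):
        out[s] = _pair_unit(i, j, steps[s], seed)
    return out


@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * np.rint(d / L)


# ---------------------------------------------------------------------------
# cell list


@njit(cache=True)
def _assign_cells(pos, box, nc):
    """Cell index per bead; positions just under L land in the last cell."""
    n = pos.shape[0]
    cell = np.empty(n, dtype=np.int64)
    for b in range(n):
        ix = np.int64(pos[b, 0] / box[0] * nc[0])
        iy = np.int64(pos[b, 1] / box[1] * nc[1])
        iz = np.int64(pos[b, 2] / box[2] * nc[2])
        if ix >= nc[0]:
            ix = nc[0] - 1
        if iy >= nc[1]:
            iy = nc[1] - 1
        if iz >= nc[2]:
            iz = nc[2] - 1
        if ix < 0:
            ix = 0
        if iy < 0:
            iy = 0
        if iz < 0:
            iz = 0
        cell[b] = (ix * nc[1] + iy) * nc[2] + iz
    return cell


@njit(cache=True)
def _bucket_sort(cell, ncells):
    """Counting sort: beads ordered by cell, plus per-cell start offsets."""
    n = cell.shape[0]
    count = np.zeros(ncells + 1, dtype=np.int64)
    for b in range(n):
        count[cell[b] + 1] += 1
    for c in range(ncells):
        count[c + 1] += count[c]
    order = np.empty(n, dtype=np.int64)
    fill = count[:ncells].copy()
    for b in range(n):
        c = cell[b]
        order[fill[c]] = b
        fill[c] += 1
    return order, count


# half-shell of 13 neighbor offsets (plus the self cell handled separately)
_HALF_OFFSETS = np.array(
    [
        (1, 0, 0),
        (0, 1, 0),
        (0, 0, 1),
        (1, 1, 0),
        (1, -1, 0),
        (1, 0, 1),
        (1, 0, -1),
        (0, 1, 1),
        (0, 1, -1),
        (1, 1, 1),
        (1, 1, -1),
        (1, -1, 1),
        (1, -1, -1),
    ],
    dtype=np.int64,
)


@njit(cache=True)
def _collect_pairs(pos, box, nc, cutoff):
    """All unordered pairs with minimum-image distance < cutoff.

    Enumerated via the cell list; requires >= 3 cells per axis and cell
    edges >= cutoff.
    """
    n = pos.shape[0]
    ncells = nc[0] * nc[1] * nc[2]
    cell = _assign_cells(pos, box, nc)
    order, start = _bucket_sort(cell, ncells)
    cap = max(64, n * 32)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    cut2 = cutoff * cutoff
    m = 0
    for cx in range(nc[0]):
        for cy in range(nc[1]):
            for cz in range(nc[2]):
                c = (cx * nc[1] + cy) * nc[2] + cz
                a0, a1 = start[c], start[c + 1]
                # pairs within the cell
                for u in range(a0, a1):
                    i = order[u]
                    for v in range(u + 1, a1):
                        j = order[v]
                        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                        if dx * dx + dy * dy + dz * dz < cut2:
                            if m >= cap:
                                raise ValueError("pair capacity exceeded")
                            # pairs stored lower id first
                            if i < j:
                                pi[m] = i
                                pj[m] = j
                            else:
                                pi[m] = j
                                pj[m] = i
                            m += 1
                # pairs with the 13 half-shell neighbor cells
                for o in range(13):
                    dx_ = (cx + _HALF_OFFSETS[o, 0]) % nc[0]
                    dy_ = (cy + _HALF_OFFSETS[o, 1]) % nc[1]
                    dz_ = (cz + _HALF_OFFSETS[o, 2]) % nc[2]
                    d = (dx_ * nc[1] + dy_) * nc[2] + dz_
                    b0, b1 = start[d], start[d + 1]
                    for u in range(a0, a1):
                        i = order[u]
                        for v in range(b0, b1):
                            j = order[v]
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz < cut2:
                                if m >= cap:
                                    raise ValueError("pair capacity exceeded")
                                if i < j:
                                    pi[m] = i
                                    pj[m] = j
                                else:
                                    pi[m] = j
                                    pj[m] = i
                                m += 1
    return pi[:m], pj[:m]


@njit(cache=True, inline="always")
def _pair_force_comp(
    xi, yi, zi, xj, yj, zj, vxi, vyi, vzi, vxj, vyj, vzj,
    aij, gij, sij, Lx, Ly, Lz, zeta, inv_sqrt_dt,
):
    """Force on bead i from bead j (conservative + dissipative + random).

    Returns a zero vector at r >= 1; exactly overlapping beads (r = 0) also
    contribute nothing (the soft potential is finite there, the direction
    undefined).
    """
    dx = _min_image(xi - xj, Lx)
    dy = _min_image(yi - yj, Ly)
    dz = _min_image(zi - zj, Lz)
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= 1.0 or r2 <= 0.0:
        return 0.0, 0.0, 0.0
    r = np.sqrt(r2)
    w = 1.0 - r
    ex = dx / r
    ey = dy / r
    ez = dz / r
    rdotv = ex * (vxi - vxj) + ey * (vyi - vyj) + ez * (vzi - vzj)
    fmag = aij * w - gij * w * w * rdotv + sij * w * zeta * inv_sqrt_dt
    return fmag * ex, fmag * ey, fmag * ez


@njit(cache=True)
def pair_force_values(pi, pj, pos, vel, types, a, gamma, sigma, box, step, seed, dt):
    """Per-pair force vectors (on the lower-id bead) for an explicit pair list."""
    m = pi.shape[0]
    fv = np.zeros((m, 3))
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    for p in range(m):
        i = pi[p]
        j = pj[p]
        zeta = _pair_unit(i, j, step, seed)
        ti = types[i]
        tj = types[j]
        fx, fy, fz = _pair_force_comp(
            pos[i, 0], pos[i, 1], pos[i, 2], pos[j, 0], pos[j, 1], pos[j, 2],
            vel[i, 0], vel[i, 1], vel[i, 2], vel[j, 0], vel[j, 1], vel[j, 2],
            a[ti, tj], gamma[ti, tj], sigma[ti, tj],
            box[0], box[1], box[2], zeta, inv_sqrt_dt,
        )
        fv[p, 0] = fx
        fv[p, 1] = fy
        fv[p, 2] = fz
    return fv


@njit(cache=True)
def accumulate_pairs_sorted(pi, pj, fv, n):
    """Accumulate pair forces in canonical (i, j) order (strict mode).

    Sorting by the unique key i*n + j makes the floating-point summation
    order identical across backends, giving bitwise-equal totals.
    """
    key = pi * np.int64(n) + pj
    order = np.argsort(key)
    f = np.zeros((n, 3))
    for t in range(order.shape[0]):
        p = order[t]
        i = pi[p]
        j = pj[p]
        f[i, 0] += fv[p, 0]
        f[i, 1] += fv[p, 1]
        f[i, 2] += fv[p, 2]
        f[j, 0] -= fv[p, 0]
        f[j, 1] -= fv[p, 1]
        f[j, 2] -= fv[p, 2]
    return f


@njit(cache=True, fastmath=True)
def _nonbonded_fused(pos, vel, types, a, gamma, sigma, box, nc, step, seed, dt):
    """Single-pass cell-list sweep accumulating forces in enumeration order."""
    n = pos.shape[0]
    ncells = nc[0] * nc[1] * nc[2]
    cell = _assign_cells(pos, box, nc)
    order, start = _bucket_sort(cell, ncells)
    f = np.zeros((n, 3))
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    for cx in range(nc[0]):
        for cy in range(nc[1]):
            for cz in range(nc[2]):
                c = (cx * nc[1] + cy) * nc[2] + cz
                a0, a1 = start[c], start[c + 1]
                for o in range(14):
                    if o == 13:
                        d = c  # pairs within the cell itself
                    else:
                        dx_ = (cx + _HALF_OFFSETS[o, 0]) % nc[0]
                        dy_ = (cy + _HALF_OFFSETS[o, 1]) % nc[1]
                        dz_ = (cz + _HALF_OFFSETS[o, 2]) % nc[2]
                        d = (dx_ * nc[1] + dy_) * nc[2] + dz_
                    b0, b1 = start[d], start[d + 1]
                    for u in range(a0, a1):
                        i = order[u]
                        v0 = u + 1 if o == 13 else b0
                        for v in range(v0, b1):
                            j = order[v]
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= 1.0 or r2 <= 0.0:
                                continue
                            r = np.sqrt(r2)
                            w = 1.0 - r
                            ex = dx / r
                            ey = dy / r
                            ez = dz / r
                            rdotv = (
                                ex * (vel[i, 0] - vel[j, 0])
                                + ey * (vel[i, 1] - vel[j, 1])
                                + ez * (vel[i, 2] - vel[j, 2])
                            )
                            ti = types[i]
                            tj = types[j]
                            zeta = _pair_unit(i, j, step, seed)
                            fmag = (
                                a[ti, tj] * w
                                - gamma[ti, tj] * w * w * rdotv
                                + sigma[ti, tj] * w * zeta * inv_sqrt_dt
                            )
                            fx = fmag * ex
                            fy = fmag * ey
                            fz = fmag * ez
                            f[i, 0] += fx
                            f[i, 1] += fy
                            f[i, 2] += fz
                            f[j, 0] -= fx
                            f[j, 1] -= fy
                            f[j, 2] -= fz
    return f


@njit(cache=True)
def nonbonded_forces(
    pos, vel, types, a, gamma, sigma, box, nc, step, seed, dt, strict
):
    """Cell-list sweep: all non-bonded pair forces accumulated into (N, 3).

    ``strict`` selects canonical pair-order accumulation (for cross-backend
    bitwise comparison); the default fused path accumulates in enumeration
    order, which differs only in floating-point summation order.
    """
    if not strict:
        return _nonbonded_fused(pos, vel, types, a, gamma, sigma, box, nc, step, seed, dt)
    n = pos.shape[0]
    pi, pj = _collect_pairs(pos, box, nc, 1.0)
    fv = pair_force_values(pi, pj, pos, vel, types, a, gamma, sigma, box, step, seed, dt)
    return accumulate_pairs_sorted(pi, pj, fv, n)


# ---------------------------------------------------------------------------
# bonded terms


@njit(cache=True)
def bond_forces(pos, bond_ij, bond_kl, box, f):
    """Hookean springs accumulated in bond-list order; returns total energy.

    A fully collapsed bond (r = 0) is nudged along x by machine epsilon so
    the restoring direction is defined.
    """
    e = 0.0
    for b in range(bond_ij.shape[0]):
        i = bond_ij[b, 0]
        j = bond_ij[b, 1]
        k = bond_kl[b, 0]
        l0 = bond_kl[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r == 0.0:
            dx = 2.220446049250313e-16
            r = dx
        fmag = -k * (r - l0)
        e += 0.5 * k * (r - l0) * (r - l0)
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
        f[j, 0] -= fx
        f[j, 1] -= fy
        f[j, 2] -= fz
    return e


@njit(cache=True)
def angle_forces(pos, angle_ijk, angle_par, box, f):
    """Bending terms k3*(1 - cos(phi - phi0)) accumulated in list order.

    ``phi`` is the angle between consecutive bond vectors b1 = r_j - r_i and
    b2 = r_k - r_j (0 for a straight triple).  cos(phi) is clamped to
    [-1, 1]; the anti-collinear configuration yields zero force (the limit).
    Returns total bending energy.
    """
    e = 0.0
    for t in range(angle_ijk.shape[0]):
        i = angle_ijk[t, 0]
        j = angle_ijk[t, 1]
        k = angle_ijk[t, 2]
        k3 = angle_par[t, 0]
        phi0 = angle_par[t, 1]
        b1x = _min_image(pos[j, 0] - pos[i, 0], box[0])
        b1y = _min_image(pos[j, 1] - pos[i, 1], box[1])
        b1z = _min_image(pos[j, 2] - pos[i, 2], box[2])
        b2x = _min_image(pos[k, 0] - pos[j, 0], box[0])
        b2y = _min_image(pos[k, 1] - pos[j, 1], box[1])
        b2z = _min_image(pos[k, 2] - pos[j, 2], box[2])
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 == 0.0 or n2 == 0.0:
            continue
        u1x, u1y, u1z = b1x / n1, b1y / n1, b1z / n1
        u2x, u2y, u2z = b2x / n2, b2y / n2, b2z / n2
        c = u1x * u2x + u1y * u2y + u1z * u2z
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        if phi0 == 0.0:
            coef = k3
            e += k3 * (1.0 - c)
        else:
            s = np.sqrt(max(1.0 - c * c, 1e-16))
            phi = np.arccos(c)
            e += k3 * (1.0 - np.cos(phi - phi0))
            coef = k3 * (np.cos(phi0) - np.sin(phi0) * c / s) if s > 1e-8 else k3 * np.cos(phi0)
        # F = coef * grad(cos phi)
        gi_x = -coef * (u2x - c * u1x) / n1
        gi_y = -coef * (u2y - c * u1y) / n1
        gi_z = -coef * (u2z - c * u1z) / n1
        gk_x = coef * (u1x - c * u2x) / n2
        gk_y = coef * (u1y - c * u2y) / n2
        gk_z = coef * (u1z - c * u2z) / n2
        f[i, 0] += gi_x
        f[i, 1] += gi_y
        f[i, 2] += gi_z
        f[k, 0] += gk_x
        f[k, 1] += gk_y
        f[k, 2] += gk_z
        f[j, 0] -= gi_x + gk_x
        f[j, 1] -= gi_y + gk_y
        f[j, 2] -= gi_z + gk_z
    return e
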