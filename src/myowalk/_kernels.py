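"""Numba kernels: RNG streams, ray-triangle queries, lattice folding, walks.

Everything here operates on flat float64/int64 arrays so the hot loop
(one particle-timestep with reflections) compiles to machine code.

Determinism contract: every particle owns a counter-based RNG stream
derived from (master seed, particle index), so results are bitwise
independent of thread count and execution order.

Epsilon policy (micrometre units, coordinates O(1e3)):
* intersections closer than 1e-9 of the current segment length are
  ignored and the triangle just reflected off is excluded, preventing
  immediate re-hits;
* after a reflection the position is nudged 1e-9 um along the incoming
  side of the wall normal; after a tile crossing 1e-9 um across the
  boundary.  Path-length bookkeeping includes the nudges, keeping the
  sub-step lengths summing to the drawn step length to ~1e-12 relative.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

U64 = np.uint64
_GOLDEN = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)
_NUDGE = 1e-9  # um
_T_EPS_REL = 1e-9

# parity-test ray direction: fixed, irrational-ish, away from mesh axes
_PARITY_DIR = np.array([1.0, 2.0, 3.0]) / np.sqrt(14.0)


# ---------------------------------------------------------------------------
# splitmix64 counter RNG

@njit(cache=False, inline="always")
def _mix64(z):
    z = (z ^ (z >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    return z ^ (z >> U64(31))


@njit(cache=False, inline="always")
def _next_u64(state):
    state = state + _GOLDEN
    return state, _mix64(state)


@njit(cache=False, inline="always")
def _next_unit(state):
    """Uniform double in (0, 1]."""
    state, z = _next_u64(state)
    return state, (np.float64(z >> U64(11)) + 1.0) * (1.0 / 9007199254740992.0)


@njit(cache=False, inline="always")
def _next_normal(state, cap):
    """Standard normal via Box-Muller, rejection-resampled beyond cap."""
    while True:
        state, u1 = _next_unit(state)
        state, u2 = _next_unit(state)
        n = np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)
        if np.abs(n) <= cap:
            return state, n


def particle_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent per-particle stream seeds from one master seed."""
    idx = np.arange(n, dtype=np.uint64)
    base = U64(master_seed & 0xFFFFFFFFFFFFFFFF)
    with np.errstate(over="ignore"):  # uint64 wraparound is intended
        z = (base + _GOLDEN) * _MIX1 ^ (idx + U64(1)) * _MIX2
        z ^= z >> U64(30)
        z *= _MIX1
        z ^= z >> U64(27)
        z *= _MIX2
        z ^= z >> U64(31)
    return z


# ---------------------------------------------------------------------------
# geometry primitives

@njit(cache=False, inline="always")
def _moller_trumbore(ox, oy, oz, dx, dy, dz,
                     v0, e1, e2, tri):
    """Ray-triangle intersection; returns t (np.inf on miss)."""
    p_x = dy * e2[tri, 2] - dz * e2[tri, 1]
    p_y = dz * e2[tri, 0] - dx * e2[tri, 2]
    p_z = dx * e2[tri, 1] - dy * e2[tri, 0]
    det = e1[tri, 0] * p_x + e1[tri, 1] * p_y + e1[tri, 2] * p_z
    if np.abs(det) < 1e-14:
        return np.inf
    inv = 1.0 / det
    tx = ox - v0[tri, 0]
    ty = oy - v0[tri, 1]
    tz = oz - v0[tri, 2]
    u = (tx * p_x + ty * p_y + tz * p_z) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return np.inf
    q_x = ty * e1[tri, 2] - tz * e1[tri, 1]
    q_y = tz * e1[tri, 0] - tx * e1[tri, 2]
    q_z = tx * e1[tri, 1] - ty * e1[tri, 0]
    v = (dx * q_x + dy * q_y + dz * q_z) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return np.inf
    t = (e2[tri, 0] * q_x + e2[tri, 1] * q_y + e2[tri, 2] * q_z) * inv
    return t


@njit(cache=False, inline="always")
def _aabb_entry(ox, oy, oz, idx, idy, idz, lo, hi, node, t_max):
    """Slab test against node bounds over ray range [0, t_max];
    returns the entry parameter (np.inf on miss)."""
    t0 = 0.0
    t1 = t_max
    tx0 = (lo[node, 0] - ox) * idx
    tx1 = (hi[node, 0] - ox) * idx
    if tx0 > tx1:
        tx0, tx1 = tx1, tx0
    t0 = max(t0, tx0)
    t1 = min(t1, tx1)
    ty0 = (lo[node, 1] - oy) * idy
    ty1 = (hi[node, 1] - oy) * idy
    if ty0 > ty1:
        ty0, ty1 = ty1, ty0
    t0 = max(t0, ty0)
    t1 = min(t1, ty1)
    tz0 = (lo[node, 2] - oz) * idz
    tz1 = (hi[node, 2] - oz) * idz
    if tz0 > tz1:
        tz0, tz1 = tz1, tz0
    t0 = max(t0, tz0)
    t1 = min(t1, tz1)
    if t0 <= t1:
        return t0
    return np.inf


@njit(cache=False, inline="always")
def _aabb_hit(ox, oy, oz, idx, idy, idz, lo, hi, node, t_max):
    """Slab test against node bounds over ray range [0, t_max]."""
    return _aabb_entry(ox, oy, oz, idx, idy, idz, lo, hi, node,
                       t_max) != np.inf


@njit(cache=False)
def _bvh_nearest(ox, oy, oz, dx, dy, dz, t_max, skip_tri, eps_t,
                 v0, e1, e2,
                 nmin, nmax, nleft, nright, nstart, ncount, order, stack):
    """Nearest triangle hit with t in (eps_t, t_max]; ties broken by the
    lowest original triangle index.  Returns (t, triangle).  ``stack``
    is caller-provided int64 traversal workspace (no allocation in the
    hot loop)."""
    idx = 1.0 / dx if dx != 0.0 else np.inf
    idy = 1.0 / dy if dy != 0.0 else np.inf
    idz = 1.0 / dz if dz != 0.0 else np.inf
    best_t = np.inf
    best_tri = -1
    top = 0
    stack[top] = 0
    top += 1
    while top > 0:
        top -= 1
        node = stack[top]
        limit = best_t if best_t < t_max else t_max
        if not _aabb_hit(ox, oy, oz, idx, idy, idz, nmin, nmax, node, limit):
            continue
        if nleft[node] < 0:
            for k in range(nstart[node], nstart[node] + ncount[node]):
                tri = order[k]
                if tri == skip_tri:
                    continue
                t = _moller_trumbore(ox, oy, oz, dx, dy, dz, v0, e1, e2, tri)
                if t <= eps_t or t > t_max:
                    continue
                if t < best_t or (t == best_t and tri < best_tri):
                    best_t = t
                    best_tri = tri
        else:
            # descend into the nearer child first so early hits shrink
            # the pruning limit for the rest of the traversal
            el = _aabb_entry(ox, oy, oz, idx, idy, idz, nmin, nmax,
                             nleft[node], limit)
            er = _aabb_entry(ox, oy, oz, idx, idy, idz, nmin, nmax,
                             nright[node], limit)
            if el <= er:
                if er != np.inf:
                    stack[top] = nright[node]
                    top += 1
                if el != np.inf:
                    stack[top] = nleft[node]
                    top += 1
            else:
                if el != np.inf:
                    stack[top] = nleft[node]
                    top += 1
                stack[top] = nright[node]
                top += 1
    return best_t, best_tri


@njit(cache=False)
def _bvh_parity(ox, oy, oz, dx, dy, dz,
                v0, e1, e2, tri_cell, counts,
                nmin, nmax, nleft, nright, nstart, ncount, order, stack):
    """Count ray crossings per cell id along an unbounded ray."""
    idx = 1.0 / dx if dx != 0.0 else np.inf
    idy = 1.0 / dy if dy != 0.0 else np.inf
    idz = 1.0 / dz if dz != 0.0 else np.inf
    top = 0
    stack[top] = 0
    top += 1
    while top > 0:
        top -= 1
        node = stack[top]
        if not _aabb_hit(ox, oy, oz, idx, idy, idz, nmin, nmax, node, np.inf):
            continue
        if nleft[node] < 0:
            for k in range(nstart[node], nstart[node] + ncount[node]):
                tri = order[k]
                t = _moller_trumbore(ox, oy, oz, dx, dy, dz, v0, e1, e2, tri)
                if t > 1e-9 and t < np.inf:
                    counts[tri_cell[tri]] += 1
        else:
            stack[top] = nleft[node]
            top += 1
            stack[top] = nright[node]
            top += 1


# ---------------------------------------------------------------------------
# lattice folding
#
# params layout (float64):
# 0: Lx   1: Ly (= layer height)   2: Lz
# 3: rotation per layer (rad, about global y at x = z = 0)
# 4: stagger flag (0/1; odd x'-columns shifted by Lz/2 in z')
# 5,6,7: voxel half-extents (um)

@njit(cache=False, inline="always")
def _fold(x, y, z, params):
    """Global point -> canonical block coordinates + fold context."""
    ly = params[1]
    k = np.floor(y / ly)
    theta = params[3] * k
    c = np.cos(theta)
    s = np.sin(theta)
    # rotate by -theta about y: canonical frame of layer k
    xp = c * x - s * z
    zp = s * x + c * z
    yp = y - k * ly
    lx = params[0]
    lz = params[2]
    i = np.floor(xp / lx)
    xc = xp - i * lx
    zs = zp
    if params[4] != 0.0 and (np.int64(i) & 1) != 0:
        zs = zp - 0.5 * lz
    j = np.floor(zs / lz)
    zc = zs - j * lz
    return xc, yp, zc, k, i, j, c, s


@njit(cache=False, inline="always")
def _unfold(xc, yp, zc, k, i, j, c, s, params):
    """Inverse of :func:`_fold` for the same context (k, i, j)."""
    lx = params[0]
    ly = params[1]
    lz = params[2]
    zs = zc + j * lz
    if params[4] != 0.0 and (np.int64(i) & 1) != 0:
        zs = zs + 0.5 * lz
    xp = xc + i * lx
    # rotate by +theta
    x = c * xp + s * zs
    z = -s * xp + c * zs
    y = yp + k * ly
    return x, y, z


@njit(cache=False, inline="always")
def _rot_to_canonical(dx, dy, dz, c, s):
    return c * dx - s * dz, dy, s * dx + c * dz


@njit(cache=False, inline="always")
def _rot_to_global(dx, dy, dz, c, s):
    return c * dx + s * dz, dy, -s * dx + c * dz


@njit(cache=False, inline="always")
def _box_exit(x, y, z, dx, dy, dz, lx, ly, lz):
    """Distance to the canonical box boundary along (dx, dy, dz)."""
    t = np.inf
    if dx > 0.0:
        t = min(t, (lx - x) / dx)
    elif dx < 0.0:
        t = min(t, -x / dx)
    if dy > 0.0:
        t = min(t, (ly - y) / dy)
    elif dy < 0.0:
        t = min(t, -y / dy)
    if dz > 0.0:
        t = min(t, (lz - z) / dz)
    elif dz < 0.0:
        t = min(t, -z / dz)
    return t


@njit(cache=False)
def fold_points(points, params, out_canonical, out_context):
    for n in range(points.shape[0]):
        xc, yp, zc, k, i, j, c, s = _fold(
            points[n, 0], points[n, 1], points[n, 2], params)
        out_canonical[n, 0] = xc
        out_canonical[n, 1] = yp
        out_canonical[n, 2] = zc
        out_context[n, 0] = k
        out_context[n, 1] = i
        out_context[n, 2] = j


@njit(cache=False)
def unfold_points(canonical, context, params, out_global):
    for n in range(canonical.shape[0]):
        k = context[n, 0]
        i = context[n, 1]
        j = context[n, 2]
        theta = params[3] * k
        c = np.cos(theta)
        s = np.sin(theta)
        x, y, z = _unfold(canonical[n, 0], canonical[n, 1], canonical[n, 2],
                          k, i, j, c, s, params)
        out_global[n, 0] = x
        out_global[n, 1] = y
        out_global[n, 2] = z


@njit(cache=False, parallel=True)
def locate_points(points, params, v0, e1, e2, tri_cell, n_cells,
                  nmin, nmax, nleft, nright, nstart, ncount, order,
                  out_comp):
    """Compartment per point: cell id from ray-parity, 0 for ECS."""
    ddx, ddy, ddz = _PARITY_DIR[0], _PARITY_DIR[1], _PARITY_DIR[2]
    for n in prange(points.shape[0]):
        xc, yp, zc, k, i, j, c, s = _fold(
            points[n, 0], points[n, 1], points[n, 2], params)
        counts = np.zeros(n_cells + 1, dtype=np.int64)
        stack = np.empty(128, dtype=np.int64)
        _bvh_parity(xc, yp, zc, ddx, ddy, ddz,
                    v0, e1, e2, tri_cell, counts,
                    nmin, nmax, nleft, nright, nstart, ncount, order, stack)
        comp = 0
        for cid in range(1, n_cells + 1):
            if counts[cid] & 1:
                comp = cid
                break
        out_comp[n] = comp


# ---------------------------------------------------------------------------
# the random walk

@njit(cache=False, inline="always")
def _resolve_substeps(px, py, pz, rx, ry, rz, params, has_geom,
                      v0, e1, e2, normals,
                      nmin, nmax, nleft, nright, nstart, ncount, order,
                      max_substeps, stack):
    """Advance one drawn displacement with elastic wall reflections.

    Returns the end position, the number of sub-steps used and a
    truncation flag (1 when max_substeps was exhausted before the full
    path length was spent).
    """
    step_len = np.sqrt(rx * rx + ry * ry + rz * rz)
    if step_len == 0.0:
        return px, py, pz, 1, 0
    if not has_geom:
        return px + rx, py + ry, pz + rz, 1, 0
    dx = rx / step_len
    dy = ry / step_len
    dz = rz / step_len
    remaining = step_len
    eps_t = _T_EPS_REL * step_len
    last_tri = -1
    substeps = 0
    truncated = 0
    lx = params[0]
    ly = params[1]
    lz = params[2]
    while remaining > 0.0:
        if substeps >= max_substeps:
            truncated = 1
            break
        substeps += 1
        xc, yp, zc, k, i, j, c, s = _fold(px, py, pz, params)
        cdx, cdy, cdz = _rot_to_canonical(dx, dy, dz, c, s)
        t_box = _box_exit(xc, yp, zc, cdx, cdy, cdz, lx, ly, lz)
        t_lim = remaining if remaining < t_box else t_box
        t_hit, tri = _bvh_nearest(xc, yp, zc, cdx, cdy, cdz, t_lim,
                                  last_tri, eps_t,
                                  v0, e1, e2,
                                  nmin, nmax, nleft, nright,
                                  nstart, ncount, order, stack)
        if t_hit <= t_lim:
            # advance to the wall, reflect, nudge back off the surface
            hx = xc + t_hit * cdx
            hy = yp + t_hit * cdy
            hz = zc + t_hit * cdz
            nx = normals[tri, 0]
            ny = normals[tri, 1]
            nz = normals[tri, 2]
            dn = cdx * nx + cdy * ny + cdz * nz
            cdx -= 2.0 * dn * nx
            cdy -= 2.0 * dn * ny
            cdz -= 2.0 * dn * nz
            side = -1.0 if dn > 0.0 else 1.0
            hx += side * _NUDGE * nx
            hy += side * _NUDGE * ny
            hz += side * _NUDGE * nz
            remaining -= t_hit
            px, py, pz = _unfold(hx, hy, hz, k, i, j, c, s, params)
            dx, dy, dz = _rot_to_global(cdx, cdy, cdz, c, s)
            last_tri = tri
        elif t_box < remaining:
            # cross into the neighbouring tile/layer and refold
            adv = t_box + _NUDGE
            hx = xc + adv * cdx
            hy = yp + adv * cdy
            hz = zc + adv * cdz
            remaining -= adv
            px, py, pz = _unfold(hx, hy, hz, k, i, j, c, s, params)
            last_tri = -1
        else:
            hx = xc + remaining * cdx
            hy = yp + remaining * cdy
            hz = zc + remaining * cdz
            px, py, pz = _unfold(hx, hy, hz, k, i, j, c, s, params)
            remaining = 0.0
    return px, py, pz, substeps, truncated


@njit(cache=False, parallel=True)
def walk_ensemble(pos0, comp, seeds, d_ic, d_ec, cap,
                  dts, g_mid, gamma,
                  params, has_geom,
                  v0, e1, e2, normals,
                  nmin, nmax, nleft, nright, nstart, ncount, order,
                  max_substeps,
                  out_phase, out_pos, out_trunc):
    """Full random walk + phase accrual for every particle.

    Phase quadrature: mid-point of the straight-line chord of each
    timestep (second-order accurate for the 0.1 ms gradient-on steps).
    """
    n_steps = dts.shape[0]
    for p in prange(pos0.shape[0]):
        stack = np.empty(128, dtype=np.int64)
        state = seeds[p]
        d_local = d_ic if comp[p] > 0 else d_ec
        px = pos0[p, 0]
        py = pos0[p, 1]
        pz = pos0[p, 2]
        phase = 0.0
        trunc = 0
        for kstep in range(n_steps):
            dt = dts[kstep]
            sigma = np.sqrt(2.0 * d_local * dt)
            state, n1 = _next_normal(state, cap)
            state, n2 = _next_normal(state, cap)
            state, n3 = _next_normal(state, cap)
            sx = px
            sy = py
            sz = pz
            px, py, pz, _, tr = _resolve_substeps(
                px, py, pz, sigma * n1, sigma * n2, sigma * n3,
                params, has_geom,
                v0, e1, e2, normals,
                nmin, nmax, nleft, nright, nstart, ncount, order,
                max_substeps, stack)
            trunc += tr
            gx = g_mid[kstep, 0]
            if gx != 0.0 or g_mid[kstep, 1] != 0.0 or g_mid[kstep, 2] != 0.0:
                mx = 0.5 * (sx + px)
                my = 0.5 * (sy + py)
                mz = 0.5 * (sz + pz)
                phase += gamma * dt * (gx * mx + g_mid[kstep, 1] * my
                                       + g_mid[kstep, 2] * mz)
        out_phase[p] = phase
        out_pos[p, 0] = px
        out_pos[p, 1] = py
        out_pos[p, 2] = pz
        out_trunc[p] = trunc


@njit(cache=False)
def draw_steps(d_local, dt, n, seed, cap, out):
    """n displacement vectors from one stream (moment/bound tests)."""
    state = U64(seed)
    sigma = np.sqrt(2.0 * d_local * dt)
    for k in range(n):
        state, n1 = _next_normal(state, cap)
        state, n2 = _next_normal(state, cap)
        state, n3 = _next_normal(state, cap)
        out[k, 0] = sigma * n1
        out[k, 1] = sigma * n2
        out[k, 2] = sigma * n3


@njit(cache=False)
def resolve_step_trace(px, py, pz, rx, ry, rz, params,
                       v0, e1, e2, normals,
                       nmin, nmax, nleft, nright, nstart, ncount, order,
                       max_substeps, out_points, out_tris):
    """Single-step resolution that records every sub-step endpoint and
    reflected triangle index (diagnostics / oracle comparison).

    Returns (number of sub-steps, truncation flag).  ``out_points`` must
    be (max_substeps + 1, 3); row 0 is the start position.
    """
    step_len = np.sqrt(rx * rx + ry * ry + rz * rz)
    out_points[0, 0] = px
    out_points[0, 1] = py
    out_points[0, 2] = pz
    if step_len == 0.0:
        return 0, 0
    dx = rx / step_len
    dy = ry / step_len
    dz = rz / step_len
    remaining = step_len
    eps_t = _T_EPS_REL * step_len
    last_tri = -1
    m = 0
    truncated = 0
    stack = np.empty(128, dtype=np.int64)
    lx = params[0]
    ly = params[1]
    lz = params[2]
    while remaining > 0.0:
        if m >= max_substeps:
            truncated = 1
            break
        xc, yp, zc, k, i, j, c, s = _fold(px, py, pz, params)
        cdx, cdy, cdz = _rot_to_canonical(dx, dy, dz, c, s)
        t_box = _box_exit(xc, yp, zc, cdx, cdy, cdz, lx, ly, lz)
        t_lim = remaining if remaining < t_box else t_box
        t_hit, tri = _bvh_nearest(xc, yp, zc, cdx, cdy, cdz, t_lim,
                                  last_tri, eps_t,
                                  v0, e1, e2,
                                  nmin, nmax, nleft, nright,
                                  nstart, ncount, order, stack)
        if t_hit <= t_lim:
            hx = xc + t_hit * cdx
            hy = yp + t_hit * cdy
            hz = zc + t_hit * cdz
            nx = normals[tri, 0]
            ny = normals[tri, 1]
            nz = normals[tri, 2]
            dn = cdx * nx + cdy * ny + cdz * nz
            cdx -= 2.0 * dn * nx
            cdy -= 2.0 * dn * ny
            cdz -= 2.0 * dn * nz
            side = -1.0 if dn > 0.0 else 1.0
            hx += side * _NUDGE * nx
            hy += side * _NUDGE * ny
            hz += side * _NUDGE * nz
            remaining -= t_hit
            px, py, pz = _unfold(hx, hy, hz, k, i, j, c, s, params)
            dx, dy, dz = _rot_to_global(cdx, cdy, cdz, c, s)
            m += 1
            out_points[m, 0] = px
            out_points[m, 1] = py
            out_points[m, 2] = pz
            out_tris[m - 1] = tri
            last_tri = tri
        elif t_box < remaining:
            adv = t_box + _NUDGE
            remaining -= adv
            px, py, pz = _unfold(xc + adv * cdx, yp + adv * cdy,
                                 zc + adv * cdz, k, i, j, c, s, params)
            last_tri = -1
        else:
            px, py, pz = _unfold(xc + remaining * cdx, yp + remaining * cdy,
                                 zc + remaining * cdz, k, i, j, c, s, params)
            remaining = 0.0
            m += 1
            out_points[m, 0] = px
            out_points[m, 1] = py
            out_points[m, 2] = pz
            out_tris[m - 1] = -1
    return m, truncated
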