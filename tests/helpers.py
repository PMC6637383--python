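"""Shared test utilities: the naive all-triangle reflection oracle."""

import numpy as np

from myowalk._kernels import _NUDGE


def oracle_resolve(block, start, disp, max_substeps=100):
    """Brute-force single-step resolver: no BVH, no lattice folding.

    Implements the identical arithmetic (Moller-Trumbore, elastic
    reflection, epsilon policy) with an exhaustive scan over every
    triangle, for paths that stay inside the canonical tile.
    """
    tris = block.triangles
    v0 = tris[:, 0, :]
    e1 = tris[:, 1, :] - tris[:, 0, :]
    e2 = tris[:, 2, :] - tris[:, 0, :]
    n = np.cross(e1, e2)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    step_len = float(np.linalg.norm(disp))
    d = disp / step_len
    p = start.astype(float).copy()
    remaining = step_len
    eps_t = 1e-9 * step_len
    last = -1
    pts = [p.copy()]
    hit_tris = []
    while remaining > 0 and len(hit_tris) < max_substeps:
        pvec = np.cross(np.broadcast_to(d, e2.shape), e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        tvec = p[None, :] - v0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            u = np.einsum("ij,ij->i", tvec, pvec) * inv
            qvec = np.cross(tvec, e1)
            v = np.einsum("j,ij->i", d, qvec) * inv
            t = np.einsum("ij,ij->i", e2, qvec) * inv
        ok = ((np.abs(det) >= 1e-14)
              & (u >= -1e-9) & (u <= 1 + 1e-9)
              & (v >= -1e-9) & (u + v <= 1 + 1e-9)
              & (t > eps_t) & (t <= remaining))
        if last >= 0:
            ok[last] = False
        if not np.any(ok):
            p = p + remaining * d
            pts.append(p.copy())
            hit_tris.append(-1)
            break
        idx = np.flatnonzero(ok)
        best = int(idx[np.argmin(t[idx])])
        t_hit = t[best]
        nb = n[best]
        p = p + t_hit * d
        dn = float(d @ nb)
        d = d - 2.0 * dn * nb
        side = -1.0 if dn > 0.0 else 1.0
        p = p + side * _NUDGE * nb
        remaining -= t_hit
        pts.append(p.copy())
        hit_tris.append(best)
        last = best
    return np.asarray(pts), hit_tris
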