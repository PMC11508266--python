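"""Independent oracles used by the test suite.

These deliberately avoid the package's incremental traversal and distance-map
code paths: the supercover oracle does an analytic closed slab intersection
test per cell, and the clearance oracle is an O(n^2) pairwise minimum.
"""

from __future__ import annotations

import numpy as np


def supercover_oracle(origin, u, shape, spacing, t_end, tol=1e-9):
    """All voxels whose closed cell intersects the segment
    ``[origin, origin + t_end * u]``, by brute slab tests over the segment's
    bounding box, ordered by entry parameter then lexicographic index.

    Returns (list of index tuples, list of entry t values).
    """
    o = np.asarray(origin, float)
    u = np.asarray(u, float)
    u = u / np.linalg.norm(u)
    sp = np.asarray(spacing, float)
    p1 = o + u * t_end
    lo = np.floor(np.minimum(o, p1) / sp).astype(int) - 1
    hi = np.floor(np.maximum(o, p1) / sp).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape, int) - 1)
    if np.any(hi < lo):
        return [], []
    grids = np.meshgrid(*(np.arange(lo[a], hi[a] + 1) for a in range(3)), indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    tmin = np.zeros(len(idx))
    tmax = np.full(len(idx), float(t_end))
    ok = np.ones(len(idx), bool)
    for a in range(3):
        c0 = idx[:, a] * sp[a]
        c1 = c0 + sp[a]
        if abs(u[a]) < 1e-15:
            ok &= (o[a] >= c0 - tol) & (o[a] <= c1 + tol)
        else:
            ta = (c0 - o[a]) / u[a]
            tb = (c1 - o[a]) / u[a]
            lo_t = np.minimum(ta, tb)
            hi_t = np.maximum(ta, tb)
            tmin = np.maximum(tmin, lo_t)
            tmax = np.minimum(tmax, hi_t)
    # tolerance in t units: a graze within tol mm along an axis widens the
    # parametric window by tol / |u[a]|
    slack = tol / max(np.abs(u[np.abs(u) > 1e-15]).min(), 1e-15)
    ok &= tmin <= tmax + slack
    entry = np.maximum(tmin, 0.0)
    sel = np.where(ok)[0]
    order = sorted(sel, key=lambda n: (entry[n], tuple(idx[n])))
    return [tuple(int(v) for v in idx[n]) for n in order], [float(entry[n]) for n in order]


def pairwise_clearance(route_voxels, obstacle_mask, spacing):
    """Min center-to-center distance (mm) between any route voxel and any
    obstacle voxel, by explicit pairwise enumeration."""
    sp = np.asarray(spacing, float)
    obs = np.argwhere(obstacle_mask)
    if len(obs) == 0:
        return None
    route = np.asarray(route_voxels, float)
    best = np.inf
    for r in route:
        d2 = (((obs - r) * sp) ** 2).sum(axis=1)
        best = min(best, float(d2.min()))
    return float(np.sqrt(best))


def segment_hits_mask(p0, p1, mask, spacing, step=1e-3):
    """Dense line sampling: does the open segment touch any True voxel?"""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    sp = np.asarray(spacing, float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(length / step), 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    idx = np.floor(pts / sp).astype(int)
    inb = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    idx = idx[inb]
    return bool(mask[idx[:, 0], idx[:, 1], idx[:, 2]].any())
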