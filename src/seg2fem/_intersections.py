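"""Exact triangle-triangle overlap detection for surface self-intersection tests.

Implements the interval variant of the Moller triangle-triangle test,
vectorized over candidate pairs; candidates come from an AABB broad phase.
Pairs sharing a vertex coordinate (adjacency, including bitwise-shared
snapped nodes) are excluded: only genuine crossings count as intersections.
Grazing contact within floating-point noise is not reported.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _signed_distances(tri_pts: np.ndarray, normals: np.ndarray, origins: np.ndarray) -> np.ndarray:
    """Signed distances of 3 vertices (n,3,3) to planes (normal, origin)."""
    return np.einsum("nij,nj->ni", tri_pts - origins[:, None, :], normals)


def _interval(pp: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersection interval of each triangle with the other's plane.

    ``pp``: (n,3) vertex projections on the intersection line direction;
    ``d``: (n,3) signed plane distances.  Returns (t_lo, t_hi, valid) where
    valid is False when the triangle does not straddle the plane.
    """
    sign = np.where(d >= 0.0, 1.0, -1.0)
    # index of the vertex alone on its side of the plane
    alone = np.full(len(d), -1)
    for i, (j, k) in enumerate(((1, 2), (0, 2), (0, 1))):
        mask = (sign[:, i] != sign[:, j]) & (sign[:, i] != sign[:, k])
        alone[mask] = i
    valid = alone >= 0
    a = np.where(valid, alone, 0)
    idx = np.arange(len(d))
    others = np.array([[1, 2], [0, 2], [0, 1]])[a]
    da = d[idx, a]
    pa = pp[idx, a]
    lo = np.empty(len(d))
    hi = np.empty(len(d))
    ts = []
    for col in (0, 1):
        b = others[:, col]
        db = d[idx, b]
        denom = da - db
        denom = np.where(np.abs(denom) < _EPS, _EPS, denom)
        ts.append(pa + (pp[idx, b] - pa) * da / denom)
    lo = np.minimum(ts[0], ts[1])
    hi = np.maximum(ts[0], ts[1])
    return lo, hi, valid


def _tri_overlap_2d(t1: np.ndarray, t2: np.ndarray) -> bool:
    """Separating-axis overlap test of two 2D triangles (strict interior overlap)."""
    for tri_a, tri_b in ((t1, t2), (t2, t1)):
        for i in range(3):
            edge = tri_a[(i + 1) % 3] - tri_a[i]
            axis = np.array([-edge[1], edge[0]])
            norm = np.linalg.norm(axis)
            if norm < _EPS:
                continue
            axis = axis / norm
            pa = tri_a @ axis
            pb = tri_b @ axis
            if pa.max() <= pb.min() + 1e-9 or pb.max() <= pa.min() + 1e-9:
                return False
    return True


def triangle_pairs_intersect(tris_a: np.ndarray, tris_b: np.ndarray) -> np.ndarray:
    """Elementwise overlap test for paired triangles (n,3,3) vs (n,3,3)."""
    tris_a = np.asarray(tris_a, dtype=float)
    tris_b = np.asarray(tris_b, dtype=float)
    n = len(tris_a)
    if n == 0:
        return np.zeros(0, dtype=bool)
    n1 = np.cross(tris_a[:, 1] - tris_a[:, 0], tris_a[:, 2] - tris_a[:, 0])
    n2 = np.cross(tris_b[:, 1] - tris_b[:, 0], tris_b[:, 2] - tris_b[:, 0])
    scale = np.maximum(np.linalg.norm(n1, axis=1), np.linalg.norm(n2, axis=1))
    scale = np.where(scale < _EPS, 1.0, scale)
    db = _signed_distances(tris_b, n1, tris_a[:, 0])
    da = _signed_distances(tris_a, n2, tris_b[:, 0])
    tol = 1e-10 * scale[:, None]

    sep_b = np.all(db > tol, axis=1) | np.all(db < -tol, axis=1)
    sep_a = np.all(da > tol, axis=1) | np.all(da < -tol, axis=1)
    result = np.zeros(n, dtype=bool)
    active = ~(sep_a | sep_b)

    coplanar = active & np.all(np.abs(db) <= tol, axis=1)
    general = active & ~coplanar
    if general.any():
        ga, gb = tris_a[general], tris_b[general]
        gn1, gn2 = n1[general], n2[general]
        gda, gdb = da[general], db[general]
        line = np.cross(gn1, gn2)
        axis = np.argmax(np.abs(line), axis=1)
        idx = np.arange(len(ga))
        ppa = ga[idx, :, axis]
        ppb = gb[idx, :, axis]
        lo_a, hi_a, va = _interval(ppa, gda)
        lo_b, hi_b, vb = _interval(ppb, gdb)
        span = np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b)
        ref = np.maximum(hi_a - lo_a, hi_b - lo_b)
        result[np.flatnonzero(general)] = va & vb & (span > 1e-9 * np.maximum(ref, 1.0))
    if coplanar.any():
        for i in np.flatnonzero(coplanar):
            drop = np.argmax(np.abs(n1[i]))
            keep = [k for k in range(3) if k != drop]
            result[i] = _tri_overlap_2d(tris_a[i][:, keep], tris_b[i][:, keep])
    return result


def candidate_face_pairs(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """AABB-overlapping face pairs that do not share a vertex coordinate.

    Uses a sorted sweep along the axis of largest extent followed by exact
    AABB overlap; shared coordinates are compared bitwise so that faces
    meeting at a merged or snapped node never count as candidates.
    """
    tris = vertices[faces]
    lo = tris.min(axis=1)
    hi = tris.max(axis=1)
    axis = int(np.argmax(hi.max(axis=0) - lo.min(axis=0)))
    order = np.argsort(lo[:, axis], kind="stable")
    lo_s, hi_s = lo[order], hi[order]

    pairs = []
    n = len(faces)
    ends = hi_s[:, axis]
    starts = lo_s[:, axis]
    # sweep: for each face i (sorted by start), candidates are faces j > i
    # with start_j <= end_i
    upper = np.searchsorted(starts, ends, side="right")
    for i in range(n):
        j = np.arange(i + 1, upper[i])
        if len(j) == 0:
            continue
        ok = np.all(lo_s[j] <= hi_s[i], axis=1) & np.all(hi_s[j] >= lo_s[i], axis=1)
        j = j[ok]
        if len(j):
            pairs.append(np.stack([np.full(len(j), i), j], axis=1))
    if not pairs:
        return np.zeros((0, 2), dtype=int)
    pairs = np.concatenate(pairs)
    pairs = order[pairs]

    # exclude pairs sharing any vertex coordinate (bitwise)
    coord_keys = {}
    key_of = np.empty(len(vertices), dtype=int)
    for vi, v in enumerate(vertices):
        key = v.tobytes()
        key_of[vi] = coord_keys.setdefault(key, len(coord_keys))
    fk = key_of[faces]
    a, b = fk[pairs[:, 0]], fk[pairs[:, 1]]
    shares = np.zeros(len(pairs), dtype=bool)
    for i in range(3):
        for j in range(3):
            shares |= a[:, i] == b[:, j]
    return pairs[~shares]


def find_self_intersections(
    vertices: np.ndarray, faces: np.ndarray, max_pairs_chunk: int = 200_000
) -> np.ndarray:
    """Face-index pairs of a mesh that genuinely cross each other."""
    pairs = candidate_face_pairs(vertices, faces)
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=int)
    hits = []
    for start in range(0, len(pairs), max_pairs_chunk):
        chunk = pairs[start:start + max_pairs_chunk]
        mask = triangle_pairs_intersect(vertices[faces[chunk[:, 0]]],
                                        vertices[faces[chunk[:, 1]]])
        if mask.any():
            hits.append(chunk[mask])
    if not hits:
        return np.zeros((0, 2), dtype=int)
    return np.concatenate(hits)
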