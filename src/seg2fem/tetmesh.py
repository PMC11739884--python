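"""Tetrahedral filling of watertight surfaces and mesh-quality statistics.

The mesher keeps the contract that matters downstream: every surface vertex
appears in the volume mesh at its exact coordinates (the interface node
sets are found again later by coordinate matching, and the shared-node
property between bodies survives volume meshing).  Interior nodes are laid
out on an isotropic lattice at the target edge length, the union of points
is Delaunay-tessellated, and tetrahedra are kept when their centroid lies
inside the surface (parity ray casting).  A few fixed-boundary Laplacian
sweeps over the interior nodes relax the lattice against the boundary.

Quality is measured as the ratio of the longest to the shortest of the six
element edges; elements with ratio > 5 count as poor, and meshes are
conventionally expected to keep poor elements below 10 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .surface import DiagnosticsReport, TriSurfaceMesh, diagnose

#: C3D10 edge ordering: midnode k lies on edge EDGE_PAIRS[k] of the corners.
EDGE_PAIRS = np.array([(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)])


class MeshingFailureError(RuntimeError):
    """Raised when a surface cannot be filled (bad input or broken contract)."""

    def __init__(self, message: str, report: DiagnosticsReport | None = None):
        super().__init__(message)
        self.report = report


class DegenerateElementError(ValueError):
    """Raised for zero-length element edges."""


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with a surface-vertex-to-node map.

    ``elements`` rows hold corner nodes first; quadratic (10-node) elements
    append the six edge midpoints in the C3D10 convention.
    ``surface_node_map[i]`` is the volume node carrying surface vertex ``i``
    at bitwise-identical coordinates.
    """

    nodes: np.ndarray
    elements: np.ndarray
    surface_node_map: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    order: str = "linear"

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64).reshape(-1, 3)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.surface_node_map = np.asarray(self.surface_node_map, dtype=np.int64)
        width = 4 if self.order == "linear" else 10
        if self.elements.size and self.elements.shape[1] != width:
            raise ValueError(f"{self.order} elements need {width} nodes per row")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def corners(self) -> np.ndarray:
        return self.elements[:, :4]

    def element_volumes(self) -> np.ndarray:
        c = self.nodes[self.corners]
        return np.einsum("ij,ij->i", c[:, 1] - c[:, 0],
                         np.cross(c[:, 2] - c[:, 0], c[:, 3] - c[:, 0])) / 6.0

    def total_volume(self) -> float:
        return float(self.element_volumes().sum())

    def copy(self) -> "TetMesh":
        return TetMesh(self.nodes.copy(), self.elements.copy(),
                       self.surface_node_map.copy(), self.order)


def points_inside(mesh: TriSurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Parity test: which points lie inside a closed surface.

    Casts a +z ray per point and counts triangle crossings, vectorized by
    binning triangles and points into a 2D grid.  Points are nudged by an
    irrational sub-micrometre offset so rays never pass exactly through
    triangle edges.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    tris = mesh.vertices[mesh.faces]
    jitter = np.array([1e-4 * np.sqrt(2.0), 1e-4 * np.sqrt(3.0)])
    pxy = points[:, :2] + jitter
    pz = points[:, 2]

    lo = tris[:, :, :2].min(axis=1)
    hi = tris[:, :, :2].max(axis=1)
    origin = lo.min(axis=0) - 1e-9
    cell = max(np.median(hi[:, 0] - lo[:, 0]), np.median(hi[:, 1] - lo[:, 1]), 1e-6) * 2.0
    extent = np.maximum(hi.max(axis=0) - origin, cell)
    ncell = np.maximum((extent / cell).astype(int) + 1, 1)

    def cell_of(xy):
        c = np.clip((xy - origin) // cell, 0, ncell - 1).astype(int)
        return c[:, 0] * ncell[1] + c[:, 1]

    # triangle -> covered cells
    clo = np.clip(((lo - origin) // cell), 0, ncell - 1).astype(int)
    chi = np.clip(((hi - origin) // cell), 0, ncell - 1).astype(int)
    span = (chi - clo + 1)
    reps = span[:, 0] * span[:, 1]
    tri_ids = np.repeat(np.arange(len(tris)), reps)
    local = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    sx = np.repeat(span[:, 1], reps)
    dx = local // sx
    dy = local % sx
    tcell = (np.repeat(clo[:, 0], reps) + dx) * ncell[1] + (np.repeat(clo[:, 1], reps) + dy)

    pcell = cell_of(pxy)
    crossings = np.zeros(len(points), dtype=np.int64)

    order_t = np.argsort(tcell, kind="stable")
    tcell_s, tri_s = tcell[order_t], tri_ids[order_t]
    order_p = np.argsort(pcell, kind="stable")
    pcell_s, pid_s = pcell[order_p], np.arange(len(points))[order_p]

    tb = np.searchsorted(tcell_s, np.arange(ncell[0] * ncell[1] + 1))
    pb = np.searchsorted(pcell_s, np.arange(ncell[0] * ncell[1] + 1))
    a = tris[:, 0]
    v0 = tris[:, 1] - a
    v1 = tris[:, 2] - a
    denom2d = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    denom2d = np.where(np.abs(denom2d) < 1e-30, 1e-30, denom2d)

    for c in np.unique(pcell_s):
        t0, t1 = tb[c], tb[c + 1]
        if t0 == t1:
            continue
        p0, p1 = pb[c], pb[c + 1]
        t_idx = tri_s[t0:t1]
        p_idx = pid_s[p0:p1]
        d = pxy[p_idx][:, None, :] - a[t_idx][None, :, :2]  # (np, nt, 2)
        s = (d[:, :, 0] * v1[t_idx, 1] - d[:, :, 1] * v1[t_idx, 0]) / denom2d[t_idx]
        t = (v0[t_idx, 0] * d[:, :, 1] - v0[t_idx, 1] * d[:, :, 0]) / denom2d[t_idx]
        hit = (s > 0) & (t > 0) & (s + t < 1)
        if not hit.any():
            continue
        zc = (a[t_idx, 2][None, :] + s * v0[t_idx, 2][None, :] + t * v1[t_idx, 2][None, :])
        above = hit & (zc > pz[p_idx][:, None])
        np.add.at(crossings, p_idx, above.sum(axis=1))
    return crossings % 2 == 1


def _relax_interior(nodes: np.ndarray, elements: np.ndarray, n_fixed: int,
                    iters: int = 4) -> np.ndarray:
    """Laplacian sweeps over interior nodes (surface nodes fixed), reverted
    where they would invert an element."""
    if iters == 0:
        return nodes
    import scipy.sparse as sp

    edges = np.concatenate([elements[:, p] for p in
                            ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))])
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = sp.coo_matrix((np.ones(len(i)), (i, j)), shape=(len(nodes),) * 2).tocsr()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0

    def volumes(nd):
        c = nd[elements[:, :4]]
        return np.einsum("ij,ij->i", c[:, 1] - c[:, 0],
                         np.cross(c[:, 2] - c[:, 0], c[:, 3] - c[:, 0]))

    out = nodes.copy()
    for _ in range(iters):
        mean = (adj @ out) / deg[:, None]
        cand = out.copy()
        cand[n_fixed:] = 0.5 * (out[n_fixed:] + mean[n_fixed:])
        if volumes(cand).min() <= 0:
            bad = np.unique(elements[volumes(cand) <= 0, :4])
            cand[bad[bad >= n_fixed]] = out[bad[bad >= n_fixed]]
            if volumes(cand).min() <= 0:
                break
        out = cand
    return out


def fill_volume(
    mesh: TriSurfaceMesh,
    target_edge_mm: float = 1.0,
    min_size_mm: float = 0.1,
    check_self_intersection: bool = True,
    relax_iters: int = 4,
) -> TetMesh:
    """Fill a watertight surface with tetrahedra, retaining surface vertices.

    Raises :class:`MeshingFailureError` (with diagnostics) for non-watertight,
    non-manifold or self-intersecting input.  ``min_size_mm`` is the smallest
    admissible element edge; lattice nodes are kept clear of the boundary so
    no edge falls below it.
    """
    if target_edge_mm <= 0:
        raise ValueError("target_edge_mm must be positive")
    report = diagnose(mesh, check_self_intersection=check_self_intersection)
    if not (report.watertight and report.manifold) or report.self_intersecting:
        raise MeshingFailureError(
            f"body {mesh.body_id}: surface unsuitable for meshing "
            f"(watertight={report.watertight}, manifold={report.manifold}, "
            f"self_intersecting={report.self_intersecting})", report)

    verts = mesh.vertices
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    axes = [np.arange(lo[k] + 0.5 * target_edge_mm, hi[k], target_edge_mm)
            for k in range(3)]
    if all(len(ax) for ax in axes):
        lattice = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        # deterministic jitter breaks the lattice's cospherical degeneracies,
        # which would otherwise produce zero-volume Delaunay slivers
        rng = np.random.default_rng(0)
        lattice = lattice + rng.uniform(-0.15, 0.15, lattice.shape) * target_edge_mm
        d, _ = cKDTree(verts).query(lattice)
        clearance = max(0.7 * target_edge_mm, min_size_mm)
        lattice = lattice[d >= clearance]
        if len(lattice):
            lattice = lattice[points_inside(mesh, lattice)]
    else:
        lattice = np.zeros((0, 3))

    points = np.vstack([verts, lattice])
    tri = Delaunay(points)
    tets = tri.simplices
    centroids = points[tets].mean(axis=1)
    tets = tets[points_inside(mesh, centroids)]
    if len(tets) == 0:
        raise MeshingFailureError(f"body {mesh.body_id}: no interior tetrahedra", report)
    # drop flat boundary slivers: nearly no volume (far below the 0.5 %
    # conservation budget) but catastrophic for stiffness conditioning
    c = points[tets]
    vol = np.abs(np.einsum("ij,ij->i", c[:, 1] - c[:, 0],
                           np.cross(c[:, 2] - c[:, 0], c[:, 3] - c[:, 0]))) / 6.0
    el = np.linalg.norm(c[:, EDGE_PAIRS[:, 0]] - c[:, EDGE_PAIRS[:, 1]], axis=2)
    rms = np.sqrt((el ** 2).mean(axis=1))
    tets = tets[vol > 2e-3 * rms ** 3]

    used = np.unique(tets)
    missing_surface = np.setdiff1d(np.arange(len(verts)), used[used < len(verts)])
    if missing_surface.size:
        raise MeshingFailureError(
            f"body {mesh.body_id}: {missing_surface.size} surface vertices dropped "
            "during tetrahedralization (retention contract broken)", report)
    # compact: surface nodes keep ids 0..n-1, used lattice nodes follow
    remap = -np.ones(len(points), dtype=np.int64)
    n_surf = len(verts)
    remap[:n_surf] = np.arange(n_surf)
    interior_used = used[used >= n_surf]
    remap[interior_used] = n_surf + np.arange(len(interior_used))
    nodes = np.vstack([verts, points[interior_used]])
    tets = remap[tets]

    # orient positively
    c = nodes[tets]
    vol6 = np.einsum("ij,ij->i", c[:, 1] - c[:, 0],
                     np.cross(c[:, 2] - c[:, 0], c[:, 3] - c[:, 0]))
    flip = vol6 < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]

    nodes = _relax_interior(nodes, tets, n_surf, iters=relax_iters)
    return TetMesh(nodes=nodes, elements=tets,
                   surface_node_map=np.arange(n_surf), order="linear")


def to_quadratic(tm: TetMesh) -> TetMesh:
    """Insert one midpoint node per unique edge (C3D10 layout)."""
    if tm.order != "linear":
        raise ValueError("mesh is already quadratic")
    edges = tm.elements[:, EDGE_PAIRS]  # (E, 6, 2)
    flat = np.sort(edges.reshape(-1, 2), axis=1)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    midpoints = 0.5 * (tm.nodes[uniq[:, 0]] + tm.nodes[uniq[:, 1]])
    mid_ids = tm.n_nodes + inverse.reshape(-1, 6)
    elements = np.concatenate([tm.elements, mid_ids], axis=1)
    return TetMesh(nodes=np.vstack([tm.nodes, midpoints]), elements=elements,
                   surface_node_map=tm.surface_node_map.copy(), order="quadratic")


def aspect_ratio(corner_coords: np.ndarray) -> float:
    """Max over min edge length of one tetrahedron (>= 1)."""
    c = np.asarray(corner_coords, dtype=float).reshape(4, 3)
    lengths = np.linalg.norm(c[EDGE_PAIRS[:, 0]] - c[EDGE_PAIRS[:, 1]], axis=1)
    if lengths.min() == 0:
        raise DegenerateElementError("zero-length element edge")
    return float(lengths.max() / lengths.min())


def aspect_ratios(tm: TetMesh) -> np.ndarray:
    """Per-element max/min edge ratio, computed on corner nodes."""
    c = tm.nodes[tm.corners]
    lengths = np.linalg.norm(c[:, EDGE_PAIRS[:, 0]] - c[:, EDGE_PAIRS[:, 1]], axis=2)
    mins = lengths.min(axis=1)
    if np.any(mins == 0):
        raise DegenerateElementError("zero-length element edge")
    return lengths.max(axis=1) / mins


def poor_quality_fraction(tm: TetMesh, threshold: float = 5.0) -> float:
    """Percentage of elements with aspect ratio above ``threshold``."""
    if tm.n_elements == 0:
        raise ValueError("empty mesh has no quality fraction")
    ratios = aspect_ratios(tm)
    return float(100.0 * np.count_nonzero(ratios > threshold) / tm.n_elements)


def structured_box_mesh(
    size, divisions, origin=(0.0, 0.0, 0.0)
) -> TetMesh:
    """Conforming 6-tet-per-cube mesh of a box (FE verification fixture)."""
    size = np.asarray(size, dtype=float)
    nx, ny, nz = (int(n) for n in divisions)
    xs = [np.linspace(0, size[k], (nx, ny, nz)[k] + 1) + origin[k] for k in range(3)]
    grid = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    nodes = grid.reshape(-1, 3)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    kuhn = [
        (0b000, 0b100, 0b110, 0b111),
        (0b000, 0b110, 0b010, 0b111),
        (0b000, 0b010, 0b011, 0b111),
        (0b000, 0b011, 0b001, 0b111),
        (0b000, 0b001, 0b101, 0b111),
        (0b000, 0b101, 0b100, 0b111),
    ]
    elements = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = {}
                for b in range(8):
                    corner[b] = nid(i + (b >> 2 & 1), j + (b >> 1 & 1), k + (b & 1))
                for tet in kuhn:
                    elements.append([corner[b] for b in tet])
    elements = np.asarray(elements, dtype=np.int64)
    tm = TetMesh(nodes=nodes, elements=elements, order="linear")
    vols = tm.element_volumes()
    flip = vols < 0
    tm.elements[flip] = tm.elements[flip][:, [0, 2, 1, 3]]
    return tm
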