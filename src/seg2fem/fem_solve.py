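"""Static linear-elastic FE solver for 4- and 10-node tetrahedra.

Small-strain isoparametric assembly: linear tetrahedra are constant-strain
(integrated exactly by their volume), quadratic tetrahedra use the 4-point
interior Gauss rule.  The kinematic coupling constraint is realized by DoF
elimination — coupled node displacements are expressed through the
reference node's 6 generalized DoF via the small-rotation rigid map
``u_i = u_ref + theta x (x_i - x_ref)`` — which keeps the reduced operator
symmetric positive definite once supports are applied.  Singular systems
yield a non-converged result with diagnostics instead of an exception.

Stress is recovered per element as the quadrature average; the von Mises
equivalent serves as the reporting scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem_build import FEModel, Material
from .tetmesh import TetMesh

_GAUSS4 = np.array([
    [0.58541020, 0.13819660, 0.13819660],
    [0.13819660, 0.58541020, 0.13819660],
    [0.13819660, 0.13819660, 0.58541020],
    [0.13819660, 0.13819660, 0.13819660],
])
_GAUSS4_W = np.full(4, 0.25)


class AssemblyError(RuntimeError):
    """Raised for inverted (non-positive-Jacobian) elements."""


@dataclass
class FEResult:
    """Solution of one static analysis."""

    displacements: np.ndarray            # (n_nodes, 3) mm
    element_von_mises: np.ndarray        # (n_elements,) MPa
    ref_node_motion: np.ndarray          # (6,) 3 translations mm + 3 rotations rad
    converged: bool
    reactions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    diagnostics: str = ""

    @property
    def max_von_mises(self) -> float:
        return float(self.element_von_mises.max()) if self.element_von_mises.size else 0.0

    @property
    def mean_von_mises(self) -> float:
        return float(self.element_von_mises.mean()) if self.element_von_mises.size else 0.0

    def summary(self) -> dict:
        return {
            "converged": bool(self.converged),
            "max_von_mises_mpa": self.max_von_mises,
            "mean_von_mises_mpa": self.mean_von_mises,
            "max_displacement_mm": float(np.linalg.norm(self.displacements, axis=1).max())
            if self.displacements.size else 0.0,
            "ref_node_motion": self.ref_node_motion.tolist(),
            "diagnostics": self.diagnostics,
        }


def elasticity_matrix(material: Material) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
    e, nu = material.youngs_modulus, material.poisson_ratio
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] += 2 * mu
    d[3:, 3:] = np.eye(3) * mu
    return d


def _tet10_shape_gradients() -> np.ndarray:
    """dN/d(xi,eta,zeta) of the 10 shape functions at the 4 Gauss points.

    Natural coordinates: L1 = 1-xi-eta-zeta, L2 = xi, L3 = eta, L4 = zeta;
    corner i: Li(2Li - 1); midnodes 4 La Lb on edges
    (1,2),(2,3),(3,1),(1,4),(2,4),(3,4).
    """
    grads = np.zeros((len(_GAUSS4), 10, 3))
    dL = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    edges = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    for q, (xi, eta, zeta) in enumerate(_GAUSS4):
        L = np.array([1 - xi - eta - zeta, xi, eta, zeta])
        for i in range(4):
            grads[q, i] = (4 * L[i] - 1) * dL[i]
        for m, (a, b) in enumerate(edges):
            grads[q, 4 + m] = 4 * (L[a] * dL[b] + L[b] * dL[a])
    return grads


_TET10_GRADS = _tet10_shape_gradients()


def _b_matrix(grad_xyz: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 3*nn) from shape gradients (nn, 3)."""
    nn = grad_xyz.shape[0]
    b = np.zeros((6, 3 * nn))
    gx, gy, gz = grad_xyz[:, 0], grad_xyz[:, 1], grad_xyz[:, 2]
    b[0, 0::3] = gx
    b[1, 1::3] = gy
    b[2, 2::3] = gz
    b[3, 0::3] = gy
    b[3, 1::3] = gx
    b[4, 1::3] = gz
    b[4, 2::3] = gy
    b[5, 0::3] = gz
    b[5, 2::3] = gx
    return b


def _b_batch(grad: np.ndarray) -> np.ndarray:
    """Vectorized strain-displacement matrices (e, 6, 3*nn) from (e, nn, 3)."""
    e, nn, _ = grad.shape
    b = np.zeros((e, 6, 3 * nn))
    gx, gy, gz = grad[:, :, 0], grad[:, :, 1], grad[:, :, 2]
    b[:, 0, 0::3] = gx
    b[:, 1, 1::3] = gy
    b[:, 2, 2::3] = gz
    b[:, 3, 0::3] = gy
    b[:, 3, 1::3] = gx
    b[:, 4, 1::3] = gz
    b[:, 4, 2::3] = gy
    b[:, 5, 0::3] = gz
    b[:, 5, 2::3] = gx
    return b


def _element_quadrature(tm: TetMesh, material: Material):
    """Yield (element ids, B matrices (e,q,6,3nn), weights (e,q)) in chunks."""
    d = elasticity_matrix(material)
    nn = 4 if tm.order == "linear" else 10
    chunk = max(1, int(8e7 // (nn * nn * 36)))
    for start in range(0, tm.n_elements, chunk):
        elems = tm.elements[start:start + chunk]
        coords = tm.nodes[elems]  # (e, nn, 3)
        if tm.order == "linear":
            dN = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
            jac = np.einsum("ni,enj->eij", dN, coords)
            det = np.linalg.det(jac)
            if np.any(det <= 0):
                bad = start + int(np.argmax(det <= 0))
                raise AssemblyError(f"inverted element {bad}")
            inv = np.linalg.inv(jac)
            grad = np.einsum("eij,nj->eni", inv, dN)
            bmats = _b_batch(grad)[:, None, :, :]
            weights = (det / 6.0)[:, None]
        else:
            nq = len(_GAUSS4)
            bmats = np.empty((len(elems), nq, 6, 30))
            weights = np.empty((len(elems), nq))
            for q in range(nq):
                dN = _TET10_GRADS[q]
                jac = np.einsum("ni,enj->eij", dN, coords)
                det = np.linalg.det(jac)
                if np.any(det <= 0):
                    bad = start + int(np.argmax(det <= 0))
                    raise AssemblyError(f"inverted element {bad}")
                inv = np.linalg.inv(jac)
                grad = np.einsum("eij,nj->eni", inv, dN)
                bmats[:, q] = _b_batch(grad)
                weights[:, q] = det / 6.0 * _GAUSS4_W[q]
        yield start, elems, bmats, weights, d


def assemble_stiffness(tm: TetMesh, material: Material) -> sp.csr_matrix:
    """Global stiffness operator (3N x 3N), symmetric PSD with a
    6-dimensional rigid-body null space before constraints."""
    ndof = 3 * tm.n_nodes
    rows, cols, vals = [], [], []
    for _, elems, bmats, weights, d in _element_quadrature(tm, material):
        ke = np.einsum("eqji,jk,eqkl,eq->eil", bmats, d, bmats, weights,
                       optimize=True)
        dof = (3 * elems[:, :, None] + np.arange(3)[None, None, :]).reshape(len(elems), -1)
        nloc = dof.shape[1]
        rows.append(np.repeat(dof, nloc, axis=1).ravel())
        cols.append(np.tile(dof, (1, nloc)).ravel())
        vals.append(ke.ravel())
    k = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof)).tocsr()
    return k


def coupling_transform(
    tm: TetMesh, coupled_set: np.ndarray, ref: int
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """DoF-elimination map for a rigid kinematic coupling.

    Returns ``(T, free_nodes, ref_cols)`` with ``u_full = T @ q``; ``q``
    stacks the retained nodal DoFs (nodes outside the coupled set, original
    order) followed by the reference node's 6 generalized DoF.  Coupled
    nodes follow ``u_i = u_ref + theta x (x_i - x_ref)``.
    """
    coupled = np.unique(np.asarray(coupled_set, dtype=np.int64))
    coupled = np.union1d(coupled, [ref])
    n = tm.n_nodes
    is_slave = np.zeros(n, dtype=bool)
    is_slave[coupled] = True
    free_nodes = np.flatnonzero(~is_slave)
    ncols = 3 * len(free_nodes) + 6
    col_base = -np.ones(n, dtype=np.int64)
    col_base[free_nodes] = 3 * np.arange(len(free_nodes))
    ref_cols = np.arange(ncols - 6, ncols)

    rows, cols, vals = [], [], []
    fr = 3 * free_nodes[:, None] + np.arange(3)
    fc = col_base[free_nodes][:, None] + np.arange(3)
    rows.append(fr.ravel()); cols.append(fc.ravel()); vals.append(np.ones(fr.size))
    r = tm.nodes[coupled] - tm.nodes[ref]
    for d in range(3):
        rows.append(3 * coupled + d)
        cols.append(np.full(len(coupled), ref_cols[d]))
        vals.append(np.ones(len(coupled)))
    # u = theta x r: x: ty*rz - tz*ry ; y: tz*rx - tx*rz ; z: tx*ry - ty*rx
    terms = [
        (0, 4, r[:, 2]), (0, 5, -r[:, 1]),
        (1, 5, r[:, 0]), (1, 3, -r[:, 2]),
        (2, 3, r[:, 1]), (2, 4, -r[:, 0]),
    ]
    for row_d, col_d, val in terms:
        rows.append(3 * coupled + row_d)
        cols.append(np.full(len(coupled), ref_cols[col_d]))
        vals.append(val)
    t = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n, ncols)).tocsr()
    return t, free_nodes, ref_cols


def von_mises(stress: np.ndarray) -> float:
    """Equivalent (von Mises) stress of a symmetric 3x3 stress tensor."""
    s = np.asarray(stress, dtype=float).reshape(3, 3)
    return float(np.sqrt(
        0.5 * ((s[0, 0] - s[1, 1]) ** 2 + (s[1, 1] - s[2, 2]) ** 2
               + (s[2, 2] - s[0, 0]) ** 2)
        + 3.0 * (s[0, 1] ** 2 + s[1, 2] ** 2 + s[2, 0] ** 2)))


def _von_mises_voigt(sig: np.ndarray) -> np.ndarray:
    """Von Mises from Voigt stresses (..., 6)."""
    return np.sqrt(
        0.5 * ((sig[..., 0] - sig[..., 1]) ** 2 + (sig[..., 1] - sig[..., 2]) ** 2
               + (sig[..., 2] - sig[..., 0]) ** 2)
        + 3.0 * (sig[..., 3] ** 2 + sig[..., 4] ** 2 + sig[..., 5] ** 2))


def element_stresses(tm: TetMesh, material: Material, u: np.ndarray) -> np.ndarray:
    """Quadrature-averaged per-element von Mises stress (MPa)."""
    u = np.asarray(u, dtype=float).reshape(-1, 3)
    out = np.empty(tm.n_elements)
    for start, elems, bmats, weights, d in _element_quadrature(tm, material):
        ue = u[elems].reshape(len(elems), -1)
        strain = np.einsum("eqij,ej->eqi", bmats, ue, optimize=True)
        sig = np.einsum("ij,eqj->eqi", d, strain)
        wsum = weights.sum(axis=1, keepdims=True)
        avg = (sig * (weights / wsum)[:, :, None]).sum(axis=1)
        out[start:start + len(elems)] = _von_mises_voigt(avg)
    return out


#: above this many DoF the solver switches from sparse LU to Jacobi-
#: preconditioned conjugate gradients (LU fill-in grows prohibitively for
#: flat, plate-like bodies such as discs)
_DIRECT_SOLVE_LIMIT = 15_000


def _solve_spd(kff: sp.csc_matrix, rhs: np.ndarray) -> np.ndarray:
    """Solve the reduced SPD system; raises RuntimeError on singularity."""
    if kff.shape[0] <= _DIRECT_SOLVE_LIMIT:
        return spla.splu(kff).solve(rhs)
    diag = kff.diagonal()
    if np.any(diag <= 0):
        raise RuntimeError("non-positive diagonal in reduced operator")
    precond = spla.LinearOperator(kff.shape, lambda x: x / diag)
    sol, info = spla.cg(kff, rhs, M=precond, rtol=1e-10, atol=0.0, maxiter=10_000)
    if info != 0:
        raise RuntimeError(f"iterative solve did not converge (info={info})")
    return sol


def solve_linear_static(
    tm: TetMesh,
    material: Material,
    fixed: dict[int, np.ndarray] | None = None,
    nodal_forces: dict[int, np.ndarray] | None = None,
    coupling: tuple[int, np.ndarray] | None = None,
    ref_load: np.ndarray | None = None,
    stiffness: sp.csr_matrix | None = None,
) -> FEResult:
    """General static solve with supports, loads and optional coupling.

    ``fixed`` maps node id to a prescribed displacement vector (zeros for a
    full restraint); ``ref_load`` is the 6-vector (forces N, moments N*mm)
    on the coupling reference's generalized DoF.  Returns ``converged=False``
    with diagnostics on a singular reduced system.
    """
    fixed = fixed or {}
    nodal_forces = nodal_forces or {}
    n = tm.n_nodes
    k = assemble_stiffness(tm, material) if stiffness is None else stiffness
    f = np.zeros(3 * n)
    for node, vec in nodal_forces.items():
        f[3 * node:3 * node + 3] += np.asarray(vec, dtype=float)

    if coupling is not None:
        ref, coupled = coupling
        if any(node in fixed for node in np.atleast_1d(coupled)) or ref in fixed:
            raise ValueError("coupled set intersects the restrained set")
        t, free_nodes, ref_cols = coupling_transform(tm, coupled, ref)
    else:
        t = sp.identity(3 * n, format="csr")
        free_nodes = np.arange(n)
        ref_cols = None

    kq = (t.T @ k @ t).tocsr()
    fq = t.T @ f
    if ref_load is not None:
        if ref_cols is None:
            raise ValueError("ref_load requires a coupling")
        fq[ref_cols] += np.asarray(ref_load, dtype=float)

    nq = kq.shape[0]
    col_of_node = -np.ones(n, dtype=np.int64)
    col_of_node[free_nodes] = 3 * np.arange(len(free_nodes))
    presc_cols = []
    presc_vals = []
    for node, vec in fixed.items():
        if col_of_node[node] < 0:
            raise ValueError(f"node {node} is coupled and cannot also be restrained")
        presc_cols.extend(col_of_node[node] + np.arange(3))
        presc_vals.extend(np.asarray(vec, dtype=float))
    presc_cols = np.asarray(presc_cols, dtype=np.int64)
    presc_vals = np.asarray(presc_vals, dtype=float)
    keep = np.setdiff1d(np.arange(nq), presc_cols)

    q = np.zeros(nq)
    q[presc_cols] = presc_vals
    rhs = fq[keep] - kq[keep][:, presc_cols] @ presc_vals
    kff = kq[keep][:, keep].tocsc()
    try:
        sol = _solve_spd(kff, rhs)
    except RuntimeError as exc:
        return FEResult(
            displacements=np.zeros((n, 3)),
            element_von_mises=np.zeros(tm.n_elements),
            ref_node_motion=np.zeros(6),
            converged=False,
            diagnostics=f"singular system: {exc}")
    if not np.all(np.isfinite(sol)):
        return FEResult(
            displacements=np.zeros((n, 3)),
            element_von_mises=np.zeros(tm.n_elements),
            ref_node_motion=np.zeros(6),
            converged=False,
            diagnostics="non-finite solution (ill-conditioned system)")
    q[keep] = sol
    u = (t @ q).reshape(n, 3)
    for node, vec in fixed.items():
        u[node] = vec  # exact, not merely to solver tolerance
    reactions = (k @ u.ravel() - f).reshape(n, 3)
    ref_motion = q[ref_cols] if ref_cols is not None else np.zeros(6)
    return FEResult(
        displacements=u,
        element_von_mises=element_stresses(tm, material, u),
        ref_node_motion=np.asarray(ref_motion, dtype=float),
        converged=True,
        reactions=reactions,
    )


def solve_static(model: FEModel) -> FEResult:
    """Solve the standalone body model: superior set rigidly coupled and
    loaded by the flexion moment, inferior set fully restrained."""
    fixed = {int(nid): np.zeros(3) for nid in model.nset_inferior}
    ref_load = np.concatenate([np.zeros(3), model.load_moment_nmm])
    return solve_linear_static(
        model.mesh, model.material,
        fixed=fixed,
        coupling=model.coupling,
        ref_load=ref_load,
    )


def write_vtu(path, tm: TetMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Minimal ASCII VTU export (displacement/stress fields for inspection)."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    vtk_type = 10 if tm.order == "linear" else 24
    npts, ncell = tm.n_nodes, tm.n_elements
    width = tm.elements.shape[1]

    def arr(a, per_line):
        a = np.asarray(a)
        return "\n".join(" ".join(repr(float(x)) if isinstance(x, (float, np.floating)) else str(x)
                                  for x in row) for row in a.reshape(-1, per_line))

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncell}">',
        '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(tm.nodes, 3),
        '</DataArray></Points>',
        '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(tm.elements, width),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(width * (i + 1)) for i in range(ncell)),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(vtk_type) for _ in range(ncell)),
        '</DataArray>',
        '</Cells>',
    ]
    if point_data:
        parts.append('<PointData>')
        for name, data in point_data.items():
            data = np.asarray(data, dtype=float)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            parts.append(f'<DataArray type="Float64" Name="{name}" '
                         f'NumberOfComponents="{ncomp}" format="ascii">')
            parts.append(arr(data, ncomp))
            parts.append('</DataArray>')
        parts.append('</PointData>')
    if cell_data:
        parts.append('<CellData>')
        for name, data in cell_data.items():
            data = np.asarray(data, dtype=float)
            ncomp = 1 if data.ndim == 1 else data.shape[1]
            parts.append(f'<DataArray type="Float64" Name="{name}" '
                         f'NumberOfComponents="{ncomp}" format="ascii">')
            parts.append(arr(data, ncomp))
            parts.append('</DataArray>')
        parts.append('</CellData>')
    parts += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    Path(path).write_text("\n".join(parts) + "\n")
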