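"""FE model assembly: node sets, reference nodes, coupling, loads, .inp I/O.

The volume mesher renumbers nodes, so interface surface vertices are found
again in the volume mesh by comparing coordinates rounded to a fixed
precision (micrometre by default).  Each model carries two interface node
sets (superior/inferior contact surface), a reference node per set (the set
member closest to the set centroid), a kinematic coupling that rigidly ties
the superior set to its reference node, a full restraint of the inferior
set, a flexion moment at the superior reference node, and a linear elastic
isotropic material.  Models serialize to the ABAQUS/CalculiX ``.inp``
keyword dialect (C3D4/C3D10 element blocks, named node sets, coupling,
boundary, concentrated moment on rotational components 4-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .smoothing import InterfaceMap
from .tetmesh import TetMesh


class MappingError(RuntimeError):
    """Raised when an interface vertex has no rounded-coordinate match."""


class ModelError(ValueError):
    """Raised for inconsistent model definitions."""


class InpParseError(ValueError):
    """Raised on malformed .inp input, with the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class Material:
    """Linear elastic isotropic material (model units: MPa, mm, N)."""

    youngs_modulus: float
    poisson_ratio: float
    name: str = "MAT"

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ModelError("youngs_modulus must be positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ModelError("poisson_ratio must lie in (0, 0.5)")


#: Configurable default materials (placeholders from config, not ground truth).
DEFAULT_VERTEBRA_MATERIAL = Material(youngs_modulus=10_000.0, poisson_ratio=0.3, name="BONE")
DEFAULT_IVD_MATERIAL = Material(youngs_modulus=10.0, poisson_ratio=0.45, name="DISC")


@dataclass
class FEModel:
    """Simulation-ready model of one body.

    ``load_moment_nmm`` is the concentrated moment vector in N*mm applied to
    the rotational DoF of ``ref_superior``; ``nset_inferior`` is fully
    restrained (all translations of every member node, which collectively
    also restrains the surface's rigid rotations).
    """

    mesh: TetMesh
    nset_superior: np.ndarray
    nset_inferior: np.ndarray
    ref_superior: int
    ref_inferior: int
    load_moment_nmm: np.ndarray
    material: Material
    body_name: str = "BODY"
    analysis: str = "static"

    def __post_init__(self) -> None:
        self.nset_superior = np.unique(np.asarray(self.nset_superior, dtype=np.int64))
        self.nset_inferior = np.unique(np.asarray(self.nset_inferior, dtype=np.int64))
        self.load_moment_nmm = np.asarray(self.load_moment_nmm, dtype=float).reshape(3)
        if self.nset_superior.size == 0 or self.nset_inferior.size == 0:
            raise ModelError("superior and inferior node sets must be non-empty")
        if np.intersect1d(self.nset_superior, self.nset_inferior).size:
            raise ModelError("superior and inferior node sets must be disjoint")
        n = self.mesh.n_nodes
        for ref in (self.ref_superior, self.ref_inferior):
            if not 0 <= ref < n:
                raise ModelError(f"reference node {ref} outside mesh")
        if self.ref_superior not in self.nset_superior:
            raise ModelError("superior reference node must belong to the superior set")

    @property
    def coupling(self) -> tuple[int, np.ndarray]:
        """(reference node, rigidly coupled node set)."""
        return self.ref_superior, self.nset_superior


def map_surface_to_volume_nodes(
    coords: np.ndarray, tm: TetMesh, decimals: int = 3
) -> np.ndarray:
    """Find the volume node matching each coordinate after rounding.

    ``decimals=3`` compares at micrometre precision — far below element
    size, far above float noise.  Ambiguous rounded matches resolve to the
    nearest candidate; a coordinate with no match raises
    :class:`MappingError` naming the vertex (the meshing stage broke the
    vertex-retention contract).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    rounded_nodes = np.round(tm.nodes, decimals)
    lookup: dict[bytes, list[int]] = {}
    for idx, row in enumerate(rounded_nodes):
        lookup.setdefault(row.tobytes(), []).append(idx)
    result = np.empty(len(coords), dtype=np.int64)
    for i, c in enumerate(np.round(coords, decimals)):
        cand = lookup.get(c.tobytes())
        if not cand:
            raise MappingError(
                f"interface vertex {i} at {coords[i]} has no volume-node match "
                f"at {decimals}-decimal rounding")
        if len(cand) == 1:
            result[i] = cand[0]
        else:
            d = np.linalg.norm(tm.nodes[cand] - coords[i], axis=1)
            result[i] = cand[int(np.argmin(d))]
    return result


def interface_node_set(
    iface: InterfaceMap, side: str, surface_vertices: np.ndarray, tm: TetMesh,
    decimals: int = 3,
) -> np.ndarray:
    """Volume node ids of one interface side of a body."""
    ids = iface.side_ids(side)
    if ids.size == 0:
        return np.zeros(0, dtype=np.int64)
    return map_surface_to_volume_nodes(surface_vertices[ids], tm, decimals)


def reference_node(tm: TetMesh, nset: np.ndarray) -> int:
    """Member of ``nset`` nearest to the set centroid (ties: lowest id)."""
    nset = np.unique(np.asarray(nset, dtype=np.int64))
    if nset.size == 0:
        raise ModelError("empty node set has no reference node")
    pts = tm.nodes[nset]
    d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    return int(nset[d == d.min()].min())


def build_model(
    tm: TetMesh,
    iface: InterfaceMap,
    surface_vertices: np.ndarray,
    material: Material,
    moment_nm: float = 7.5,
    flexion_axis=(1.0, 0.0, 0.0),
    body_name: str = "BODY",
    decimals: int = 3,
) -> FEModel:
    """Populate the standalone simulation model of one body.

    The flexion moment (default 7.5 N*m = 7500 N*mm, about the axis
    orthogonal to the stacking and anterior-posterior directions) acts on
    the superior reference node; the superior set is kinematically coupled
    to it and the inferior set is fully restrained.
    """
    sup = interface_node_set(iface, "superior", surface_vertices, tm, decimals)
    inf = interface_node_set(iface, "inferior", surface_vertices, tm, decimals)
    if sup.size == 0 or inf.size == 0:
        raise ModelError(f"{body_name}: zero-measure interface set")
    axis = np.asarray(flexion_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ModelError("flexion axis must be a nonzero vector")
    moment = moment_nm * 1000.0 * axis / norm  # N*m -> N*mm in mm model space
    return FEModel(
        mesh=tm,
        nset_superior=sup,
        nset_inferior=inf,
        ref_superior=reference_node(tm, sup),
        ref_inferior=reference_node(tm, inf),
        load_moment_nmm=moment,
        material=material,
        body_name=body_name,
    )


# --------------------------------------------------------------------------
# .inp serialization (1-based node/element ids, 16 data entries per line)

_MAX_ENTRIES_PER_LINE = 16


def _wrap(entries: list[str]) -> list[str]:
    lines = []
    for start in range(0, len(entries), _MAX_ENTRIES_PER_LINE):
        chunk = entries[start:start + _MAX_ENTRIES_PER_LINE]
        cont = "," if start + _MAX_ENTRIES_PER_LINE < len(entries) else ""
        lines.append(", ".join(chunk) + cont)
    return lines


def write_inp(model: FEModel, path) -> None:
    """Emit the model in the .inp keyword dialect (bit-readable by read_inp)."""
    m = model.mesh
    name = model.body_name.upper()
    lines: list[str] = ["*HEADING", f"{model.body_name} generated by seg2fem"]
    lines.append("*NODE")
    for i, (x, y, z) in enumerate(m.nodes, start=1):
        lines.append(f"{i}, {float(x)!r}, {float(y)!r}, {float(z)!r}")
    eltype = "C3D10" if m.order == "quadratic" else "C3D4"
    lines.append(f"*ELEMENT, TYPE={eltype}, ELSET=EALL")
    for eid, row in enumerate(m.elements, start=1):
        lines.extend(_wrap([str(eid)] + [str(int(n) + 1) for n in row]))
    for set_name, nset in ((f"{name}_SUP", model.nset_superior),
                           (f"{name}_INF", model.nset_inferior)):
        lines.append(f"*NSET, NSET={set_name}")
        lines.extend(_wrap([str(int(n) + 1) for n in nset]))
    lines.append(f"*NSET, NSET={name}_REF_SUP")
    lines.append(f"{model.ref_superior + 1}")
    lines.append(f"*NSET, NSET={name}_REF_INF")
    lines.append(f"{model.ref_inferior + 1}")
    lines.append(f"*MATERIAL, NAME={model.material.name}")
    lines.append("*ELASTIC")
    lines.append(f"{float(model.material.youngs_modulus)!r}, "
                 f"{float(model.material.poisson_ratio)!r}")
    lines.append(f"*SOLID SECTION, ELSET=EALL, MATERIAL={model.material.name}")
    lines.append(f"*COUPLING, CONSTRAINT NAME=CPL_{name}, "
                 f"REF NODE={model.ref_superior + 1}, NSET={name}_SUP")
    lines.append("*KINEMATIC")
    lines.append("*STEP")
    lines.append("*STATIC")
    lines.append("*BOUNDARY")
    lines.append(f"{name}_INF, 1, 3, 0.0")
    lines.append("*CLOAD")
    for dof, comp in zip((4, 5, 6), model.load_moment_nmm):
        if comp != 0.0:
            lines.append(f"{model.ref_superior + 1}, {dof}, {float(comp)!r}")
    lines.append("*END STEP")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_keyword(line: str) -> tuple[str, dict[str, str]]:
    parts = [p.strip() for p in line.lstrip("*").split(",")]
    options = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            options[k.strip().upper()] = v.strip()
        else:
            options[p.upper()] = ""
    return parts[0].upper(), options


_KNOWN_KEYWORDS = {
    "HEADING", "NODE", "ELEMENT", "NSET", "MATERIAL", "ELASTIC",
    "SOLID SECTION", "COUPLING", "KINEMATIC", "STEP", "STATIC",
    "BOUNDARY", "CLOAD", "END STEP",
}


def read_inp(path) -> FEModel:
    """Parse a model written by :func:`write_inp` (inverse up to the
    surface-node map, which serialization does not carry)."""
    text = Path(path).read_text().splitlines()
    nodes: list[list[float]] = []
    elements: list[list[int]] = []
    nsets: dict[str, list[int]] = {}
    eltype = "C3D4"
    material: dict[str, float | str] = {}
    ref_sup = ref_inf = None
    coupling_ref = None
    moment = np.zeros(3)
    body_name = "BODY"
    section = None
    current_nset = None
    pending: list[str] = []

    def flush_element(entries: list[str], lineno: int) -> None:
        width = 11 if eltype == "C3D10" else 5
        if len(entries) != width:
            raise InpParseError(f"element record with {len(entries)} entries", lineno)
        elements.append([int(e) - 1 for e in entries[1:]])

    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            keyword, opts = _parse_keyword(line)
            if keyword not in _KNOWN_KEYWORDS:
                raise InpParseError(f"unknown keyword *{keyword}", lineno)
            section = keyword
            pending = []
            if keyword == "ELEMENT":
                eltype = opts.get("TYPE", "C3D4")
            elif keyword == "NSET":
                current_nset = opts["NSET"]
                nsets[current_nset] = []
            elif keyword == "MATERIAL":
                material["name"] = opts.get("NAME", "MAT")
            elif keyword == "COUPLING":
                coupling_ref = int(opts["REF NODE"]) - 1
            continue
        entries = [e for e in line.split(",") if e.strip()]
        entries = [e.strip() for e in entries]
        if section == "HEADING":
            body_name = line.split()[0] if line else body_name
        elif section == "NODE":
            if len(entries) != 4:
                raise InpParseError("node record needs id and 3 coordinates", lineno)
            nodes.append([float(v) for v in entries[1:]])
        elif section == "ELEMENT":
            pending.extend(entries)
            if not line.rstrip().endswith(","):
                flush_element(pending, lineno)
                pending = []
        elif section == "NSET":
            nsets[current_nset].extend(int(v) - 1 for v in entries)
        elif section == "ELASTIC":
            material["E"], material["nu"] = float(entries[0]), float(entries[1])
        elif section == "CLOAD":
            node, dof, value = int(entries[0]) - 1, int(entries[1]), float(entries[2])
            if dof not in (4, 5, 6):
                raise InpParseError(f"unsupported load DoF {dof}", lineno)
            moment[dof - 4] = value
            coupling_ref = coupling_ref if coupling_ref is not None else node
        # BOUNDARY/SOLID SECTION/STEP blocks are fixed-form and re-derived

    sup_name = next((n for n in nsets if n.endswith("_SUP") and "REF" not in n), None)
    inf_name = next((n for n in nsets if n.endswith("_INF") and "REF" not in n), None)
    if sup_name is None or inf_name is None:
        raise InpParseError("missing interface node sets", len(text))
    for n, ids in nsets.items():
        if n.endswith("_REF_SUP"):
            ref_sup = ids[0]
        elif n.endswith("_REF_INF"):
            ref_inf = ids[0]
    mesh = TetMesh(
        nodes=np.asarray(nodes, dtype=float),
        elements=np.asarray(elements, dtype=np.int64),
        order="quadratic" if eltype == "C3D10" else "linear",
    )
    return FEModel(
        mesh=mesh,
        nset_superior=np.asarray(nsets[sup_name], dtype=np.int64),
        nset_inferior=np.asarray(nsets[inf_name], dtype=np.int64),
        ref_superior=int(ref_sup if ref_sup is not None else coupling_ref),
        ref_inferior=int(ref_inf if ref_inf is not None else 0),
        load_moment_nmm=moment,
        material=Material(youngs_modulus=float(material["E"]),
                          poisson_ratio=float(material["nu"]),
                          name=str(material.get("name", "MAT"))),
        body_name=sup_name[:-4] if sup_name else body_name,
    )
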