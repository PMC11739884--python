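"""Per-subject orchestration, failure classification and cohort statistics.

``run_subject`` executes the full chain for every labeled body of one
subject: mask cleanup -> surface extraction -> repair -> smoothing (all
vertebrae first, then discs adaptively against the smoothed vertebrae) ->
tetrahedral filling -> quadratic conversion -> interface node sets -> FE
model -> static solve.  A body that fails at any stage is recorded with a
failure category and the run continues; body-level failures are data, not
process errors.

Cohort statistics mirror the label-wise evaluation of the mesh quality:
per-label mean poor-element percentage over successful models (failed
models excluded), failure tallies by category, and the share of models
under the 5 % and 10 % quality marks.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import phantom as ph
from .fem_build import (
    DEFAULT_IVD_MATERIAL,
    DEFAULT_VERTEBRA_MATERIAL,
    FEModel,
    MappingError,
    Material,
    ModelError,
    build_model,
    write_inp,
)
from .fem_solve import FEResult, solve_static, write_vtu
from .smoothing import InterfaceMap, SmoothingParams, smooth_ivd_adaptive, smooth_vertebra
from .surface import (
    DiagnosticsReport,
    RepairFailureError,
    TriSurfaceMesh,
    diagnose,
    enclosed_volume,
    extract_surface,
)
from .tetmesh import MeshingFailureError, TetMesh, fill_volume, poor_quality_fraction, to_quadratic
from .volume_io import LabelVolume, count_components, remove_small_components

FAILURE_CATEGORIES = (
    "none",
    "small_segmentation_volume",
    "disconnected_volumes",
    "hole",
    "non_manifold_edges",
    "self_intersecting_faces",
    "mapping_error",
    "non_convergence",
)

STAGES = ("cleanup", "surface", "smoothing", "fill", "fem_build", "solve")


class SubjectError(RuntimeError):
    """Raised when a whole subject cannot be processed (e.g. empty volume)."""


def default_interface_threshold(label: int) -> float:
    """Per-level contact threshold (mm): tighter for the smaller cervical
    anatomy (low labels), wider for thoracic/lumbar levels."""
    level = label - ph.IVD_LABEL_OFFSET if ph.is_ivd_label(label) else label
    return 0.6 if level <= 10 else 0.8


@dataclass
class PipelineConfig:
    """All tunables of a subject run (documented defaults, fully overridable)."""

    min_component_voxels: int = 4
    connectivity: int = 26
    small_volume_min_voxels: int = 200
    vertebra_smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    ivd_smoothing: SmoothingParams = field(
        default_factory=lambda: SmoothingParams(laplace_iters=3))
    interface_threshold_mm: dict[int, float] | None = None
    target_edge_mm: float = 1.0
    min_size_mm: float = 0.1
    quadratic: bool = True
    solve: bool = True
    moment_nm: float = 7.5
    flexion_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    vertebra_material: Material = field(default_factory=lambda: DEFAULT_VERTEBRA_MATERIAL)
    ivd_material: Material = field(default_factory=lambda: DEFAULT_IVD_MATERIAL)
    decimals: int = 3
    check_self_intersection: bool = True
    outdir: str | None = None
    #: testing hook: body label -> "self_intersection"; applied to the
    #: smoothed surface so the meshing stage sees a corrupt mesh
    mesh_defects: dict[int, str] = field(default_factory=dict)

    def threshold_for(self, label: int) -> float:
        if self.interface_threshold_mm and label in self.interface_threshold_mm:
            return self.interface_threshold_mm[label]
        return default_interface_threshold(label)

    def smoothing_for(self, label: int) -> SmoothingParams:
        base = self.ivd_smoothing if ph.is_ivd_label(label) else self.vertebra_smoothing
        params = SmoothingParams(**{**base.__dict__})
        params.interface_threshold_mm = self.threshold_for(label)
        return params


@dataclass
class BodyReport:
    """Outcome of one body's run through the pipeline."""

    body_id: int
    body_name: str = ""
    status: str = "ok"
    failure_category: str = "none"
    n_nodes: int = 0
    n_elements: int = 0
    poor_fraction_pct: float = float("nan")
    volume_drift_pct: float = float("nan")
    max_von_mises_mpa: float = float("nan")
    stage_durations: dict[str, float] = field(default_factory=dict)
    message: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortSummary:
    """Label-wise aggregation over a cohort of body reports."""

    per_label_mean_poor_pct: dict[int, float]
    per_label_model_count: dict[int, int]
    failure_tally: dict[str, int]
    n_attempted: int
    n_ok: int
    n_failed: int
    share_below_5pct: float
    share_below_10pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def classify_failure(
    report: DiagnosticsReport | None,
    stage: str,
    component_count: int = 1,
    voxel_count: int | None = None,
    small_volume_min: int = 200,
) -> str:
    """Deterministic failure attribution with fixed priority:
    disconnected > small volume > hole > non-manifold > self-intersection >
    mapping > non-convergence."""
    if component_count > 1:
        return "disconnected_volumes"
    if voxel_count is not None and voxel_count < small_volume_min:
        return "small_segmentation_volume"
    if report is not None:
        if report.n_boundary_edges > 0 or report.n_components > 1:
            return "hole"
        if report.n_nonmanifold_edges > 0:
            return "non_manifold_edges"
        if report.self_intersecting:
            return "self_intersecting_faces"
    if stage == "fem_build":
        return "mapping_error"
    return "non_convergence"


def _inject_mesh_self_intersection(mesh: TriSurfaceMesh) -> TriSurfaceMesh:
    """Corrupt a surface so faces cross (testing hook for the failure path)."""
    out = mesh.copy()
    top = int(np.argmax(out.vertices[:, 2]))
    target = out.vertices[:, 2].min() - 1.0
    out.vertices[top, 2] = target
    return out


def _adjacent_ivd_labels(vert_label: int, present: set[int]) -> list[int]:
    cand = [ph.ivd_label(vert_label), ph.ivd_label(vert_label - 1)]
    return [c for c in cand if c in present]


class _BodyFailure(Exception):
    def __init__(self, category: str, message: str):
        super().__init__(message)
        self.category = category


def _timed(durations: dict, stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()

        def __exit__(self, *exc):
            durations[stage] = durations.get(stage, 0.0) + time.perf_counter() - self.t0
            return False
    return _Ctx()


def run_subject(volume: LabelVolume, config: PipelineConfig | None = None) -> list[BodyReport]:
    """Process every labeled body of one subject; never aborts on body failures."""
    config = config or PipelineConfig()
    labels = volume.labels()
    if labels.size == 0:
        raise SubjectError("volume contains no labeled body")

    cleaned = remove_small_components(volume, config.min_component_voxels,
                                      config.connectivity)
    vert_labels = sorted(int(l) for l in labels if not ph.is_ivd_label(int(l)))
    ivd_labels = sorted(int(l) for l in labels if ph.is_ivd_label(int(l)))

    reports: dict[int, BodyReport] = {}
    raw_surfaces: dict[int, TriSurfaceMesh] = {}
    smoothed: dict[int, TriSurfaceMesh] = {}
    interfaces: dict[int, InterfaceMap] = {}

    def precheck(label: int, rep: BodyReport) -> None:
        with _timed(rep.stage_durations, "cleanup"):
            n_comp = count_components(cleaned, label, config.connectivity)
            n_vox = cleaned.voxel_count(label)
        if n_comp > 1 or n_vox < config.small_volume_min_voxels:
            raise _BodyFailure(
                classify_failure(None, "cleanup", n_comp, n_vox,
                                 config.small_volume_min_voxels),
                f"segmentation mask unusable ({n_comp} components, {n_vox} voxels)")

    def extract(label: int, rep: BodyReport) -> TriSurfaceMesh:
        with _timed(rep.stage_durations, "surface"):
            mesh = extract_surface(cleaned, label)
            diag = diagnose(mesh, check_self_intersection=False)
        if diag.n_boundary_edges > 0 or diag.n_components > 1:
            raise _BodyFailure(classify_failure(diag, "surface"),
                               "raw surface contains holes or nested components")
        return mesh

    # ---- stage 1: prechecks and raw surfaces for every body
    for label in vert_labels + ivd_labels:
        rep = BodyReport(body_id=label, body_name=volume.names.get(label, str(label)))
        reports[label] = rep
        try:
            precheck(label, rep)
            raw_surfaces[label] = extract(label, rep)
        except _BodyFailure as exc:
            rep.status, rep.failure_category, rep.message = "failed", exc.category, str(exc)

    def fail(rep: BodyReport, exc: _BodyFailure) -> None:
        rep.status, rep.failure_category, rep.message = "failed", exc.category, str(exc)

    # ---- stage 2: vertebra smoothing (against raw adjacent disc surfaces)
    for label in vert_labels:
        rep = reports[label]
        if rep.status == "failed":
            continue
        adj = [raw_surfaces[l] for l in _adjacent_ivd_labels(label, set(raw_surfaces))
               if reports[l].status != "failed"]
        try:
            with _timed(rep.stage_durations, "smoothing"):
                try:
                    mesh, iface = smooth_vertebra(raw_surfaces[label], adj,
                                                  config.smoothing_for(label))
                except RepairFailureError as err:
                    raise _BodyFailure(classify_failure(err.report, "smoothing"), str(err))
            smoothed[label], interfaces[label] = mesh, iface
        except _BodyFailure as exc:
            fail(rep, exc)

    # ---- stage 3: adaptive disc smoothing against smoothed vertebrae
    for label in ivd_labels:
        rep = reports[label]
        if rep.status == "failed":
            continue
        lower = label - ph.IVD_LABEL_OFFSET
        below = smoothed.get(lower)
        above = smoothed.get(lower + 1)
        try:
            with _timed(rep.stage_durations, "smoothing"):
                try:
                    mesh, iface = smooth_ivd_adaptive(raw_surfaces[label], above, below,
                                                      config.smoothing_for(label))
                except RepairFailureError as err:
                    raise _BodyFailure(classify_failure(err.report, "smoothing"), str(err))
            smoothed[label], interfaces[label] = mesh, iface
        except _BodyFailure as exc:
            fail(rep, exc)

    # ---- stage 4: meshing, model building, solving per body
    for label in vert_labels + ivd_labels:
        rep = reports[label]
        if rep.status == "failed":
            continue
        mesh = smoothed[label]
        if config.mesh_defects.get(label) == "self_intersection":
            mesh = _inject_mesh_self_intersection(mesh)
        raw_vol = abs(enclosed_volume(raw_surfaces[label]))
        smooth_vol = abs(enclosed_volume(mesh))
        rep.volume_drift_pct = 100.0 * (smooth_vol - raw_vol) / raw_vol
        try:
            with _timed(rep.stage_durations, "fill"):
                try:
                    tm = fill_volume(mesh, config.target_edge_mm, config.min_size_mm,
                                     check_self_intersection=config.check_self_intersection)
                except MeshingFailureError as err:
                    raise _BodyFailure(
                        classify_failure(err.report, "fill"), str(err))
                if config.quadratic:
                    tm = to_quadratic(tm)
            rep.n_nodes, rep.n_elements = tm.n_nodes, tm.n_elements
            rep.poor_fraction_pct = poor_quality_fraction(tm)

            iface = interfaces[label]
            model = None
            result = None
            if iface.superior_vertex_ids.size and iface.inferior_vertex_ids.size:
                with _timed(rep.stage_durations, "fem_build"):
                    material = (config.ivd_material if ph.is_ivd_label(label)
                                else config.vertebra_material)
                    try:
                        model = build_model(
                            tm, iface, mesh.vertices, material,
                            moment_nm=config.moment_nm,
                            flexion_axis=config.flexion_axis,
                            body_name=rep.body_name or f"body_{label}",
                            decimals=config.decimals)
                    except MappingError as err:
                        raise _BodyFailure("mapping_error", str(err))
                    except ModelError as err:
                        raise _BodyFailure("mapping_error", str(err))
                if config.solve:
                    with _timed(rep.stage_durations, "solve"):
                        result = solve_static(model)
                    if not result.converged:
                        raise _BodyFailure("non_convergence", result.diagnostics)
                    rep.max_von_mises_mpa = result.max_von_mises
            _export_body(config, rep, mesh, tm, model, result)
        except _BodyFailure as exc:
            fail(rep, exc)
    return [reports[l] for l in vert_labels + ivd_labels]


def _export_body(config: PipelineConfig, rep: BodyReport, mesh: TriSurfaceMesh,
                 tm: TetMesh, model: FEModel | None, result: FEResult | None) -> None:
    if config.outdir is None:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = rep.body_name or f"body_{rep.body_id}"
    mesh.export(outdir / f"{stem}_smoothed.stl")
    if model is not None:
        write_inp(model, outdir / f"{stem}.inp")
    if result is not None:
        write_vtu(outdir / f"{stem}_result.vtu", tm,
                  point_data={"displacement": result.displacements},
                  cell_data={"von_mises": result.element_von_mises})
    (outdir / f"{stem}_report.json").write_text(json.dumps(rep.to_dict(), indent=1))


def run_phantom_cohort(specs, config: PipelineConfig | None = None) -> list[BodyReport]:
    """Generate and process a cohort of phantom subjects; concatenated reports."""
    reports: list[BodyReport] = []
    for spec in specs:
        volume = ph.generate_phantom(spec)
        reports.extend(run_subject(volume, config))
    return reports


def summarize_cohort(reports: list[BodyReport]) -> CohortSummary:
    """Label-wise means over successful models; category tallies over failures."""
    if not reports:
        raise ValueError("no reports to summarize")
    ok = [r for r in reports if r.status == "ok"]
    failed = [r for r in reports if r.status != "ok"]
    per_label: dict[int, list[float]] = {}
    for r in ok:
        per_label.setdefault(r.body_id, []).append(r.poor_fraction_pct)
    tally = {cat: 0 for cat in FAILURE_CATEGORIES if cat != "none"}
    for r in failed:
        tally[r.failure_category] = tally.get(r.failure_category, 0) + 1
    n_ok = len(ok)
    return CohortSummary(
        per_label_mean_poor_pct={k: float(np.mean(v)) for k, v in sorted(per_label.items())},
        per_label_model_count={k: len(v) for k, v in sorted(per_label.items())},
        failure_tally=tally,
        n_attempted=len(reports),
        n_ok=n_ok,
        n_failed=len(failed),
        share_below_5pct=100.0 * sum(r.poor_fraction_pct < 5.0 for r in ok) / n_ok if n_ok else 0.0,
        share_below_10pct=100.0 * sum(r.poor_fraction_pct < 10.0 for r in ok) / n_ok if n_ok else 0.0,
    )
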