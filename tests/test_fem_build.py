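"""Node-set mapping, reference nodes, model assembly and .inp round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seg2fem.fem_build import (
    FEModel,
    InpParseError,
    MappingError,
    Material,
    ModelError,
    build_model,
    map_surface_to_volume_nodes,
    read_inp,
    reference_node,
    write_inp,
)
from seg2fem.smoothing import InterfaceMap
from seg2fem.tetmesh import fill_volume, structured_box_mesh, to_quadratic


class TestMaterial:
    @pytest.mark.parametrize("e,nu", [(-1.0, 0.3), (1000.0, 0.0), (1000.0, 0.5)])
    def test_invalid_parameters_rejected(self, e, nu):
        with pytest.raises(ModelError):
            Material(youngs_modulus=e, poisson_ratio=nu)


class TestCoordinateMapping:
    def test_identity_mesh_maps_to_itself(self):
        tm = structured_box_mesh((2, 2, 2), (2, 2, 2))
        ids = map_surface_to_volume_nodes(tm.nodes[:5], tm, decimals=3)
        assert np.array_equal(ids, np.arange(5))

    def test_micrometre_perturbation_does_not_change_mapping(self):
        tm = structured_box_mesh((2, 2, 2), (2, 2, 2))
        coords = tm.nodes[:8] + 1e-6  # below the rounding precision
        ids = map_surface_to_volume_nodes(coords, tm, decimals=3)
        assert np.array_equal(ids, np.arange(8))

    def test_mapping_is_total_on_meshed_phantom_body(self, processed_fsu):
        mesh = processed_fsu["smoothed"][11]
        iface = processed_fsu["interfaces"][11]
        tm = fill_volume(mesh, check_self_intersection=False)
        for side in ("superior", "inferior"):
            ids = iface.side_ids(side)
            mapped = map_surface_to_volume_nodes(mesh.vertices[ids], tm)
            assert len(mapped) == len(ids)
            assert np.array_equal(tm.nodes[mapped], mesh.vertices[ids])

    def test_unmatched_vertex_raises_named_error(self):
        tm = structured_box_mesh((2, 2, 2), (2, 2, 2))
        with pytest.raises(MappingError):
            map_surface_to_volume_nodes(np.array([[10.0, 10.0, 10.0]]), tm)


class TestReferenceNode:
    def test_planar_grid_centre_selected(self):
        tm = structured_box_mesh((2, 2, 1), (2, 2, 1))
        plane = np.flatnonzero(np.abs(tm.nodes[:, 2]) < 1e-12)
        ref = reference_node(tm, plane)
        assert np.allclose(tm.nodes[ref], [1.0, 1.0, 0.0])

    def test_two_node_tie_breaks_to_lower_id(self):
        tm = structured_box_mesh((1, 1, 1), (1, 1, 1))
        pair = np.array([0, 7])
        assert reference_node(tm, pair) == 0

    @given(st.integers(min_value=1, max_value=2 ** 31 - 1))
    def test_matches_exhaustive_argmin_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(50, 3))
        from seg2fem.tetmesh import TetMesh
        tm = TetMesh(nodes=pts, elements=np.zeros((0, 4), dtype=int))
        nset = rng.choice(50, size=20, replace=False)
        ref = reference_node(tm, nset)
        centroid = pts[np.unique(nset)].mean(axis=0)
        dists = {int(n): np.linalg.norm(pts[n] - centroid) for n in np.unique(nset)}
        best = min(dists.values())
        assert dists[ref] == pytest.approx(best)

    def test_empty_set_rejected(self):
        tm = structured_box_mesh((1, 1, 1), (1, 1, 1))
        with pytest.raises(ModelError):
            reference_node(tm, np.array([], dtype=int))


@pytest.fixture(scope="module")
def box_model():
    tm = to_quadratic(structured_box_mesh((2, 2, 4), (2, 2, 4)))
    top = np.flatnonzero(np.abs(tm.nodes[:, 2] - 4.0) < 1e-12)
    bottom = np.flatnonzero(np.abs(tm.nodes[:, 2]) < 1e-12)
    iface = InterfaceMap(body_id=10, superior_vertex_ids=top,
                         inferior_vertex_ids=bottom)
    surface_vertices = tm.nodes  # identity: box nodes play the surface role
    return build_model(tm, iface, surface_vertices,
                       Material(10_000.0, 0.3, name="BONE"),
                       body_name="vert_10")


class TestBuildModel:
    def test_default_moment_is_7500_nmm_about_flexion_axis(self, box_model):
        assert np.allclose(box_model.load_moment_nmm, [7500.0, 0.0, 0.0])

    def test_inferior_set_fully_restrained_and_disjoint(self, box_model):
        assert np.intersect1d(box_model.nset_superior, box_model.nset_inferior).size == 0
        assert box_model.ref_superior in box_model.nset_superior

    def test_identical_sets_rejected(self):
        tm = to_quadratic(structured_box_mesh((1, 1, 1), (1, 1, 1)))
        ids = np.arange(4)
        with pytest.raises(ValueError):
            FEModel(mesh=tm, nset_superior=ids, nset_inferior=ids,
                    ref_superior=0, ref_inferior=0,
                    load_moment_nmm=np.zeros(3),
                    material=Material(1.0, 0.3))

    def test_zero_measure_interface_rejected(self, processed_fsu):
        mesh = processed_fsu["smoothed"][10]
        tm = fill_volume(mesh, check_self_intersection=False)
        empty = InterfaceMap(body_id=10)
        with pytest.raises(ModelError):
            build_model(tm, empty, mesh.vertices, Material(1.0, 0.3))


class TestInpRoundTrip:
    def test_write_read_structural_equality(self, box_model, tmp_path):
        path = tmp_path / "model.inp"
        write_inp(box_model, path)
        back = read_inp(path)
        assert np.array_equal(back.mesh.nodes, box_model.mesh.nodes)
        assert np.array_equal(back.mesh.elements, box_model.mesh.elements)
        assert back.mesh.order == "quadratic"
        assert np.array_equal(back.nset_superior, box_model.nset_superior)
        assert np.array_equal(back.nset_inferior, box_model.nset_inferior)
        assert back.ref_superior == box_model.ref_superior
        assert np.array_equal(back.load_moment_nmm, box_model.load_moment_nmm)
        assert back.material.youngs_modulus == box_model.material.youngs_modulus
        assert back.material.poisson_ratio == box_model.material.poisson_ratio

    def test_set_names_encode_body_name(self, box_model, tmp_path):
        path = tmp_path / "model.inp"
        write_inp(box_model, path)
        text = path.read_text()
        assert "NSET=VERT_10_SUP" in text
        assert "NSET=VERT_10_INF" in text
        assert "TYPE=C3D10" in text

    def test_single_tet_dialect_conformance(self, tmp_path):
        # quadratic single-tet: 11 entries fit one data line; all data lines
        # obey the 16-entries-per-line continuation rule
        tm = to_quadratic(structured_box_mesh((1, 1, 1), (1, 1, 1)))
        top = np.flatnonzero(np.abs(tm.nodes[:, 2] - 1.0) < 1e-12)
        bottom = np.flatnonzero(np.abs(tm.nodes[:, 2]) < 1e-12)
        iface = InterfaceMap(body_id=4, superior_vertex_ids=top,
                             inferior_vertex_ids=bottom)
        model = build_model(tm, iface, tm.nodes, Material(1.0, 0.3),
                            body_name="vert_4")
        path = tmp_path / "single.inp"
        write_inp(model, path)
        in_elements = False
        for line in path.read_text().splitlines():
            if line.startswith("*"):
                in_elements = line.upper().startswith("*ELEMENT")
                continue
            entries = [e for e in line.split(",") if e.strip()]
            assert len(entries) <= 16
            if in_elements and not line.rstrip().endswith(","):
                pass  # complete element record
        back = read_inp(path)
        assert back.mesh.elements.shape[1] == 10

    def test_unknown_keyword_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.inp"
        path.write_text("*HEADING\nx\n*WOBBLE\n1, 2\n")
        with pytest.raises(InpParseError) as err:
            read_inp(path)
        assert err.value.line == 3
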