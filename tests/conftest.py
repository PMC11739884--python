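"""Shared fixtures: small phantoms and processed spinal-unit meshes.

Unit tests run on deliberately small phantom stacks (7 mm body radius,
2 mm slices) so every stage stays fast; the acceptance suite uses the
full study-scale cohorts.
"""

import numpy as np
import pytest
import trimesh
from hypothesis import settings

from seg2fem.phantom import PhantomSpec, generate_phantom, ivd_label
from seg2fem.pipeline import PipelineConfig
from seg2fem.smoothing import smooth_ivd_adaptive, smooth_vertebra
from seg2fem.surface import TriSurfaceMesh, extract_surface

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")

SMALL_BODY = dict(
    body_radius_mm=8.0,
    body_height_mm=10.0,
    disc_height_mm=4.0,
    spacing_mm=(1.0, 1.0, 2.0),
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(n_levels=3, jitter=0.1, seed=7, **SMALL_BODY)


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def raw_surfaces(small_spec, small_volume):
    """Raw marching-cubes surfaces of every body of the small stack."""
    labels = small_spec.vertebra_labels + small_spec.ivd_labels
    return {label: extract_surface(small_volume, label) for label in labels}


@pytest.fixture(scope="session")
def processed_fsu(small_spec, raw_surfaces):
    """Smoothed vertebrae and adaptively smoothed discs with interface maps."""
    config = PipelineConfig()
    smoothed, interfaces = {}, {}
    for v in small_spec.vertebra_labels:
        adj = [raw_surfaces[l] for l in (ivd_label(v), ivd_label(v - 1))
               if l in raw_surfaces]
        smoothed[v], interfaces[v] = smooth_vertebra(
            raw_surfaces[v], adj, config.smoothing_for(v))
    for l in small_spec.ivd_labels:
        v = l - 100
        smoothed[l], interfaces[l] = smooth_ivd_adaptive(
            raw_surfaces[l], smoothed.get(v + 1), smoothed.get(v),
            config.smoothing_for(l))
    return {"smoothed": smoothed, "interfaces": interfaces}


@pytest.fixture(scope="session")
def icosphere():
    """Watertight unit icosphere as a TriSurfaceMesh."""
    ico = trimesh.creation.icosphere(subdivisions=3)
    return TriSurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces), body_id=1)


def signed_volume_oracle(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Independent divergence-theorem volume (scalar loop formulation)."""
    total = 0.0
    for f in faces:
        a, b, c = vertices[f]
        total += np.dot(a, np.cross(b, c)) / 6.0
    return total
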