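"""Shared fixtures: small deterministic geometries and sphere conductors.

Heavy objects are session-scoped; sizes are reduced (density factors well
below 1) so the whole suite exercises the full pipeline quickly.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from spinefield.geometry import GeometryConfig, build_geometry
from spinefield.mesh import TriMesh
from spinefield.bem import Compartment, ConductorModel, build_bem_system


SPHERE_RADIUS = 100.0
SPHERE_SIGMA = 0.33


def make_sphere_mesh(subdivisions: int = 3, radius: float = SPHERE_RADIUS) -> TriMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces),
                   name="sphere")


@pytest.fixture(scope="session")
def sphere_mesh() -> TriMesh:
    return make_sphere_mesh(3)


@pytest.fixture(scope="session")
def sphere_system(sphere_mesh):
    model = ConductorModel(
        [Compartment(sphere_mesh, SPHERE_SIGMA, 0.0, "sphere")], tag="1c")
    return build_bem_system(model)


@pytest.fixture(scope="session")
def small_config() -> GeometryConfig:
    return GeometryConfig(density=0.3)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_geometry(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-resolution geometry (used only for count/containment checks)."""
    return build_geometry(GeometryConfig())


@pytest.fixture(scope="session")
def study_half():
    """Half-density study over the five BEM variants (the scaled-down
    reproduction conditions); lead fields are computed lazily and shared
    across the whole session."""
    from spinefield.study import Study, StudyConfig
    cfg = StudyConfig(geometry=GeometryConfig(density=0.5),
                      models=("1c-lc", "3c-lc", "4c-lc", "5c-lc", "5c-lci"))
    return Study(cfg)


@pytest.fixture
def external_sensors():
    """40 pseudo-random triaxial sites on a 130 mm sphere."""
    from spinefield.geometry import SensorArray
    rng = np.random.default_rng(7)
    p = rng.normal(size=(40, 3))
    p = 130.0 * p / np.linalg.norm(p, axis=1, keepdims=True)
    return SensorArray(p, np.tile(np.eye(3), (40, 1, 1)))
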