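"""Shared fixtures: small analytic meshes and one default synthetic femur.

All fixtures are generated programmatically; session scope keeps the
marching-cubes generation cost to one femur per run where possible.
"""

import numpy as np
import pytest
import trimesh

from femur3d.mesh_io import TriangleMesh
from femur3d.synthetic_femur import SyntheticFemurSpec, build_femur

TETRA_VERTS = np.array([
    [0.0, 0.0, 0.0],
    [1.0, 0.0, 0.0],
    [0.0, 1.0, 0.0],
    [0.0, 0.0, 1.0],
])
TETRA_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


@pytest.fixture
def tetrahedron():
    return TriangleMesh(vertices=TETRA_VERTS.copy(),
                        faces=TETRA_FACES.copy(), provenance="synthetic")


def icosphere(radius=1.0, center=(0.0, 0.0, 0.0), subdivisions=3):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(vertices=np.asarray(tm.vertices) + np.asarray(center),
                        faces=np.asarray(tm.faces), provenance="synthetic")


def tube(radius=3.0, length=60.0, sections=64, rings=120, axis_origin=(0, 0, 0)):
    """Open-ended cylinder along +z starting at axis_origin."""
    zs = np.linspace(0.0, length, rings)
    angs = np.linspace(0.0, 2 * np.pi, sections, endpoint=False)
    verts = []
    for z in zs:
        for a in angs:
            verts.append([radius * np.cos(a), radius * np.sin(a), z])
    verts = np.asarray(verts) + np.asarray(axis_origin, dtype=float)
    faces = []
    for i in range(rings - 1):
        for j in range(sections):
            a = i * sections + j
            b = i * sections + (j + 1) % sections
            c = (i + 1) * sections + j
            d = (i + 1) * sections + (j + 1) % sections
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriangleMesh(vertices=verts, faces=np.asarray(faces),
                        provenance="synthetic")


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticFemurSpec()


@pytest.fixture(scope="session")
def default_femur(default_spec):
    """Default synthetic femur (mesh, ground truth); built once per session."""
    return build_femur(default_spec)
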