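"""Shared fixtures: the default synthetic subject, its geometry and
meshes, and one solved velocity field reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest

from aqflow.cohort import SubjectRecord, generate_waveform
from aqflow.flow import FluidProps
from aqflow.geometry import build_geometry, mesh_geometry
from aqflow.solver import SolverConfig, build_wall_program, solve_cycle


def make_default_subject(stroke_volume: float = 15.3) -> SubjectRecord:
    """One subject at the healthy-cohort means with a sinusoidal cycle."""
    return SubjectRecord(
        id="S0",
        group="healthy",
        sex="M",
        age=52.0,
        weight=60.0,
        lv_volume=23.3,
        v3_volume=1.1,
        v4_volume=1.6,
        aqueduct_diameter=2.82,
        aqueduct_length=12.0,
        cardiac_period=1.0,
        velocity=stroke_volume * np.pi / 6.246,
        stroke_volume=stroke_volume,
        waveform=generate_waveform(stroke_volume, 1.0, 8),
    )


@pytest.fixture(scope="session")
def default_subject():
    return make_default_subject()


@pytest.fixture(scope="session")
def subject_factory():
    """The default-subject constructor, injectable without imports."""
    return make_default_subject


@pytest.fixture(scope="session")
def default_geometry(default_subject):
    return build_geometry(default_subject)


@pytest.fixture(scope="session")
def coarse_mesh(default_geometry):
    return mesh_geometry(default_geometry, 1.4)


@pytest.fixture(scope="session")
def medium_mesh(default_geometry):
    return mesh_geometry(default_geometry, 0.7)


@pytest.fixture(scope="session")
def solved_field(default_subject, medium_mesh):
    """Cohort-default cycle: default subject, 0.7 mm mesh, default solver."""
    bc = build_wall_program(medium_mesh, default_subject.waveform)
    return solve_cycle(medium_mesh, bc, FluidProps(), SolverConfig())


@pytest.fixture(scope="session")
def cube_mesh():
    """Unit cube [0,1]^3 split into six tets (tracking/mixing oracle mesh)."""
    from aqflow.mesh import TetMesh, boundary_faces, orient_tets

    pts = np.array(
        [[x, y, z] for z in (0.0, 1.0) for y in (0.0, 1.0) for x in (0.0, 1.0)]
    )
    # Kuhn triangulation of the cube
    tets = np.array(
        [
            [0, 1, 3, 7],
            [0, 1, 5, 7],
            [0, 4, 5, 7],
            [0, 2, 3, 7],
            [0, 2, 6, 7],
            [0, 4, 6, 7],
        ]
    )
    tets = orient_tets(pts, tets)
    btris, _ = boundary_faces(tets)
    labels = np.full(btris.shape[0], 2, dtype=np.int64)
    return TetMesh(points=pts, tets=tets, boundary_tris=btris,
                   boundary_labels=labels)
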