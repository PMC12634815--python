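"""Idealized geometry and structured meshing: volume matching,
label partitioning, refinement behavior and mesh quality."""

import numpy as np
import pytest

from aqflow.geometry import (
    GeometryError,
    GeometryTemplate,
    build_geometry,
    mesh_geometry,
    section_flux_triangles,
    tube_mesh,
)
from aqflow.mesh import (
    MOVING_WALL,
    OUTLET,
    RIGID_WALL,
    mesh_quality,
    outlet_components,
    tet_aspect_ratios,
    tet_volumes,
)


def test_chamber_volumes_match_targets(default_geometry):
    for seg, name in zip(
        (default_geometry.segments[0], default_geometry.segments[1],
         default_geometry.segments[3]),
        ("lv", "v3", "v4"),
    ):
        from aqflow.geometry import _segment_volume

        target = default_geometry.chamber_volumes[name]
        assert _segment_volume(seg) == pytest.approx(target, rel=0.02)


def test_aqueduct_cross_section_area(default_geometry):
    assert default_geometry.aqueduct_area() == pytest.approx(
        np.pi * (2.82 / 2) ** 2, rel=1e-12
    )
    assert default_geometry.aqueduct_area() == pytest.approx(6.246, abs=5e-4)


def test_degenerate_diameter_raises(subject_factory):
    s = subject_factory()
    s.aqueduct_diameter = 0.0
    with pytest.raises(GeometryError):
        build_geometry(s)


def test_build_is_deterministic(default_subject):
    g1 = build_geometry(default_subject)
    g2 = build_geometry(default_subject)
    m1 = mesh_geometry(g1, 1.4)
    m2 = mesh_geometry(g2, 1.4)
    np.testing.assert_array_equal(m1.points, m2.points)
    np.testing.assert_array_equal(m1.tets, m2.tets)


def test_refinement_increases_element_count(default_geometry):
    coarse = mesh_geometry(default_geometry, 1.4)
    fine = mesh_geometry(default_geometry, 0.9)
    assert fine.n_tets > coarse.n_tets


def test_mesh_validity_and_label_partition(coarse_mesh):
    assert coarse_mesh.tet_volumes().min() > 0
    labels = coarse_mesh.boundary_labels
    assert set(np.unique(labels)) <= {MOVING_WALL, RIGID_WALL, OUTLET}
    assert coarse_mesh.label_area(MOVING_WALL) > 0
    assert coarse_mesh.label_area(OUTLET) > 0
    # labels partition the boundary: every boundary face has one label
    assert labels.shape[0] == coarse_mesh.boundary_tris.shape[0]


def test_outlet_triangles_lie_on_outlet_disks(default_geometry, coarse_mesh):
    tris = coarse_mesh.label_tris(OUTLET)
    cent = coarse_mesh.points[tris].mean(axis=1)
    ztop = coarse_mesh.meta["layer_z"][-1]
    assert np.allclose(cent[:, 2], ztop)
    ok = np.zeros(len(cent), dtype=bool)
    for cx, cy, rd in default_geometry.outlet_disks:
        ok |= np.hypot(cent[:, 0] - cx, cent[:, 1] - cy) <= rd * 1.25
    assert ok.all()


def test_two_disk_variant_has_two_outlet_components(default_subject):
    g = build_geometry(default_subject, GeometryTemplate(outlet_mode="two-disks"))
    assert len(g.outlet_disks) == 2
    for bs in (1.4, 0.7):
        m = mesh_geometry(g, bs)
        assert outlet_components(m) == 2


def test_volume_convergence_monotone(default_geometry):
    exact = default_geometry.volume()
    errors = []
    for bs in (2.0, 1.4, 1.0):
        m = mesh_geometry(default_geometry, bs)
        errors.append(abs(np.abs(tet_volumes(m.points, m.tets)).sum() - exact))
    assert errors[0] > errors[1] > errors[2]


def test_min_four_elements_across_aqueduct(default_geometry):
    m = mesh_geometry(default_geometry, 2.82 / 4)
    assert m.meta["rings_m"] >= 2  # 2 rings = 4 elements across a diameter


def test_unit_cylinder_outlet_area():
    m = tube_mesh(0.5, 1.0, 0.25)
    area = m.label_area(OUTLET)
    assert area == pytest.approx(np.pi / 4, rel=0.05)


def test_mesh_quality_regular_tet():
    from aqflow.mesh import TetMesh, boundary_faces

    a = 1.0
    pts = np.array(
        [[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0],
         [a / 2, a * np.sqrt(3) / 6, a * np.sqrt(2.0 / 3.0)]]
    )
    tets = np.array([[0, 1, 2, 3]])
    ar = tet_aspect_ratios(pts, tets)
    assert ar[0] == pytest.approx(1.0, rel=1e-9)


def test_mesh_quality_detects_inversion(coarse_mesh):
    bad = coarse_mesh.tets.copy()
    bad[0, [2, 3]] = bad[0, [3, 2]]  # invert one element
    from aqflow.mesh import TetMesh

    m = TetMesh(points=coarse_mesh.points, tets=bad,
                boundary_tris=coarse_mesh.boundary_tris,
                boundary_labels=coarse_mesh.boundary_labels)
    assert mesh_quality(m).n_inverted >= 1


def test_label_areas_sum_to_boundary_area(coarse_mesh):
    q = mesh_quality(coarse_mesh)
    total = coarse_mesh.boundary_areas().sum()
    assert sum(q.label_areas.values()) == pytest.approx(total, rel=1e-12)


def test_section_triangles_area(medium_mesh):
    z0, z1 = medium_mesh.meta["aqueduct_z"]
    _, area = section_flux_triangles(medium_mesh, 0.5 * (z0 + z1))
    # discrete polygon area slightly below pi r^2
    assert area == pytest.approx(np.pi * 1.41**2, rel=0.03)
    assert area < np.pi * 1.41**2


def test_meshing_errors(subject_factory):
    with pytest.raises(GeometryError):
        tube_mesh(1.0, 1.0, 0.0)
    s = subject_factory()
    s.v3_volume = 1e-9  # chamber volume below the neck-cylinder minimum
    with pytest.raises(GeometryError):
        build_geometry(s)
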