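"""Lagrangian tracking: lattice seeding, P1-exact interpolation,
integrator exactness and trajectory accuracy."""

import numpy as np
import pytest

from aqflow.flow import FluidProps
from aqflow.solver import VelocityField
from aqflow.tracking import (
    ACTIVE,
    EXITED,
    TrackingConfig,
    advect,
    build_locator,
    locate_and_interpolate,
    seed_particles,
)


def _field(mesh, vfunc, period=1.0, phases=8):
    t = period * np.arange(phases) / phases
    v = np.zeros((phases, mesh.n_points, 3))
    for k in range(phases):
        v[k] = vfunc(mesh.points, t[k])
    return VelocityField(mesh=mesh, phase_times=t, velocity=v,
                         pressure=np.zeros((phases, mesh.n_points)),
                         period=period, props=FluidProps())


def test_cube_lattice_seeding_strict_interior(cube_mesh):
    """Closed 5^3 lattice on the unit cube keeps the 3^3 interior points."""
    ps = seed_particles(cube_mesh, 0.25)
    assert ps.n == 27
    assert np.all(ps.positions > 0.0) and np.all(ps.positions < 1.0)
    # oracle: the strict interior of the closed lattice
    expected = {(i * 0.25, j * 0.25, k * 0.25)
                for i in range(1, 4) for j in range(1, 4) for k in range(1, 4)}
    got = {tuple(np.round(p, 9)) for p in ps.positions}
    assert got == expected


def test_huge_spacing_gives_few_particles(cube_mesh):
    with pytest.warns(UserWarning):
        ps = seed_particles(cube_mesh, 100.0)
    assert ps.n <= 1


def test_seeded_particles_locate_in_mesh(medium_mesh):
    loc = build_locator(medium_mesh)
    ps = seed_particles(medium_mesh, 0.8, loc)
    assert ps.n > 100
    assert np.all(ps.tet >= 0)
    assert np.all(ps.status == ACTIVE)


def test_interpolation_constant_and_linear_fields(cube_mesh):
    const = _field(cube_mesh, lambda x, t: np.tile([1.0, -2.0, 0.5], (len(x), 1)))
    for p in ([0.3, 0.3, 0.3], [0.71, 0.12, 0.55]):
        v = locate_and_interpolate(p, const, 0.13)
        np.testing.assert_allclose(v, [1.0, -2.0, 0.5], rtol=1e-12)
    A = np.array([[0.2, -0.1, 0.4], [1.0, 0.3, 0.0], [-0.2, 0.5, 0.9]])
    lin = _field(cube_mesh, lambda x, t: x @ A.T)
    rng = np.random.default_rng(0)
    for p in rng.uniform(0.05, 0.95, size=(5, 3)):
        v = locate_and_interpolate(p, lin, 0.0)
        np.testing.assert_allclose(v, A @ p, rtol=1e-10, atol=1e-12)


def test_interpolation_nodal_exactness(cube_mesh):
    lin = _field(cube_mesh, lambda x, t: x * 2.0)
    node = cube_mesh.points[6] * 0.999 + 0.0005  # just inside
    v = locate_and_interpolate(node, lin, 0.0)
    np.testing.assert_allclose(v, node * 2.0, rtol=1e-9)


def test_outside_point_returns_none(cube_mesh):
    f = _field(cube_mesh, lambda x, t: x)
    assert locate_and_interpolate([5.0, 5.0, 5.0], f, 0.0) is None


def test_advect_zero_field_identity(cube_mesh):
    zero = _field(cube_mesh, lambda x, t: np.zeros_like(x))
    ps = seed_particles(cube_mesh, 0.25)
    out = advect(ps, zero, TrackingConfig(n_cycles=20, substeps=2))
    np.testing.assert_array_equal(out.positions, ps.positions)
    np.testing.assert_array_equal(out.origins, ps.origins)
    assert np.all(out.status == ACTIVE)


def test_advect_uniform_field_exact_displacement(cube_mesh):
    u = np.array([0.02, 0.01, -0.015])
    f = _field(cube_mesh, lambda x, t: np.tile(u, (len(x), 1)))
    ps = seed_particles(cube_mesh, 0.25)
    dur = 2.0
    out = advect(ps, f, TrackingConfig(n_cycles=2, substeps=4), duration=dur)
    np.testing.assert_allclose(out.positions, ps.positions + u * dur, atol=1e-12)


def test_solid_body_rotation_returns_to_start(cube_mesh):
    """One revolution about the cube's central axis."""
    om = 2 * np.pi  # one revolution per unit time

    def rot(x, t):
        dx = x[:, 0] - 0.5
        dy = x[:, 1] - 0.5
        return np.column_stack([-om * dy, om * dx, np.zeros(len(x))])

    f = _field(cube_mesh, rot, period=1.0, phases=40)
    start = np.array([[0.7, 0.5, 0.5], [0.5, 0.35, 0.3]])
    from aqflow.tracking import ParticleSet

    ps = ParticleSet(positions=start.copy(), origins=start.copy(),
                     status=np.zeros(2, np.int8), tet=np.full(2, -1), spacing=0.1)
    out = advect(ps, f, TrackingConfig(n_cycles=1, substeps=8))
    radius = 0.2
    assert np.linalg.norm(out.positions - start, axis=1).max() < 1e-3 * radius


def test_forward_backward_reversibility(cube_mesh):
    def swirl(x, t):
        return np.column_stack([
            0.05 * np.sin(np.pi * x[:, 1]),
            0.05 * np.cos(np.pi * x[:, 0]),
            np.zeros(len(x)),
        ])

    fwd = _field(cube_mesh, swirl)
    bwd = _field(cube_mesh, lambda x, t: -swirl(x, t))
    ps = seed_particles(cube_mesh, 0.25)
    mid = advect(ps, fwd, TrackingConfig(n_cycles=1, substeps=8))
    back = advect(mid, bwd, TrackingConfig(n_cycles=1, substeps=8))
    np.testing.assert_allclose(back.positions, ps.positions, atol=1e-6)


def test_exit_freezes_particles(cube_mesh):
    """A uniform field pushes particles out; they freeze and stay out."""
    u = np.array([0.0, 0.0, 0.4])
    f = _field(cube_mesh, lambda x, t: np.tile(u, (len(x), 1)))
    ps = seed_particles(cube_mesh, 0.25)
    out = advect(ps, f, TrackingConfig(n_cycles=5, substeps=4))
    assert np.all(out.status == EXITED)
    assert np.all(out.positions[:, 2] <= 1.0 + 1e-9)
    # exited particles do not move further
    again = advect(out, f, TrackingConfig(n_cycles=1, substeps=4))
    np.testing.assert_array_equal(again.positions, out.positions)


def test_divergence_free_occupancy_stable(cube_mesh):
    """Solid-body rotation preserves counts in a central ball."""
    om = 2 * np.pi

    def rot(x, t):
        dx = x[:, 0] - 0.5
        dy = x[:, 1] - 0.5
        return np.column_stack([-om * dy, om * dx, np.zeros(len(x))])

    f = _field(cube_mesh, rot, phases=40)
    ps = seed_particles(cube_mesh, 0.1)
    c0 = np.linalg.norm(ps.positions - 0.5, axis=1) < 0.25
    out = advect(ps, f, TrackingConfig(n_cycles=1, substeps=8))
    c1 = np.linalg.norm(out.positions - 0.5, axis=1) < 0.25
    assert abs(c1.sum() - c0.sum()) <= 0.03 * max(c0.sum(), 1)
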