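"""MRI-style flow descriptors: stroke volume, representative velocity,
equivalent diameter, Reynolds number, cross-section flux and the
four-section consistency rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqflow.cohort import FlowWaveform, generate_waveform
from aqflow.flow import (
    FluidProps,
    FlowError,
    consistency_error,
    cross_section_flow,
    equivalent_diameter,
    representative_velocity,
    reynolds,
    stroke_volume,
)


def _sine_wf(n, q0=48.07, period=1.0):
    t = period * np.arange(n) / n
    return FlowWaveform(times=t, flow_rate=q0 * np.sin(2 * np.pi * t / period),
                        period=period)


def test_stroke_volume_sinusoid_closed_form():
    assert stroke_volume(_sine_wf(2048)) == pytest.approx(15.3, rel=1e-3)


def test_stroke_volume_zero_and_linearity():
    z = FlowWaveform(times=np.arange(8) / 8, flow_rate=np.zeros(8), period=1.0)
    assert stroke_volume(z) == 0.0
    wf = _sine_wf(64)
    doubled = FlowWaveform(times=wf.times, flow_rate=2 * wf.flow_rate, period=1.0)
    assert stroke_volume(doubled) == pytest.approx(2 * stroke_volume(wf), rel=1e-12)


def test_stroke_volume_quadrature_second_order():
    """Trapezoid error for the rectified sinusoid decreases with phases."""
    exact = 15.3
    errs = [abs(stroke_volume(_sine_wf(n)) - exact) for n in (8, 16, 32)]
    assert errs[0] > errs[1] > errs[2]
    assert errs[0] / errs[1] > 2.5  # ~4 for O(h^2)


def test_representative_velocity_example():
    wf = _sine_wf(8)
    assert representative_velocity(wf, 6.246) == pytest.approx(7.70, abs=0.01)
    assert representative_velocity(wf, 2 * 6.246) == pytest.approx(7.70 / 2, abs=0.01)
    z = FlowWaveform(times=np.arange(8) / 8, flow_rate=np.zeros(8), period=1.0)
    assert representative_velocity(z, 6.246) == 0.0
    with pytest.raises(FlowError):
        representative_velocity(wf, 0.0)


def test_equivalent_diameter():
    assert equivalent_diameter([6.246]) == pytest.approx(2.82, abs=1e-3)
    assert equivalent_diameter([np.pi, np.pi]) == pytest.approx(2.0, rel=1e-12)
    areas = [5.0, 6.0, 7.0, 8.0]
    assert equivalent_diameter(areas) == pytest.approx(
        equivalent_diameter(areas[::-1]), rel=1e-15
    )
    with pytest.raises(FlowError):
        equivalent_diameter([])


def test_reynolds_printed_values():
    assert reynolds(10.14, 2.82) == pytest.approx(28.59, abs=0.01)
    assert reynolds(20.57, 2.82) == pytest.approx(58.0, abs=0.01)
    assert reynolds(0.0, 2.82) == 0.0
    with pytest.raises(FlowError):
        reynolds(-1.0, 2.82)


def test_reynolds_unit_safety():
    """Same physical inputs expressed with rescaled properties agree."""
    re1 = reynolds(10.0, 3.0, FluidProps(density=1e3, viscosity=1e-3))
    re2 = reynolds(10.0, 3.0, FluidProps(density=2e3, viscosity=2e-3))
    assert re1 == pytest.approx(re2, rel=1e-12)


@given(u=st.floats(0.0, 100.0), d=st.floats(0.1, 10.0))
@settings(max_examples=50, deadline=None)
def test_reynolds_is_ud_in_mm_units(u, d):
    assert reynolds(u, d) == pytest.approx(u * d, rel=1e-12)


def test_consistency_identical_series():
    q = np.sin(2 * np.pi * np.arange(8) / 8)
    err, excl = consistency_error(np.array([q, q, q, q]))
    assert err == 0.0 and not excl


def test_consistency_peak_scaled_series():
    """One section scaled 1.4x at the peak: deviation 0.3 Qp against a
    mean whose peak is 1.1 Qp gives 3/11, above the 25% cut."""
    t = np.arange(8) / 8
    q = np.sin(2 * np.pi * t)
    qs = np.array([q, q, q, q.copy()])
    qs[3, np.argmax(np.abs(q))] *= 1.4
    err, excl = consistency_error(qs)
    assert err == pytest.approx(3 / 11, rel=1e-12)
    assert excl


def test_consistency_zero_series_defined():
    err, excl = consistency_error(np.zeros((4, 8)))
    assert err == 0.0 and not excl


def test_consistency_boundary_not_excluded():
    """Error of exactly 25% is kept (strict inequality)."""
    qs = np.array([[0.0, 3.0, 0.0, -3.0], [0.0, 5.0, 0.0, -5.0]])
    err, excl = consistency_error(qs)
    assert err == 0.25
    assert not excl


def test_consistency_needs_two_sections():
    with pytest.raises(FlowError):
        consistency_error(np.zeros((1, 8)))


def test_cross_section_flow_of_waveform_passthrough():
    wf = _sine_wf(8)
    t, q, _ = cross_section_flow(wf, 0.0)
    np.testing.assert_array_equal(q, wf.flow_rate)


def _make_field(mesh, vz):
    """Synthetic VelocityField with uniform axial velocity vz."""
    from aqflow.flow import FluidProps
    from aqflow.solver import VelocityField

    P = 4
    v = np.zeros((P, mesh.n_points, 3))
    v[:, :, 2] = vz
    return VelocityField(mesh=mesh, phase_times=np.arange(P) / P, velocity=v,
                         pressure=np.zeros((P, mesh.n_points)), period=1.0,
                         props=FluidProps())


def test_cross_section_flow_uniform_field(medium_mesh):
    field = _make_field(medium_mesh, 2.5)
    z0, z1 = medium_mesh.meta["aqueduct_z"]
    t, q, area = cross_section_flow(field, 0.5 * (z0 + z1))
    np.testing.assert_allclose(q, 2.5 * area, rtol=1e-12)
    zero = _make_field(medium_mesh, 0.0)
    _, q0, _ = cross_section_flow(zero, 0.5 * (z0 + z1))
    assert np.all(q0 == 0.0)


def test_cross_section_flow_poiseuille_profile():
    """Parabolic profile integrates to u_max * pi r^2 / 2."""
    from aqflow.geometry import tube_mesh
    from aqflow.solver import VelocityField

    R = 1.0
    mesh = tube_mesh(R, 4.0, 0.125)
    r2 = mesh.points[:, 0] ** 2 + mesh.points[:, 1] ** 2
    u_max = 3.0
    v = np.zeros((2, mesh.n_points, 3))
    v[:, :, 2] = u_max * (1 - r2 / R**2)
    field = VelocityField(mesh=mesh, phase_times=np.array([0.0, 0.5]),
                          velocity=v, pressure=np.zeros((2, mesh.n_points)),
                          period=1.0, props=FluidProps())
    _, q, _ = cross_section_flow(field, 2.0)
    assert q[0] == pytest.approx(u_max * np.pi * R**2 / 2, rel=0.02)
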