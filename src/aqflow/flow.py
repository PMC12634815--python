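"""MRI-style flow descriptors for the cerebral aqueduct.

Cross-sectional flow rates, the four-section consistency/exclusion
rule, stroke volume, representative (areal-averaged peak) velocity,
equivalent diameter and the Reynolds number

    Re = rho * U * D / mu

with water-like CSF properties (rho = 1e3 kg/m^3, mu = 1e-3 Pa s).
Interface units are mm / mm/s / ul / s; conversion to SI happens inside
``reynolds``.  With the default properties Re equals U*D numerically
when U is in mm/s and D in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import FlowWaveform

# fraction of aqueduct length at which the four evaluation planes sit
SECTION_FRACTIONS = (0.2, 0.4, 0.6, 0.8)
EXCLUSION_THRESHOLD = 0.25  # strict: error must exceed 25% to exclude


class FlowError(ValueError):
    pass


@dataclass(frozen=True)
class FluidProps:
    """Newtonian CSF properties (SI)."""

    density: float = 1.0e3     # kg/m^3
    viscosity: float = 1.0e-3  # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise FlowError("density and viscosity must be positive")

    @property
    def kinematic_mm2_s(self) -> float:
        """Kinematic viscosity in mm^2/s (1.0 for the defaults)."""
        return self.viscosity / self.density * 1e6


@dataclass
class FlowMetrics:
    """Per-subject flow descriptor row."""

    subject_id: str
    diameter: float          # mm (equivalent)
    area: float              # mm^2
    stroke_volume: float     # ul
    velocity: float          # mm/s
    reynolds: float
    consistency_error: float
    excluded: bool


def stroke_volume(waveform: FlowWaveform) -> float:
    """Bidirectional stroke volume, SV = 0.5 * integral |Q| dt (ul).

    Trapezoidal quadrature on the phase grid with periodic closure; the
    mean of the systolic and diastolic displaced volumes, which reduces
    to the one-directional volume for a pure sinusoid.
    """
    t, q = waveform.closed_cycle()
    return 0.5 * float(np.trapezoid(np.abs(q), t))


def representative_velocity(waveform: FlowWaveform, area: float) -> float:
    """Peak areal-averaged velocity over the cycle, U = max |Q|/A (mm/s)."""
    if area <= 0:
        raise FlowError("cross-section area must be positive")
    return float(np.abs(waveform.flow_rate).max() / area)


def equivalent_diameter(areas) -> float:
    """Mean equivalent circular diameter of the sections, 2*sqrt(A/pi)."""
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise FlowError("need at least one section area")
    if (areas <= 0).any():
        raise FlowError("section areas must be positive")
    return float(np.mean(2.0 * np.sqrt(areas / np.pi)))


def reynolds(velocity: float, diameter: float, props: FluidProps = FluidProps()) -> float:
    """Re = rho*U*D/mu with U in mm/s and D in mm (converted to SI)."""
    if velocity < 0:
        raise FlowError("velocity must be >= 0 (use |Q| upstream)")
    if diameter <= 0:
        raise FlowError("diameter must be positive")
    return props.density * (velocity * 1e-3) * (diameter * 1e-3) / props.viscosity


def cross_section_flow(field, plane_z: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Phase-resolved flow rate through one aqueduct cross-section.

    ``field`` is either a FlowWaveform (returns its own samples; the
    waveform is the section-integrated rate by definition) or a solved
    VelocityField, for which Q(t) is the surface integral of the axial
    velocity over the structured cross-section nearest plane_z.

    Returns (times, Q, area).  Sign follows the craniocaudal convention
    (positive = toward the fourth ventricle, +z).
    """
    if isinstance(field, FlowWaveform):
        area = np.nan
        return field.times.copy(), field.flow_rate.copy(), area
    from .geometry import section_flux_triangles

    mesh = field.mesh
    tris, area = section_flux_triangles(mesh, plane_z)
    q = np.empty(field.phase_times.size)
    p = mesh.points
    n = np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]]) * 0.5
    sign = np.sign(n[:, 2])
    a_z = np.abs(n[:, 2])  # triangles lie in a z-plane; |n| = n_z
    for k in range(field.phase_times.size):
        vz = field.velocity[k][:, 2]
        q[k] = float(np.sum(a_z * vz[tris].mean(axis=1)))
    return field.phase_times.copy(), q, area


def consistency_error(q_sections: np.ndarray) -> tuple[float, bool]:
    """Across-section consistency of the four aqueduct flow series.

    error = max over phases and sections of |Q_j(t) - Qbar(t)| divided
    by max_t |Qbar(t)|, with Qbar the across-section mean; normalizing
    by the peak of the mean series avoids division by near-zero flow at
    reversal phases.  Cases with error strictly greater than 25% are
    excluded.  All-zero series define error 0.
    """
    q = np.asarray(q_sections, dtype=float)
    if q.ndim != 2 or q.shape[0] < 2:
        raise FlowError("need at least two sections on a common phase grid")
    qbar = q.mean(axis=0)
    denom = np.abs(qbar).max()
    if denom == 0.0:
        return 0.0, False
    err = float(np.abs(q - qbar).max() / denom)
    return err, err > EXCLUSION_THRESHOLD


def metrics_from_waveform(subject, props: FluidProps = FluidProps()) -> FlowMetrics:
    """MRI-style metrics straight from a subject's waveform (no CFD)."""
    area = subject.area
    sv = stroke_volume(subject.waveform)
    u = representative_velocity(subject.waveform, area)
    d = equivalent_diameter([area])
    return FlowMetrics(
        subject_id=subject.id,
        diameter=d,
        area=area,
        stroke_volume=sv,
        velocity=u,
        reynolds=reynolds(u, d, props),
        consistency_error=0.0,
        excluded=False,
    )


def metrics_from_field(subject, field, props: FluidProps = FluidProps()) -> FlowMetrics:
    """Flow metrics from a solved field via the four-section protocol."""
    z0, z1 = field.mesh.meta["aqueduct_z"]
    qs, areas = [], []
    for f in SECTION_FRACTIONS:
        _, q, a = cross_section_flow(field, z0 + f * (z1 - z0))
        qs.append(q)
        areas.append(a)
    qs = np.array(qs)
    err, excl = consistency_error(qs)
    d = equivalent_diameter(areas)
    area = float(np.mean(areas))
    qbar = qs.mean(axis=0)
    u = float(np.abs(qbar).max() / area)
    sv = stroke_volume(subject.waveform)
    return FlowMetrics(
        subject_id=subject.id,
        diameter=d,
        area=area,
        stroke_volume=sv,
        velocity=u,
        reynolds=reynolds(u, d, props),
        consistency_error=err,
        excluded=excl,
    )
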