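"""Incompressible Navier-Stokes solver for moving-wall ventricular CSF flow.

Incremental pressure-correction (fractional-step) scheme on first-order
tetrahedra: explicit advection with streamline-upwind (SUPG)
stabilization, Crank-Nicolson implicit diffusion, and a pressure
Poisson projection enforcing continuity.  Equal-order P1/P1 velocity
and pressure.

The transient lateral-ventricle volume change that sources the
aqueduct flow is imposed as a wall-normal velocity program on the
moving_wall label; the measured or synthetic flow waveform Q(t)
determines the uniform normal speed so the discrete wall flux equals
-Q(t) to machine precision.  Wall displacements at physiological
stroke volumes are two orders of magnitude below the element size, so
the momentum equation is solved on the fixed reference mesh with the
wall velocity as Dirichlet data (linearized small-displacement form of
the moving-boundary problem); the mesh-motion operator used to export
deformed configurations is ``ale_mesh_motion``.

Internally the momentum equation is advanced in kinematic form
(divided by density) in mm units, so viscosity enters as nu in mm^2/s
(= 1.0 for CSF) and pressure is carried as p/rho in mm^2/s^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import fem
from .cohort import FlowWaveform
from .flow import FluidProps
from .geometry import section_flux_triangles
from .mesh import MOVING_WALL, OUTLET, TetMesh


class SolverError(RuntimeError):
    pass


@dataclass
class SolverConfig:
    """Time discretization and stabilization controls.

    steps_per_cycle sets dt = T_c / steps_per_cycle (rounded up to a
    multiple of store_phases).  The default keeps the advective CFL
    number far below one at cohort Reynolds numbers and the projection
    splitting error small; the CFL number is monitored during the run
    and the solve aborts with advice if it exceeds cfl_abort.
    """

    steps_per_cycle: int = 400
    cfl_abort: float = 1.5
    n_cycles: int = 3
    store_phases: int = 40
    waveform_interp: str = "cubic"   # periodic cubic or linear in time
    supg: bool = True

    def __post_init__(self):
        if self.store_phases < 4:
            raise SolverError("store_phases must be >= 4")
        if self.n_cycles < 1:
            raise SolverError("n_cycles must be >= 1")
        if self.steps_per_cycle < self.store_phases:
            raise SolverError("steps_per_cycle must be >= store_phases")


@dataclass
class BoundaryConditions:
    """Moving-wall program, no-slip walls, and zero-pressure outlets.

    w(x, t) = alpha(t) * n(x) on the moving wall with alpha scaled so
    that sum_i w_i . N_i = -Q(t) exactly on the discrete mesh (N_i the
    nodal outward area vector assembled from the moving facets).
    """

    mesh: TetMesh
    waveform: FlowWaveform
    moving_nodes: np.ndarray        # node ids
    moving_dirs: np.ndarray         # (n_mov, 3) unit outward normals
    nodal_area: float               # sum_i |N_i| over moving nodes
    rigid_nodes: np.ndarray
    outlet_nodes: np.ndarray
    interp: str = "cubic"

    def alpha(self, t) -> np.ndarray:
        return -np.asarray(self.waveform.sample(t, self.interp)) / self.nodal_area

    def wall_velocity(self, t: float) -> np.ndarray:
        """(n_mov, 3) wall velocity at time t, mm/s."""
        return float(self.alpha(t)) * self.moving_dirs

    def discrete_wall_flux(self, t: float) -> float:
        return float(self.alpha(t)) * self.nodal_area


def build_wall_program(
    mesh: TetMesh, waveform: FlowWaveform, interp: str = "cubic"
) -> BoundaryConditions:
    """Uniform-normal-speed wall program with exact discrete flux.

    Nodes shared between the moving and rigid labels follow the moving
    program (their area vectors are assembled from moving facets only).
    """
    tris = mesh.label_tris(MOVING_WALL)
    if tris.shape[0] == 0:
        raise SolverError("mesh has no moving_wall facets")
    p = mesh.points
    avec = 0.5 * np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])
    N = np.zeros((mesh.n_points, 3))
    for k in range(3):
        np.add.at(N, tris[:, k], avec / 3.0)
    moving = np.unique(tris)
    Nm = N[moving]
    mag = np.linalg.norm(Nm, axis=1)
    keep = mag > 1e-14
    moving, Nm, mag = moving[keep], Nm[keep], mag[keep]
    dirs = Nm / mag[:, None]
    nodal_area = float(mag.sum())
    if nodal_area <= 0:
        raise SolverError("moving wall has zero area")
    wall_nodes = set(moving.tolist())
    rigid = np.array(
        sorted(set(mesh.nodes_on_label(2).tolist()) - wall_nodes), dtype=np.int64
    )
    outlet = mesh.nodes_on_label(OUTLET)
    return BoundaryConditions(
        mesh=mesh,
        waveform=waveform,
        moving_nodes=moving,
        moving_dirs=dirs,
        nodal_area=nodal_area,
        rigid_nodes=rigid,
        outlet_nodes=outlet,
        interp=interp,
    )


def ale_mesh_motion(
    mesh: TetMesh, boundary_disp: np.ndarray, check: bool = True
) -> np.ndarray:
    """Laplacian-smoothed interior displacement for a boundary motion.

    boundary_disp is (n_points, 3); only its values on boundary nodes
    are used as Dirichlet data, the interior solves grad^2 d = 0
    componentwise.  Raises if any element inverts after the motion.
    """
    grads, vols = fem.p1_gradients(mesh)
    K = fem.stiffness(mesh, grads, vols)
    bnodes = mesh.boundary_nodes()
    free = np.setdiff1d(np.arange(mesh.n_points), bnodes)
    disp = np.array(boundary_disp, dtype=float)
    if free.size:
        Kff = K[free][:, free].tocsc()
        lu = splu(Kff)
        for d in range(3):
            rhs = -K[free][:, bnodes] @ disp[bnodes, d]
            disp[free, d] = lu.solve(rhs)
    if check:
        from .mesh import tet_volumes

        vols_new = tet_volumes(mesh.points + disp, mesh.tets)
        if vols_new.min() <= 0:
            bad = np.where(vols_new <= 0)[0]
            raise SolverError(f"mesh motion inverted elements {bad[:10].tolist()}")
    return disp


@dataclass
class VelocityField:
    """Periodic phase-resolved solution over one cardiac cycle."""

    mesh: TetMesh
    phase_times: np.ndarray          # (P,) s within [0, T_c)
    velocity: np.ndarray             # (P, n_points, 3) mm/s
    pressure: np.ndarray             # (P, n_points) Pa
    period: float                    # s
    props: FluidProps
    logs: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return self.phase_times.size

    def peak_speed(self) -> float:
        return float(np.linalg.norm(self.velocity, axis=2).max())


def _outlet_flux(mesh: TetMesh, v: np.ndarray) -> float:
    tris = mesh.label_tris(OUTLET)
    p = mesh.points
    avec = 0.5 * np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])
    vmean = v[tris].mean(axis=1)
    return float(np.einsum("fd,fd->", avec, vmean))


def _choose_dt(period: float, cfg: SolverConfig):
    """dt with an integer number of steps between stored phases."""
    spp = max(1, math.ceil(cfg.steps_per_cycle / cfg.store_phases))
    return period / (cfg.store_phases * spp), spp


def solve_cycle(
    mesh: TetMesh,
    bc: BoundaryConditions,
    props: FluidProps = FluidProps(),
    cfg: SolverConfig = None,
) -> VelocityField:
    """March the flow to a periodic state and return the last cycle.

    Per step: explicit SUPG advection, Crank-Nicolson diffusion for the
    tentative velocity, pressure-Poisson projection with p = 0 on the
    outlets, lumped-mass velocity correction.  Logs per-step divergence
    and wall/outlet flux-balance residuals and the cycle periodicity.
    """
    cfg = cfg or SolverConfig()
    nu = props.kinematic_mm2_s
    T = bc.waveform.period
    dt, spp = _choose_dt(T, cfg)
    n_steps_cycle = cfg.store_phases * spp

    grads, vols = fem.p1_gradients(mesh)
    h_e = fem.element_sizes(vols)
    h_min = float(h_e.min())
    ml = fem.lumped_mass(mesh, vols)
    K = fem.stiffness(mesh, grads, vols)

    dir_nodes = np.concatenate([bc.moving_nodes, bc.rigid_nodes])
    out_nodes = bc.outlet_nodes

    Av = sp.diags(ml / dt).tocsr() + 0.5 * nu * K
    Av = fem.dirichlet_rows_identity(Av, dir_nodes)
    lu_v = splu(Av.tocsc())
    Kp = fem.dirichlet_rows_identity(K.copy(), out_nodes)
    lu_p = splu(Kp.tocsc())

    n = mesh.n_points
    v = np.zeros((n, 3))
    p_kin = np.zeros(n)

    P = cfg.store_phases
    stored_v = np.zeros((P, n, 3))
    stored_p = np.zeros((P, n))
    first_phase0 = np.zeros((n, 3))  # start of the stored cycle (rest if 1 cycle)

    peak_q = float(np.abs(bc.waveform.flow_rate).max())
    div_log, flux_log = [], []
    total_steps = cfg.n_cycles * n_steps_cycle
    for step in range(total_steps):
        t_new = (step + 1) * dt
        # tentative velocity: explicit advection + CN diffusion
        adv = fem.advection_rhs(mesh, grads, vols, h_e, v, v, nu, dt, cfg.supg)
        gp = fem.pressure_gradient_rhs(mesh, grads, vols, p_kin)
        rhs = ml[:, None] * v / dt - 0.5 * nu * (K @ v) - adv - gp
        wall_v = bc.wall_velocity(t_new)
        rhs[bc.moving_nodes] = wall_v
        rhs[bc.rigid_nodes] = 0.0
        v_star = np.column_stack([lu_v.solve(rhs[:, d]) for d in range(3)])

        # pressure increment: grad^2 phi = div(v*)/dt, phi = 0 at outlets
        rhs_p = -fem.divergence_rhs(mesh, grads, vols, v_star) / dt
        rhs_p[out_nodes] = 0.0
        phi = lu_p.solve(rhs_p)
        p_kin = p_kin + phi

        # lumped-mass correction on free nodes
        gphi = fem.pressure_gradient_rhs(mesh, grads, vols, phi)
        v = v_star - dt * gphi / ml[:, None]
        v[bc.moving_nodes] = wall_v
        v[bc.rigid_nodes] = 0.0

        if not np.isfinite(v).all():
            raise SolverError(f"solution diverged at step {step} (t={t_new:.4f}s)")
        if step % 20 == 0:
            cfl_now = float(np.abs(v).max()) * dt / h_min
            if cfl_now > cfg.cfl_abort:
                raise SolverError(
                    f"advective CFL {cfl_now:.2f} exceeds {cfg.cfl_abort} at fixed "
                    f"dt={dt:.3g}s; increase steps_per_cycle or coarsen the mesh"
                )

        div_e = fem.element_divergence(mesh, grads, v)
        div_log.append(float(np.sqrt(np.sum(vols * div_e**2))))
        wall_flux = bc.discrete_wall_flux(t_new)
        flux_log.append(wall_flux + _outlet_flux(mesh, v))

        done = step + 1
        last_start = total_steps - n_steps_cycle
        if done == last_start:
            first_phase0 = v.copy()
            stored_v[0] = v
            stored_p[0] = p_kin
        elif done > last_start and (done - last_start) % spp == 0:
            k = (done - last_start) // spp
            if k < P:
                stored_v[k] = v
                stored_p[k] = p_kin

    # periodicity: compare cycle start vs cycle end states
    v_end = v
    peak_norm = max(
        float(np.sqrt(np.sum(ml * (stored_v**2).sum(axis=2), axis=1)).max()), 1e-30
    )
    per = float(
        np.sqrt(np.sum(ml * ((v_end - first_phase0) ** 2).sum(axis=1))) / peak_norm
    )
    phase_times = np.arange(P) * (T / P)
    p_pa = stored_p * props.density * 1e-6  # mm^2/s^2 -> Pa
    mass_residual = float(np.abs(flux_log).max() / max(peak_q, 1e-30)) if peak_q > 0 else float(np.abs(flux_log).max())
    return VelocityField(
        mesh=mesh,
        phase_times=phase_times,
        velocity=stored_v,
        pressure=p_pa,
        period=T,
        props=props,
        logs={
            "dt": dt,
            "steps_per_cycle": n_steps_cycle,
            "divergence": np.array(div_log),
            "flux_residual": np.array(flux_log),
            "mass_residual_rel": mass_residual,
            "periodicity": per,
        },
    )


def peak_section_velocity(field: VelocityField, z: float | None = None) -> float:
    """Peak area-averaged axial velocity at an aqueduct cross-section."""
    from .flow import cross_section_flow

    if z is None:
        z0, z1 = field.mesh.meta["aqueduct_z"]
        z = 0.5 * (z0 + z1)
    _, q, area = cross_section_flow(field, z)
    return float(np.abs(q).max() / area)


def mesh_convergence(
    geometry,
    waveform: FlowWaveform,
    sizes=(1.4, 0.7, 0.35),
    props: FluidProps = FluidProps(),
    cfg: SolverConfig | None = None,
    scale_with_diameter: bool = True,
) -> dict:
    """Three-level mesh-independency protocol.

    Runs the same cardiac cycle on coarse/medium/fine meshes (base
    sizes scaled by D/2.82 so small aqueducts stay resolved) and
    reports pairwise relative differences of the peak area-averaged
    aqueduct velocity.
    """
    from .geometry import mesh_geometry

    sizes = sorted(sizes, reverse=True)
    if len(sizes) != 3 or not all(a > b for a, b in zip(sizes, sizes[1:])):
        raise SolverError("need three strictly decreasing mesh sizes")
    scale = geometry.aqueduct_diameter / 2.82 if scale_with_diameter else 1.0
    cfg = cfg or SolverConfig(n_cycles=1)
    rows = {}
    peaks = {}
    for name, s in zip(("coarse", "medium", "fine"), sizes):
        try:
            m = mesh_geometry(geometry, s * scale)
            bc = build_wall_program(m, waveform, cfg.waveform_interp)
            fld = solve_cycle(m, bc, props, cfg)
            peaks[name] = peak_section_velocity(fld)
            rows[name] = {
                "base_size": s * scale,
                "n_tets": m.n_tets,
                "peak_velocity": peaks[name],
                "failed": False,
            }
        except Exception as exc:  # partial table with failure marks
            rows[name] = {"base_size": s * scale, "failed": True, "error": str(exc)}
    pairs = {}
    for a, b in (("coarse", "medium"), ("medium", "fine"), ("coarse", "fine")):
        if a in peaks and b in peaks:
            pairs[f"{a}_vs_{b}"] = abs(peaks[a] - peaks[b]) / abs(peaks[b])
    return {"runs": rows, "relative_errors": pairs}
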