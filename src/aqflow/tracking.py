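"""Lagrangian particle tracking through the periodic velocity field.

Massless tracers are seeded on an axis-aligned lattice strictly inside
the fluid domain and advected by explicit Runge-Kutta through the
stored cycle, reused periodically.  Spatial interpolation is
barycentric within the containing tetrahedron (P1-exact); temporal
interpolation is linear between stored phases with periodic extension.
Particles that leave the domain (through the outlet foramina) are
frozen at their last in-domain position and marked exited; origin
positions are immutable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .mesh import TetMesh

ACTIVE = 0
EXITED = 1


@dataclass
class TrackingConfig:
    n_cycles: int = 20
    integrator: str = "rk4"      # rk4 | rk2
    substeps: int = 4            # RK steps per stored phase interval
    spacing: float = 0.5         # mm, lattice interval (0.25 at full scale)
    time_interp: str = "linear"

    def __post_init__(self):
        if self.n_cycles < 1 or self.substeps < 1:
            raise ValueError("n_cycles and substeps must be >= 1")
        if self.integrator not in ("rk4", "rk2"):
            raise ValueError("integrator must be rk4 or rk2")


@dataclass
class ParticleSet:
    """Tracer positions with frozen origin bookkeeping."""

    positions: np.ndarray   # (n, 3) mm, current
    origins: np.ndarray     # (n, 3) mm, frozen at seed time
    status: np.ndarray      # (n,) ACTIVE or EXITED
    tet: np.ndarray         # (n,) containing-tet cache
    spacing: float

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def n_active(self) -> int:
        return int((self.status == ACTIVE).sum())


# ---------------------------------------------------------------------------
# cell location
# ---------------------------------------------------------------------------


@dataclass
class Locator:
    """Uniform background grid over tetrahedra for point location."""

    p0: np.ndarray          # (ne, 3) first vertex of each tet
    minv: np.ndarray        # (ne, 3, 3) barycentric maps
    tets: np.ndarray
    lo: np.ndarray
    cell: float
    dims: np.ndarray        # (3,) grid shape
    start: np.ndarray       # CSR offsets per grid cell
    items: np.ndarray       # tet indices


def build_locator(mesh: TetMesh, cells_per_tet: float = 1.0) -> Locator:
    pts, tets = mesh.points, mesh.tets
    corners = pts[tets]                       # (ne,4,3)
    bmin = corners.min(axis=1)
    bmax = corners.max(axis=1)
    sizes = (bmax - bmin).max(axis=1)
    cell = max(float(np.median(sizes)) * 1.2, 1e-9)
    lo = pts.min(axis=0) - 1e-9
    hi = pts.max(axis=0) + 1e-9
    dims = np.maximum(np.ceil((hi - lo) / cell).astype(np.int64), 1)

    ij_min = np.floor((bmin - lo) / cell).astype(np.int64)
    ij_max = np.floor((bmax - lo) / cell).astype(np.int64)
    ij_min = np.clip(ij_min, 0, dims - 1)
    ij_max = np.clip(ij_max, 0, dims - 1)
    counts_per_tet = (ij_max - ij_min + 1).prod(axis=1)
    total = int(counts_per_tet.sum())
    cell_ids = np.empty(total, dtype=np.int64)
    tet_ids = np.empty(total, dtype=np.int64)
    pos = 0
    for e in range(tets.shape[0]):
        for i in range(ij_min[e, 0], ij_max[e, 0] + 1):
            for j in range(ij_min[e, 1], ij_max[e, 1] + 1):
                for k in range(ij_min[e, 2], ij_max[e, 2] + 1):
                    cell_ids[pos] = (i * dims[1] + j) * dims[2] + k
                    tet_ids[pos] = e
                    pos += 1
    order = np.argsort(cell_ids, kind="stable")
    cell_ids = cell_ids[order]
    items = tet_ids[order]
    ncell = int(dims.prod())
    start = np.zeros(ncell + 1, dtype=np.int64)
    np.add.at(start, cell_ids + 1, 1)
    start = np.cumsum(start)

    M = np.stack([pts[tets[:, i]] - pts[tets[:, 0]] for i in (1, 2, 3)], axis=2)
    minv = np.linalg.inv(M)
    return Locator(
        p0=pts[tets[:, 0]].copy(),
        minv=minv,
        tets=tets,
        lo=lo,
        cell=cell,
        dims=dims,
        start=start,
        items=items,
    )


@njit(cache=True)
def _bary(p0, minv, x):
    d0 = x[0] - p0[0]
    d1 = x[1] - p0[1]
    d2 = x[2] - p0[2]
    l1 = minv[0, 0] * d0 + minv[0, 1] * d1 + minv[0, 2] * d2
    l2 = minv[1, 0] * d0 + minv[1, 1] * d1 + minv[1, 2] * d2
    l3 = minv[2, 0] * d0 + minv[2, 1] * d1 + minv[2, 2] * d2
    return 1.0 - l1 - l2 - l3, l1, l2, l3


@njit(cache=True)
def _inside(p0, minv, x, tol):
    l0, l1, l2, l3 = _bary(p0, minv, x)
    return l0 >= -tol and l1 >= -tol and l2 >= -tol and l3 >= -tol


@njit(cache=True)
def _locate(x, hint, p0, minv, lo, cell, dims, start, items, tol):
    if hint >= 0 and _inside(p0[hint], minv[hint], x, tol):
        return hint
    i = int((x[0] - lo[0]) / cell)
    j = int((x[1] - lo[1]) / cell)
    k = int((x[2] - lo[2]) / cell)
    if i < 0 or j < 0 or k < 0 or i >= dims[0] or j >= dims[1] or k >= dims[2]:
        return -1
    c = (i * dims[1] + j) * dims[2] + k
    for idx in range(start[c], start[c + 1]):
        e = items[idx]
        if _inside(p0[e], minv[e], x, tol):
            return e
    return -1


@njit(cache=True)
def _velocity(x, t, hint, vphases, tets, p0, minv, lo, cell, dims, start, items,
              phase_dt, n_phases, period, tol):
    """Interpolated velocity; returns (ok, tet, vx, vy, vz)."""
    e = _locate(x, hint, p0, minv, lo, cell, dims, start, items, tol)
    if e < 0:
        return False, -1, 0.0, 0.0, 0.0
    tm = t % period
    kf = tm / phase_dt
    k0 = int(kf) % n_phases
    k1 = (k0 + 1) % n_phases
    w = kf - int(kf)
    l0, l1, l2, l3 = _bary(p0[e], minv[e], x)
    vx = 0.0
    vy = 0.0
    vz = 0.0
    n0, n1, n2, n3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
    for c in range(3):
        a = (
            l0 * vphases[k0, n0, c]
            + l1 * vphases[k0, n1, c]
            + l2 * vphases[k0, n2, c]
            + l3 * vphases[k0, n3, c]
        )
        b = (
            l0 * vphases[k1, n0, c]
            + l1 * vphases[k1, n1, c]
            + l2 * vphases[k1, n2, c]
            + l3 * vphases[k1, n3, c]
        )
        val = (1.0 - w) * a + w * b
        if c == 0:
            vx = val
        elif c == 1:
            vy = val
        else:
            vz = val
    return True, e, vx, vy, vz


@njit(cache=True)
def _advect_kernel(pos, status, tetc, vphases, tets, p0, minv, lo, cell, dims,
                   start, items, phase_dt, n_phases, period, t0, dt, n_steps,
                   order, tol):
    n = pos.shape[0]
    x = np.empty(3)
    xs = np.empty(3)
    for ip in range(n):
        if status[ip] != 0:
            continue
        x[0], x[1], x[2] = pos[ip, 0], pos[ip, 1], pos[ip, 2]
        hint = tetc[ip]
        t = t0
        alive = True
        for s in range(n_steps):
            ok, e, k1x, k1y, k1z = _velocity(
                x, t, hint, vphases, tets, p0, minv, lo, cell, dims, start,
                items, phase_dt, n_phases, period, tol)
            if not ok:
                alive = False
                break
            hint = e
            if order == 2:
                xs[0] = x[0] + 0.5 * dt * k1x
                xs[1] = x[1] + 0.5 * dt * k1y
                xs[2] = x[2] + 0.5 * dt * k1z
                ok, e, k2x, k2y, k2z = _velocity(
                    xs, t + 0.5 * dt, hint, vphases, tets, p0, minv, lo, cell,
                    dims, start, items, phase_dt, n_phases, period, tol)
                if not ok:
                    alive = False
                    break
                x[0] += dt * k2x
                x[1] += dt * k2y
                x[2] += dt * k2z
            else:
                xs[0] = x[0] + 0.5 * dt * k1x
                xs[1] = x[1] + 0.5 * dt * k1y
                xs[2] = x[2] + 0.5 * dt * k1z
                ok, e, k2x, k2y, k2z = _velocity(
                    xs, t + 0.5 * dt, hint, vphases, tets, p0, minv, lo, cell,
                    dims, start, items, phase_dt, n_phases, period, tol)
                if not ok:
                    alive = False
                    break
                xs[0] = x[0] + 0.5 * dt * k2x
                xs[1] = x[1] + 0.5 * dt * k2y
                xs[2] = x[2] + 0.5 * dt * k2z
                ok, e, k3x, k3y, k3z = _velocity(
                    xs, t + 0.5 * dt, hint, vphases, tets, p0, minv, lo, cell,
                    dims, start, items, phase_dt, n_phases, period, tol)
                if not ok:
                    alive = False
                    break
                xs[0] = x[0] + dt * k3x
                xs[1] = x[1] + dt * k3y
                xs[2] = x[2] + dt * k3z
                ok, e, k4x, k4y, k4z = _velocity(
                    xs, t + dt, hint, vphases, tets, p0, minv, lo, cell, dims,
                    start, items, phase_dt, n_phases, period, tol)
                if not ok:
                    alive = False
                    break
                x[0] += dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
                x[1] += dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
                x[2] += dt / 6.0 * (k1z + 2 * k2z + 2 * k3z + k4z)
            t += dt
            # confirm the new position is still in the domain
            e = _locate(x, hint, p0, minv, lo, cell, dims, start, items, tol)
            if e < 0:
                alive = False
                break
            hint = e
        if not alive:
            status[ip] = 1
        pos[ip, 0], pos[ip, 1], pos[ip, 2] = x[0], x[1], x[2]
        tetc[ip] = hint


def seed_particles(mesh: TetMesh, spacing: float, locator: Locator | None = None) -> ParticleSet:
    """Axis-aligned lattice of tracers strictly inside the fluid domain.

    The closed lattice is anchored at the mesh bounding-box minimum
    corner; a point is kept when it lies strictly inside the *domain*
    (points on internal element faces are interior; points touching
    the boundary are not, decided by probing six axis perturbations).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    loc = locator or build_locator(mesh)
    lo = mesh.points.min(axis=0)
    hi = mesh.points.max(axis=0)
    axes = [np.arange(lo[d], hi[d] + 1e-9, spacing) for d in range(3)]
    if min(a.size for a in axes) > 0:
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        cand = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        tet = _locate_many(cand, loc, tol=1e-12)
        keep = tet >= 0
        # interior test: every slightly perturbed copy stays in the mesh
        delta = 1e-6 * spacing
        for d in range(3):
            for sgn in (-1.0, 1.0):
                if not keep.any():
                    break
                shifted = cand[keep].copy()
                shifted[:, d] += sgn * delta
                inside = _locate_many(shifted, loc, tol=1e-12) >= 0
                idx = np.where(keep)[0]
                keep[idx[~inside]] = False
        pos = cand[keep]
        tet = tet[keep]
    else:
        pos = np.empty((0, 3))
        tet = np.empty(0, dtype=np.int64)
    if pos.shape[0] == 0:
        import warnings

        warnings.warn("spacing too large for the domain; empty particle set")
    return ParticleSet(
        positions=pos.copy(),
        origins=pos.copy(),
        status=np.zeros(pos.shape[0], dtype=np.int8),
        tet=tet.astype(np.int64),
        spacing=spacing,
    )


@njit(cache=True)
def _locate_many_kernel(pts, p0, minv, lo, cell, dims, start, items, tol):
    out = np.empty(pts.shape[0], dtype=np.int64)
    for i in range(pts.shape[0]):
        out[i] = _locate(pts[i], -1, p0, minv, lo, cell, dims, start, items, tol)
    return out


def _locate_many(pts, loc: Locator, tol: float = 1e-10) -> np.ndarray:
    return _locate_many_kernel(
        np.ascontiguousarray(pts, dtype=np.float64), loc.p0, loc.minv, loc.lo,
        loc.cell, loc.dims, loc.start, loc.items, tol,
    )


def locate_and_interpolate(position, field, t: float, locator: Locator | None = None):
    """Velocity at one point and time; returns None if outside the domain."""
    loc = locator or build_locator(field.mesh)
    phase_dt = field.period / field.n_phases
    x = np.asarray(position, dtype=np.float64)
    ok, _, vx, vy, vz = _velocity(
        x, float(t), -1, field.velocity, loc.tets, loc.p0, loc.minv, loc.lo,
        loc.cell, loc.dims, loc.start, loc.items, phase_dt, field.n_phases,
        field.period, 1e-10,
    )
    return np.array([vx, vy, vz]) if ok else None


def advect(
    particles: ParticleSet,
    field,
    cfg: TrackingConfig | None = None,
    locator: Locator | None = None,
    duration: float | None = None,
) -> ParticleSet:
    """Advect tracers for n_cycles cardiac cycles (or a given duration).

    Returns a new ParticleSet at T = n_cycles * T_c with origins and
    exit status carried along; the input set is not modified.
    """
    cfg = cfg or TrackingConfig()
    loc = locator or build_locator(field.mesh)
    T = duration if duration is not None else cfg.n_cycles * field.period
    phase_dt = field.period / field.n_phases
    dt = phase_dt / cfg.substeps
    n_steps = int(round(T / dt))
    pos = particles.positions.copy()
    status = particles.status.copy()
    tetc = particles.tet.copy()
    if not np.isfinite(field.velocity).all():
        raise RuntimeError("velocity field contains non-finite values")
    _advect_kernel(
        pos, status, tetc, field.velocity, loc.tets, loc.p0, loc.minv, loc.lo,
        loc.cell, loc.dims, loc.start, loc.items, phase_dt, field.n_phases,
        field.period, 0.0, dt, n_steps, 4 if cfg.integrator == "rk4" else 2,
        1e-9,
    )
    return ParticleSet(
        positions=pos,
        origins=particles.origins.copy(),
        status=status,
        tet=tetc,
        spacing=particles.spacing,
    )
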