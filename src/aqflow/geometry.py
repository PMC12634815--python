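"""Idealized ventricle-aqueduct geometries and structured tet meshing.

The patient-specific ventricular segmentations are replaced by a
parametric axisymmetric idealization: four chambers along a straight
axis (lateral-ventricle analogue, third ventricle, cerebral aqueduct,
fourth ventricle) described by a smooth radius profile R(z).  Chamber
bulge radii are solved so each chamber volume matches its target.  The
mesh is built by extruding a polar disk triangulation along the axis,
scaling each cross-section by R(z), and splitting the resulting prisms
into tetrahedra with the vertex-order rule, which guarantees a
conforming, watertight mesh with strictly positive element volumes.

All lengths in mm, volumes in mm^3 (= microlitres).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .mesh import (
    MOVING_WALL,
    OUTLET,
    RIGID_WALL,
    MeshError,
    TetMesh,
    boundary_faces,
    orient_tets,
    tet_volumes,
)


class GeometryError(ValueError):
    """Raised for non-manifold or degenerate geometry parameters."""


@dataclass
class GeometryTemplate:
    """Tunable shape parameters of the idealization.

    chamber_scale rescales the chamber volume targets (the aqueduct is
    always kept at true scale); the desk-scale default of 0.1 keeps
    meshes small while preserving aqueduct Reynolds number and dynamics.
    """

    chamber_scale: float = 0.1
    lv_length: float = 14.0
    v3_length: float = 6.0
    v4_length: float = 14.0
    ramp_frac: float = 0.32       # fraction of a chamber segment per ramp
    cap_radius_frac: float = 0.5  # z=0 cap radius relative to LV mean radius
    monro_radius: float = 1.6     # LV -> 3V neck, mm
    # "common-plane": one outflow disk covering the funnel end cap (the
    # foramina treated as a single 0 Pa cross-sectional plane; keeps the
    # discrete wall/outlet mass balance well under 1% of peak Q at desk
    # scale).  "two-disks": two separated foramen-analogue disks (more
    # literal anatomy; costs a few % of peak Q in flux-balance residual
    # because the rigid separator strip obstructs the outflow).
    outlet_mode: str = "common-plane"
    outlet_disk_frac: float = 0.46  # two-disks: disk radius / cap radius
    outlet_offset_frac: float = 0.52  # two-disks: center offset / cap radius


@dataclass
class _Segment:
    z0: float
    z1: float
    r_in: float
    r_out: float
    r_max: float
    ramp: float  # ramp fraction of segment length

    def radius(self, z):
        s = (np.asarray(z, dtype=float) - self.z0) / (self.z1 - self.z0)
        s = np.clip(s, 0.0, 1.0)
        f = self.ramp
        r = np.full_like(s, self.r_max)
        lo = s < f
        hi = s > 1.0 - f
        h = lambda u: 0.5 * (1.0 - np.cos(np.pi * u))
        r = np.where(lo, self.r_in + (self.r_max - self.r_in) * h(s / f), r)
        r = np.where(
            hi, self.r_out + (self.r_max - self.r_out) * h((1.0 - s) / f), r
        )
        return r


def _segment_volume(seg: _Segment, n: int = 2001) -> float:
    z = np.linspace(seg.z0, seg.z1, n)
    return float(np.trapezoid(np.pi * seg.radius(z) ** 2, z))


def _solve_funnel(z0, z1, r_in, volume) -> _Segment:
    """Monotone expanding segment whose exit radius matches the volume.

    Smooth expansion over the first half followed by a straight duct,
    so the outflow cap sees an organized, almost developed flow.
    """
    def make(r_out):
        return _Segment(z0, z1, r_in, r_out, r_out, 0.5)

    v_min = _segment_volume(make(r_in))
    if volume <= v_min * (1.0 + 1e-9):
        if volume >= v_min * (1.0 - 5e-3):
            return make(r_in)
        raise GeometryError(
            f"funnel volume {volume:.3g} mm^3 below the cylinder minimum "
            f"{v_min:.3g} mm^3 at inlet radius {r_in:.3g} mm"
        )
    r_hi = r_in + 2.0 * math.sqrt(volume / (np.pi * (z1 - z0)))

    def f(r):
        return _segment_volume(make(r)) - volume

    while f(r_hi) < 0:
        r_hi *= 1.6
    return make(brentq(f, r_in, r_hi, xtol=1e-10))


def _solve_bulge(z0, z1, r_in, r_out, volume, ramp) -> _Segment:
    """Solve the bulge radius so the segment volume hits its target."""
    r_floor = max(r_in, r_out)
    seg_min = _Segment(z0, z1, r_in, r_out, r_floor, ramp)
    v_min = _segment_volume(seg_min)
    if volume <= v_min * (1.0 + 1e-9):
        if volume >= v_min * (1.0 - 5e-3):
            return seg_min
        raise GeometryError(
            f"chamber volume {volume:.3g} mm^3 below the minimum "
            f"{v_min:.3g} mm^3 reachable with neck radius {r_floor:.3g} mm"
        )
    r_hi = r_floor + 2.0 * math.sqrt(volume / (np.pi * (z1 - z0)))

    def f(rm):
        return _segment_volume(_Segment(z0, z1, r_in, r_out, rm, ramp)) - volume

    while f(r_hi) < 0:
        r_hi *= 1.6
    rm = brentq(f, r_floor, r_hi, xtol=1e-10)
    return _Segment(z0, z1, r_in, r_out, rm, ramp)


@dataclass
class VentricleGeometry:
    """Axisymmetric idealized ventricle-aqueduct geometry.

    The flow axis is z; R(z) is the local cross-section radius.  The
    z=0 end cap and the lateral surface of the LV segment form the
    moving wall; the outlet disk(s) sit on the z = total_length end
    cap (one common outflow plane by default, or two foramen-analogue
    disks in the two-disks template variant).
    """

    aqueduct_diameter: float
    aqueduct_length: float
    segments: list = field(default_factory=list)
    moving_z_end: float = 0.0
    aqueduct_z: tuple = (0.0, 0.0)
    outlet_disks: list = field(default_factory=list)  # [(cx, cy, r), ...]
    chamber_volumes: dict = field(default_factory=dict)

    @property
    def total_length(self) -> float:
        return self.segments[-1].z1

    def radius(self, z):
        z = np.asarray(z, dtype=float)
        r = np.zeros_like(z)
        for seg in self.segments:
            m = (z >= seg.z0) & (z <= seg.z1)
            r = np.where(m, seg.radius(z), r)
        return r

    def volume(self, n: int = 4001) -> float:
        z = np.linspace(0.0, self.total_length, n)
        return float(np.trapezoid(np.pi * self.radius(z) ** 2, z))

    def aqueduct_area(self) -> float:
        return np.pi * (self.aqueduct_diameter / 2.0) ** 2


def build_geometry(subject, template: GeometryTemplate | None = None) -> VentricleGeometry:
    """Idealized geometry for one subject.

    ``subject`` needs attributes aqueduct_diameter (mm), aqueduct_length
    (mm), and lv/v3/v4_volume (ml); a plain namespace works.
    """
    tpl = template or GeometryTemplate()
    D = float(subject.aqueduct_diameter)
    L_aq = float(subject.aqueduct_length)
    if D <= 0 or L_aq <= 0:
        raise GeometryError("aqueduct diameter and length must be positive")
    r_aq = D / 2.0
    # ml -> mm^3, then desk rescale
    v_lv = float(subject.lv_volume) * 1e3 * tpl.chamber_scale
    v_3 = float(subject.v3_volume) * 1e3 * tpl.chamber_scale
    v_4 = float(subject.v4_volume) * 1e3 * tpl.chamber_scale
    if min(v_lv, v_3, v_4) <= 0:
        raise GeometryError("chamber volumes must be positive")

    r_lv_mean = math.sqrt(v_lv / (np.pi * tpl.lv_length))
    r_cap = max(tpl.cap_radius_frac * r_lv_mean, 1.2 * r_aq)
    r_monro = max(tpl.monro_radius, r_aq)

    z = 0.0
    segs = []
    segs.append(_solve_bulge(z, z + tpl.lv_length, r_cap, r_monro, v_lv, tpl.ramp_frac))
    z += tpl.lv_length
    segs.append(_solve_bulge(z, z + tpl.v3_length, r_monro, r_aq, v_3, tpl.ramp_frac))
    z += tpl.v3_length
    aq = _Segment(z, z + L_aq, r_aq, r_aq, r_aq, 1e-6)
    segs.append(aq)
    z += L_aq
    # fourth ventricle as a volume-matched expanding outflow funnel: the
    # aqueduct jet decelerates gradually and reaches the foramina plane
    # as an organized near-axial flow
    v4_seg = _solve_funnel(z, z + tpl.v4_length, r_aq, v_4)
    segs.append(v4_seg)
    z += tpl.v4_length
    r_end = v4_seg.r_out

    if tpl.outlet_mode == "two-disks":
        off = tpl.outlet_offset_frac * r_end
        r_disk = tpl.outlet_disk_frac * r_end
        disks = [(off, 0.0, r_disk), (-off, 0.0, r_disk)]
    elif tpl.outlet_mode == "common-plane":
        disks = [(0.0, 0.0, 1.02 * r_end)]
    else:
        raise GeometryError(f"unknown outlet_mode {tpl.outlet_mode!r}")
    return VentricleGeometry(
        aqueduct_diameter=D,
        aqueduct_length=L_aq,
        segments=segs,
        moving_z_end=tpl.lv_length,
        aqueduct_z=(aq.z0, aq.z1),
        outlet_disks=disks,
        chamber_volumes={"lv": v_lv, "v3": v_3, "v4": v_4},
    )


# ---------------------------------------------------------------------------
# structured meshing
# ---------------------------------------------------------------------------


def _disk_template(m: int, n_layers: int = 0):
    """Polar triangulation of the unit disk.

    Ring k (k = 1..m) carries 6k nodes at radius k/m; optional thin
    wall-refinement rings (all with 6m nodes) are inserted near r = 1.
    Returns (points2d, triangles) with counter-clockwise triangles.
    """
    radii = [k / m for k in range(m)]
    counts = [max(6 * k, 1) for k in range(m)]
    if n_layers > 0:
        t = 0.5 / m
        offs = sorted(t * 0.55 ** i for i in range(n_layers))
        radii += [1.0 - o for o in reversed(offs)]
        counts += [6 * m] * n_layers
    radii.append(1.0)
    counts.append(6 * m)

    pts = [(0.0, 0.0)]
    ring_idx = [[0]]
    ring_ang = [[0.0]]
    for r, c in zip(radii[1:], counts[1:]):
        ang = 2.0 * np.pi * np.arange(c) / c
        idx = list(range(len(pts), len(pts) + c))
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        ring_idx.append(idx)
        ring_ang.append(list(ang))
    tris = []
    for k in range(1, len(radii)):
        tris.extend(
            _zip_rings(ring_idx[k - 1], ring_ang[k - 1], ring_idx[k], ring_ang[k])
        )
    pts = np.array(pts)
    tris = np.array(tris, dtype=np.int64)
    # enforce CCW
    a, b, c = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    area2 = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    flip = area2 < 0
    tris[flip, 1], tris[flip, 2] = tris[flip, 2].copy(), tris[flip, 1].copy()
    return pts, tris


def _zip_rings(inner_idx, inner_ang, outer_idx, outer_ang):
    """Triangulate the annulus between two concentric node rings."""
    n1, n2 = len(inner_idx), len(outer_idx)
    if n1 == 1:
        return [
            (inner_idx[0], outer_idx[j], outer_idx[(j + 1) % n2]) for j in range(n2)
        ]
    tris = []
    i = j = ci = cj = 0
    two_pi = 2.0 * np.pi
    while ci < n1 or cj < n2:
        ai = inner_ang[(i + 1) % n1] + two_pi * ((i + 1) // n1)
        aj = outer_ang[(j + 1) % n2] + two_pi * ((j + 1) // n2)
        if cj >= n2 or (ci < n1 and ai <= aj):
            tris.append((inner_idx[i % n1], outer_idx[j % n2], inner_idx[(i + 1) % n1]))
            i += 1
            ci += 1
        else:
            tris.append((inner_idx[i % n1], outer_idx[j % n2], outer_idx[(j + 1) % n2]))
            j += 1
            cj += 1
    return tris


def _prisms_to_tets(tris: np.ndarray, npl: int, n_layers: int) -> np.ndarray:
    """Split extruded prisms into tets with the sorted-vertex rule.

    Adjacent prisms always agree on shared-quad diagonals because the
    diagonal is chosen from the global vertex order, so the mesh is
    conforming by construction.
    """
    srt = np.sort(tris, axis=1)  # a < b < c within a layer
    tets = []
    for layer in range(n_layers):
        lo = layer * npl
        hi = (layer + 1) * npl
        a, b, c = srt[:, 0] + lo, srt[:, 1] + lo, srt[:, 2] + lo
        A, B, C = srt[:, 0] + hi, srt[:, 1] + hi, srt[:, 2] + hi
        tets.append(np.stack([a, b, c, C], axis=1))
        tets.append(np.stack([a, b, C, B], axis=1))
        tets.append(np.stack([a, B, C, A], axis=1))
    return np.concatenate(tets, axis=0)


def _z_grid(geom: VentricleGeometry, base_size: float, m: int) -> np.ndarray:
    """Axial layer positions, graded with the radius profile.

    The axial step grows with R(z) in the chambers (capped), shrinks
    where R' is steep so the sheared prisms stay well-shaped, and stays
    near the base size close to the outlet cap, where the aqueduct jet
    impinges and the outflow must be resolved for clean mass balance.
    """
    r_aq = geom.aqueduct_diameter / 2.0
    L = geom.total_length
    zs = [0.0]
    z = 0.0
    eps = 1e-4
    while z < L - 1e-9:
        R = float(geom.radius(z))
        dR = (float(geom.radius(min(z + eps, L))) - float(geom.radius(max(z - eps, 0.0)))) / (
            2 * eps
        )
        grow = min(max(R / r_aq, 1.0), 4.0)
        if L - z < 3.0:  # outlet-cap refinement band, mm
            grow = min(grow, 1.2)
        dz = base_size * grow
        shear_cap = 0.8 * (R / m) / max(abs(dR), 0.25)
        dz = max(min(dz, shear_cap), 0.5 * base_size)
        if L - z < 1.45 * dz:
            dz = L - z
        z += dz
        zs.append(min(z, L))
    return np.array(zs)


def mesh_geometry(
    geom: VentricleGeometry, base_size: float, n_layers: int = 0,
    rings: int | None = None,
) -> TetMesh:
    """Structured labeled tet mesh of an idealized geometry.

    ``base_size`` is the target element size in the aqueduct; the
    cross-section ring count guarantees at least four elements across
    the aqueduct diameter whenever base_size <= D/4, and can be raised
    explicitly via ``rings`` to resolve the outlet cap independently of
    the axial grading.  ``n_layers`` inserts thin wall-refinement rings
    (the boundary-layer analogue).
    """
    if base_size <= 0:
        raise GeometryError("base_size must be positive")
    D = geom.aqueduct_diameter
    m = rings if rings is not None else max(2, math.ceil(D / (2.0 * base_size)))
    m = max(2, m)
    pts2, tris2 = _disk_template(m, n_layers)
    zs = _z_grid(geom, base_size, m)
    npl = pts2.shape[0]
    R = geom.radius(zs)
    points = np.empty((zs.size * npl, 3))
    for k, (zk, rk) in enumerate(zip(zs, R)):
        points[k * npl : (k + 1) * npl, 0] = pts2[:, 0] * rk
        points[k * npl : (k + 1) * npl, 1] = pts2[:, 1] * rk
        points[k * npl : (k + 1) * npl, 2] = zk
    tets = _prisms_to_tets(tris2, npl, zs.size - 1)
    tets = orient_tets(points, tets)
    vols = tet_volumes(points, tets)
    if vols.min() <= 0:
        raise MeshError("structured extrusion produced degenerate elements")

    btris, _ = boundary_faces(tets)
    cz = points[btris].mean(axis=1)[:, 2]
    ztop = zs[-1]
    labels = np.full(btris.shape[0], RIGID_WALL, dtype=np.int64)
    labels[cz <= geom.moving_z_end + 1e-9] = MOVING_WALL
    top = cz >= ztop - 1e-9
    if geom.outlet_disks:
        cxy = points[btris].mean(axis=1)[:, :2]
        on_outlet = np.zeros(btris.shape[0], dtype=bool)
        for cx, cy0, rd in geom.outlet_disks:
            d = np.hypot(cxy[:, 0] - cx, cxy[:, 1] - cy0)
            hit = top & (d <= rd)
            if not hit.any():  # guarantee one facet per disk
                cand = np.where(top)[0]
                hit_i = cand[np.argmin(d[cand])]
                on_outlet[hit_i] = True
            on_outlet |= hit
        labels[on_outlet] = OUTLET

    mesh = TetMesh(
        points=points,
        tets=tets,
        boundary_tris=btris,
        boundary_labels=labels,
        meta={
            "kind": "ventricle",
            "layer_z": zs,
            "nodes_per_layer": npl,
            "template_tris": tris2,
            "rings_m": m,
            "base_size": base_size,
            "aqueduct_z": geom.aqueduct_z,
            "aqueduct_diameter": D,
            "moving_z_end": geom.moving_z_end,
        },
    )
    mesh.validate()
    return mesh


def tube_mesh(radius: float, length: float, base_size: float, n_layers: int = 0) -> TetMesh:
    """Straight circular tube with a piston cap at z=0 and a full outlet cap.

    The z=0 cap carries the moving_wall label (piston inflow), the
    lateral surface is rigid, and the whole z=length cap is the outlet.
    Used by the Poiseuille and Womersley validation cases.
    """
    if radius <= 0 or length <= 0 or base_size <= 0:
        raise GeometryError("radius, length, base_size must be positive")
    seg = _Segment(0.0, length, radius, radius, radius, 1e-6)
    geom = VentricleGeometry(
        aqueduct_diameter=2 * radius,
        aqueduct_length=length,
        segments=[seg],
        moving_z_end=0.0,
        aqueduct_z=(0.0, length),
        outlet_disks=[(0.0, 0.0, radius * 1.01)],
    )
    mesh = mesh_geometry(geom, base_size, n_layers)
    mesh.meta["kind"] = "tube"
    return mesh


def section_flux_triangles(mesh: TetMesh, z: float) -> tuple[np.ndarray, float]:
    """Cross-section triangles (node ids) at the node layer nearest z.

    Only defined for structured meshes; the returned triangles are the
    extruded template triangles, which are exact faces of the tet mesh,
    so flux integrals over them are consistent with the FEM field.
    """
    if "layer_z" not in mesh.meta:
        raise GeometryError("cross-sections need a structured mesh")
    zs = mesh.meta["layer_z"]
    npl = mesh.meta["nodes_per_layer"]
    k = int(np.argmin(np.abs(zs - z)))
    tris = mesh.meta["template_tris"] + k * npl
    p = mesh.points
    areas = 0.5 * np.linalg.norm(
        np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]]), axis=1
    )
    return tris, float(areas.sum())
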