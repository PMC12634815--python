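"""Labeled tetrahedral meshes and elementary mesh geometry.

Meshes live in millimetres.  Boundary triangles are outward-oriented and
each carries exactly one label from {moving_wall, rigid_wall, outlet}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

MOVING_WALL = 1
RIGID_WALL = 2
OUTLET = 3

LABEL_NAMES = {MOVING_WALL: "moving_wall", RIGID_WALL: "rigid_wall", OUTLET: "outlet"}


class MeshError(ValueError):
    """Raised when a mesh violates its validity invariants."""


@dataclass
class TetMesh:
    """First-order tetrahedral mesh with a labeled boundary partition.

    Attributes
    ----------
    points : (n_points, 3) float array, mm
    tets : (n_tets, 4) int array, positively oriented
    boundary_tris : (n_btris, 3) int array, oriented so the right-hand
        normal points out of the fluid domain
    boundary_labels : (n_btris,) int array with values in LABEL_NAMES
    meta : free-form metadata; structured meshes store their layer table
        here so cross-sections can be evaluated exactly
    """

    points: np.ndarray
    tets: np.ndarray
    boundary_tris: np.ndarray
    boundary_labels: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def tet_volumes(self) -> np.ndarray:
        return tet_volumes(self.points, self.tets)

    def boundary_area_vectors(self) -> np.ndarray:
        """Outward area vector (normal times area) of each boundary triangle."""
        p = self.points
        t = self.boundary_tris
        return 0.5 * np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])

    def boundary_areas(self) -> np.ndarray:
        return np.linalg.norm(self.boundary_area_vectors(), axis=1)

    def label_area(self, label: int) -> float:
        return float(self.boundary_areas()[self.boundary_labels == label].sum())

    def label_tris(self, label: int) -> np.ndarray:
        return self.boundary_tris[self.boundary_labels == label]

    def nodes_on_label(self, label: int) -> np.ndarray:
        return np.unique(self.label_tris(label))

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_tris)

    def validate(self) -> None:
        vols = self.tet_volumes()
        if vols.min() <= 0.0:
            bad = int((vols <= 0).sum())
            raise MeshError(f"{bad} non-positive tetrahedron volumes")
        if self.boundary_labels.shape[0] != self.boundary_tris.shape[0]:
            raise MeshError("boundary label count mismatch")
        if not np.isin(self.boundary_labels, list(LABEL_NAMES)).all():
            raise MeshError("unknown boundary label")


def tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    a = points[tets[:, 1]] - points[tets[:, 0]]
    b = points[tets[:, 2]] - points[tets[:, 0]]
    c = points[tets[:, 3]] - points[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def orient_tets(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two vertices of every negatively oriented tet."""
    tets = tets.copy()
    neg = tet_volumes(points, tets) < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()
    return tets


def boundary_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Faces belonging to exactly one tet, with the owning tet index.

    Returned faces keep the node ordering that makes the right-hand
    normal point away from the opposite vertex of the owner.
    """
    # local faces ordered so normals point outward for a positive tet
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local].reshape(-1, 3)
    owners = np.repeat(np.arange(tets.shape[0]), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T[::-1])
    ks = key[order]
    dup = np.ones(ks.shape[0], dtype=bool)
    same = (ks[1:] == ks[:-1]).all(axis=1)
    dup[1:] &= ~same
    dup[:-1] &= ~same
    sel = order[dup]
    return faces[sel], owners[sel]


@dataclass
class QualityReport:
    n_tets: int
    min_volume: float
    mean_volume: float
    total_volume: float
    n_inverted: int
    aspect_min: float
    aspect_mean: float
    aspect_max: float
    aspect_hist: np.ndarray
    aspect_bins: np.ndarray
    label_areas: dict


def tet_aspect_ratios(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumradius over three inradii; 1 for the regular tetrahedron."""
    p = [points[tets[:, i]] for i in range(4)]
    vols = np.abs(tet_volumes(points, tets))
    # inradius = 3V / (sum of face areas)
    def tri_area(a, b, c):
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    s = (
        tri_area(p[1], p[2], p[3])
        + tri_area(p[0], p[2], p[3])
        + tri_area(p[0], p[1], p[3])
        + tri_area(p[0], p[1], p[2])
    )
    r_in = 3.0 * vols / np.maximum(s, 1e-300)
    # circumcenter from 2 (p_i - p0) . c = |p_i|^2 - |p0|^2
    A = np.stack([p[i] - p[0] for i in (1, 2, 3)], axis=1)
    rhs = np.stack(
        [((p[i] ** 2).sum(1) - (p[0] ** 2).sum(1)) * 0.5 for i in (1, 2, 3)], axis=1
    )
    c = np.linalg.solve(A, rhs[..., None])[..., 0]
    r_circ = np.linalg.norm(c - p[0], axis=1)
    return r_circ / np.maximum(3.0 * r_in, 1e-300)


def mesh_quality(mesh: TetMesh, n_bins: int = 20) -> QualityReport:
    """Element volume/aspect statistics and per-label boundary areas."""
    vols = mesh.tet_volumes()
    ar = tet_aspect_ratios(mesh.points, mesh.tets)
    hist, bins = np.histogram(ar, bins=n_bins)
    areas = {
        name: mesh.label_area(lab)
        for lab, name in LABEL_NAMES.items()
    }
    return QualityReport(
        n_tets=mesh.n_tets,
        min_volume=float(vols.min()),
        mean_volume=float(vols.mean()),
        total_volume=float(np.abs(vols).sum()),
        n_inverted=int((vols <= 0).sum()),
        aspect_min=float(ar.min()),
        aspect_mean=float(ar.mean()),
        aspect_max=float(ar.max()),
        aspect_hist=hist,
        aspect_bins=bins,
        label_areas=areas,
    )


def outlet_components(mesh: TetMesh) -> int:
    """Number of edge-connected components of the outlet label."""
    tris = mesh.label_tris(OUTLET)
    if tris.shape[0] == 0:
        return 0
    edges = {}
    for i, tri in enumerate(tris):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            e = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            edges.setdefault(e, []).append(i)
    parent = list(range(tris.shape[0]))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for members in edges.values():
        for j in members[1:]:
            parent[find(j)] = find(members[0])
    return len({find(i) for i in range(tris.shape[0])})
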