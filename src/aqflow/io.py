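"""Plain-text export of meshes, fields and particle clouds.

ASCII VTU (XML unstructured grid) for visualization and Gmsh MSH 2.2
for mesh interchange; both are self-contained writers so no meshing
toolkit is required at run time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import LABEL_NAMES, TetMesh


def write_vtu(path, points: np.ndarray, tets: np.ndarray | None = None,
              point_data: dict | None = None) -> Path:
    """ASCII .vtu file; tets=None writes a vertex cloud (particles)."""
    path = Path(path)
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if tets is None:
        cells = np.arange(n)[:, None]
        ctype = 1  # VTK_VERTEX
    else:
        cells = np.asarray(tets)
        ctype = 10  # VTK_TETRA
    nc = cells.shape[0]
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{nc}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines.extend(" ".join(f"{v:.9g}" for v in row) for row in points)
    lines += ["</DataArray>", "</Points>", "<Cells>",
              '<DataArray type="Int64" Name="connectivity" format="ascii">']
    lines.extend(" ".join(str(int(v)) for v in row) for row in cells)
    lines += ["</DataArray>",
              '<DataArray type="Int64" Name="offsets" format="ascii">',
              " ".join(str((i + 1) * cells.shape[1]) for i in range(nc)),
              "</DataArray>",
              '<DataArray type="UInt8" Name="types" format="ascii">',
              " ".join(str(ctype) for _ in range(nc)),
              "</DataArray>", "</Cells>"]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            comp = 1 if arr.ndim == 1 else arr.shape[1]
            lines.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{comp}" format="ascii">'
            )
            if arr.ndim == 1:
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)
            lines.append("</DataArray>")
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))
    return path


def write_field_series(outdir, field, stride: int = 1) -> list:
    """One VTU per stored phase plus a .pvd time index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for k in range(0, field.n_phases, stride):
        f = write_vtu(
            outdir / f"phase_{k:03d}.vtu",
            field.mesh.points,
            field.mesh.tets,
            {"velocity": field.velocity[k], "pressure": field.pressure[k]},
        )
        files.append((float(field.phase_times[k]), f))
    pvd = ['<?xml version="1.0"?>',
           '<VTKFile type="Collection" version="0.1"><Collection>']
    pvd += [f'<DataSet timestep="{t}" file="{f.name}"/>' for t, f in files]
    pvd += ["</Collection></VTKFile>"]
    (outdir / "series.pvd").write_text("\n".join(pvd))
    return [f for _, f in files]


def write_msh(path, mesh: TetMesh) -> Path:
    """Gmsh MSH 2.2 ASCII with boundary triangles as physical groups."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(LABEL_NAMES) + 1)]
    for lab, name in LABEL_NAMES.items():
        lines.append(f'2 {lab} "{name}"')
    lines.append('3 10 "fluid"')
    lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(mesh.n_points)]
    lines += [f"{i + 1} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
              for i, p in enumerate(mesh.points)]
    lines += ["$EndNodes", "$Elements",
              str(mesh.boundary_tris.shape[0] + mesh.n_tets)]
    eid = 1
    for tri, lab in zip(mesh.boundary_tris, mesh.boundary_labels):
        lines.append(f"{eid} 2 2 {lab} {lab} " + " ".join(str(v + 1) for v in tri))
        eid += 1
    for tet in mesh.tets:
        lines.append(f"{eid} 4 2 10 10 " + " ".join(str(v + 1) for v in tet))
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines))
    return path


def read_msh(path) -> TetMesh:
    """Read a mesh written by :func:`write_msh`."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    points, tets, btris, blabels = [], [], [], []
    for line in it:
        if line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                points.append([float(v) for v in parts[1:4]])
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                tag = int(parts[3])
                conn = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype == 2:
                    btris.append(conn)
                    blabels.append(tag)
                elif etype == 4:
                    tets.append(conn)
    return TetMesh(
        points=np.array(points),
        tets=np.array(tets, dtype=np.int64),
        boundary_tris=np.array(btris, dtype=np.int64),
        boundary_labels=np.array(blabels, dtype=np.int64),
    )
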