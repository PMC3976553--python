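"""File formats: legacy ASCII VTK PolyData, OBJ meshes, HDF5 resume states.

The VTK writer emits standard `DATASET POLYDATA` files (points, triangle
polygons, truss lines, point/cell/field data) readable by common viewers;
values are printed with 17 significant digits so a write/read round trip is
lossless to double precision.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from . import geometry as geo
from .errors import InputError

__all__ = [
    "write_vtk_polydata",
    "read_vtk_polydata",
    "export_frame",
    "import_frame",
    "write_geometry_vtk",
    "write_obj",
    "read_obj",
    "save_state_h5",
    "load_state_h5",
]

_FMT = "%.17g"


def _fmt_rows(arr: np.ndarray) -> str:
    return "\n".join(" ".join(_FMT % v for v in row) for row in np.atleast_2d(arr))


def write_vtk_polydata(
    path,
    points: np.ndarray,
    polygons: np.ndarray | None = None,
    lines: np.ndarray | None = None,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    field_data: dict | None = None,
    title: str = "mvsim polydata",
) -> None:
    points = np.asarray(points, float)
    out = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} double",
        _fmt_rows(points),
    ]
    n_cells = 0
    if polygons is not None and len(polygons):
        polygons = np.asarray(polygons, int)
        out.append(f"POLYGONS {len(polygons)} {4 * len(polygons)}")
        out.append("\n".join("3 " + " ".join(map(str, tri)) for tri in polygons))
        n_cells += len(polygons)
    if lines is not None and len(lines):
        lines = np.asarray(lines, int)
        out.append(f"LINES {len(lines)} {3 * len(lines)}")
        out.append("\n".join("2 " + " ".join(map(str, seg)) for seg in lines))
        n_cells += len(lines)
    if field_data:
        out.append(f"FIELD FieldData {len(field_data)}")
        for name, arr in field_data.items():
            arr = np.atleast_1d(np.asarray(arr, float))
            out.append(f"{name} 1 {arr.size} double")
            out.append(" ".join(_FMT % v for v in arr.ravel()))
    if point_data:
        out.append(f"POINT_DATA {len(points)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 2 and arr.shape[1] == 3:
                out.append(f"VECTORS {name} double")
                out.append(_fmt_rows(arr))
            else:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.append("\n".join(_FMT % v for v in arr.ravel()))
    if cell_data:
        out.append(f"CELL_DATA {n_cells}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, float)
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out.append("\n".join(_FMT % v for v in arr.ravel()))
    Path(path).write_text("\n".join(out) + "\n")


def read_vtk_polydata(path) -> dict:
    """Parse a file produced by :func:`write_vtk_polydata`."""
    tokens_lines = Path(path).read_text().splitlines()
    if not tokens_lines or not tokens_lines[0].startswith("# vtk DataFile"):
        raise InputError(f"{path}: not a legacy VTK file (bad header)")
    out: dict = {"point_data": {}, "cell_data": {}, "field_data": {}}
    i = 3  # skip header comment, free-form title line, ASCII marker
    n_lines = len(tokens_lines)

    def fail(msg, k):
        raise InputError(f"{path}:{k + 1}: {msg}")

    section = None
    while i < n_lines:
        line = tokens_lines[i].strip()
        i += 1
        if not line:
            continue
        parts = line.split()
        kw = parts[0].upper()
        if kw in ("#", "ASCII") or kw.startswith("#"):
            continue
        if kw == "DATASET":
            if parts[1].upper() != "POLYDATA":
                fail("only POLYDATA supported", i - 1)
        elif kw == "POINTS":
            n = int(parts[1])
            vals = []
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in tokens_lines[i].split())
                i += 1
            out["points"] = np.array(vals).reshape(n, 3)
        elif kw in ("POLYGONS", "LINES"):
            n = int(parts[1])
            cells = []
            for _ in range(n):
                row = [int(v) for v in tokens_lines[i].split()]
                cells.append(row[1 : 1 + row[0]])
                i += 1
            out["polygons" if kw == "POLYGONS" else "lines"] = np.array(cells, int)
        elif kw == "FIELD":
            k = int(parts[2])
            for _ in range(k):
                name, _, size, _ = tokens_lines[i].split()
                i += 1
                vals = []
                while len(vals) < int(size):
                    vals.extend(float(v) for v in tokens_lines[i].split())
                    i += 1
                out["field_data"][name] = np.array(vals)
        elif kw == "POINT_DATA":
            section = "point_data"
        elif kw == "CELL_DATA":
            section = "cell_data"
        elif kw == "SCALARS":
            name = parts[1]
            n = len(out["points"]) if section == "point_data" else None
            i += 1  # LOOKUP_TABLE line
            vals = []
            target = n if n is not None else None
            while i < n_lines:
                s = tokens_lines[i].strip()
                if not s or s.split()[0].upper() in (
                    "SCALARS",
                    "VECTORS",
                    "CELL_DATA",
                    "POINT_DATA",
                    "FIELD",
                ):
                    break
                vals.extend(float(v) for v in s.split())
                i += 1
                if target is not None and len(vals) >= target:
                    break
            out[section][name] = np.array(vals)
        elif kw == "VECTORS":
            name = parts[1]
            n = len(out["points"])
            vals = []
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in tokens_lines[i].split())
                i += 1
            out[section][name] = np.array(vals).reshape(n, 3)
        else:
            fail(f"unexpected keyword {kw!r}", i - 1)
    if "points" not in out:
        raise InputError(f"{path}: no POINTS section")
    return out


_FRAME_REQUIRED = ("velocity", "contact_pressure", "contact_pressure_leaflet")


def export_frame(state, geom: geo.MVGeometry, path) -> None:
    """Write one simulation snapshot as VTK PolyData (positions in mm)."""
    pos_mm = state.positions * 1e3
    pd = {
        "velocity": state.velocities,
        "contact_pressure": state.contact.pressure if state.contact else np.zeros(len(pos_mm)),
        "contact_pressure_leaflet": state.contact.pressure_leaflet
        if state.contact
        else np.zeros(len(pos_mm)),
        "contact_force": state.contact.force if state.contact else np.zeros_like(pos_mm),
    }
    cd = {
        "region": np.concatenate(
            [geom.tri_region.astype(float), geom.truss_type.astype(float) + 10.0]
        )
    }
    write_vtk_polydata(
        path,
        pos_mm,
        polygons=geom.triangles,
        lines=geom.truss_segments,
        point_data=pd,
        cell_data=cd,
        field_data={"time": [state.time]},
        title="mvsim frame",
    )


def import_frame(path):
    """Read a frame back: (positions_mm, point_data, field_data).

    Raises :class:`InputError` naming any missing required array."""
    data = read_vtk_polydata(path)
    for name in _FRAME_REQUIRED:
        if name not in data["point_data"]:
            raise InputError(f"{path}: missing point-data array {name!r}")
    return data["points"], data["point_data"], data["field_data"]


def write_geometry_vtk(geom: geo.MVGeometry, path) -> None:
    """Valve geometry with region labels (cell data) and node sets (field data)."""
    field = {f"set_{k}": v.astype(float) for k, v in geom.node_sets.items()}
    field["truss_rest_length"] = geom.truss_rest_length
    write_vtk_polydata(
        path,
        geom.nodes,
        polygons=geom.triangles,
        lines=geom.truss_segments,
        point_data={
            "region": geom.node_region.astype(float),
            "param_s": geom.node_param_s,
            "param_t": geom.node_param_t,
        },
        cell_data={
            "region": np.concatenate(
                [geom.tri_region.astype(float), geom.truss_type.astype(float) + 10.0]
            )
        },
        field_data=field,
        title="mvsim geometry",
    )


def write_obj(path, points: np.ndarray, triangles: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# mvsim OBJ export\n")
        for p in points:
            fh.write("v " + " ".join(_FMT % v for v in p) + "\n")
        for t in triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def read_obj(path):
    verts, faces = [], []
    for k, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            if len(parts) < 4:
                raise InputError(f"{path}:{k + 1}: malformed vertex")
            verts.append([float(v) for v in parts[1:4]])
        elif parts[0] == "f":
            try:
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
            except ValueError:
                raise InputError(f"{path}:{k + 1}: malformed face") from None
    return np.array(verts, float), np.array(faces, int)


def save_state_h5(path, state, geom: geo.MVGeometry | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["time"] = state.time
        f.create_dataset("positions", data=state.positions)
        f.create_dataset("velocities", data=state.velocities)
        if geom is not None:
            g = f.create_group("geometry")
            g.create_dataset("nodes", data=geom.nodes)
            g.create_dataset("triangles", data=geom.triangles)
            g.create_dataset("truss_segments", data=geom.truss_segments)


def load_state_h5(path):
    from .solver import SimState

    with h5py.File(path, "r") as f:
        return SimState(
            time=float(f.attrs["time"]),
            positions=f["positions"][...],
            velocities=f["velocities"][...],
        )
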