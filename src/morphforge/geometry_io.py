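"""Readers/writers for surfaces (STL), FE meshes (LS-DYNA keyword, legacy VTK)
and images/fields (NIfTI, MetaImage).

Every pair is an identity on its own output: integer data round-trips
bit-exactly, floats to better than 1e-6 relative.  Element order is never
changed by a read, so downstream morphs preserve ordering by construction.
"""

from __future__ import annotations

import os
import re
import warnings
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .core import (
    DisplacementField,
    ElementBlock,
    FEMesh,
    GridMismatchError,
    LabelImage,
    SurfaceMesh,
)


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


# ---------------------------------------------------------------------------
# surfaces (STL)
# ---------------------------------------------------------------------------

def read_surface(path: str | os.PathLike, region_tag: str = "") -> SurfaceMesh:
    """Read a binary or ASCII STL surface.

    Vertices are deduplicated to 1e-6 mm; triangle winding is preserved.
    A non-watertight surface only sets ``watertight=False`` (with a warning),
    it is not fatal.
    """
    path = Path(path)
    if not path.is_file() or path.stat().st_size == 0:
        raise FormatError(f"unreadable or empty surface file: {path}")
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False, force="mesh")
    except Exception as exc:  # pragma: no cover - trimesh error paths
        raise FormatError(f"cannot parse STL {path}: {exc}") from exc
    if tm.faces.shape[0] == 0:
        raise FormatError(f"surface file has no triangles: {path}")
    verts, faces = _deduplicate(np.asarray(tm.vertices, float), np.asarray(tm.faces))
    mesh = SurfaceMesh(verts, faces, region_tag)
    mesh.watertight = is_watertight(mesh)
    if not mesh.watertight:
        warnings.warn(f"surface {path} is not watertight (tag={region_tag!r})")
    return mesh


def write_surface(path: str | os.PathLike, mesh: SurfaceMesh) -> None:
    mesh.to_trimesh().export(str(path))


def _deduplicate(vertices: np.ndarray, faces: np.ndarray, tol: float = 1e-6):
    """Merge vertices closer than ``tol`` (by rounded-coordinate hashing)."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_faces = rank[inverse][faces]
    keep = ~(
        (new_faces[:, 0] == new_faces[:, 1])
        | (new_faces[:, 1] == new_faces[:, 2])
        | (new_faces[:, 0] == new_faces[:, 2])
    )
    return vertices[first[order]], new_faces[keep]


def is_watertight(mesh: SurfaceMesh) -> bool:
    """True iff every edge borders exactly two triangles."""
    if mesh.n_triangles == 0:
        return False
    tri = mesh.triangles
    edges = np.sort(
        np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


# ---------------------------------------------------------------------------
# FE meshes
# ---------------------------------------------------------------------------

def read_fe_mesh(path: str | os.PathLike, dialect: str | None = None) -> FEMesh:
    """Read an FE mesh; ``dialect`` is 'lsdyna_keyword', 'vtk' or None (guess
    from the extension: .k/.key/.dyn → keyword, .vtk → legacy VTK)."""
    path = Path(path)
    if dialect is None:
        dialect = "vtk" if path.suffix.lower() == ".vtk" else "lsdyna_keyword"
    if dialect == "lsdyna_keyword":
        return _read_lsdyna(path)
    if dialect == "vtk":
        return _read_vtk(path)
    raise ValueError(f"unknown FE mesh dialect: {dialect}")


def write_fe_mesh(path: str | os.PathLike, mesh: FEMesh, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "vtk" if path.suffix.lower() == ".vtk" else "lsdyna_keyword"
    if dialect == "lsdyna_keyword":
        _write_lsdyna(path, mesh)
    elif dialect == "vtk":
        _write_vtk(path, mesh)
    else:
        raise ValueError(f"unknown FE mesh dialect: {dialect}")


_HANDLED_KEYWORDS = ("*NODE", "*ELEMENT_SOLID", "*ELEMENT_SHELL", "*PART", "*CONTACT")


def _split_fields(line: str, widths: tuple[int, ...]) -> list[str]:
    """Split an LS-DYNA card: comma-separated if a comma is present, else
    fixed-width columns."""
    if "," in line:
        return [f.strip() for f in line.split(",")]
    fields, pos = [], 0
    for w in widths:
        fields.append(line[pos : pos + w].strip())
        pos += w
    while fields and fields[-1] == "":
        fields.pop()
    return fields


def _read_lsdyna(path: Path) -> FEMesh:
    text = path.read_text()
    if "*NODE" not in text.upper():
        raise FormatError(f"no *NODE block in {path}")
    # split into keyword blocks, dropping $ comments
    blocks: list[tuple[str, list[str]]] = []
    current: list[str] | None = None
    for raw in text.splitlines():
        if raw.startswith("$"):
            continue
        if raw.startswith("*"):
            current = []
            blocks.append((raw.strip().upper(), current))
        elif current is not None and raw.strip():
            current.append(raw)

    node_ids: list[int] = []
    coords: list[list[float]] = []
    sol_ids, sol_parts, sol_conn = [], [], []
    sh_ids, sh_parts, sh_conn = [], [], []
    contact_pairs: list[tuple[int, int]] = []
    part_titles: dict[int, str] = {}
    extra: list[str] = []

    for key, lines in blocks:
        if key == "*NODE":
            for ln in lines:
                f = _split_fields(ln, (8, 16, 16, 16))
                node_ids.append(int(f[0]))
                coords.append([float(f[1] or 0), float(f[2] or 0), float(f[3] or 0)])
        elif key.startswith("*ELEMENT_SOLID"):
            for ln in lines:
                f = _split_fields(ln, (8,) * 10)
                vals = [int(v) for v in f if v != ""]
                eid, pid, nodes = vals[0], vals[1], vals[2:]
                if len(nodes) == 4:  # tet: repeat 4th node, LS-DYNA style
                    nodes = nodes + [nodes[3]] * 4
                if len(nodes) != 8:
                    raise FormatError(f"solid element {eid} has {len(nodes)} nodes")
                sol_ids.append(eid)
                sol_parts.append(pid)
                sol_conn.append(nodes)
        elif key.startswith("*ELEMENT_SHELL"):
            for ln in lines:
                f = _split_fields(ln, (8,) * 6)
                vals = [int(v) for v in f if v != ""]
                eid, pid, nodes = vals[0], vals[1], vals[2:]
                if len(nodes) == 3:
                    nodes = nodes + [nodes[2]]
                if len(nodes) != 4:
                    raise FormatError(f"shell element {eid} has {len(nodes)} nodes")
                sh_ids.append(eid)
                sh_parts.append(pid)
                sh_conn.append(nodes)
        elif key.startswith("*PART"):
            # title line then id line (first field)
            if len(lines) >= 2:
                pid = int(_split_fields(lines[1], (10,) * 8)[0])
                part_titles[pid] = lines[0].strip()
            elif len(lines) == 1:
                pid = int(_split_fields(lines[0], (10,) * 8)[0])
                part_titles[pid] = ""
        elif key.startswith("*CONTACT"):
            # simplified surface-to-surface card: first data line holds
            # "ssid msid ..." interpreted as part IDs
            if lines:
                f = _split_fields(lines[0], (10,) * 8)
                contact_pairs.append((int(f[0]), int(f[1])))
        elif key in ("*KEYWORD", "*END"):
            continue
        else:
            extra.append("\n".join([key] + lines))

    mesh = FEMesh(
        np.asarray(node_ids, np.int64),
        np.asarray(coords, float),
        ElementBlock(np.asarray(sol_ids, np.int64), np.asarray(sol_parts, np.int64),
                     np.asarray(sol_conn, np.int64).reshape(-1, 8)),
        ElementBlock(np.asarray(sh_ids, np.int64), np.asarray(sh_parts, np.int64),
                     np.asarray(sh_conn, np.int64).reshape(-1, 4)),
        contact_pairs,
        part_titles,
        extra,
    )
    return mesh


def _write_lsdyna(path: Path, mesh: FEMesh) -> None:
    out = ["*KEYWORD"]
    for pid in sorted(mesh.part_titles):
        out.append("*PART")
        out.append(mesh.part_titles[pid] or f"part_{pid}")
        out.append(f"{pid:10d}")
    out.append("*NODE")
    for nid, (x, y, z) in zip(mesh.node_ids, mesh.node_coords):
        out.append(f"{nid:8d}{x:16.8f}{y:16.8f}{z:16.8f}")
    if len(mesh.solids):
        out.append("*ELEMENT_SOLID")
        for eid, pid, conn in zip(mesh.solids.ids, mesh.solids.parts, mesh.solids.conn):
            out.append(f"{eid:8d}{pid:8d}" + "".join(f"{n:8d}" for n in conn))
    if len(mesh.shells):
        out.append("*ELEMENT_SHELL")
        for eid, pid, conn in zip(mesh.shells.ids, mesh.shells.parts, mesh.shells.conn):
            out.append(f"{eid:8d}{pid:8d}" + "".join(f"{n:8d}" for n in conn))
    for a, b in mesh.contact_pairs:
        out.append("*CONTACT_AUTOMATIC_SURFACE_TO_SURFACE")
        out.append(f"{a:10d}{b:10d}{3:10d}{3:10d}")
    out.extend(mesh.extra_cards)
    out.append("*END")
    path.write_text("\n".join(out) + "\n")


_VTK_HEX, _VTK_TET, _VTK_QUAD, _VTK_TRI = 12, 10, 9, 5


def _read_vtk(path: Path) -> FEMesh:
    """Minimal legacy-ASCII VTK unstructured grid reader (points, cells,
    CELL_DATA part IDs as written by :func:`_write_vtk`)."""
    tokens = iter(re.split(r"\s+", path.read_text().strip()))

    def take(n):
        return [next(tokens) for _ in range(n)]

    points = None
    cells = None
    types = None
    parts = None
    for tok in tokens:
        up = tok.upper()
        if up == "POINTS":
            n = int(next(tokens))
            next(tokens)  # dtype
            points = np.array(take(3 * n), float).reshape(n, 3)
        elif up == "CELLS":
            n = int(next(tokens))
            size = int(next(tokens))
            flat = np.array(take(size), np.int64)
            cells, pos = [], 0
            for _ in range(n):
                k = flat[pos]
                cells.append(flat[pos + 1 : pos + 1 + k])
                pos += 1 + k
        elif up == "CELL_TYPES":
            n = int(next(tokens))
            types = np.array(take(n), np.int64)
        elif up == "SCALARS":
            next(tokens)  # name
            next(tokens)  # dtype
        elif up == "LOOKUP_TABLE":
            next(tokens)
            parts = np.array(take(len(cells)), np.int64)
    if points is None or cells is None or types is None:
        raise FormatError(f"not a legacy VTK unstructured grid: {path}")
    if parts is None:
        parts = np.ones(len(cells), np.int64)

    node_ids = np.arange(1, len(points) + 1, dtype=np.int64)
    sol_ids, sol_parts, sol_conn = [], [], []
    sh_ids, sh_parts, sh_conn = [], [], []
    eid = 0
    for cell, ctype, pid in zip(cells, types, parts):
        eid += 1
        conn = (cell + 1).tolist()
        if ctype == _VTK_HEX:
            sol_ids.append(eid); sol_parts.append(pid); sol_conn.append(conn)
        elif ctype == _VTK_TET:
            sol_ids.append(eid); sol_parts.append(pid); sol_conn.append(conn + [conn[3]] * 4)
        elif ctype == _VTK_QUAD:
            sh_ids.append(eid); sh_parts.append(pid); sh_conn.append(conn)
        elif ctype == _VTK_TRI:
            sh_ids.append(eid); sh_parts.append(pid); sh_conn.append(conn + [conn[2]])
        else:
            raise FormatError(f"unsupported VTK cell type {ctype}")
    return FEMesh(
        node_ids,
        points,
        ElementBlock(np.asarray(sol_ids, np.int64), np.asarray(sol_parts, np.int64),
                     np.asarray(sol_conn, np.int64).reshape(-1, 8)),
        ElementBlock(np.asarray(sh_ids, np.int64), np.asarray(sh_parts, np.int64),
                     np.asarray(sh_conn, np.int64).reshape(-1, 4)),
    )


def _write_vtk(path: Path, mesh: FEMesh) -> None:
    index = mesh.id_to_index()
    lines = [
        "# vtk DataFile Version 3.0",
        "morphforge unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y, z in mesh.node_coords:
        lines.append(f"{x:.9g} {y:.9g} {z:.9g}")
    cells, types, parts = [], [], []
    for _, pid, conn in zip(mesh.solids.ids, mesh.solids.parts, mesh.solids.conn):
        idx = [index[int(n)] for n in conn]
        if idx[4] == idx[3] == idx[5] == idx[6] == idx[7]:  # degenerate hex = tet
            cells.append(idx[:4]); types.append(_VTK_TET)
        else:
            cells.append(idx); types.append(_VTK_HEX)
        parts.append(int(pid))
    for _, pid, conn in zip(mesh.shells.ids, mesh.shells.parts, mesh.shells.conn):
        idx = [index[int(n)] for n in conn]
        if idx[2] == idx[3]:
            cells.append(idx[:3]); types.append(_VTK_TRI)
        else:
            cells.append(idx); types.append(_VTK_QUAD)
        parts.append(int(pid))
    lines.append(f"CELLS {len(cells)} {sum(len(c) + 1 for c in cells)}")
    for c in cells:
        lines.append(str(len(c)) + " " + " ".join(map(str, c)))
    lines.append(f"CELL_TYPES {len(types)}")
    lines.extend(map(str, types))
    lines.append(f"CELL_DATA {len(parts)}")
    lines.append("SCALARS part_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(map(str, parts))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# images and displacement fields (NIfTI / MetaImage via SimpleITK)
# ---------------------------------------------------------------------------

def read_image(path: str | os.PathLike) -> LabelImage | DisplacementField:
    """Read a scalar image as :class:`LabelImage` or a 3-vector image as
    :class:`DisplacementField` (NIfTI or MetaImage)."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x[, c])
    spacing = np.asarray(img.GetSpacing())
    origin = np.asarray(img.GetOrigin())
    ncomp = img.GetNumberOfComponentsPerPixel()
    if ncomp == 1:
        data = np.ascontiguousarray(arr.transpose(2, 1, 0))
        if np.issubdtype(data.dtype, np.floating):
            data = np.rint(data).astype(np.int16)
        return LabelImage(data, spacing, origin)
    if ncomp == 3:
        data = np.ascontiguousarray(arr.transpose(2, 1, 0, 3)).astype(float)
        return DisplacementField(data, spacing, origin)
    raise FormatError(f"unsupported component count {ncomp} in {path}")


def write_image(path: str | os.PathLike, image: LabelImage | DisplacementField) -> None:
    if isinstance(image, DisplacementField):
        arr = np.ascontiguousarray(image.data.transpose(2, 1, 0, 3))
        img = sitk.GetImageFromArray(arr, isVector=True)
    else:
        arr = np.ascontiguousarray(image.data.transpose(2, 1, 0).astype(np.uint8))
        img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in image.spacing))
    img.SetOrigin(tuple(float(o) for o in image.origin))
    sitk.WriteImage(img, str(path))


def load_image_field_pair(image_path, field_path) -> tuple[LabelImage, DisplacementField]:
    """Load an image and its displacement field, enforcing a common grid."""
    img = read_image(image_path)
    fld = read_image(field_path)
    if not isinstance(img, LabelImage) or not isinstance(fld, DisplacementField):
        raise FormatError("expected a scalar image and a vector field")
    if not img.same_grid(fld, atol=1e-6):
        raise GridMismatchError(
            f"field grid does not match image grid: {image_path} vs {field_path}"
        )
    return img, fld
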