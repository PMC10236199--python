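"""Personalization accuracy metrics and mesh-health checks.

Accuracy: the baseline label image is warped through the inverse displacement
field (nearest-neighbour, labels never blended) and compared to the subject's
image with DICE and the 95th-percentile Hausdorff distance; per-vertex
surface distance maps localize residual error.  Health: per-element scaled
Jacobian, aspect ratio and minimum edge length, plus strict contact-surface
penetration counting.

Metric conventions (fixed so reported numbers are reproducible):
  * "flesh" masks are label==1, i.e. the body minus the skeleton.
  * Hausdorff distances are measured between boundary-voxel center sets in
    world mm; HD95 is the max of the two directed 95th percentiles.
  * Contact intersections count strict penetrations only - coplanar or
    exactly touching faces do not count.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import DisplacementField, FEMesh, LabelImage, SurfaceMesh


class EmptyMaskError(ValueError):
    """A metric was requested on an empty voxel set."""


LABEL_SETS = {
    "flesh": (1,),        # body minus skeleton
    "skeleton": (2,),
    "body": (1, 2),       # whole foreground
}


def _mask(image: LabelImage, labels) -> np.ndarray:
    if isinstance(labels, str):
        labels = LABEL_SETS[labels]
    return np.isin(image.data, list(labels))


# ---------------------------------------------------------------------------
# image-space metrics
# ---------------------------------------------------------------------------

def warp_image(img: LabelImage, u_inv: DisplacementField) -> LabelImage:
    """Warp a label image through an (inverse) displacement field: the output
    voxel at x takes img's label at x + u_inv(x), nearest-neighbour."""
    img.require_same_grid(u_inv, "displacement field")
    idx = np.indices(img.shape, dtype=float)
    coords = [idx[a] + u_inv.data[..., a] / img.spacing[a] for a in range(3)]
    warped = ndimage.map_coordinates(
        img.data.astype(np.uint8), coords, order=0, mode="constant", cval=0
    )
    return img.like(warped.astype(np.uint8))


def dice(a: LabelImage, b: LabelImage, labels="body") -> float:
    """DICE(A,B) = 2|A∩B| / (|A|+|B|) over the voxel sets with the chosen
    labels; 1 is perfect overlap, 0 none.  Raises if both sets are empty."""
    a.require_same_grid(b, "second image")
    ma, mb = _mask(a, labels), _mask(b, labels)
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        raise EmptyMaskError(f"DICE undefined: both {labels!r} masks are empty")
    return 2.0 * int(np.logical_and(ma, mb).sum()) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def hausdorff(
    a: LabelImage, b: LabelImage, percentile: float = 95.0, labels="body"
) -> tuple[float, float]:
    """(HD, HDp) in mm between the boundary-voxel center sets of the two
    masks.  HD = max of the two directed maxima; HDp = max of the two
    directed p-th percentiles."""
    a.require_same_grid(b, "second image")
    ma, mb = _mask(a, labels), _mask(b, labels)
    if not ma.any() or not mb.any():
        raise EmptyMaskError(f"Hausdorff undefined: empty {labels!r} mask")
    ba, bb = _boundary(ma), _boundary(mb)
    # exact Euclidean distance (mm) to the nearest boundary voxel of the other set
    dt_b = ndimage.distance_transform_edt(~bb, sampling=a.spacing)
    dt_a = ndimage.distance_transform_edt(~ba, sampling=a.spacing)
    d_ab = dt_b[ba]
    d_ba = dt_a[bb]
    hd = max(float(d_ab.max()), float(d_ba.max()))
    hdp = max(
        float(np.percentile(d_ab, percentile)), float(np.percentile(d_ba, percentile))
    )
    return hd, hdp


@dataclass
class EvalReport:
    """Accuracy metrics of one personalization run."""

    dice_flesh: float
    dice_body: float
    dice_skeleton: float | None
    hd_mm: float
    hd95_mm: float
    skin_distance_mean_mm: float | None = None
    skin_distance_p95_mm: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def evaluate_images(warped: LabelImage, subject: LabelImage) -> EvalReport:
    """DICE/HD metrics of a warped baseline image against the subject truth.

    Flesh (label 1) is the primary region; skeleton DICE is reported but can
    be misleading when baseline and subject skeletons differ topologically.
    """
    hd, hd95 = hausdorff(warped, subject, labels="flesh")
    try:
        dsk = dice(warped, subject, labels="skeleton")
    except EmptyMaskError:
        dsk = None
    return EvalReport(
        dice_flesh=dice(warped, subject, labels="flesh"),
        dice_body=dice(warped, subject, labels="body"),
        dice_skeleton=dsk,
        hd_mm=hd,
        hd95_mm=hd95,
    )


# ---------------------------------------------------------------------------
# surface distance maps
# ---------------------------------------------------------------------------

def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from each point to each triangle: (n_pts, n_tri).

    Vectorized closest-point-on-triangle (region classification on
    barycentric coordinates)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    p = points[:, None, :]
    ap = p - a[None, :, :]
    d1 = np.einsum("tj,ptj->pt", ab, ap)
    d2 = np.einsum("tj,ptj->pt", ac, ap)
    bp = p - b[None, :, :]
    d3 = np.einsum("tj,ptj->pt", ab, bp)
    d4 = np.einsum("tj,ptj->pt", ac, bp)
    cp = p - c[None, :, :]
    d5 = np.einsum("tj,ptj->pt", ab, cp)
    d6 = np.einsum("tj,ptj->pt", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = np.maximum(va + vb + vc, 1e-300)
    v = np.clip(vb / denom, 0.0, 1.0)
    w = np.clip(vc / denom, 0.0, 1.0)
    closest = a[None] + v[..., None] * ab[None] + w[..., None] * ac[None]

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest = np.where(m[..., None], a[None], closest)
    m = (d3 >= 0) & (d4 <= d3)
    closest = np.where(m[..., None], b[None], closest)
    m = (d6 >= 0) & (d5 <= d6)
    closest = np.where(m[..., None], c[None], closest)
    # edge AB
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = np.where(np.abs(d1 - d3) > 1e-300, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0)
    t = np.clip(t, 0.0, 1.0)
    closest = np.where(m[..., None], a[None] + t[..., None] * ab[None], closest)
    # edge AC
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = np.clip(d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0, 1.0)
    closest = np.where(m[..., None], a[None] + t[..., None] * ac[None], closest)
    # edge BC
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    t = np.clip(num / np.where(den == 0, 1, den), 0.0, 1.0)
    closest = np.where(m[..., None], b[None] + t[..., None] * (c - b)[None], closest)

    return np.linalg.norm(p - closest, axis=-1)


def surface_distance_map(
    test: SurfaceMesh, reference: SurfaceMesh, chunk: int = 256
) -> np.ndarray:
    """Per-vertex distance (mm) from each ``test`` vertex to the nearest
    point on the ``reference`` triangles (point-to-triangle, not
    vertex-to-vertex)."""
    if test.n_vertices == 0 or reference.n_triangles == 0:
        raise ValueError("surface_distance_map needs nonempty meshes")
    tri = reference.triangle_coords()
    centroids = tri.mean(axis=1)
    radius = np.linalg.norm(tri - centroids[:, None, :], axis=-1).max(axis=1)
    rmax = float(radius.max())
    tree = cKDTree(centroids)
    out = np.empty(test.n_vertices)
    for s in range(0, test.n_vertices, chunk):
        pts = test.vertices[s : s + chunk]
        # upper bound from nearest centroid, then exact on a safe candidate set
        d_hint, _ = tree.query(pts)
        d_all = _point_triangle_distance(pts, tri) if len(tri) <= 2048 else None
        if d_all is not None:
            out[s : s + chunk] = d_all.min(axis=1)
            continue
        for i, (p, dh) in enumerate(zip(pts, d_hint)):
            cand = tree.query_ball_point(p, dh + 2.0 * rmax)
            d = _point_triangle_distance(p[None], tri[cand])
            out[s + i] = d.min()
    return out


# ---------------------------------------------------------------------------
# element quality
# ---------------------------------------------------------------------------

# hex corner -> (three adjacent corners) ordered right-handed for the
# standard node numbering (0-3 bottom counterclockwise, 4-7 top)
_HEX_CORNERS = (
    (0, (1, 3, 4)),
    (1, (2, 0, 5)),
    (2, (3, 1, 6)),
    (3, (0, 2, 7)),
    (4, (7, 5, 0)),
    (5, (4, 6, 1)),
    (6, (5, 7, 2)),
    (7, (6, 4, 3)),
)
_HEX_EDGES = (
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
)
_TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class QualityReport:
    """Per-element quality of a volume mesh.

    scaled_jacobian: 1 for an ideal rectangular hex, <=0 for inverted;
    aspect_ratio: longest/shortest element edge (>=1); min_edge: shortest
    edge (mm).  Degenerate elements (an edge below ``eps``) are excluded from
    the ratio metrics and counted separately.
    """

    element_ids: np.ndarray
    part_ids: np.ndarray
    scaled_jacobian: np.ndarray
    aspect_ratio: np.ndarray
    min_edge: np.ndarray
    degenerate_ids: np.ndarray = dc_field(default_factory=lambda: np.empty(0, np.int64))

    def fraction(self, metric: str, predicate) -> float:
        values = getattr(self, metric)
        return float(np.mean(predicate(values))) if len(values) else float("nan")

    def summary(self) -> dict:
        def stats(v):
            return {
                "min": float(v.min()), "mean": float(v.mean()), "max": float(v.max()),
            } if len(v) else {}

        return {
            "n_elements": int(len(self.element_ids)),
            "n_degenerate": int(len(self.degenerate_ids)),
            "scaled_jacobian": stats(self.scaled_jacobian),
            "aspect_ratio": stats(self.aspect_ratio),
            "min_edge_mm": stats(self.min_edge),
            "frac_jacobian_ge_0.5": self.fraction("scaled_jacobian", lambda v: v >= 0.5),
            "frac_aspect_le_3": self.fraction("aspect_ratio", lambda v: v <= 3.0),
        }

    def histograms(self, bins: int = 20) -> dict:
        """Per-part histogram summaries of the three metrics."""
        out = {}
        for pid in np.unique(self.part_ids):
            sel = self.part_ids == pid
            out[int(pid)] = {
                name: np.histogram(getattr(self, name)[sel], bins=bins)
                for name in ("scaled_jacobian", "aspect_ratio", "min_edge")
            }
        return out


def element_quality(mesh: FEMesh, eps: float = 1e-12) -> QualityReport:
    """Scaled Jacobian, aspect ratio and min edge length for all solid
    elements (8-node hexes; 4-node tets scaled via normalized volume)."""
    if len(mesh.solids) == 0:
        raise ValueError("element_quality needs solid elements")
    idx = mesh.conn_indices(mesh.solids)
    xyz = mesh.node_coords[idx]  # (m, 8, 3)
    is_tet = np.all(idx[:, 4:] == idx[:, 3:4], axis=1) & (idx[:, 3] != idx[:, 2])
    # a fully collapsed hex written tet-style has nodes 4..7 == node 3
    is_hex = ~is_tet

    m = len(idx)
    sj = np.empty(m)
    ar = np.empty(m)
    mn = np.empty(m)
    degen = np.zeros(m, dtype=bool)

    if is_hex.any():
        h = xyz[is_hex]
        edges = np.stack(
            [np.linalg.norm(h[:, j] - h[:, i], axis=-1) for i, j in _HEX_EDGES], axis=1
        )
        mn[is_hex] = edges.min(axis=1)
        degen[is_hex] = edges.min(axis=1) < eps
        with np.errstate(divide="ignore", invalid="ignore"):
            ar[is_hex] = edges.max(axis=1) / edges.min(axis=1)
        corner = np.full(h.shape[0], np.inf)
        for i, (a, b, c) in _HEX_CORNERS:
            e1 = h[:, a] - h[:, i]
            e2 = h[:, b] - h[:, i]
            e3 = h[:, c] - h[:, i]
            det = np.einsum("ij,ij->i", np.cross(e1, e2), e3)
            norms = (
                np.linalg.norm(e1, axis=-1)
                * np.linalg.norm(e2, axis=-1)
                * np.linalg.norm(e3, axis=-1)
            )
            corner = np.minimum(corner, det / np.maximum(norms, eps))
        sj[is_hex] = corner

    if is_tet.any():
        t = xyz[is_tet][:, :4]
        edges = np.stack(
            [np.linalg.norm(t[:, j] - t[:, i], axis=-1) for i, j in _TET_EDGES], axis=1
        )
        mn[is_tet] = edges.min(axis=1)
        degen[is_tet] = edges.min(axis=1) < eps
        with np.errstate(divide="ignore", invalid="ignore"):
            ar[is_tet] = edges.max(axis=1) / edges.min(axis=1)
        e1, e2, e3 = t[:, 1] - t[:, 0], t[:, 2] - t[:, 0], t[:, 3] - t[:, 0]
        vol = np.einsum("ij,ij->i", np.cross(e1, e2), e3) / 6.0
        l_rms = np.sqrt(np.mean(edges**2, axis=1))
        sj[is_tet] = 6.0 * np.sqrt(2.0) * vol / np.maximum(l_rms, eps) ** 3

    keep = ~degen
    return QualityReport(
        mesh.solids.ids[keep],
        mesh.solids.parts[keep],
        np.clip(sj[keep], -1.0, 1.0),
        ar[keep],
        mn[keep],
        mesh.solids.ids[degen],
    )


# ---------------------------------------------------------------------------
# contact intersection checking
# ---------------------------------------------------------------------------

_HEX_FACES = (
    (0, 3, 2, 1), (4, 5, 6, 7),
    (0, 1, 5, 4), (1, 2, 6, 5),
    (2, 3, 7, 6), (3, 0, 4, 7),
)


def part_boundary_triangles(mesh: FEMesh, part_id: int):
    """Boundary surface of a part, triangulated: (tri_coords (n,3,3),
    parent element ids (n,))."""
    face_count: dict[tuple, tuple] = {}
    sel = mesh.solids.parts == part_id
    idx_all = mesh.conn_indices(mesh.solids)
    for eid, conn in zip(mesh.solids.ids[sel], idx_all[sel]):
        for f in _HEX_FACES:
            nodes = []
            for k in f:
                if conn[k] not in nodes:
                    nodes.append(conn[k])
            if len(nodes) < 3:
                continue
            key = tuple(sorted(nodes))
            if key in face_count:
                face_count[key] = (face_count[key][0] + 1, face_count[key][1])
            else:
                face_count[key] = (1, (int(eid), tuple(nodes)))
    tris, parents = [], []
    for key, (count, payload) in face_count.items():
        if count != 1:
            continue
        eid, nodes = payload
        if len(nodes) == 3:
            tris.append(nodes)
            parents.append(eid)
        else:
            tris.append((nodes[0], nodes[1], nodes[2]))
            tris.append((nodes[0], nodes[2], nodes[3]))
            parents.extend([eid, eid])
    # shell elements belonging to the part are boundary faces in their own right
    ssel = mesh.shells.parts == part_id
    if ssel.any():
        sidx = mesh.conn_indices(mesh.shells)[ssel]
        for eid, conn in zip(mesh.shells.ids[ssel], sidx):
            nodes = [conn[0], conn[1], conn[2]]
            tris.append(tuple(nodes))
            parents.append(int(eid))
            if conn[3] != conn[2]:
                tris.append((conn[0], conn[2], conn[3]))
                parents.append(int(eid))
    if not tris:
        raise ValueError(f"part {part_id} has no boundary faces")
    tri_idx = np.asarray(tris, dtype=np.int64)
    return mesh.node_coords[tri_idx], np.asarray(parents, dtype=np.int64)


def triangles_intersect(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Pairwise strict-intersection test for triangle arrays (n,3,3) each.

    Returns a boolean per pair.  Coplanar or merely touching configurations
    (contact within ``eps``) count as non-intersecting."""
    t1 = np.asarray(t1, float).reshape(-1, 3, 3)
    t2 = np.asarray(t2, float).reshape(-1, 3, 3)
    n = len(t1)
    result = np.zeros(n, dtype=bool)
    if n == 0:
        return result

    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    d1 = np.einsum("nj,nkj->nk", n2, t1 - t2[:, 0:1])
    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    d2 = np.einsum("nj,nkj->nk", n1, t2 - t1[:, 0:1])
    scale1 = np.linalg.norm(n2, axis=1, keepdims=True) + 1e-300
    scale2 = np.linalg.norm(n1, axis=1, keepdims=True) + 1e-300
    d1n = d1 / scale1  # true signed distances
    d2n = d2 / scale2

    crossing = ~(
        np.all(d1n >= -eps, axis=1) | np.all(d1n <= eps, axis=1)
        | np.all(d2n >= -eps, axis=1) | np.all(d2n <= eps, axis=1)
    )
    if not crossing.any():
        return result

    axis = np.cross(n1, n2)
    p1 = np.einsum("nj,nkj->nk", axis, t1)
    p2 = np.einsum("nj,nkj->nk", axis, t2)

    def interval(d, p):
        lo = np.full(len(d), np.inf)
        hi = np.full(len(d), -np.inf)
        for i in range(3):
            j = (i + 1) % 3
            cross_edge = d[:, i] * d[:, j] < 0  # strictly opposite signs
            with np.errstate(divide="ignore", invalid="ignore"):
                t = d[:, i] / (d[:, i] - d[:, j])
            val = p[:, i] + t * (p[:, j] - p[:, i])
            lo = np.where(cross_edge, np.minimum(lo, val), lo)
            hi = np.where(cross_edge, np.maximum(hi, val), hi)
        return lo, hi

    lo1, hi1 = interval(d1n, p1)
    lo2, hi2 = interval(d2n, p2)
    margin = eps * (np.linalg.norm(axis, axis=1) + 1e-300)
    overlap = (np.minimum(hi1, hi2) - np.maximum(lo1, lo2)) > margin
    result[crossing & np.isfinite(lo1) & np.isfinite(lo2)] = overlap[
        crossing & np.isfinite(lo1) & np.isfinite(lo2)
    ]
    return result


def count_contact_intersections(
    mesh: FEMesh, pairs: list[tuple[int, int]] | None = None
) -> tuple[int, list[tuple[int, int]]]:
    """Count strictly penetrating boundary-face pairs between the parts of
    each declared contact pair.

    Returns ``(count, element_id_pairs)`` with the offending element ID
    pairs sorted deterministically.  Face pairs sharing a node (stitched
    interfaces of conformal meshes) are skipped.
    """
    if pairs is None:
        pairs = mesh.contact_pairs
    hits: set[tuple[int, int]] = set()
    total = 0
    for pa, pb in pairs:
        tri_a, par_a = part_boundary_triangles(mesh, pa)
        tri_b, par_b = part_boundary_triangles(mesh, pb)
        cen_a = tri_a.mean(axis=1)
        cen_b = tri_b.mean(axis=1)
        rad_a = np.linalg.norm(tri_a - cen_a[:, None], axis=-1).max(axis=1)
        rad_b = np.linalg.norm(tri_b - cen_b[:, None], axis=-1).max(axis=1)
        tree_b = cKDTree(cen_b)
        rmax_b = float(rad_b.max())
        cand_i, cand_j = [], []
        for i, (c, r) in enumerate(zip(cen_a, rad_a)):
            for j in tree_b.query_ball_point(c, r + rmax_b):
                cand_i.append(i)
                cand_j.append(j)
        if not cand_i:
            continue
        ci = np.asarray(cand_i)
        cj = np.asarray(cand_j)
        # conformal shared nodes -> same coordinates; drop pairs sharing a vertex
        shared = np.zeros(len(ci), dtype=bool)
        for a in range(3):
            for b in range(3):
                shared |= np.all(
                    np.isclose(tri_a[ci][:, a], tri_b[cj][:, b], atol=1e-12), axis=1
                )
        ci, cj = ci[~shared], cj[~shared]
        if len(ci) == 0:
            continue
        inter = triangles_intersect(tri_a[ci], tri_b[cj])
        total += int(inter.sum())
        for i, j in zip(ci[inter], cj[inter]):
            hits.add((int(par_a[i]), int(par_b[j])))
    return total, sorted(hits)
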