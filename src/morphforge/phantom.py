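"""Parametric body phantoms with known ground truth.

A phantom is a watertight "skin" surface (ellipsoid or capsule torso), a set
of interior skeleton primitives (an ellipsoid "skull" tagged ``head``, a
cylinder "spine", optional bar "limbs"), a matched structured hexahedral FE
mesh (flesh part 1, skeleton part 2, contact pair (1,2)), and a family of
closed-form deformations with exact or fixed-point inverses.  Because every
deformation has an analytic point map, the phantom provides the recovery
oracle for the registration and morphing stages: register phantom vs
deformed phantom, then compare the estimated field and morphed nodes with
the closed-form truth.

The hex mesh is built from axis-aligned voxel blocks, so every baseline
element has scaled Jacobian and aspect ratio exactly 1: any quality change
after a morph is attributable to the morph alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import trimesh

from .core import DisplacementField, ElementBlock, FEMesh, LabelImage, SurfaceMesh
from .voxelizer import compute_grid, voxelize_union


class PhantomSpecError(ValueError):
    pass


@dataclass
class Primitive:
    """One skeleton primitive: ellipsoid (semi-axes), cylinder (radius,
    half-length along z) or bar (half-extents)."""

    kind: str  # ellipsoid | cylinder | bar
    size: tuple[float, ...]
    center: tuple[float, float, float]
    tag: str = "skeleton"

    def surface(self, subdivisions: int = 3) -> SurfaceMesh:
        if self.kind == "ellipsoid":
            tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
            verts = np.asarray(tm.vertices) * np.asarray(self.size)
        elif self.kind == "cylinder":
            r, hl = self.size
            tm = trimesh.creation.cylinder(radius=r, height=2 * hl, sections=32)
            verts = np.asarray(tm.vertices)
        elif self.kind == "bar":
            tm = trimesh.creation.box(extents=2 * np.asarray(self.size))
            verts = np.asarray(tm.vertices)
        else:
            raise PhantomSpecError(f"unknown primitive kind {self.kind!r}")
        return SurfaceMesh(verts + np.asarray(self.center), np.asarray(tm.faces), self.tag)

    def volume(self) -> float:
        if self.kind == "ellipsoid":
            a, b, c = self.size
            return 4.0 / 3.0 * np.pi * a * b * c
        if self.kind == "cylinder":
            r, hl = self.size
            return np.pi * r * r * 2 * hl
        if self.kind == "bar":
            return 8.0 * float(np.prod(self.size))
        raise PhantomSpecError(self.kind)


def _default_skeleton() -> list[Primitive]:
    return [
        Primitive("ellipsoid", (11.0, 9.0, 13.0), (0.0, 0.0, 48.0), tag="head"),
        Primitive("cylinder", (6.0, 42.0), (0.0, 0.0, -13.0), tag="skeleton"),
    ]


@dataclass
class PhantomSpec:
    """Fully determines a phantom (a given seed is bit-reproducible).

    body_size: ellipsoid semi-axes (mm) or (radius, cylinder-half-length)
    for a capsule.  mesh_resolution: hex edge length (mm).  jitter_mm:
    seeded radial vertex jitter on the skin, off by default so the analytic
    body volume stays exact.
    """

    body_kind: str = "ellipsoid"  # ellipsoid | capsule
    body_size: tuple[float, ...] = (30.0, 25.0, 70.0)
    skeleton: list[Primitive] = field(default_factory=_default_skeleton)
    mesh_resolution: float = 4.0
    jitter_mm: float = 0.0
    seed: int = 0
    subdivisions: int = 3

    def body_volume(self) -> float:
        if self.body_kind == "ellipsoid":
            a, b, c = self.body_size
            return 4.0 / 3.0 * np.pi * a * b * c
        if self.body_kind == "capsule":
            r, hl = self.body_size
            return np.pi * r * r * 2 * hl + 4.0 / 3.0 * np.pi * r**3
        raise PhantomSpecError(f"unknown body kind {self.body_kind!r}")

    def _inside_body(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        p = np.asarray(points, float)
        if self.body_kind == "ellipsoid":
            ax = np.asarray(self.body_size) - margin
            return np.sum((p / ax) ** 2, axis=-1) < 1.0
        r, hl = self.body_size
        zc = np.clip(p[..., 2], -hl, hl)
        d = p.copy()
        d[..., 2] -= zc
        return np.linalg.norm(d, axis=-1) < r - margin


@dataclass
class Phantom:
    """Generated geometry bundle: skin + skeleton surfaces and the FE mesh."""

    spec: PhantomSpec
    skin_surfaces: list[SurfaceMesh]
    skeleton_surfaces: list[SurfaceMesh]
    mesh: FEMesh

    @property
    def surfaces(self) -> list[SurfaceMesh]:
        return self.skin_surfaces + self.skeleton_surfaces

    def height(self) -> float:
        v = np.concatenate([s.vertices for s in self.skin_surfaces])
        return float(v[:, 2].max() - v[:, 2].min())


def _body_surface(spec: PhantomSpec) -> SurfaceMesh:
    if spec.body_kind == "ellipsoid":
        tm = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
        verts = np.asarray(tm.vertices) * np.asarray(spec.body_size)
        faces = np.asarray(tm.faces)
    elif spec.body_kind == "capsule":
        r, hl = spec.body_size
        tm = trimesh.creation.capsule(radius=r, height=2 * hl, count=(32, 32))
        verts = np.asarray(tm.vertices)
        faces = np.asarray(tm.faces)
    else:
        raise PhantomSpecError(f"unknown body kind {spec.body_kind!r}")
    if spec.jitter_mm > 0:
        rng = np.random.default_rng(spec.seed)
        normals = verts / np.maximum(np.linalg.norm(verts, axis=1, keepdims=True), 1e-12)
        verts = verts + normals * rng.normal(0.0, spec.jitter_mm, size=(len(verts), 1))
    return SurfaceMesh(verts, faces, "skin")


def _block_hex_mesh(spec: PhantomSpec, skin: list[SurfaceMesh],
                    skeleton: list[SurfaceMesh]) -> FEMesh:
    h = spec.mesh_resolution
    grid = compute_grid(skin + skeleton, voxel_size=h, padding=0.0)
    body_mask = voxelize_union(skin, grid)
    skel_mask = voxelize_union(skeleton, grid) if skeleton else np.zeros_like(body_mask)
    skel_mask &= body_mask
    nx, ny, nz = grid.shape
    lo = grid.origin - grid.spacing / 2.0  # lower corner of cell (0,0,0)

    cells = np.argwhere(body_mask)
    parts = np.where(skel_mask[tuple(cells.T)], 2, 1)

    def node_id(i, j, k):
        return 1 + i + j * (nx + 1) + k * (nx + 1) * (ny + 1)

    i, j, k = cells[:, 0], cells[:, 1], cells[:, 2]
    conn = np.stack(
        [
            node_id(i, j, k), node_id(i + 1, j, k),
            node_id(i + 1, j + 1, k), node_id(i, j + 1, k),
            node_id(i, j, k + 1), node_id(i + 1, j, k + 1),
            node_id(i + 1, j + 1, k + 1), node_id(i, j + 1, k + 1),
        ],
        axis=1,
    )
    used = np.unique(conn)
    lin = used - 1
    kk, rem = np.divmod(lin, (nx + 1) * (ny + 1))
    jj, ii = np.divmod(rem, nx + 1)
    coords = lo + np.stack([ii, jj, kk], axis=1) * grid.spacing
    eids = np.arange(1, len(cells) + 1, dtype=np.int64)
    order = np.argsort(parts, kind="stable")  # flesh block then skeleton block
    return FEMesh(
        used.astype(np.int64),
        coords,
        ElementBlock(eids, parts[order], conn[order]),
        contact_pairs=[(1, 2)],
        part_titles={1: "flesh", 2: "skeleton"},
    )


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Generate surfaces and the matched structured hex mesh."""
    spec = spec or PhantomSpec()
    skin = _body_surface(spec)
    skeleton = [p.surface(spec.subdivisions) for p in spec.skeleton]
    for prim, surf in zip(spec.skeleton, skeleton):
        if not np.all(spec._inside_body(surf.vertices)):
            raise PhantomSpecError(
                f"skeleton primitive {prim.kind}@{prim.center} escapes the body"
            )
    mesh = _block_hex_mesh(spec, [skin], skeleton)
    return Phantom(spec, [skin], skeleton, mesh)


# ---------------------------------------------------------------------------
# analytic deformations
# ---------------------------------------------------------------------------

@dataclass
class Deformation:
    """Closed-form point map x -> phi(x) with an exact or fixed-point
    inverse; supplies ground-truth displacement fields for registration
    recovery tests.

    Kinds:
      uniform_scale(s)               - isotropic scaling about ``center``
      axis_scale(sx, sy, sz)         - anisotropic scaling about ``center``
      belly_bulge(amplitude, radius) - outward Gaussian push along
                                       ``direction``, sigma = radius/2,
                                       peak displacement = amplitude at
                                       ``center`` (put it on the belly skin)
      bend(angle_deg, z0, z1)        - rotation about the x-axis line through
                                       z0, angle ramping linearly to
                                       angle_deg between z0 and z1
      none                           - identity
    """

    kind: str = "none"
    params: tuple[float, ...] = ()
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        known = {"none", "uniform_scale", "axis_scale", "belly_bulge", "bend"}
        if self.kind not in known:
            raise ValueError(f"unsupported deformation {self.kind!r}; one of {sorted(known)}")
        if self.kind == "belly_bulge":
            amp, radius = self.params
            sigma = radius / 2.0
            if amp / (sigma * np.sqrt(np.e)) >= 1.0:
                raise ValueError(
                    "belly_bulge too sharp to stay a diffeomorphism: need "
                    f"amplitude < radius/2*sqrt(e), got {self.params}"
                )

    # --- forward map -------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        c = np.asarray(self.center)
        if self.kind == "none":
            return p.copy()
        if self.kind == "uniform_scale":
            (s,) = self.params
            return c + s * (p - c)
        if self.kind == "axis_scale":
            s = np.asarray(self.params)
            return c + s * (p - c)
        if self.kind == "belly_bulge":
            amp, radius = self.params
            sigma = radius / 2.0
            d = np.asarray(self.direction) / np.linalg.norm(self.direction)
            r2 = np.sum((p - c) ** 2, axis=-1, keepdims=True)
            return p + amp * np.exp(-r2 / (2 * sigma**2)) * d
        if self.kind == "bend":
            angle_deg, z0, z1 = self.params
            t = np.clip((p[..., 2] - z0) / (z1 - z0), 0.0, 1.0)
            theta = np.deg2rad(angle_deg) * t
            y = p[..., 1] - c[1]
            z = p[..., 2] - z0
            out = p.copy()
            out[..., 1] = c[1] + np.cos(theta) * y - np.sin(theta) * z
            out[..., 2] = z0 + np.sin(theta) * y + np.cos(theta) * z
            return out
        raise AssertionError(self.kind)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points) - np.asarray(points, float)

    # --- inverse map -------------------------------------------------------
    def inverse_apply(
        self, points: np.ndarray, tol: float = 1e-9, max_iter: int = 200
    ) -> np.ndarray:
        p = np.asarray(points, float)
        c = np.asarray(self.center)
        if self.kind == "none":
            return p.copy()
        if self.kind == "uniform_scale":
            (s,) = self.params
            return c + (p - c) / s
        if self.kind == "axis_scale":
            s = np.asarray(self.params)
            return c + (p - c) / s
        # fixed-point x <- y - u(x) for the displacement-style maps
        x = p.copy()
        for _ in range(max_iter):
            x_new = p - self.displacement(x)
            err = np.max(np.linalg.norm(x_new - x, axis=-1)) if x.size else 0.0
            x = x_new
            if err < tol:
                break
        return x

    def rasterize(self, grid: LabelImage) -> DisplacementField:
        """Exact displacement field phi(x)-x sampled at the grid's voxel
        centers (the ground truth a perfect registration would return)."""
        xs, ys, zs = grid.voxel_centers()
        pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        disp = self.displacement(pts.reshape(-1, 3)).reshape(pts.shape)
        return DisplacementField(disp, grid.spacing, grid.origin)


def deform_phantom(
    phantom: Phantom, deformation: Deformation, deform_skeleton: bool = True
) -> Phantom:
    """Apply a closed-form deformation to every surface vertex and mesh node.

    With ``deform_skeleton=False`` only the skin moves - the configuration
    used to show why the skeleton must take part in the registration.  The
    returned mesh nodes are then only meaningful for the skin/flesh."""

    def warp_surface(s: SurfaceMesh) -> SurfaceMesh:
        return replace(s, vertices=deformation.apply(s.vertices))

    skin = [warp_surface(s) for s in phantom.skin_surfaces]
    if deform_skeleton:
        skeleton = [warp_surface(s) for s in phantom.skeleton_surfaces]
    else:
        skeleton = [replace(s) for s in phantom.skeleton_surfaces]
    mesh = phantom.mesh.with_coords(deformation.apply(phantom.mesh.node_coords))
    return Phantom(phantom.spec, skin, skeleton, mesh)
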