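"""Core containers shared by every stage of the morphing pipeline.

All coordinates are world millimetres.  Images live on a regular grid whose
``origin`` is the world position of the *center* of voxel ``[0, 0, 0]`` and
whose axes are world-axis aligned (no direction matrix).  Arrays are indexed
``[ix, iy, iz]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# Label values used throughout: 0 background, 1 flesh, 2 skeleton.
BACKGROUND = 0
FLESH = 1
SKELETON = 2


class GridMismatchError(ValueError):
    """Two grid-based objects do not share shape/spacing/origin."""


class MeshIntegrityError(ValueError):
    """An FE mesh references nodes that do not exist."""


@dataclass
class AffineTransform:
    """World-space affine map ``y = A @ x + t`` with composition helpers."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t: Sequence[float]) -> "AffineTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def scaling(cls, factors: Sequence[float], center: Sequence[float]) -> "AffineTransform":
        f = np.asarray(factors, dtype=float)
        if np.any(f <= 0):
            raise ValueError(f"scale factors must be positive, got {f}")
        c = np.asarray(center, dtype=float)
        return cls(np.diag(f), c - f * c)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return ``self ∘ other`` (``other`` applied first)."""
        return AffineTransform(
            self.matrix @ other.matrix,
            self.matrix @ other.translation + self.translation,
        )

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.matrix, np.eye(3), atol=1e-12)
            and np.allclose(self.translation, 0.0, atol=1e-12)
        )


@dataclass
class _Grid:
    """Shared grid metadata + world/index conversions."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points (mm)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=float) * self.spacing + self.origin

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D world coordinates of voxel centers along each axis."""
        nx, ny, nz = self.shape
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(n)
            for a, n in enumerate((nx, ny, nz))
        )

    def same_grid(self, other: "_Grid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "_Grid", what: str = "operand") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch with {what}: shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )


@dataclass
class LabelImage(_Grid):
    """3-D integer label image: 0 background, 1 flesh, 2 skeleton."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.ascontiguousarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelImage data must be 3-D, got shape {self.data.shape}")

    @classmethod
    def empty(cls, shape, spacing, origin) -> "LabelImage":
        return cls(np.zeros(tuple(int(s) for s in shape), dtype=np.uint8), spacing, origin)

    def like(self, data: np.ndarray) -> "LabelImage":
        if data.shape[:3] != self.shape:
            raise GridMismatchError("replacement data has a different shape")
        return replace(self, data=data)

    def foreground(self) -> np.ndarray:
        return self.data > 0


@dataclass
class DisplacementField(_Grid):
    """Per-voxel 3-vector displacement (mm) on a fixed-image grid.

    Convention: a point ``x`` in fixed space corresponds to ``x + u(x)`` in
    moving space.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.ascontiguousarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError(
                f"DisplacementField data must be (nx,ny,nz,3), got {self.data.shape}"
            )

    @classmethod
    def zeros_like(cls, image: _Grid) -> "DisplacementField":
        return cls(np.zeros(image.shape + (3,)), image.spacing, image.origin)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)


@dataclass
class SurfaceMesh:
    """Watertight triangulated surface with a named region tag."""

    vertices: np.ndarray
    triangles: np.ndarray
    region_tag: str = ""
    watertight: bool | None = None  # None = not yet validated

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles) and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise IndexError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def transformed(self, transform: AffineTransform) -> "SurfaceMesh":
        return replace(self, vertices=transform.apply(self.vertices))

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh, region_tag: str = "") -> "SurfaceMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), region_tag)

    def triangle_coords(self) -> np.ndarray:
        """(n_triangles, 3, 3) vertex coordinates per triangle."""
        return self.vertices[self.triangles]


# Solid connectivity is stored LS-DYNA style: 8 columns, tets repeat the 4th
# node into columns 4..7.  Shells use 4 columns, triangles repeat the 3rd.
@dataclass
class ElementBlock:
    ids: np.ndarray
    parts: np.ndarray
    conn: np.ndarray  # node IDs, not positional indices

    def __post_init__(self) -> None:
        self.ids = np.ascontiguousarray(self.ids, dtype=np.int64)
        self.parts = np.ascontiguousarray(self.parts, dtype=np.int64)
        self.conn = np.ascontiguousarray(self.conn, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def empty(cls, width: int) -> "ElementBlock":
        return cls(np.empty(0, np.int64), np.empty(0, np.int64), np.empty((0, width), np.int64))


@dataclass
class FEMesh:
    """FE mesh: nodes + solid/shell elements with part IDs and contact pairs.

    Node and element IDs are opaque integers and are never renumbered; a morph
    only moves ``node_coords``.
    """

    node_ids: np.ndarray
    node_coords: np.ndarray
    solids: ElementBlock = field(default_factory=lambda: ElementBlock.empty(8))
    shells: ElementBlock = field(default_factory=lambda: ElementBlock.empty(4))
    contact_pairs: list[tuple[int, int]] = field(default_factory=list)
    part_titles: dict[int, str] = field(default_factory=dict)
    extra_cards: list[str] = field(default_factory=list)  # verbatim passthrough

    def __post_init__(self) -> None:
        self.node_ids = np.ascontiguousarray(self.node_ids, dtype=np.int64)
        self.node_coords = np.ascontiguousarray(self.node_coords, dtype=float).reshape(-1, 3)
        if len(self.node_ids) != len(self.node_coords):
            raise ValueError("node_ids and node_coords length mismatch")
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise MeshIntegrityError("duplicate node IDs")
        self._id_to_index = None
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def id_to_index(self) -> dict[int, int]:
        if self._id_to_index is None:
            self._id_to_index = {int(nid): i for i, nid in enumerate(self.node_ids)}
        return self._id_to_index

    def validate(self) -> None:
        known = set(int(i) for i in self.node_ids)
        for name, block in (("solid", self.solids), ("shell", self.shells)):
            if len(block) == 0:
                continue
            missing = sorted(set(int(n) for n in block.conn.ravel()) - known)
            if missing:
                raise MeshIntegrityError(
                    f"{name} elements reference missing node IDs: {missing[:20]}"
                )

    def conn_indices(self, block: ElementBlock) -> np.ndarray:
        """Positional node indices for a connectivity block."""
        lookup = self.id_to_index()
        return np.vectorize(lookup.__getitem__, otypes=[np.int64])(block.conn)

    def with_coords(self, coords: np.ndarray) -> "FEMesh":
        """Same mesh, new nodal coordinates (connectivity untouched)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.node_coords.shape:
            raise ValueError("coordinate array shape mismatch")
        return FEMesh(
            self.node_ids.copy(),
            coords.copy(),
            ElementBlock(self.solids.ids.copy(), self.solids.parts.copy(), self.solids.conn.copy()),
            ElementBlock(self.shells.ids.copy(), self.shells.parts.copy(), self.shells.conn.copy()),
            list(self.contact_pairs),
            dict(self.part_titles),
            list(self.extra_cards),
        )
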