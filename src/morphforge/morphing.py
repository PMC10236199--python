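"""Mesh morphing: apply a displacement field to FE mesh nodes, and the
surface "shielding" substitution used to keep selected regions unmorphed.

The nodal update is ``x_i = X_i + u_i`` where ``u_i`` is the trilinearly
interpolated displacement at node ``i``; element definitions, IDs, parts and
contact declarations are untouched.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import AffineTransform, DisplacementField, FEMesh, SurfaceMesh


def sample_field(
    u: DisplacementField,
    points: np.ndarray,
    outside_policy: str = "nearest",
) -> np.ndarray:
    """Trilinearly interpolate the field at world points (mm).

    ``outside_policy``: 'nearest' clamps to the border value, 'zero' returns
    a zero vector outside the grid, 'error' raises listing the offenders.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite query points")
    idx = u.world_to_index(pts)
    upper = np.asarray(u.shape, dtype=float) - 1.0
    outside = np.any((idx < 0) | (idx > upper), axis=1)
    if outside_policy == "error" and outside.any():
        bad = np.nonzero(outside)[0]
        raise ValueError(
            f"{len(bad)} points outside the field grid, first: "
            f"{pts[bad[:5]].tolist()}"
        )
    coords = [idx[:, a] for a in range(3)]
    out = np.stack(
        [
            ndimage.map_coordinates(u.data[..., c], coords, order=1, mode="nearest")
            for c in range(3)
        ],
        axis=-1,
    )
    if outside_policy == "zero":
        out[outside] = 0.0
    sample_field.last_outside_count = int(outside.sum())  # bookkeeping for callers
    return out


def morph_mesh(
    mesh: FEMesh,
    u: DisplacementField,
    pre_transform: AffineTransform | None = None,
    post_transform: AffineTransform | None = None,
    outside_policy: str = "nearest",
) -> FEMesh:
    """Morph nodes through the field: ``x_i = X_i + u(X_i)``.

    ``pre_transform`` moves the baseline nodes into the fixed-image space
    first (when the baseline was rigidly aligned); ``post_transform`` is
    applied to the displaced positions (e.g. the inverse global scaling of a
    pre-scaled subject).  The outside-grid node count is attached as
    ``result.meta['outside_nodes']``.
    """
    coords = mesh.node_coords
    if pre_transform is not None:
        coords = pre_transform.apply(coords)
    disp = sample_field(u, coords, outside_policy=outside_policy)
    n_outside = sample_field.last_outside_count
    if n_outside > 0.01 * len(coords):
        warnings.warn(
            f"{n_outside}/{len(coords)} mesh nodes fall outside the field grid"
        )
    new = coords + disp
    if post_transform is not None:
        new = post_transform.apply(new)
    if not np.all(np.isfinite(new)):
        raise ValueError("morph produced non-finite nodal coordinates")
    out = mesh.with_coords(new)
    out.meta = {"outside_nodes": n_outside}
    return out


def shield_regions(
    subject_surfaces: list[SurfaceMesh],
    baseline_surfaces: list[SurfaceMesh],
    regions: list[str],
) -> list[SurfaceMesh]:
    """Replace the subject's surfaces for the named regions with the
    baseline's, so those regions present no shape difference to the
    registration and therefore receive (near-)zero displacement.

    Baseline surfaces must already be rigidly aligned into subject space.
    Surfaces are matched by ``region_tag``; tags occurring several times are
    matched pairwise in order.
    """
    if not regions:
        return list(subject_surfaces)
    by_tag: dict[str, list[SurfaceMesh]] = {}
    for s in baseline_surfaces:
        by_tag.setdefault(s.region_tag, []).append(s)
    for r in regions:
        n_subj = sum(1 for s in subject_surfaces if s.region_tag == r)
        n_base = len(by_tag.get(r, []))
        if n_subj == 0 or n_base == 0:
            raise KeyError(f"region tag {r!r} missing from subject or baseline surfaces")
        if n_subj != n_base:
            raise KeyError(
                f"region tag {r!r}: {n_subj} subject vs {n_base} baseline surfaces"
            )
    counters = {r: 0 for r in regions}
    out = []
    for s in subject_surfaces:
        if s.region_tag in counters:
            k = counters[s.region_tag]
            counters[s.region_tag] += 1
            out.append(by_tag[s.region_tag][k])
        else:
            out.append(s)
    return out
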