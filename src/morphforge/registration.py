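"""Label-image registration: rigid pre-alignment, diffeomorphic Demons, and
displacement-field inversion.

The Demons registration here is the pipeline's core: given a *fixed* label
image (the baseline body model) and a *moving* label image (the subject), it
estimates a dense displacement field ``u`` on the fixed grid such that a
fixed-space point ``x`` corresponds to ``x + u(x)`` in moving space.  Each
iteration computes the classical Demons force with symmetric gradients,
smooths the update with a Gaussian of sigma ``smooth_factor`` voxels
(fluid-like regularization, default 2), maps it to a diffeomorphic step by
scaling-and-squaring of a stationary velocity, composes it with the
accumulated field, and mildly smooths the accumulated field
(``field_smooth``, diffusion-like).
A coarse-to-fine pyramid handles displacements larger than the gradient
support of the binarized inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .core import AffineTransform, DisplacementField, LabelImage


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationConfig:
    """Knobs of the Demons registration.

    smooth_factor
        Sigma (voxels) of the Gaussian applied to each update (velocity)
        before exponentiation - fluid-like regularization.  Default 2.
    field_smooth
        Sigma (voxels) of the Gaussian applied to the accumulated
        displacement field after every composition - mild diffusion-like
        regularization that propagates boundary motion into object
        interiors.  Default 1.
    presmooth
        Sigma (voxels) of the Gaussian applied once to the binarized label
        images so they carry usable gradients.  Default 0.5.
    iterations / shrink
        Per-pyramid-level iteration caps and integer shrink factors, coarse
        to fine; equal length.
    tol
        Convergence threshold on the mean update magnitude (voxels).
    per_label
        Register labels {1, 2} as separate binary channels whose forces are
        summed, instead of as one composite intensity image.
    """

    smooth_factor: float = 2.0
    field_smooth: float = 1.0
    presmooth: float = 0.5
    iterations: tuple[int, ...] = (100, 50, 25)
    shrink: tuple[int, ...] = (4, 2, 1)
    tol: float = 0.01
    per_label: bool = False
    max_step: float = 2.0  # clamp on raw update magnitude, voxels

    def __post_init__(self) -> None:
        if self.smooth_factor < 0:
            raise ValueError("smooth_factor must be >= 0")
        if len(self.iterations) != len(self.shrink):
            raise ValueError("iterations and shrink must have equal length")
        if any(i <= 0 for i in self.iterations):
            raise ValueError("iterations must be positive")


# ---------------------------------------------------------------------------
# voxel-space field algebra (displacements in voxel units, index order x,y,z)
# ---------------------------------------------------------------------------

def _identity_grid(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij"), axis=-1
    )


def _sample(volume: np.ndarray, coords: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample ``volume`` at continuous index coords (..., 3), edge-clamped."""
    return ndimage.map_coordinates(
        volume, [coords[..., a] for a in range(3)], order=order, mode="nearest"
    )


def _warp_scalar(img: np.ndarray, disp: np.ndarray, base: np.ndarray) -> np.ndarray:
    return _sample(img, base + disp)


def _compose(a: np.ndarray, b: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Displacement of the composed map x -> (x + b) -> (x + b + a(x+b))."""
    coords = base + b
    return b + np.stack([_sample(a[..., c], coords) for c in range(3)], axis=-1)


def _exp_field(v: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Exponential of a stationary velocity field by scaling-and-squaring."""
    mx = float(np.max(np.linalg.norm(v, axis=-1)))
    if mx == 0.0:
        return v.copy()
    n = max(0, int(np.ceil(np.log2(mx / 0.5))))
    u = v / (2.0 ** n)
    for _ in range(n):
        u = _compose(u, u, base)
    return u


def _smooth_vec(v: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return v
    out = np.empty_like(v)
    for c in range(3):
        ndimage.gaussian_filter(v[..., c], sigma, output=out[..., c], mode="nearest")
    return out


def _shrink_image(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, 0.5 * factor, mode="nearest")
    target = tuple(int(np.ceil(n / factor)) for n in img.shape)
    return ndimage.zoom(sm, [t / n for t, n in zip(target, img.shape)], order=1, mode="nearest")


def _resize_field(v: np.ndarray, target_shape: tuple[int, int, int], scale: float) -> np.ndarray:
    """Resample a voxel-unit field to a new shape, rescaling the vectors."""
    factors = [t / n for t, n in zip(target_shape, v.shape[:3])]
    out = np.empty(tuple(target_shape) + (3,))
    for c in range(3):
        out[..., c] = ndimage.zoom(v[..., c], factors, order=1, mode="nearest") * scale
    return out


def _dice_binary(a: np.ndarray, b: np.ndarray) -> float:
    s = a.sum() + b.sum()
    return 1.0 if s == 0 else 2.0 * np.logical_and(a, b).sum() / s


# ---------------------------------------------------------------------------
# rigid / affine pre-alignment
# ---------------------------------------------------------------------------

def _moments(image: LabelImage) -> tuple[np.ndarray, np.ndarray]:
    """Foreground centroid (mm) and second-moment matrix."""
    idx = np.argwhere(image.foreground())
    if len(idx) == 0:
        raise RegistrationError("empty foreground")
    pts = image.index_to_world(idx)
    c = pts.mean(axis=0)
    d = pts - c
    return c, (d.T @ d) / len(d)


def _principal_axes(cov: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector basis: columns sorted by descending
    eigenvalue, each flipped so its largest-magnitude entry is positive,
    overall determinant forced to +1."""
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    for k in range(3):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def rigid_align(
    fixed: LabelImage, moving: LabelImage, mode: str = "translation"
) -> AffineTransform:
    """Transform mapping moving-space world points into fixed space.

    ``mode='translation'`` matches foreground centroids; ``mode='axes'``
    additionally aligns the principal axes of the second moments (up to the
    inherent axis-sign ambiguity, resolved deterministically).
    """
    cf, covf = _moments(fixed)
    cm, covm = _moments(moving)
    if mode == "translation":
        return AffineTransform.from_translation(cf - cm)
    if mode == "axes":
        R = _principal_axes(covf) @ _principal_axes(covm).T
        return AffineTransform(R, cf - R @ cm)
    raise ValueError(f"unknown rigid_align mode: {mode}")


def make_scaling_transform(factors, center) -> AffineTransform:
    """Anisotropic scaling about a world point, e.g. the 178/160 global
    elongation used to pre-condition a short subject against a tall baseline."""
    return AffineTransform.scaling(factors, center)


def resample_label(
    moving: LabelImage, grid: LabelImage, transform: AffineTransform
) -> LabelImage:
    """Resample ``moving`` onto ``grid`` through a moving→fixed world
    transform, nearest-neighbour (labels are never blended)."""
    inv = transform.inverse()
    xs, ys, zs = grid.voxel_centers()
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    src = moving.world_to_index(inv.apply(pts.reshape(-1, 3))).reshape(pts.shape)
    out = ndimage.map_coordinates(
        moving.data.astype(np.uint8),
        [src[..., a] for a in range(3)],
        order=0, mode="constant", cval=0,
    )
    return grid.like(out.astype(np.uint8))


# ---------------------------------------------------------------------------
# diffeomorphic demons
# ---------------------------------------------------------------------------

def _label_channels(data: np.ndarray, per_label: bool) -> list[np.ndarray]:
    if per_label:
        return [(data == 1).astype(float), (data == 2).astype(float)]
    return [data.astype(float)]


def demons_register(
    fixed: LabelImage,
    moving: LabelImage,
    config: RegistrationConfig | None = None,
) -> DisplacementField:
    """Diffeomorphic Demons registration of two label images on one grid.

    Returns the displacement field (mm, on the fixed grid).  Per-level
    foreground DICE of the warped moving image and iteration counts are
    attached as ``field.meta``.
    """
    config = config or RegistrationConfig()
    fixed.require_same_grid(moving, "moving image")

    chans_f = [
        ndimage.gaussian_filter(c, config.presmooth, mode="nearest")
        for c in _label_channels(fixed.data, config.per_label)
    ]
    chans_m = [
        ndimage.gaussian_filter(c, config.presmooth, mode="nearest")
        for c in _label_channels(moving.data, config.per_label)
    ]
    fg_f = fixed.foreground()
    fg_m = moving.foreground()

    u = None  # voxel units of the current level
    prev_shrink = None
    meta = {"level_dice": [], "level_iterations": [], "converged": []}

    for shrink, iters in zip(config.shrink, config.iterations):
        f_l = [_shrink_image(c, shrink) for c in chans_f]
        m_l = [_shrink_image(c, shrink) for c in chans_m]
        shape = f_l[0].shape
        base = _identity_grid(shape)
        grads_f = [np.stack(np.gradient(c), axis=-1) for c in f_l]

        if u is None:
            u = np.zeros(shape + (3,))
        else:
            u = _resize_field(u, shape, prev_shrink / shrink)

        converged = False
        it_done = 0
        for it in range(iters):
            update = np.zeros(shape + (3,))
            sq_sum = np.zeros(shape)
            for cf, cm, gf in zip(f_l, m_l, grads_f):
                m_w = _warp_scalar(cm, u, base)
                diff = m_w - cf
                grad_m = np.stack(np.gradient(m_w), axis=-1)
                grad = 0.5 * (gf + grad_m)
                g2 = np.sum(grad * grad, axis=-1)
                denom = g2 + diff * diff
                w = np.where(denom > 1e-9, -diff / np.maximum(denom, 1e-9), 0.0)
                update += w[..., None] * grad
                sq_sum += diff * diff
            mag = np.linalg.norm(update, axis=-1)
            over = mag > config.max_step
            if over.any():
                update[over] *= (config.max_step / mag[over])[:, None]
            update = _smooth_vec(update, config.smooth_factor)
            step = _exp_field(update, base)
            u = _compose(u, step, base)
            u = _smooth_vec(u, config.field_smooth)
            if not np.all(np.isfinite(u)):
                raise RegistrationError(
                    f"field diverged (non-finite) at shrink {shrink}, iteration {it}"
                )
            it_done = it + 1
            if float(np.mean(np.linalg.norm(step, axis=-1))) < config.tol:
                converged = True
                break

        # warped-moving foreground overlap, for the monotonicity diagnostic
        fgm_l = _shrink_image(fg_m.astype(float), shrink) > 0.5
        fgf_l = _shrink_image(fg_f.astype(float), shrink) > 0.5
        warped_fg = _warp_scalar(fgm_l.astype(float), u, base) > 0.5
        meta["level_dice"].append(_dice_binary(warped_fg, fgf_l))
        meta["level_iterations"].append(it_done)
        meta["converged"].append(converged)
        prev_shrink = shrink

    if prev_shrink != 1:
        u = _resize_field(u, fixed.shape, float(prev_shrink))

    field = DisplacementField(u * fixed.spacing, fixed.spacing, fixed.origin)
    field.meta = meta
    return field


def invert_field(
    u: DisplacementField, tol: float = 0.1, max_iter: int = 50
) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration
    ``v_{k+1}(x) = -u(x + v_k(x))``.

    ``tol`` is on the max composition residual ``|u(x+v(x)) + v(x)|`` in mm.
    If the residual is still above ``tol`` after ``max_iter`` iterations a
    warning is attached (and emitted); the field is returned regardless.
    Residual statistics live in ``result.meta``.
    """
    if not np.all(np.isfinite(u.data)):
        raise ValueError("cannot invert a non-finite field")
    base = _identity_grid(u.shape)
    uv = u.data / u.spacing  # voxel units
    v = -uv
    tol_vox = tol / float(np.min(u.spacing))
    resid = None
    for _ in range(max_iter):
        uv_at = np.stack(
            [_sample(uv[..., c], base + v) for c in range(3)], axis=-1
        )
        resid = np.linalg.norm(uv_at + v, axis=-1)
        if float(resid.max()) < tol_vox:
            v = -uv_at
            break
        v = -uv_at
    uv_at = np.stack([_sample(uv[..., c], base + v) for c in range(3)], axis=-1)
    resid = np.linalg.norm(uv_at + v, axis=-1) * float(np.min(u.spacing))
    out = DisplacementField(v * u.spacing, u.spacing, u.origin)
    out.meta = {
        "residual_max_mm": float(resid.max()),
        "residual_mean_mm": float(resid.mean()),
    }
    if resid.max() > tol:
        import warnings

        warnings.warn(
            f"invert_field did not reach tol={tol} mm: "
            f"max residual {resid.max():.3g} mm, mean {resid.mean():.3g} mm"
        )
    return out


def warp_jacobian_determinant(u: DisplacementField) -> np.ndarray:
    """Determinant of the Jacobian of the warp ``x + u(x)`` per voxel.

    Positive everywhere (interior) for a fold-free, diffeomorphic field.
    """
    uv = u.data / u.spacing
    jac = np.empty(u.shape + (3, 3))
    for c in range(3):
        g = np.gradient(uv[..., c])
        for a in range(3):
            jac[..., c, a] = g[a]
        jac[..., c, c] += 1.0
    return np.linalg.det(jac)
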