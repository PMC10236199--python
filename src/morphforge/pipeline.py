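"""End-to-end personalization pipelines.

Type I:  voxelize -> rigid align -> Demons -> morph -> invert/warp -> metrics.
Type II: Type I with a global pre-scaling of the subject image (e.g. the
         178/160 elongation of a short subject against a tall baseline); the
         inverse scaling is composed back into the nodal displacement.
Type III: Type I after "shielding" - named subject regions are replaced by
         the baseline's surfaces so they present no difference to the
         registration and stay unmorphed.

Intermediates follow the naming scheme img_hbm / img_subj /
img_basewarped2subj / gdemons / gdemons_inv.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import AffineTransform, DisplacementField, FEMesh, LabelImage, SurfaceMesh
from .evaluation import (
    EvalReport,
    QualityReport,
    count_contact_intersections,
    element_quality,
    evaluate_images,
    warp_image,
)
from .geometry_io import write_fe_mesh, write_image
from .morphing import morph_mesh, shield_regions
from .registration import (
    RegistrationConfig,
    demons_register,
    invert_field,
    make_scaling_transform,
    resample_label,
    rigid_align,
)
from .voxelizer import compute_grid, voxelize_body


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    baseline_skin: list[SurfaceMesh] = field(default_factory=list)
    baseline_skeleton: list[SurfaceMesh] = field(default_factory=list)
    baseline_mesh: FEMesh | None = None
    subject_skin: list[SurfaceMesh] = field(default_factory=list)
    subject_skeleton: list[SurfaceMesh] = field(default_factory=list)
    pipeline_type: str = "I"  # I | II | III
    voxel_size: float = 2.0
    padding: float = 8.0
    scale_factors: tuple[float, float, float] | None = None  # Type II
    shield: list[str] = field(default_factory=list)  # Type III region tags
    skin_only: bool = False
    rigid_mode: str = "translation"  # translation | axes | none
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    check_contacts: bool = True
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.pipeline_type not in ("I", "II", "III"):
            raise ValueError(f"pipeline_type must be I, II or III, got {self.pipeline_type!r}")
        if self.pipeline_type == "II" and self.scale_factors is None:
            raise ValueError("Type II needs scale_factors")
        if self.pipeline_type == "III" and not self.shield:
            raise ValueError("Type III needs shield region tags")


@dataclass
class PipelineResult:
    mesh: FEMesh
    field: DisplacementField
    field_inv: DisplacementField
    img_fixed: LabelImage       # img_hbm
    img_moving: LabelImage      # img_subj (aligned/scaled/shielded)
    img_warped: LabelImage      # img_basewarped2subj
    eval_report: EvalReport
    quality: QualityReport | None
    baseline_quality: QualityReport | None
    contact_intersections: tuple[int, list] | None
    rigid: AffineTransform
    scaling: AffineTransform


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:  # noqa: BLE001 - stage context, then re-raise
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Personalize the baseline mesh to the subject surfaces."""
    if not config.baseline_skin or not config.subject_skin:
        raise ValueError("baseline and subject skin surfaces are required")

    # -- voxelize subject on its own grid (for the rigid estimate) ----------
    vox = _stage("voxelize")(voxelize_body)
    img_subj_own = vox(
        config.subject_skin, config.subject_skeleton,
        voxel_size=config.voxel_size, padding=config.padding,
        skin_only=config.skin_only,
    )

    # -- rigid alignment: subject world -> baseline world --------------------
    base_surfaces = list(config.baseline_skin) + list(config.baseline_skeleton)
    grid0 = compute_grid(base_surfaces, config.voxel_size, config.padding)
    img_base0 = vox(
        config.baseline_skin, config.baseline_skeleton, grid=grid0,
        skin_only=config.skin_only,
    )
    if config.rigid_mode == "none":
        rigid = AffineTransform.identity()
    else:
        rigid = _stage("rigid_align")(rigid_align)(img_base0, img_subj_own, config.rigid_mode)

    subj_skin = [s.transformed(rigid) for s in config.subject_skin]
    subj_skel = [s.transformed(rigid) for s in config.subject_skeleton]

    # -- Type III: shield named regions with baseline surfaces ---------------
    if config.pipeline_type == "III":
        shield = _stage("shield")(shield_regions)
        combined = shield(
            subj_skin + subj_skel,
            list(config.baseline_skin) + list(config.baseline_skeleton),
            config.shield,
        )
        subj_skin = combined[: len(subj_skin)]
        subj_skel = combined[len(subj_skin):]

    # -- common fixed grid covering both bodies ------------------------------
    grid = compute_grid(
        base_surfaces + subj_skin + subj_skel, config.voxel_size, config.padding
    )
    img_fixed = vox(config.baseline_skin, config.baseline_skeleton, grid=grid,
                    skin_only=config.skin_only)
    img_moving = vox(subj_skin, subj_skel, grid=grid, skin_only=config.skin_only)

    # -- Type II: global pre-scaling of the subject image --------------------
    scaling = AffineTransform.identity()
    if config.pipeline_type == "II":
        fg = np.argwhere(img_moving.foreground())
        center = img_moving.index_to_world(fg).mean(axis=0)
        scaling = make_scaling_transform(config.scale_factors, center)
        img_moving = _stage("scale_subject")(resample_label)(img_moving, grid, scaling)

    # -- Demons registration --------------------------------------------------
    u = _stage("demons")(demons_register)(img_fixed, img_moving, config.registration)
    u_inv = _stage("invert_field")(invert_field)(u, tol=0.25 * float(np.min(grid.spacing)))

    # -- accuracy metrics ------------------------------------------------------
    img_warped = _stage("warp")(warp_image)(img_fixed, u_inv)
    report = _stage("evaluate")(evaluate_images)(img_warped, img_moving)

    # -- morph the FE mesh -----------------------------------------------------
    personalized = None
    quality = base_quality = contacts = None
    if config.baseline_mesh is not None:
        post = scaling.inverse() if config.pipeline_type == "II" else None
        personalized = _stage("morph")(morph_mesh)(config.baseline_mesh, u, post_transform=post)
        if len(config.baseline_mesh.solids):
            quality = _stage("quality")(element_quality)(personalized)
            base_quality = element_quality(config.baseline_mesh)
        if config.check_contacts and config.baseline_mesh.contact_pairs:
            contacts = _stage("contacts")(count_contact_intersections)(personalized)
    else:
        personalized = None

    result = PipelineResult(
        mesh=personalized,
        field=u,
        field_inv=u_inv,
        img_fixed=img_fixed,
        img_moving=img_moving,
        img_warped=img_warped,
        eval_report=report,
        quality=quality,
        baseline_quality=base_quality,
        contact_intersections=contacts,
        rigid=rigid,
        scaling=scaling,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_image(out / "img_hbm.nii.gz", img_fixed)
        write_image(out / "img_subj.nii.gz", img_moving)
        write_image(out / "img_basewarped2subj.nii.gz", img_warped)
        write_image(out / "gdemons.mha", u)
        write_image(out / "gdemons_inv.mha", u_inv)
        if personalized is not None:
            write_fe_mesh(out / "personalized.k", personalized)
    return result
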