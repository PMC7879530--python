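"""End-to-end analysis: frame -> registration -> morphometry -> statistics.

Per case: derive the anatomical frame from the preoperative plan model, mask
the intact proximal shaft in both scenes, register the post-operative shaft
onto the plan shaft with trimmed ICP, measure the reduction metrics in the
plan frame, then aggregate the cohort statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import io as wio
from .errors import WristmorphError
from .frame import AnatomicFrame, AxisEstimate, build_frame, fit_long_axis, locate_origin
from .metrics import CaseMetrics, measure_case
from .register import RegistrationResult, icp_rigid, mask_intact_region
from .stats import CohortSummary, summarize_cohort
from .synthetic import Scene
from .transforms import RigidTransform

__all__ = ["CaseResult", "derive_frame", "analyze_case", "run_pipeline", "quick_case_metrics"]

log = logging.getLogger("wristmorph")

METRIC_COLUMNS = [
    "case_id", "d1", "d2", "d3", "d_bary",
    "area_plan", "area_post",
    "volar_tilt_plan", "volar_tilt_post",
    "radial_inclination_plan", "radial_inclination_post",
]


@dataclass(frozen=True)
class CaseResult:
    case_id: str
    metrics: CaseMetrics
    frame: AnatomicFrame
    registration: RegistrationResult


def derive_frame(
    mesh: trimesh.Trimesh,
    landmarks: dict,
    shaft_band: tuple[float, float] = (0.35, 0.95),
    side: str = "right",
) -> tuple[AnatomicFrame, AxisEstimate]:
    """Anatomical frame of one scene: long-axis fit, articular origin, then
    axes from the styloid and sigmoid-notch-base landmarks."""
    axis = fit_long_axis(mesh, shaft_band=shaft_band)
    origin = locate_origin(mesh, axis)
    frame = build_frame(
        axis,
        origin,
        styloid=landmarks["radial_styloid"],
        sigmoid_base=landmarks["sigmoid_notch_base"],
        side=side,
    )
    return frame, axis


def analyze_case(
    plan: Scene,
    post: Scene,
    case_id: str = "case",
    shaft_band: tuple[float, float] = (0.35, 0.95),
    proximal_cutoff: float = 20.0,
    icp_tol: float = 1e-6,
    icp_max_iter: int = 200,
    icp_trim_fraction: float = 0.1,
    side: str = "right",
) -> CaseResult:
    """Evaluate one plan/post-operative pair end to end."""
    if plan.mesh is None or post.mesh is None:
        raise WristmorphError("analyze_case requires surface meshes in both scenes")

    frame, _ = derive_frame(plan.mesh, plan.landmarks, shaft_band, side=side)
    plan_shaft = mask_intact_region(plan.mesh, frame, proximal_cutoff)

    # the post-op scene sits in its own pose: mask its shaft with a
    # provisional frame derived from its own long axis
    post_frame, _ = derive_frame(post.mesh, post.landmarks, shaft_band, side=side)
    post_shaft = mask_intact_region(post.mesh, post_frame, proximal_cutoff)

    reg = icp_rigid(
        post_shaft,
        plan_shaft,
        tol=icp_tol,
        max_iter=icp_max_iter,
        trim_fraction=icp_trim_fraction,
    )
    metrics = measure_case(plan.landmarks, post.landmarks, frame, reg.transform)
    return CaseResult(case_id=case_id, metrics=metrics, frame=frame, registration=reg)


def quick_case_metrics(plan: Scene, post: Scene, true_transform: RigidTransform,
                       frame: AnatomicFrame | None = None) -> CaseMetrics:
    """Landmark-only evaluation using a known scene transform in place of
    surface registration (exact-registration surrogate for mesh-free cohorts).

    The generator emits plan scenes in the canonical pose, so the long axis is
    +y with the origin at zero; the remaining frame axes are built from the
    plan's own frame landmarks exactly as the full pipeline does.
    """
    if frame is None:
        axis = AxisEstimate(direction=np.array([0.0, 1.0, 0.0]), point=np.zeros(3), rms_residual=0.0)
        frame = build_frame(
            axis,
            np.zeros(3),
            styloid=plan.landmarks["radial_styloid"],
            sigmoid_base=plan.landmarks["sigmoid_notch_base"],
        )
    return measure_case(plan.landmarks, post.landmarks, frame, true_transform.inverse())


def run_pipeline(config: wio.RunConfig) -> tuple[CohortSummary, pd.DataFrame]:
    """Run the full analysis over a cohort directory written by the generator
    (or any directory with the same manifest layout).  Writes the per-case
    metrics CSV, registration transforms, and the summary JSON + Markdown
    report into ``config.output_dir``."""
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(in_dir / "manifest.csv")

    level = {0: logging.WARNING, 1: logging.INFO, 2: logging.DEBUG}[config.verbosity]
    logging.basicConfig(level=level, format="%(levelname)s %(message)s")
    log.info(
        "run defaults in effect: icc_form=%s correction=%s trim=%.2f cutoff=%.1f mm",
        config.icc_form, config.correction, config.icp_trim_fraction, config.proximal_cutoff,
    )

    results: list[CaseResult] = []
    failures: list[str] = []
    for row in manifest.itertuples():
        case_id = row.case_id
        try:
            plan = Scene(
                landmarks=wio.read_landmarks(in_dir / row.plan_landmarks),
                mesh=wio.read_mesh(in_dir / row.plan_mesh),
            )
            post = Scene(
                landmarks=wio.read_landmarks(in_dir / row.post_landmarks),
                mesh=wio.read_mesh(in_dir / row.post_mesh),
            )
            res = analyze_case(
                plan, post, case_id=case_id,
                shaft_band=tuple(config.shaft_band),
                proximal_cutoff=config.proximal_cutoff,
                icp_tol=config.icp_tol,
                icp_max_iter=config.icp_max_iter,
                icp_trim_fraction=config.icp_trim_fraction,
            )
            results.append(res)
            res.registration.transform.to_json(out_dir / f"{case_id}_registration.json")
            log.info("%s: ICP rms %.4f mm in %d iterations", case_id,
                     res.registration.rms, res.registration.iterations)
        except WristmorphError as exc:
            failures.append(f"{case_id}: {exc}")
            log.warning("case %s failed: %s", case_id, exc)

    if not results:
        raise WristmorphError("all cases failed: " + "; ".join(failures))

    metrics_df = pd.DataFrame(
        [{"case_id": r.case_id, **r.metrics.to_dict()} for r in results]
    )[METRIC_COLUMNS]
    metrics_df.to_csv(out_dir / "metrics.csv", index=False, float_format="%.12g")

    summary = summarize_cohort(
        metrics_df.drop(columns="case_id"),
        icc_form=config.icc_form,
        correction=config.correction,
    )
    payload = summary.to_dict()
    payload["failures"] = failures
    payload["config"] = config.model_dump()
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (out_dir / "summary.md").write_text(summary.to_markdown() + "\n")
    return summary, metrics_df
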