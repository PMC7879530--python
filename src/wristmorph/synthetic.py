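"""Synthetic distal-radius cohorts with known ground truth.

Real plan/post-operative CT surface models are patient data; this module
generates stylised stand-ins that preserve exactly the properties the
measurement pipeline depends on:

* a shaft with a well-defined long axis (an elliptic tube along +y, so the
  axial rotation of the registration problem is identifiable),
* a distal articular cap that passes through the frame origin and carries
  the three reference points at anatomically calibrated positions — the
  template magnitudes (~14.4, ~16.9, ~13.6 mm), octants, volar tilt (~10.9°)
  and radial inclination (~20.8°) match the cohort means reported for this
  kind of anatomy,
* between-subject anatomical variation and plan-to-post-op reduction error
  as iid per-axis Gaussian landmark noise (an optional systematic offset
  models a directional reduction bias),
* an arbitrary rigid offset of the post-operative scene that registration
  must remove, recorded as ground truth.

With per-axis noise σ, the landmark displacement magnitude follows a chi
distribution with 3 degrees of freedom, mean σ·2√(2/π) ≈ 1.5958 σ; the
default σ = 2.0/1.5958 mm therefore reproduces the ≈2 mm per-point plan-to-
post error scale of the clinical cohort this generator emulates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import RBFInterpolator

from .errors import ConstraintViolationError, MeshError, WristmorphError
from .metrics import LandmarkTriad, radial_inclination, volar_tilt
from .transforms import RigidTransform, random_rigid_transform

__all__ = [
    "CHI3_MEAN",
    "TemplateGeometry",
    "GeneratorConfig",
    "GroundTruth",
    "Scene",
    "make_template",
    "build_mesh",
    "sample_case",
    "sample_cohort",
    "simulate_paired_ratings",
]

#: mean of the chi distribution with 3 df: E‖N(0, I₃)‖ = 2·√(2/π)
CHI3_MEAN = 2.0 * np.sqrt(2.0 / np.pi)

# Canonical landmark coordinates (mm, frame coordinates: x palmar+,
# y proximal+, z radial+).  Chosen to satisfy simultaneously the printed
# cohort means for the landmark magnitudes, their octants, and the two
# articular angles.
_CANONICAL_LANDMARKS = {
    "radial_styloid": np.array([-1.5, -7.0, 12.5]),
    "sigmoid_notch_volar": np.array([7.0, 3.3, -15.0]),
    "sigmoid_notch_dorsal": np.array([-5.0, 1.0, -12.6]),
    # auxiliary frame landmark: placed so the projected base->styloid line is
    # exactly radial in the template pose
    "sigmoid_notch_base": np.array([-1.5, 2.0, -14.0]),
}


@dataclass(frozen=True)
class TemplateGeometry:
    """Parametric template of a distal radius (mm, canonical frame pose)."""

    landmarks: dict
    shaft_length: float = 90.0
    shaft_radius_x: float = 9.0  # palmar-dorsal semi-axis of the shaft ellipse
    shaft_radius_z: float = 11.0  # radial-ulnar semi-axis
    rim_radius: float = 17.5  # radius of the articular cap rim
    rim_y: float = 4.5  # proximal coordinate of the cap rim
    flare_y: float = 12.0  # where the metaphyseal flare meets the shaft
    shaft_taper: float = 0.85  # proximal/distal shaft radius ratio (narrows proximally)

    def triad(self) -> LandmarkTriad:
        return LandmarkTriad.from_dict(self.landmarks)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``sigma_between`` is the between-subject per-axis landmark SD;
    ``sigma_error`` the plan-to-post-op per-axis displacement SD (default
    calibrated so the mean per-landmark displacement is ≈2 mm);
    ``systematic_offset`` an optional directional reduction bias (mm).
    The rigid offset applied to every post-operative scene is uniform in
    rotation angle and translation norm up to the configured maxima.
    """

    n_cases: int = 63
    sigma_between: float = 1.6
    sigma_error: float = 2.0 / CHI3_MEAN
    systematic_offset: tuple = (0.0, 0.0, 0.0)
    max_rotation_deg: float = 15.0
    max_translation: float = 10.0
    mesh_resolution: float = 2.0  # target edge length, mm
    with_meshes: bool = True
    # calibration bands validated on the template (mm / degrees)
    norm_bands: dict = field(
        default_factory=lambda: {
            "radial_styloid": (13.0, 16.0),
            "sigmoid_notch_volar": (15.0, 19.0),
            "sigmoid_notch_dorsal": (12.0, 15.5),
        }
    )
    volar_tilt_band: tuple = (8.0, 14.0)
    radial_inclination_band: tuple = (17.0, 24.0)

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise WristmorphError("n_cases must be >= 1")
        if self.sigma_between < 0 or self.sigma_error < 0:
            raise WristmorphError("noise SDs must be >= 0")
        if not 0.0 <= self.max_rotation_deg < 180.0:
            raise WristmorphError("max_rotation_deg must be in [0, 180)")
        if self.max_translation < 0:
            raise WristmorphError("max_translation must be >= 0")
        if self.mesh_resolution <= 0:
            raise WristmorphError("mesh_resolution must be > 0")


@dataclass(frozen=True)
class Scene:
    """One wrist state: optional surface mesh plus named landmarks (mm)."""

    landmarks: dict
    mesh: trimesh.Trimesh | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    plan_landmarks: dict
    post_landmarks_pre_offset: dict
    scene_transform: RigidTransform  # applied to the post-op scene
    between_noise: dict
    error_noise: dict


def make_template(config: GeneratorConfig | None = None) -> TemplateGeometry:
    """Return the calibrated template and verify it against the configured
    magnitude and angle bands.  Deterministic for a fixed config."""
    config = config or GeneratorConfig()
    landmarks = {k: v.copy() for k, v in _CANONICAL_LANDMARKS.items()}
    template = TemplateGeometry(landmarks=landmarks)

    for name, (lo, hi) in config.norm_bands.items():
        r = float(np.linalg.norm(landmarks[name]))
        if not lo <= r <= hi:
            raise ConstraintViolationError(
                f"landmark magnitude band violated: ‖{name}‖ = {r:.2f} mm "
                f"outside [{lo}, {hi}] mm"
            )
    triad = template.triad()
    vt = volar_tilt(triad)
    lo, hi = config.volar_tilt_band
    if not lo <= vt <= hi:
        raise ConstraintViolationError(
            f"volar tilt band violated: {vt:.2f}° outside [{lo}, {hi}]°"
        )
    ri = radial_inclination(triad)
    lo, hi = config.radial_inclination_band
    if not lo <= ri <= hi:
        raise ConstraintViolationError(
            f"radial inclination band violated: {ri:.2f}° outside [{lo}, {hi}]°"
        )
    return template


def _cap_height_field(template: TemplateGeometry) -> RBFInterpolator:
    """Thin-plate interpolant y = f(x, z) for the articular cap: passes
    through the origin, every landmark, and the rim ring."""
    n_rim = 32
    theta = np.linspace(0, 2 * np.pi, n_rim, endpoint=False)
    rim_xz = np.column_stack(
        [template.rim_radius * np.cos(theta), template.rim_radius * np.sin(theta)]
    )
    pts = [np.zeros((1, 2))]
    vals = [np.zeros(1)]
    for p in template.landmarks.values():
        pts.append(np.array([[p[0], p[2]]]))
        vals.append(np.array([p[1]]))
    pts.append(rim_xz)
    vals.append(np.full(n_rim, template.rim_y))
    return RBFInterpolator(np.vstack(pts), np.concatenate(vals), kernel="thin_plate_spline")


def build_mesh(template: TemplateGeometry, resolution: float = 2.0) -> trimesh.Trimesh:
    """Triangulate the stylised radius: articular cap (a smooth height field
    through the landmarks), metaphyseal flare, elliptic shaft tube along +y,
    and a flat proximal cap.  Watertight by construction."""
    if resolution <= 0:
        raise MeshError("mesh resolution must be > 0")
    t = template
    n_theta = max(24, int(np.ceil(2 * np.pi * t.rim_radius / resolution)))
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    f = _cap_height_field(t)

    def ellipse_r(rx: float, rz: float) -> np.ndarray:
        return rx * rz / np.sqrt((rz * cos_t) ** 2 + (rx * sin_t) ** 2)

    vertices: list[np.ndarray] = []
    rings: list[np.ndarray] = []  # vertex index arrays, distal to proximal

    def add_ring(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        start = len(vertices)
        for xi, yi, zi in zip(x, y, z):
            vertices.append(np.array([xi, yi, zi]))
        idx = np.arange(start, start + n_theta)
        rings.append(idx)
        return idx

    # distal cap centre vertex: exactly the frame origin
    vertices.append(np.zeros(3))
    centre_distal = 0

    # cap rings from near-centre out to the rim, warped by the height field
    n_cap = max(4, int(np.ceil(t.rim_radius / resolution)))
    for k in range(1, n_cap + 1):
        r = t.rim_radius * k / n_cap
        x, z = r * cos_t, r * sin_t
        y = f(np.column_stack([x, z]))
        add_ring(x, y, z)

    # metaphyseal flare: rim circle -> shaft ellipse
    n_flare = max(2, int(np.ceil((t.flare_y - t.rim_y) / resolution)))
    for k in range(1, n_flare + 1):
        s = k / n_flare
        rx = (1 - s) * t.rim_radius + s * t.shaft_radius_x
        rz = (1 - s) * t.rim_radius + s * t.shaft_radius_z
        r = ellipse_r(rx, rz)
        y = (1 - s) * t.rim_y + s * t.flare_y
        add_ring(r * cos_t, np.full(n_theta, y), r * sin_t)

    # shaft tube, tapering toward the proximal end (breaks the end-to-end
    # symmetry of a plain tube, as the metaphysis does anatomically)
    n_shaft = max(3, int(np.ceil((t.shaft_length - t.flare_y) / resolution)))
    r_shaft = ellipse_r(t.shaft_radius_x, t.shaft_radius_z)
    for k in range(1, n_shaft + 1):
        s = k / n_shaft
        y = t.flare_y + (t.shaft_length - t.flare_y) * s
        scale = 1.0 + (t.shaft_taper - 1.0) * s
        add_ring(scale * r_shaft * cos_t, np.full(n_theta, y), scale * r_shaft * sin_t)

    # proximal cap centre
    vertices.append(np.array([0.0, t.shaft_length, 0.0]))
    centre_proximal = len(vertices) - 1

    faces: list[tuple[int, int, int]] = []
    first = rings[0]
    for i in range(n_theta):
        j = (i + 1) % n_theta
        faces.append((centre_distal, first[i], first[j]))
    for a, b in zip(rings[:-1], rings[1:]):
        for i in range(n_theta):
            j = (i + 1) % n_theta
            faces.append((a[i], b[i], b[j]))
            faces.append((a[i], b[j], a[j]))
    last = rings[-1]
    for i in range(n_theta):
        j = (i + 1) % n_theta
        faces.append((centre_proximal, last[j], last[i]))

    mesh = trimesh.Trimesh(
        vertices=np.asarray(vertices), faces=np.asarray(faces), process=False
    )
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        raise MeshError("constructed surface is not watertight")
    return mesh


def _draw_noise(rng: np.random.Generator, names, sigma: float) -> dict:
    return {n: rng.normal(0.0, sigma, size=3) for n in names}


def sample_case(
    template: TemplateGeometry,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[Scene, Scene, GroundTruth]:
    """Draw one plan/post-operative pair.

    Plan landmarks = template + between-subject noise; post-op landmarks =
    plan + systematic offset + reduction-error noise.  The whole post-op
    scene is then moved by a random rigid transform recorded in the ground
    truth.  The proximal shaft is identical geometry in both scenes up to
    that transform.
    """
    names = list(template.landmarks)
    between = _draw_noise(rng, names, config.sigma_between)
    error = _draw_noise(rng, names, config.sigma_error)
    offset = np.asarray(config.systematic_offset, dtype=float)

    plan_lm = {n: template.landmarks[n] + between[n] for n in names}
    post_lm = {n: plan_lm[n] + offset + error[n] for n in names}
    transform = random_rigid_transform(
        rng, config.max_rotation_deg, config.max_translation
    )

    plan_mesh = post_mesh = None
    if config.with_meshes:
        plan_mesh = build_mesh(replace(template, landmarks=plan_lm), config.mesh_resolution)
        post_mesh = build_mesh(replace(template, landmarks=post_lm), config.mesh_resolution)
        post_mesh.vertices = transform.apply(np.asarray(post_mesh.vertices))

    post_lm_moved = {n: transform.apply(post_lm[n]) for n in names}
    gt = GroundTruth(
        plan_landmarks={n: plan_lm[n].copy() for n in names},
        post_landmarks_pre_offset={n: post_lm[n].copy() for n in names},
        scene_transform=transform,
        between_noise=between,
        error_noise=error,
    )
    return Scene(landmarks=plan_lm, mesh=plan_mesh), Scene(landmarks=post_lm_moved, mesh=post_mesh), gt


def sample_cohort(
    n: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[Scene, Scene, GroundTruth]], pd.DataFrame]:
    """Draw a reproducible cohort of *n* plan/post-op pairs.

    If *out_dir* is given, every case is written to disk (meshes as PLY,
    landmarks as JSON and long CSV, ground-truth transform as JSON) and the
    manifest CSV points at the files.
    """
    if n < 1:
        raise WristmorphError("cohort size must be >= 1")
    config = config or GeneratorConfig()
    template = make_template(config)
    rng = np.random.default_rng(seed)

    cases = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "metadata.json").write_text(
            json.dumps(
                {
                    "units": "mm",
                    "coordinate_convention": "x palmar+, y proximal+, z radial+",
                    "seed": seed,
                    "n_cases": n,
                },
                indent=2,
            )
        )

    from . import io as wio  # deferred: io imports nothing from here

    for i in range(n):
        case_id = f"case{i:03d}"
        plan, post, gt = sample_case(template, config, rng)
        cases.append((plan, post, gt))
        row = {"case_id": case_id}
        if out is not None:
            for state, scene in (("plan", plan), ("post", post)):
                lm_path = out / f"{case_id}_{state}_landmarks.json"
                wio.write_landmarks(scene.landmarks, lm_path)
                wio.write_landmarks_csv(
                    scene.landmarks, out / f"{case_id}_{state}_landmarks.csv",
                    case_id=case_id, state=state,
                )
                row[f"{state}_landmarks"] = lm_path.name
                if scene.mesh is not None:
                    mesh_path = out / f"{case_id}_{state}.ply"
                    wio.write_mesh(scene.mesh, mesh_path)
                    row[f"{state}_mesh"] = mesh_path.name
            gt.scene_transform.to_json(out / f"{case_id}_true_transform.json")
            row["true_transform"] = f"{case_id}_true_transform.json"
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return cases, manifest


def simulate_paired_ratings(
    n: int,
    true_icc: float,
    rng: np.random.Generator,
    rater_variance_fraction: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired ratings from the two-way random-effects model
    y_ij = s_i + r_j + e_ij with variance components set so the population
    absolute-agreement ICC equals *true_icc* (total variance 1)."""
    if not 0.0 <= true_icc < 1.0:
        raise WristmorphError("true_icc must be in [0, 1)")
    var_s = true_icc
    var_r = rater_variance_fraction * (1.0 - true_icc)
    var_e = (1.0 - rater_variance_fraction) * (1.0 - true_icc)
    s = rng.normal(0.0, np.sqrt(var_s), size=n)
    r = rng.normal(0.0, np.sqrt(var_r), size=2)
    e = rng.normal(0.0, np.sqrt(var_e), size=(n, 2))
    a = s + r[0] + e[:, 0]
    b = s + r[1] + e[:, 1]
    return a, b
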