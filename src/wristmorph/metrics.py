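"""Per-wrist morphometry of the distal radius reduction.

All quantities are computed from the three articular reference points —
(1) the radial styloid process, (2) the volar edge and (3) the dorsal edge of
the sigmoid notch — expressed in the plan-derived anatomical frame
(x palmar+, y proximal+, z radial+, mm):

* ``d1, d2, d3`` — Euclidean plan-to-post distance of each reference point;
* ``d_bary`` — distance between the barycenters (centroids) of the two
  reference-point triangles;
* plane area of the reference-point triangle, per state;
* volar tilt — sagittal-plane (x-y) angle of the volar->dorsal notch line
  against the perpendicular to the long axis, positive when the dorsal edge
  is the more distal (normal palmar tilt);
* radial inclination — coronal-plane (y-z) angle of the styloid->volar-notch
  line against the perpendicular to the long axis, positive when the styloid
  is the more distal.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import DegenerateProjectionError, WristmorphError
from .frame import AnatomicFrame
from .transforms import RigidTransform

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkTriad",
    "CaseMetrics",
    "barycenter",
    "triangle_area",
    "volar_tilt",
    "radial_inclination",
    "landmark_distances",
    "measure_case",
]

#: canonical landmark names: the measurement triad plus the auxiliary frame landmark
LANDMARK_NAMES = {
    "radial_styloid": "radial styloid process",
    "sigmoid_notch_volar": "sigmoid notch volar edge",
    "sigmoid_notch_dorsal": "sigmoid notch dorsal edge",
    "sigmoid_notch_base": "sigmoid notch base (frame landmark)",
}

TRIAD_NAMES = ("radial_styloid", "sigmoid_notch_volar", "sigmoid_notch_dorsal")


@dataclass(frozen=True)
class LandmarkTriad:
    """The three reference points of one wrist state, in frame coordinates (mm)."""

    p1: np.ndarray  # radial styloid process
    p2: np.ndarray  # sigmoid notch volar edge
    p3: np.ndarray  # sigmoid notch dorsal edge

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if (
            np.allclose(self.p1, self.p2)
            or np.allclose(self.p1, self.p3)
            or np.allclose(self.p2, self.p3)
        ):
            raise WristmorphError("triad landmarks must be three distinct points")

    @classmethod
    def from_dict(cls, landmarks: dict) -> "LandmarkTriad":
        missing = [n for n in TRIAD_NAMES if n not in landmarks]
        if missing:
            pretty = ", ".join(f"{n} ({LANDMARK_NAMES[n]})" for n in missing)
            raise WristmorphError(f"missing required landmark(s): {pretty}")
        return cls(*(landmarks[n] for n in TRIAD_NAMES))

    def as_array(self) -> np.ndarray:
        return np.stack([self.p1, self.p2, self.p3])


@dataclass(frozen=True)
class CaseMetrics:
    """Per-wrist outputs of the reduction evaluation (mm, mm², degrees)."""

    d1: float
    d2: float
    d3: float
    d_bary: float
    area_plan: float
    area_post: float
    volar_tilt_plan: float
    volar_tilt_post: float
    radial_inclination_plan: float
    radial_inclination_post: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def barycenter(triad: LandmarkTriad) -> np.ndarray:
    """Centroid of the reference-point triangle, (P1 + P2 + P3) / 3."""
    return triad.as_array().mean(axis=0)


def triangle_area(triad: LandmarkTriad) -> float:
    """Area of the plane connecting the three reference points (mm²)."""
    a = triad.as_array()
    return 0.5 * float(np.linalg.norm(np.cross(a[1] - a[0], a[2] - a[0])))


def volar_tilt(triad: LandmarkTriad) -> float:
    """Volar tilt in degrees, from the sagittal (x-y) projection of the
    volar-edge -> dorsal-edge line.  Positive = dorsal edge more distal
    (y more negative) than the volar edge, i.e. normal palmar tilt."""
    dx = triad.p2[0] - triad.p3[0]
    if abs(dx) < 1e-12:
        raise DegenerateProjectionError(
            "volar tilt undefined: sigmoid notch edges share the same palmar coordinate"
        )
    return float(np.degrees(np.arctan((triad.p2[1] - triad.p3[1]) / abs(dx))))


def radial_inclination(triad: LandmarkTriad) -> float:
    """Radial inclination in degrees, from the coronal (y-z) projection of the
    styloid -> volar-notch line.  Positive = styloid more distal than the
    sigmoid notch volar edge."""
    dz = triad.p1[2] - triad.p2[2]
    if abs(dz) < 1e-12:
        raise DegenerateProjectionError(
            "radial inclination undefined: styloid and volar notch edge share the same radial coordinate"
        )
    return float(np.degrees(np.arctan((triad.p2[1] - triad.p1[1]) / abs(dz))))


def landmark_distances(
    plan: LandmarkTriad, post: LandmarkTriad
) -> tuple[float, float, float, float]:
    """Per-point plan-to-post distances (d1, d2, d3) plus the barycenter
    distance d_bary.  Both triads must already sit in the same (plan) frame."""
    a = plan.as_array()
    b = post.as_array()
    d = np.linalg.norm(a - b, axis=1)
    d_bary = float(np.linalg.norm(barycenter(plan) - barycenter(post)))
    return float(d[0]), float(d[1]), float(d[2]), d_bary


def measure_case(
    plan_landmarks: dict,
    post_landmarks: dict,
    frame: AnatomicFrame,
    transform: RigidTransform,
) -> CaseMetrics:
    """Full per-wrist evaluation: map the post-operative landmarks into the
    plan scene with the registration *transform*, express both states in the
    plan anatomical *frame*, and compute every metric."""
    plan_f = {k: frame.to_frame(np.asarray(v, float)) for k, v in plan_landmarks.items()}
    post_f = {
        k: frame.to_frame(transform.apply(np.asarray(v, float)))
        for k, v in post_landmarks.items()
    }
    plan_t = LandmarkTriad.from_dict(plan_f)
    post_t = LandmarkTriad.from_dict(post_f)
    d1, d2, d3, d_bary = landmark_distances(plan_t, post_t)
    return CaseMetrics(
        d1=d1,
        d2=d2,
        d3=d3,
        d_bary=d_bary,
        area_plan=triangle_area(plan_t),
        area_post=triangle_area(post_t),
        volar_tilt_plan=volar_tilt(plan_t),
        volar_tilt_post=volar_tilt(post_t),
        radial_inclination_plan=radial_inclination(plan_t),
        radial_inclination_post=radial_inclination(post_t),
    )
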