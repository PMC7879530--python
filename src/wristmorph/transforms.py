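"""Rigid (proper Euclidean) transforms in 3D.

A :class:`RigidTransform` maps points by ``p -> R @ p + t`` where ``R`` is a
proper rotation (orthogonal, det = +1) and ``t`` a translation in mm.  The
class is closed under composition and inversion and serialises to a 4x4
row-major homogeneous matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import WristmorphError

__all__ = ["RigidTransform", "random_rigid_transform"]

_ORTHO_TOL = 1e-9


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise WristmorphError(f"rotation must be 3x3, got {rotation.shape}")
    err = np.abs(rotation @ rotation.T - np.eye(3)).max()
    if err > 1e-8:
        raise WristmorphError(f"rotation is not orthogonal (max deviation {err:.2e})")
    det = np.linalg.det(rotation)
    if abs(det - 1.0) > 1e-8:
        raise WristmorphError(f"rotation determinant {det:.12f} != +1 (improper transform)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array or single 3-vector of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation.T @ self.translation
        )

    # -- angular/translational distance to another transform (for recovery tests)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def deviation_from(self, other: "RigidTransform") -> tuple[float, float]:
        """(rotation deg, translation mm) separating this transform from *other*."""
        delta = self.compose(other.inverse())
        return delta.rotation_angle_deg(), float(np.linalg.norm(delta.translation))

    # -- serialisation -----------------------------------------------------

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise WristmorphError(f"homogeneous matrix must be 4x4, got {m.shape}")
        return cls(rotation=m[:3, :3], translation=m[:3, 3])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"matrix": self.as_matrix().tolist(), "units": "mm"}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        data = json.loads(Path(path).read_text())
        return cls.from_matrix(np.asarray(data["matrix"]))


def random_rigid_transform(
    rng: np.random.Generator,
    max_rotation_deg: float = 15.0,
    max_translation: float = 10.0,
) -> RigidTransform:
    """Draw a rigid motion with rotation angle and translation norm uniform in
    [0, max]; the rotation axis and translation direction are isotropic."""
    if not 0.0 <= max_rotation_deg < 180.0:
        raise WristmorphError("max_rotation_deg must be in [0, 180)")
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    # Rodrigues formula
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rotation = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = direction * rng.uniform(0.0, max_translation)
    return RigidTransform(rotation=rotation, translation=translation)
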