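"""Anatomical coordinate frame of the distal radius.

The frame follows the ISB-style convention for the forearm: the y-axis is the
long axis of the radius with the proximal direction positive; the z-axis is
the projection, onto the plane perpendicular to y, of the line from the base
of the ulnar sigmoid notch to the radial styloid process, radial direction
positive; the x-axis completes a right-handed system with the palmar
direction positive.  The origin sits where the long axis pierces the distal
articular surface.  All measurements of a plan/post-operative pair are
expressed in the frame derived from the preoperative plan model.

Left-sided anatomy is mirrored into the right-handed convention before the
frame is built; the mirror plane is recorded on the frame so that point
transforms remain consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._geom import line_mesh_intersections
from .errors import AxisFitError, FrameError, OriginError

__all__ = ["AxisEstimate", "AnatomicFrame", "fit_long_axis", "locate_origin", "build_frame", "to_frame", "from_frame"]


@dataclass(frozen=True)
class AxisEstimate:
    """A fitted long axis: unit direction (proximal positive), a point on the
    axis, and the RMS distance of cross-section centroids to the line."""

    direction: np.ndarray
    point: np.ndarray
    rms_residual: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise AxisFitError("axis direction must be non-zero")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        if self.rms_residual < 0:
            raise AxisFitError("rms_residual must be >= 0")


@dataclass(frozen=True)
class AnatomicFrame:
    """Origin plus right-handed orthonormal axes (columns x palmar+,
    y proximal+, z radial+).  ``mirror_normal`` is set for left-sided input
    that was reflected into the right-handed convention."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns = x, y, z
    side: str = "right"
    mirror_normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float)
        if axes.shape != (3, 3):
            raise FrameError("axes must be a 3x3 matrix with axis columns")
        gram = axes.T @ axes
        if np.abs(gram - np.eye(3)).max() > 1e-9:
            raise FrameError("frame axes must be orthonormal")
        if abs(np.linalg.det(axes) - 1.0) > 1e-9:
            raise FrameError("frame must be right-handed (det = +1)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)
        if self.mirror_normal is not None:
            n = np.asarray(self.mirror_normal, dtype=float).reshape(3)
            object.__setattr__(self, "mirror_normal", n / np.linalg.norm(n))

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def _mirror(self, pts: np.ndarray) -> np.ndarray:
        n = self.mirror_normal
        return pts - 2.0 * np.outer((pts - self.origin) @ n, n)

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World -> frame coordinates: ``p' = axesᵀ (p - origin)`` (after the
        recorded mirror reflection, if any)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        if self.mirror_normal is not None:
            pts = self._mirror(pts)
        out = (pts - self.origin) @ self.axes
        return out[0] if single else out

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_frame`."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.axes.T + self.origin
        if self.mirror_normal is not None:
            out = self._mirror(out)
        return out[0] if single else out

    def to_dict(self) -> dict:
        return {
            "origin_mm": self.origin.tolist(),
            "x_palmar": self.x.tolist(),
            "y_proximal": self.y.tolist(),
            "z_radial": self.z.tolist(),
            "side": self.side,
            "mirror_normal": None if self.mirror_normal is None else self.mirror_normal.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnatomicFrame":
        axes = np.column_stack(
            [data["x_palmar"], data["y_proximal"], data["z_radial"]]
        )
        return cls(
            origin=np.asarray(data["origin_mm"]),
            axes=axes,
            side=data.get("side", "right"),
            mirror_normal=data.get("mirror_normal"),
        )


def _orient_proximal(
    direction: np.ndarray,
    vertices: np.ndarray,
    proximal_hint: np.ndarray | None,
) -> np.ndarray:
    """Resolve the sign of the axis so it points proximally.

    With a hint, align to it.  Without one, exploit the anatomy: the distal
    metaphysis flares, so the end of the bone with the larger mean
    cross-sectional radius is distal.
    """
    if proximal_hint is not None:
        hint = np.asarray(proximal_hint, dtype=float)
        return direction if direction @ hint > 0 else -direction
    s = vertices @ direction
    s0, s1 = s.min(), s.max()
    lo = s0 + 0.25 * (s1 - s0)
    hi = s1 - 0.25 * (s1 - s0)
    centroid = vertices.mean(axis=0)
    r = np.linalg.norm(
        (vertices - centroid) - np.outer((vertices - centroid) @ direction, direction),
        axis=1,
    )
    # near-maximum cross-sectional radius in each end quarter: the flared
    # (metaphyseal) end is distal
    r_neg = np.quantile(r[s <= lo], 0.98)
    r_pos = np.quantile(r[s >= hi], 0.98)
    if abs(r_pos - r_neg) > 0.05 * max(r_pos, r_neg):
        return -direction if r_pos > r_neg else direction
    # symmetric shape (plain tube): deterministic canonical sign
    k = int(np.argmax(np.abs(direction)))
    return direction if direction[k] > 0 else -direction


def fit_long_axis(
    mesh: trimesh.Trimesh,
    shaft_band: tuple[float, float] = (0.35, 0.95),
    n_sections: int = 25,
    proximal_hint: np.ndarray | None = None,
    tol_rad: float = 1e-8,
    max_iter: int = 100,
) -> AxisEstimate:
    """Fit the long axis of the radius from the intact shaft.

    The vertex cloud's principal direction initialises the axis; the band
    ``shaft_band`` (fractions of the extent along the current axis, 0 = distal
    end, 1 = proximal end) selects the shaft, which is cut into
    ``n_sections`` cross-sections.  A least-squares line through the section
    centroids is iterated until the direction changes by less than
    ``tol_rad``.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    if len(v) < 10:
        raise AxisFitError("mesh has too few vertices for an axis fit")
    lo_f, hi_f = shaft_band
    if not (0.0 <= lo_f < hi_f <= 1.0):
        raise AxisFitError(f"shaft_band fractions must satisfy 0 <= lo < hi <= 1, got {shaft_band}")

    centred = v - v.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = _orient_proximal(vt[0], v, proximal_hint)
    point = v.mean(axis=0)

    for _ in range(max_iter):
        direction = _orient_proximal(direction, v, proximal_hint)
        s = v @ direction
        s0, s1 = s.min(), s.max()
        lo = s0 + lo_f * (s1 - s0)
        hi = s0 + hi_f * (s1 - s0)
        edges = np.linspace(lo, hi, n_sections + 1)
        idx = np.digitize(s, edges) - 1
        centroids = []
        for k in range(n_sections):
            sel = idx == k
            if sel.sum() >= 3:
                centroids.append(v[sel].mean(axis=0))
        if len(centroids) < 10:
            raise AxisFitError(
                f"shaft band selects only {len(centroids)} non-empty cross-sections (need >= 10)"
            )
        centroids = np.asarray(centroids)
        mean_c = centroids.mean(axis=0)
        u, sv, vt = np.linalg.svd(centroids - mean_c, full_matrices=False)
        if sv[0] < 1e-12:
            raise AxisFitError("cross-section centroids are rank-deficient")
        new_dir = vt[0] if vt[0] @ direction > 0 else -vt[0]
        change = np.arccos(np.clip(new_dir @ direction, -1.0, 1.0))
        direction, point = new_dir, mean_c
        if change < tol_rad:
            break

    direction = _orient_proximal(direction, v, proximal_hint)
    resid = centroids - point
    resid -= np.outer(resid @ direction, direction)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AxisEstimate(direction=direction, point=point, rms_residual=rms)


def locate_origin(mesh: trimesh.Trimesh, axis: AxisEstimate) -> np.ndarray:
    """Most distal intersection of the long axis with the surface: the point
    where the axis pierces the distal articular surface."""
    hits = line_mesh_intersections(
        axis.point, axis.direction, mesh.vertices, mesh.faces
    )
    if len(hits) == 0:
        raise OriginError("long axis does not intersect the mesh surface")
    # most distal = smallest coordinate along the proximal-positive direction
    return hits[0]


def build_frame(
    axis: AxisEstimate,
    origin: np.ndarray,
    styloid: np.ndarray,
    sigmoid_base: np.ndarray,
    side: str = "right",
) -> AnatomicFrame:
    """Construct the anatomical frame from the fitted axis, the articular
    origin, and the two frame landmarks (radial styloid process and base of
    the ulnar sigmoid notch)."""
    if side not in ("right", "left"):
        raise FrameError(f"side must be 'right' or 'left', got {side!r}")
    origin = np.asarray(origin, dtype=float).reshape(3)
    styloid = np.asarray(styloid, dtype=float).reshape(3)
    sigmoid_base = np.asarray(sigmoid_base, dtype=float).reshape(3)
    if np.allclose(styloid, sigmoid_base):
        raise FrameError("styloid and sigmoid base landmarks coincide")

    y = axis.direction
    raw = styloid - sigmoid_base
    proj = raw - (raw @ y) * y
    norm = np.linalg.norm(proj)
    if norm < 1e-9 * np.linalg.norm(raw) or norm < 1e-12:
        raise FrameError("sigmoid->styloid line is parallel to the long axis")
    z = proj / norm

    mirror_normal = None
    if side == "left":
        # reflect across the plane through the origin perpendicular to the raw
        # radial direction; this turns left anatomy into the right-handed
        # convention (z then flips to point radially in the mirrored scene)
        mirror_normal = z
        z = -z  # reflected radial direction

    x = np.cross(y, z)
    axes = np.column_stack([x, y, z])
    # re-orthogonalise against accumulated round-off
    u, _, vt = np.linalg.svd(axes)
    axes = u @ vt
    return AnatomicFrame(origin=origin, axes=axes, side=side, mirror_normal=mirror_normal)


def to_frame(points: np.ndarray, frame: AnatomicFrame) -> np.ndarray:
    """Express world-coordinate points in the anatomical frame."""
    return frame.to_frame(points)


def from_frame(points: np.ndarray, frame: AnatomicFrame) -> np.ndarray:
    """Map frame-coordinate points back to world coordinates."""
    return frame.from_frame(points)
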