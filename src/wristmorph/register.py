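"""Rigid registration of the post-operative model onto the preoperative plan.

Only the intact proximal shaft — the region unaffected by the fracture and
shared by both models — drives the superposition.  The registration is a
trimmed point-to-point iterative closest point (ICP) with a closed-form SVD
(Kabsch) inner solve, initialised by centroid alignment.  The registration
direction is post-operative scene -> plan scene, because all measurements are
expressed in the plan-derived anatomical frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import RegistrationError
from .frame import AnatomicFrame
from .transforms import RigidTransform

__all__ = [
    "RegistrationResult",
    "mask_intact_region",
    "kabsch",
    "principal_axes_init",
    "icp_rigid",
    "apply_transform",
]


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of an ICP run: the recovered transform plus diagnostics."""

    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool
    n_correspondences: int
    rms_history: tuple[float, ...] = field(default=())


def mask_intact_region(
    mesh: trimesh.Trimesh, frame: AnatomicFrame, proximal_cutoff: float
) -> np.ndarray:
    """Vertices of the intact proximal shaft: frame y-coordinate >= cutoff.

    Returned points stay in the mesh's own (world) coordinates so they can be
    registered across scenes.
    """
    v = np.asarray(mesh.vertices, dtype=float)
    y = frame.to_frame(v)[:, 1]
    sel = y >= proximal_cutoff
    if not sel.any():
        raise RegistrationError(
            f"proximal cutoff {proximal_cutoff} mm selects no vertices "
            f"(mesh frame-y range {y.min():.1f}..{y.max():.1f} mm)"
        )
    return v[sel]


def _validate_point_set(points: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise RegistrationError(f"{name} must be an (n>=3, 3) point set")
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise RegistrationError(f"{name} points are collinear or degenerate")
    return pts


def kabsch(source: np.ndarray, target: np.ndarray, validate: bool = True) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping paired *source*
    points onto *target* (SVD solution with determinant correction)."""
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise RegistrationError("kabsch requires paired point sets of equal shape")
    if validate:
        _validate_point_set(src, "source")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    h = (src - mu_s).T @ (tgt - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rotation, translation=mu_t - rotation @ mu_s)


def principal_axes_init(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Initial alignment from centroids and covariance eigenvectors.

    The eigenvector sign ambiguity leaves four proper-rotation candidates;
    the one with the smallest nearest-neighbour RMS wins.  For congruent
    point sets this is already (near-)exact, which keeps the subsequent ICP
    out of sampling-aligned local minima.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    _, es = np.linalg.eigh(np.cov((src - mu_s).T))
    _, et = np.linalg.eigh(np.cov((tgt - mu_t).T))
    if np.linalg.det(es) < 0:
        es[:, 0] = -es[:, 0]
    if np.linalg.det(et) < 0:
        et[:, 0] = -et[:, 0]
    tree = cKDTree(tgt)
    best: RigidTransform | None = None
    best_rms = np.inf
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            d = np.diag([s1, s2, s1 * s2])  # keeps det = +1
            rotation = et @ d @ es.T
            cand = RigidTransform(rotation=rotation, translation=mu_t - rotation @ mu_s)
            dist, _ = tree.query(cand.apply(src))
            rms = float(np.sqrt((dist**2).mean()))
            if rms < best_rms:
                best, best_rms = cand, rms
    assert best is not None
    return best


def icp_rigid(
    source: np.ndarray,
    target: np.ndarray,
    init: RigidTransform | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    trim_fraction: float = 0.1,
) -> RegistrationResult:
    """Trimmed point-to-point ICP aligning *source* onto *target*.

    Each iteration finds nearest-neighbour correspondences, optionally drops
    the worst ``trim_fraction`` of them, solves the rigid fit in closed form,
    and stops when the RMS residual changes by less than ``tol`` mm.  When no
    *init* is supplied the principal-axes alignment seeds the iteration.
    """
    src = _validate_point_set(source, "source")
    tgt = _validate_point_set(target, "target")
    if not 0.0 <= trim_fraction < 1.0:
        raise RegistrationError("trim_fraction must be in [0, 1)")

    if init is None:
        init = principal_axes_init(src, tgt)
    transform = init
    tree = cKDTree(tgt)
    n_keep = max(3, int(np.ceil(len(src) * (1.0 - trim_fraction))))

    rms_prev = np.inf
    history: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        moved = transform.apply(src)
        dist, nn = tree.query(moved)
        if trim_fraction > 0 and n_keep < len(src):
            keep = np.argpartition(dist, n_keep - 1)[:n_keep]
        else:
            keep = np.arange(len(src))
        transform = kabsch(src[keep], tgt[nn[keep]], validate=False)
        resid = np.linalg.norm(transform.apply(src[keep]) - tgt[nn[keep]], axis=1)
        rms = float(np.sqrt((resid**2).mean()))
        history.append(rms)
        if abs(rms_prev - rms) < tol:
            converged = True
            break
        rms_prev = rms

    return RegistrationResult(
        transform=transform,
        rms=history[-1],
        iterations=iteration,
        converged=converged,
        n_correspondences=int(n_keep),
        rms_history=tuple(history),
    )


def apply_transform(t: RigidTransform, geometry):
    """Apply a rigid transform to points, a landmark dict, or a mesh."""
    if isinstance(geometry, trimesh.Trimesh):
        out = geometry.copy()
        out.vertices = t.apply(np.asarray(geometry.vertices, dtype=float))
        return out
    if isinstance(geometry, dict):
        return {name: t.apply(np.asarray(p, dtype=float)) for name, p in geometry.items()}
    return t.apply(geometry)
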