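"""Low-level triangle geometry used by frame construction and mesh checks.

Vectorised over all faces of a mesh; adequate for the stylised bone models
this package works with (thousands of triangles).
"""

from __future__ import annotations

import numpy as np

__all__ = ["line_mesh_intersections", "point_mesh_distance"]


def line_mesh_intersections(
    origin: np.ndarray,
    direction: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """All intersection points of an infinite line with a triangulated surface.

    Moeller-Trumbore without the t >= 0 cut, so hits behind the origin are
    included.  Returns an (m, 3) array sorted by the signed parameter t along
    *direction* (ascending).
    """
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    tri = np.asarray(vertices, dtype=float)[np.asarray(faces)]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", d, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    hit = ok & (u >= -1e-10) & (v >= -1e-10) & (u + v <= 1.0 + 1e-10)
    t = np.sort(t[hit])
    return origin + t[:, None] * d


def point_mesh_distance(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray
) -> np.ndarray:
    """Unsigned distance from each query point to the nearest triangle.

    Classic region-based closest-point-on-triangle (Ericson), vectorised as
    points x faces; memory is fine for the mesh sizes used here.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))  # (n, 3)
    tri = np.asarray(vertices, dtype=float)[np.asarray(faces)]  # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    # broadcast to (n, m, 3)
    ap = p[:, None, :] - a[None, :, :]
    d1 = np.einsum("mj,nmj->nm", ab, ap)
    d2 = np.einsum("mj,nmj->nm", ac, ap)
    bp = p[:, None, :] - b[None, :, :]
    d3 = np.einsum("mj,nmj->nm", ab, bp)
    d4 = np.einsum("mj,nmj->nm", ac, bp)
    cp = p[:, None, :] - c[None, :, :]
    d5 = np.einsum("mj,nmj->nm", ab, cp)
    d6 = np.einsum("mj,nmj->nm", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_edge_ab = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0), 0, 1)
        w_edge_ac = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0), 0, 1)
        num_bc = d4 - d3
        den_bc = (d4 - d3) + (d5 - d6)
        w_edge_bc = np.clip(np.where(den_bc != 0, num_bc / np.where(den_bc != 0, den_bc, 1.0), 0.0), 0, 1)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / np.where(denom != 0, denom, 1.0), 0.0)
        w_in = np.where(denom != 0, vc / np.where(denom != 0, denom, 1.0), 0.0)

    # candidate closest points per region
    n_pts, m = d1.shape
    closest = np.empty((n_pts, m, 3))

    # region: inside face
    closest[:] = a[None, :, :] + v_in[..., None] * ab[None, :, :] + w_in[..., None] * ac[None, :, :]
    # edge BC
    mask = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    cand = b[None, :, :] + w_edge_bc[..., None] * (c - b)[None, :, :]
    closest = np.where(mask[..., None], cand, closest)
    # edge AC
    mask = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    cand = a[None, :, :] + w_edge_ac[..., None] * ac[None, :, :]
    closest = np.where(mask[..., None], cand, closest)
    # edge AB
    mask = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    cand = a[None, :, :] + v_edge_ab[..., None] * ab[None, :, :]
    closest = np.where(mask[..., None], cand, closest)
    # vertex regions
    mask = (d1 <= 0) & (d2 <= 0)
    closest = np.where(mask[..., None], np.broadcast_to(a, closest.shape), closest)
    mask = (d3 >= 0) & (d4 <= d3)
    closest = np.where(mask[..., None], np.broadcast_to(b, closest.shape), closest)
    mask = (d6 >= 0) & (d5 <= d6)
    closest = np.where(mask[..., None], np.broadcast_to(c, closest.shape), closest)

    dist = np.linalg.norm(p[:, None, :] - closest, axis=-1)
    return dist.min(axis=1)
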