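"""Low-level spatial queries on triangle meshes.

Implements exactly the primitives the package needs — signed triangle solid
angles (van Oosterom & Strackee), winding-number containment, orthographic
ray casting and point-to-surface distances — vectorised with numpy/scipy.
The solid-angle kernel is shared with the boundary-element assembly, where
its exactness gives the solid-angle row-sum identity to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "triangle_solid_angles",
    "total_solid_angle",
    "contains",
    "signed_distance",
    "raycast_first_hit",
]


def triangle_solid_angles(points: np.ndarray, tri_a: np.ndarray,
                          tri_b: np.ndarray, tri_c: np.ndarray) -> np.ndarray:
    """Signed solid angle of triangles (a, b, c) seen from ``points``.

    Broadcasts ``points`` (n, 3) against triangles (m, 3) to an (n, m) array,
    using the van Oosterom-Strackee formula.  The sign is positive when the
    triangle winds counter-clockwise seen from the point (outward-oriented
    closed surfaces subtend -4pi from inside with this convention flipped;
    see :func:`total_solid_angle` for the normalised version).
    """
    r1 = tri_a[None, :, :] - points[:, None, :]
    r2 = tri_b[None, :, :] - points[:, None, :]
    r3 = tri_c[None, :, :] - points[:, None, :]
    n1 = np.linalg.norm(r1, axis=2)
    n2 = np.linalg.norm(r2, axis=2)
    n3 = np.linalg.norm(r3, axis=2)
    triple = np.einsum("nmi,nmi->nm", r1, np.cross(r2, r3))
    denom = (n1 * n2 * n3 + np.einsum("nmi,nmi->nm", r1, r2) * n3
             + np.einsum("nmi,nmi->nm", r1, r3) * n2
             + np.einsum("nmi,nmi->nm", r2, r3) * n1)
    return 2.0 * np.arctan2(triple, denom)


def total_solid_angle(points: np.ndarray, vertices: np.ndarray,
                      faces: np.ndarray, chunk: int = 2_000_000) -> np.ndarray:
    """Total solid angle (~4pi inside, ~0 outside) of a closed surface."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    out = np.empty(len(points))
    step = max(1, chunk // max(1, len(faces)))
    for i in range(0, len(points), step):
        out[i:i + step] = triangle_solid_angles(points[i:i + step], a, b, c).sum(axis=1)
    return out


def contains(points: np.ndarray, vertices: np.ndarray,
             faces: np.ndarray) -> np.ndarray:
    """Winding-number point containment for a closed, outward-oriented mesh."""
    return np.abs(total_solid_angle(points, vertices, faces)) > 2.0 * np.pi


def _point_triangle_dist(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                         c: np.ndarray) -> np.ndarray:
    """Exact distances for paired points/triangles (n, 3) -> (n,).

    Closest-point-on-triangle by region classification (Ericson).
    """
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ni,ni->n", ab, ap)
    d2 = np.einsum("ni,ni->n", ac, ap)
    bp = points - b
    d3 = np.einsum("ni,ni->n", ab, bp)
    d4 = np.einsum("ni,ni->n", ac, bp)
    cp = points - c
    d5 = np.einsum("ni,ni->n", ab, cp)
    d6 = np.einsum("ni,ni->n", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                      # vertex a
    closest[m] = a[m]; done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)           # vertex b
    closest[m] = b[m]; done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)           # vertex c
    closest[m] = c[m]; done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
    closest[m] = a[m] + t[m, None] * ab[m]; done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
    closest[m] = a[m] + t[m, None] * ac[m]; done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    closest[m] = b[m] + t[m, None] * (c[m] - b[m]); done |= m

    m = ~done                                        # interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    return np.linalg.norm(points - closest, axis=1)


def signed_distance(points: np.ndarray, vertices: np.ndarray,
                    faces: np.ndarray, k: int = 24) -> np.ndarray:
    """Distance to a closed mesh, negative inside.

    Candidate faces come from a k-NN query on face centroids, widened by the
    largest face circumradius so the true nearest face is never missed.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    centroids = (a + b + c) / 3.0
    spread = np.max(np.linalg.norm(
        np.stack([a, b, c]) - centroids[None], axis=2))
    tree = cKDTree(centroids)
    k = min(k, len(faces))
    d_cent, idx = tree.query(points, k=k)
    d_cent = np.atleast_2d(d_cent)
    idx = np.atleast_2d(idx)

    dist = np.full(len(points), np.inf)
    for j in range(k):
        fj = idx[:, j]
        dist = np.minimum(dist, _point_triangle_dist(points, a[fj], b[fj], c[fj]))

    # widen where further centroids could still host a closer face
    bound = d_cent[:, -1] - spread
    unsure = dist > bound
    if np.any(unsure) and k < len(faces):
        pts_u = points[unsure]
        cand = tree.query_ball_point(pts_u, r=(dist[unsure] + spread) * 1.0001)
        du = dist[unsure]
        for i, faces_i in enumerate(cand):
            if not faces_i:
                continue
            fi = np.asarray(faces_i)
            p = np.repeat(pts_u[i][None], len(fi), axis=0)
            du[i] = min(du[i], _point_triangle_dist(p, a[fi], b[fi], c[fi]).min())
        dist[unsure] = du

    inside = contains(points, vertices, faces)
    return np.where(inside, -dist, dist)


def raycast_first_hit(origins: np.ndarray, direction: np.ndarray,
                      vertices: np.ndarray, faces: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First intersection of parallel rays with a mesh (Moller-Trumbore).

    Returns (ray_indices, hit_points, face_indices) for rays that hit,
    keeping the nearest (smallest positive t) intersection per ray.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)

    a = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - a
    e2 = vertices[faces[:, 2]] - a
    pvec = np.cross(d, e2)                      # (m, 3)
    det = np.einsum("mi,mi->m", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    best_t = np.full(len(origins), np.inf)
    best_face = np.full(len(origins), -1, dtype=np.int64)
    chunk = max(1, 4_000_000 // max(1, len(faces)))
    eps = 1e-9
    for i in range(0, len(origins), chunk):
        o = origins[i:i + chunk]
        tvec = o[:, None, :] - a[None, :, :]
        u = np.einsum("nmi,mi->nm", tvec, pvec) * inv_det[None, :]
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("nmi,i->nm", qvec, d) * inv_det[None, :]
        t = np.einsum("nmi,mi->nm", qvec, e2) * inv_det[None, :]
        hit = (ok[None, :] & (u >= -eps) & (v >= -eps)
               & (u + v <= 1 + eps) & (t > eps))
        t = np.where(hit, t, np.inf)
        jmin = np.argmin(t, axis=1)
        tmin = t[np.arange(len(o)), jmin]
        sel = tmin < best_t[i:i + chunk]
        best_t[i:i + chunk][sel] = tmin[sel]
        best_face[i:i + chunk][sel] = jmin[sel]

    hit_rays = np.flatnonzero(np.isfinite(best_t))
    pts = origins[hit_rays] + best_t[hit_rays, None] * d[None, :]
    return hit_rays, pts, best_face[hit_rays]
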