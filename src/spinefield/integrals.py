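"""Surface-integral assembly for linear-collocation boundary elements.

Two operators are built over a triangulated surface with a linear (hat)
vertex basis:

* the double-layer (solid-angle) operator used in the boundary potential
  equation, and
* the Geselowitz magnetic surface-integral weights mapping vertex potentials
  to a field component at a sensor.

Both use the same strategy: the signed solid angle of every (sub)triangle is
evaluated exactly (van Oosterom-Strackee) or by a centroid rule for the
magnetic kernel, and attributed to the parent triangle's vertices with the
linear shape functions evaluated at the subtriangle centroid.  Triangles are
4-way subdivided with a depth that grows as the field point approaches, so
near-singular interactions are resolved while far pairs cost one evaluation.
Because subdivision preserves the total solid angle exactly, the operator's
row sums satisfy the solid-angle identity to machine precision — the property
used to complete the diagonal of the potential equation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse

__all__ = ["double_layer_matrix", "magnetic_weight_matrix"]

# distance-to-diameter thresholds for subdivision depths 1..4 (below the
# last threshold depth 4 is used; above the first, a single evaluation)
_BANDS = (4.0, 2.0, 1.0, 0.5)
_MAX_DEPTH = 4


@lru_cache(maxsize=None)
def _subdivision_bary(depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric corners (K, 3, 3) and centroids (K, 3) of the uniform
    4-way subdivision of a triangle at the given depth (K = 4**depth)."""
    corners = np.eye(3)[None, :, :]
    for _ in range(depth):
        new = []
        for tri in corners:
            a, b, c = tri
            ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
            new.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
        corners = np.asarray(new)
    return corners, corners.mean(axis=1)


def _vos_pairs(p: np.ndarray, a: np.ndarray, b: np.ndarray,
               c: np.ndarray) -> np.ndarray:
    """Signed solid angles for paired points/triangles, all (n, 3)."""
    r1, r2, r3 = a - p, b - p, c - p
    n1 = np.linalg.norm(r1, axis=-1)
    n2 = np.linalg.norm(r2, axis=-1)
    n3 = np.linalg.norm(r3, axis=-1)
    triple = np.einsum("...i,...i->...", r1, np.cross(r2, r3))
    denom = (n1 * n2 * n3 + np.einsum("...i,...i->...", r1, r2) * n3
             + np.einsum("...i,...i->...", r1, r3) * n2
             + np.einsum("...i,...i->...", r2, r3) * n1)
    return 2.0 * np.arctan2(triple, denom)


def _face_geometry(vertices: np.ndarray, faces: np.ndarray):
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    centroids = (a + b + c) / 3.0
    cross = np.cross(b - a, c - a)
    areas2 = np.linalg.norm(cross, axis=1)
    normals = cross / areas2[:, None]
    diam = np.maximum.reduce([
        np.linalg.norm(b - a, axis=1),
        np.linalg.norm(c - b, axis=1),
        np.linalg.norm(a - c, axis=1)])
    return a, b, c, centroids, normals, areas2 / 2.0, diam


def _vertex_scatter(faces: np.ndarray, n_vertices: int) -> sparse.csr_matrix:
    """(F, V) matrix distributing a per-face value equally to its vertices."""
    m = len(faces)
    rows = np.repeat(np.arange(m), 3)
    return sparse.csr_matrix(
        (np.full(3 * m, 1.0 / 3.0), (rows, faces.ravel())),
        shape=(m, n_vertices))


def double_layer_matrix(points: np.ndarray, vertices: np.ndarray,
                        faces: np.ndarray, point_chunk: int = 96) -> np.ndarray:
    """Linear-collocation double-layer operator W of shape (P, V).

    ``(W @ phi)[i]`` approximates (1/4pi) times the integral of
    ``phi(r') (r' - y_i) . n' / |r' - y_i|^3`` over the surface, with phi
    linearly interpolated from vertex values.  Row sums equal the normalised
    solid angle of the closed surface seen from each point: 1 inside,
    0 outside, the interior vertex solid angle / 4pi on the surface (flat
    triangles meeting at the collocation vertex contribute exactly zero).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    a, b, c, cent, _, _, diam = _face_geometry(vertices, faces)
    scatter = _vertex_scatter(faces, len(vertices))
    P = len(points)
    out = np.zeros((P, len(vertices)))

    for i0 in range(0, P, point_chunk):
        pts = points[i0:i0 + point_chunk]
        omega = _vos_pairs(pts[:, None, :], a[None], b[None], c[None])
        dist = np.linalg.norm(pts[:, None, :] - cent[None], axis=2)
        depth = np.digitize(-(dist / diam[None]), -np.asarray(_BANDS))
        near = depth > 0
        omega_far = np.where(near, 0.0, omega)
        out[i0:i0 + point_chunk] = omega_far @ scatter

        if np.any(near):
            ii, jj = np.nonzero(near)
            _refine_pairs(out, i0 + ii, jj, depth[ii, jj], points, faces,
                          a, b, c, kind="omega")
    out /= 4.0 * np.pi
    return out


def magnetic_weight_matrix(points: np.ndarray, orientations: np.ndarray,
                           vertices: np.ndarray, faces: np.ndarray,
                           point_chunk: int = 96) -> np.ndarray:
    """Geselowitz magnetic surface-integral weights, shape (P, V).

    ``(G @ phi)[i]`` approximates the integral of
    ``phi(r') o_i . (n' x (r_i - r')) / |r_i - r'|^3`` over the surface
    (linear phi interpolation, centroid rule with distance-adaptive 4-way
    refinement).  The quantity is dimensionless: any consistent length unit
    may be used.  Field points must not lie on the surface.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    orientations = np.atleast_2d(np.asarray(orientations, dtype=np.float64))
    a, b, c, cent, normals, areas, diam = _face_geometry(vertices, faces)
    scatter = _vertex_scatter(faces, len(vertices))
    P = len(points)
    out = np.zeros((P, len(vertices)))

    for i0 in range(0, P, point_chunk):
        pts = points[i0:i0 + point_chunk]
        ori = orientations[i0:i0 + point_chunk]
        rvec = pts[:, None, :] - cent[None]
        dist = np.linalg.norm(rvec, axis=2)
        kern = np.cross(normals[None], rvec) / dist[..., None] ** 3
        val = np.einsum("pfi,pi->pf", kern, ori) * areas[None]
        depth = np.digitize(-(dist / diam[None]), -np.asarray(_BANDS))
        near = depth > 0
        val = np.where(near, 0.0, val)
        out[i0:i0 + point_chunk] = val @ scatter

        if np.any(near):
            ii, jj = np.nonzero(near)
            touching = depth[ii, jj] >= _MAX_DEPTH - 1
            if np.any(touching):
                from .spatial import _point_triangle_dist
                it, jt = ii[touching], jj[touching]
                exact = _point_triangle_dist(pts[it], a[jt], b[jt], c[jt])
                if np.any(exact < 1e-6 * diam[jt]):
                    raise ValueError(
                        "field point lies on the integration surface")
            _refine_pairs(out, i0 + ii, jj, depth[ii, jj], points, faces,
                          a, b, c, kind="biot", normals=normals, areas=areas,
                          orientations=orientations)
    return out


def _refine_pairs(out: np.ndarray, ipt: np.ndarray, jfc: np.ndarray,
                  depth: np.ndarray, points: np.ndarray, faces: np.ndarray,
                  a: np.ndarray, b: np.ndarray, c: np.ndarray, kind: str,
                  normals: np.ndarray | None = None,
                  areas: np.ndarray | None = None,
                  orientations: np.ndarray | None = None,
                  budget: int = 2_000_000) -> None:
    """Recompute near pairs at their subdivision depth and accumulate."""
    for d in np.unique(depth):
        sel = depth == d
        lvl = min(int(d), _MAX_DEPTH)
        corners_b, cent_b = _subdivision_bary(lvl)
        K = len(corners_b)
        idx_p, idx_f = ipt[sel], jfc[sel]
        step = max(1, budget // K)
        for s0 in range(0, len(idx_p), step):
            ip = idx_p[s0:s0 + step]
            jf = idx_f[s0:s0 + step]
            tri = np.stack([a[jf], b[jf], c[jf]], axis=1)      # (n, 3corner, 3)
            pts = points[ip]                                    # (n, 3)
            if kind == "omega":
                sub = np.einsum("kqm,nmx->nkqx", corners_b, tri)  # (n,K,3,3)
                vals = _vos_pairs(pts[:, None, :], sub[:, :, 0],
                                  sub[:, :, 1], sub[:, :, 2])     # (n, K)
            else:
                cen = np.einsum("km,nmx->nkx", cent_b, tri)       # (n, K, 3)
                rv = pts[:, None, :] - cen
                dist = np.linalg.norm(rv, axis=2)
                kern = np.cross(normals[jf][:, None, :], rv) / dist[..., None] ** 3
                vals = (np.einsum("nki,ni->nk", kern, orientations[ip])
                        * (areas[jf] / K)[:, None])
            # linear shape functions at subtriangle centroids
            w = np.einsum("nk,kq->nq", vals, cent_b)              # (n, 3)
            for q in range(3):
                np.add.at(out, (ip, faces[jf, q]), w[:, q])
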