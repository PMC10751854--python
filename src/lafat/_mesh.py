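"""Low-level triangle-mesh geometry used across the pipeline.

All routines work without a spatial-index backend: candidate triangles are
found with a :class:`scipy.spatial.cKDTree` over face centroids and refined
with exact point-to-triangle distances, and voxel containment is evaluated
slice by slice via planar cross-section polygons.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from shapely import contains_xy


def _exact_candidate_distances(mesh: trimesh.Trimesh, points: np.ndarray,
                               candidates: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact distances from each point to each of its candidate faces.

    candidates: (n_points, k) face indices.  Returns (distance, closest
    point, face index) of the best candidate per point.
    """
    n, k = candidates.shape
    flat_faces = candidates.reshape(-1)
    flat_points = np.repeat(points, k, axis=0)
    closest = trimesh.triangles.closest_point(mesh.triangles[flat_faces], flat_points)
    d = np.linalg.norm(closest - flat_points, axis=1).reshape(n, k)
    best = np.argmin(d, axis=1)
    rows = np.arange(n)
    return (d[rows, best],
            closest.reshape(n, k, 3)[rows, best],
            candidates[rows, best])


def nearest_on_surface(mesh: trimesh.Trimesh, points: np.ndarray, k: int = 32
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest point on a triangulated surface for each query point.

    Two-phase exact search: the k nearest face centroids give an upper
    bound d0 on the true distance; any face whose centroid lies within
    d0 + r_max (r_max = largest centroid-to-vertex radius) could carry a
    closer point, so queries whose guarantee ball holds more than k
    centroids are re-examined against every face in the ball.

    Returns (distance mm, closest point, face index).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = mesh.triangles_center
    tree = cKDTree(centers)
    k = min(k, len(centers))
    _, idx = tree.query(points, k=k)
    idx = idx.reshape(len(points), k)
    dist, closest, face = _exact_candidate_distances(mesh, points, idx)

    r_max = np.linalg.norm(mesh.triangles - centers[:, None, :], axis=2).max()
    radius = dist + r_max + 1e-9
    n_in_ball = tree.query_ball_point(points, radius, return_length=True)
    for i in np.nonzero(n_in_ball > k)[0]:
        cand = np.asarray(tree.query_ball_point(points[i], radius[i]), dtype=int)
        cand = np.setdiff1d(cand, idx[i], assume_unique=False)
        if len(cand) == 0:
            continue
        c = trimesh.triangles.closest_point(mesh.triangles[cand],
                                            np.repeat(points[i][None], len(cand), axis=0))
        d = np.linalg.norm(c - points[i], axis=1)
        j = np.argmin(d)
        if d[j] < dist[i]:
            dist[i], closest[i], face[i] = d[j], c[j], cand[j]
    return dist, closest, face


def signed_distance(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Signed distance to a closed, outward-wound surface (positive inside).

    The sign comes from the outward normal of the face carrying the nearest
    point; adequate for the smooth closed shells used here.
    """
    dist, closest, face = nearest_on_surface(mesh, points)
    outward = np.einsum("ij,ij->i", np.atleast_2d(points) - closest, mesh.face_normals[face])
    return np.where(outward <= 0.0, dist, -dist)


def _section_polygons(mesh: trimesh.Trimesh, z_values: np.ndarray):
    """World-frame xy polygons of the mesh cross-section at each z level."""
    origin = mesh.bounds.mean(axis=0)
    sections = mesh.section_multiplane(plane_origin=[0.0, 0.0, float(origin[2])],
                                       plane_normal=[0.0, 0.0, 1.0],
                                       heights=z_values - origin[2])
    from shapely.geometry import Polygon

    out = []
    for sec in sections:
        if sec is None:
            out.append([])
            continue
        T = sec.metadata["to_3D"]
        polys = []
        for curve in sec.discrete:  # closed 2D polylines, one per section loop
            uv = np.asarray(curve)
            pts = np.column_stack([uv, np.zeros(len(uv)), np.ones(len(uv))])
            world = (T @ pts.T).T[:, :2]
            if len(world) >= 4:
                polys.append(Polygon(world))
        out.append(polys)
    return out


def inside_mask(mesh: trimesh.Trimesh, origin: np.ndarray, spacing: np.ndarray,
                shape: tuple[int, int, int]) -> np.ndarray:
    """Boolean grid marking voxel centers strictly inside a closed mesh.

    The grid must be axis-aligned: voxel center (i,j,k) sits at
    origin + (i,j,k) * spacing.  Containment is evaluated per z-slice by
    even-odd point-in-polygon tests against the closed section curves of
    the mesh, so nested cross-sections (holes) are handled correctly.
    """
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    lo, hi = mesh.bounds
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    k_sel = np.nonzero((zs > lo[2]) & (zs < hi[2]))[0]
    if len(k_sel) == 0:
        return mask
    polys_per_slice = _section_polygons(mesh, zs[k_sel])

    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    for k, polys in zip(k_sel, polys_per_slice):
        parity = np.zeros((shape[0], shape[1]), dtype=np.uint8)
        for poly in polys:
            bx0, by0, bx1, by1 = poly.bounds
            i_sel = np.nonzero((xs >= bx0) & (xs <= bx1))[0]
            j_sel = np.nonzero((ys >= by0) & (ys <= by1))[0]
            if len(i_sel) == 0 or len(j_sel) == 0:
                continue
            gx, gy = np.meshgrid(xs[i_sel], ys[j_sel], indexing="ij")
            hit = contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
            parity[i_sel[:, None], j_sel[None, :]] += hit
        mask[:, :, k] = (parity % 2).astype(bool)
    return mask


def point_to_segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to the 3D segment [a, b]."""
    points = np.atleast_2d(points)
    ab = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)
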