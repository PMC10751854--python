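"""Left atrial wall thickness (LAWT) maps.

Thickness at each endocardial vertex is the Euclidean distance to its
projection on the epicardial shell.  The projection is the nearest point
on the epicardial surface by default (point-to-triangle minimisation);
an alternative mode casts a ray along the outward vertex normal.  The
colour scale follows the conventional five-bin map: red < 1 mm,
1 mm <= yellow < 2 mm, 2 mm <= green < 3 mm, 3 mm <= blue < 4 mm and
purple >= 4 mm, with boundary values going to the upper-named bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from ._mesh import nearest_on_surface, signed_distance

COLOUR_BINS = ("red", "yellow", "green", "blue", "purple")
_BIN_EDGES = np.array([1.0, 2.0, 3.0, 4.0])


class GeometryError(ValueError):
    pass


@dataclass
class ThicknessMap:
    """Per-endocardial-vertex wall thickness with colour bins."""

    thickness_mm: np.ndarray        # (n_vertices,)
    colour: np.ndarray              # (n_vertices,) strings from COLOUR_BINS
    mean_thickness_mm: float        # area-weighted vertex average
    vertex_area_mm2: np.ndarray     # lumped (barycentric) vertex areas

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "vertex": np.arange(len(self.thickness_mm)),
            "thickness_mm": self.thickness_mm,
            "colour": self.colour,
        })


def bin_thickness(t):
    """Map thickness (mm) to its colour bin; accepts scalars or arrays."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("thickness must be non-negative")
    idx = np.searchsorted(_BIN_EDGES, arr, side="right")
    if arr.ndim == 0:
        return COLOUR_BINS[int(idx)]
    return np.asarray(COLOUR_BINS, dtype=object)[idx]


def vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Lumped vertex areas: one third of each incident triangle's area."""
    areas = np.zeros(len(mesh.vertices))
    np.add.at(areas, mesh.faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    return areas


def _validate_nested(endo: trimesh.Trimesh, epi: trimesh.Trimesh, tol: float = 1e-6) -> None:
    sd = signed_distance(epi, endo.vertices)  # positive inside
    outside = np.nonzero(sd < -tol)[0]
    if len(outside):
        v = int(outside[np.argmin(sd[outside])])
        raise GeometryError(
            f"endocardial vertex {v} lies {-sd[v]:.3f} mm outside the epicardial shell")


def compute_lawt(endo: trimesh.Trimesh, epi: trimesh.Trimesh,
                 mode: str = "nearest") -> ThicknessMap:
    """Wall thickness at every endocardial vertex.

    mode="nearest" measures to the nearest point on the epicardial surface;
    mode="ray" casts along the outward endocardial vertex normal and falls
    back to the nearest point where the ray misses.
    """
    _validate_nested(endo, epi)
    dist, closest, _ = nearest_on_surface(epi, endo.vertices)
    if mode == "ray":
        dist = _ray_thickness(endo, epi, fallback=dist)
    elif mode != "nearest":
        raise ValueError(f"unknown projection mode {mode!r}")
    areas = vertex_areas(endo)
    mean = float(np.average(dist, weights=areas)) if areas.sum() > 0 else float(dist.mean())
    return ThicknessMap(thickness_mm=dist, colour=bin_thickness(dist),
                        mean_thickness_mm=mean, vertex_area_mm2=areas)


def _ray_thickness(endo: trimesh.Trimesh, epi: trimesh.Trimesh,
                   fallback: np.ndarray) -> np.ndarray:
    """First-hit distance along outward vertex normals (vectorised Möller–Trumbore)."""
    origins = endo.vertices
    dirs = endo.vertex_normals
    v0 = epi.triangles[:, 0]
    e1 = epi.triangles[:, 1] - v0
    e2 = epi.triangles[:, 2] - v0
    out = fallback.copy()
    for i in range(len(origins)):
        o, d = origins[i], dirs[i]
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > 1e-12
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - v0
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = (q @ d) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        if np.any(hit):
            out[i] = t[hit].min()
    return out
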