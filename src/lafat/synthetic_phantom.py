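"""Synthetic CT phantoms with known two-shell LA geometry and planted fat.

Three phantom shapes are available:

* ``concentric_spheres`` — endocardial sphere of radius r inside an
  epicardial sphere of radius R; every derived quantity is analytic.
* ``ellipsoid_shell`` — anisotropic version; shells are scaled icospheres.
* ``la_like`` — an ellipsoidal atrial body with four pulmonary-vein tubes
  and an appendage stub, built from a signed-distance field; the
  epicardial shell is the constant-thickness outward offset of the
  endocardial surface, meshes are marching-cubes isosurfaces, and a full
  landmark set (PV ostium loops and planes, appendage ostium, mitral
  annulus, body frame) is derived from the construction.

Voxel HU equal the level of the region containing the voxel center
(contrast blood pool +350 HU, myocardium +40 HU, optional epicardial fat
-100 HU, background -1000 HU by default) plus Gaussian noise (default
sd 10 HU).  Fat deposits are grown by breadth-first voxel accretion from
a deterministic seed voxel inside the (eroded) wall, and their HU are
drawn uniformly from a configurable range strictly inside the target
class interval, so the planted support never straddles a class boundary.
A single generator seed fixes the noise field, deposit HU draws and
cohort draws.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from . import la_parcellation
from .io_formats import (CtVolume, Frame, LandmarkSet, Plane, ValidationError,
                         GROUPS, PV_LABELS)

log = logging.getLogger(__name__)

#: default HU ranges for planted deposits, strictly inside the class bounds
DEFAULT_DEPOSIT_HU = {"dense": (-130.0, -70.0), "admixture": (-45.0, -10.0)}
_CLASS_BOUNDS = {"dense": (-194.0, -50.0), "admixture": (-50.0, -5.0)}

#: default inward/outward directions (landmark-frame) of the PV tubes and
#: appendage stub of the la_like shape
_PV_DIRECTIONS = {
    "LSPV": (0.70, -0.38, 0.38),
    "LIPV": (0.70, -0.38, -0.38),
    "RSPV": (-0.70, -0.38, 0.38),
    "RIPV": (-0.70, -0.38, -0.38),
}
_LAA_DIRECTION = (0.62, 0.47, 0.55)
_MITRAL_NORMAL = (0.0, 0.42, -0.91)


@dataclass
class HuLevels:
    blood_pool: float = 350.0
    myocardium: float = 40.0
    epicardial_fat: float = -100.0
    background: float = -1000.0


@dataclass
class PhantomSpec:
    """Geometry, HU levels and sampling of a synthetic phantom."""

    shape: str = "la_like"           # concentric_spheres | ellipsoid_shell | la_like
    endo_radius: float = 20.0        # spheres
    epi_radius: float = 22.0
    endo_axes: tuple = (32.0, 27.0, 25.0)   # ellipsoid / la_like body semi-axes, mm
    wall_thickness: float = 2.0      # ellipsoid / la_like constant offset, mm
    spacing: tuple = (0.5, 0.5, 0.5)
    hu: HuLevels = field(default_factory=HuLevels)
    noise_sd: float = 10.0
    seed: int = 0
    # grid placement: world offset of the phantom center, chosen off-lattice
    # so that no voxel center sits exactly on an analytic surface
    center: tuple = (0.1234, 0.2173, 0.3391)
    eat_thickness: float = 0.0       # epicardial fat layer outside the epi shell, mm
    margin: float = 3.0
    # la_like extras
    pv_radius: float = 5.0
    pv_length: float = 12.0
    laa_radius: float = 4.5
    laa_length: float = 10.0
    mesh_pitch: float = 0.8          # marching-cubes grid pitch, mm

    def __post_init__(self) -> None:
        if min(self.spacing) <= 0:
            raise ValidationError("voxel spacing must be positive")
        if self.shape == "concentric_spheres":
            if not 0 < self.endo_radius < self.epi_radius:
                raise ValidationError("need 0 < endo_radius < epi_radius")
        elif self.shape in ("ellipsoid_shell", "la_like"):
            if self.wall_thickness <= 0:
                raise ValidationError("wall thickness must be positive")
        else:
            raise ValidationError(f"unknown phantom shape {self.shape!r}")
        if self.wall_voxels_across < 2:
            warnings.warn("wall thinner than 2 voxels: partial-volume regime",
                          stacklevel=2)

    @property
    def wall_voxels_across(self) -> float:
        t = (self.epi_radius - self.endo_radius
             if self.shape == "concentric_spheres" else self.wall_thickness)
        return t / max(self.spacing)


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a phantom volume."""

    endo_mesh: trimesh.Trimesh
    epi_mesh: trimesh.Trimesh
    cavity_volume_ml: float
    wall_volume_ml: float
    landmarks: LandmarkSet | None
    deposits: list = field(default_factory=list)
    wall_mask: np.ndarray | None = None     # analytic voxel-center wall mask
    blood_mask: np.ndarray | None = None
    rng: np.random.Generator | None = None
    _geometry: object = None                 # cached parcellation geometry

    def geometry(self) -> la_parcellation.ParcellationGeometry:
        if self.landmarks is None:
            raise ValidationError("phantom has no landmarks")
        if self._geometry is None:
            self._geometry = la_parcellation.derive_geometry(self.epi_mesh, self.landmarks)
        return self._geometry

    def manifest(self) -> dict:
        return {
            "cavity_volume_ml": self.cavity_volume_ml,
            "wall_volume_ml": self.wall_volume_ml,
            "deposits": [
                {k: d[k] for k in ("segment", "class", "volume_ml", "n_voxels", "hu_range")}
                for d in self.deposits
            ],
        }

    def write_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.manifest(), indent=1))
        return path


# ---------------------------------------------------------------------------
# signed-distance construction
# ---------------------------------------------------------------------------

def _ellipsoid_sdf(points: np.ndarray, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """First-order signed distance to an ellipsoid (negative inside)."""
    rel = points - center
    q = np.sqrt(np.sum((rel / axes) ** 2, axis=-1))
    g = np.sqrt(np.sum((rel / axes**2) ** 2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (q - 1.0) * q / np.maximum(g, 1e-12)
    deep = q < 0.25
    return np.where(deep, (q - 1.0) * min(axes), f)


def _capsule_sdf(points: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    ab = b - a
    h = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(points - a - h[..., None] * ab, axis=-1) - r


class _LaLikeGeometry:
    """Analytic definition of the la_like shape in world coordinates."""

    def __init__(self, spec: PhantomSpec):
        self.center = np.asarray(spec.center, dtype=float)
        self.axes = np.asarray(spec.endo_axes, dtype=float)
        self.tubes = {}
        for label, d in _PV_DIRECTIONS.items():
            self.tubes[label] = self._tube(d, spec.pv_radius, spec.pv_length)
        self.tubes["LAA"] = self._tube(_LAA_DIRECTION, spec.laa_radius, spec.laa_length)
        m = np.asarray(_MITRAL_NORMAL, dtype=float)
        m /= np.linalg.norm(m)
        support = float(np.sqrt(np.sum((self.axes * m) ** 2)))
        self.mitral_plane = Plane(self.center + m * 0.72 * support, m)

    def _tube(self, direction, radius, length):
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        t = 1.0 / np.sqrt(np.sum((d / self.axes) ** 2))
        junction = self.center + t * d
        return {"direction": d, "radius": radius, "junction": junction,
                "a": junction - 4.0 * d, "b": junction + length * d}

    def endo_sdf(self, points: np.ndarray) -> np.ndarray:
        f = _ellipsoid_sdf(points, self.center, self.axes)
        for tube in self.tubes.values():
            f = np.minimum(f, _capsule_sdf(points, tube["a"], tube["b"], tube["radius"]))
        return f


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------

#: fixed sub-voxel grid shift: keeps voxel centers off the analytic
#: surfaces even when radii are integer multiples of the spacing
_GRID_SHIFT = np.array([0.2437, 0.3171, 0.1193])


def _make_grid(center: np.ndarray, half_extent: float, spacing: np.ndarray):
    n = np.ceil(2.0 * half_extent / spacing).astype(int) + 2
    origin = center - (n - 1) / 2.0 * spacing + _GRID_SHIFT * spacing
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return n, origin, affine


def _grid_points(origin: np.ndarray, spacing: np.ndarray, n: np.ndarray) -> np.ndarray:
    ax = [origin[i] + np.arange(n[i]) * spacing[i] for i in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def _mc_mesh(field: np.ndarray, level: float, origin: np.ndarray, pitch: float
             ) -> trimesh.Trimesh:
    verts, faces, _, _ = marching_cubes(field, level=level, allow_degenerate=False)
    mesh = trimesh.Trimesh(vertices=origin + verts * pitch, faces=faces, process=True)
    if not mesh.is_watertight:
        raise ValidationError("marching-cubes shell is not watertight; "
                              "increase the grid margin")
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> tuple[CtVolume, PhantomTruth]:
    """Build the CT volume, true shells, landmarks and truth manifest."""
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(spec.center, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)

    if spec.shape == "concentric_spheres":
        r, R = spec.endo_radius, spec.epi_radius
        n, origin, affine = _make_grid(center, R + spec.eat_thickness + spec.margin, spacing)
        pts = _grid_points(origin, spacing, n)
        f = np.linalg.norm(pts - center, axis=-1) - r      # exact SDF
        thickness = R - r
        endo = trimesh.creation.icosphere(subdivisions=4, radius=r)
        epi = trimesh.creation.icosphere(subdivisions=4, radius=R)
        endo.apply_translation(center)
        epi.apply_translation(center)
        cavity_ml = 4.0 / 3.0 * np.pi * r**3 / 1000.0
        landmarks = None
    elif spec.shape == "ellipsoid_shell":
        axes = np.asarray(spec.endo_axes, dtype=float)
        t = spec.wall_thickness
        n, origin, affine = _make_grid(center, axes.max() + t + spec.eat_thickness
                                       + spec.margin, spacing)
        pts = _grid_points(origin, spacing, n)
        f = _ellipsoid_sdf(pts, center, axes)
        thickness = t
        endo = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        endo.vertices = endo.vertices * axes + center
        # the epicardial shell is the constant-thickness normal offset of the
        # endocardial ellipsoid (not a larger ellipsoid)
        epi = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        epi.vertices = epi.vertices * axes + center
        normals = epi.vertex_normals.copy()
        epi = trimesh.Trimesh(vertices=epi.vertices + t * normals, faces=epi.faces,
                              process=True)
        cavity_ml = 4.0 / 3.0 * np.pi * float(np.prod(axes)) / 1000.0
        landmarks = None
    else:  # la_like
        geom = _LaLikeGeometry(spec)
        t = spec.wall_thickness
        reach = max(np.linalg.norm(tube["b"] - center) + tube["radius"]
                    for tube in geom.tubes.values())
        half_extent = max(geom.axes.max(), reach) + t + spec.eat_thickness + spec.margin
        n, origin, affine = _make_grid(center, half_extent, spacing)
        pts = _grid_points(origin, spacing, n)
        f = geom.endo_sdf(pts)
        thickness = t
        endo, epi = _la_like_meshes(spec, geom, half_extent)
        cavity_ml = float(endo.volume) / 1000.0
        landmarks = _la_like_landmarks(spec, geom, epi)

    blood = f < 0.0
    wall = (f >= 0.0) & (f < thickness)
    data = np.full(f.shape, spec.hu.background, dtype=np.float32)
    if spec.eat_thickness > 0:
        data[(f >= thickness) & (f < thickness + spec.eat_thickness)] = spec.hu.epicardial_fat
    data[wall] = spec.hu.myocardium
    data[blood] = spec.hu.blood_pool
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)

    ct = CtVolume(data=data, affine=affine)
    truth = PhantomTruth(
        endo_mesh=endo, epi_mesh=epi,
        cavity_volume_ml=cavity_ml,
        wall_volume_ml=float(wall.sum()) * ct.voxel_volume_ml,
        landmarks=landmarks, wall_mask=wall, blood_mask=blood, rng=rng)
    log.info("phantom %s: %.2f mL cavity, %.2f mL wall, %d wall voxels",
             spec.shape, truth.cavity_volume_ml, truth.wall_volume_ml, int(wall.sum()))
    return ct, truth


def _la_like_meshes(spec: PhantomSpec, geom: _LaLikeGeometry, half_extent: float):
    pitch = spec.mesh_pitch
    n = int(np.ceil(2.0 * (half_extent + 2.0) / pitch)) + 1
    origin = geom.center - (n - 1) / 2.0 * pitch + _GRID_SHIFT * pitch
    ax = [origin[i] + np.arange(n) * pitch for i in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    f = geom.endo_sdf(np.stack([gx, gy, gz], axis=-1))
    endo = _mc_mesh(f, 0.0, origin, pitch)
    epi = _mc_mesh(f, spec.wall_thickness, origin, pitch)
    return endo, epi


def _snap_loop(epi: trimesh.Trimesh, plane: Plane, near: np.ndarray,
               max_radius: float) -> list[int]:
    """Closed vertex loop on the mesh tracing the plane section nearest a point."""
    section = epi.section(plane_origin=plane.point, plane_normal=plane.normal)
    if section is None:
        raise ValidationError("landmark plane does not intersect the mesh")
    best, best_d = None, np.inf
    for curve in section.discrete:
        c = curve.mean(axis=0)
        d = np.linalg.norm(c - near)
        if d < best_d and np.linalg.norm(curve - c, axis=1).max() <= max_radius:
            best, best_d = curve, d
    if best is None:
        raise ValidationError("no section curve found near the ostium")
    from scipy.spatial import cKDTree
    _, vid = cKDTree(epi.vertices).query(best)
    vid = np.unique(vid)
    pts = epi.vertices[vid]
    centroid = pts.mean(axis=0)
    # order by angle in the plane for a simple closed polyline
    e1 = np.cross(plane.normal, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(plane.normal, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(plane.normal, e1)
    ang = np.arctan2((pts - centroid) @ e2, (pts - centroid) @ e1)
    order = np.argsort(ang, kind="stable")
    loop = [int(i) for i in vid[order]]
    if len(loop) < 3:
        raise ValidationError("degenerate landmark loop")
    return loop


def _la_like_landmarks(spec: PhantomSpec, geom: _LaLikeGeometry,
                       epi: trimesh.Trimesh) -> LandmarkSet:
    frame = Frame(center=geom.center, left=[1, 0, 0], anterior=[0, 1, 0],
                  superior=[0, 0, 1])
    pv_ostia = {}
    for label in PV_LABELS:
        tube = geom.tubes[label]
        plane = Plane(tube["junction"], tube["direction"])
        loop = _snap_loop(epi, plane, tube["junction"],
                          max_radius=3.0 * (tube["radius"] + spec.wall_thickness))
        pv_ostia[label] = {"loop": loop, "plane": plane}
    laa_tube = geom.tubes["LAA"]
    laa_plane = Plane(laa_tube["junction"], laa_tube["direction"])
    laa = {"loop": _snap_loop(epi, laa_plane, laa_tube["junction"],
                              max_radius=3.0 * (laa_tube["radius"] + spec.wall_thickness)),
           "plane": laa_plane}
    mv_plane = geom.mitral_plane
    mv = {"loop": _snap_loop(epi, mv_plane, mv_plane.point, max_radius=1e9),
          "plane": mv_plane}
    return LandmarkSet(frame=frame, pv_ostia=pv_ostia, laa_ostium=laa,
                       mitral_annulus=mv)


# ---------------------------------------------------------------------------
# fat planting
# ---------------------------------------------------------------------------

_NEIGHBOURS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def plant_fat(ct: CtVolume, truth: PhantomTruth, *, fat_class: str,
              target_volume_ml: float, segment: int | None = None,
              hu_range: tuple[float, float] | None = None,
              seed_point: np.ndarray | None = None) -> tuple[CtVolume, PhantomTruth]:
    """Grow a connected fat deposit of known volume inside the wall.

    The deposit is grown by breadth-first accretion over the eroded wall
    mask (so every planted voxel lies strictly between the shells), within
    the requested anatomical segment when one is given, starting from the
    region voxel nearest the region centroid (or nearest ``seed_point``).
    Planted voxels get HU drawn uniformly from ``hu_range``, whose support
    must lie strictly inside the class interval.  Modifies ct and truth
    in place and returns them.
    """
    if fat_class not in _CLASS_BOUNDS:
        raise ValidationError(f"fat_class must be one of {sorted(_CLASS_BOUNDS)}")
    lo_b, hi_b = _CLASS_BOUNDS[fat_class]
    lo, hi = hu_range or DEFAULT_DEPOSIT_HU[fat_class]
    if not (lo_b <= lo < hi < hi_b):
        raise ValidationError(
            f"{fat_class} HU range must lie inside [{lo_b}, {hi_b})")

    interior = ndimage.binary_erosion(truth.wall_mask, structure=np.array(
        [[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
         [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
         [[0, 0, 0], [0, 1, 0], [0, 0, 0]]], dtype=bool))
    region = interior.copy()
    for dep in truth.deposits:
        region[tuple(np.asarray(dep["indices"]).T)] = False

    if truth.landmarks is not None:
        geom = truth.geometry()
        idx = np.argwhere(region)
        pts = ct.voxel_centers_world(region)
        labels = la_parcellation.classify_points(pts, geom)
        if segment is not None:
            keep = labels == segment
        else:
            keep = labels > 0
        region = np.zeros_like(region)
        region[tuple(idx[keep].T)] = True
    elif segment is not None:
        raise ValidationError("segment-targeted planting requires landmarks")

    n_target = int(round(target_volume_ml / ct.voxel_volume_ml))
    if n_target < 1 or region.sum() < n_target:
        raise ValidationError("deposit too large for the available wall compartment")

    idx = np.argwhere(region)
    pts = ct.voxel_centers_world(region)
    anchor = pts.mean(axis=0) if seed_point is None else np.asarray(seed_point, float)
    seed_voxel = tuple(idx[np.argmin(np.linalg.norm(pts - anchor, axis=1))])

    chosen = _bfs_grow(region, seed_voxel, n_target)
    if len(chosen) < n_target:
        raise ValidationError("deposit too large: connected region exhausted")

    rng = truth.rng or np.random.default_rng(0)
    hu = rng.uniform(lo, hi, size=n_target)
    ct.data[tuple(chosen.T)] = hu
    truth.deposits.append({
        "segment": segment, "class": fat_class,
        "volume_ml": n_target * ct.voxel_volume_ml,
        "n_voxels": n_target, "hu_range": (lo, hi),
        "indices": chosen,
    })
    return ct, truth


def _bfs_grow(region: np.ndarray, seed: tuple, n_target: int) -> np.ndarray:
    shape = region.shape
    visited = np.zeros(shape, dtype=bool)
    visited[seed] = True
    queue = deque([seed])
    chosen = []
    while queue and len(chosen) < n_target:
        vox = queue.popleft()
        chosen.append(vox)
        for d in _NEIGHBOURS:
            nb = (vox[0] + d[0], vox[1] + d[1], vox[2] + d[2])
            if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]
                    and region[nb] and not visited[nb]):
                visited[nb] = True
                queue.append(nb)
    return np.asarray(chosen, dtype=int)


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

def _iqr_sigma(q1: float, q3: float) -> float:
    return float(np.log(q3 / q1) / (2.0 * 0.674489750196082))


#: per-metric, per-group generating distributions.  Log-normal volumes are
#: parameterised by (median, q1, q3); normal metrics by (mean, sd).
DEFAULT_COHORT_SPEC = {
    "infat_ml": {"dist": "lognormal",
                 "paroxysmal": (0.415, 0.252, 0.593),
                 "persistent": (0.460, 0.350, 1.045),
                 "control": (0.275, 0.198, 0.375)},
    "dense_ml": {"dist": "lognormal",
                 "paroxysmal": (0.130, 0.090, 0.215),
                 "persistent": (0.195, 0.110, 0.397),
                 "control": (0.050, 0.028, 0.118)},
    "admix_ml": {"dist": "lognormal",
                 "paroxysmal": (0.280, 0.150, 0.432),
                 "persistent": (0.335, 0.233, 0.505),
                 "control": (0.210, 0.165, 0.290)},
    "infat_hu": {"dist": "normal",
                 "paroxysmal": (-38.621, 8.708),
                 "persistent": (-43.125, 7.587),
                 "control": (-34.862, 8.417)},
    "dense_hu": {"dist": "normal",
                 "paroxysmal": (-76.285, 8.571),
                 "persistent": (-78.665, 4.268),
                 "control": (-73.665, 5.744)},
    "admix_hu": {"dist": "normal",
                 "paroxysmal": (-23.190, 0.762),
                 "persistent": (-23.710, 0.892),
                 "control": (-22.955, 2.063)},
    "la_vol_ml": {"dist": "normal",
                  "paroxysmal": (106.0, 21.0),
                  "persistent": (102.0, 14.0),
                  "control": (89.0, 22.0)},
    "lawt_mm": {"dist": "normal",
                "paroxysmal": (1.25, 0.22),
                "persistent": (1.33, 0.20),
                "control": (1.13, 0.21)},
    "wall_vol_ml": {"dist": "normal",
                    "paroxysmal": (11.3, 4.6),
                    "persistent": (11.9, 4.3),
                    "control": (9.7, 2.7)},
    "bmi": {"dist": "normal",
            "paroxysmal": (26.7, 3.9),
            "persistent": (27.8, 3.9),
            "control": (24.8, 3.3)},
    "age": {"dist": "normal",
            "paroxysmal": (64.9, 10.2),
            "persistent": (64.1, 10.4),
            "control": (62.7, 9.0)},
    "male_fraction": {"dist": "bernoulli",
                      "paroxysmal": (0.500,),
                      "persistent": (0.567,),
                      "control": (0.650,)},
}


def null_cohort_spec(base_group: str = "control") -> dict:
    """Effect spec with identical distributions in all three groups."""
    spec = {}
    for metric, entry in DEFAULT_COHORT_SPEC.items():
        ref = entry[base_group]
        spec[metric] = {"dist": entry["dist"],
                        **{g: ref for g in GROUPS}}
    return spec


def _draw(rng: np.random.Generator, dist: str, params: tuple, n: int) -> np.ndarray:
    if dist == "lognormal":
        median, q1, q3 = params
        return rng.lognormal(np.log(median), _iqr_sigma(q1, q3), size=n)
    if dist == "normal":
        mean, sd = params
        return rng.normal(mean, sd, size=n)
    if dist == "bernoulli":
        return (rng.random(n) < params[0]).astype(float)
    raise ValidationError(f"unknown distribution {dist!r}")


def make_cohort(n_per_group: tuple[int, int, int] = (30, 30, 20),
                effect_spec: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Synthetic per-patient metric table shaped like the study cohort.

    ``n_per_group`` is (paroxysmal, persistent, control).  Each metric is
    drawn independently per patient from its group-specific distribution;
    normalized fat metrics are computed as ratios of the drawn volumes.
    """
    spec = effect_spec or DEFAULT_COHORT_SPEC
    ns = dict(zip(("paroxysmal", "persistent", "control"), n_per_group))
    if min(ns.values()) < 1:
        raise ValidationError("every group needs at least one patient")
    rng = np.random.default_rng(seed)
    frames = []
    pid = 0
    for group in ("paroxysmal", "persistent", "control"):
        n = ns[group]
        cols = {"patient_id": [f"P{pid + i:03d}" for i in range(n)],
                "group": [group] * n}
        pid += n
        for metric, entry in spec.items():
            vals = _draw(rng, entry["dist"], entry[group], n)
            if metric.endswith("_ml") or metric in ("bmi", "lawt_mm"):
                vals = np.abs(vals)  # physical quantities are non-negative
            cols[metric] = vals
        df = pd.DataFrame(cols)
        if "male_fraction" in df:
            df["sex"] = np.where(df.pop("male_fraction") > 0.5, "male", "female")
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for comp in ("infat", "dense", "admix"):
        if (f"{comp}_ml" in out and "la_vol_ml" in out and "wall_vol_ml" in out):
            out[f"{comp}_la_norm"] = out[f"{comp}_ml"] / out["la_vol_ml"]
            out[f"{comp}_wall_norm"] = out[f"{comp}_ml"] / out["wall_vol_ml"]
    return out
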