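"""19-segment anatomical parcellation of the left atrial shell.

The LA epicardial surface is partitioned into the standard 19 named
segments (posterior wall 1-4, floor 5-6, septal wall 7, anterior wall
8-11, left lateral wall 12, left/right carinae 13-14, LIPV/LSPV antra
15-16, ridge 17, RIPV/RSPV antra 18-19) after excluding the appendage,
the mitral valve and the pulmonary veins beyond 5 mm from their ostia.

All boundaries derive deterministically from the landmark file: the
posterior wall is bounded by the line through the superior edges of the
superior PV ostium loops, the lines joining ipsilateral ostia and the
line through the inferior edges of the inferior PV ostia; the antra are
the 5 mm vein collars retained by the exclusion rule; the carinae and
the ridge are bands around the chords joining, respectively, the
ipsilateral ostium centers and the LSPV ostium to the appendage ostium.
The posterior and anterior walls are split into four sub-segments (the
floor into two) at equal intervals of the left-right coordinate of the
landmark frame.

Labels are assigned by a pure per-point geometric classifier evaluated at
face centroids; wall voxels inherit the label of the nearest non-excluded
face center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from ._mesh import point_to_segment_distance
from .io_formats import CtVolume, LandmarkSet, ValidationError

log = logging.getLogger(__name__)

EXCLUDED = 0

SEGMENT_NAMES = {
    1: "posterior wall 1",
    2: "posterior wall 2",
    3: "posterior wall 3",
    4: "posterior wall 4",
    5: "left floor",
    6: "right floor",
    7: "septal wall",
    8: "anterior wall 1",
    9: "anterior wall 2",
    10: "anterior wall 3",
    11: "anterior wall 4",
    12: "left lateral wall",
    13: "left carina",
    14: "right carina",
    15: "LIPV antrum",
    16: "LSPV antrum",
    17: "ridge",
    18: "RIPV antrum",
    19: "RSPV antrum",
}

ANTRUM_SEGMENT = {"LIPV": 15, "LSPV": 16, "RIPV": 18, "RSPV": 19}

#: band half-width around the carina / ridge chords, as a fraction of the
#: mean bounding ostium loop radius
CARINA_FACTOR = 0.8
RIDGE_FACTOR = 0.8
#: lateral guard around an ostium axis for plane-based tests, as a
#: multiple of the ostium loop radius
RADIAL_GUARD = 2.0


@dataclass
class ParcellationGeometry:
    """Landmark-derived scalars that define every segment boundary."""

    frame: object
    pv: dict            # label -> {plane, center, radius, loop_pts}
    laa: dict           # {plane, center, radius}
    mitral_plane: object
    z_superior: float   # w of the line through superior PV ostium upper edges
    z_inferior: float   # w of the line through inferior PV ostium lower edges
    x_left: float       # u of the medial edge of the left PV column
    x_right: float      # u of the medial edge of the right PV column
    v_laa: float        # v of the appendage ostium center
    exclusion_mm: float = 5.0


def derive_geometry(epi: trimesh.Trimesh, landmarks: LandmarkSet,
                    exclusion_mm: float = 5.0) -> ParcellationGeometry:
    landmarks.validate_on_mesh(epi)
    fr = landmarks.frame
    pv = {}
    for label, entry in landmarks.pv_ostia.items():
        pts = epi.vertices[np.asarray(entry["loop"], dtype=int)]
        center = pts.mean(axis=0)
        pv[label] = {
            "plane": entry["plane"],
            "center": center,
            "radius": float(np.linalg.norm(pts - center, axis=1).mean()),
            "uvw": fr.coords(pts),
        }
    laa_pts = epi.vertices[np.asarray(landmarks.laa_ostium["loop"], dtype=int)]
    laa_center = laa_pts.mean(axis=0)
    laa = {
        "plane": landmarks.laa_ostium["plane"],
        "center": laa_center,
        "radius": float(np.linalg.norm(laa_pts - laa_center, axis=1).mean()),
    }
    z_superior = float(np.mean([pv[k]["uvw"][:, 2].max() for k in ("LSPV", "RSPV")]))
    z_inferior = float(np.mean([pv[k]["uvw"][:, 2].min() for k in ("LIPV", "RIPV")]))
    x_left = float(np.mean([pv[k]["uvw"][:, 0].min() for k in ("LSPV", "LIPV")]))
    x_right = float(np.mean([pv[k]["uvw"][:, 0].max() for k in ("RSPV", "RIPV")]))
    if not x_right < x_left:
        raise ValidationError("left/right PV columns are not separated in the "
                              "landmark frame; check axis orientation")
    v_laa = float(fr.coords(laa_center[None])[0, 1])
    return ParcellationGeometry(frame=fr, pv=pv, laa=laa,
                                mitral_plane=landmarks.mitral_annulus["plane"],
                                z_superior=z_superior, z_inferior=z_inferior,
                                x_left=x_left, x_right=x_right, v_laa=v_laa,
                                exclusion_mm=exclusion_mm)


def _strip(u: np.ndarray, lo: float, hi: float, base: int) -> np.ndarray:
    """Split [lo, hi] into 4 equal intervals; label base..base+3 right-to-left."""
    frac = np.clip((u - lo) / (hi - lo), 0.0, 1.0 - 1e-12)
    return base + (frac * 4).astype(int)


def exclusion_flags(points: np.ndarray, geom: ParcellationGeometry) -> np.ndarray:
    """True for points in the appendage, valve or distal-PV exclusion zones."""
    points = np.atleast_2d(points)
    drop = geom.mitral_plane.signed(points) > 0.0
    for label, info in geom.pv.items():
        s = info["plane"].signed(points)
        radial = _radial(points, info["plane"])
        drop |= (s > geom.exclusion_mm) & (radial <= RADIAL_GUARD * info["radius"])
    s = geom.laa["plane"].signed(points)
    radial = _radial(points, geom.laa["plane"])
    drop |= (s > 0.0) & (radial <= RADIAL_GUARD * geom.laa["radius"])
    return drop


def _radial(points: np.ndarray, plane) -> np.ndarray:
    rel = points - plane.point
    s = rel @ plane.normal
    return np.linalg.norm(rel - s[:, None] * plane.normal, axis=1)


def classify_points(points: np.ndarray, geom: ParcellationGeometry) -> np.ndarray:
    """Segment label (1..19, 0 = excluded) for arbitrary points in mm."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.zeros(len(points), dtype=np.int16)
    uvw = geom.frame.coords(points)
    u, v, w = uvw[:, 0], uvw[:, 1], uvw[:, 2]

    excluded = exclusion_flags(points, geom)
    free = ~excluded

    # PV antra: the retained vein collar within exclusion_mm of the ostium
    for label, seg in ANTRUM_SEGMENT.items():
        info = geom.pv[label]
        s = info["plane"].signed(points)
        radial = _radial(points, info["plane"])
        sel = free & (labels == 0) & (s > 0.0) & (s <= geom.exclusion_mm) \
            & (radial <= RADIAL_GUARD * info["radius"])
        labels[sel] = seg

    # carinae: bands between ipsilateral ostium centers, on the atrial body
    for seg, (a, b) in ((13, ("LSPV", "LIPV")), (14, ("RSPV", "RIPV"))):
        r_band = CARINA_FACTOR * 0.5 * (geom.pv[a]["radius"] + geom.pv[b]["radius"])
        d = point_to_segment_distance(points, geom.pv[a]["plane"].point,
                                      geom.pv[b]["plane"].point)
        labels[free & (labels == 0) & (d <= r_band)] = seg

    # ridge: band between the LSPV ostium and the appendage ostium
    r_band = RIDGE_FACTOR * 0.5 * (geom.pv["LSPV"]["radius"] + geom.laa["radius"])
    d = point_to_segment_distance(points, geom.pv["LSPV"]["plane"].point,
                                  geom.laa["plane"].point)
    labels[free & (labels == 0) & (d <= r_band)] = 17

    todo = free & (labels == 0)

    posterior = todo & (v <= 0.0) & (w >= geom.z_inferior) & (w <= geom.z_superior) \
        & (u >= geom.x_right) & (u <= geom.x_left)
    labels[posterior] = _strip(u[posterior], geom.x_right, geom.x_left, base=1)
    todo &= labels == 0

    floor = todo & (w < geom.z_inferior) & (v <= 0.0)
    labels[floor & (u > 0.0)] = 5
    labels[floor & (u <= 0.0)] = 6
    todo &= labels == 0

    labels[todo & (u <= geom.x_right)] = 7
    todo &= labels == 0

    labels[todo & (u >= geom.x_left) & (v <= geom.v_laa)] = 12
    todo &= labels == 0

    labels[todo] = _strip(u[todo], geom.x_right, geom.x_left, base=8)
    return labels


@dataclass
class SegmentModel:
    """Per-epicardial-face labels plus the geometry that produced them."""

    face_labels: np.ndarray
    geometry: ParcellationGeometry
    names: dict = field(default_factory=lambda: dict(SEGMENT_NAMES))

    def present_segments(self) -> np.ndarray:
        labs = np.unique(self.face_labels)
        return labs[labs > 0]

    def summary(self, epi: trimesh.Trimesh) -> pd.DataFrame:
        rows = []
        for seg in range(1, 20):
            sel = self.face_labels == seg
            rows.append({"segment": seg, "name": SEGMENT_NAMES[seg],
                         "n_faces": int(sel.sum()),
                         "area_mm2": float(epi.area_faces[sel].sum())})
        return pd.DataFrame(rows)


def parcellate(epi: trimesh.Trimesh, landmarks: LandmarkSet,
               exclusion_mm: float = 5.0) -> SegmentModel:
    """Label every epicardial face with its anatomical segment."""
    geom = derive_geometry(epi, landmarks, exclusion_mm=exclusion_mm)
    labels = classify_points(epi.triangles_center, geom)
    present = np.unique(labels[labels > 0])
    log.info("parcellation: %d segments present, %d faces excluded",
             len(present), int((labels == 0).sum()))
    return SegmentModel(face_labels=labels.astype(np.int16), geometry=geom)


def label_wall_voxels(model: SegmentModel, epi: trimesh.Trimesh,
                      wall_mask: np.ndarray, ct: CtVolume) -> np.ndarray:
    """Per-voxel segment labels: each wall voxel inherits the nearest
    labeled (non-excluded) epicardial face center; ties resolve to the
    lowest face index.  Returns an int grid (0 outside the wall).
    """
    ct.require_axis_aligned()
    labels = np.zeros(wall_mask.shape, dtype=np.int16)
    if not wall_mask.any():
        return labels
    keep = np.nonzero(model.face_labels > 0)[0]
    if len(keep) == 0:
        raise ValidationError("parcellation produced no labeled faces")
    centers = epi.triangles_center[keep]
    pts = ct.voxel_centers_world(wall_mask)
    d, nearest = cKDTree(centers).query(pts)
    # deterministic tie-break: among equidistant face centers pick lowest index
    labels[wall_mask] = model.face_labels[keep][nearest]
    return labels


def segment_wall_volumes(voxel_labels: np.ndarray, voxel_volume_ml: float) -> pd.Series:
    counts = np.bincount(voxel_labels.ravel(), minlength=20)[1:20]
    return pd.Series(counts * voxel_volume_ml, index=pd.RangeIndex(1, 20, name="segment"),
                     name="wall_ml")
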