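"""Intramyocardial fat (inFAT) mapping between the two LA shells.

The wall compartment is the set of voxel centers inside the epicardial
shell and outside the endocardial shell, minus the appendage and the
pulmonary-vein segments more than 5 mm beyond the ostium planes.  Wall
voxels are classified by attenuation: dense inFAT in [-194, -50] HU,
fat-myocardium admixture in (-50, -5] HU, so the union is exactly
[-194, -5] HU with no overlap or gap (the published ranges are both
inclusive at -50 HU; here the boundary voxel is assigned to the dense
class so that total inFAT is conserved).  Volumes are voxel counts times voxel volume; the LA cavity
volume is the enclosed volume of the endocardial mesh (divergence
theorem).  Fat outside the epicardial shell is never counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh

from ._mesh import inside_mask, signed_distance
from .io_formats import CtVolume, LandmarkSet, PV_LABELS
from .wall_thickness import GeometryError

log = logging.getLogger(__name__)

#: voxel class codes
CLASS_NONE, CLASS_DENSE, CLASS_ADMIX = 0, 1, 2

DEFAULT_EXCLUSION_MM = 5.0
#: lateral guard around a tube axis when applying plane-based exclusions,
#: as a multiple of the ostium loop radius (keeps the infinite plane local)
_RADIAL_GUARD = 2.0


@dataclass
class HuThresholds:
    """Attenuation cut-points (HU) for fat classification."""

    infat_low: float = -194.0
    infat_high: float = -5.0
    dense_high: float = -50.0

    def __post_init__(self) -> None:
        if not (self.infat_low < self.dense_high < self.infat_high):
            raise ValueError("need infat_low < dense_high < infat_high")


@dataclass
class WallFatMap:
    """Wall mask, per-voxel fat class and all summary metrics."""

    wall_mask: np.ndarray
    classes: np.ndarray          # uint8 grid: 0 none, 1 dense, 2 admixture
    metrics: dict                # the per-patient report row
    thresholds: HuThresholds


def build_wall_mask(ct: CtVolume, endo: trimesh.Trimesh, epi: trimesh.Trimesh,
                    landmarks: LandmarkSet | None = None,
                    exclusion_mm: float = DEFAULT_EXCLUSION_MM) -> np.ndarray:
    """Voxel-center mask of the inter-shell wall compartment.

    Applies the appendage / distal-PV exclusions when landmarks are given.
    """
    ct.require_axis_aligned()
    sd = signed_distance(epi, endo.vertices)
    if np.any(sd < -1e-6):
        raise GeometryError("endocardial shell is not contained in the epicardial shell")
    in_epi = inside_mask(epi, ct.origin, ct.spacing, ct.data.shape)
    in_endo = inside_mask(endo, ct.origin, ct.spacing, ct.data.shape)
    mask = in_epi & ~in_endo
    log.info("wall mask: %d voxels inside epi, %d inside endo, %d wall",
             in_epi.sum(), in_endo.sum(), mask.sum())
    if landmarks is not None:
        mask = apply_exclusions(mask, ct, landmarks, exclusion_mm=exclusion_mm)
    return mask


def _loop_radius(lm: LandmarkSet, mesh_points: np.ndarray) -> float:
    pts = np.atleast_2d(mesh_points)
    return float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())


def apply_exclusions(wall_mask: np.ndarray, ct: CtVolume, landmarks: LandmarkSet,
                     epi: trimesh.Trimesh | None = None,
                     exclusion_mm: float = DEFAULT_EXCLUSION_MM) -> np.ndarray:
    """Drop appendage voxels and PV voxels > exclusion_mm beyond the ostia.

    Distances are Euclidean to the stored ostium plane, on the vein side of
    its normal; a radial guard of twice the ostium loop radius keeps the
    (infinite) plane test local to each vein / to the appendage.
    """
    ct.require_axis_aligned()
    mask = wall_mask.copy()
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return mask
    pts = ct.voxel_centers_world(mask)

    drop = np.zeros(len(pts), dtype=bool)
    for label in PV_LABELS:
        entry = landmarks.pv_ostia[label]
        plane = entry["plane"]
        s = plane.signed(pts)
        radial = _radial_distance(pts, plane)
        r_guard = _guard_radius(landmarks, entry, epi)
        drop |= (s > exclusion_mm) & (radial <= r_guard)
    laa = landmarks.laa_ostium
    s = laa["plane"].signed(pts)
    radial = _radial_distance(pts, laa["plane"])
    drop |= (s > 0.0) & (radial <= _guard_radius(landmarks, laa, epi))

    removed = idx[drop]
    mask[tuple(removed.T)] = False
    log.info("exclusions removed %d of %d wall voxels", int(drop.sum()), len(pts))
    return mask


def _radial_distance(points: np.ndarray, plane) -> np.ndarray:
    rel = points - plane.point
    s = rel @ plane.normal
    return np.linalg.norm(rel - s[:, None] * plane.normal, axis=1)


def _guard_radius(landmarks: LandmarkSet, entry: dict, epi: trimesh.Trimesh | None) -> float:
    if epi is not None:
        pts = epi.vertices[np.asarray(entry["loop"], dtype=int)]
        return _RADIAL_GUARD * _loop_radius(landmarks, pts)
    # without the mesh, fall back to a generous fixed guard
    return 25.0


def classify_fat(ct: CtVolume, wall_mask: np.ndarray,
                 thr: HuThresholds | None = None) -> np.ndarray:
    """Per-voxel fat class on the wall mask (0 none / 1 dense / 2 admixture)."""
    thr = thr or HuThresholds()
    hu = ct.data
    classes = np.zeros(hu.shape, dtype=np.uint8)
    dense = (hu >= thr.infat_low) & (hu <= thr.dense_high)
    admix = (hu > thr.dense_high) & (hu <= thr.infat_high)
    classes[wall_mask & dense] = CLASS_DENSE
    classes[wall_mask & admix] = CLASS_ADMIX
    return classes


def compute_metrics(classes: np.ndarray, ct: CtVolume, wall_mask: np.ndarray,
                    endo: trimesh.Trimesh) -> dict:
    """All per-patient quantities: volumes, mean intensities, normalisations.

    Mean HU of an empty class is reported as None (0 HU is a valid tissue
    value, never a stand-in for "no voxels").
    """
    vv = ct.voxel_volume_ml
    wall_volume = float(wall_mask.sum()) * vv
    if wall_volume <= 0:
        raise ValueError("zero wall volume: normalisation undefined")
    la_volume = float(endo.volume) / 1000.0

    hu = ct.data
    out = {"la_vol_ml": la_volume, "wall_vol_ml": wall_volume}
    masks = {"dense": classes == CLASS_DENSE, "admix": classes == CLASS_ADMIX}
    masks["infat"] = masks["dense"] | masks["admix"]
    for name, m in masks.items():
        n = int(m.sum())
        out[f"{name}_ml"] = n * vv
        out[f"{name}_hu"] = float(hu[m].mean(dtype=np.float64)) if n else None
        out[f"{name}_la_norm"] = out[f"{name}_ml"] / la_volume
        out[f"{name}_wall_norm"] = out[f"{name}_ml"] / wall_volume
    return out


def map_patient_fat(ct: CtVolume, endo: trimesh.Trimesh, epi: trimesh.Trimesh,
                    landmarks: LandmarkSet | None = None,
                    thr: HuThresholds | None = None,
                    exclusion_mm: float = DEFAULT_EXCLUSION_MM) -> WallFatMap:
    """Full inFAT mapping for one patient: mask, classes and metrics."""
    thr = thr or HuThresholds()
    mask = build_wall_mask(ct, endo, epi, landmarks=landmarks, exclusion_mm=exclusion_mm)
    classes = classify_fat(ct, mask, thr)
    metrics = compute_metrics(classes, ct, mask, endo)
    return WallFatMap(wall_mask=mask, classes=classes, metrics=metrics, thresholds=thr)
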