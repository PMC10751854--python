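"""Readers and writers for every external artifact of the pipeline.

Conventions (fixed throughout the package):

* volumes are NIfTI with calibrated Hounsfield Units; the 0-based voxel
  index maps to the voxel *center* in world mm through the affine;
* surfaces are triangulated PLY/OBJ meshes in world mm, validated as
  closed 2-manifolds and normalised to outward winding;
* anatomical landmarks are a JSON file whose loops are ordered vertex
  indices on the epicardial mesh, with the pulmonary-vein ostium planes
  stored explicitly (point + vein-ward normal, mm);
* reports are plain CSV with a deterministic column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

GROUPS = ("control", "paroxysmal", "persistent")
PV_LABELS = ("LSPV", "LIPV", "RSPV", "RIPV")

#: per-patient report columns, in the order they are written
PATIENT_METRIC_COLUMNS = (
    "infat_ml", "dense_ml", "admix_ml",
    "infat_hu", "dense_hu", "admix_hu",
    "la_vol_ml", "wall_vol_ml",
    "infat_la_norm", "dense_la_norm", "admix_la_norm",
    "infat_wall_norm", "dense_wall_norm", "admix_wall_norm",
)

SEGMENT_REPORT_COLUMNS = (
    "segment", "name", "infat_ml", "rel_infat_pct", "wall_ml",
    "regional_vol_pct", "dense_ml", "admix_ml",
)


class FormatError(ValueError):
    """Raised when an input file violates the documented contract."""


class ValidationError(ValueError):
    """Raised when an input is well-formed but geometrically invalid."""


# ---------------------------------------------------------------------------
# CT volumes
# ---------------------------------------------------------------------------

@dataclass
class CtVolume:
    """A 3D grid of calibrated Hounsfield Units with a voxel-to-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("HU values must be finite")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (dx, dy, dz) in mm, derived from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    @property
    def origin(self) -> np.ndarray:
        """World coordinate of voxel center (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    def is_axis_aligned(self, tol: float = 1e-9) -> bool:
        m = self.affine[:3, :3]
        return bool(np.all(np.abs(m - np.diag(np.diag(m))) <= tol)
                    and np.all(np.diag(m) > 0))

    def require_axis_aligned(self) -> None:
        if not self.is_axis_aligned():
            raise FormatError("volume must be axis-aligned (diagonal positive affine) "
                              "for voxel-mask operations")

    def voxel_centers_world(self, index_mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers, optionally restricted to a mask."""
        if index_mask is None:
            idx = np.stack(np.meshgrid(*map(np.arange, self.data.shape),
                                       indexing="ij"), axis=-1).reshape(-1, 3)
        else:
            idx = np.argwhere(index_mask)
        homog = np.column_stack([idx, np.ones(len(idx))])
        return (self.affine @ homog.T).T[:, :3]


def read_ct_volume(path: str | Path) -> CtVolume:
    """Load a 3D NIfTI volume; HU are assumed already calibrated."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D scalar image, got shape {data.shape}")
    if img.affine is None:
        raise FormatError(f"{path}: missing affine")
    return CtVolume(data=np.asarray(data, dtype=np.float32), affine=img.affine)


def write_ct_volume(vol: CtVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Surface meshes
# ---------------------------------------------------------------------------

def validate_shell(mesh: trimesh.Trimesh, role: str = "shell") -> trimesh.Trimesh:
    """Check closed-2-manifold topology and normalise to outward winding."""
    if not mesh.is_watertight:
        raise ValidationError(f"{role}: surface is not a closed 2-manifold")
    if not mesh.is_winding_consistent:
        raise ValidationError(f"{role}: inconsistent triangle winding")
    if mesh.volume < 0:
        mesh = mesh.copy()
        mesh.invert()
    if mesh.volume <= 0:
        raise ValidationError(f"{role}: enclosed volume must be positive")
    return mesh


def read_mesh(path: str | Path, role: str = "shell", require_closed: bool = True
              ) -> trimesh.Trimesh:
    """Read a triangulated PLY/OBJ surface in mm coordinates."""
    mesh = trimesh.load(str(path), force="mesh", process=True)
    if mesh.faces.shape[1] != 3:
        raise FormatError(f"{path}: surface must be triangulated")
    if require_closed:
        mesh = validate_shell(mesh, role=role)
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    path = Path(path)
    mesh.export(str(path))
    return path


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class Plane:
    """Oriented plane (point + unit normal) in world mm."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValidationError("plane normal must be non-zero")
        self.normal = self.normal / n

    def signed(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass
class Frame:
    """Patient-specific body frame: center plus left/anterior/superior axes."""

    center: np.ndarray
    left: np.ndarray
    anterior: np.ndarray
    superior: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        for name in ("left", "anterior", "superior"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v / np.linalg.norm(v))

    def coords(self, points: np.ndarray) -> np.ndarray:
        """(u, v, w) = projections on (left, anterior, superior)."""
        rel = np.atleast_2d(points) - self.center
        return np.column_stack([rel @ self.left, rel @ self.anterior, rel @ self.superior])


@dataclass
class LandmarkSet:
    """Anatomical landmark loops and planes on the epicardial mesh."""

    frame: Frame
    pv_ostia: dict  # label -> {"loop": [int], "plane": Plane}
    laa_ostium: dict  # {"loop": [int], "plane": Plane}
    mitral_annulus: dict  # {"loop": [int], "plane": Plane}

    def __post_init__(self) -> None:
        missing = [p for p in PV_LABELS if p not in self.pv_ostia]
        if missing:
            raise ValidationError(f"missing PV ostium labels: {missing}")
        for name, entry in self._loops():
            loop = list(entry["loop"])
            if len(loop) < 3 or len(set(loop)) != len(loop):
                raise ValidationError(f"{name}: loop must be a simple closed polyline "
                                      "with >= 3 distinct vertices")
            if not isinstance(entry["plane"], Plane):
                raise ValidationError(f"{name}: missing ostium plane")

    def _loops(self):
        for label in PV_LABELS:
            yield label, self.pv_ostia[label]
        yield "laa_ostium", self.laa_ostium
        yield "mitral_annulus", self.mitral_annulus

    def validate_on_mesh(self, mesh: trimesh.Trimesh) -> None:
        n = len(mesh.vertices)
        for name, entry in self._loops():
            loop = np.asarray(entry["loop"], dtype=int)
            if loop.min() < 0 or loop.max() >= n:
                raise ValidationError(f"{name}: loop vertex index out of range for mesh")

    def loop_points(self, mesh: trimesh.Trimesh, name: str) -> np.ndarray:
        entry = self.laa_ostium if name == "laa_ostium" else (
            self.mitral_annulus if name == "mitral_annulus" else self.pv_ostia[name])
        return mesh.vertices[np.asarray(entry["loop"], dtype=int)]


def _plane_to_json(p: Plane) -> dict:
    return {"point": p.point.tolist(), "normal": p.normal.tolist()}


def _entry_to_json(e: dict) -> dict:
    return {"loop": [int(i) for i in e["loop"]], "plane": _plane_to_json(e["plane"])}


def write_landmarks(lm: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "frame": {"center": lm.frame.center.tolist(),
                  "left": lm.frame.left.tolist(),
                  "anterior": lm.frame.anterior.tolist(),
                  "superior": lm.frame.superior.tolist()},
        "pv_ostia": {k: _entry_to_json(v) for k, v in lm.pv_ostia.items()},
        "laa_ostium": _entry_to_json(lm.laa_ostium),
        "mitral_annulus": _entry_to_json(lm.mitral_annulus),
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def _entry_from_json(e: dict) -> dict:
    return {"loop": [int(i) for i in e["loop"]],
            "plane": Plane(np.asarray(e["plane"]["point"]), np.asarray(e["plane"]["normal"]))}


def read_landmarks(path: str | Path) -> LandmarkSet:
    doc = json.loads(Path(path).read_text())
    fr = doc["frame"]
    return LandmarkSet(
        frame=Frame(np.asarray(fr["center"]), np.asarray(fr["left"]),
                    np.asarray(fr["anterior"]), np.asarray(fr["superior"])),
        pv_ostia={k: _entry_from_json(v) for k, v in doc["pv_ostia"].items()},
        laa_ostium=_entry_from_json(doc["laa_ostium"]),
        mitral_annulus=_entry_from_json(doc["mitral_annulus"]),
    )


# ---------------------------------------------------------------------------
# Reports and tables
# ---------------------------------------------------------------------------

def write_patient_report(metrics: dict, path: str | Path) -> Path:
    """One-row CSV with the per-patient fat and volume metrics.

    Missing mean intensities (empty class) are written as empty cells;
    volume columns are always numeric (zero for an empty fat map).
    """
    row = {}
    for col in PATIENT_METRIC_COLUMNS:
        val = metrics.get(col)
        row[col] = np.nan if val is None else val
    df = pd.DataFrame([row], columns=list(PATIENT_METRIC_COLUMNS))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_patient_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_segment_report(table: pd.DataFrame, path: str | Path) -> Path:
    """19-row CSV with the per-segment regional distribution."""
    cols = [c for c in SEGMENT_REPORT_COLUMNS if c in table.columns]
    path = Path(path)
    table[cols].to_csv(path, index=False)
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    bad = set(df["group"].unique()) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
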