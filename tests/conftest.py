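"""Shared phantom fixtures.

Heavy phantoms are session-scoped: one sphere shell, one ellipsoid shell
with planted fat deposits, and one full LA-like phantom with landmarks
and deposits, reused by the geometry, mapping, parcellation, regional and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lafat import (PhantomSpec, make_phantom, plant_fat, map_patient_fat,
                   parcellate, label_wall_voxels)
from lafat.regional_stats import regional_table

SPHERE_R_ENDO = 20.0
SPHERE_R_EPI = 22.0


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free concentric-sphere phantom (r=20 mm, R=22 mm, 0.5 mm voxels)."""
    spec = PhantomSpec(shape="concentric_spheres", endo_radius=SPHERE_R_ENDO,
                       epi_radius=SPHERE_R_EPI, noise_sd=0.0, seed=1)
    ct, truth = make_phantom(spec)
    return spec, ct, truth


@pytest.fixture(scope="session")
def sphere_fatmap(sphere_phantom):
    _, ct, truth = sphere_phantom
    return map_patient_fat(ct, truth.endo_mesh, truth.epi_mesh)


@pytest.fixture(scope="session")
def ellipsoid_fat_phantom():
    """Ellipsoid shell with a 0.5 mL dense and a 0.3 mL admixture deposit,
    10 HU noise — the volume-recovery workhorse."""
    spec = PhantomSpec(shape="ellipsoid_shell", endo_axes=(30.0, 25.0, 20.0),
                       wall_thickness=3.0, noise_sd=10.0, seed=4)
    ct, truth = make_phantom(spec)
    plant_fat(ct, truth, fat_class="dense", target_volume_ml=0.5,
              seed_point=np.array([0.0, 0.0, 21.0]))
    plant_fat(ct, truth, fat_class="admixture", target_volume_ml=0.3,
              seed_point=np.array([0.0, 0.0, -21.0]))
    return spec, ct, truth


@pytest.fixture(scope="session")
def ellipsoid_fatmap(ellipsoid_fat_phantom):
    _, ct, truth = ellipsoid_fat_phantom
    return map_patient_fat(ct, truth.endo_mesh, truth.epi_mesh)


@pytest.fixture(scope="session")
def la_phantom():
    """Complete LA-like phantom (4 PV tubes, appendage stub, annulus) with a
    dense deposit in the LSPV antrum (16) and an admixture deposit in the
    septal wall (7)."""
    spec = PhantomSpec(shape="la_like", wall_thickness=2.5, noise_sd=10.0, seed=3)
    ct, truth = make_phantom(spec)
    plant_fat(ct, truth, fat_class="dense", target_volume_ml=0.5, segment=16)
    plant_fat(ct, truth, fat_class="admixture", target_volume_ml=0.3, segment=7)
    return spec, ct, truth


@pytest.fixture(scope="session")
def la_pipeline(la_phantom):
    """Full per-patient pipeline products on the LA-like phantom."""
    _, ct, truth = la_phantom
    fat = map_patient_fat(ct, truth.endo_mesh, truth.epi_mesh,
                          landmarks=truth.landmarks)
    model = parcellate(truth.epi_mesh, truth.landmarks)
    voxel_labels = label_wall_voxels(model, truth.epi_mesh, fat.wall_mask, ct)
    table = regional_table(voxel_labels, fat.classes, ct.voxel_volume_ml)
    return {"ct": ct, "truth": truth, "fat": fat, "model": model,
            "voxel_labels": voxel_labels, "regional": table}
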