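# lafat

Quantification of **left atrial (LA) intramyocardial fat infiltration
(inFAT)** from contrast-enhanced cardiac CT, for imaging researchers and
electrophysiology groups studying the fatty substrate of atrial
fibrillation.

Given a HU-calibrated CT volume and triangulated endocardial and
epicardial LA surfaces (plus an anatomical landmark file), the pipeline
computes:

* **LA wall thickness (LAWT) maps** — at every endocardial vertex,
  LAWT(x) = ‖x − proj_epi(x)‖, the distance to the projection of the
  vertex on the epicardial shell, displayed with the conventional colour
  scale (red < 1 mm ≤ yellow < 2 mm ≤ green < 3 mm ≤ blue < 4 mm ≤ purple);
* **inFAT maps** — a threshold-based segmentation of the inter-shell wall
  compartment: inFAT = wall voxels with HU ∈ [−194, −5], split into
  *dense inFAT* (HU ∈ [−194, −50]) and *fat–myocardium admixture*
  (HU ∈ (−50, −5]), after excluding the LA appendage and the pulmonary
  veins more than 5 mm beyond their ostia.  Volumes (mL), mean
  intensities (HU), LA cavity volume (endocardial mesh volume), wall
  volume, and all volumes normalised by LA volume and by wall volume;
* a **19-segment anatomical parcellation** of the LA shell (posterior
  wall 1–4, floor 5–6, septal wall 7, anterior wall 8–11, left lateral
  wall 12, carinae 13–14, PV antra 15/16/18/19, ridge 17) and the
  per-segment **relative inFAT percentage**
  (100 · V_fat(s) / Σ V_fat) and **regional volume percentage**
  (100 · V_wall(s) / Σ V_wall);
* **cohort statistics** across control / paroxysmal AF / persistent AF
  groups: Shapiro–Wilk-gated mean±SD vs median (IQR) summaries, one-way
  ANOVA or Kruskal–Wallis omnibus tests, Bonferroni-adjusted pairwise
  post-hoc tests, chi-squared for categoricals, and BMI-adjusted ANCOVA
  (type-II F on the group factor).

Because clinical scans and shells are rarely shareable, the package
includes a first-class **synthetic phantom generator**: concentric
spheres, ellipsoid shells, and a full LA-like geometry (ellipsoidal body,
four pulmonary-vein tubes, appendage stub, mitral annulus) with known
cavity/wall volumes, planted fat deposits of known volume, class, HU
distribution and segment location, plus a synthetic cohort generator with
configurable group-level effects.  Every downstream number can therefore
be checked against ground truth.

## Worked example

```python
from lafat import (PhantomSpec, make_phantom, plant_fat, map_patient_fat,
                   compute_lawt, parcellate, label_wall_voxels)
from lafat.regional_stats import regional_table

spec = PhantomSpec(shape="la_like", wall_thickness=2.5, noise_sd=10.0, seed=3)
ct, truth = make_phantom(spec)
plant_fat(ct, truth, fat_class="dense", target_volume_ml=0.5, segment=16)
plant_fat(ct, truth, fat_class="admixture", target_volume_ml=0.3, segment=7)

lawt = compute_lawt(truth.endo_mesh, truth.epi_mesh)
fat = map_patient_fat(ct, truth.endo_mesh, truth.epi_mesh,
                      landmarks=truth.landmarks)
model = parcellate(truth.epi_mesh, truth.landmarks)
vox = label_wall_voxels(model, truth.epi_mesh, fat.wall_mask, ct)
table = regional_table(vox, fat.classes, ct.voxel_volume_ml)

m = fat.metrics
print(f"mean LAWT            {lawt.mean_thickness_mm:.2f} mm")
print(f"LA volume            {m['la_vol_ml']:.1f} mL")
print(f"wall volume          {m['wall_vol_ml']:.1f} mL")
print(f"inFAT                {m['infat_ml']:.3f} mL   mean {m['infat_hu']:.1f} HU")
print(f"  dense inFAT        {m['dense_ml']:.3f} mL   mean {m['dense_hu']:.1f} HU")
print(f"  admixture          {m['admix_ml']:.3f} mL   mean {m['admix_hu']:.1f} HU")
print(f"inFAT / LA volume    {m['infat_la_norm']:.4f} a.u.")
print(table.nlargest(2, "rel_infat_pct")[["segment", "name", "rel_infat_pct"]]
      .to_string(index=False))
```

prints:

```
mean LAWT            2.52 mm
LA volume            96.1 mL
wall volume          26.5 mL
inFAT                0.800 mL   mean -72.9 HU
  dense inFAT        0.500 mL   mean -100.2 HU
  admixture          0.300 mL   mean -27.6 HU
inFAT / LA volume    0.0083 a.u.
 segment        name  rel_infat_pct
      16 LSPV antrum      61.146696
       7 septal wall      37.509764
```

The phantom's wall is a constant 2.5 mm offset of the endocardial
surface, so the mean LAWT reads 2.52 mm; the two planted deposits
(0.5 mL dense in the LSPV antrum, 0.3 mL admixture in the septal wall)
are recovered at their planted volumes, class-mean HU sit inside the
planted uniform ranges, and the relative inFAT distribution concentrates
in segments 16 and 7 at 62.5 % / 37.5 % of total fat up to the
voxel-labeling tolerance.

The same run is available from the shell:

```bash
lafat phantom --shape la_like --seed 3 --out ph --plant 16:dense:0.5
lafat map --volume ph/ct.nii.gz --endo ph/endo.ply --epi ph/epi.ply \
          --landmarks ph/landmarks.json --out report
lafat cohort --simulate 30,30,20 --seed 3 --out cohort_report
```

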