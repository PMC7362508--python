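# epifat

Quantification of **epicardial adipose tissue** from cine Dixon water–fat
cardiac MRI, with a synthetic cine phantom for validation.

Epicardial fat — the adipose depot between the myocardium and the parietal
pericardium — is linked to atrial fibrillation, coronary artery disease and
ventricular dysfunction, and is hard to delineate from the adjacent
*paracardial* fat on single-phase images because only a thin pericardium
separates the two. Time-resolved (cine) Dixon imaging helps: the epicardial
fat moves with the beating heart (notably with the atrioventricular-plane
descent in systole) while the paracardial fat stays nearly static, so the
boundary can be inferred from motion. This package implements the full
quantification workflow such a study needs:

- **`epifat.phantom`** — a seeded cine Dixon phantom: nested-ellipsoid heart
  (blood pool, myocardium, epicardial fat rind, 1-voxel pericardium) with
  sin²-phase longitudinal motion and radial contraction, plus static
  paracardial fat and lungs; renders water/fat channels, complex two-echo
  data, and ground truth (masks, per-frame volumes, outer epicardial ROIs).
- **`epifat.dixon`** — reference two-point Dixon inversion: per-voxel least
  squares of `s_k = (W + F·e^{iθ_k})·e^{i2πψTE_k}` with a known field map ψ.
- **`epifat.fatfraction`** — the fat-fraction map `FF = F/(F + W)`, with a
  signal-void convention (FF = 0 where W + F ≈ 0).
- **`epifat.quantify`** — cine-frame selection by trigger-delay match,
  threshold segmentation (voxels with FF **> 0.35** inside the per-slice
  outer epicardial ROI), per-slice volumes and the integrated patient total.
- **`epifat.stats`** — observer-agreement statistics: Bland–Altman mean ±
  SD of per-slice differences with ±1.96 SD limits of agreement, per-slice
  errors in ml and % of the patient total, ICC(2,1)/ICC(3,1) with the
  poor/moderate/good/excellent categories (0.5 / 0.75 / 0.9), BSA-indexed
  fat-volume vs BMI regression, paired t and Wilcoxon tests.
- **`epifat.observers`** — a simulated two-observer study that perturbs the
  ground-truth ROIs with per-slice boundary jitter and measures how
  agreement (ICC) degrades.
- **`epifat.cli` / `epifat.pipeline`** — `epifat simulate|recon|ff|quantify|stats|run`
  over NIfTI volumes, JSON/CSV tables and YAML configs.

## Worked example

```python
import dataclasses
import epifat as ef

spec = dataclasses.replace(ef.PhantomSpec(), noise_sigma=0.02, seed=3)
labels = ef.build_anatomy(spec)                 # 64x64x40, 15 frames @ 65 ms
series, truth = ef.render_dixon(labels, spec)

frame = ef.select_frame(series.frame_times_ms, trigger_delay_ms=730.0)
ff = ef.compute_ff(series.water[..., frame], series.fat[..., frame])
roi = truth.roi[frame]                          # outer epicardial boundary
mask = ef.classify_fat(ff.ff, roi, threshold=0.35)
q = ef.quantify_volume(mask, spec.voxel_spacing_mm, roi.slice_range)
print(f"frame {frame}: {q.total_ml:.2f} ml (truth "
      f"{truth.true_volume_ml[frame]:.2f} ml)")
```

prints

```
frame 11: 60.39 ml (truth 60.39 ml)
```

Frame 11 (715 ms) is the closest cine frame to the 730 ms trigger delay;
the 60.39 ml is the epicardial fat volume of that systolic/diastolic phase
of the phantom, recovered by thresholding the fat-fraction map at 0.35
inside the ground-truth ROI and integrating slice volumes (voxel volume
1.5×1.5×3.0 mm³). The simulated observer study is one call:

```python
summary, tables = ef.observer_study(jitter_levels=(0, 1, 2, 3), seed=1)
print(summary[["jitter_vox", "icc", "icc_category"]])
```

```
   jitter_vox       icc icc_category
0           0  1.000000    excellent
1           1  0.963815    excellent
2           2  0.875806         good
3           3  0.732900     moderate
```

i.e. agreement between the two simulated observers decays monotonically as
their ROI boundaries are jittered by 0–3 voxel layers.

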