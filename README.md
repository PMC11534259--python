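# natsc — quantitative ²³Na-MRI of SRS-treated brain metastases

`natsc` is a simulation and analysis pipeline for longitudinal **tissue
sodium concentration (TSC)** studies of brain metastases treated with
single-fraction stereotactic radiosurgery (SRS). It is aimed at MR
physicists and radiation oncologists who want to prototype, validate, or
power such studies without patient data: every stage of the clinical
workflow — from the sodium acquisition to the final dose–response
statistics — is reproduced on a controllable digital phantom whose ground
truth is known.

The pipeline covers:

- **Phantom simulation** — a head phantom with WM / GM / CSF / vitreous
  humor (VH) / metastasis / edema compartments at literature sodium
  concentrations (healthy brain ≈ 30–56 mM, CSF 135 mM, VH 145 mM, tumor
  ≈ 61 mM), evolving over three scans: baseline (I, 2 days pre-SRS), acute
  (II, 5 days post), late (III, 40 days post).
- **SRS dose model** — GTV→PTV margin expansion and a Gamma-Knife-like
  field prescribed to the 50% isodose enclosing the PTV (16–22 Gy), with a
  configurable exponential fall-off.
- **Acquisition & reconstruction** — density-adapted 3-D radial sampling
  (9,000 spokes × 384 points, TR 100 ms, TE 0.4 ms, nominal 4 mm), exact
  NUDFT and fast Kaiser–Bessel NUFFT forward models, and regridding
  reconstruction with a Hanning kernel of width 4, zero-filling factor 2
  (2 mm apparent voxels), Pipe–Menon density compensation and
  deapodization.
- **Registration & segmentation** — rigid mutual-information
  co-registration of every sodium image to the scan-I anatomical reference,
  and Gaussian-mixture WM/GM/CSF segmentation for CSF exclusion.
- **TSC quantification** — normalization to the left vitreous humor with a
  saturation-recovery T1 correction:

  ```
  SI_T1corr(VH) = SI(VH) / (1 − e^(−TR/T1_VH)),   T1_VH = 50 ms
  TSC(x)        = SI(x) · 145 mM / SI_T1corr(VH)
  ```

- **ROI dosimetry & statistics** — GTV, healthy white-matter cylinders
  (r 5 mm × h 10 mm), nested isodose shells at D = 2, 3, 4, 6, 8, 10, 12,
  18 Gy (each shell is the region ≥ D minus the next-higher region, GTV/PTV
  and the prescription region excluded), CSF subtraction, paired Student
  t-tests with a Lilliefors normality gate, and the Pearson dose–TSC
  correlation per scan.

## Worked example

Simulate two patients of the reference cohort at desk scale (64³ phantom at
2.5 mm, 1,200 spokes) and run the full longitudinal analysis:

```python
from natsc import StudyConfig, run_study
from natsc.cohort import reference_cohort

cfg = StudyConfig.reduced(seed=1, use_true_transform=True,
                          motion_max_mm=0.0, motion_max_deg=0.0)
patients = reference_cohort().query("patient in [5, 6]")
report = run_study(cfg, cohort=patients)

print(report.summary[["region", "scan_I_mean", "scan_II_mean",
                      "scan_III_mean", "I-II", "I-III"]].round(1).to_string(index=False))
print(report.correlations[["scan", "r", "p"]].round(3).to_string(index=False))
```

which prints:

```
    region  scan_I_mean  scan_II_mean  scan_III_mean       I-II      I-III
       GTV         59.0          64.8           55.4 ↑ p=0.0068 ↓ p=0.0689
        HR         36.6          36.6           36.4 ↓ p=0.9216 ↓ p=0.1971
shell_12Gy         50.0          54.2           45.4 ↑ p=0.0048 ↓ p=0.0226
 shell_2Gy         42.7          43.5           42.5 ↑ p=0.0087 ↓ p=0.1272
 shell_4Gy         45.6          47.3           43.8 ↑ p=0.0290 ↓ p=0.0104
 shell_6Gy         50.1          52.4           47.5 ↑ p=0.0769 ↓ p=0.0007
 shell_8Gy         49.0          52.1           45.2 ↑ p=0.0414 ↓ p=0.0007

scan     r     p
   I 0.827 0.084
  II 0.901 0.037
 III 0.540 0.348
```

Read it as the clinical study would be read: tumor TSC rises acutely after
SRS (59 → 65 mM, +10%) and falls below baseline at six weeks (55 mM);
the peritumoral shells show the same rise-then-recovery, strongest at high
dose; the healthy cylinders are flat at ≈ 37 mM (recovered from a 40 mM
ground truth — the residual is the known T1-weighting factor
1 − e^(−100/35) ≈ 0.94); and shell TSC correlates positively with dose at
every scan. Per-ROI records, comparison tables and CSV/JSON reports come
out of `report.write(out_dir)`.

A command-line interface exposes the stages individually
(`natsc simulate-phantom`, `simulate-dose`, `acquire`, `recon`, `register`,
`segment`, `quantify`, `shells`, `roistats`, `run`).

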