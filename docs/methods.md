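# Methods

This note documents the models behind `natsc`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic validation
does and does not demonstrate about real data.

## Digital head phantom

The ground-truth phantom lives on a fine grid (1 mm isotropic by default;
2.5 mm in the desk-scale preset) so that partial-volume effects at the
4 mm sodium resolution *emerge* from the forward model rather than being
modelled ad hoc. Geometry is parametric, scaled to the field of view:
a brain ellipsoid with a 2 mm outer CSF rim and a 4 mm cortical GM shell
around a WM core, two lateral ventricles, and two vitreous-humor (VH)
spheres anterior and slightly inferior to the brain (11 mm radius at full
FOV, shrunk proportionally on small grids; the patient-left eye is the
calibration reference, LPS convention). Metastases are spheres placed in
parenchyma; lesions below 64 mm³ are rejected as sub-resolution
(the evaluability rule of the study design). Peritumoral edema occupies
two decay lengths around each lesion, with TSC decaying exponentially from
the rim toward the WM baseline (default decay length 8 mm, rim elevation
12 mM — chosen to put near-lesion baseline TSC in the mid-50s mM, as
reported for untreated peritumoral tissue).

Compartment baselines (mM): WM 40, GM 45 (inside the 30–56 normal range),
CSF 135, VH fixed at 145 (extracellular sodium; the quantification
reference), metastasis 61 with a between-lesion SD of 5 mM. Voxel-wise
biological jitter defaults to 2 mM SD; fluids (CSF, VH) are exactly
constant, which preserves the calibration invariant. Relaxation: T1
35 ms in tissue, 50 ms in VH *and* CSF (fluids assumed to relax alike);
T2* is monoexponential and uniform at 4 ms. Uniform T2* is a deliberate
simplification: at TE = 0.4 ms the decay factor is 0.905 everywhere and
cancels exactly in the VH normalization, so quantification bias is pure
T1 mismatch and can be checked against a closed form. Real tissue has
biexponential T2* and a fluid/tissue difference; that residual bias
(≈ 1–9% depending on compartments) is *not* probed by these phantoms.

## Longitudinal dose response

No voxel-level biophysical model of radiation response exists for TSC, so
the evolution is phenomenological, with the shapes the clinical data
motivate:

- scan I := baseline + γ·D in peritumoral tissue (γ = 0.5 mM/Gy):
  tissue destined for high dose sits near the tumor and already carries
  elevated sodium from edema;
- scan II := scan I + α·D (α = 0.35 mM/Gy): acute post-SRS rise;
- scan III := scan I − β·max(0, D − 2 Gy) (β = 0.55 mM/Gy): late decline
  below baseline in the high-dose region, recovery elsewhere;
- the GTV follows fixed offsets (+7 mM at II, −3 mM at III against a
  61 mM baseline), reproducing the rise-then-fall trajectory of responding
  metastases; lesions receiving no dose do not respond.

Progressive (non-responding) lesions get their own parameter set: a low
flat baseline (49 mM), no acute surge, and — for the early progressor —
a late *rise* instead of recovery.

The slopes are identifiable: regressing scan II − scan I shell-mean
differences on shell mean dose recovers α within ~15% noise-free and ~30%
at realistic noise; the attenuation is partial-volume smoothing, not
estimator bias.

## Dose model

Planning-system physics is out of scope; only the isodose-shell geometry
matters downstream. Per lesion, with s(x) the signed Euclidean distance to
the PTV surface (negative inside, computed by a half-voxel-offset distance
transform):

    dose(x) = 2·rx · min(1, 0.5 · 2^(−s/falloff_half_mm))

giving exactly rx on the PTV surface (the 50% prescription convention),
a 2·rx cap from one half-distance inside the surface, and dose halving
every `falloff_half_mm` (default 2 mm — the "sharp gradient" regime of
radiosurgery; the study data constrain no particular value). Multiple
lesions sum voxel-wise, capped at 2·max(rx). The field is monotone along
outward rays, so isodose regions are nested by construction.

## Acquisition and reconstruction

**Trajectory.** Spoke directions follow spiral phyllotaxis (quasi-uniform
over the sphere; the vendor's exact ordering is unpublished, and only the
angular density matters here). Radial positions are density-adapted: linear
ramp up to k₀ = 0.2·k_max (configurable; the ramp radius is a free
simulator parameter), then uniform spherical density (k ∝ t^⅓), the two
branches joined with continuous k and dk/dt. The analytic DCF assigns each
sample the spherical-shell volume it represents, split at midpoints of the
volume coordinate v = k³ — exactly ∝ k² on the ramp and constant to
machine precision on the uniform segment.

**Forward models.** The exact NUDFT (O(voxels × samples), numba) is the
oracle; production simulation uses a type-2 Kaiser–Bessel NUFFT (2×
oversampling, width-4 kernel, numeric deapodization) that agrees with the
oracle to ≲ 0.1% RMS. Complex Gaussian k-space noise is seeded per scan.
Reduced-scale runs shorten the *spoke count only*; the 384-point radial
readout is kept, because the first radial samples carry the object's
near-DC energy and coarsening them corrupts low-frequency quantitation.

**Reconstruction.** Density compensation → gridding with a separable
Hanning kernel of full width 4 k-space cells (the most literal regridding
reading of a "Hanning filter with width 4"; matching image-space
deapodization is applied, so the kernel is transparent rather than an
extra smoothing filter) → zero-filling ×2 (4 mm nominal → 2 mm apparent
voxels) → inverse FFT → deapodization → magnitude. Two numerical choices
matter:

1. *Internal 2× k-space oversampling of the gridding matrix.* The Hanning
   kernel's image-domain transform crosses zero exactly at the FOV edge,
   so near-edge voxels (the eyes!) are strongly attenuated and their
   deapodization amplifies any gridding aliasing. Oversampling pushes the
   aliasing replicas outside the FOV, making the numerator accurate where
   the division is large. Pixels where the kernel transform is below 10⁻³
   of its peak are zeroed, not amplified.
2. *Pipe–Menon density-compensation refinement* (12 fixed-point
   iterations, cached per trajectory). A per-sample analytic DCF makes the
   adjoint a midpoint quadrature of an oscillatory integrand, which biases
   large smooth objects by ~(2πXΔk)²/24 ≈ 10–15% at head scale; the
   fixed point instead flattens the gridded sampling density so the
   uniform-grid FFT integrates exactly. The absolute scale follows
   analytically from the fixed point (Δk·C(0)² per axis), and is verified
   against uniform-object and analytic-ball oracles.

## Registration and segmentation

6-DOF Euler registration (SimpleITK): Mattes mutual information with 64
histogram bins (the synthetic contrasts are nearly discrete; coarse
histograms create spurious rotational optima), dense (deterministic)
sampling, a 4/2/1 multi-resolution pyramid, and a fixed-image foreground
mask (above 5% of the robust maximum) — without the mask the empty
background flattens the MI landscape and cross-contrast registration
fails. Recovery on reconstructed sodium phantoms is ≲ 0.4 mm / 0.2° for
perturbations up to 5 mm / 5°. The sodium *magnitude* image is registered
to the anatomical reference directly (assumption: no proton image from
the dual-tuned coil is simulated). Labels are resampled nearest-neighbour,
scalars trilinearly; all ROIs live on the scan-I reference grid and
sodium images are transformed to it, never the reverse.

Segmentation is a seeded 3-class Gaussian mixture on anatomical intensity
inside the brain mask, classes ordered by mean (CSF < GM < WM under
T1-weighted contrast). On the phantom it agrees with ground truth ≥ 95%
voxel-wise; real MPRAGE bias fields and partial volume would degrade this,
which is why CSF subtraction uses a posterior threshold (0.5) rather than
hard labels.

## Quantification

Only the VH reference is T1-corrected (saturation-recovery division
SI/(1−e^(−TR/T1)), the standard model for long-TR spoiled acquisitions;
recorded in the calibration metadata). Tissue maps keep their residual
T1 weighting — the long TR minimizes it — so a compartment with T1 = T1_t
is recovered with the closed-form factor (1−e^(−TR/T1_t)) ≈ 0.94 for
brain at TR = 100 ms, and the VH compartment itself reads
145·(1−e^(−TR/T1_VH)) ≈ 125 mM in the map. End-to-end phantom recovery
matches these factors within ~2.5%; the absolute-recovery criterion
(within 10%) therefore applies to brain compartments. The VH ROI is eroded
by one apparent voxel before calibration (whether the clinical contours
were eroded is unstated; erosion is our choice), the left VH is the
reference, and negative reconstructed values are kept by default so ROI
means stay unbiased.

## ROIs and statistics

Shells are 3-D volumes (the slice-wise alternative was rejected as less
robust at 4 mm resolution), evaluated on the reference grid, with GTV and
PTV excluded from every shell so tumor signal never contaminates
peritumoral statistics (implied but not stated by the clinical procedure;
documented as our choice). A level at or above the lesion's prescription
yields an empty, flagged shell (e.g. the 18 Gy shell of a 16 Gy lesion).
Healthy cylinders are placed automatically: fully inside WM, outside all
shells, ≥ 20 mm from any GTV, contralateral when feasible, axis
superior–inferior, half-open height interval so voxel-centre counting
matches the analytic volume.

Lesions are the paired unit (a per-patient-averaging flag exists);
incomplete scans are handled pairwise-available. The normality gate is a
Lilliefors-corrected KS test (parameters estimated from the sample),
warning rather than blocking. No multiple-testing correction by default
(raw α = 0.05 per comparison, matching the study design); Holm adjustment
is available but off. The dose–TSC correlation is computed per scan on the
eight across-lesion shell means — the only interpretation consistent with
one r per scan. Percent changes are reported at integer precision.

## Problem sizes

Default study conditions are the full reference cohort (12 patients,
14 metastases, doses twelve × 22, one × 16, one × 20 Gy; two frame-fixated
patients with 0 mm margin, 1 mm otherwise) on the 1 mm phantom grid with
the full 9,000-spoke sequence. The test suite and the acceptance script
use the reduced preset — 64³ phantom at 2.5 mm, 1,200 spokes × 384 points,
subsets of 2–4 patients — which preserves the statistical structure
(documented throughout as the package's desk-scale configuration). At
this scale k-space noise at 2% of the RMS sample magnitude gives healthy-
ROI SNR comparable to clinical sodium imaging and is what "realistic
noise" means in the tests.

## Known limitations

- Phenomenological dose response; no mechanism, only observed shapes.
- Single-channel birdcage model; no B0/B1 inhomogeneity, no biexponential
  T2*, no coil sensitivity.
- Ellipsoidal anatomy without cortical folding; segmentation difficulty is
  therefore optimistic.
- The clinical study's correlation coefficients were computed on unrounded
  ROI means from patient data that is not available; the simulated cohort
  reproduces their sign and magnitude range, not their exact values.
- Rigid volumes across scans (no tumor shrinkage or mass effect), matching
  the clinical analysis but not tumor biology.
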