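"""Synthetic longitudinal head phantom with brain-metastasis lesions.

Generates the ground truth that the acquisition/quantification chain is asked
to recover: a compartment label map (WM, GM, CSF, the two vitreous humours,
per-lesion GTVs, peritumoral edema), voxel-wise tissue sodium concentration
(TSC, mM) at three scan timepoints — baseline (I), a few days post-SRS (II),
and ~6 weeks post-SRS (III) — relaxation-time maps, and an MPRAGE-like
anatomical reference used as the registration target.

The ground-truth grid is deliberately finer (1 mm isotropic by default) than
the 4 mm nominal sodium acquisition so that partial-volume effects emerge
from the forward model instead of being modelled ad hoc.

Compartment TSC defaults sit at literature values for healthy brain
(WM ≈ 40 mM, GM ≈ 45 mM, both inside the 30–56 mM normal range), fluid
compartments near extracellular sodium (CSF 135 mM, vitreous humour fixed at
145 mM), and an elevated metastasis baseline (61 mM). The longitudinal dose
response — an acute post-SRS rise and a late decline — is applied by
:func:`compose_evolution` once a dose field exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import GridMeta, LabelVolume, ScalarVolume

__all__ = [
    "LABELS",
    "LABEL_GTV_BASE",
    "TSCEvolutionParams",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "compose_evolution",
]

# compartment label codes; GTVs are LABEL_GTV_BASE + lesion index
LABELS = {
    "background": 0,
    "wm": 1,
    "gm": 2,
    "csf": 3,
    "vh_left": 4,
    "vh_right": 5,
    "edema": 6,
}
LABEL_GTV_BASE = 10

EVALUABLE_MIN_VOLUME_MM3 = 64.0  # below the nominal-resolution inclusion limit


@dataclass(frozen=True)
class TSCEvolutionParams:
    """Compartment TSC baselines (mM) and the dose-response couplings.

    ``baseline_slope_gamma`` couples baseline peritumoral TSC to the eventual
    local dose: lesions sit inside their edema, so tissue destined for high
    dose already carries elevated sodium at scan I. ``acute_alpha`` is the
    acute (scan II) rise per Gy; ``late_beta`` the late (scan III) decline
    per Gy above ``recovery_floor_gy``. The GTV follows its own trajectory
    (rise at II, fall below baseline at III) via fixed offsets, since no
    voxel-level biophysical model is available for tumour response.
    """

    tsc_wm: float = 40.0
    tsc_gm: float = 45.0
    tsc_csf: float = 135.0
    tsc_vh: float = 145.0
    tsc_gtv_baseline: float = 61.0
    baseline_slope_gamma: float = 0.5  # mM/Gy
    acute_alpha: float = 0.35  # mM/Gy, scan II rise
    late_beta: float = 0.55  # mM/Gy above the floor, scan III decline
    recovery_floor_gy: float = 2.0
    gtv_acute_offset: float = 7.0  # mM, scan II GTV rise
    gtv_late_offset: float = -3.0  # mM, scan III GTV change vs baseline
    lesion_offset_sd: float = 5.0  # mM, between-lesion baseline spread
    edema_rim_elevation: float = 12.0  # mM of TSC elevation at the lesion rim
    noise_sd: float = 2.0  # mM, voxel-wise biological jitter

    def __post_init__(self) -> None:
        for name in ("tsc_wm", "tsc_gm", "tsc_csf", "tsc_vh", "tsc_gtv_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tsc_gtv_baseline <= self.tsc_wm:
            raise ValueError("tsc_gtv_baseline must exceed tsc_wm")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and randomness of one synthetic head phantom."""

    grid_shape: tuple[int, int, int] = (176, 192, 160)
    voxel_size_mm: float = 1.0
    lesion_centers: tuple[tuple[float, float, float], ...] | None = None
    lesion_radii_mm: tuple[float, ...] = (5.0,)
    edema_extent_mm: float = 8.0
    tsc_params: TSCEvolutionParams = field(default_factory=TSCEvolutionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.lesion_centers is not None and len(self.lesion_centers) != len(
            self.lesion_radii_mm
        ):
            raise ValueError("one radius per lesion centre required")
        for r in self.lesion_radii_mm:
            vol = 4.0 / 3.0 * np.pi * r**3
            if vol < EVALUABLE_MIN_VOLUME_MM3:
                raise ValueError(
                    f"lesion volume {vol:.1f} mm^3 below the evaluability "
                    f"threshold of {EVALUABLE_MIN_VOLUME_MM3:.0f} mm^3 "
                    f"(radius {r} mm)"
                )

    @property
    def grid(self) -> GridMeta:
        return GridMeta(
            shape=tuple(self.grid_shape), spacing=(self.voxel_size_mm,) * 3
        )

    def n_lesions(self) -> int:
        return len(self.lesion_radii_mm)


@dataclass
class GroundTruth:
    """Everything the pipeline is later asked to recover."""

    labels: LabelVolume
    tsc_maps: dict[str, ScalarVolume]  # keys "I", "II", "III"
    t1_map: ScalarVolume  # ms
    t2star_map: ScalarVolume  # ms
    reference_anatomy: ScalarVolume
    spec: PhantomSpec
    lesion_centers: tuple[tuple[float, float, float], ...]
    lesion_tsc_baseline: tuple[float, ...]

    @property
    def brain_mask(self) -> np.ndarray:
        lab = self.labels.data
        return (lab == LABELS["wm"]) | (lab == LABELS["gm"]) | (
            lab == LABELS["csf"]
        ) | (lab == LABELS["edema"]) | (lab >= LABEL_GTV_BASE)

    def gtv_mask(self, lesion: int | None = None) -> np.ndarray:
        if lesion is None:
            return self.labels.data >= LABEL_GTV_BASE
        return self.labels.data == LABEL_GTV_BASE + lesion


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _head_geometry(grid: GridMeta):
    """Anatomical landmark geometry, scaled to the grid's field of view.

    LPS convention: +x is patient-left, +y posterior, +z superior; the eyes
    sit anterior (−y) and slightly inferior to the brain.
    """
    fov = np.asarray(grid.fov_mm)
    center = fov / 2.0
    brain_axes = np.array([0.34 * fov[0], 0.36 * fov[1], 0.32 * fov[2]])
    eye_radius = min(11.0, 0.066 * fov[1] - 0.5)
    if eye_radius <= 1.0:
        raise ValueError(f"field of view {tuple(fov)} too small to place eyes")
    eye_y = center[1] - brain_axes[1] - eye_radius - 1.0
    eye_z = center[2] - 0.25 * brain_axes[2]
    eye_left = np.array([center[0] + 0.38 * brain_axes[0], eye_y, eye_z])
    eye_right = np.array([center[0] - 0.38 * brain_axes[0], eye_y, eye_z])
    return center, brain_axes, eye_radius, eye_left, eye_right


def default_lesion_centers(spec: PhantomSpec) -> tuple[tuple[float, float, float], ...]:
    """Deterministic default lesion placement inside white matter."""
    center, axes, *_ = _head_geometry(spec.grid)
    offsets = [
        np.array([-0.42, -0.30, 0.10]),  # right frontal
        np.array([0.42, 0.28, 0.05]),  # left occipital
        np.array([-0.35, 0.32, -0.12]),
        np.array([0.30, -0.35, -0.15]),
    ]
    pts = []
    for i in range(spec.n_lesions()):
        off = offsets[i % len(offsets)]
        pts.append(tuple(center + off * axes))
    return tuple(pts)


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Build the ground-truth phantom for one synthetic patient.

    Deterministic for a fixed ``spec.seed``. Raises if a lesion centre falls
    outside the brain's white/grey matter or overlaps a vitreous humour.
    Before any dose is composed in, the three timepoint TSC maps are
    identical (no treatment, no evolution).
    """
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)
    coords = grid.coordinate_arrays()
    center, brain_axes, eye_r, eye_l, eye_r_pos = _head_geometry(grid)

    brain = _ellipsoid(coords, center, brain_axes)
    # concentric shells: outer 2 mm CSF rim, next 4 mm GM, WM core
    gm_outer = _ellipsoid(coords, center, np.maximum(brain_axes - 2.0, 1.0))
    wm_core = _ellipsoid(coords, center, np.maximum(brain_axes - 6.0, 1.0))

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[brain] = LABELS["csf"]
    labels[gm_outer] = LABELS["gm"]
    labels[wm_core] = LABELS["wm"]

    # lateral ventricles: two CSF ellipsoids flanking the midline
    for sx in (+1.0, -1.0):
        vent = _ellipsoid(
            coords,
            center + np.array([sx * 0.14 * brain_axes[0], 0.05 * brain_axes[1], 0.1 * brain_axes[2]]),
            np.array([0.09 * brain_axes[0], 0.30 * brain_axes[1], 0.14 * brain_axes[2]]),
        )
        labels[vent & wm_core] = LABELS["csf"]

    vh_left = _ellipsoid(coords, eye_l, np.full(3, eye_r))
    vh_right = _ellipsoid(coords, eye_r_pos, np.full(3, eye_r))
    if np.any(vh_left & brain) or np.any(vh_right & brain):
        raise ValueError("vitreous humour spheres overlap the brain mask")
    labels[vh_left] = LABELS["vh_left"]
    labels[vh_right] = LABELS["vh_right"]

    lesion_centers = (
        spec.lesion_centers
        if spec.lesion_centers is not None
        else default_lesion_centers(spec)
    )
    x, y, z = coords
    dist_rim = np.full(grid.shape, np.inf)  # distance outside nearest lesion rim
    for i, (c, r) in enumerate(zip(lesion_centers, spec.lesion_radii_mm)):
        cidx = tuple(np.round(grid.physical_to_index(np.asarray(c))).astype(int))
        if any(j < 0 or j >= n for j, n in zip(cidx, grid.shape)):
            raise ValueError(f"lesion {i} centre {c} outside the grid")
        if labels[cidx] not in (LABELS["wm"], LABELS["gm"]):
            raise ValueError(
                f"lesion {i} centre {c} not inside brain parenchyma "
                f"(label {int(labels[cidx])})"
            )
        d = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        sphere = d <= r
        if np.any(sphere & (vh_left | vh_right)):
            raise ValueError(f"lesion {i} overlaps a vitreous humour")
        labels[sphere] = LABEL_GTV_BASE + i
        dist_rim = np.minimum(dist_rim, d - r)

    # peritumoral edema: parenchyma within 2 decay lengths of a lesion rim
    edema_zone = (
        (dist_rim > 0)
        & (dist_rim <= 2.0 * spec.edema_extent_mm)
        & ((labels == LABELS["wm"]) | (labels == LABELS["gm"]))
    )
    labels[edema_zone] = LABELS["edema"]

    p = spec.tsc_params
    lesion_tsc = tuple(
        float(p.tsc_gtv_baseline + rng.normal(0.0, p.lesion_offset_sd))
        for _ in lesion_centers
    )

    tsc = np.zeros(grid.shape, dtype=float)
    tsc[labels == LABELS["wm"]] = p.tsc_wm
    tsc[labels == LABELS["gm"]] = p.tsc_gm
    tsc[labels == LABELS["csf"]] = p.tsc_csf
    tsc[labels == LABELS["vh_left"]] = p.tsc_vh
    tsc[labels == LABELS["vh_right"]] = p.tsc_vh
    # edema TSC decays exponentially from the rim toward the WM baseline
    if np.any(edema_zone):
        base = np.where(
            _ellipsoid(coords, center, np.maximum(brain_axes - 6.0, 1.0)),
            p.tsc_wm,
            p.tsc_gm,
        )
        tsc[edema_zone] = base[edema_zone] + p.edema_rim_elevation * np.exp(
            -dist_rim[edema_zone] / spec.edema_extent_mm
        )
    for i in range(len(lesion_centers)):
        tsc[labels == LABEL_GTV_BASE + i] = lesion_tsc[i]

    if p.noise_sd > 0:
        jitter = rng.normal(0.0, p.noise_sd, size=grid.shape)
        fluid_or_bg = (
            (labels == 0)
            | (labels == LABELS["csf"])
            | (labels == LABELS["vh_left"])
            | (labels == LABELS["vh_right"])
        )
        tsc = np.where(fluid_or_bg, tsc, np.maximum(tsc + jitter, 0.0))

    t1 = np.full(grid.shape, 35.0)
    fluid = (labels == LABELS["csf"]) | (labels == LABELS["vh_left"]) | (
        labels == LABELS["vh_right"]
    )
    t1[fluid] = 50.0  # vitreous humour and CSF assumed to relax alike
    t2star = np.full(grid.shape, 4.0)

    anatomy = _mprage_like(labels, rng)

    lab_vol = LabelVolume(labels, grid, {v: k for k, v in LABELS.items()})
    mk = lambda a, u: ScalarVolume(a, grid, u)  # noqa: E731
    return GroundTruth(
        labels=lab_vol,
        tsc_maps={s: mk(tsc.copy(), "mM") for s in ("I", "II", "III")},
        t1_map=mk(t1, "ms"),
        t2star_map=mk(t2star, "ms"),
        reference_anatomy=mk(anatomy, "a.u."),
        spec=spec,
        lesion_centers=tuple(tuple(float(v) for v in c) for c in lesion_centers),
        lesion_tsc_baseline=lesion_tsc,
    )


def _mprage_like(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """T1-weighted contrast: WM bright, GM mid, fluids dark, lesions enhancing."""
    intensity = {
        LABELS["background"]: 0.0,
        LABELS["wm"]: 1.0,
        LABELS["gm"]: 0.70,
        LABELS["csf"]: 0.15,
        LABELS["vh_left"]: 0.12,
        LABELS["vh_right"]: 0.12,
        LABELS["edema"]: 0.85,
    }
    anat = np.zeros(labels.shape, dtype=float)
    for lab, val in intensity.items():
        anat[labels == lab] = val
    anat[labels >= LABEL_GTV_BASE] = 1.25  # contrast-enhancing metastasis
    anat += rng.normal(0.0, 0.02, size=labels.shape)
    return np.clip(anat, 0.0, None)


def compose_evolution(
    gt: GroundTruth, dose: ScalarVolume, params: TSCEvolutionParams | None = None
) -> GroundTruth:
    """Impose the dose-dependent longitudinal TSC evolution on a phantom.

    scan I  := scan I + gamma·D                      (pre-existing peritumoral elevation)
    scan II := scan I + alpha·D + jitter             (acute post-SRS rise)
    scan III:= scan I − beta·max(0, D − floor) + jitter  (late recovery/decline)

    Fluids are invariant: CSF and vitreous humour keep their baseline values
    at every timepoint. GTV voxels follow their own offsets (rise at II, fall
    below baseline at III) rather than the peritumoral dose law.
    """
    if params is None:
        params = gt.spec.tsc_params
    if not dose.meta.matches(gt.labels.meta):
        raise ValueError(
            f"dose grid {dose.meta.shape}@{dose.meta.spacing} does not match "
            f"phantom grid {gt.labels.meta.shape}@{gt.labels.meta.spacing}"
        )
    lab = gt.labels.data
    d = np.asarray(dose.data, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([gt.spec.seed, 0x5EED]))

    fluid = (
        (lab == LABELS["csf"]) | (lab == LABELS["vh_left"]) | (lab == LABELS["vh_right"])
    )
    bg = lab == LABELS["background"]
    gtv = lab >= LABEL_GTV_BASE
    tissue = ~(fluid | bg | gtv)

    base = gt.tsc_maps["I"].data.copy()
    base[tissue] += params.baseline_slope_gamma * d[tissue]

    gtv_treated = gtv & (d > 0)  # untreated lesions do not respond
    scan2 = base.copy()
    scan2[tissue] += params.acute_alpha * d[tissue]
    scan2[gtv_treated] += params.gtv_acute_offset

    scan3 = base.copy()
    scan3[tissue] -= params.late_beta * np.maximum(
        0.0, d[tissue] - params.recovery_floor_gy
    )
    scan3[gtv_treated] += params.gtv_late_offset

    if params.noise_sd > 0:
        varying = tissue | gtv
        scan2[varying] += rng.normal(0.0, params.noise_sd, size=int(varying.sum()))
        scan3[varying] += rng.normal(0.0, params.noise_sd, size=int(varying.sum()))
        scan2 = np.where(varying, np.maximum(scan2, 0.0), scan2)
        scan3 = np.where(varying, np.maximum(scan3, 0.0), scan3)

    meta = gt.labels.meta
    maps = {
        "I": ScalarVolume(base, meta, "mM"),
        "II": ScalarVolume(scan2, meta, "mM"),
        "III": ScalarVolume(scan3, meta, "mM"),
    }
    return replace(gt, tsc_maps=maps)
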