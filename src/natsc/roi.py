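"""Analysis ROIs: isodose shells, healthy-WM cylinders, CSF subtraction, and
per-ROI TSC statistics.

An isodose *shell* for level D is the region receiving at least D Gy minus
the region receiving at least the next-higher analysed level — a nested ring
around the target. The innermost (18 Gy) shell is closed from inside by the
prescription region {dose ≥ rx}, which is excluded from analysis, as are
GTV and PTV voxels, so shell statistics describe peritumoral tissue only.
Shells are evaluated as 3-D volumes on the reference grid.

Healthy reference ROIs are cylinders (r = 5 mm, h = 10 mm, axis
superior–inferior) placed automatically in healthy-appearing white matter:
inside WM, outside every shell, and at least 20 mm from any GTV,
contralateral to the lesion when feasible.

CSF voxels (p_CSF above threshold) are subtracted from every ROI before
statistics, since CSF's high sodium would otherwise bias tissue means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import GridMeta, LabelVolume, ScalarVolume
from .dose import DoseGrid
from .register import TissueProbabilityMaps

__all__ = [
    "IsodoseShellSet",
    "HealthyROI",
    "ROIStatistics",
    "build_isodose_shells",
    "subtract_csf",
    "place_healthy_rois",
    "roi_statistics",
    "cylinder_mask",
]


@dataclass
class IsodoseShellSet:
    """Nested, pairwise-disjoint isodose shells on one grid."""

    levels: tuple[float, ...]
    shell_masks: dict[float, LabelVolume]
    upper_bound_mask: np.ndarray  # {dose >= prescription}, excluded
    lower_level_gy: float
    rx_gy: float
    gtv_excluded: bool = True
    empty_levels: tuple[float, ...] = ()

    def union(self) -> np.ndarray:
        out = np.zeros(self.shell_masks[self.levels[0]].data.shape, dtype=bool)
        for lev in self.levels:
            out |= self.shell_masks[lev].data != 0
        return out

    def any_shell(self) -> np.ndarray:
        return self.union()

    def check_partition(self, dose: np.ndarray, excluded: np.ndarray) -> bool:
        """Shells must partition {dose ≥ lowest} \\ {dose ≥ rx} \\ excluded."""
        total = np.zeros(dose.shape, dtype=np.int32)
        for lev in self.levels:
            total += (self.shell_masks[lev].data != 0).astype(np.int32)
        if total.max() > 1:
            return False
        target = (dose >= self.lower_level_gy) & ~self.upper_bound_mask & ~excluded
        return bool(np.array_equal(total > 0, target))


@dataclass
class HealthyROI:
    """Cylindrical reference ROI in healthy-appearing white matter."""

    center: tuple[float, float, float]
    mask: LabelVolume
    radius_mm: float = 5.0
    height_mm: float = 10.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @property
    def analytic_volume_mm3(self) -> float:
        return float(np.pi * self.radius_mm**2 * self.height_mm)


@dataclass
class ROIStatistics:
    """Mean ± SD of TSC over one ROI at one scan."""

    roi: str
    scan: str
    n_voxels: int
    mean_tsc: float
    sd_tsc: float
    excluded_csf_voxels: int = 0
    missing: bool = False

    def as_dict(self) -> dict:
        return {
            "roi": self.roi,
            "scan": self.scan,
            "n": self.n_voxels,
            "mean": self.mean_tsc,
            "sd": self.sd_tsc,
            "excluded_csf": self.excluded_csf_voxels,
            "missing": self.missing,
        }


def build_isodose_shells(
    dose: DoseGrid,
    gtv: LabelVolume | np.ndarray,
    ptv: LabelVolume | np.ndarray | None = None,
) -> IsodoseShellSet:
    """Partition the dose field into the analysis shells.

    shell(Dᵢ) = {dose ≥ Dᵢ} \\ {dose ≥ Dᵢ₊₁} for consecutive analysed
    levels; the top shell is bounded inside by {dose ≥ rx} with rx the
    (smallest) prescription. GTV and PTV voxels are removed from every
    shell. Empty shells are kept with n = 0 and flagged — a small lesion
    with a steep gradient legitimately produces them.
    """
    levels = tuple(sorted(dose.d_levels))
    d = dose.dose.data
    meta = dose.dose.meta
    rx = min(p.rx_dose_gy for p in dose.prescriptions)
    # levels at or above the prescription cannot form a peritumoral shell
    # (their region lies inside the excluded prescription isodose) and are
    # retained empty below
    gtv_arr = gtv.data != 0 if isinstance(gtv, LabelVolume) else np.asarray(gtv, bool)
    if ptv is None:
        ptv_arr = np.zeros_like(gtv_arr)
        if dose.ptv_masks:
            for m in dose.ptv_masks:
                ptv_arr |= m
    else:
        ptv_arr = ptv.data != 0 if isinstance(ptv, LabelVolume) else np.asarray(ptv, bool)
    excluded = gtv_arr | ptv_arr

    upper = d >= rx
    shells: dict[float, LabelVolume] = {}
    empties = []
    bounds = [min(b, rx) for b in list(levels[1:]) + [rx]]
    for lev, nxt in zip(levels, bounds):
        m = (d >= lev) & (d < nxt) & ~excluded & ~upper
        if not m.any():
            empties.append(lev)
            warnings.warn(
                f"isodose shell {lev:g} Gy is empty (steep gradient or small "
                "lesion); retained with n=0",
                stacklevel=2,
            )
        shells[lev] = LabelVolume(m.astype(np.int16), meta, {1: f"shell_{lev:g}Gy"})
    return IsodoseShellSet(
        levels=levels,
        shell_masks=shells,
        upper_bound_mask=upper | excluded,
        lower_level_gy=levels[0],
        rx_gy=rx,
        empty_levels=tuple(empties),
    )


def subtract_csf(
    roi: LabelVolume,
    tissue: TissueProbabilityMaps,
    threshold: float = 0.5,
) -> tuple[LabelVolume, int]:
    """Remove probable-CSF voxels (p_csf > threshold) from an ROI.

    Returns the filtered ROI and the number of voxels removed. An ROI left
    empty is flagged with a warning, not an error.
    """
    if not roi.meta.matches(tissue.meta):
        raise ValueError("ROI and tissue maps must share one grid")
    m = roi.data != 0
    remove = m & (tissue.p_csf.data > threshold)
    out = roi.data.copy()
    out[remove] = 0
    n_removed = int(remove.sum())
    if m.any() and not (out != 0).any():
        warnings.warn("ROI empty after CSF subtraction", stacklevel=2)
    return LabelVolume(out, roi.meta, dict(roi.names)), n_removed


def cylinder_mask(
    meta: GridMeta,
    center: tuple[float, float, float],
    radius_mm: float = 5.0,
    height_mm: float = 10.0,
) -> np.ndarray:
    """Boolean mask of an axis-aligned (superior–inferior) cylinder."""
    x, y, z = meta.coordinate_arrays()
    r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    # half-open height interval: voxel-centre counting would otherwise
    # include both boundary slices and overshoot the analytic volume
    dz = z - center[2]
    return (r2 <= radius_mm**2) & (dz >= -height_mm / 2.0) & (dz < height_mm / 2.0)


def place_healthy_rois(
    tissue: TissueProbabilityMaps,
    shells: IsodoseShellSet | None,
    gtvs: np.ndarray | LabelVolume,
    seed: int = 0,
    n_rois: int = 2,
    radius_mm: float = 5.0,
    height_mm: float = 10.0,
    min_gtv_distance_mm: float = 20.0,
    wm_fraction: float = 0.95,
) -> list[HealthyROI]:
    """Deterministically place healthy-WM reference cylinders.

    Candidate centres are voxels whose full cylinder lies within WM
    (p_wm > 0.5), outside every isodose shell and ≥ 20 mm from any GTV;
    the seeded choice prefers the hemisphere contralateral to the (first)
    lesion and spaces multiple ROIs at least one cylinder diameter apart.
    """
    meta = tissue.meta
    rng = np.random.default_rng(seed)
    wm = tissue.p_wm.data > 0.5
    gtv_arr = gtvs.data != 0 if isinstance(gtvs, LabelVolume) else np.asarray(gtvs, bool)

    allowed = wm.copy()
    if shells is not None:
        allowed &= ~shells.any_shell()
        allowed &= ~shells.upper_bound_mask
    if gtv_arr.any():
        dist = ndimage.distance_transform_edt(~gtv_arr, sampling=meta.spacing)
        allowed &= dist >= min_gtv_distance_mm

    # erode by the cylinder footprint so every candidate centre fits fully
    sp = np.asarray(meta.spacing)
    rx_v = max(1, int(np.ceil(radius_mm / sp[0])))
    ry_v = max(1, int(np.ceil(radius_mm / sp[1])))
    rz_v = max(1, int(np.ceil(height_mm / 2.0 / sp[2])))
    ii, jj, kk = np.mgrid[-rx_v : rx_v + 1, -ry_v : ry_v + 1, -rz_v : rz_v + 1]
    struct = ((ii * sp[0]) ** 2 + (jj * sp[1]) ** 2 <= radius_mm**2) & (
        np.abs(kk * sp[2]) <= height_mm / 2.0
    )
    candidates = ndimage.binary_erosion(allowed, structure=struct)
    idx = np.argwhere(candidates)
    if idx.shape[0] == 0:
        raise ValueError(
            "no placement satisfies the healthy-ROI constraints "
            f"(WM volume {wm.sum() * meta.voxel_volume_mm3:.0f} mm^3, "
            f"{int(allowed.sum())} allowed voxels before erosion)"
        )
    pts = meta.index_to_physical(idx)

    # contralateral preference: opposite left-right (x) side of the lesion
    if gtv_arr.any():
        gtv_cx = meta.index_to_physical(np.argwhere(gtv_arr)).mean(axis=0)[0]
        mid_x = meta.index_to_physical(np.asarray(meta.shape, float) / 2.0)[0]
        contra = (pts[:, 0] - mid_x) * (gtv_cx - mid_x) < 0
    else:
        contra = np.ones(pts.shape[0], dtype=bool)

    order = rng.permutation(pts.shape[0])
    order = np.concatenate([order[contra[order]], order[~contra[order]]])

    chosen: list[np.ndarray] = []
    min_sep = 2.0 * radius_mm + 2.0
    for i in order:
        p = pts[i]
        if all(np.linalg.norm(p - q) >= min_sep for q in chosen):
            chosen.append(p)
        if len(chosen) == n_rois:
            break
    if len(chosen) < n_rois:
        raise ValueError(
            f"only {len(chosen)} healthy-ROI placements found, {n_rois} requested"
        )

    rois = []
    for p in chosen:
        cyl = cylinder_mask(meta, tuple(p), radius_mm, height_mm)
        frac = float(wm[cyl].mean()) if cyl.any() else 0.0
        if frac < wm_fraction:
            warnings.warn(
                f"healthy ROI at {tuple(np.round(p, 1))} has WM fraction "
                f"{frac:.2f} < {wm_fraction}",
                stacklevel=2,
            )
        rois.append(
            HealthyROI(
                center=tuple(float(v) for v in p),
                mask=LabelVolume(cyl.astype(np.int16), meta, {1: "healthy_roi"}),
                radius_mm=radius_mm,
                height_mm=height_mm,
            )
        )
    return rois


def roi_statistics(
    tsc: ScalarVolume,
    roi: LabelVolume | np.ndarray,
    roi_name: str = "",
    scan: str = "",
    excluded_csf_voxels: int = 0,
) -> ROIStatistics:
    """Mean and n−1 SD of TSC over the ROI's voxels.

    An empty ROI yields a flagged-missing record (NaN statistics) so that
    downstream group tests can drop it via pairwise-available analysis.
    """
    mask = roi.data != 0 if isinstance(roi, LabelVolume) else np.asarray(roi, bool)
    if isinstance(roi, LabelVolume) and not roi.meta.matches(tsc.meta):
        raise ValueError("ROI and TSC map must share one grid")
    vals = tsc.data[mask]
    if vals.size == 0:
        return ROIStatistics(
            roi=roi_name, scan=scan, n_voxels=0, mean_tsc=float("nan"),
            sd_tsc=float("nan"), excluded_csf_voxels=excluded_csf_voxels,
            missing=True,
        )
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return ROIStatistics(
        roi=roi_name,
        scan=scan,
        n_voxels=int(vals.size),
        mean_tsc=float(np.mean(vals)),
        sd_tsc=sd,
        excluded_csf_voxels=excluded_csf_voxels,
    )
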