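"""Single-fraction SRS dose fields prescribed to the 50% isodose.

Gamma-Knife-style plans prescribe the treatment dose to the isodose surface
that just encloses the PTV; the dose inside climbs to twice the prescription
at the core and falls off steeply outside. The planning system itself is out
of scope here — only the *geometry* of the resulting isodose shells matters
downstream — so the field is modelled as an exponential function of the
signed Euclidean distance to the PTV surface:

    dose(x) = 2 · rx · g(s(x)),   g(s) = min(1, 0.5 · 2^(−s / falloff_half_mm))

with ``s`` negative inside the PTV. This gives exactly the prescription on
the PTV surface, dose halving every ``falloff_half_mm`` outward (default
2 mm, mimicking the sharp gradients of radiosurgery), and the 2·rx cap a
half-distance inside the surface. Multiple lesions add voxel-wise, capped at
twice the largest prescription.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelVolume, ScalarVolume

__all__ = [
    "PrescriptionSpec",
    "DoseGrid",
    "expand_margin",
    "compute_dose",
    "summarize_prescriptions",
    "DEFAULT_SHELL_LEVELS_GY",
]

DEFAULT_SHELL_LEVELS_GY: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 18.0)


@dataclass(frozen=True)
class PrescriptionSpec:
    """Per-lesion SRS prescription.

    ``margin_mm`` is the GTV→PTV expansion: 0 for stereotactic frame
    fixation, 1 mm for thermoplastic mask fixation.
    """

    rx_dose_gy: float
    margin_mm: float = 1.0
    falloff_half_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.rx_dose_gy <= 0:
            raise ValueError("rx_dose_gy must be positive")
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be non-negative")
        if self.falloff_half_mm <= 0:
            raise ValueError("falloff_half_mm must be positive")
        if not (16.0 <= self.rx_dose_gy <= 22.0):
            warnings.warn(
                f"prescription {self.rx_dose_gy} Gy outside the usual "
                "single-fraction SRS range of 16-22 Gy",
                stacklevel=2,
            )
        if self.margin_mm not in (0.0, 1.0):
            warnings.warn(
                f"PTV margin {self.margin_mm} mm; typical values are 0 mm "
                "(frame) or 1 mm (mask fixation)",
                stacklevel=2,
            )


@dataclass
class DoseGrid:
    """A dose field plus its prescriptions and the shell analysis levels."""

    dose: ScalarVolume
    prescriptions: tuple[PrescriptionSpec, ...]
    d_levels: tuple[float, ...] = DEFAULT_SHELL_LEVELS_GY
    ptv_masks: tuple[np.ndarray, ...] = ()

    @property
    def rx_max_gy(self) -> float:
        return max(p.rx_dose_gy for p in self.prescriptions)


def expand_margin(gtv_mask: LabelVolume, margin_mm: float) -> LabelVolume:
    """Expand a GTV mask isotropically by ``margin_mm`` (Euclidean) to a PTV.

    A voxel belongs to the PTV iff its centre lies within ``margin_mm`` of
    the GTV voxel set. Zero margin returns the mask unchanged.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    src = gtv_mask.data != 0
    if not src.any():
        raise ValueError("cannot expand an empty mask")
    if margin_mm == 0:
        return gtv_mask.copy()
    dist = ndimage.distance_transform_edt(~src, sampling=gtv_mask.meta.spacing)
    out = (dist <= margin_mm + 1e-9).astype(gtv_mask.data.dtype)
    return LabelVolume(out, gtv_mask.meta, dict(gtv_mask.names))


def _signed_distance_to_surface(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed Euclidean distance to the mask surface; negative inside."""
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    # distance_transform_edt measures to the nearest *voxel* of the other
    # set; offsetting by half a voxel puts the zero level on the surface.
    half = float(np.min(spacing)) / 2.0
    s = np.where(mask, -(inside - half), outside - half)
    return s


def compute_dose(
    labels: LabelVolume,
    specs: list[PrescriptionSpec] | tuple[PrescriptionSpec, ...],
    gtv_labels: list[int] | None = None,
    d_levels: tuple[float, ...] = DEFAULT_SHELL_LEVELS_GY,
) -> DoseGrid:
    """Compose the summed dose field for all lesions of one phantom.

    ``labels`` must contain one GTV label per prescription; by default GTV
    labels are taken as ``LABEL_GTV_BASE + i`` (phantom convention), or pass
    ``gtv_labels`` explicitly. PTVs are built from the per-lesion margin.
    """
    from .phantom import LABEL_GTV_BASE

    specs = tuple(specs)
    if not specs:
        raise ValueError("at least one prescription required")
    if gtv_labels is None:
        gtv_labels = [LABEL_GTV_BASE + i for i in range(len(specs))]
    if len(gtv_labels) != len(specs):
        raise ValueError("one GTV label per prescription required")

    meta = labels.meta
    total = np.zeros(meta.shape, dtype=float)
    ptvs = []
    for spec, lab in zip(specs, gtv_labels):
        gtv = labels.data == lab
        if not gtv.any():
            raise ValueError(f"GTV label {lab} not present in the label volume")
        ptv = expand_margin(
            LabelVolume(gtv.astype(np.int16), meta), spec.margin_mm
        ).data.astype(bool)
        s = _signed_distance_to_surface(ptv, meta.spacing)
        g = np.minimum(1.0, 0.5 * np.exp2(-s / spec.falloff_half_mm))
        total += 2.0 * spec.rx_dose_gy * g
        ptvs.append(ptv)

    cap = 2.0 * max(p.rx_dose_gy for p in specs)
    total = np.minimum(total, cap)
    return DoseGrid(
        dose=ScalarVolume(total, meta, "Gy"),
        prescriptions=specs,
        d_levels=tuple(sorted(d_levels)),
        ptv_masks=tuple(ptvs),
    )


def summarize_prescriptions(
    specs: list[PrescriptionSpec] | tuple[PrescriptionSpec, ...] | list[float],
) -> dict[str, float]:
    """Cohort mean and sample (n−1) SD of the prescribed doses, 1 decimal."""
    if len(specs) == 0:
        raise ValueError("no prescriptions to summarize")
    doses = np.array(
        [p.rx_dose_gy if isinstance(p, PrescriptionSpec) else float(p) for p in specs]
    )
    mean = float(np.mean(doses))
    sd = float(np.std(doses, ddof=1)) if len(doses) >= 2 else 0.0
    return {"n": len(doses), "mean_gy": round(mean, 1), "sd_gy": round(sd, 1)}
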