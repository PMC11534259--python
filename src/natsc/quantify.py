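"""Tissue sodium concentration mapping by vitreous-humor normalization.

The sodium image is converted to absolute concentration by normalizing to
the mean signal in the left vitreous humor (VH), whose sodium concentration
is taken as constant at 145 mM (extracellular sodium). Because the VH's T1
(≈ 50 ms) is not negligible against TR = 100 ms, the VH reference signal is
first corrected for its residual T1 saturation:

    SI_T1corr(VH) = SI(VH) / (1 − e^(−TR/T1_VH))
    TSC(x) = SI(x) · 145 mM / SI_T1corr(VH)

Only the reference is T1-corrected; tissue T1 weighting is left to the long
TR, mirroring standard practice for long-TR spoiled sodium acquisitions.
The residual quantification bias for a tissue with relaxation (T1, T2*) vs
the VH reference is therefore the closed-form mismatch factor returned by
:func:`expected_bias_factor`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelVolume, ScalarVolume
from .recon import SequenceParams

__all__ = [
    "C_VH_MM",
    "T1_VH_MS",
    "QuantCalibration",
    "TSCMap",
    "t1_correction_factor",
    "calibrate_vh",
    "quantify_tsc",
    "expected_bias_factor",
]

C_VH_MM = 145.0  # vitreous humor sodium concentration, mM
T1_VH_MS = 50.0  # assumed VH longitudinal relaxation time, ms


def t1_correction_factor(tr_ms: float, t1_ms: float) -> float:
    """Saturation-recovery weighting factor 1 − e^(−TR/T1)."""
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("TR and T1 must be positive")
    return float(1.0 - np.exp(-tr_ms / t1_ms))


@dataclass
class QuantCalibration:
    """VH reference calibration for one sodium scan."""

    si_vh: float
    correction_factor: float
    c_vh_mm: float = C_VH_MM
    t1_vh_ms: float = T1_VH_MS
    tr_ms: float = 100.0
    n_vh_voxels: int = 0
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.correction_factor < 1.0):
            raise ValueError("correction_factor must lie in (0, 1)")
        if self.si_vh <= 0:
            raise ValueError("VH signal must be positive")

    @property
    def si_vh_t1corr(self) -> float:
        return self.si_vh / self.correction_factor

    def as_dict(self) -> dict:
        return {
            "si_vh": self.si_vh,
            "si_vh_t1corr": self.si_vh_t1corr,
            "correction_factor": self.correction_factor,
            "c_vh_mm": self.c_vh_mm,
            "t1_vh_ms": self.t1_vh_ms,
            "tr_ms": self.tr_ms,
            "n_vh_voxels": self.n_vh_voxels,
            "low_confidence": self.low_confidence,
            "t1_model": "saturation_recovery",
        }


@dataclass
class TSCMap:
    """Voxel-wise tissue sodium concentration in mM."""

    values: ScalarVolume
    calibration: QuantCalibration
    scan_id: str = ""


def calibrate_vh(
    sodium_img: ScalarVolume,
    vh_mask: LabelVolume,
    params: SequenceParams,
    erode_mm: float | None = None,
    noise_floor: float = 0.0,
) -> QuantCalibration:
    """Measure the VH reference signal and apply the T1 correction.

    The VH mask (already transferred to the sodium grid) is eroded by one
    apparent voxel (default: ``params.apparent_res_mm``) to suppress partial
    volume with surrounding tissue; if erosion would empty the mask the
    uneroded mask is used and the calibration flagged low-confidence, as is
    a single-voxel mask or a reference below the noise floor.
    """
    if not vh_mask.meta.matches(sodium_img.meta):
        raise ValueError("VH mask must live on the sodium image grid")
    mask = vh_mask.data != 0
    if not mask.any():
        raise ValueError("VH mask is empty")
    if erode_mm is None:
        erode_mm = params.apparent_res_mm
    low_confidence = False
    if erode_mm > 0:
        it = max(1, int(round(erode_mm / min(sodium_img.meta.spacing))))
        eroded = ndimage.binary_erosion(mask, iterations=it)
        if eroded.any():
            mask = eroded
        else:
            low_confidence = True
            warnings.warn(
                "VH mask vanished under erosion; using the uneroded mask "
                "(low-confidence calibration)",
                stacklevel=2,
            )
    n = int(mask.sum())
    si = float(np.mean(sodium_img.data[mask]))
    if n < 2:
        low_confidence = True
        warnings.warn("single-voxel VH reference; calibration is low-confidence",
                      stacklevel=2)
    if si <= noise_floor:
        low_confidence = True
        warnings.warn(
            f"VH signal {si:.3g} at or below the noise floor {noise_floor:.3g}",
            stacklevel=2,
        )
    factor = t1_correction_factor(params.tr_ms, T1_VH_MS)
    return QuantCalibration(
        si_vh=si,
        correction_factor=factor,
        tr_ms=params.tr_ms,
        n_vh_voxels=n,
        low_confidence=low_confidence,
    )


def quantify_tsc(
    sodium_img: ScalarVolume,
    cal: QuantCalibration,
    scan_id: str = "",
    clip_nonneg: bool = False,
) -> TSCMap:
    """Voxel-wise TSC(x) = SI(x) · 145 mM / SI_T1corr(VH).

    Negative values (possible around noise in complex-difference regions)
    are kept by default so that ROI means stay unbiased; set
    ``clip_nonneg`` to clip at zero.
    """
    tsc = sodium_img.data * (cal.c_vh_mm / cal.si_vh_t1corr)
    if clip_nonneg:
        tsc = np.maximum(tsc, 0.0)
    return TSCMap(
        values=ScalarVolume(tsc, sodium_img.meta, "mM"),
        calibration=cal,
        scan_id=scan_id,
    )


def expected_bias_factor(
    tr_ms: float,
    t1_tissue_ms: float,
    t1_vh_ms: float = T1_VH_MS,
    te_ms: float = 0.0,
    t2star_tissue_ms: float | None = None,
    t2star_vh_ms: float | None = None,
) -> float:
    """Closed-form quantification bias for a homogeneous compartment.

    With the VH reference T1-corrected, its saturation term cancels and the
    recovered/true TSC ratio of a large compartment reduces to the tissue's
    own residual weighting relative to a fully relaxed reference:

        bias = (1 − e^(−TR/T1_tissue)) · e^(−TE/T2*_tissue) / e^(−TE/T2*_VH)

    (the tissue-vs-VH T1 mismatch factor, with the VH side removed by the
    applied correction). T2* terms are skipped when not given; with matched
    tissue/reference T2* they cancel exactly.
    """
    bias = t1_correction_factor(tr_ms, t1_tissue_ms)
    if te_ms > 0 and t2star_tissue_ms and t2star_vh_ms:
        bias *= np.exp(-te_ms / t2star_tissue_ms) / np.exp(-te_ms / t2star_vh_ms)
    return float(bias)
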