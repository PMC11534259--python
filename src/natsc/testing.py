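"""Validation experiments used by the test suite and the acceptance script.

These run the *real* pipeline on purpose-built synthetic inputs and return
plain numbers (recovered means, errors, slopes) that callers compare to
ground truth or closed forms.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import GridMeta, LabelVolume, ScalarVolume
from .quantify import calibrate_vh, quantify_tsc
from .recon import (
    SequenceParams,
    make_trajectory,
    reconstruct,
    simulate_acquisition,
    steady_state_signal,
)
from .register import RigidTransform, register_rigid, resample_scalar

__all__ = [
    "quantification_recovery",
    "registration_recovery",
    "recover_acute_slope",
]


def quantification_recovery(
    n: int = 64, spacing_mm: float = 2.5, n_spokes: int = 1500
) -> dict:
    """Noise-free end-to-end TSC recovery on a large-compartment phantom.

    Three smooth-edged compartments (a WM-like sphere at 40 mM / T1 35 ms,
    a lesion at 61 mM / T1 35 ms, a VH reference at 145 mM / T1 50 ms) are
    acquired, reconstructed, VH-calibrated and quantified; interior ROI
    means (6–8 mm erosion, clear of partial volume) are returned per
    compartment with the true values and tissue T1.
    """
    meta = GridMeta(shape=(n,) * 3, spacing=(spacing_mm,) * 3)
    x, y, z = meta.coordinate_arrays()
    c = np.array(meta.fov_mm) / 2

    def ball(ctr, radius):
        return (
            (x - (c[0] + ctr[0])) ** 2
            + (y - (c[1] + ctr[1])) ** 2
            + (z - (c[2] + ctr[2])) ** 2
        ) <= radius**2

    brain = ball((0, 10, 0), 30)
    lesion = ball((-12, 10, 0), 10)
    vh = ball((0, -46, 0), 13)
    tsc = np.zeros(meta.shape)
    t1 = np.full(meta.shape, 35.0)
    t2s = np.full(meta.shape, 4.0)
    tsc[brain] = 40.0
    tsc[lesion] = 61.0
    tsc[vh] = 145.0
    t1[vh] = 50.0

    params = SequenceParams(n_spokes=n_spokes, n_samples=384)
    sig = steady_state_signal(
        ScalarVolume(tsc, meta),
        ScalarVolume(t1, meta),
        ScalarVolume(t2s, meta),
        params,
    )
    smooth = ScalarVolume(ndimage.gaussian_filter(sig.data, sigma=1.2), meta)
    ks = simulate_acquisition(smooth, make_trajectory(params))
    img = reconstruct(ks)

    def on_recon(mask):
        return (
            resample_scalar(
                ScalarVolume(mask.astype(float), meta), RigidTransform(), img.meta
            ).data
            > 0.5
        )

    cal = calibrate_vh(
        img,
        LabelVolume(on_recon(vh).astype(np.int16), img.meta),
        params,
        erode_mm=6.0,
    )
    tsc_map = quantify_tsc(img, cal)

    out = {}
    truths = {
        "WM": (brain & ~lesion, 40.0, 35.0),
        "GTV": (lesion, 61.0, 35.0),
        "VH": (vh, 145.0, 50.0),
    }
    erosion_iters = {"WM": 4, "GTV": 3, "VH": 4}  # 2 mm recon voxels
    for name, (mask, true_val, t1_ms) in truths.items():
        roi = ndimage.binary_erosion(on_recon(mask), iterations=erosion_iters[name])
        out[name] = {
            "recovered_mM": float(tsc_map.values.data[roi].mean()),
            "true_mM": true_val,
            "t1_ms": t1_ms,
            "n_voxels": int(roi.sum()),
        }
    return out


def registration_recovery(
    sodium: ScalarVolume,
    translation_mm=(3.0, -2.0, 1.0),
    rotation_deg=(0.0, 0.0, 4.0),
    metric: str = "corr",
    fixed: ScalarVolume | None = None,
) -> dict:
    """Apply a known rigid perturbation (rotation about the FOV centre) to a
    reconstructed sodium image and measure how well registration recovers it.

    Errors are reported as the displacement mismatch at the FOV centre and
    the Euler-angle mismatch."""
    center = np.array(sodium.meta.fov_mm) / 2.0
    true = RigidTransform.from_params(tuple(rotation_deg), translation_mm, center)
    moved = resample_scalar(sodium, true.inverse(), sodium.meta)
    target = sodium if fixed is None else fixed
    rec = register_rigid(moved, target, metric=metric)
    terr = np.abs(rec.apply(center) - true.apply(center))
    rerr = np.abs(np.asarray(rec.rotation_deg) - np.asarray(true.rotation_deg))
    return {
        "translation_error_mm": terr.tolist(),
        "rotation_error_deg": rerr.tolist(),
        "max_translation_error_mm": float(terr.max()),
        "max_rotation_error_deg": float(rerr.max()),
        "metric_value": rec.metric_value,
    }


def recover_acute_slope(report) -> float:
    """Least-squares slope of scan II − scan I shell means against the
    shells' mean dose — the estimator of the generator's acute_alpha."""
    df = report.roi_stats
    sh = df[df["region"].str.startswith("shell_")]
    piv = sh.pivot_table(index="roi", columns="scan", values="mean", aggfunc="first")
    dose = sh.groupby("roi")["mean_dose_gy"].first()
    ok = piv["I"].notna() & piv["II"].notna()
    d = dose[piv.index[ok]].to_numpy()
    dy = (piv["II"] - piv["I"])[ok].to_numpy()
    if len(d) < 3:
        raise ValueError("too few shell observations to estimate a slope")
    slope = np.linalg.lstsq(np.vstack([d, np.ones_like(d)]).T, dy, rcond=None)[0][0]
    return float(slope)
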