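"""Reference SRS cohort: 12 patients, 14 brain metastases.

Printed per-lesion characteristics of the prospective single-fraction SRS
cohort this pipeline models: lesion location, GTV volume, prescribed dose,
primary histology, progression during follow-up, and which of the three
sodium scans (I: 2 days pre-SRS, II: 5 days post, III: 40 days post) each
lesion completed. These records are input data for the cohort-level
arithmetic (dose summary, completion counts) and for configuring
paper-faithful simulated studies.
"""

from __future__ import annotations

import pandas as pd

from .dose import summarize_prescriptions

__all__ = ["reference_cohort", "cohort_summary"]

_ROWS = [
    # patient, bm, location, gtv_cm3, dose_gy, histology, progressive, I, II, III
    (1, 1, "Frontal left", 0.423, 22, "NSCLC", False, True, True, True),
    (1, 2, "Frontal left", 0.315, 22, "NSCLC", False, True, True, True),
    (2, 3, "Frontal left", 0.264, 22, "Mammary carcinoma", False, True, True, True),
    (2, 4, "Frontal right", 1.456, 22, "Mammary carcinoma", False, True, True, True),
    (3, 5, "Occipital right", 0.124, 16, "NSCLC", False, True, True, False),
    (4, 6, "Occipital right", 1.637, 22, "NSCLC", False, True, True, True),
    (5, 7, "Occipital left", 0.416, 22, "Malignant melanoma", False, True, True, True),
    (6, 8, "Postcentral right", 0.411, 22, "Renal cell carcinoma", False, True, True, True),
    (7, 9, "Occipital right", 0.723, 22, "Soft tissue sarcoma", True, True, True, True),
    (8, 10, "Cerebellar right", 0.428, 22, "Esophageal cancer", False, True, False, False),
    (9, 11, "Frontal left", 0.197, 22, "Renal cell carcinoma", False, True, True, False),
    (10, 12, "Frontal right", 0.891, 22, "CUP syndrome", False, True, True, True),
    (11, 13, "Temporal left", 1.075, 22, "Mammary carcinoma", True, True, True, True),
    (12, 14, "Occipital right", 2.272, 20, "NSCLC", False, True, True, True),
]


def reference_cohort() -> pd.DataFrame:
    """The cohort listing as a tidy DataFrame (one row per metastasis)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "patient",
            "bm",
            "location",
            "gtv_cm3",
            "dose_gy",
            "histology",
            "progressive",
            "scan_I",
            "scan_II",
            "scan_III",
        ],
    )


def cohort_summary(cohort: pd.DataFrame | None = None) -> dict:
    """Cohort-level arithmetic: dose mean ± SD and scan-completion counts."""
    df = reference_cohort() if cohort is None else cohort
    dose = summarize_prescriptions(df["dose_gy"].tolist())
    complete_all = df["scan_I"] & df["scan_II"] & df["scan_III"]
    return {
        "n_patients": int(df["patient"].nunique()),
        "n_metastases": int(len(df)),
        "dose_mean_gy": dose["mean_gy"],
        "dose_sd_gy": dose["sd_gy"],
        "n_completed_all_scans": int(complete_all.sum()),
        "n_progressive": int(df["progressive"].sum()),
    }
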