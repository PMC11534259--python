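"""Longitudinal ROI statistics: paired t-tests with a normality gate, and the
dose–TSC Pearson correlation over isodose-shell means.

The analysis treats lesions as the paired unit: each region's mean TSC is
compared between scan pairs (I–II, I–III, II–III) with a two-sided paired
Student t-test at α = 0.05, gated (warn, don't stop) by a Lilliefors-type
Kolmogorov–Smirnov normality check on the differences. The dose–TSC
relation is summarized per scan as the Pearson correlation between the
analysed dose levels and the across-lesion mean TSC of the corresponding
shells. No multiple-testing correction is applied by default (raw α per
comparison); a Holm adjustment is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "NormalityResult",
    "PairedComparison",
    "DoseCorrelation",
    "ks_normality",
    "paired_t_test",
    "dose_tsc_correlation",
    "percent_change",
    "holm_adjust",
]

ALPHA = 0.05


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False

    @property
    def normal_at_05(self) -> bool:
        return (not self.degenerate) and self.p_value > ALPHA


@dataclass
class PairedComparison:
    region: str
    scan_pair: tuple[str, str]
    n_pairs: int
    mean_difference: float  # mean(y − x), mM
    direction: str  # "↑", "↓" or "="
    t_statistic: float
    p_value: float
    tied: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def as_dict(self) -> dict:
        return {
            "region": self.region,
            "pair": "-".join(self.scan_pair),
            "n": self.n_pairs,
            "mean_diff": self.mean_difference,
            "direction": self.direction,
            "t": self.t_statistic,
            "p": self.p_value,
            "significant": self.significant,
        }


@dataclass
class DoseCorrelation:
    scan: str
    levels: tuple[float, ...]
    shell_means: tuple[float, ...]
    pearson_r: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "scan": self.scan,
            "levels": list(self.levels),
            "shell_means": list(self.shell_means),
            "r": self.pearson_r,
            "p": self.p_value,
        }


def ks_normality(values) -> NormalityResult:
    """Kolmogorov–Smirnov normality check with estimated parameters.

    Uses the Lilliefors correction (mean and SD estimated from the sample),
    the appropriate form when no reference normal is pre-specified. Constant
    samples are degenerate and flagged rather than tested.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"normality check needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        return NormalityResult(float("nan"), float("nan"), int(x.size), degenerate=True)
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(float(stat), float(p), int(x.size))


def paired_t_test(
    x, y, region: str = "", scan_pair: tuple[str, str] = ("a", "b")
) -> PairedComparison:
    """Two-sided paired Student t-test on matched measurements.

    ``x`` and ``y`` must be matched by lesion/patient in the same order.
    Direction is the sign of mean(y − x). All-zero differences are an exact
    tie: p = 1 by convention, flagged. NaN pairs are dropped
    (pairwise-available analysis for incomplete scans).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError(f"paired t-test needs >= 2 complete pairs, got {x.size}")
    d = y - x
    md = float(np.mean(d))
    direction = "↑" if md > 0 else ("↓" if md < 0 else "=")
    if np.ptp(d) == 0:
        if md == 0.0:
            return PairedComparison(
                region, scan_pair, int(x.size), 0.0, "=", 0.0, 1.0, tied=True
            )
        # constant non-zero difference: zero variance, effect is exact
        return PairedComparison(
            region, scan_pair, int(x.size), md, direction,
            float(np.inf) * np.sign(md), 0.0, tied=True,
        )
    t, p = sps.ttest_rel(y, x)
    return PairedComparison(
        region, scan_pair, int(x.size), md, direction, float(t), float(p)
    )


def dose_tsc_correlation(
    levels, shell_means, scan: str = ""
) -> DoseCorrelation:
    """Pearson correlation between dose levels and shell mean TSC.

    p-value is two-sided from the t distribution with n−2 degrees of
    freedom. Requires ≥ 3 paired values and non-constant inputs.
    """
    lv = np.asarray(levels, dtype=float)
    mm = np.asarray(shell_means, dtype=float)
    keep = ~np.isnan(mm)
    lv, mm = lv[keep], mm[keep]
    if lv.size < 3:
        raise ValueError("correlation needs >= 3 paired values")
    if np.ptp(lv) == 0 or np.ptp(mm) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(lv, mm)
    return DoseCorrelation(
        scan=scan,
        levels=tuple(float(v) for v in lv),
        shell_means=tuple(float(v) for v in mm),
        pearson_r=float(r),
        p_value=float(p),
    )


def percent_change(before: float, after: float) -> int:
    """Integer-rounded percent change from ``before`` to ``after``."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return int(round((after - before) / before * 100.0))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; raw p is the default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def run_study(*args, **kwargs):
    """Full simulated-study orchestration; see :func:`natsc.pipeline.run_study`."""
    from .pipeline import run_study as _run_study

    return _run_study(*args, **kwargs)
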