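"""Frank-Starling and tidal-volume regression statistics.

Per subject, each metric (EDVi, ESVi, SVi, EF) is regressed on the
estimated class tidal volume (TVi, ml/cm) over the four depth bands of one
respiratory phase, and stroke volume is regressed on end-diastolic volume
across the same classes — the Frank-Starling slope dSVi/dEDVi.  Changes are
summarized per typical tidal volume (TTVi) relative to the end-expiratory
reference, and groups are compared with an independent-samples t-test after
normality checks (Kolmogorov-Smirnov and Shapiro-Wilk) on regression
residuals.  P < 0.05 is called significant throughout.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, InsufficientDataError

__all__ = [
    "StarlingFit",
    "GroupComparison",
    "regress_vs_tidal_volume",
    "starling_fit",
    "relative_change_per_ttvi",
    "group_compare",
    "mean_phase_interval",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StarlingFit:
    """Per-subject least-squares slope of SVi on EDVi in one respiratory phase."""

    subject: str
    ventricle: str
    resp_phase: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_points: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    significant: bool
    ks_p: float | None = None
    shapiro_p: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _ols(x: np.ndarray, y: np.ndarray):
    if len(x) < 3:
        raise InsufficientDataError(f"regression needs >= 3 points, got {len(x)}")
    if np.var(x) <= 0:
        raise DegenerateSignalError("zero predictor variance")
    return stats.linregress(x, y)


def regress_vs_tidal_volume(
    values: np.ndarray, class_tvi: np.ndarray
) -> dict:
    """OLS of a volumetric metric on the estimated class tidal volume."""
    x = np.asarray(class_tvi, dtype=float)
    y = np.asarray(values, dtype=float)
    fit = _ols(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue) ** 2,
        "p_value": float(fit.pvalue),
        "n_points": int(len(x)),
        "residuals": (y - (fit.intercept + fit.slope * x)).tolist(),
    }


def starling_fit(
    edvi: np.ndarray,
    svi: np.ndarray,
    subject: str = "",
    ventricle: str = "RV",
    resp_phase: str = "inspiration",
) -> StarlingFit:
    """Frank-Starling slope: least squares of SVi on EDVi across classes."""
    x = np.asarray(edvi, dtype=float)
    y = np.asarray(svi, dtype=float)
    fit = _ols(x, y)
    return StarlingFit(
        subject=subject,
        ventricle=ventricle,
        resp_phase=resp_phase,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n_points=int(len(x)),
    )


def relative_change_per_ttvi(
    slope: float, ttvi: float, reference: float | None = None
) -> tuple[float, float | None]:
    """(absolute change per TTVi, percent of the end-expiratory reference).

    The absolute change of a metric over one typical tidal volume is
    slope * TTVi; the percentage references the metric's value in the
    shallowest expiration class ("end-expiratory" value).  With a zero or
    missing reference only the absolute change is returned.
    """
    absolute = slope * ttvi
    if reference is None:
        return absolute, None
    if reference == 0:
        raise ZeroDivisionError("zero end-expiratory reference for percent change")
    return absolute, 100.0 * absolute / reference


def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    residuals: np.ndarray | None = None,
    equal_var: bool = True,
) -> GroupComparison:
    """Independent-samples t-test between two groups of subject-level values.

    ``residuals`` (pooled regression residuals) feed the Kolmogorov-Smirnov
    and Shapiro-Wilk normality diagnostics.  The equal-variance test is the
    default; Welch's variant is available via ``equal_var=False``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    ks_p = shapiro_p = None
    if residuals is not None and len(residuals) >= 3:
        r = np.asarray(residuals, dtype=float)
        sd = np.std(r, ddof=1)
        if sd > 0:
            ks_p = float(stats.kstest((r - r.mean()) / sd, "norm").pvalue)
            shapiro_p = float(stats.shapiro(r).pvalue)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < ALPHA),
        ks_p=ks_p,
        shapiro_p=shapiro_p,
    )


def mean_phase_interval(heart_rates_bpm: list[float], n_phases: int = 25) -> float:
    """Mean per-subject cardiac-phase duration (ms) at a given binning depth."""
    rates = np.asarray(heart_rates_bpm, dtype=float)
    if rates.size == 0:
        raise InsufficientDataError("empty heart-rate list")
    if np.any(rates <= 0):
        raise ValueError("heart rates must be positive")
    return float(np.mean(60000.0 / rates / n_phases))


def summarize_fits(fits: list[StarlingFit]) -> pd.DataFrame:
    return pd.DataFrame([f.to_dict() for f in fits])
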