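"""Calibration and Bland-Altman agreement between EM and ZS velocities.

EM velocity is in g/kg/d while ZS velocity is a dimensionless z-score
change, so the two are first put on a common scale: ordinary least
squares predicts the EM velocity from the ZS velocity, and the per-infant
difference

    d_i = em_i - (intercept + slope * zs_i)

is the disagreement in g/kg/d.  Agreement is then summarised by the
Bland-Altman 95% limits of agreement (mean +/- 1.96 * sample sd of d) and
a three-tier classification of |d|: fair below 2 g/kg/d, poor in [2, 4),
disagreement at or above 4 g/kg/d (thresholds configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationFit",
    "LimitsOfAgreement",
    "AgreementReport",
    "CLASS_LABELS",
    "DEFAULT_THRESHOLDS",
    "calibrate",
    "differences",
    "limits_of_agreement",
    "classify",
    "agreement_report",
    "subgroup_differences",
    "scatter_export",
]

CLASS_LABELS = ("fair", "poor", "disagreement")
DEFAULT_THRESHOLDS = (2.0, 4.0)

#: Max sample size passed to the Shapiro-Wilk normality check.
_SHAPIRO_MAX_N = 4999


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line mapping ZS velocity (z-units) to EM velocity (g/kg/d)."""

    slope: float
    intercept: float
    n: int
    r_squared: float

    def predict(self, zs) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(zs, dtype=float)


@dataclass(frozen=True)
class LimitsOfAgreement:
    mean: float
    sd: float
    low: float
    high: float


@dataclass
class AgreementReport:
    """Full agreement summary between the two velocity metrics."""

    fit: CalibrationFit
    differences: np.ndarray
    loa: LimitsOfAgreement
    skewness: float
    excess_kurtosis: float
    shapiro_p: float | None
    thresholds: tuple[float, float]
    counts: dict = field(default_factory=dict)
    proportions: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.differences)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "calibration": {
                "slope": self.fit.slope,
                "intercept": self.fit.intercept,
                "r_squared": self.fit.r_squared,
                "n": self.fit.n,
            },
            "limits_of_agreement": {
                "mean": self.loa.mean,
                "sd": self.loa.sd,
                "low": self.loa.low,
                "high": self.loa.high,
            },
            "normality": {
                "skewness": self.skewness,
                "excess_kurtosis": self.excess_kurtosis,
                "shapiro_p": self.shapiro_p,
            },
            "thresholds": list(self.thresholds),
            "classes": {
                label: {
                    "n": self.counts[label],
                    "pct": self.proportions[label] * 100.0,
                }
                for label in CLASS_LABELS
            },
        }


def calibrate(em, zs) -> CalibrationFit:
    """OLS regression of EM velocity on ZS velocity (with intercept).

    Raises on fewer than 3 pairs or a constant predictor (the fit would
    be degenerate).
    """
    em = np.asarray(em, dtype=float)
    zs = np.asarray(zs, dtype=float)
    if em.shape != zs.shape:
        raise ValueError("em and zs must have equal length")
    if em.size < 3:
        raise ValueError("calibration needs at least 3 pairs")
    if np.var(zs) == 0:
        raise ValueError("degenerate fit: ZS velocity has zero variance")
    res = stats.linregress(zs, em)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(em.size),
        r_squared=float(res.rvalue**2),
    )


def differences(em, fit: CalibrationFit, zs) -> np.ndarray:
    """Per-infant differences em - (intercept + slope * zs), in g/kg/d."""
    em = np.asarray(em, dtype=float)
    zs = np.asarray(zs, dtype=float)
    if em.shape != zs.shape:
        raise ValueError("em and zs must have equal length")
    return em - fit.predict(zs)


def limits_of_agreement(d) -> LimitsOfAgreement:
    """Bland-Altman 95% limits: mean +/- 1.96 * sample sd (n-1 denominator)."""
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise ValueError("limits of agreement need at least 2 differences")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return LimitsOfAgreement(mean=mean, sd=sd, low=mean - 1.96 * sd, high=mean + 1.96 * sd)


def classify(d, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS):
    """Tiered agreement class of each difference.

    fair if |d| < t1, poor if t1 <= |d| < t2, disagreement if |d| >= t2,
    with (t1, t2) = (2, 4) g/kg/d by default.
    """
    t1, t2 = thresholds
    if not 0 < t1 < t2:
        raise ValueError("thresholds must satisfy 0 < t1 < t2")
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    a = np.abs(d)
    labels = np.select([a < t1, a < t2], CLASS_LABELS[:2], default=CLASS_LABELS[2])
    if d.ndim == 0:
        return str(labels)
    return labels.astype(object)


def agreement_report(
    results: pd.DataFrame,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> AgreementReport:
    """Compose calibrate -> differences -> limits -> classify on a cohort.

    ``results`` must carry ``em_velocity`` and ``zs_change`` columns (one
    row per infant).  The normality of the differences is summarised by
    skewness, excess kurtosis and (for n below 5000) a Shapiro-Wilk
    p-value.
    """
    em = results["em_velocity"].to_numpy(dtype=float)
    zs = results["zs_change"].to_numpy(dtype=float)
    fit = calibrate(em, zs)
    d = differences(em, fit, zs)
    loa = limits_of_agreement(d)
    labels = classify(d, thresholds)
    counts = {lab: int(np.sum(labels == lab)) for lab in CLASS_LABELS}
    n = len(d)
    shapiro_p = None
    if n <= _SHAPIRO_MAX_N and np.ptp(d) > 0:
        shapiro_p = float(stats.shapiro(d).pvalue)
    return AgreementReport(
        fit=fit,
        differences=d,
        loa=loa,
        skewness=float(stats.skew(d)),
        excess_kurtosis=float(stats.kurtosis(d)),
        shapiro_p=shapiro_p,
        thresholds=tuple(thresholds),
        counts=counts,
        proportions={lab: counts[lab] / n for lab in CLASS_LABELS},
    )


def subgroup_differences(d, groups) -> pd.DataFrame:
    """Per-group summary of the differences (n, mean, sd, quartiles).

    ``groups`` is a per-infant label vector (e.g. sex, GA stratum or
    birth-weight-z stratum); group sizes partition the total n.
    """
    d = np.asarray(d, dtype=float)
    groups = pd.Series(groups, name="group")
    if len(groups) != len(d):
        raise ValueError("groups must align with differences")
    if groups.isna().any():
        raise ValueError("every record must carry a grouping value")
    frame = pd.DataFrame({"d": d, "group": groups.to_numpy()})
    out = (
        frame.groupby("group", observed=True)["d"]
        .agg(
            n="size",
            mean="mean",
            sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
            q25=lambda x: float(np.percentile(x, 25)),
            median="median",
            q75=lambda x: float(np.percentile(x, 75)),
        )
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def scatter_export(
    results: pd.DataFrame,
    fit: CalibrationFit,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Row-per-infant table for scatter plotting downstream.

    Columns ``id, em, predicted_em, diff, class``; the class label drives
    the usual green/yellow/red rendering.
    """
    em = results["em_velocity"].to_numpy(dtype=float)
    zs = results["zs_change"].to_numpy(dtype=float)
    pred = fit.predict(zs)
    d = em - pred
    return pd.DataFrame(
        {
            "id": results["id"].to_numpy(),
            "em": em,
            "predicted_em": pred,
            "diff": d,
            "class": classify(d, thresholds),
        }
    )
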