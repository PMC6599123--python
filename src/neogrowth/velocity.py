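"""Per-infant growth velocity by exponential model (EM) and z-score change (ZS).

Two standard ways to quantify weight gain between birth and discharge in
preterm infants:

* **EM velocity** (g/kg/d), from the exponential weight-gain model in
  which weight grows at a constant fraction of itself:
  ``1000 * ln(Wn / W1) / D`` with birth weight ``W1`` (g), discharge
  weight ``Wn`` (g) and length of stay ``D`` (days).
* **ZS velocity** (dimensionless), the change in weight z-score against a
  sex-specific reference chart: z at discharge minus z at birth, with the
  postmenstrual age at birth equal to gestational age and at discharge
  equal to gestational age plus the stay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charts import ChartRangeError, GrowthChart

__all__ = [
    "InfantRecord",
    "COHORT_CORE_COLUMNS",
    "GA_STRATUM_LABELS",
    "BW_STRATUM_LABELS",
    "BWZ_STRATUM_LABELS",
    "em_velocity",
    "cohort_velocities",
    "cohort_summary",
    "ga_stratum",
    "bw_stratum",
    "bwz_stratum",
]

logger = logging.getLogger(__name__)

COHORT_CORE_COLUMNS = (
    "id",
    "sex",
    "ga_days",
    "birth_weight",
    "discharge_weight",
    "stay_days",
)

# Completed-week strata: "23-26 wk" means 23*7 <= ga_days < 27*7.
GA_STRATUM_EDGES_DAYS = (22 * 7, 27 * 7, 29 * 7, 31 * 7, 33 * 7)
GA_STRATUM_LABELS = ("23-26 wk", "27-28 wk", "29-30 wk", "31-32 wk")

BW_STRATUM_LABELS = ("< 1000 g", "1000-1500 g", "> 1500 g")
BWZ_STRATUM_LABELS = ("< -2", "[-2,-1)", "[-1,0)", ">= 0")


@dataclass(frozen=True)
class InfantRecord:
    """One infant's two-point weight record plus optional covariates."""

    id: str
    sex: str
    ga_days: int
    birth_weight: float
    discharge_weight: float
    stay_days: int
    covariates: dict | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if not self.birth_weight > 0 or not self.discharge_weight > 0:
            raise ValueError("weights must be positive")
        if self.stay_days < 1:
            raise ValueError("stay_days must be >= 1")
        if not (22 * 7 <= self.ga_days < 33 * 7):
            raise ValueError(
                f"ga_days must lie in [154, 231) (22-32 completed weeks), "
                f"got {self.ga_days}"
            )


def em_velocity(w1, wn, days):
    """Exponential-model growth velocity, 1000*ln(wn/w1)/days, in g/kg/d.

    Accepts scalars or aligned arrays.  Zero iff ``wn == w1`` and
    antisymmetric under swapping the two weights.
    """
    w1 = np.asarray(w1, dtype=float)
    wn = np.asarray(wn, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(w1 <= 0) or np.any(wn <= 0):
        raise ValueError("weights must be positive")
    if np.any(days < 1):
        raise ValueError("length of stay must be >= 1 day")
    out = 1000.0 * np.log(wn / w1) / days
    return float(out) if out.ndim == 0 else out


def ga_stratum(ga_days) -> pd.Categorical:
    """Gestational-age stratum labels on completed weeks (23-26 ... 31-32)."""
    return pd.cut(
        np.asarray(ga_days, dtype=float),
        bins=GA_STRATUM_EDGES_DAYS,
        labels=GA_STRATUM_LABELS,
        right=False,
    )

def bw_stratum(birth_weight) -> pd.Categorical:
    """Birth-weight strata <1000 / 1000-1500 (closed) / >1500 g."""
    w = np.asarray(birth_weight, dtype=float)
    labels = np.where(
        w < 1000, BW_STRATUM_LABELS[0],
        np.where(w <= 1500, BW_STRATUM_LABELS[1], BW_STRATUM_LABELS[2]),
    )
    return pd.Categorical(labels, categories=list(BW_STRATUM_LABELS), ordered=True)


def bwz_stratum(z_birth) -> pd.Categorical:
    """Birth-weight z-score strata < -2 / [-2,-1) / [-1,0) / >= 0."""
    z = np.asarray(z_birth, dtype=float)
    labels = np.select(
        [z < -2, z < -1, z < 0],
        list(BWZ_STRATUM_LABELS[:3]),
        default=BWZ_STRATUM_LABELS[3],
    )
    return pd.Categorical(labels, categories=list(BWZ_STRATUM_LABELS), ordered=True)


def cohort_velocities(
    cohort: pd.DataFrame,
    chart: GrowthChart,
    on_chart_error: str = "raise",
) -> pd.DataFrame:
    """EM and ZS velocities for every infant of a cohort table.

    Parameters
    ----------
    cohort:
        Table with columns ``id, sex, ga_days, birth_weight,
        discharge_weight, stay_days``.
    chart:
        Reference used for z-scoring; birth is scored at PMA = gestational
        age, discharge at PMA = gestational age + stay.
    on_chart_error:
        ``"raise"`` (default) aborts listing the offending infant ids;
        ``"skip"`` drops and logs them.

    Returns
    -------
    DataFrame with columns ``id, em_velocity, z_birth, z_discharge,
    zs_change`` (``zs_change = z_discharge - z_birth`` exactly).
    """
    if on_chart_error not in ("raise", "skip"):
        raise ValueError("on_chart_error must be 'raise' or 'skip'")
    missing = set(COHORT_CORE_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if cohort.empty:
        return pd.DataFrame(
            columns=["id", "em_velocity", "z_birth", "z_discharge", "zs_change"]
        )

    ga = cohort["ga_days"].to_numpy(dtype=float)
    stay = cohort["stay_days"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=object)

    # Range-check per infant so failures can be reported by id.
    bad: list[str] = []
    ok = np.ones(len(cohort), dtype=bool)
    for i, (s, a, d) in enumerate(zip(sex, ga, stay)):
        lo, hi = chart.age_range(s)
        if not (lo <= a <= hi and lo <= a + d <= hi):
            ok[i] = False
            bad.append(str(cohort["id"].iloc[i]))
    if bad:
        if on_chart_error == "raise":
            raise ChartRangeError(
                f"{len(bad)} infant(s) outside chart {chart.name!r} range: "
                + ", ".join(bad[:10])
                + ("..." if len(bad) > 10 else "")
            )
        logger.warning(
            "skipping %d infant(s) outside chart range: %s",
            len(bad), ", ".join(bad[:10]),
        )

    sub = cohort.loc[ok]
    ga, stay, sex = ga[ok], stay[ok], sex[ok]
    z_birth = chart.zscore(sub["birth_weight"].to_numpy(dtype=float), sex, ga)
    z_discharge = chart.zscore(
        sub["discharge_weight"].to_numpy(dtype=float), sex, ga + stay
    )
    em = em_velocity(
        sub["birth_weight"].to_numpy(dtype=float),
        sub["discharge_weight"].to_numpy(dtype=float),
        stay,
    )
    return pd.DataFrame(
        {
            "id": sub["id"].to_numpy(),
            "em_velocity": np.atleast_1d(em),
            "z_birth": z_birth,
            "z_discharge": z_discharge,
            "zs_change": z_discharge - z_birth,
        }
    ).reset_index(drop=True)


def _median_iqr(x) -> dict:
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def _counts(labels) -> dict:
    s = pd.Series(labels)
    counts = s.value_counts(sort=False)
    total = int(counts.sum())
    return {
        str(level): {"n": int(n), "pct": 100.0 * float(n) / total}
        for level, n in counts.items()
    }


def cohort_summary(cohort: pd.DataFrame, results: pd.DataFrame) -> dict:
    """Population description: medians/IQR and category counts.

    Mirrors the usual baseline table of a neonatal cohort: medians with
    25th/75th percentiles for weights, z-scores and velocities, counts
    and proportions for sex, gestational-age strata and birth-weight
    strata.
    """
    if cohort.empty:
        raise ValueError("cannot summarise an empty cohort")
    merged = cohort.merge(results, on="id", validate="one_to_one")
    continuous = {
        "birth_weight": _median_iqr(merged["birth_weight"]),
        "discharge_weight": _median_iqr(merged["discharge_weight"]),
        "z_birth": _median_iqr(merged["z_birth"]),
        "z_discharge": _median_iqr(merged["z_discharge"]),
        "em_velocity": _median_iqr(merged["em_velocity"]),
        "zs_change": _median_iqr(merged["zs_change"]),
        "stay_days": _median_iqr(merged["stay_days"]),
    }
    categorical = {
        "sex": _counts(merged["sex"]),
        "ga_stratum": _counts(ga_stratum(merged["ga_days"])),
        "bw_stratum": _counts(bw_stratum(merged["birth_weight"])),
    }
    return {"n": int(len(merged)), "continuous": continuous, "categorical": categorical}
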