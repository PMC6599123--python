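"""Synthetic LMS chart and preterm cohort generation.

Every pipeline stage is testable without fetching any published chart or
study data: the generator builds a smooth sex-specific LMS reference and
then draws a cohort whose weights are obtained by *inverting* that chart
at sampled z-scores.  That construction guarantees exact consistency
between cohort and reference — z-scoring a generated weight against the
generating chart recovers the sampled z — which is precisely the property
real chart data cannot give a test suite.

The cohort emulates the structure of a large French very-preterm
follow-up population: four gestational-age strata below 33 weeks with a
heavily right-weighted mix, a slight male excess, birth z-scores centred
below zero, a postnatal z-score decline during the stay, and discharge
around 38 weeks postmenstrual age.

The chart's weekly fractional growth declines linearly with
postmenstrual age (fetal-growth velocity falls from roughly 17 to 10
g/kg/d between 23 and 40 weeks).  That decline is what makes the
exponential-model velocity depend on gestational age while the z-score
change does not, i.e. it is the structural source of disagreement
between the two metrics.  Setting the decline to zero yields the simple
constant-fraction chart M(pma) = M23 * (1+g)^(weeks-23).

Measurement noise (``em_zs_noise_sd``) is applied multiplicatively to the
recorded discharge weight, scaled so that it perturbs the EM velocity by
roughly that many g/kg/d; it deliberately breaks the exact chart
round-trip at discharge, as scale error does in real data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .charts import GrowthChart, SEXES

__all__ = [
    "ChartParams",
    "SyntheticConfig",
    "generate_chart",
    "generate_cohort",
    "simulate_velocity_pairs",
    "expected_stratum_em_offsets",
]

#: (low, high) completed-week bounds of the four GA strata; an infant with
#: ga_days in [low*7, high*7) belongs to the stratum.
GA_STRATA_WEEKS = ((23, 27), (27, 29), (29, 31), (31, 33))

_RESAMPLE_CAP = 100


@dataclass(frozen=True)
class ChartParams:
    """Shape of the synthetic LMS reference.

    ``weekly_growth`` is the fractional weight gain per week at 23 weeks
    PMA; it declines linearly by ``weekly_growth_decline`` per week
    (zero decline gives a constant-fraction geometric median curve).
    ``sex_offset`` is the symmetric male/female multiplier on the median
    (males ``1 + offset``, females ``1 - offset``).
    """

    m23: float = 660.0          # median weight at 23 wk PMA, grams
    weekly_growth: float = 0.13
    weekly_growth_decline: float = 0.003  # per week of PMA
    S: float = 0.13
    L: float = 1.0
    sex_offset: float = 0.02
    min_weeks: int = 22
    max_weeks: int = 44

    def growth_at(self, weeks: float) -> float:
        return self.weekly_growth - self.weekly_growth_decline * (weeks - 23.0)

    def validate(self) -> None:
        if self.m23 <= 0 or self.S <= 0:
            raise ValueError("m23 and S must be positive")
        if self.weekly_growth < 0:
            raise ValueError("weekly_growth must be non-negative")
        if self.growth_at(self.max_weeks) < 0:
            raise ValueError(
                "weekly growth becomes negative inside the chart span; "
                "reduce weekly_growth_decline"
            )
        if not 0 <= self.sex_offset < 1:
            raise ValueError("sex_offset must lie in [0, 1)")
        if not 22 <= self.min_weeks < self.max_weeks:
            raise ValueError("need 22 <= min_weeks < max_weeks")


@dataclass(frozen=True)
class SyntheticConfig:
    """All distributional knobs plus the seed for chart and cohort."""

    seed: int = 0
    n: int = 3954
    ga_strata_probs: tuple[float, ...] = (0.071, 0.173, 0.263, 0.493)
    p_male: float = 0.531
    birth_z_mean: float = -0.45
    birth_z_sd: float = 0.9
    z_drop_mean: float = 0.7
    z_drop_sd: float = 0.4
    truncate_z_drop: bool = True
    discharge_pma_weeks_mean: float = 38.0
    discharge_pma_weeks_sd: float = 1.5
    em_zs_noise_sd: float = 1.5  # g/kg/d-scale measurement noise on discharge weight
    chart: ChartParams = field(default_factory=ChartParams)

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        probs = np.asarray(self.ga_strata_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("ga_strata_probs must be 4 non-negative values summing to 1")
        if not 0 <= self.p_male <= 1:
            raise ValueError("p_male must lie in [0, 1]")
        for name in ("birth_z_sd", "z_drop_sd", "discharge_pma_weeks_sd", "em_zs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.chart.validate()

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["ga_strata_probs"] = list(self.ga_strata_probs)
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def generate_chart(config: SyntheticConfig) -> GrowthChart:
    """Deterministic weekly-grid LMS chart from the config's chart params."""
    p = config.chart
    p.validate()
    weeks = np.arange(p.min_weeks, p.max_weeks + 1)
    # Median anchored at m23; integrate weekly fractional growth outward.
    log_m = np.empty(len(weeks), dtype=float)
    anchor = int(np.searchsorted(weeks, 23))
    log_m[anchor] = np.log(p.m23)
    for i in range(anchor + 1, len(weeks)):
        log_m[i] = log_m[i - 1] + np.log1p(p.growth_at(float(weeks[i - 1])))
    for i in range(anchor - 1, -1, -1):
        log_m[i] = log_m[i + 1] - np.log1p(p.growth_at(float(weeks[i])))
    rows = []
    for sex, mult in (("male", 1.0 + p.sex_offset), ("female", 1.0 - p.sex_offset)):
        for wk, lm in zip(weeks, log_m):
            rows.append(
                {
                    "sex": sex,
                    "pma_days": int(wk) * 7,
                    "L": p.L,
                    "M": float(np.exp(lm)) * mult,
                    "S": p.S,
                }
            )
    return GrowthChart("synthetic", pd.DataFrame(rows))


def _draw_one(rng: np.random.Generator, config: SyntheticConfig, chart: GrowthChart) -> dict:
    probs = np.asarray(config.ga_strata_probs, dtype=float)
    stratum = int(rng.choice(4, p=probs))
    lo_wk, hi_wk = GA_STRATA_WEEKS[stratum]
    ga_days = int(rng.integers(lo_wk * 7, hi_wk * 7))
    sex = "male" if rng.random() < config.p_male else "female"

    z_birth = rng.normal(config.birth_z_mean, config.birth_z_sd)
    drop = rng.normal(config.z_drop_mean, config.z_drop_sd)
    if config.truncate_z_drop:
        drop = max(0.0, drop)
    z_discharge = z_birth - drop

    lo_pma, hi_pma = chart.age_range(sex)
    for attempt in range(_RESAMPLE_CAP):
        pma_discharge = rng.normal(
            config.discharge_pma_weeks_mean * 7.0,
            config.discharge_pma_weeks_sd * 7.0,
        )
        pma_discharge = float(round(pma_discharge))
        if ga_days + 7 <= pma_discharge <= hi_pma:
            break
    else:
        raise RuntimeError(
            f"could not draw a discharge PMA above GA+7d for ga_days={ga_days} "
            f"after {_RESAMPLE_CAP} attempts"
        )
    stay_days = int(pma_discharge) - ga_days

    birth_weight = float(chart.weight_for_z(z_birth, sex, ga_days)[0])
    discharge_weight = float(chart.weight_for_z(z_discharge, sex, ga_days + stay_days)[0])
    if config.em_zs_noise_sd > 0:
        # Scale error on the discharge weighing: exp(eps * D / 1000) shifts
        # the EM velocity by eps g/kg/d for that infant.
        eps = rng.normal(0.0, config.em_zs_noise_sd)
        discharge_weight *= float(np.exp(eps * stay_days / 1000.0))

    return {
        "sex": sex,
        "ga_days": ga_days,
        "birth_weight": birth_weight,
        "discharge_weight": discharge_weight,
        "stay_days": stay_days,
        "z_birth_true": z_birth,
        "z_discharge_true": z_discharge,
        "birth_order": int(1 + rng.poisson(0.3)),
        "apgar5": int(np.clip(round(rng.normal(8.5, 1.5)), 0, 10)),
        "antenatal_steroids": int(rng.random() < 0.80),
        "bpd": int(rng.random() < 0.15),
        "late_onset_infection": int(rng.random() < 0.20),
        "breastfeeding_discharge": int(rng.random() < 0.45),
        "socioeconomic_level": str(rng.choice(["low", "middle", "high"], p=[0.3, 0.5, 0.2])),
        "multiple_pregnancy": int(rng.random() < 0.30),
        "maternal_hypertension": int(rng.random() < 0.18),
    }


def generate_cohort(config: SyntheticConfig, chart: GrowthChart | None = None) -> pd.DataFrame:
    """Draw a cohort table reproducibly under ``config.seed``.

    Each infant uses an independent counter-derived stream
    (``default_rng([seed, i])``) so row order does not couple the draws.
    The returned frame carries the core record columns, the sampled
    "true" z-scores (``z_birth_true``/``z_discharge_true``, pre
    measurement noise) and a set of plausible covariates.
    """
    config.validate()
    if chart is None:
        chart = generate_chart(config)
    rows = []
    for i in range(config.n):
        rng = np.random.default_rng([config.seed, i])
        row = _draw_one(rng, config, chart)
        row["id"] = f"sim{i:05d}"
        rows.append(row)
    cols = [
        "id", "sex", "ga_days", "birth_weight", "discharge_weight", "stay_days",
        "z_birth_true", "z_discharge_true",
        "birth_order", "apgar5", "antenatal_steroids", "bpd",
        "late_onset_infection", "breastfeeding_discharge",
        "socioeconomic_level", "multiple_pregnancy", "maternal_hypertension",
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_velocity_pairs(
    n: int,
    seed: int,
    slope: float = 2.2,
    intercept: float = 12.5,
    zs_mean: float = -0.7,
    zs_sd: float = 0.4,
    residual_sd: float = 1.0,
) -> pd.DataFrame:
    """Velocity-space simulation: EM linear in ZS plus Gaussian residuals.

    Draws ``zs ~ N(zs_mean, zs_sd)`` and
    ``em = intercept + slope * zs + N(0, residual_sd)``, bypassing the
    chart entirely.  Used to validate the agreement estimators: the
    calibration residual sd (``sd_diff``) must recover ``residual_sd``.
    Returns a frame with columns ``id, em_velocity, zs_change``.
    """
    rng = np.random.default_rng(seed)
    zs = rng.normal(zs_mean, zs_sd, size=n)
    em = intercept + slope * zs + rng.normal(0.0, residual_sd, size=n)
    return pd.DataFrame(
        {"id": [f"v{i:05d}" for i in range(n)], "em_velocity": em, "zs_change": zs}
    )


def expected_stratum_em_offsets(config: SyntheticConfig) -> dict[str, float]:
    """Chart-velocity component of the GA gradient in the difference ``d``.

    For each GA stratum, the median-curve EM velocity over a stay from
    the stratum's midpoint GA to the mean discharge PMA, expressed as an
    offset (g/kg/d) against the oldest stratum.  This is the structural
    gradient the chart's declining fractional growth builds into the
    cohort; subgroup summaries of ``d`` should recover it (the z-score
    term adds a same-signed contribution on top).
    """
    chart = generate_chart(config)
    pma2 = config.discharge_pma_weeks_mean * 7.0
    from .velocity import GA_STRATUM_LABELS

    gammas = {}
    for (lo_wk, hi_wk), label in zip(GA_STRATA_WEEKS, GA_STRATUM_LABELS):
        ga_mid = 7.0 * (lo_wk + hi_wk) / 2.0
        stay = pma2 - ga_mid
        _, m1, _ = chart.params("male", ga_mid)
        _, m2, _ = chart.params("male", pma2)
        gammas[label] = 1000.0 * float(np.log(m2 / m1)) / stay
    ref = gammas[GA_STRATUM_LABELS[-1]]
    return {label: g - ref for label, g in gammas.items()}
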