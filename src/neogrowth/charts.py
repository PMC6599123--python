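"""Sex-specific LMS growth-reference charts and z-score transforms.

The LMS (lambda-mu-sigma) method summarises a reference distribution at
each age by a Box-Cox power ``L``, a median ``M`` and a coefficient of
variation ``S``.  The z-score of a measurement ``x`` is

    z = ((x / M)**L - 1) / (L * S)    if L != 0
    z = ln(x / M) / S                 if L == 0

Preterm growth references (Fenton, Olsen, or the synthetic chart shipped
with this package) tabulate ``(L, M, S)`` per sex on a postmenstrual-age
(PMA) grid, typically weekly.  Infant ages are daily, so lookups linearly
interpolate each of ``L``, ``M`` and ``S`` between adjacent grid rows.
Ages outside the grid are a hard error: extrapolated reference values are
clinically meaningless.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "LMSEntry",
    "GrowthChart",
    "ChartRangeError",
    "lms_zscore",
    "lms_inverse",
    "lookup_lms",
    "read_chart_csv",
    "write_chart_csv",
    "validate_chart_csv",
]

SEXES = ("male", "female")

#: |L| below this is treated as the logarithmic (Box-Cox) limit.
_L_EPS = 1e-12

#: Minimum plausible postmenstrual age for a preterm reference (22 weeks).
MIN_PMA_DAYS = 22 * 7

CHART_CSV_COLUMNS = ("sex", "pma_weeks", "L", "M", "S")


class ChartRangeError(ValueError):
    """Requested age lies outside the chart's tabulated span."""


@dataclass(frozen=True)
class LMSEntry:
    """One row of an LMS reference: the distribution at a single sex/age."""

    sex: str
    pma_days: int
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.pma_days < MIN_PMA_DAYS:
            raise ValueError(
                f"pma_days must be >= {MIN_PMA_DAYS}, got {self.pma_days}"
            )
        if not self.M > 0:
            raise ValueError(f"M must be positive, got {self.M}")
        if not self.S > 0:
            raise ValueError(f"S must be positive, got {self.S}")


def _zscore_arrays(x, L, M, S):
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0):
        raise ValueError("weight must be positive")
    ratio = x / M
    log_branch = np.log(ratio) / S
    with np.errstate(divide="ignore", invalid="ignore"):
        power_branch = (np.power(ratio, L) - 1.0) / (L * S)
    return np.where(np.abs(L) < _L_EPS, log_branch, power_branch)


def _inverse_arrays(z, L, M, S):
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    t = 1.0 + L * S * z
    log_limit = np.abs(L) < _L_EPS
    if np.any(~log_limit & (t <= 0)):
        raise ValueError(
            "z outside invertible range: 1 + L*S*z must be positive when L != 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        power_branch = M * np.power(np.where(log_limit, 1.0, t), 1.0 / np.where(log_limit, 1.0, L))
    return np.where(log_limit, M * np.exp(S * z), power_branch)


def lms_zscore(weight: float, entry: LMSEntry) -> float:
    """Z-score of ``weight`` (grams) against one LMS reference entry.

    Strictly increasing in ``weight``; the logarithmic limit is used when
    ``|L| < 1e-12``.
    """
    return float(_zscore_arrays(weight, entry.L, entry.M, entry.S))


def lms_inverse(z: float, entry: LMSEntry) -> float:
    """Weight (grams) whose z-score against ``entry`` equals ``z``.

    Inverse of :func:`lms_zscore`; for ``L != 0`` requires
    ``1 + L*S*z > 0``, otherwise a :class:`ValueError` is raised.
    """
    return float(_inverse_arrays(z, entry.L, entry.M, entry.S))


class GrowthChart:
    """A sex-specific LMS reference on an increasing PMA grid.

    Parameters
    ----------
    name:
        Identifier such as ``"fenton2013"`` or ``"synthetic"``.
    frame:
        DataFrame with columns ``sex, pma_days, L, M, S``; both sexes must
        be present and ages strictly increasing within each sex.
    """

    def __init__(self, name: str, frame: pd.DataFrame):
        required = {"sex", "pma_days", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"chart frame missing columns: {sorted(missing)}")
        self.name = str(name)
        self._grids: dict[str, dict[str, np.ndarray]] = {}
        for sex in SEXES:
            block = frame[frame["sex"] == sex].sort_index()
            if block.empty:
                raise ValueError(f"chart {name!r} has no entries for sex {sex!r}")
            ages = block["pma_days"].to_numpy(dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(
                    f"chart {name!r}: pma_days not strictly increasing for {sex}"
                )
            M = block["M"].to_numpy(dtype=float)
            S = block["S"].to_numpy(dtype=float)
            if np.any(M <= 0) or np.any(S <= 0):
                raise ValueError(f"chart {name!r}: M and S must be positive")
            if np.any(np.diff(M) < 0):
                warnings.warn(
                    f"chart {name!r}: median weight decreases with age for {sex}",
                    stacklevel=2,
                )
            self._grids[sex] = {
                "pma_days": ages,
                "L": block["L"].to_numpy(dtype=float),
                "M": M,
                "S": S,
            }
        unknown = set(frame["sex"]) - set(SEXES)
        if unknown:
            raise ValueError(f"unknown sex values in chart: {sorted(unknown)}")

    @classmethod
    def from_entries(cls, name: str, entries: Iterable[LMSEntry]) -> "GrowthChart":
        rows = [
            {"sex": e.sex, "pma_days": e.pma_days, "L": e.L, "M": e.M, "S": e.S}
            for e in entries
        ]
        frame = pd.DataFrame(rows).sort_values(["sex", "pma_days"], kind="stable")
        return cls(name, frame.reset_index(drop=True))

    def age_range(self, sex: str) -> tuple[float, float]:
        grid = self._grid(sex)
        return float(grid["pma_days"][0]), float(grid["pma_days"][-1])

    def _grid(self, sex: str) -> dict[str, np.ndarray]:
        try:
            return self._grids[sex]
        except KeyError:
            raise ValueError(f"sex must be one of {SEXES}, got {sex!r}") from None

    def _check_range(self, sex: str, pma_days) -> None:
        lo, hi = self.age_range(sex)
        pma = np.asarray(pma_days, dtype=float)
        if np.any(pma < lo) or np.any(pma > hi):
            bad = pma[(pma < lo) | (pma > hi)]
            raise ChartRangeError(
                f"postmenstrual age {np.atleast_1d(bad)[0]:g} d outside chart "
                f"{self.name!r} span [{lo:g}, {hi:g}] d for {sex}"
            )

    def params(self, sex: str, pma_days) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated ``(L, M, S)`` at day-resolution ages for one sex."""
        grid = self._grid(sex)
        self._check_range(sex, pma_days)
        pma = np.asarray(pma_days, dtype=float)
        L = np.interp(pma, grid["pma_days"], grid["L"])
        M = np.interp(pma, grid["pma_days"], grid["M"])
        S = np.interp(pma, grid["pma_days"], grid["S"])
        return L, M, S

    def lookup(self, sex: str, pma_days: float) -> LMSEntry:
        """LMS entry at ``pma_days`` (exact on grid points, interpolated between)."""
        L, M, S = self.params(sex, pma_days)
        return LMSEntry(sex=sex, pma_days=int(round(float(np.asarray(pma_days)))),
                        L=float(L), M=float(M), S=float(S))

    def zscore(self, weight, sex, pma_days) -> np.ndarray:
        """Vectorised z-scores; ``sex`` may be a scalar or a per-element array."""
        weight = np.atleast_1d(np.asarray(weight, dtype=float))
        pma = np.atleast_1d(np.asarray(pma_days, dtype=float))
        sexes = np.atleast_1d(np.asarray(sex, dtype=object))
        weight, pma, sexes = np.broadcast_arrays(weight, pma, sexes)
        out = np.empty(weight.shape, dtype=float)
        for s in SEXES:
            mask = sexes == s
            if not mask.any():
                continue
            L, M, S = self.params(s, pma[mask])
            out[mask] = _zscore_arrays(weight[mask], L, M, S)
        unknown = ~np.isin(sexes, SEXES)
        if unknown.any():
            raise ValueError(f"unknown sex value {sexes[unknown][0]!r}")
        return out

    def weight_for_z(self, z, sex, pma_days) -> np.ndarray:
        """Vectorised inverse transform: weight at a given z-score."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        pma = np.atleast_1d(np.asarray(pma_days, dtype=float))
        sexes = np.atleast_1d(np.asarray(sex, dtype=object))
        z, pma, sexes = np.broadcast_arrays(z, pma, sexes)
        out = np.empty(z.shape, dtype=float)
        for s in SEXES:
            mask = sexes == s
            if not mask.any():
                continue
            L, M, S = self.params(s, pma[mask])
            out[mask] = _inverse_arrays(z[mask], L, M, S)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Chart as a tidy frame with ``pma_weeks`` (decimal weeks)."""
        rows = []
        for sex in SEXES:
            grid = self._grids[sex]
            for i in range(len(grid["pma_days"])):
                rows.append(
                    {
                        "sex": sex,
                        "pma_weeks": grid["pma_days"][i] / 7.0,
                        "L": grid["L"][i],
                        "M": grid["M"][i],
                        "S": grid["S"][i],
                    }
                )
        return pd.DataFrame(rows, columns=list(CHART_CSV_COLUMNS))


def lookup_lms(chart: GrowthChart, sex: str, pma_days: float) -> LMSEntry:
    """Entry of ``chart`` for ``sex`` at ``pma_days`` (interpolated off-grid)."""
    return chart.lookup(sex, pma_days)


def validate_chart_csv(path) -> list[str]:
    """Validate a chart CSV; returns line-numbered problem descriptions.

    Dialect: header ``sex,pma_weeks,L,M,S``; ``sex`` in {male, female};
    ``pma_weeks`` decimal weeks; comma-separated, dot decimal.
    """
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return ["line 1: empty file"]
        if [c.strip() for c in header] != list(CHART_CSV_COLUMNS):
            errors.append(
                f"line 1: header must be {','.join(CHART_CSV_COLUMNS)}, "
                f"got {','.join(header)}"
            )
            return errors
        seen: dict[str, float] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                errors.append(f"line {lineno}: expected 5 fields, got {len(row)}")
                continue
            sex = row[0].strip()
            if sex not in SEXES:
                errors.append(f"line {lineno}: unknown sex {sex!r}")
                continue
            try:
                weeks, L, M, S = (float(v) for v in row[1:])
            except ValueError:
                errors.append(f"line {lineno}: non-numeric value in {row[1:]}")
                continue
            if weeks * 7 < MIN_PMA_DAYS:
                errors.append(f"line {lineno}: pma_weeks {weeks} below 22 weeks")
            if M <= 0:
                errors.append(f"line {lineno}: M must be positive, got {M}")
            if S <= 0:
                errors.append(f"line {lineno}: S must be positive, got {S}")
            prev = seen.get(sex)
            if prev is not None and weeks <= prev:
                errors.append(
                    f"line {lineno}: pma_weeks not strictly increasing for {sex}"
                )
            seen[sex] = weeks
        for sex in SEXES:
            if sex not in seen:
                errors.append(f"line 1: no rows for sex {sex!r}")
    return errors


def read_chart_csv(path, name: str | None = None) -> GrowthChart:
    """Load a chart CSV (``sex,pma_weeks,L,M,S``); raises on malformed files."""
    problems = validate_chart_csv(path)
    if problems:
        raise ValueError(
            f"invalid chart file {path}:\n" + "\n".join(problems)
        )
    frame = pd.read_csv(path)
    frame["pma_days"] = (frame["pma_weeks"] * 7).round().astype(int)
    chart_name = name if name is not None else str(path)
    return GrowthChart(chart_name, frame[["sex", "pma_days", "L", "M", "S"]])


def write_chart_csv(chart: GrowthChart, path) -> None:
    frame = chart.to_frame()
    frame.to_csv(path, index=False, float_format="%.10g")
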