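"""Multivariable regression of the per-infant method difference.

After calibration, the difference ``d`` between EM velocity and its
ZS-based prediction can be regressed on infant, maternal and stay
characteristics to find what drives the disagreement between the two
velocity metrics.  Categorical covariates use treatment (dummy) coding
against declared reference levels; the default specification uses sex
(reference male), gestational-age stratum (reference 31-32 wk) and
birth-weight z-score stratum (reference >= 0).

Because the way "variance explained" is attributed to a single variable
is not unique, :func:`variance_explained` reports both the univariate R^2
of the variable alone and its incremental R^2 when added last to the
remaining terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .velocity import BWZ_STRATUM_LABELS, GA_STRATUM_LABELS

__all__ = [
    "Term",
    "RegressionSpec",
    "DeterminantsResult",
    "SingularFitError",
    "default_spec",
    "design_matrix",
    "fit_ols",
    "variance_explained",
    "determinants_report",
]


class SingularFitError(ValueError):
    """Design matrix is rank deficient (collinear columns)."""


@dataclass(frozen=True)
class Term:
    """One covariate: continuous, or categorical with a reference level."""

    name: str
    kind: str = "continuous"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"kind must be continuous/categorical, got {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical term {self.name!r} needs a reference level")


@dataclass(frozen=True)
class RegressionSpec:
    outcome: str
    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(names) != len(set(names)):
            raise ValueError("duplicated terms in regression spec")


def default_spec() -> RegressionSpec:
    """Sex + GA stratum + birth-weight-z stratum on the difference ``d``."""
    return RegressionSpec(
        outcome="diff",
        terms=(
            Term("sex", "categorical", reference="male"),
            Term("ga_stratum", "categorical", reference=GA_STRATUM_LABELS[-1]),
            Term("bwz_stratum", "categorical", reference=BWZ_STRATUM_LABELS[-1]),
        ),
    )


@dataclass
class DeterminantsResult:
    """Estimates, 95% CIs and p-values, plus the fit's global numbers."""

    table: pd.DataFrame  # columns: term, estimate, ci_low, ci_high, p_value
    n: int
    r_squared: float
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_dropped": self.n_dropped,
            "r_squared": self.r_squared,
            "terms": self.table.to_dict(orient="records"),
        }


def _dummy_columns(frame: pd.DataFrame, term: Term) -> pd.DataFrame:
    col = frame[term.name]
    levels = list(pd.unique(col.dropna()))
    if isinstance(col.dtype, pd.CategoricalDtype):
        levels = [lv for lv in col.cat.categories if lv in set(levels)]
    if term.reference not in levels:
        raise ValueError(
            f"reference level {term.reference!r} absent from data for "
            f"term {term.name!r} (levels: {levels})"
        )
    out = {}
    for lv in levels:
        if lv == term.reference:
            continue
        out[f"{term.name}[{lv}]"] = (col == lv).astype(float)
    return pd.DataFrame(out, index=frame.index)


def design_matrix(
    frame: pd.DataFrame,
    spec: RegressionSpec,
    terms: tuple[Term, ...] | None = None,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Outcome vector and treatment-coded design matrix (with intercept).

    Rows with a missing outcome or covariate are dropped (complete-case
    analysis); the number dropped is returned.
    """
    use_terms = spec.terms if terms is None else terms
    needed = [spec.outcome] + [t.name for t in use_terms]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"terms absent from data: {missing}")
    complete = frame[needed].dropna()
    n_dropped = len(frame) - len(complete)
    if complete.empty:
        raise ValueError("no complete cases for the requested terms")
    X = pd.DataFrame({"const": np.ones(len(complete))}, index=complete.index)
    for term in use_terms:
        if term.kind == "continuous":
            X[term.name] = complete[term.name].astype(float)
        else:
            X = pd.concat([X, _dummy_columns(complete, term)], axis=1)
    y = complete[spec.outcome].astype(float)
    return y, X, n_dropped


def fit_ols(X: pd.DataFrame, y: pd.Series, n_dropped: int = 0) -> DeterminantsResult:
    """Least-squares fit with 95% t-based confidence intervals.

    Raises :class:`SingularFitError` naming the collinear columns when
    the design matrix is rank deficient.
    """
    Xv = np.asarray(X, dtype=float)
    if len(y) <= Xv.shape[1]:
        raise ValueError(
            f"need more observations ({len(y)}) than parameters ({Xv.shape[1]})"
        )
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # Columns loading on near-null singular directions are the culprits.
        _, s, vt = np.linalg.svd(Xv, full_matrices=False)
        null_mask = s < s[0] * 1e-10
        loads = np.abs(vt[null_mask]).max(axis=0)
        culprits = [c for c, w in zip(X.columns, loads) if w > 1e-8]
        raise SingularFitError(f"design matrix is singular; collinear columns: {culprits}")
    fit = sm.OLS(np.asarray(y, dtype=float), Xv).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": fit.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p_value": fit.pvalues,
        }
    )
    return DeterminantsResult(
        table=table.reset_index(drop=True),
        n=int(len(y)),
        r_squared=float(fit.rsquared),
        n_dropped=n_dropped,
    )


def _r_squared(frame: pd.DataFrame, spec: RegressionSpec, terms: tuple[Term, ...]) -> float:
    y, X, _ = design_matrix(frame, spec, terms=terms)
    if X.shape[1] == 1:  # intercept only
        return 0.0
    fit = sm.OLS(np.asarray(y, dtype=float), np.asarray(X, dtype=float)).fit()
    return float(fit.rsquared)


def variance_explained(frame: pd.DataFrame, spec: RegressionSpec, variable: str) -> dict:
    """Share of outcome variance attributable to one variable.

    Returns both readings because neither is canonical:

    * ``univariate_r2`` — R^2 of the outcome on the variable alone;
    * ``incremental_r2`` — increase in R^2 when the variable is added
      last to the remaining terms of the spec.
    """
    term_names = [t.name for t in spec.terms]
    if variable not in term_names:
        raise ValueError(f"variable {variable!r} not in regression spec")
    target = tuple(t for t in spec.terms if t.name == variable)
    rest = tuple(t for t in spec.terms if t.name != variable)
    full = _r_squared(frame, spec, spec.terms)
    uni = _r_squared(frame, spec, target)
    without = _r_squared(frame, spec, rest) if rest else 0.0
    return {"univariate_r2": uni, "incremental_r2": full - without}


def determinants_report(frame: pd.DataFrame, spec: RegressionSpec | None = None) -> dict:
    """Fit the spec's model and decompose variance per variable."""
    spec = default_spec() if spec is None else spec
    y, X, n_dropped = design_matrix(frame, spec)
    result = fit_ols(X, y, n_dropped=n_dropped)
    variance = {t.name: variance_explained(frame, spec, t.name) for t in spec.terms}
    out = result.to_dict()
    out["variance_explained"] = variance
    return out
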