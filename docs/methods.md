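# Methods

## The two velocity metrics

EM velocity treats postnatal weight gain as exponential: if weight grows at a
constant fraction k of itself, then `Wn = W1·exp(k·D)` and
`k = ln(Wn/W1)/D`; scaled by 1000 this is a rate in g/kg/d. Only the two
endpoint weights and the stay length enter — the metric is blind to sex and
gestational age.

ZS velocity is the change in weight z-score against a sex-specific LMS
reference over the stay. The LMS method summarises the reference distribution
at each postmenstrual age (PMA) by a Box-Cox power L, median M and coefficient
of variation S, with `z = ((x/M)^L − 1)/(L·S)` and the logarithmic limit
`ln(x/M)/S` taken when `|L| < 1e-12`. PMA at birth equals gestational age;
PMA at discharge equals gestational age plus the stay (the only consistent
reading of scoring birth and discharge against a fetal-reference chart).

Charts are stored on any strictly increasing PMA grid per sex (weekly in
practice) and queried at day resolution by linear interpolation of L, M and S
independently — simple, monotone, and what chart tools commonly do; splines
are deliberately out of scope. Ages outside the grid raise an error rather
than extrapolate, because extrapolated reference values are clinically
meaningless.

## Calibration and agreement

Because EM is in g/kg/d and ZS is dimensionless, the comparison first puts
them on one scale: OLS with intercept predicting EM from ZS. The intercept is
included so that the residuals (the per-infant differences d) average exactly
to zero — the Bland–Altman mean difference is then a pure identity check.
Agreement is summarised by:

* 95% limits of agreement `mean(d) ± 1.96·sd(d)`, with the sample sd
  (n−1 denominator, the Bland–Altman convention);
* a tiered classification of |d|: fair on [0, 2), poor on [2, 4),
  disagreement on [4, ∞) g/kg/d. The boundaries are half-open downward
  ("a difference of less than 2" fixes the first); they are measure-zero, so
  the convention cannot materially move reported proportions. Thresholds are
  configurable because the cut-offs, while clinically motivated, are
  arbitrary;
* a normality report on d — skewness, excess kurtosis, and a Shapiro–Wilk
  p-value when n < 5000 (the statistic is unreliable above that and omitted).

Subgroup summaries (n, mean, sd, quartiles of d) are produced by sex,
gestational-age stratum (completed weeks: 23–26, 27–28, 29–30, 31–32) and
birth-weight z-score stratum (< −2, [−2,−1), [−1,0), ≥ 0). The determinant
regression fits d on those three variables with treatment coding against the
references male / 31–32 wk / ≥ 0, via statsmodels OLS with t-based 95%
intervals. Variance explained by a single variable is reported both as the
univariate R² of the variable alone and as its incremental R² when added last,
because single-variable attribution is not unique; rather than pick one, both
are surfaced. Covariates are analysed complete-case, with the dropped count
reported.

## The synthetic study conditions

The generator exists so that every stage is testable against ground truth.
Its defaults describe a large very-preterm cohort: GA strata probabilities
(0.071, 0.173, 0.263, 0.493) for 23–26/27–28/29–30/31–32 completed weeks with
GA uniform within the stratum; P(male) = 0.531; birth z ~ N(−0.45, 0.9);
z-score decline during the stay ~ N(0.7, 0.4) truncated at 0 (by default no
infant gains z during the stay; configurable off); discharge PMA ~
N(38, 1.5) weeks, resampled to stay ≥ 7 days. Each infant draws from an
independent counter-derived stream (`default_rng([seed, i])`), so a record
depends only on the seed and the infant index, never on cohort size.

Weights are generated by *inverting* the chart at the sampled z-scores, which
guarantees that z-scoring a generated weight against the generating chart
recovers the sampled z (verified to ~1e-15). The synthetic chart has a weekly
grid over 22–44 weeks, constant S = 0.13 and L = 1, a ±2% sex multiplier on
the median, and a median curve defined by a weekly fractional growth that
declines linearly with PMA: g(wk) = 0.13 − 0.003·(wk − 23), anchored at
M(23 wk) = 660 g. Those numbers track published preterm references (median
≈ 1470 g at 30 wk and ≈ 3100 g at 38 wk; fractional growth ≈ 17 → 10 g/kg/d
from 23 to 40 wk). Setting the decline to zero recovers the plain geometric
chart M(wk) = M23·(1+g)^(wk−23).

The decline is not cosmetic: it is the structural source of disagreement
between the metrics. With a constant fractional-growth chart, every infant on
any centile has the same chart-implied EM velocity regardless of gestational
age, EM becomes (nearly) an exact affine function of ZS, and the whole
agreement analysis degenerates. With declining fractional growth, infants born
earlier traverse faster-growing chart regions, so their EM velocity is higher
at the same z-change — exactly the gestational-age gradient the determinant
regression measures. `expected_stratum_em_offsets` computes the median-curve
component of that gradient per stratum; recovery tests require subgroup means
of d to be monotone in GA and the extreme-strata gap to fall within
[0.5, 2.5]× that prediction: the z-term of EM adds a contribution of the same
sign and comparable size on top of the median-curve component, which bounds
the recovered gap to that range.

`em_zs_noise_sd` (default 1.5) adds multiplicative measurement noise to the
recorded discharge weight, scaled as `exp(ε·D/1000)` with ε ~ N(0, sd) so that
it perturbs the EM velocity by about ε g/kg/d. It deliberately breaks the
exact chart round-trip at discharge, as scale error does in real data. An
important structural fact, derived analytically and confirmed numerically:
because both metrics are recomputed from the same recorded weight, such noise
moves (EM, ZS) almost exactly along the per-infant calibration direction, so
the calibration residual sd responds only sub-linearly to this knob. The
residual-scale recovery check therefore uses `simulate_velocity_pairs`, which
simulates directly in velocity space (ZS Gaussian, EM affine in ZS plus a
configured residual); there the residual sd is recovered within 10% at
n = 4000.

What the generator does *not* emulate: real charts' age-varying L and S,
within-stay weight trajectories, informative discharge timing, morbidity–
growth causal structure, and missing data. Passing tests therefore show the
estimators are correct and the structural GA mechanism is recovered; they do
not certify magnitudes on any real cohort, where chart granularity and
measurement practice add further disagreement.

## Numerical choices and degenerate inputs

* Box-Cox switch threshold |L| < 1e-12; continuity at the switch verified to
  1e-6.
* LMS inversion requires `1 + L·S·z > 0` when L ≠ 0; outside it is a domain
  error.
* Quantiles use linear interpolation between order statistics (the numpy
  default; medians and IQRs are robust to the convention).
* Calibration needs ≥ 3 pairs and a non-constant predictor; limits of
  agreement need ≥ 2 differences; the determinant fit needs full column rank
  (a rank-deficient design raises an error naming the collinear columns) and
  more rows than parameters.
* Report JSON rounds floats to 10 significant digits, so identical inputs
  give byte-identical files.
* Chart CSV ages are decimal weeks converted to days (×7, rounded to nearest
  day); cohort ages are integer days, with a `--pma-weeks` convenience on the
  CLI.
* Problem sizes: recovery and identity tests run at n = 4000 (3 seeds where
  averaging matters); the strata goodness-of-fit test at n = 10000; the
  acceptance script at n = 3954. These sizes give sampling error well inside
  the stated tolerances while keeping the full suite in the tens of seconds.

## Known limitations

* The pipeline uses exactly two weight points per infant; daily trajectories
  and length/head-circumference velocities are out of scope.
* The shipped determinant specification uses only sex, GA stratum and
  birth-weight-z stratum; the full covariate set a richer cohort would carry
  (steroids, BPD, infection, feeding, socioeconomic level, ...) is accepted by
  `RegressionSpec` but not fitted by default, since which covariates belong in
  the canonical model is cohort-dependent.
* Published LMS tables are supported through the chart CSV dialect but not
  bundled; the legacy .xls spreadsheet format has no reader here, so such
  exports must be re-saved as .xlsx or CSV before `convert-table`.
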