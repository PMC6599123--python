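import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neogrowth import (
    agreement_report,
    calibrate,
    classify,
    differences,
    limits_of_agreement,
    scatter_export,
    simulate_velocity_pairs,
    subgroup_differences,
)


class TestCalibrate:
    def test_perfect_line_recovered(self):
        zs = np.array([-1.0, 0.0, 0.5, 2.0])
        em = 2.0 * zs + 1.0
        fit = calibrate(em, zs)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(differences(em, fit, zs), 0.0, atol=1e-12)

    def test_three_point_closed_form(self):
        # closed-form simple regression: slope = Sxy/Sxx = 3/2, intercept = 5/6
        zs = np.array([0.0, 1.0, 2.0])
        em = np.array([1.0, 2.0, 4.0])
        fit = calibrate(em, zs)
        assert fit.slope == pytest.approx(1.5, abs=1e-12)
        assert fit.intercept == pytest.approx(5.0 / 6.0, abs=1e-12)
        d = differences(em, fit, zs)
        assert d == pytest.approx([1 / 6, -1 / 3, 1 / 6], abs=1e-12)

    def test_constant_predictor_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            calibrate([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            calibrate([1.0, 2.0], [0.0, 1.0])

    def test_ols_residual_identities(self, rng):
        zs = rng.normal(-0.7, 0.4, size=500)
        em = 12 + 2.2 * zs + rng.normal(0, 1.0, size=500)
        fit = calibrate(em, zs)
        d = differences(em, fit, zs)
        scale = 1e-8 * len(d) * np.abs(em).mean()
        assert abs(d.sum()) < scale
        assert abs((d * zs).sum()) < scale


class TestLimitsOfAgreement:
    def test_all_zero_differences(self):
        loa = limits_of_agreement([0.0, 0.0, 0.0, 0.0])
        assert (loa.mean, loa.sd, loa.low, loa.high) == (0.0, 0.0, 0.0, 0.0)

    def test_two_point_hand_calculation(self):
        loa = limits_of_agreement([-1.0, 1.0])
        assert loa.mean == 0.0
        assert loa.sd == pytest.approx(np.sqrt(2), abs=1e-12)
        assert loa.high == pytest.approx(1.96 * np.sqrt(2), abs=1e-12)
        assert loa.low == pytest.approx(-1.96 * np.sqrt(2), abs=1e-12)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            limits_of_agreement([1.0])

    def test_sample_sd_uses_n_minus_1(self, rng):
        d = rng.normal(size=50)
        assert limits_of_agreement(d).sd == pytest.approx(np.std(d, ddof=1), rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(-10, 10))
    def test_shift_equivariance(self, c):
        d = np.array([-1.3, 0.2, 0.9, 2.4, -0.6])
        base, shifted = limits_of_agreement(d), limits_of_agreement(d + c)
        assert shifted.mean == pytest.approx(base.mean + c, abs=1e-9)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-9)
        assert shifted.low == pytest.approx(base.low + c, abs=1e-9)
        assert shifted.high == pytest.approx(base.high + c, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (1.5, "fair"),
            (-1.999, "fair"),
            (2.0, "poor"),
            (-3.0, "poor"),
            (4.0, "disagreement"),
            (4.5, "disagreement"),
            (-6.0, "disagreement"),
        ],
    )
    def test_tier_boundaries(self, d, expected):
        assert classify(d) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify([1.0, np.nan])

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify(1.0, thresholds=(4.0, 2.0))

    def test_partition_and_brute_force_agreement(self, rng):
        d = rng.normal(0, 2.5, size=1000)
        labels = classify(d)
        brute = [
            "fair" if abs(x) < 2 else ("poor" if abs(x) < 4 else "disagreement") for x in d
        ]
        assert list(labels) == brute
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == 1000


class TestAgreementReport:
    def test_exact_linear_cohort_is_all_fair(self):
        zs = np.linspace(-2, 0.5, 20)
        frame = pd.DataFrame(
            {"id": range(20), "em_velocity": 3.0 * zs + 12.0, "zs_change": zs}
        )
        rep = agreement_report(frame)
        assert rep.proportions["fair"] == 1.0
        assert rep.loa.sd == pytest.approx(0.0, abs=1e-9)
        assert rep.loa.low == pytest.approx(0.0, abs=1e-9)
        assert rep.loa.high == pytest.approx(0.0, abs=1e-9)

    def test_counts_match_enumeration_oracle(self):
        frame = simulate_velocity_pairs(n=2000, seed=77, residual_sd=2.5)
        rep = agreement_report(frame)
        d = rep.differences
        assert rep.counts["fair"] == int(np.sum(np.abs(d) < 2))
        assert rep.counts["poor"] == int(np.sum((np.abs(d) >= 2) & (np.abs(d) < 4)))
        assert rep.counts["disagreement"] == int(np.sum(np.abs(d) >= 4))
        assert sum(rep.counts.values()) == rep.n
        assert sum(rep.proportions.values()) == pytest.approx(1.0)

    def test_residual_scale_recovery_velocity_space(self):
        # em = a + b*zs + noise: the calibration residual sd must recover
        # the injected residual scale (10%, n=4000, 3 seeds).
        sigma = 1.3
        for seed in (101, 102, 103):
            frame = simulate_velocity_pairs(n=4000, seed=seed, residual_sd=sigma)
            rep = agreement_report(frame)
            assert rep.loa.sd == pytest.approx(sigma, rel=0.10)

    def test_normality_summary_present(self):
        frame = simulate_velocity_pairs(n=500, seed=5)
        rep = agreement_report(frame)
        assert np.isfinite(rep.skewness) and np.isfinite(rep.excess_kurtosis)
        assert rep.shapiro_p is not None and 0 <= rep.shapiro_p <= 1

    def test_report_dict_class_percentages(self):
        frame = simulate_velocity_pairs(n=300, seed=6, residual_sd=2.0)
        d = agreement_report(frame).to_dict()
        total_pct = sum(d["classes"][k]["pct"] for k in ("fair", "poor", "disagreement"))
        assert total_pct == pytest.approx(100.0)


class TestSubgroups:
    def test_single_group_equals_whole_sample(self, rng):
        d = rng.normal(size=100)
        out = subgroup_differences(d, ["all"] * 100)
        assert len(out) == 1
        assert out.loc[0, "n"] == 100
        assert out.loc[0, "mean"] == pytest.approx(d.mean())
        assert out.loc[0, "sd"] == pytest.approx(np.std(d, ddof=1))

    def test_identical_distributions_equal_means(self):
        d = np.concatenate([np.array([-1.0, 0.0, 1.0]), np.array([-1.0, 0.0, 1.0])])
        out = subgroup_differences(d, ["a"] * 3 + ["b"] * 3)
        means = out.set_index("group")["mean"]
        assert means["a"] == pytest.approx(means["b"])

    def test_group_sizes_partition_total(self, rng):
        d = rng.normal(size=60)
        groups = rng.choice(["x", "y", "z"], size=60)
        out = subgroup_differences(d, groups)
        assert out["n"].sum() == 60

    def test_missing_group_value_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            subgroup_differences([1.0, 2.0], ["a", None])


class TestScatterExport:
    def test_rows_and_classes_consistent(self):
        frame = simulate_velocity_pairs(n=250, seed=8, residual_sd=2.0)
        rep = agreement_report(frame)
        table = scatter_export(frame, rep.fit)
        assert len(table) == 250
        assert list(table.columns) == ["id", "em", "predicted_em", "diff", "class"]
        assert list(table["class"]) == list(classify(table["diff"].to_numpy()))
        # class tallies agree with the report
        tallies = table["class"].value_counts().to_dict()
        for label, n in rep.counts.items():
            assert tallies.get(label, 0) == n

    def test_perfect_line_all_fair(self):
        zs = np.linspace(-1, 1, 10)
        frame = pd.DataFrame({"id": range(10), "em_velocity": zs * 2 + 10, "zs_change": zs})
        rep = agreement_report(frame)
        table = scatter_export(frame, rep.fit)
        assert (table["class"] == "fair").all()
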