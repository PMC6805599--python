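import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hemivol import (CohortSpec, ConversionFit, bland_altman,
                     cohort_table_from_parameters, estimate_full,
                     fit_conversion, group_compare, r_squared, run_validation)
from hemivol import refdata


def _table(ref, left_frac, compartment="asat"):
    ref = np.asarray(ref, dtype=float)
    left = np.asarray(left_frac, dtype=float) * ref
    other = "vat" if compartment == "asat" else "asat"
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(ref))],
        f"{compartment}_total": ref,
        f"{compartment}_left": left,
        f"{compartment}_right": ref - left,
        f"{other}_total": np.linspace(1000, 2000, len(ref)),
    })
    df[f"{other}_left"] = 0.55 * df[f"{other}_total"]
    df[f"{other}_right"] = df[f"{other}_total"] - df[f"{other}_left"]
    return df


class TestFitConversion:
    def test_exact_linear_relation(self):
        table = _table([1000, 2000, 3000, 4000, 5000], 0.5)
        fit = fit_conversion(table, "asat", "left")
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_three_point_fit_matches_normal_equations(self):
        x = np.array([1.0, 2.0, 5.0])
        y = np.array([2.0, 3.0, 9.0])
        table = pd.DataFrame({
            "subject_id": list("abc"),
            "asat_total": x, "asat_left": y, "asat_right": x - y,
            "vat_total": x, "vat_left": y / 2, "vat_right": x - y / 2,
        })
        fit = fit_conversion(table, "asat", "left")
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_degenerate_predictor_rejected(self):
        table = _table([1000, 1000, 1000], 0.5)
        with pytest.raises(ValueError, match="degenerate"):
            fit_conversion(table, "asat", "left")

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_conversion(_table([1000, 2000], 0.5), "asat", "left")

    @given(st.lists(st.floats(1000.0, 25000.0), min_size=4, max_size=12,
                    unique=True),
           st.integers(0, 2 ** 31 - 1))
    def test_complementary_side_identities(self, totals, seed):
        # whenever left + right = total exactly, f_L + f_R = 1 and
        # b_L + b_R = 0 (the published parameter sets obey both)
        rng = np.random.default_rng(seed)
        fracs = rng.uniform(0.35, 0.65, len(totals))
        table = _table(totals, fracs)
        fl = fit_conversion(table, "asat", "left")
        fr = fit_conversion(table, "asat", "right")
        scale = max(abs(fl.intercept), 1.0)
        assert fl.slope + fr.slope == pytest.approx(1.0, abs=1e-9)
        assert fl.intercept + fr.intercept == pytest.approx(0.0, abs=1e-9 * scale)

    def test_published_parameter_sets_are_complementary(self):
        for comp in ("asat", "vat"):
            (fl, bl) = refdata.CONVERSION_PARAMS[(comp, "left")]
            (fr, br) = refdata.CONVERSION_PARAMS[(comp, "right")]
            assert fl + fr == pytest.approx(1.0, abs=1e-12)
            assert bl + br == pytest.approx(0.0, abs=1e-12)


class TestEstimateFull:
    def _fit(self, f, b):
        return ConversionFit(compartment="asat", side="left", slope=f,
                             intercept=b, r_squared=1.0, n=26)

    def test_simple_inversion(self):
        assert estimate_full(100.0, self._fit(0.5, 0.0)) == pytest.approx(200.0)

    def test_published_means_reproduce_published_estimate(self):
        # (6605 - (-211.1)) / 0.5253 agrees with the published cohort-mean
        # estimate 12,976.4 cm^3 to the rounding of the printed inputs
        f, b = refdata.CONVERSION_PARAMS[("asat", "left")]
        side = refdata.MEAN_SIDE_VOLUMES[("asat", "left")]
        est = estimate_full(side, self._fit(f, b))
        assert est == pytest.approx(refdata.MEAN_ESTIMATES[("asat", "left")], abs=2.5)

    def test_as_printed_form_differs(self):
        f, b = 0.5253, -211.1
        est = estimate_full(6605.0, self._fit(f, b), as_printed=True)
        assert est == pytest.approx(6605.0 / f + b)
        assert abs(est - estimate_full(6605.0, self._fit(f, b))) > 300

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_full(100.0, self._fit(0.0, 0.0))

    def test_in_sample_mean_preservation(self):
        rng = np.random.default_rng(11)
        table = _table(rng.uniform(8000, 24000, 30), rng.uniform(0.45, 0.55, 30))
        fit = fit_conversion(table, "asat", "left")
        est = estimate_full(table["asat_left"].to_numpy(), fit)
        assert est.mean() == pytest.approx(table["asat_total"].mean(), rel=1e-9)

    def test_constant_fraction_recovers_parameters(self):
        table = _table(np.linspace(8000, 24000, 20), 0.53)
        fit = fit_conversion(table, "asat", "left")
        assert fit.slope == pytest.approx(0.53, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6 * 24000)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


class TestAgreement:
    def test_hand_computed_three_pair_example(self):
        stats = bland_altman([10.0, 20.0, 30.0], [12.0, 19.0, 33.0])
        assert stats.mean_diff == pytest.approx(-4.0 / 3.0)
        assert stats.sd_diff == pytest.approx(2.0817, abs=1e-4)
        assert stats.loa_low == pytest.approx(stats.mean_diff - 1.96 * stats.sd_diff)
        assert stats.loa_high == pytest.approx(stats.mean_diff + 1.96 * stats.sd_diff)

    def test_identical_vectors(self):
        stats = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stats.mean_diff == 0.0 and stats.sd_diff == 0.0
        assert (stats.loa_low, stats.loa_high) == (0.0, 0.0)
        assert stats.shapiro_w is None  # constant differences: no normality test

    def test_constant_shift(self):
        stats = bland_altman([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert stats.mean_diff == pytest.approx(-3.0)
        assert stats.sd_diff == 0.0

    def test_shapiro_three_point_closed_form(self):
        # for n = 3, W = (a1 (x(3) - x(1)))^2 / sum((x - mean)^2) with
        # a1 = 1/sqrt(2); the sample (1, 2, 3) attains the maximum W = 1
        stats = bland_altman([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert stats.shapiro_w == pytest.approx(1.0, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            bland_altman([1.0, 2.0], [1.0])


class TestRSquared:
    def test_hand_computed_example(self):
        assert r_squared([1, 2, 3], [1, 3, 2]) == pytest.approx(0.25)

    def test_perfect_linearity(self):
        assert r_squared([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(1.0)

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0),
           st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_affine_invariance(self, ax, bx, ay, by):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 6.0])
        base = r_squared(x, y)
        assert r_squared(ax * x + bx, ay * y + by) == pytest.approx(base, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_shift_matches_pooled_variance_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 10.0
        res = group_compare({"a": a, "b": b})
        sp = 1.0  # pooled SD of two samples with unit variance
        expected_t = -10.0 / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert res.t == pytest.approx(expected_t, rel=1e-12)
        assert res.p < 1e-3

    def test_p_invariant_under_common_affine_transform(self):
        g = {"a": [1.0, 3.0, 6.0], "b": [2.0, 5.0, 9.0]}
        g2 = {k: [3.0 * v - 7.0 for v in vals] for k, vals in g.items()}
        assert group_compare(g).p == pytest.approx(group_compare(g2).p, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            group_compare({"a": [1.0, 2.0]})


class TestRunValidation:
    def test_symmetric_cohort_yields_half_slopes(self):
        table = _table(np.linspace(8000, 24000, 10), 0.5)
        table["vat_left"] = 0.5 * table["vat_total"]
        table["vat_right"] = table["vat_total"] - table["vat_left"]
        report, _ = run_validation(table)
        for key in ("asat_left", "asat_right", "vat_left", "vat_right"):
            assert report["fits"][key]["slope"] == pytest.approx(0.5, abs=1e-9)
            assert report["fits"][key]["intercept"] == pytest.approx(0.0, abs=1e-6)
            assert report["fits"][key]["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_population_emulation_reaches_published_r2(self):
        # cohort drawn from the published ranges and side-fraction spread
        params = CohortSpec(n_subjects=200, seed=42).sample_parameters()
        table = cohort_table_from_parameters(params)
        report, per_subject = run_validation(table)
        assert report["fits"]["asat_left"]["r_squared"] >= 0.99
        assert report["fits"]["asat_right"]["r_squared"] >= 0.99
        assert report["fits"]["vat_left"]["r_squared"] >= 0.97
        assert report["fits"]["vat_right"]["r_squared"] >= 0.97
        # Bland-Altman bias of in-sample estimates is zero
        assert report["agreement"]["asat_left"]["mean_diff"] == pytest.approx(
            0.0, abs=1e-6)
        assert len(per_subject) == 200

    def test_report_matches_independent_recomputation(self, tmp_path):
        # totals in the report equal a from-scratch recomputation off the
        # per-subject CSV using the closed-form normal equations
        params = CohortSpec(n_subjects=30, seed=7).sample_parameters()
        table = cohort_table_from_parameters(params)
        report, per_subject = run_validation(table)
        csv = tmp_path / "per_subject.csv"
        per_subject.to_csv(csv, index=False)
        back = pd.read_csv(csv)
        x = back["asat_total"].to_numpy()
        y = back["asat_left"].to_numpy()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert report["fits"]["asat_left"]["slope"] == pytest.approx(slope, rel=1e-9)
        assert report["fits"]["asat_left"]["intercept"] == pytest.approx(
            intercept, rel=1e-6)
        est = (y - intercept) / slope
        assert np.allclose(back["asat_est_left"], est, rtol=1e-9)

    def test_group_comparison_present_with_two_groups(self):
        from hemivol import study_cohort_spec

        params = study_cohort_spec(n_subjects=26, seed=2).sample_parameters()
        table = cohort_table_from_parameters(params)
        report, _ = run_validation(table)
        assert set(report["groups"]) == {"asat_total", "vat_total"}
        assert 0.0 <= report["groups"]["asat_total"]["p"] <= 1.0

    def test_negative_volumes_rejected(self):
        table = _table([1000, 2000, 3000], 0.5)
        table.loc[0, "asat_left"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            run_validation(table)
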