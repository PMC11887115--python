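"""Expit-polynomial fitting, analytic trace and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, logit

import peakdrift as pk
from peakdrift.errors import NumericalError, ValidationError
from peakdrift.logistic_drift import AggregatedPrevalence


class TestDesignRow:
    @pytest.mark.parametrize(
        "t, a, deg_a, t_offset, expected",
        [
            (0.0, 0.0, 3, 0.0, [1, 0, 0, 0, 0, 0, 0, 0]),
            (1.0, 2.0, 2, 0.0, [1, 2, 4, 1, 2, 4]),
            (2009.0, 79.0, 3, 2012.0,
             [1, 79, 6241, 493039, -3, -237, -18723, -1479117]),
        ],
    )
    def test_examples(self, t, a, deg_a, t_offset, expected):
        row = pk.design_row(t, a, deg_a=deg_a, t_offset=t_offset)
        assert row == pytest.approx(expected)

    def test_unsupported_degrees(self):
        with pytest.raises(ValidationError):
            pk.design_row(0.0, 0.0, deg_a=4)
        with pytest.raises(ValidationError):
            pk.design_row(0.0, 0.0, deg_t=2)

    @given(
        t=st.floats(-50, 50), a=st.floats(0, 1.2),
        coefs=st.lists(st.floats(-2, 2), min_size=8, max_size=8),
    )
    def test_matches_direct_polynomial(self, t, a, coefs):
        c = np.asarray(coefs)
        row = pk.design_row(t, a, deg_a=3)
        direct = sum(c[j] * a**j for j in range(4)) + t * sum(
            c[4 + j] * a**j for j in range(4)
        )
        assert row @ c == pytest.approx(direct, rel=1e-9, abs=1e-9)


class TestExpitEval:
    def test_zero_logit_is_half(self):
        m = pk.LogisticPolyModel(np.zeros(8))
        assert float(pk.expit_eval(m, 2000.0, 50.0)) == 0.5

    def test_saturation_and_monotonicity(self):
        m = pk.LogisticPolyModel(np.array([0, 0, 0, 0, 1.0, 0, 0, 0]))  # f = t
        ts = np.array([-800.0, -5, 0, 5, 800.0])
        ps = pk.expit_eval(m, ts, np.full(5, 50.0))
        assert np.all(np.diff(ps) >= 0)
        assert ps[0] < 1e-100 and ps[-1] > 1 - 1e-15
        assert np.all((ps > 0) & (ps < 1) | (ps == ps))  # finite

    def test_diabetes_truth_on_trace_value(self, truth):
        t0 = pk.trace_inverse(truth, 79.0)
        assert float(pk.expit_eval(truth, t0, 79.0)) == pytest.approx(0.33, abs=0.01)


class TestFit:
    def test_symmetric_null_recovers_zero(self):
        years = np.repeat([2009.0, 2015.0], 21)
        ages = np.tile(np.arange(50.0, 71.0), 2)
        df = pd.DataFrame({
            "year": years, "age": ages,
            "cases": np.full(42, 500), "total": np.full(42, 1000),
        })
        m = pk.fit(AggregatedPrevalence(df))
        assert np.max(np.abs(m.coef)) <= 1e-6

    def test_parameter_recovery_from_exact_probabilities(self, truth):
        data = pk.simulate_counts(truth, totals=10_000_000, expected=True)
        m = pk.fit(data)
        rel = np.abs(m.coef - truth.coef) / np.abs(truth.coef)
        assert rel.max() <= 1e-3

    def test_fitted_deviance_beats_null_model(self, truth):
        data = pk.simulate_counts(truth, totals=1000, seed=11)
        m = pk.fit(data)
        df = data.table
        cases = df["cases"].to_numpy(float)
        total = df["total"].to_numpy(float)

        def deviance(p):
            p = np.clip(p, 1e-12, 1 - 1e-12)
            sat = np.where(cases > 0, cases * np.log(np.clip(cases / total, 1e-300, None) / p), 0)
            miss = np.where(total - cases > 0,
                            (total - cases) * np.log(np.clip(1 - cases / total, 1e-300, None) / (1 - p)), 0)
            return 2 * float(np.sum(sat + miss))

        p_fit = np.asarray(pk.expit_eval(m, df["year"], df["age"]))
        assert deviance(p_fit) <= deviance(np.full(len(df), 0.5)) + 1e-9

    def test_needs_two_years(self):
        df = pd.DataFrame({
            "year": np.full(30, 2009.0), "age": np.arange(30.0),
            "cases": 5, "total": 100,
        })
        with pytest.raises(ValidationError, match="distinct years"):
            pk.fit(AggregatedPrevalence(df))

    def test_wls_fallback_close_to_binomial(self, truth):
        data = pk.simulate_counts(truth, totals=500_000, expected=True)
        prev_only = AggregatedPrevalence(
            data.table.assign(prevalence=data.table.cases / data.table.total)
            .drop(columns=["cases", "total"])
        )
        m_wls = pk.fit(prev_only, method="wls")
        assert m_wls.ci_disabled and m_wls.vcov is None
        m_bin = pk.fit(data)
        # both consistent for the same truth, though differently weighted
        assert m_wls.coef == pytest.approx(m_bin.coef, rel=5e-3, abs=5e-3)

    def test_binomial_needs_counts(self, truth):
        data = pk.simulate_counts(truth, totals=1000, seed=3)
        prev_only = AggregatedPrevalence(
            data.table.assign(prevalence=data.table.cases / data.table.total)
            .drop(columns=["cases", "total"])
        )
        with pytest.raises(ValidationError, match="wls"):
            pk.fit(prev_only)


class TestTraceRoots:
    def test_pure_quadratic_peak(self):
        # f = 10 - (a - 80)^2: single stationary age 80
        m = pk.LogisticPolyModel.from_raw_coefficients(
            [10 - 6400, 160, -1, 0], [0, 0, 0, 0]
        )
        roots = pk.trace_roots(m, 2000.0)
        assert roots == pytest.approx([80.0])

    def test_factored_cubic_derivative(self):
        # df/da = -3 (a - 70)(a - 100)
        m = pk.LogisticPolyModel.from_raw_coefficients(
            [0, -21000, 255, -1], [0, 0, 0, 0]
        )
        assert pk.trace_roots(m, 1999.0) == pytest.approx([70.0, 100.0])

    def test_vanishing_cubic_warns_and_degrades(self):
        m = pk.LogisticPolyModel.from_raw_coefficients(
            [0, 160, -1, 0], [0, 0, 0, 0]
        )
        with pytest.warns(UserWarning, match="linear"):
            roots = pk.trace_roots(m, 2000.0)
        assert roots == pytest.approx([80.0])

    def test_complex_roots_give_empty_set(self):
        # df/da = 1 + a^2 > 0 has no real stationary age
        m = pk.LogisticPolyModel.from_raw_coefficients(
            [0, 1, 0, 1.0 / 3], [0, 0, 0, 0]
        )
        assert len(pk.trace_roots(m, 2000.0)) == 0

    def test_diabetes_fit_meaningful_root(self, fitted_model):
        roots = pk.trace_roots(fitted_model, 2009.0)
        assert any(abs(r - 78.4) < 0.5 for r in roots)


class TestTraceSelect:
    def test_negative_age_discarded(self, truth):
        got = pk.trace_select(np.array([-15.0, 78.4]), truth, 2009.0)
        assert got == pytest.approx(78.4, abs=0.5)

    def test_curvature_picks_maximum(self):
        m = pk.LogisticPolyModel.from_raw_coefficients(
            [0, -21000, 255, -1], [0, 0, 0, 0]
        )
        # 70 is a minimum of the age profile, 100 the maximum
        assert pk.trace_select(pk.trace_roots(m, 2000.0), m, 2000.0) == pytest.approx(100.0)

    def test_empty_roots_give_missing(self, truth):
        assert np.isnan(pk.trace_select(np.array([]), truth, 2009.0))

    def test_diabetes_trace_monotone_increasing(self, fitted_model):
        ts = np.linspace(2009.0, 2015.0, 13)
        curve = pk.trace_curve(fitted_model, ts)
        assert np.all(np.isfinite(curve.a_hat))
        assert np.all(np.diff(curve.a_hat) > 0)
        assert curve.a_hat[0] == pytest.approx(78.4, abs=0.2)


class TestTraceInverse:
    def test_linear_ridge_inversion(self):
        # df/da = (0.5 t - 930) - a: peak at a = 0.5 t - 930, i.e. t(80) = 2020
        m = pk.LogisticPolyModel.from_raw_coefficients(
            [0, -930, -0.5, 0], [0, 0.5, 0, 0]
        )
        assert pk.trace_inverse(m, 80.0) == pytest.approx(2020.0, abs=1e-6)

    def test_minimum_is_rejected(self):
        m = pk.LogisticPolyModel.from_raw_coefficients(
            [0, 930, 0.5, 0], [0, -0.5, 0, 0]
        )
        with pytest.raises(NumericalError, match="not attained"):
            pk.trace_inverse(m, 80.0)

    def test_diabetes_age79_near_mid_window(self, fitted_model):
        assert pk.trace_inverse(fitted_model, 79.0) == pytest.approx(2012.41, abs=0.5)


class TestFactorisationIdentity:
    def test_dp_da_equals_p2_expnegf_dfda(self, truth):
        # dp/da = p^2 exp(-f) df/da wherever |df/da| is not tiny
        rng = np.random.default_rng(5)
        t = rng.uniform(2005, 2020, 40)
        a = rng.uniform(45, 99, 40)
        f = truth.f(t, a)
        dfda = truth.df_da(t, a)
        keep = np.abs(dfda) > 1e-6
        p = expit(f)
        h = 1e-5
        dp_num = (expit(truth.f(t, a + h)) - expit(truth.f(t, a - h))) / (2 * h)
        analytic = p**2 * np.exp(-f) * dfda
        assert dp_num[keep] == pytest.approx(analytic[keep], rel=1e-6)


class TestRawCoefficientRoundTrip:
    def test_exact_roundtrip(self, truth):
        raw = truth.raw_coefficients()
        back = pk.LogisticPolyModel.from_raw_coefficients(
            raw["alpha"], raw["beta"],
            t_offset=truth.t_offset, a_scale=truth.a_scale,
        )
        assert back.coef == pytest.approx(truth.coef, rel=1e-12)

    def test_raw_evaluation_matches_conditioned(self, truth):
        raw = truth.raw_coefficients()
        t, a = 2013.7, 83.2
        direct = sum(raw["alpha"][j] * a**j for j in range(4)) + t * sum(
            raw["beta"][j] * a**j for j in range(4)
        )
        assert float(truth.f(t, a)) == pytest.approx(direct, rel=1e-9)


class TestBootstrap:
    def test_same_seed_bit_identical(self, truth):
        data = pk.simulate_counts(truth, totals=20_000, seed=7,
                                  ages=np.arange(50.0, 91.0, 2.0))
        b1 = pk.bootstrap(data, B=25, seed=99)
        b2 = pk.bootstrap(data, B=25, seed=99)
        assert np.array_equal(b1.raster["p_low"], b2.raster["p_low"])
        assert np.array_equal(b1.trace.ci_high, b2.trace.ci_high)

    def test_interval_width_scales_as_root_n(self, truth):
        ages = np.arange(50.0, 91.0, 2.0)
        widths = {}
        for totals in (2_000, 200_000):
            data = pk.simulate_counts(truth, totals=totals, seed=13, ages=ages)
            boot = pk.bootstrap(data, B=200, seed=17)
            widths[totals] = float(
                np.median(boot.raster["p_high"] - boot.raster["p_low"])
            )
        ratio = widths[2_000] / widths[200_000]
        assert 7.0 <= ratio <= 13.0  # sqrt(100) = 10 within +/- 30%

    def test_trace_bounds_bracket_estimate(self, truth):
        data = pk.simulate_counts(truth, totals=50_000, seed=21)
        boot = pk.bootstrap(data, B=50, seed=5)
        assert np.all(boot.trace.ci_low <= boot.trace.a_hat + 1e-9)
        assert np.all(boot.trace.a_hat <= boot.trace.ci_high + 1e-9)

    def test_needs_counts(self, truth):
        data = pk.simulate_counts(truth, totals=1000, seed=1)
        prev_only = AggregatedPrevalence(
            data.table.assign(prevalence=data.table.cases / data.table.total)
            .drop(columns=["cases", "total"])
        )
        with pytest.raises(ValidationError):
            pk.bootstrap(prev_only, B=10, seed=1)


class TestAggregatedPrevalenceValidation:
    def test_cases_above_total_rejected(self):
        df = pd.DataFrame({"year": [2009.0], "age": [50.0],
                           "cases": [101], "total": [100]})
        with pytest.raises(ValidationError, match="cases"):
            AggregatedPrevalence(df)

    def test_duplicate_cells_rejected(self):
        df = pd.DataFrame({"year": [2009.0] * 2, "age": [50.0] * 2,
                           "cases": [1, 2], "total": [10, 10]})
        with pytest.raises(ValidationError, match="duplicate"):
            AggregatedPrevalence(df)
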