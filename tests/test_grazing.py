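import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flpgraze.core_io import DEFAULT_CONSTANTS
from flpgraze.grazing import (FitError, SlopeFit, fit_uptake_slope,
                              rate_chain, rates_from_clearance, rates_table,
                              summarize)


def ols_oracle(x, y):
    """Brute-force normal-equations OLS: slope, intercept, slope stderr."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([np.ones(len(x)), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(x) - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta[1], beta[0], math.sqrt(cov[1, 1])


class TestSlopeFit:
    def test_exact_line(self, exp_factory):
        exp = exp_factory([(0, 0.0), (10, 1.0), (20, 2.0)])
        fit = fit_uptake_slope(exp)
        assert fit.slope == pytest.approx(0.100)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_flat_series_gives_zero_slope(self, exp_factory):
        exp = exp_factory([(0, 0.5), (10, 0.5), (40, 0.5)])
        fit = fit_uptake_slope(exp)
        assert fit.slope == 0.0
        assert rate_chain(fit, exp).below_detection

    def test_noisy_series_frozen_oracle_values(self, exp_factory):
        # frozen from the normal-equations oracle on these four pairs
        exp = exp_factory([(0, 0.20), (10, 0.15), (15, 0.35), (40, 0.31)])
        fit = fit_uptake_slope(exp)
        assert fit.slope == pytest.approx(0.0031510791366906508, rel=1e-9)
        assert fit.stderr == pytest.approx(0.003168997377998407, rel=1e-9)
        assert fit.n_points == 4

    def test_igt_final_timepoint_removed(self, exp_factory):
        clean = [(0, 0.0), (10, 0.5), (20, 1.0)]
        corrupted = clean + [(40, 0.1)]  # Tf anomaly
        igt = exp_factory(corrupted, approach="igt")
        fit = fit_uptake_slope(igt)
        assert fit.dropped_final and fit.n_points == 3
        assert fit.slope == pytest.approx(0.05)
        # an ambient experiment keeps its final point
        ambient = exp_factory(corrupted, approach="ambient")
        assert fit_uptake_slope(ambient).n_points == 4

    def test_too_few_points_names_experiment(self, exp_factory):
        exp = exp_factory([(0, 0.0), (40, 0.5)], approach="igt",
                          experiment_id="igt-short")
        with pytest.raises(FitError, match="igt-short"):
            fit_uptake_slope(exp)

    def test_agrees_with_normal_equations_on_random_series(self, exp_factory):
        rng = np.random.default_rng(7)
        for _ in range(50):
            times = [0.0] + sorted(rng.choice(
                np.arange(5, 41, 5), size=3, replace=False).tolist())
            means = np.round(rng.uniform(0, 2, size=4), 2)
            exp = exp_factory(list(zip(times, means)))
            fit = fit_uptake_slope(exp)
            slope, intercept, stderr = ols_oracle(times, means)
            assert fit.slope == pytest.approx(slope, rel=1e-10, abs=1e-12)
            if not math.isclose(stderr, 0.0, abs_tol=1e-12):
                assert fit.stderr == pytest.approx(stderr, rel=1e-8)


class TestRateChain:
    def test_specific_grazing_from_fallback_prey(self, exp_factory):
        # clearance 4.22e-5 x fallback 7.11e4 = 3.0004 prey grazer^-1 hr^-1
        exp = exp_factory([(0, 0.0), (10, 0.1)], prok=None, euk=349.86)
        rates = rates_from_clearance(4.22e-5, exp)
        assert rates.specific_grazing == pytest.approx(3.00042, rel=1e-5)
        assert rates.prey_conc_source == "fallback"

    def test_turnover_from_counted_prey(self, exp_factory):
        exp = exp_factory([(0, 0.0), (10, 0.1)], prok=3.79e4, euk=91.838)
        rates = rates_from_clearance(3.70e-5, exp)
        assert rates.grazing_rate_hr == pytest.approx(128.78, rel=1e-3)
        expected_turnover = 100 * rates.grazing_rate_day / 3.79e4
        assert rates.turnover_pct_day == pytest.approx(expected_turnover)

    def test_negative_slope_gates_everything_to_zero(self, exp_factory):
        exp = exp_factory([(0, 0.5), (10, 0.4), (40, 0.1)])
        rates = rate_chain(fit_uptake_slope(exp), exp)
        assert rates.below_detection
        assert rates.hourly_uptake == 0.0
        assert rates.grazing_rate_hr == 0.0
        assert rates.turnover_pct_day == 0.0
        assert rates.slope_flp_per_grazer_min < 0  # raw slope retained

    def test_exact_identities(self, exp_factory):
        exp = exp_factory([(0, 0.0), (10, 0.2), (40, 0.9)])
        fit = fit_uptake_slope(exp)
        rates = rate_chain(fit, exp)
        assert rates.hourly_uptake == 60.0 * fit.slope
        assert rates.grazing_rate_day == 24.0 * rates.grazing_rate_hr

    def test_zero_flp_conc_rejected(self, exp_factory):
        exp = exp_factory([(0, 0.0), (10, 0.2)])
        exp.flp_conc_t0 = 0.0
        exp.timepoints = []  # bypass construction guard; direct contract
        with pytest.raises(ValueError):
            rate_chain(SlopeFit(0.01, 0.0, 0.001, 3), exp)

    def test_zero_prey_with_positive_clearance_rejected(self, exp_factory):
        exp = exp_factory([(0, 0.0), (10, 0.2)], prok=0.0)
        with pytest.raises(ZeroDivisionError):
            rates_from_clearance(1e-5, exp)

    @settings(derandomize=True, max_examples=50)
    @given(slope=st.floats(1e-5, 1e-2), prey=st.floats(1e3, 1e6),
           euk=st.floats(1.0, 1e3), bump=st.floats(1.001, 10.0))
    def test_rate_monotone_in_slope_prey_and_grazers(
            self, slope, prey, euk, bump):
        from conftest import make_experiment

        def rate(s, p, e):
            exp = make_experiment([(0, 0.0), (10, 0.1)], prok=p, euk=e)
            return rate_chain(SlopeFit(s, 0.0, 0.0, 2), exp).grazing_rate_hr
        base = rate(slope, prey, euk)
        assert rate(slope * bump, prey, euk) >= base
        assert rate(slope, prey * bump, euk) >= base
        assert rate(slope, prey, euk * bump) >= base

    def test_flp_scale_property(self, exp_factory):
        """Doubling the FLP dose halves clearance; with prey doubled too,
        specific grazing is unchanged."""
        fit = SlopeFit(0.005, 0.0, 0.0, 3)
        exp1 = exp_factory([(0, 0.0), (10, 0.1)], flp=1000.0, prok=5e4)
        exp2 = exp_factory([(0, 0.0), (10, 0.1)], flp=2000.0, prok=1e5)
        r1, r2 = rate_chain(fit, exp1), rate_chain(fit, exp2)
        assert r2.clearance_ml_per_grazer_hr == pytest.approx(
            r1.clearance_ml_per_grazer_hr / 2)
        assert r2.specific_grazing == pytest.approx(r1.specific_grazing)


class TestSummarize:
    @pytest.fixture
    def frame(self):
        # six detected vent assays + three non-vent + two below detection
        vent_rates = [1050.38, 116.86, 15867.10, 1166.28, 6006.91, 17284.68]
        rows = [dict(habitat="vent", vent_field="VonDamm", approach="ambient",
                     grazing_rate_hr=r, below_detection=False)
                for r in vent_rates]
        rows += [dict(habitat=h, vent_field="VonDamm", approach="ambient",
                      grazing_rate_hr=r, below_detection=False)
                 for h, r in [("background", 127.07), ("plume", 24.03),
                              ("plume", 44.26)]]
        rows += [dict(habitat="vent", vent_field="Piccard", approach="ambient",
                      grazing_rate_hr=0.0, below_detection=True)] * 2
        return pd.DataFrame(rows)

    def test_vent_mean_excludes_below_detection(self, frame):
        out = summarize(frame, by="vent_nonvent")
        vent = out[out["group"] == "vent"].iloc[0]
        assert vent["mean"] == pytest.approx(6915.468, rel=1e-4)
        assert vent["n_detected"] == 6
        assert vent["n_below_detection"] == 2

    def test_nonvent_mean(self, frame):
        out = summarize(frame, by="vent_nonvent")
        nonvent = out[out["group"] == "nonvent"].iloc[0]
        assert nonvent["mean"] == pytest.approx(65.12, rel=1e-3)
        assert nonvent["min"] == pytest.approx(24.03)
        assert nonvent["max"] == pytest.approx(127.07)

    def test_singleton_group(self):
        df = pd.DataFrame([dict(habitat="vent", vent_field="Piccard",
                                approach="igt", grazing_rate_hr=42.0,
                                below_detection=False)])
        out = summarize(df, by="field").iloc[0]
        assert out["mean"] == out["min"] == out["max"] == 42.0

    def test_all_below_detection_group_reports_nan_not_zero(self):
        df = pd.DataFrame([dict(habitat="vent", vent_field="Piccard",
                                approach="igt", grazing_rate_hr=0.0,
                                below_detection=True)])
        out = summarize(df, by="field").iloc[0]
        assert out["n_detected"] == 0
        assert math.isnan(out["mean"])

    def test_unknown_grouping_rejected(self, frame):
        with pytest.raises(KeyError):
            summarize(frame, by="fluid")


def test_rates_table_end_to_end(exp_factory):
    exps = [exp_factory([(0, 0.0), (10, 0.5), (20, 1.0)],
                        experiment_id="up"),
            exp_factory([(0, 0.5), (10, 0.4), (40, 0.2)],
                        experiment_id="down")]
    table = rates_table(exps)
    assert list(table["experiment_id"]) == ["up", "down"]
    assert not table.loc[0, "below_detection"]
    assert table.loc[1, "below_detection"]
    assert table.loc[0, "grazing_rate_hr"] > 0
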