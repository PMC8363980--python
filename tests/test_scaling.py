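"""SMA / OLS scaling fits: closed-form identities, classification, table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import kelpmech as km
from kelpmech.errors import AmbiguousSign, DegenerateInput, MissingVariable, TooFewPoints
from kelpmech.scaling import ScalingFit, life_stage_mask


def gaussian_pairs(n=30, slope=1.19, sd=0.08, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.3, 1.6, n)
    y = -1.0 + slope * x + rng.normal(0, sd, n)
    return x, y


class TestSMA:
    def test_perfect_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = km.sma_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.ci_low == fit.ci_high == pytest.approx(2.0)

    def test_sma_equals_ols_over_r(self):
        """|b_SMA| = |b_OLS| / |r| against an independent OLS implementation."""
        x, y = gaussian_pairs(seed=2)
        fit = km.sma_fit(x, y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        r = np.corrcoef(x, y)[0, 1]
        assert abs(fit.slope) == pytest.approx(abs(ols.params[1]) / abs(r), rel=1e-10)
        assert fit.r_squared == pytest.approx(ols.rsquared, rel=1e-10)

    def test_swap_symmetry(self):
        x, y = gaussian_pairs(seed=3)
        assert km.sma_fit(x, y).slope == pytest.approx(1 / km.sma_fit(y, x).slope, rel=1e-12)

    def test_log_base_invariance(self):
        """Slope, CI and R² identical whether logs are base 10 or natural."""
        x, y = gaussian_pairs(seed=4)
        raw_x, raw_y = 10.0**x, 10.0**y
        f10 = km.sma_fit(np.log10(raw_x), np.log10(raw_y))
        fe = km.sma_fit(np.log(raw_x), np.log(raw_y))
        assert f10.slope == pytest.approx(fe.slope, rel=1e-12)
        assert f10.ci_low == pytest.approx(fe.ci_low, rel=1e-12)
        assert f10.ci_high == pytest.approx(fe.ci_high, rel=1e-12)
        assert f10.r_squared == pytest.approx(fe.r_squared, rel=1e-12)

    def test_unit_change_shifts_only_intercept(self):
        x, y = gaussian_pairs(seed=5)
        f1 = km.sma_fit(x, y)
        f2 = km.sma_fit(x + np.log10(10.0), y)    # mm -> cm in log space
        assert f2.slope == pytest.approx(f1.slope, rel=1e-12)
        assert f2.ci_low == pytest.approx(f1.ci_low, rel=1e-12)
        assert f2.intercept != pytest.approx(f1.intercept)

    def test_negative_slope_ci_is_ordered(self):
        x, y = gaussian_pairs(slope=-1.23, seed=6)
        fit = km.sma_fit(x, y)
        assert fit.ci_low <= fit.slope <= fit.ci_high
        assert fit.slope < 0

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_abs_sma_at_least_abs_ols(self, seed):
        """|b_SMA| >= |b_OLS| always, equality iff |r| = 1."""
        x, y = gaussian_pairs(seed=seed)
        sma = km.sma_fit(x, y)
        ols = km.ols_fit(x, y)
        assert abs(sma.slope) >= abs(ols.slope) - 1e-12

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInput):
            km.sma_fit([1, 2, 3], [1.0, 1.0, 1.0])
        with pytest.raises(TooFewPoints):
            km.sma_fit([1, 2], [1, 2])
        # exactly zero correlation -> sign of the SMA slope is undefined
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, 0.0, 1.0])
        with pytest.raises(AmbiguousSign):
            km.sma_fit(x, y)


class TestOLS:
    def test_constant_y_gives_zero_slope(self):
        fit = km.ols_fit([1, 2, 3, 4], [2.0, 2.0, 2.0, 2.0], h0_slope=0)
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0
        assert fit.ci_low == pytest.approx(-fit.ci_high)
        assert fit.classification == "independent"

    def test_four_point_hand_dataset(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 5.0])
        fit = km.ols_fit(x, y)
        expect = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(expect, rel=1e-12)

    def test_ci_matches_statsmodels(self):
        x, y = gaussian_pairs(seed=7)
        fit = km.ols_fit(x, y, alpha=0.05)
        ci = sm.OLS(y, sm.add_constant(x)).fit().conf_int(alpha=0.05)
        assert fit.ci_low == pytest.approx(ci[1][0], rel=1e-9)
        assert fit.ci_high == pytest.approx(ci[1][1], rel=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "lo,hi,h0,expected",
        [
            (0.96, 1.49, 1.0, "isometric"),
            (0.54, 0.91, 1.0, "negative_allometry"),
            (-0.17, 0.21, 0.0, "independent"),
            (0.98, 1.75, 0.0, "positive_allometry"),
            (-1.44, -1.05, 0.0, "negative_allometry"),
        ],
    )
    def test_reference_intervals(self, lo, hi, h0, expected):
        fit = ScalingFit(method="SMA", slope=(lo + hi) / 2, ci_low=lo, ci_high=hi,
                         intercept=0.0, r_squared=0.5, n=22, h0_slope=h0)
        assert km.classify_scaling(fit) == expected

    def test_monotone_in_alpha(self):
        """Widening the CI never moves a classification away from isometric."""
        x, y = gaussian_pairs(n=22, slope=1.25, sd=0.08, seed=8)
        for strict, loose in [(0.05, 0.01)]:  # smaller alpha => wider CI
            f_strict = km.sma_fit(x, y, alpha=strict, h0_slope=1.0)
            f_loose = km.sma_fit(x, y, alpha=loose, h0_slope=1.0)
            if f_strict.classification == "isometric":
                assert f_loose.classification == "isometric"


class TestScalingTable:
    def test_power_law_recovery_within_ci(self):
        slopes = {"a": 1.19, "b": 2.0, "c": 3.0}
        n = 40
        x, _ = km.simulate_property_scaling(n, 1.0, seed=1)
        df = pd.DataFrame({"specimen_id": [f"s{i}" for i in range(n)],
                           "stipe_length_cm": x})
        specs = [km.RegressionSpec(name, name, h0_slope=b, subset=None)
                 for name, b in slopes.items()]
        rng = np.random.default_rng(17)
        for name, b in slopes.items():
            df[name] = 10 ** (b * np.log10(df.stipe_length_cm) + rng.normal(0, 0.05, n))
        fits = km.run_scaling_table(df, specs)
        assert len(fits) == 3
        for fit in fits:
            b = slopes[fit.name]
            assert fit.ci_low <= b <= fit.ci_high
            assert fit.classification == ("independent" if b == 0 else "isometric")

    def test_empty_spec_list(self, morph_default):
        df, _ = morph_default
        assert km.run_scaling_table(df, []) == []

    def test_missing_variable_is_isolated(self, morph_default):
        df, _ = morph_default
        errors = []
        specs = [km.RegressionSpec("bad", "absent_column"),
                 km.RegressionSpec("good", "bulb_width_mm", h0_slope=1, subset="juvenile")]
        fits = km.run_scaling_table(df, specs, on_error=lambda s, e: errors.append((s.name, e)))
        assert [f.name for f in fits] == ["good"]
        assert errors and isinstance(errors[0][1], MissingVariable)

    def test_life_stage_subsetting(self, morph_default):
        df, _ = morph_default
        juv = life_stage_mask(df.stipe_length_cm, "juvenile")
        adult = life_stage_mask(df.stipe_length_cm, "adult")
        assert (df.stipe_length_cm[juv] < 40).all()
        assert (df.stipe_length_cm[adult] > 200).all()
        assert not (juv & adult).any()
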