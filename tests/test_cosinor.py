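"""Cosinor fitting, the zero-amplitude test, and the genome-wide screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhythmage import (
    bonferroni_adjust,
    fit_cosinor,
    fit_cosinor_combined,
    oscillation_summary,
    screen_sites,
)
from tests.conftest import WBC_NEU_TIMES


def cosine(t, mesor, amplitude, acrophase, period=24.0):
    return mesor + amplitude * np.cos(2 * np.pi * (t - acrophase) / period)


class TestFitCosinor:
    @pytest.mark.parametrize(
        "mesor,amplitude,acrophase",
        [(5.0, 2.0, 8.0), (50.0, 0.5, 23.5), (-3.0, 10.0, 0.0), (0.0, 1.0, 12.75)],
    )
    def test_noiseless_recovery(self, mesor, amplitude, acrophase):
        t = WBC_NEU_TIMES
        fit = fit_cosinor(t, cosine(t, mesor, amplitude, acrophase))
        assert fit.mesor == pytest.approx(mesor, abs=1e-8)
        assert fit.amplitude == pytest.approx(amplitude, abs=1e-8)
        gap = (fit.acrophase - acrophase) % 24.0
        assert min(gap, 24.0 - gap) == pytest.approx(0.0, abs=1e-8)
        assert fit.p_value == 0.0

    def test_constant_series_convention(self):
        fit = fit_cosinor(WBC_NEU_TIMES, np.full(24, 3.7))
        assert fit.amplitude == 0.0
        assert fit.p_value == 1.0
        assert fit.mesor == 3.7

    def test_acrophase_wraps_into_day(self):
        t = WBC_NEU_TIMES
        f1 = fit_cosinor(t, cosine(t, 5, 2, 8.0))
        f2 = fit_cosinor(t, cosine(t, 5, 2, 32.0))  # same curve, phase + 24
        assert f1.acrophase == pytest.approx(8.0, abs=1e-8)
        assert f2.acrophase == pytest.approx(f1.acrophase, abs=1e-8)
        assert 0 <= f1.acrophase < 24

    def test_nadir_is_half_period_after_acrophase(self):
        t = WBC_NEU_TIMES
        fit = fit_cosinor(t, cosine(t, 5, 2, 20.0))
        assert fit.nadir == pytest.approx(8.0, abs=1e-8)

    def test_too_few_or_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            fit_cosinor([0, 3, 6], [1, 2, 3])
        with pytest.raises(ValueError):
            # all times coincide modulo the period
            fit_cosinor([0, 24, 48, 72], [1, 2, 3, 4])

    def test_time_shift_equivariance(self):
        t = WBC_NEU_TIMES
        rng = np.random.default_rng(5)
        y = cosine(t, 5, 2, 8.0) + rng.normal(0, 0.5, t.size)
        base = fit_cosinor(t, y)
        shifted = fit_cosinor(t + 5.0, y)
        assert shifted.mesor == pytest.approx(base.mesor, abs=1e-10)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-10)
        assert shifted.p_value == pytest.approx(base.p_value, abs=1e-10)
        assert (shifted.acrophase - base.acrophase) % 24 == pytest.approx(
            5.0, abs=1e-8
        )

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(min_value=-5, max_value=5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_equivariance(self, a, b):
        t = WBC_NEU_TIMES
        rng = np.random.default_rng(7)
        y = cosine(t, 5, 2, 8.0) + rng.normal(0, 0.5, t.size)
        base = fit_cosinor(t, y)
        mapped = fit_cosinor(t, a * y + b)
        assert mapped.mesor == pytest.approx(a * base.mesor + b, rel=1e-8, abs=1e-8)
        assert mapped.amplitude == pytest.approx(abs(a) * base.amplitude, rel=1e-8)
        assert mapped.p_value == pytest.approx(base.p_value, abs=1e-9)


class TestCombinedCosinor:
    def test_single_subject_reduces_to_plain_fit(self):
        t = WBC_NEU_TIMES
        rng = np.random.default_rng(3)
        y = cosine(t, 5, 2, 8.0) + rng.normal(0, 0.3, t.size)
        single = fit_cosinor(t, y)
        combined = fit_cosinor_combined(t, y, np.repeat("s1", t.size))
        assert combined.mesor == pytest.approx(single.mesor, abs=1e-10)
        assert combined.amplitude == pytest.approx(single.amplitude, abs=1e-10)
        assert combined.acrophase == pytest.approx(single.acrophase, abs=1e-10)
        assert combined.p_value == pytest.approx(single.p_value, abs=1e-10)

    def test_noiseless_per_subject_recovery(self):
        t = np.arange(0.0, 25.0, 3.0)  # 9 points over 24 h
        params = {"a": (50, 2.0, 4.0), "b": (55, 2.5, 10.0), "c": (60, 3.0, 18.0)}
        times, values, ids = [], [], []
        for sid, (m, a, phi) in params.items():
            times.append(t)
            values.append(cosine(t, m, a, phi))
            ids.extend([sid] * t.size)
        fit = fit_cosinor_combined(
            np.concatenate(times), np.concatenate(values), np.array(ids)
        )
        assert fit.p_value < 1e-10
        for sid, (m, a, phi) in params.items():
            sub = fit.subjects[sid]
            assert sub.mesor == pytest.approx(m, abs=1e-8)
            assert sub.amplitude == pytest.approx(a, abs=1e-8)
            assert sub.acrophase == pytest.approx(phi, abs=1e-8)

    def test_subject_with_too_few_points_named(self):
        t = np.concatenate([np.arange(0.0, 25.0, 3.0), [0.0, 6.0, 12.0]])
        ids = np.array(["ok"] * 9 + ["short"] * 3)
        with pytest.raises(ValueError, match="short"):
            fit_cosinor_combined(t, np.arange(t.size, dtype=float), ids)

    def test_null_joint_test_calibrated(self):
        # all-zero amplitude: joint p approximately uniform
        rng = np.random.default_rng(17)
        t = np.tile(np.arange(0.0, 25.0, 3.0), 3)
        ids = np.repeat(["a", "b", "c"], 9)
        pvals = []
        for _ in range(400):
            y = np.repeat([50.0, 55.0, 60.0], 9) + rng.normal(0, 1, t.size)
            pvals.append(fit_cosinor_combined(t, y, ids).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestScreen:
    def test_null_significant_count_within_binomial_bounds(self):
        rng = np.random.default_rng(23)
        y = rng.normal(size=(1000, 24))
        res = screen_sites(pd.DataFrame(y), WBC_NEU_TIMES, alpha=0.05)
        lo, hi = stats.binom.interval(0.99, 1000, 0.05)
        assert lo <= res.count <= hi

    def test_planted_oscillators_detected(self):
        from rhythmage.experiments import site_screen_power

        res = site_screen_power(seed=2, amplitude=0.05, noise_sd=0.01)
        assert res["sensitivity"] >= 0.80

    def test_zero_variance_rows_excluded(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(10, 24))
        y[0] = 0.5  # constant row
        res = screen_sites(pd.DataFrame(y), WBC_NEU_TIMES)
        assert res.p_values.iloc[0] == 1.0
        assert 0 not in res.significant
        assert res.count == len(res.significant)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            screen_sites(pd.DataFrame(np.zeros((5, 10))), WBC_NEU_TIMES)


class TestBonferroniAndSummary:
    def test_adjustment_arithmetic(self):
        assert bonferroni_adjust(0.01, m=17) == pytest.approx(0.17)
        assert bonferroni_adjust(0.2, m=17) == 1.0
        assert bonferroni_adjust(0.3, m=1) == pytest.approx(0.3)
        out = bonferroni_adjust([0.01, 0.2], m=17)
        assert out[0] == pytest.approx(0.17) and out[1] == 1.0
        with pytest.raises(ValueError):
            bonferroni_adjust(1.2, m=2)

    def test_amplitude_as_percent_of_mesor(self):
        from rhythmage.cosinor import CosinorFit

        fit = CosinorFit(1756.0, 309.0, 14.0, 24.0, 0.001, 9)
        row = oscillation_summary(fit)
        assert round(row["amplitude_pct_of_mesor"], 1) == 17.6
        assert row["peak_to_nadir_pct"] > 35.0
        assert row["nadir_h"] == pytest.approx(2.0)

    def test_zero_amplitude_and_zero_mesor(self):
        from rhythmage.cosinor import CosinorFit

        zero_amp = oscillation_summary(CosinorFit(10.0, 0.0, 0.0, 24.0, 1.0, 9))
        assert zero_amp["amplitude_pct_of_mesor"] == 0.0
        assert zero_amp["peak_to_nadir_pct"] == 0.0
        with pytest.warns(UserWarning):
            row = oscillation_summary(CosinorFit(0.0, 1.0, 0.0, 24.0, 0.5, 9))
        assert not row["percent_defined"]
        assert np.isnan(row["amplitude_pct_of_mesor"])
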