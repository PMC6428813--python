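"""Growth-law tests: interpolation shape, fitting, penalty."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dispersim.config import PenaltyModel, default_growth_table
from dispersim.growth import (StrainGrowthProfile, build_profiles,
                              closed_form_population, fit_growth_parameters,
                              growth_rate_at)
from dispersim.synthetic import lognormal_factors

PROFILES = build_profiles(default_growth_table())


class TestClosedForm:
    def test_worked_example(self):
        # 120 * exp(0.02 * (240 - 60)) = 120 * e^3.6
        assert closed_form_population(120, 60, 0.02, 240) == pytest.approx(
            120 * np.exp(3.6), rel=1e-12)
        assert closed_form_population(120, 60, 0.02, 240) == pytest.approx(
            4391.9, rel=1e-4)

    def test_continuity_at_lag_end(self):
        assert closed_form_population(120, 60, 0.02, 60) == 120

    def test_zero_rate_constant(self):
        t = np.linspace(0, 240, 9)
        np.testing.assert_array_equal(
            closed_form_population(120, 60, 0.0, t), 120.0)


class TestInterpolation:
    def test_passes_through_anchors(self):
        table = default_growth_table()
        for strain, prof in PROFILES.items():
            rows = table[table.strain == strain]
            np.testing.assert_allclose(
                prof.rate(rows["temperature_C"].to_numpy()),
                rows["r_growth_per_min"].to_numpy(), rtol=1e-12)

    def test_no_overshoot_between_anchors(self):
        """Shape preservation: within each anchor interval the interpolant
        stays inside the bracket of its endpoint values."""
        for prof in PROFILES.values():
            T = prof.anchor_temperatures
            r = prof.anchor_rates
            for i in range(len(T) - 1):
                dense = np.linspace(T[i], T[i + 1], 200)
                vals = prof.rate(dense)
                lo, hi = min(r[i], r[i + 1]), max(r[i], r[i + 1])
                assert vals.min() >= lo - 1e-12
                assert vals.max() <= hi + 1e-12

    def test_clamped_outside_anchor_range(self):
        prof = PROFILES["E310"]
        assert prof.rate(10.0) == pytest.approx(prof.rate(25.0))
        assert prof.rate(60.0) == pytest.approx(prof.rate(42.0))

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            StrainGrowthProfile.from_anchors("x", [25, 25], [0.1, 0.1],
                                             [10, 10])


class TestFitting:
    def test_exact_recovery_on_noiseless_data(self):
        t = np.arange(0, 241, 30.0)
        n = closed_form_population(120, 60, 0.02, t)
        t0, r, flagged = fit_growth_parameters(t, n, 120)
        assert not flagged
        assert t0 == pytest.approx(60.0, abs=1e-6)
        assert r == pytest.approx(0.02, abs=1e-6)

    def test_offgrid_lag_recovered(self):
        t = np.arange(0, 241, 30.0)
        n = closed_form_population(120, 47.0, 0.015, t)
        t0, r, _ = fit_growth_parameters(t, n, 120)
        assert t0 == pytest.approx(47.0, abs=1e-4)
        assert r == pytest.approx(0.015, abs=1e-6)

    def test_constant_series_zero_rate(self):
        t = np.arange(0, 241, 30.0)
        t0, r, flagged = fit_growth_parameters(t, np.full_like(t, 120.0), 120)
        assert r == 0.0
        assert flagged

    def test_monte_carlo_recovery_under_replicate_noise(self):
        t = np.arange(0, 241, 30.0)
        clean = closed_form_population(120, 60, 0.02, t)
        rng = np.random.default_rng(7)
        errors = []
        for _ in range(100):
            noisy = clean * lognormal_factors(0.041, clean.shape, rng)
            _, r, _ = fit_growth_parameters(t, noisy, 120)
            errors.append(abs(r - 0.02) / 0.02)
        assert np.median(errors) < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_growth_parameters([0, 30, 60], [1, 2, 3], 1)


class TestPenalty:
    def test_no_penalty_at_zero_speed(self):
        pen = PenaltyModel()
        for strain in ("B42", "E310", "E111"):
            assert pen.rate_factor(strain, 0.0) == pytest.approx(1.0)
            assert pen.lag_shift_min(strain, 0.0) == pytest.approx(0.0)

    def test_maximal_penalty_at_top_speed(self):
        pen = PenaltyModel()
        assert pen.rate_factor("B42", 71.5) == pytest.approx(1 - 0.32)
        assert pen.rate_factor("E310", 71.5) == pytest.approx(1 - 0.405)
        assert pen.rate_factor("E111", 71.5) == pytest.approx(1 - 0.09)
        assert pen.lag_shift_min("B42", 71.5) == pytest.approx(7.2)
        assert pen.lag_shift_min("E310", 71.5) == pytest.approx(31.0)
        assert pen.lag_shift_min("E111", 71.5) == pytest.approx(53.3)

    @given(st.floats(0.0, 71.5), st.floats(0.0, 71.5))
    @settings(max_examples=60, deadline=None)
    def test_penalty_monotone_in_speed(self, s1, s2):
        lo, hi = sorted((s1, s2))
        pen = PenaltyModel()
        assert pen.rate_factor("E310", hi) <= pen.rate_factor("E310", lo) + 1e-12
        assert pen.lag_shift_min("E310", hi) >= pen.lag_shift_min("E310", lo) - 1e-12

    def test_linear_uniform_variant(self):
        pen = PenaltyModel(shape="linear_uniform", speed_max_ul_s=200.0,
                           uniform_dr_max=-0.3)
        assert pen.rate_factor("B42", 100.0) == pytest.approx(0.85)
        assert pen.rate_factor("E111", 100.0) == pytest.approx(0.85)
        assert pen.lag_shift_min("B42", 100.0) == 0.0


class TestRealizedRate:
    def test_zero_during_universal_lag(self):
        # before the shortest default lag (20 min) nobody grows
        for prof in PROFILES.values():
            for T in (25.0, 31.0, 37.0, 42.0):
                assert growth_rate_at(prof, T, 10.0) == 0.0

    def test_anchor_rate_after_lag_without_penalty(self):
        prof = PROFILES["E310"]
        rate = growth_rate_at(prof, 40.0, 200.0)
        assert rate == pytest.approx(0.0150, rel=1e-9)

    def test_e111_peaks_at_37(self):
        prof = PROFILES["E111"]
        r37 = growth_rate_at(prof, 37.0, 230.0)
        for T in (25.0, 28.0, 34.0, 40.0, 42.0):
            assert r37 > growth_rate_at(prof, T, 230.0)

    def test_penalty_reduces_rate_and_extends_lag(self):
        prof = PROFILES["E310"]
        pen = PenaltyModel()
        free = growth_rate_at(prof, 40.0, 70.0)           # just past lag
        stressed = growth_rate_at(prof, 40.0, 70.0, pen, 71.5)
        assert free > 0
        assert stressed == 0.0  # lag extended past t=70
        late = growth_rate_at(prof, 40.0, 200.0, pen, 71.5)
        assert late == pytest.approx(0.0150 * (1 - 0.405))
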