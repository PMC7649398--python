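"""Retention equations checked against independently scripted oracles.

The oracle functions below transcribe each equation chain literally, step
by step, with no reuse of package code, so a transcription slip on either
side shows up as a mismatch.
"""

import math

import numpy as np
import pytest

from nutrex import (
    AnimalClass,
    CowRecord,
    DesignConstants,
    n_growth,
    n_milk,
    n_preg,
    n_scurf,
    p_growth,
    p_milk,
    p_preg,
    retention_for_cow,
)
from nutrex.retention import growth_trace, mp_pregnancy


# --- oracles ---------------------------------------------------------------

def oracle_n_growth(bw, mw, wg_g):
    wg = wg_g / 1000.0
    ne = (0.84 * bw ** 0.355 * wg ** 1.2) * 0.69
    sbw = 0.96 * bw
    msbw = 0.96 * mw
    eqsbw = sbw * (478.0 / msbw)
    swg = 13.9 * ne ** 0.9116 * eqsbw ** -0.6837
    eqebw = 0.891 * eqsbw
    eqebg = 0.956 * swg
    re = 0.0635 * eqebw ** 0.75 * eqebg ** 1.097
    np_g = swg * (268.0 - 29.4 * (re / swg))
    mp_growth = np_g / (0.834 - eqsbw * 0.00114)
    return mp_growth / 6.25


def oracle_n_preg(t, cbw):
    if not 190 <= t <= 279:
        return 0.0
    return ((0.69 * t - 69.2) * (cbw / 45.0)) / 0.33 / 6.25


def oracle_p_preg(t):
    if not 190 <= t <= 279:
        return 0.0
    return (0.02743 * math.exp((0.05527 - 0.000075 * t) * t)
            - 0.02743 * math.exp((0.05527 - 0.000075 * (t - 1)) * (t - 1)))


def oracle_p_growth(bw, mw, wg_g):
    return (1.2 + (4.635 * mw ** 0.22) * (bw ** -0.22)) * ((wg_g / 1000.0) / 0.96)


# --- grid agreement --------------------------------------------------------

GROWTH_GRID = [(bw, mw, wg) for bw in (120, 180, 250, 278, 350, 420, 480)
               for mw in (480, 500, 550) for wg in (200, 450, 700)]
PREG_GRID = list(range(185, 285, 4)) + [190, 279]


class TestOracleAgreement:
    @pytest.mark.parametrize("bw,mw,wg", GROWTH_GRID)
    def test_n_growth_matches_oracle(self, bw, mw, wg):
        value, _ = n_growth(bw, mw, wg, AnimalClass.YOUNG)
        assert value == pytest.approx(oracle_n_growth(bw, mw, wg), abs=1e-9)

    @pytest.mark.parametrize("bw,mw,wg", GROWTH_GRID)
    def test_p_growth_matches_oracle(self, bw, mw, wg):
        assert p_growth(bw, mw, wg, AnimalClass.YOUNG) == pytest.approx(
            oracle_p_growth(bw, mw, wg), abs=1e-9)

    @pytest.mark.parametrize("t", PREG_GRID)
    def test_n_preg_matches_oracle(self, t):
        assert n_preg(t, cbw=40.0) == pytest.approx(
            oracle_n_preg(t, 40.0), abs=1e-9)

    @pytest.mark.parametrize("t", PREG_GRID)
    def test_p_preg_matches_oracle(self, t):
        assert p_preg(t) == pytest.approx(oracle_p_preg(t), abs=1e-9)


class TestGrowthChain:
    def test_trace_at_surveyed_young_cow_means(self):
        value, trace = n_growth(278, 500, 450, AnimalClass.YOUNG)
        assert value == pytest.approx(24.3, abs=0.05)
        assert trace.eqsbw == pytest.approx(265.8, abs=0.1)
        assert trace.ne_growth_diet == pytest.approx(1.64, abs=0.01)
        assert trace.swg == pytest.approx(0.480, abs=0.001)
        assert trace.re == pytest.approx(1.63, abs=0.01)
        assert trace.np_g == pytest.approx(80.6, abs=0.1)
        assert trace.mp_growth == pytest.approx(151.8, abs=0.1)

    def test_zero_gain_retains_nothing(self):
        value, _ = n_growth(278, 500, 0, AnimalClass.YOUNG)
        assert value == 0.0

    @pytest.mark.parametrize("cls", [AnimalClass.LACTATING, AnimalClass.DRY])
    def test_mature_classes_retain_no_growth_n(self, cls):
        value, trace = n_growth(433, 500, 450, cls)
        assert value == 0.0 and trace is None

    def test_increasing_in_weight_gain(self):
        values = [n_growth(278, 500, wg, AnimalClass.YOUNG)[0]
                  for wg in range(100, 1000, 100)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_degenerate_denominator_is_diagnosed(self):
        heavy = DesignConstants(reference_sbw=1500.0)
        with pytest.raises(ValueError, match="EQSBW"):
            growth_trace(500, 500, 450, heavy)

    def test_bw_above_mature_weight_rejected(self):
        with pytest.raises(ValueError):
            growth_trace(550, 500, 450)


class TestPregnancy:
    def test_mp_preg_at_210_days_default_calf(self):
        assert mp_pregnancy(210, 40.0) == pytest.approx(203.9, abs=0.1)
        assert n_preg(210, 40.0) == pytest.approx(32.6, abs=0.05)

    def test_reference_calf_weight_removes_scaling(self):
        # CBW = 45 makes both bracket readings coincide
        assert n_preg(279, 45.0) == pytest.approx(
            (0.69 * 279 - 69.2) / 0.33 / 6.25, rel=1e-12)

    @pytest.mark.parametrize("t", [0, 100, 150, 189.9, 279.1, 283])
    def test_zero_outside_gestation_window(self, t):
        assert n_preg(t, 40.0) == 0.0
        assert p_preg(t) == 0.0

    def test_missing_gestation_day_retains_nothing(self):
        assert n_preg(None, 40.0) == 0.0
        assert p_preg(None) == 0.0

    def test_negative_gestation_day_rejected(self):
        with pytest.raises(ValueError):
            n_preg(-5, 40.0)
        with pytest.raises(ValueError):
            p_preg(-5)

    def test_p_accretion_increases_through_late_gestation(self):
        values = [p_preg(t) for t in range(190, 280)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[40] == pytest.approx(3.6, abs=0.1)  # t = 230

    def test_p_preg_step_bounded_by_analytic_derivative(self):
        # the discrete difference of the cumulative curve stays below the
        # maximum of its derivative over [t-1, t]
        for t in range(191, 280):
            def cum(day):
                return 0.02743 * math.exp((0.05527 - 0.000075 * day) * day)

            def deriv(day):
                return cum(day) * (0.05527 - 0.00015 * day)

            bound = max(deriv(x) for x in np.linspace(t - 1, t, 11))
            assert p_preg(t) <= bound * 1.0001

    def test_alternative_bracket_reading_is_switchable(self):
        alt = DesignConstants(cbw_scales_whole_mp_preg=False)
        expected = (0.69 * 210 - 69.2 * (40.0 / 45.0)) / 0.33
        assert mp_pregnancy(210, 40.0, alt) == pytest.approx(expected, rel=1e-12)


class TestMilkAndScurf:
    def test_n_milk_at_survey_means(self):
        assert n_milk(13_000, 34.0) == pytest.approx(69.28, abs=0.01)

    def test_n_milk_round_number(self):
        assert n_milk(10_000, 31.9) == pytest.approx(50.0)

    def test_no_milk_no_n(self):
        assert n_milk(0.0, 34.0) == 0.0

    @pytest.mark.parametrize("bw,expected", [(433, 1.833), (278, 1.405), (1, 0.048)])
    def test_scurf_scales_with_metabolic_size(self, bw, expected):
        assert n_scurf(bw) == pytest.approx(0.3 * bw ** 0.6 / 6.25, rel=1e-12)
        assert n_scurf(bw) == pytest.approx(expected, abs=0.002)

    @pytest.mark.parametrize("yield_g,conc,expected",
                             [(13_000, 0.6, 7.8), (10_000, 0.6, 6.0), (0, 0.6, 0.0)])
    def test_p_milk(self, yield_g, conc, expected):
        assert p_milk(yield_g, conc) == pytest.approx(expected)


class TestCowLevelBudgets:
    def test_lactating_cow_budget(self, simple_cow):
        n_ret, p_ret, trace, flags = retention_for_cow(simple_cow)
        assert n_ret.n_milk > 0 and n_ret.n_growth == 0
        assert n_ret.total == pytest.approx(
            n_ret.n_milk + n_ret.n_preg + n_ret.n_growth + n_ret.n_scurf)
        assert p_ret.total == pytest.approx(
            p_ret.p_milk + p_ret.p_preg + p_ret.p_growth)
        assert trace is None and flags == []

    def test_dry_cow_without_gestation_day_is_flagged(self):
        cow = CowRecord(cow_id="d", animal_class=AnimalClass.DRY, bw=419.0)
        n_ret, _, _, flags = retention_for_cow(cow)
        assert n_ret.n_preg == 0.0
        assert any("days_pregnant" in f for f in flags)

    def test_components_nonnegative_for_generated_herd(self, default_herd):
        for cow in default_herd.cows:
            n_ret, p_ret, _, _ = retention_for_cow(cow)
            assert min(n_ret.n_milk, n_ret.n_preg, n_ret.n_growth,
                       n_ret.n_scurf) >= 0
            assert min(p_ret.p_milk, p_ret.p_preg, p_ret.p_growth) >= 0
            if cow.animal_class is AnimalClass.YOUNG:
                assert n_ret.n_milk == 0 and p_ret.p_milk == 0
            else:
                assert n_ret.n_growth == 0 and p_ret.p_growth == 0
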