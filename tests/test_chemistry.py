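import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcsim.chemistry import (
    BindingSystem, discretize_level, equilibrate_pair, equilibrate_with_analog,
)

from conftest import bisect_pair_oracle, grid_oracle_analog

CONC = st.floats(min_value=1e-12, max_value=1e-6)
KA = st.floats(min_value=1e6, max_value=1e12)


class TestEquilibratePair:
    def test_no_binding(self):
        eq = equilibrate_pair(1e-8, 1e-8, 0.0)
        assert eq.complex_ai == 0.0
        assert eq.free_a == 1e-8
        assert eq.free_i == 1e-8

    def test_absent_partner(self):
        eq = equilibrate_pair(0.0, 1e-8, 1e10)
        assert eq.complex_ai == 0.0
        assert eq.free_i == 1e-8

    def test_equal_totals_worked_case(self):
        # frozen from the independent bisection oracle
        expected_c = bisect_pair_oracle(1e-8, 1e-8, 1e10)
        assert expected_c == pytest.approx(9.048750780275e-09, rel=1e-9)
        eq = equilibrate_pair(1e-8, 1e-8, 1e10)
        assert eq.complex_ai == pytest.approx(expected_c, rel=1e-7)
        assert eq.free_a == pytest.approx(9.512492197250e-10, rel=1e-7)
        assert eq.free_i == pytest.approx(eq.free_a, rel=1e-12)

    def test_asymmetric_worked_case(self):
        expected_c = bisect_pair_oracle(2e-8, 1e-8, 1e10)
        assert expected_c == pytest.approx(9.901942113768e-09, rel=1e-9)
        eq = equilibrate_pair(2e-8, 1e-8, 1e10)
        assert eq.complex_ai == pytest.approx(expected_c, rel=1e-7)
        assert eq.free_i == pytest.approx(9.805788623244e-11, rel=1e-7)

    @pytest.mark.parametrize("kwargs,name", [
        (dict(total_a=-1e-9, total_i=1e-8, ka=1e10), "total_a"),
        (dict(total_a=1e-8, total_i=-1e-9, ka=1e10), "total_i"),
        (dict(total_a=1e-8, total_i=1e-8, ka=-1.0), "ka"),
    ])
    def test_negative_inputs_name_the_argument(self, kwargs, name):
        with pytest.raises(ValueError, match=name):
            equilibrate_pair(**kwargs)

    @given(total_a=CONC, total_i=CONC, ka=KA)
    @settings(max_examples=200, deadline=None)
    def test_mass_balance_and_mass_action(self, total_a, total_i, ka):
        eq = equilibrate_pair(total_a, total_i, ka)
        assert eq.free_a >= 0 and eq.free_i >= 0 and eq.complex_ai >= 0
        assert eq.free_a + eq.complex_ai == pytest.approx(total_a, rel=1e-9)
        assert eq.free_i + eq.complex_ai == pytest.approx(total_i, rel=1e-9)
        assert eq.complex_ai == pytest.approx(
            ka * eq.free_a * eq.free_i, rel=1e-7)

    @given(total_a=CONC, total_i=CONC, ka=KA)
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence(self, total_a, total_i, ka):
        eq = equilibrate_pair(total_a, total_i, ka)
        assert eq.complex_ai == pytest.approx(
            bisect_pair_oracle(total_a, total_i, ka), rel=1e-7, abs=1e-30)

    @given(total_a=CONC, total_i=CONC, ka=KA)
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, total_a, total_i, ka):
        fwd = equilibrate_pair(total_a, total_i, ka)
        rev = equilibrate_pair(total_i, total_a, ka)
        assert fwd.complex_ai == pytest.approx(rev.complex_ai, rel=1e-12)
        assert fwd.free_a == pytest.approx(rev.free_i, rel=1e-12)
        assert fwd.free_i == pytest.approx(rev.free_a, rel=1e-12)

    @given(total_a=CONC, total_i=CONC, ka=KA, bump=st.floats(1.1, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, total_a, total_i, ka, bump):
        base = equilibrate_pair(total_a, total_i, ka)
        assert equilibrate_pair(total_a, total_i, ka * bump).complex_ai >= \
            base.complex_ai * (1 - 1e-12)
        assert equilibrate_pair(total_a * bump, total_i, ka).complex_ai >= \
            base.complex_ai * (1 - 1e-12)
        more_i = equilibrate_pair(total_a, total_i * bump, ka)
        assert more_i.complex_ai >= base.complex_ai * (1 - 1e-12)
        assert more_i.free_a <= base.free_a * (1 + 1e-12)

    @given(total_a=CONC, total_i=CONC)
    @settings(max_examples=50, deadline=None)
    def test_saturation_limit(self, total_a, total_i):
        eq = equilibrate_pair(total_a, total_i, 1e16)
        assert eq.complex_ai == pytest.approx(
            min(total_a, total_i), rel=1e-4)

    def test_large_ka_stability(self):
        # the naive quadratic root would lose all digits here
        eq = equilibrate_pair(1e-9, 2e-9, 1e15)
        assert eq.complex_ai == pytest.approx(
            bisect_pair_oracle(1e-9, 2e-9, 1e15), rel=1e-7)


class TestEquilibrateWithAnalog:
    def test_zero_analog_reduces_to_pair(self, analog_system):
        eq = equilibrate_with_analog(1e-8, 1e-8, 0.0, analog_system)
        base = equilibrate_pair(1e-8, 1e-8, 1e10)
        assert eq.complex_ai == pytest.approx(base.complex_ai, rel=1e-12)
        assert eq.complex_di == 0.0

    def test_non_binding_analog(self):
        system = BindingSystem(ka=1e10, ka_analog=0.0)
        eq = equilibrate_with_analog(0.0, 1e-8, 1e-8, system)
        assert eq.complex_ai == 0.0
        assert eq.complex_di == 0.0
        assert eq.free_analog == 1e-8

    def test_weak_analog_worked_case(self, analog_system):
        """The analog barely competes: complex_di << complex_ai and the
        analog stays proportionally much freer than species a."""
        eq = equilibrate_with_analog(1e-8, 1e-8, 1e-8, analog_system)
        c_ai, c_di = grid_oracle_analog(1e-8, 1e-8, 1e-8, 1e10, 1e7)
        assert eq.complex_ai == pytest.approx(c_ai, rel=1e-4)
        assert eq.complex_di == pytest.approx(c_di, rel=1e-3)
        assert eq.complex_di < 0.05 * eq.complex_ai
        assert eq.free_analog / 1e-8 > eq.free_a / 1e-8

    @given(total_a=CONC, total_i=CONC, total_d=CONC,
           ka=KA, kd=st.floats(min_value=1e4, max_value=1e9))
    @settings(max_examples=100, deadline=None)
    def test_mass_balance_and_mass_action(self, total_a, total_i, total_d,
                                          ka, kd):
        system = BindingSystem(ka=ka, ka_analog=kd)
        eq = equilibrate_with_analog(total_a, total_i, total_d, system)
        assert eq.free_a + eq.complex_ai == pytest.approx(total_a, rel=1e-9)
        assert eq.free_i + eq.complex_ai + eq.complex_di == pytest.approx(
            total_i, rel=1e-9)
        assert eq.free_analog + eq.complex_di == pytest.approx(
            total_d, rel=1e-9)
        assert eq.complex_ai == pytest.approx(
            ka * eq.free_a * eq.free_i, rel=1e-7, abs=1e-25)
        assert eq.complex_di == pytest.approx(
            kd * eq.free_analog * eq.free_i, rel=1e-7, abs=1e-25)

    def test_target_a_orientation(self):
        """With the analog targeting species a, the roles swap exactly."""
        fwd = equilibrate_with_analog(
            1e-8, 2e-8, 5e-9, BindingSystem(ka=1e10, ka_analog=1e7,
                                            analog_target="i"))
        rev = equilibrate_with_analog(
            2e-8, 1e-8, 5e-9, BindingSystem(ka=1e10, ka_analog=1e7,
                                            analog_target="a"))
        assert rev.free_a == pytest.approx(fwd.free_i, rel=1e-10)
        assert rev.free_i == pytest.approx(fwd.free_a, rel=1e-10)
        assert rev.complex_ai == pytest.approx(fwd.complex_ai, rel=1e-10)
        assert rev.complex_di == pytest.approx(fwd.complex_di, rel=1e-10)

    def test_negative_input_rejected(self, analog_system):
        with pytest.raises(ValueError, match="total_analog"):
            equilibrate_with_analog(1e-8, 1e-8, -1e-9, analog_system)


class TestBindingSystem:
    def test_ka_must_be_positive(self):
        with pytest.raises(ValueError, match="ka"):
            BindingSystem(ka=0.0)

    def test_analog_mimics_the_non_target(self):
        assert BindingSystem(ka=1e10, analog_target="i").analog_mimics == "a"
        assert BindingSystem(ka=1e10, analog_target="a").analog_mimics == "i"


class TestDiscretizeLevel:
    @pytest.mark.parametrize("conc,expected", [
        (0.0, "Lo"),
        (1e-10, "Mid"),      # boundary value lands in the upper bin
        (5e-9, "Mid"),
        (1e-8, "Hi"),
        (2e-8, "Hi"),
    ])
    def test_examples(self, conc, expected):
        assert discretize_level(conc, 1e-10, 1e-8) == expected

    def test_negative_conc_rejected(self):
        with pytest.raises(ValueError, match="conc"):
            discretize_level(-1e-9, 1e-10, 1e-8)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            discretize_level(1e-9, 1e-8, 1e-8)

    @given(conc=st.floats(0, 1e-6), lo=st.floats(1e-12, 1e-8),
           scale=st.floats(1.5, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_total_and_ordered(self, conc, lo, scale):
        level = discretize_level(conc, lo, lo * scale)
        if conc < lo:
            assert level == "Lo"
        elif conc >= lo * scale:
            assert level == "Hi"
        else:
            assert level == "Mid"
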