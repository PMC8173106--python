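"""Forward models for two-site exchange: limits, symmetries, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allokit.exchange import (
    ExchangeParams,
    FieldContext,
    delta_omega_rad,
    r2eff_bloch_mcconnell,
    r2eff_carver_richards,
    r2eff_fast_limit,
)

NU = np.arange(25.0, 1001.0, 25.0)


class TestDeltaOmega:
    def test_zero_shift_gives_zero(self, field_900):
        p = ExchangeParams(10.0, 1000.0, 0.05, 0.0)
        assert delta_omega_rad(p, field_900) == 0.0

    def test_one_ppm_at_900(self, field_900):
        p = ExchangeParams(10.0, 1000.0, 0.05, 1.0)
        assert delta_omega_rad(p, field_900) == pytest.approx(
            2 * math.pi * 91.1961, rel=1e-6
        )

    def test_linearity_in_shift_and_field(self, field_900, field_600):
        p1 = ExchangeParams(10.0, 1000.0, 0.05, 1.0)
        p2 = ExchangeParams(10.0, 1000.0, 0.05, 2.0)
        ratio = delta_omega_rad(p2, field_600) / delta_omega_rad(p1, field_900)
        assert ratio == pytest.approx(2 * 600 / 900, rel=1e-12)

    def test_invalid_field_rejected(self):
        with pytest.raises(ValueError):
            FieldContext(-900.0)
        with pytest.raises(ValueError):
            FieldContext(900.0, t_relax=0.0)


class TestCarverRichards:
    def test_no_minor_state_is_flat(self, field_900):
        p = ExchangeParams(10.0, 1500.0, 0.0, 2.0)
        assert np.allclose(r2eff_carver_richards(p, NU, field_900), 10.0)

    def test_degenerate_states_are_flat(self, field_900):
        p = ExchangeParams(10.0, 1500.0, 0.05, 0.0)
        assert np.allclose(r2eff_carver_richards(p, NU, field_900), 10.0)

    def test_agrees_with_propagator_at_50hz(self, field_900):
        """The closed form matches the numerical oracle within 1%."""
        p = ExchangeParams(10.0, 1500.0, 0.05, 2.0)
        cr = r2eff_carver_richards(p, 50.0, field_900)
        bm = r2eff_bloch_mcconnell(p, 50.0, field_900)
        assert cr == pytest.approx(bm, rel=0.01)

    def test_monotone_nonincreasing_in_nu(self, field_900):
        for kex in (500.0, 1500.0, 6000.0):
            for pb in (0.02, 0.1):
                p = ExchangeParams(10.0, kex, pb, 2.0)
                r2 = r2eff_carver_richards(p, NU, field_900)
                assert np.all(np.diff(r2) <= 1e-9)

    def test_state_swap_symmetry(self, field_900):
        a = ExchangeParams(10.0, 800.0, 0.1, 2.0, r2_0_b=14.0)
        b = ExchangeParams(14.0, 800.0, 0.9, 2.0, r2_0_b=10.0)
        ra = r2eff_carver_richards(a, NU, field_900)
        rb = r2eff_carver_richards(b, NU, field_900)
        assert np.allclose(ra, rb, rtol=1e-9)

    def test_no_overflow_at_extreme_rates(self, field_900):
        p = ExchangeParams(10.0, 9.9e4, 0.3, 14.0)
        r2 = r2eff_carver_richards(p, np.array([1.0, 25.0, 1000.0]), field_900)
        assert np.all(np.isfinite(r2))

    def test_rejects_nonpositive_nu(self, field_900):
        p = ExchangeParams(10.0, 1500.0, 0.05, 2.0)
        with pytest.raises(ValueError):
            r2eff_carver_richards(p, 0.0, field_900)


class TestFastLimit:
    def test_low_nu_plateau(self, field_900):
        p = ExchangeParams(10.0, 5000.0, 0.05, 1.0)
        dw = delta_omega_rad(p, field_900)
        rex0 = p.p_a * p.p_b * dw**2 / p.kex
        assert r2eff_fast_limit(p, 1e-4, field_900) == pytest.approx(
            10.0 + rex0, rel=1e-6
        )

    def test_high_nu_returns_intrinsic_rate(self, field_900):
        p = ExchangeParams(10.0, 5000.0, 0.05, 1.0)
        assert r2eff_fast_limit(p, 1e7, field_900) == pytest.approx(10.0, rel=1e-6)

    def test_monotone_nonincreasing(self, field_900):
        p = ExchangeParams(10.0, 4000.0, 0.05, 1.5)
        r2 = r2eff_fast_limit(p, NU, field_900)
        assert np.all(np.diff(r2) <= 0)

    def test_agrees_with_full_form_in_fast_regime(self, field_900):
        """Luz-Meiboom within 2% of Carver-Richards when kex >= 10 dw (rad/s)."""
        for dw_ppm in (0.5, 1.0):
            for pb in (0.02, 0.05, 0.1):
                p = ExchangeParams(10.0, 1.0, pb, dw_ppm)
                kex = 10.0 * delta_omega_rad(p, field_900)
                p = ExchangeParams(10.0, kex, pb, dw_ppm)
                full = r2eff_carver_richards(p, NU, field_900)
                fast = r2eff_fast_limit(p, NU, field_900)
                assert np.all(np.abs(fast - full) / full <= 0.02)

    def test_undefined_without_exchange(self, field_900):
        p = ExchangeParams(10.0, 0.0, 0.05, 1.0)
        with pytest.raises(ValueError):
            r2eff_fast_limit(p, 50.0, field_900)


class TestBlochMcConnell:
    def test_pure_decay_exact(self, field_900):
        p = ExchangeParams(12.0, 1500.0, 0.0, 2.0)
        r2 = r2eff_bloch_mcconnell(p, NU, field_900)
        assert np.allclose(r2, 12.0, atol=1e-10)

    def test_high_nu_approaches_fast_plateau(self, field_900):
        p = ExchangeParams(10.0, 1500.0, 0.05, 1.0)
        nu = 15000.0  # >= 10 kex and >= 10 dw/2pi
        bm = r2eff_bloch_mcconnell(p, nu, field_900)
        fl = r2eff_fast_limit(p, nu, field_900)
        assert abs(bm - fl) < 0.2

    def test_echo_count_rounding_reported(self, field_900):
        p = ExchangeParams(10.0, 1500.0, 0.05, 2.0)
        _, eff = r2eff_bloch_mcconnell(p, 60.0, field_900, return_effective_nu=True)
        # 2 * 60 * 0.04 = 4.8 -> 4 echoes -> 50 Hz effective
        assert eff == pytest.approx(50.0)

    def test_rejects_grid_without_complete_echo(self, field_900):
        p = ExchangeParams(10.0, 1500.0, 0.05, 2.0)
        with pytest.raises(ValueError):
            r2eff_bloch_mcconnell(p, 5.0, field_900)  # < 1 echo in 40 ms

    def test_closed_form_equals_asymptotic_rate_everywhere(self, field_900):
        """The closed form is the exact eigenmode decay rate of the propagator."""
        for kex in (200.0, 500.0, 1500.0, 6000.0):
            for pb in (0.01, 0.1):
                for dw in (0.5, 2.0, 4.0):
                    p = ExchangeParams(10.0, kex, pb, dw)
                    cr = r2eff_carver_richards(p, NU, field_900)
                    bm = r2eff_bloch_mcconnell(p, NU, field_900, measure="asymptotic")
                    assert np.allclose(cr, bm, atol=1e-8)

    def test_finite_time_agreement_where_exchange_not_slow(self, field_900):
        """CT-experiment measure within max(1%, 0.2/s) for intermediate-to-fast
        exchange with a sparse minor state (kex >= 2 dw rad/s, p_b <= 0.05);
        slower exchange picks up a projection-amplitude term the asymptotic
        closed form does not describe."""
        for kex in (500.0, 1000.0, 1500.0, 3000.0, 6000.0):
            for pb in (0.01, 0.02, 0.05):
                for dw in (0.5, 1.0, 2.0, 4.0):
                    p = ExchangeParams(10.0, kex, pb, dw)
                    if kex < 2.0 * delta_omega_rad(p, field_900):
                        continue
                    cr = r2eff_carver_richards(p, NU, field_900)
                    bm = r2eff_bloch_mcconnell(p, NU, field_900)
                    tol = np.maximum(0.01 * np.abs(bm), 0.2)
                    assert np.all(np.abs(cr - bm) <= tol), (kex, pb, dw)

    def test_rex_scales_quadratically_with_dw_in_fast_limit(self, field_900):
        kex = 20000.0
        rex = []
        for dw in (0.5, 1.0, 2.0):
            p = ExchangeParams(10.0, kex, 0.05, dw)
            r_low = r2eff_bloch_mcconnell(p, 25.0, field_900)
            r_high = r2eff_bloch_mcconnell(p, 1000.0, field_900)
            rex.append(r_low - r_high)
        assert rex[1] / rex[0] == pytest.approx(4.0, rel=0.05)
        assert rex[2] / rex[1] == pytest.approx(4.0, rel=0.05)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    kex=st.floats(200.0, 6000.0),
    pb=st.floats(0.005, 0.1),
    dw=st.floats(0.2, 4.0),
    r2_0=st.floats(5.0, 30.0),
)
def test_r2eff_bounded_and_finite(kex, pb, dw, r2_0):
    """R2eff stays finite, non-negative and at least the population-weighted
    intrinsic rate minus numerical slack, for any plausible parameter set."""
    f = FieldContext(900.0)
    p = ExchangeParams(r2_0, kex, pb, dw)
    r2 = r2eff_carver_richards(p, NU, f)
    assert np.all(np.isfinite(r2))
    assert np.all(r2 >= 0.0)
    assert np.all(r2 >= r2_0 - 0.05 * r2_0)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        ExchangeParams(10.0, -1.0, 0.05, 1.0)
    with pytest.raises(ValueError):
        ExchangeParams(10.0, 1000.0, 1.2, 1.0)
    with pytest.raises(ValueError):
        ExchangeParams(-1.0, 1000.0, 0.05, 1.0)
    with pytest.raises(ValueError):
        ExchangeParams(10.0, 1000.0, 0.05, -1.0)
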