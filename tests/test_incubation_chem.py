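"""Alkalinity-anomaly arithmetic, blank handling, and the carbonate solver."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from barct.incubation_chem import (
    CarbonateState,
    IncubationRecord,
    blank_correct,
    calcification_rate,
    carbonate_constants,
    chamber_rates,
    frame_to_records,
    net_daily_calcification,
    oxygen_flux,
    rates_table,
    records_to_frame,
    solve_carbonate_system,
)
from barct.synthetic_data import make_incubation_set


class TestBlankCorrect:
    def test_subtracts_mean_blank(self):
        assert blank_correct(-20.0, -5.0) == pytest.approx(-15.0)
        assert blank_correct(-5.0, [-4.0, -6.0]) == pytest.approx(0.0)
        assert blank_correct(-20.0, [-4.0, -6.0]) == pytest.approx(-20.0 - (-5.0))

    def test_no_blanks_is_an_error(self):
        with pytest.raises(ValueError):
            blank_correct(-20.0, [])


class TestCalcificationRate:
    def test_zero_delta_gives_zero(self):
        assert calcification_rate(0.0, 0.656, 30.0, 1.3333) == 0.0

    def test_hand_computed_oracle(self):
        # (20/2 · 0.656) / (30 · 1.3333) µmol CaCO₃ cm⁻² h⁻¹
        g = calcification_rate(-20.0, 0.656, 30.0, 1.3333)
        assert g == pytest.approx((20.0 / 2.0) * 0.656 / (30.0 * 1.3333), rel=1e-9)
        assert g == pytest.approx(0.164, abs=5e-4)

    def test_sign_flip_is_exact(self):
        g = calcification_rate(-20.0, 0.656, 30.0, 1.3333)
        assert calcification_rate(20.0, 0.656, 30.0, 1.3333) == -g

    def test_zero_surface_area_rejected(self):
        with pytest.raises(ValueError):
            calcification_rate(-20.0, 0.656, 0.0, 1.3333)


class TestOxygenFlux:
    def test_hand_computed_oracle(self):
        # 1 mg L⁻¹ in the 0.640 l chamber over 80 min on 30 cm² = 640/2400
        f = oxygen_flux(1.0, 0.640, 30.0, 80.0)
        assert f == pytest.approx(640.0 / 2400.0, rel=1e-9)
        assert f == pytest.approx(0.2667, abs=5e-5)

    def test_zero_delta_gives_zero(self):
        assert oxygen_flux(0.0, 0.640, 30.0, 80.0) == 0.0

    @given(scale=st.floats(0.1, 10.0))
    def test_linearity_in_volume_and_delta(self, scale):
        base = oxygen_flux(1.0, 0.640, 30.0, 80.0)
        assert oxygen_flux(1.0, 0.640 * scale, 30.0, 80.0) == pytest.approx(base * scale)
        assert oxygen_flux(scale, 0.640, 30.0, 80.0) == pytest.approx(base * scale)


class TestNetDaily:
    def test_equal_rates_pass_through(self):
        assert net_daily_calcification(0.3, 0.3) == pytest.approx(0.3)

    def test_11_13_weighting(self):
        assert net_daily_calcification(0.5, -0.5) == pytest.approx((5.5 - 6.5) / 24.0)
        assert net_daily_calcification(0.5, -0.5) == pytest.approx(-0.0417, abs=5e-5)

    def test_constructed_balance_point(self):
        assert net_daily_calcification(13.0, -11.0) == pytest.approx(0.0, abs=1e-12)


class TestChamberRates:
    def test_missing_blanks_for_phase_is_an_error(self):
        recs = [r for r in make_incubation_set(0.4, -0.2, 0.8, 0.5) if not (r.is_blank and r.phase == "dark")]
        with pytest.raises(ValueError, match="blank"):
            chamber_rates(recs)

    def test_g24_bounded_by_light_and_dark(self):
        for seed in range(5):
            cr = chamber_rates(make_incubation_set(0.4, -0.2, 0.8, 0.5, noise_sd=3.0, seed=seed))
            lo, hi = sorted((cr.g_light, cr.g_dark))
            assert lo <= cr.g_24h <= hi

    def test_rates_scale_linearly_with_delta(self):
        a = chamber_rates(make_incubation_set(0.2, -0.1, 0.4, 0.3))
        b = chamber_rates(make_incubation_set(0.4, -0.2, 0.8, 0.6))
        assert b.g_light == pytest.approx(2 * a.g_light)
        assert b.g_dark == pytest.approx(2 * a.g_dark)
        assert b.p_net == pytest.approx(2 * a.p_net)
        assert b.r_dark == pytest.approx(2 * a.r_dark)

    def test_record_frame_roundtrip(self, tmp_path):
        recs = make_incubation_set(0.4, -0.2, 0.8, 0.5, treatment_ph=7.7)
        df = records_to_frame(recs)
        path = tmp_path / "records.csv"
        df.to_csv(path, index=False)
        back = frame_to_records(pd.read_csv(path))
        a, b = chamber_rates(back), chamber_rates(recs)
        for field in ("g_light", "g_dark", "g_24h", "p_net", "r_dark"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-9)

    def test_rates_table_many_chambers(self):
        recs = []
        for i, ph in enumerate((7.6, 7.9)):
            recs += make_incubation_set(
                0.1 * i, -0.05, 0.4, 0.3, treatment_ph=ph, chamber_prefix=f"bar{i}", seed=i
            )
        table = rates_table(recs)
        assert len(table) == 2
        assert set(table.bar_id) == {"bar0", "bar1"}

    def test_record_validation(self):
        with pytest.raises(ValueError):
            IncubationRecord("c", False, "light", 2300, 2290, 6, 7, 0.64, 80.0, None)
        with pytest.raises(ValueError):
            IncubationRecord("c", False, "dusk", 2300, 2290, 6, 7, 0.64, 80.0, 30.0)


# ---------------------------------------------------------------------------
# carbonate system


def _ph_polynomial_oracle(a_t, dic, t_c, s):
    """Independent route: clear denominators of the alkalinity balance and
    solve the degree-5 polynomial in [H+] by companion-matrix roots."""
    k = carbonate_constants(t_c, s)
    AT, C = a_t * 1e-6, dic * 1e-6
    K1, K2, KB, KW, TB = k["K1"], k["K2"], k["KB"], k["KW"], k["TB"]
    D = np.poly1d([1.0, K1, K1 * K2])          # h² + K1 h + K1K2
    B = np.poly1d([1.0, KB])                   # h + KB
    h = np.poly1d([1.0, 0.0])
    P = (
        (C * np.poly1d([K1, 2 * K1 * K2]) - AT * D) * B * h
        + TB * KB * D * h
        + KW * D * B
        - D * B * np.poly1d([1.0, 0.0, 0.0])
    )
    roots = np.roots(P.coeffs)
    real = roots[np.abs(roots.imag) < 1e-20 * (1 + np.abs(roots.real))].real
    real = real[(real > 1e-12) & (real < 1e-2)]
    assert len(real) >= 1
    return float(-np.log10(real.min()))


def carbonate_oracle_state(a_t, dic, t_c, s):
    """Full reference state (pH, pCO₂ µatm, Ω_arag) from the polynomial root."""
    k = carbonate_constants(t_c, s)
    h = 10.0 ** (-_ph_polynomial_oracle(a_t, dic, t_c, s))
    C = dic * 1e-6
    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    co2_star = C * h * h / denom
    co3 = C * k["K1"] * k["K2"] / denom
    return (
        -np.log10(h),
        co2_star / k["K0"] * 1e6,
        k["Ca"] * co3 / k["Ksp_arag"],
    )


REFERENCE_STATES = [
    # (A_T, DIC, T °C, S) spanning the field gradient and the chamber range
    (2300.0, 1900.0, 29.0, 35.0),
    (2300.0, 2000.0, 29.0, 35.0),
    (2300.0, 2100.0, 29.0, 35.0),
    (2300.0, 2200.0, 29.0, 35.0),
    (2250.0, 2050.0, 28.0, 34.0),
    (2350.0, 2150.0, 30.0, 35.5),
    (2400.0, 2250.0, 29.5, 36.0),
    (2200.0, 1950.0, 27.0, 33.0),
    (2300.0, 2150.0, 25.0, 35.0),
    (2320.0, 2080.0, 31.0, 34.5),
]


class TestCarbonateSystem:
    @pytest.mark.parametrize("at,dic,t,s", REFERENCE_STATES)
    def test_ph_agrees_with_polynomial_route(self, at, dic, t, s):
        state = solve_carbonate_system(at, dic, t, s)
        assert state.ph_total == pytest.approx(_ph_polynomial_oracle(at, dic, t, s), abs=1e-8)
        assert 6.0 < state.ph_total < 9.0

    def test_dic_increase_lowers_ph(self):
        phs = [solve_carbonate_system(2300, dic, 29, 35).ph_total for dic in (1900, 2000, 2100, 2200)]
        assert np.all(np.diff(phs) < 0)

    def test_omega_proportional_to_carbonate_ion(self):
        states = [solve_carbonate_system(2300, dic, 29, 35) for dic in (1900, 2050, 2200)]
        ratios = [s.omega_arag / s.co3 for s in states]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_carbonate_system(2300, 2000, 29, 10.0)
        with pytest.raises(ValueError):
            solve_carbonate_system(2300, 2000, 50.0, 35)
        with pytest.raises(ValueError):
            solve_carbonate_system(-5.0, 2000, 29, 35)

    def test_state_requires_positive_omega(self):
        with pytest.raises(ValueError):
            CarbonateState(8.0, 2300, 2000, 400, -0.1, 200, 29, 35)

    def test_vent_gradient_is_monotone_in_pco2(self):
        states = [solve_carbonate_system(2300, dic, 29, 35) for dic in (1900, 2050, 2200)]
        assert states[0].pco2 < states[1].pco2 < states[2].pco2
        assert states[0].omega_arag > states[2].omega_arag
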