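"""Closed-form thermodynamic relations of the two-state gating model."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermogate as tg
from thermogate import GatingParams, R
from thermogate.constants import F

# Random but physically sensible parameter sets: entropies 20-400 R of either
# sign, midpoints across the biologically relevant range.
valid_params = st.builds(
    GatingParams,
    delta_S=st.one_of(
        st.floats(20.0 * R, 400.0 * R),
        st.floats(-400.0 * R, -20.0 * R),
    ),
    T_half=st.floats(250.0, 350.0),
)


class TestFreeEnergy:
    def test_zero_at_midpoint(self, canonical_params):
        assert tg.conformational_free_energy(canonical_params, 313.15) == 0.0

    @pytest.mark.parametrize(
        "delta_S_in_R, T_half, T, expected",
        [
            (125.0, 313.15, 318.15, 125.0 * R * (-5.0)),  # ~ -5196.5 J/mol
            (-125.0, 300.0, 290.0, -125.0 * R * 10.0),  # type-II opens on cooling
        ],
    )
    def test_hand_evaluated_values(self, delta_S_in_R, T_half, T, expected):
        params = GatingParams(delta_S=delta_S_in_R * R, T_half=T_half)
        assert tg.conformational_free_energy(params, T) == pytest.approx(expected, rel=1e-12)

    def test_equals_general_form(self, canonical_params):
        # dS*(T_half - T) must equal dH - T*dS with dH = T_half*dS
        for T in (280.0, 313.15, 340.0):
            via_enthalpy = tg.enthalpy(canonical_params) - T * canonical_params.delta_S
            assert tg.conformational_free_energy(canonical_params, T) == pytest.approx(
                via_enthalpy, rel=1e-12
            )

    def test_rejects_nonpositive_temperature(self, canonical_params):
        with pytest.raises(ValueError, match="positive"):
            tg.conformational_free_energy(canonical_params, 0.0)
        with pytest.raises(ValueError, match="positive"):
            tg.open_probability(canonical_params, -5.0)


class TestOpenProbability:
    @pytest.mark.parametrize(
        "T, expected, tol",
        [
            (313.15, 0.5, 1e-14),
            (318.15, 0.8770172071405545, 1e-12),
            (308.15, 0.11627036066081632, 1e-12),
        ],
    )
    def test_canonical_curve_points(self, canonical_params, T, expected, tol):
        assert tg.open_probability(canonical_params, T) == pytest.approx(expected, abs=tol)

    @settings(deadline=None, derandomize=True)
    @given(params=valid_params)
    def test_midpoint_is_half(self, params):
        assert abs(tg.open_probability(params, params.T_half) - 0.5) <= 1e-14

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(params=valid_params)
    def test_restated_form_matches_boltzmann_of_free_energy(self, params):
        """The reparameterized curve equals the Boltzmann factor of dG_C."""
        T = np.linspace(max(params.T_half - 50.0, 1.0), params.T_half + 50.0, 1000)
        direct = tg.open_probability(params, T)
        dG = tg.conformational_free_energy(params, T)
        composed = 1.0 / (1.0 + np.exp(np.clip(dG / (R * T), -700, 700)))
        np.testing.assert_allclose(direct, composed, rtol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(params=valid_params)
    def test_strictly_monotone_in_temperature(self, params):
        # Strict monotonicity where the curve is resolvable in float64
        # (within +/-1.5 rise widths of the midpoint, p in ~[0.003, 0.997]),
        # non-strict on a much wider grid where the plateaus saturate.
        half_span = 1.5 * tg.linear_rise_width(params)
        T = np.linspace(max(params.T_half - half_span, 1.0), params.T_half + half_span, 400)
        p = np.asarray(tg.open_probability(params, T))
        wide = np.linspace(max(params.T_half - 200.0, 1.0), params.T_half + 200.0, 400)
        p_wide = np.asarray(tg.open_probability(params, wide))
        if params.delta_S > 0:
            assert np.all(np.diff(p) > 0)
            assert np.all(np.diff(p_wide) >= 0)
        else:
            assert np.all(np.diff(p) < 0)
            assert np.all(np.diff(p_wide) <= 0)

    def test_saturation_limits(self):
        # High-T plateau is 1/(1+exp(-dS/R)), not exactly 1; low-T limit is 0.
        for ds_in_R in (3.0, 10.0, 125.0):
            params = GatingParams(delta_S=ds_in_R * R, T_half=313.15)
            plateau = 1.0 / (1.0 + math.exp(-ds_in_R))
            assert tg.open_probability(params, 1e12) == pytest.approx(plateau, rel=1e-9)
            assert tg.open_probability(params, 1e-6) < 1e-300  # -> 0 as T -> 0+

    def test_extreme_arguments_saturate_without_overflow(self):
        params = GatingParams(delta_S=5000.0 * R, T_half=313.15)
        with np.errstate(over="raise"):
            lo = tg.open_probability(params, 1.0)
            hi = tg.open_probability(params, 10000.0)
        assert 0.0 <= lo < 1e-300  # exponent clipped at +700
        assert 0.0 < hi <= 1.0

    @pytest.mark.parametrize("delta", [0.5, 2.0, 5.0])
    def test_near_symmetry_about_midpoint(self, canonical_params, delta):
        """P(T_half+d) + P(T_half-d) - 1 is small but nonzero: the T in the
        exponent's denominator skews the curve toward lower temperatures."""
        excess = (
            tg.open_probability(canonical_params, canonical_params.T_half + delta)
            + tg.open_probability(canonical_params, canonical_params.T_half - delta)
            - 1.0
        )
        assert excess < 0  # heat-activated curve loses more on the cold side
        assert 0 < abs(excess) < delta / canonical_params.T_half


class TestGeneralForm:
    def test_zero_free_energy_gives_half(self):
        assert tg.open_probability_general(0.0, 0.0, 300.0) == 0.5

    def test_midpoint_from_enthalpy_entropy_ratio(self):
        # dH/dS = 313.19 K, so P at 313.15 K sits ~0.004 below 0.5
        dH, dS = 325.5e3, 125.0 * R
        p = tg.open_probability_general(dH, dS, 313.15)
        assert p == pytest.approx(0.5, abs=5e-3)
        assert p == pytest.approx(0.4960870, abs=1e-6)
        assert tg.open_probability_general(dH, dS, dH / dS) == pytest.approx(0.5, abs=1e-14)

    def test_pure_enthalpy_penalty(self):
        expected = 1.0 / (1.0 + math.exp(10000.0 / (R * 300.0)))
        assert tg.open_probability_general(10e3, 0.0, 300.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0178, abs=2e-4)

    @settings(deadline=None, derandomize=True)
    @given(params=valid_params, T=st.floats(260.0, 340.0))
    def test_agrees_with_midpoint_parameterization(self, params, T):
        general = tg.open_probability_general(tg.enthalpy(params), params.delta_S, T)
        assert general == pytest.approx(tg.open_probability(params, T), rel=1e-12)


class TestDerivedQuantities:
    def test_enthalpy_is_125_RT_half_for_canonical_entropy(self, canonical_params):
        dH = tg.enthalpy(canonical_params)
        assert dH / (R * canonical_params.T_half) == pytest.approx(125.0, rel=1e-14)
        assert dH == pytest.approx(325.45e3, rel=1e-3)

    def test_enthalpy_sign_follows_entropy(self):
        params = GatingParams(delta_S=-100.0 * R, T_half=300.0)
        assert tg.enthalpy(params) == pytest.approx(-100.0 * R * 300.0, rel=1e-14)

    def test_midpoint_slope_closed_form_and_numeric(self, canonical_params):
        slope = tg.slope_at_midpoint(canonical_params)
        assert slope == pytest.approx(125.0 / (4.0 * 313.15), rel=1e-12)
        h = 1e-4
        numeric = (
            tg.open_probability(canonical_params, canonical_params.T_half + h)
            - tg.open_probability(canonical_params, canonical_params.T_half - h)
        ) / (2.0 * h)
        assert slope == pytest.approx(numeric, rel=1e-8)

    @settings(deadline=None, derandomize=True)
    @given(params=valid_params)
    def test_midpoint_slope_matches_central_difference(self, params):
        h = params.T_half * 1e-6
        numeric = (
            tg.open_probability(params, params.T_half + h)
            - tg.open_probability(params, params.T_half - h)
        ) / (2.0 * h)
        assert tg.slope_at_midpoint(params) == pytest.approx(numeric, rel=1e-6)

    def test_cold_channel_has_negative_slope(self, cold_params):
        assert tg.slope_at_midpoint(cold_params) < 0

    def test_linearized_rise_spans_unity_over_ten_kelvin(self, canonical_params):
        # slope at the midpoint times a 10 K span carries P across ~the full range
        assert tg.slope_at_midpoint(canonical_params) * 10.0 == pytest.approx(0.998, abs=1e-3)

    def test_rise_width_canonical_and_scaling(self, canonical_params):
        width = tg.linear_rise_width(canonical_params)
        assert width == pytest.approx(10.02, abs=5e-3)
        steeper = GatingParams(delta_S=250.0 * R, T_half=313.15)
        assert tg.linear_rise_width(steeper) == pytest.approx(width / 2.0, rel=1e-12)

    @pytest.mark.parametrize(
        "T_half, delta_T, expected_in_R",
        [(313.0, 10.0, 125.2), (313.0, 5.0, 250.4), (300.0, 10.0, 120.0)],
    )
    def test_entropy_from_width_values(self, T_half, delta_T, expected_in_R):
        assert tg.entropy_from_width(T_half, delta_T) / R == pytest.approx(
            expected_in_R, rel=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(params=valid_params)
    def test_width_entropy_round_trip(self, params):
        recovered = tg.entropy_from_width(params.T_half, tg.linear_rise_width(params))
        assert recovered == pytest.approx(abs(params.delta_S), rel=1e-12)

    def test_entropy_from_width_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tg.entropy_from_width(-300.0, 10.0)
        with pytest.raises(ValueError):
            tg.entropy_from_width(300.0, 0.0)


class TestMutationDesign:
    def test_ten_kelvin_downshift_costs_four_RT(self, canonical_params):
        shift = tg.delta_enthalpy_for_shift(canonical_params, 303.15)
        assert shift.ddH == pytest.approx(125.0 * R * (-10.0), rel=1e-12)  # ~ -10.39 kJ/mol
        assert abs(shift.ddH_in_RT) == pytest.approx(3.992, abs=1e-3)

    def test_no_shift_no_enthalpy_change(self, canonical_params):
        assert tg.delta_enthalpy_for_shift(canonical_params, 313.15).ddH == 0.0

    def test_rejects_nonpositive_target(self, canonical_params):
        with pytest.raises(ValueError):
            tg.delta_enthalpy_for_shift(canonical_params, 0.0)


class TestThresholdTemperature:
    def test_midpoint_probability_returns_T_half(self, canonical_params):
        assert tg.threshold_temperature(canonical_params, 0.5) == pytest.approx(
            313.15, abs=1e-12
        )

    def test_default_threshold_value(self, canonical_params):
        assert tg.threshold_temperature(canonical_params, 0.05) == pytest.approx(305.94, abs=5e-3)

    @settings(deadline=None, derandomize=True)
    @given(params=valid_params, p=st.floats(0.02, 0.95))
    def test_round_trip_with_open_probability(self, params, p):
        try:
            T = tg.threshold_temperature(params, p)
        except tg.UnreachableProbabilityError:
            plateau = 1.0 / (1.0 + math.exp(-params.delta_S / R))
            assert (p >= plateau) if params.delta_S > 0 else (p <= plateau)
            return
        assert T > 0
        assert tg.open_probability(params, T) == pytest.approx(p, abs=1e-10)

    def test_unreachable_probability_is_an_error(self):
        shallow = GatingParams(delta_S=2.0 * R, T_half=313.15)  # plateau ~0.881
        with pytest.raises(tg.UnreachableProbabilityError, match="unreachable"):
            tg.threshold_temperature(shallow, 0.95)

    def test_rejects_probability_outside_unit_interval(self, canonical_params):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                tg.threshold_temperature(canonical_params, bad)


class TestClassification:
    @pytest.mark.parametrize(
        "delta_S_in_R, T_half, T_rest, entropy_class, temperature_class",
        [
            (125.0, 316.0, 310.0, "type-I", "hyperthermic"),  # TRPV1-like
            (-125.0, 299.0, 310.0, "type-II", "hypothermic"),  # TRPM8-like
            (125.0, 305.0, 310.0, "type-I", "hypothermic"),  # boundary combination
        ],
    )
    def test_labels(self, delta_S_in_R, T_half, T_rest, entropy_class, temperature_class):
        params = GatingParams(delta_S=delta_S_in_R * R, T_half=T_half)
        cls = tg.classify(params, T_rest)
        assert cls.entropy_class.value == entropy_class
        assert cls.temperature_class.value == temperature_class
        assert cls.T_rest == T_rest

    def test_rejects_nonpositive_resting_temperature(self, canonical_params):
        with pytest.raises(ValueError):
            tg.classify(canonical_params, -1.0)


class TestPolymodal:
    @pytest.fixture
    def voltage_params(self):
        return GatingParams(delta_S=125.0 * R, T_half=313.15, z=1.0, V_half=0.0)

    def test_both_terms_vanish_at_midpoints(self, voltage_params):
        assert tg.joint_open_probability(voltage_params, 313.15, 0.0) == 0.5

    def test_depolarization_opens_the_channel(self, voltage_params):
        expected = 1.0 / (1.0 + math.exp(-F * 0.1 / (R * 313.15)))
        p = tg.joint_open_probability(voltage_params, 313.15, 0.1)
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.976, abs=5e-4)

    def test_reduces_to_thermal_curve_at_midpoint_voltage(self, voltage_params):
        for T in (300.0, 313.15, 325.0):
            assert tg.joint_open_probability(voltage_params, T, 0.0) == tg.open_probability(
                voltage_params, T
            )

    def test_requires_voltage_parameters(self, canonical_params):
        with pytest.raises(ValueError, match="z and V_half"):
            tg.joint_open_probability(canonical_params, 313.15, 0.0)


class TestGatingParamsInvariants:
    def test_rejects_nonpositive_midpoint(self):
        with pytest.raises(ValueError):
            GatingParams(delta_S=125.0 * R, T_half=0.0)

    def test_rejects_zero_entropy(self):
        with pytest.raises(ValueError):
            GatingParams(delta_S=0.0, T_half=313.15)

    def test_voltage_fields_come_in_pairs(self):
        with pytest.raises(ValueError):
            GatingParams(delta_S=125.0 * R, T_half=313.15, z=1.0)
        with pytest.raises(ValueError):
            GatingParams(delta_S=125.0 * R, T_half=313.15, V_half=0.05)

    def test_entropy_reported_in_gas_constant_units(self, canonical_params):
        assert canonical_params.delta_S_in_R == pytest.approx(125.0, rel=1e-14)


class TestParameterFile:
    def test_loads_and_converts_to_si(self, tmp_path):
        path = tmp_path / "params.json"
        path.write_text(json.dumps({"delta_S_in_R": 125, "T_half_K": 313.15,
                                    "z": 1.0, "V_half_mV": 50.0}))
        params = tg.load_params(path)
        assert params.delta_S == pytest.approx(125.0 * R)
        assert params.T_half == 313.15
        assert params.V_half == pytest.approx(0.05)

    def test_missing_key_is_an_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"T_half_K": 313.15}))
        with pytest.raises(ValueError, match="delta_S_in_R"):
            tg.load_params(path)
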