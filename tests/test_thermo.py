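"""Energetics of AOM coupled to sulfate reduction: quotient, dG', regimes."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from aomlab.thermo import (
    EnergyThresholds,
    IncubationCondition,
    SolubilityParams,
    TABLE1_CONDITIONS,
    ThermoParams,
    UndefinedQuotientError,
    classify_energetic_regime,
    delta_g_prime,
    dissolved_methane,
    reaction_quotient,
)

conc = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


def make(sulfate, sulfide, methane, co2):
    return IncubationCondition("x", sulfate, sulfide, methane, co2)


class TestReactionQuotient:
    @pytest.mark.parametrize(
        "co2, sulfide, methane, sulfate, expected",
        [
            (1.0, 1.0, 1.0, 1.0, 1.0),
            (3.8, 0.4, 1.31, 21.6, 0.053718),  # (3.8*0.4)/(1.31*21.6)
            (6.9, 3.8, 1.31, 21.1, 0.948592),
        ],
    )
    def test_hand_arithmetic(self, co2, sulfide, methane, sulfate, expected):
        q = reaction_quotient(make(sulfate, sulfide, methane, co2))
        assert q == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize("zero_field", ["methane", "sulfate"])
    def test_zero_reactant_names_species(self, zero_field):
        kwargs = dict(sulfate=1.0, sulfide=1.0, methane=1.0, co2=1.0)
        kwargs[zero_field] = 0.0
        with pytest.raises(UndefinedQuotientError, match=zero_field):
            reaction_quotient(make(**kwargs))

    @settings(max_examples=200, derandomize=True)
    @given(s=conc, hs=conc, ch4=conc, co2=conc, k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, s, hs, ch4, co2, k):
        q1 = reaction_quotient(make(s, hs, ch4, co2))
        q2 = reaction_quotient(make(k * s, k * hs, k * ch4, k * co2))
        assert q2 == pytest.approx(q1, rel=1e-9)


class TestDeltaGPrime:
    # complete printed-value roster: five tabulated conditions plus the
    # two spot calculations for the no-methane controls
    @pytest.mark.parametrize(
        "sulfate, sulfide, methane, co2, expected",
        [
            (21.6, 0.4, 1.31, 3.8, -28.1),
            (21.1, 3.8, 1.31, 6.9, -21.1),
            (3.6, 0.4, 1.31, 4.4, -23.4),
            (4.0, 3.6, 1.31, 6.4, -17.4),
            (0.1, 0.1, 1.31, 2.7, -19.2),
            (21.6, 0.2, 0.2, 3.2, -25.7),  # sulfate-only at 0.2 mM CH4
            (0.4, 3.0, 1.31, 4.4, -13.1),  # sulfide-only at CH4 saturation
        ],
    )
    def test_printed_values(self, sulfate, sulfide, methane, co2, expected):
        dg = delta_g_prime(make(sulfate, sulfide, methane, co2))
        assert dg == pytest.approx(expected, abs=0.05)

    def test_q_one_returns_standard_value_exactly(self):
        assert delta_g_prime(make(2.0, 2.0, 2.0, 2.0)) == -21.0

    def test_incubation_temperature_option(self):
        cold = ThermoParams(temperature_K=288.15)
        warm = ThermoParams()
        cond = make(21.6, 0.4, 1.31, 3.8)  # ln Q < 0: colder -> less negative
        assert delta_g_prime(cond, cold) > delta_g_prime(cond, warm)

    @settings(max_examples=200, derandomize=True)
    @given(s=conc, hs=conc, ch4=conc, co2=conc, factor=st.floats(1.01, 10.0))
    def test_monotone_in_each_concentration(self, s, hs, ch4, co2, factor):
        base = delta_g_prime(make(s, hs, ch4, co2))
        assert delta_g_prime(make(s * factor, hs, ch4, co2)) < base
        assert delta_g_prime(make(s, hs, ch4 * factor, co2)) < base
        assert delta_g_prime(make(s, hs * factor, ch4, co2)) > base
        assert delta_g_prime(make(s, hs, ch4, co2 * factor)) > base


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "dg, expected",
        [
            (-28.1, "growth_permissive"),
            (-19.0, "growth_permissive"),  # boundary tie is permissive
            (-17.4, "maintenance_only"),
            (-10.6, "maintenance_only"),
            (-5.0, "below_quantum"),
            (-math.inf, "growth_permissive"),
        ],
    )
    def test_examples(self, dg, expected):
        assert classify_energetic_regime(dg) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        dg1=st.floats(-60, 10, allow_nan=False),
        dg2=st.floats(-60, 10, allow_nan=False),
    )
    def test_monotone(self, dg1, dg2):
        order = ("growth_permissive", "maintenance_only", "below_quantum")
        lo, hi = sorted((dg1, dg2))
        assert order.index(classify_energetic_regime(lo)) <= order.index(
            classify_energetic_regime(hi)
        )

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_energetic_regime(math.nan)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            EnergyThresholds(growth_threshold_kj=-5.0)


class TestDissolvedMethane:
    def test_overpressure_neglected(self):
        assert dissolved_methane(SolubilityParams(), 1.8) == 1.31
        assert dissolved_methane(SolubilityParams(), 1.0) == 1.31

    def test_henry_extension_scales_linearly(self):
        sol = SolubilityParams(neglect_overpressure=False)
        assert dissolved_methane(sol, 2.0) == pytest.approx(2.62)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            dissolved_methane(SolubilityParams(), -0.5)


def test_table_roster_concentrations_and_flags():
    """Roster carries the tabulated averages; no-methane controls flagged."""
    by_id = {c.id: c for c in TABLE1_CONDITIONS}
    assert len(TABLE1_CONDITIONS) == 7
    assert not by_id["5_highSO4"].methane_added
    assert not by_id["7_highS"].methane_added
    assert by_id["1_CH4_highSO4"].sulfate_mM == 21.6
    assert by_id["6_CH4_only"].methane_mM == 1.31
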