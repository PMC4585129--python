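"""Synthetic study generator: dynamics, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from aomlab.control import sulfur_balance
from aomlab.simulate import (
    STUDY_CONDITIONS,
    SimParams,
    aom_rate,
    fit_monod,
    generate_study,
    rate_curve,
)
from aomlab.tracer import methane_oxidized


class TestAomRate:
    def test_saturation_limit(self):
        p = SimParams()
        # sulfate >> Km, deeply negative dG
        rate = aom_rate(100.0, 0.1, 1.0, 1.31, p)
        assert rate == pytest.approx(p.vmax_mM_per_day, rel=0.02)

    def test_energetic_gate_closes(self):
        p = SimParams()
        # low-sulfate/high-sulfide tabulated concentrations: dG ~ -17.4
        assert aom_rate(4.0, 3.6, 6.4, 1.31, p) == 0.0

    def test_half_saturation(self):
        p = SimParams()
        rate = aom_rate(p.km_sulfate_mM, 0.01, 0.5, 1.31, p)
        assert rate == pytest.approx(p.vmax_mM_per_day / 2, rel=1e-9)

    def test_no_methane_no_rate(self):
        assert aom_rate(21.6, 0.4, 3.8, 0.0, SimParams()) == 0.0

    def test_smooth_gate_interpolates(self):
        hard = SimParams()
        soft = SimParams(smooth_gate=True)
        # just above the cutoff: hard gate closed, smooth gate partly open
        assert aom_rate(4.0, 3.6, 6.4, 1.31, hard) == 0.0
        partial = aom_rate(4.0, 3.6, 6.4, 1.31, soft)
        assert 0.0 < partial < soft.vmax_mM_per_day


class TestDeterminismAndNoise:
    def test_same_seed_identical_output(self):
        a = generate_study(SimParams(seed=123))
        b = generate_study(SimParams(seed=123))
        for attr in ("geochem", "gas", "amendments", "qpcr_plates"):
            pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))
        assert a.truth == b.truth

    def test_different_seed_differs(self):
        a = generate_study(SimParams(seed=1))
        b = generate_study(SimParams(seed=2))
        assert not a.geochem["sulfate_mM"].equals(b.geochem["sulfate_mM"])

    def test_zero_noise_observations_equal_truth(self, noiseless_study):
        study = noiseless_study
        for bottle_id, history in study.histories.items():
            obs = study.geochem[study.geochem["bottle_id"] == bottle_id]
            truth_by_day = {s.day: s for s, _ in history}
            for row in obs.itertuples():
                assert row.sulfate_mM == pytest.approx(
                    truth_by_day[row.day].sulfate_mM, abs=1e-12
                )
                assert row.sulfide_mM == pytest.approx(
                    truth_by_day[row.day].sulfide_mM, abs=1e-12
                )


class TestPlantedStructure:
    def test_sulfide_only_accumulates_methane_monotonically(self, default_study):
        gas = default_study.gas
        for rep in "ABC":
            sub = gas[
                (gas["bottle_id"] == f"7_highS_{rep}") & (gas["species"] == "CH4")
            ].sort_values("day")
            truth = default_study.truth["bottles"][f"7_highS_{rep}"]
            assert truth["final_state"]["ch4_aq_mM"] > 0.5
            # noiseless truth is strictly monotone; noisy observations trend up
            assert sub["amount12_mmol"].iloc[-1] > sub["amount12_mmol"].iloc[0]

    def test_gate_separates_active_from_inhibited(self, noiseless_study):
        truth = noiseless_study.truth["bottles"]
        assert truth["1_CH4_highSO4_A"]["cum_ch4_oxidized_mmol"] > 0.1
        assert truth["4_CH4_lowSO4_highS_A"]["cum_ch4_oxidized_mmol"] == 0.0

    def test_controller_produces_amendments_in_active_conditions(
        self, default_study
    ):
        reagents = set(default_study.amendments["reagent"])
        assert "FeCl2" in reagents
        bottles = set(default_study.amendments["bottle_id"])
        assert any(b.startswith("1_CH4_highSO4") for b in bottles)

    def test_ledgers_close_in_noiseless_run(self, noiseless_study):
        for bottle_id, history in noiseless_study.histories.items():
            assert abs(sulfur_balance(history)) < 1e-9, bottle_id
            carbon = noiseless_study.truth["bottles"][bottle_id][
                "carbon_residual_mmol"
            ]
            assert abs(carbon) < 1e-9, bottle_id

    def test_tracer_round_trip_recovers_true_oxidation(self, default_study):
        """Label-dilution estimate matches the ledger within the noise envelope."""
        p = default_study.params
        gas = default_study.gas
        for bottle_id, truth in default_study.truth["bottles"].items():
            true_ox = truth["cum_ch4_oxidized_post_label_mmol"]
            if true_ox < 0.05:
                continue  # inactive bottles have no signal to recover
            sub = gas[
                (gas["bottle_id"] == bottle_id) & (gas["species"] == "CO2")
            ].sort_values("day")
            pre = sub[sub["day"] <= p.label_start_day]["amount13_mmol"].iloc[-1]
            post = sub["amount13_mmol"].iloc[-1]
            estimate = methane_oxidized(post - pre, p.f13_ch4_label)
            scale = sub["amount13_mmol"].iloc[-1] / p.f13_ch4_label
            assert estimate == pytest.approx(
                true_ox, abs=3 * p.noise_sd * scale
            )


class TestParameterRecovery:
    def test_noiseless_monod_recovery(self):
        p = SimParams()
        grid = np.geomspace(0.1, 25.0, 40)
        vmax, km = fit_monod(grid, rate_curve(p, grid))
        assert vmax == pytest.approx(p.vmax_mM_per_day, rel=1e-6)
        assert km == pytest.approx(p.km_sulfate_mM, rel=1e-6)
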