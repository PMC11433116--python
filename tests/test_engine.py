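"""Cohort engine: matrices, traces, discounted accrual."""

import numpy as np
import pytest

from markovcua import (
    HealthState,
    ModelDefinition,
    ModelSettings,
    StrategyDefinition,
    TransitionRule,
    accumulate,
    build_matrix,
    copy_model,
    run_cohort,
    run_strategy,
)

from test_model import minimal_model


def single_alive_state_model(utility, discount=0.0, hazard=0.0):
    """One alive state (+ BSC/death plumbing) with optional exit hazard."""
    m = minimal_model(annual_discount_rate=discount)
    m.state("start").utility = utility
    m.rules[0].probability = hazard
    return m


class TestBuildMatrix:
    @pytest.mark.parametrize("strategy", ["PBT", "3DCRT"])
    def test_rows_are_stochastic_every_cycle(self, rare_model, strategy):
        for cycle in range(1, rare_model.settings.horizon_cycles + 1):
            m = build_matrix(rare_model, strategy, cycle)
            np.testing.assert_allclose(m.entries.sum(axis=1), 1.0, atol=1e-12)
            assert (m.entries >= 0).all()

    def test_photon_arm_first_cycle_row(self, rare_model):
        row = build_matrix(rare_model, "3DCRT", 1).row("no_late_ae")
        ids = [s.id for s in rare_model.states]
        # eleven adverse-event targets plus terminal care, complement stays
        assert row[ids.index("bsc")] == pytest.approx(0.0542)
        assert row[ids.index("no_late_ae")] == pytest.approx(0.3218)
        assert row[ids.index("pe_g3")] == pytest.approx(0.06)
        assert np.count_nonzero(row) == 13

    def test_proton_arm_after_onset_windows_close(self, rare_model):
        row = build_matrix(rare_model, "PBT", 13).row("no_late_ae")
        ids = [s.id for s in rare_model.states]
        assert row[ids.index("no_late_ae")] == pytest.approx(1 - 0.0542)
        assert row[ids.index("bsc")] == pytest.approx(0.0542)
        assert np.count_nonzero(row) == 2

    def test_absorbing_state_is_identity_row(self, rare_model):
        for cycle in (1, 10, 20):
            row = build_matrix(rare_model, "PBT", cycle).row("death")
            assert row[[s.id for s in rare_model.states].index("death")] == 1.0
            assert row.sum() == 1.0

    def test_overcommitted_row_raises_with_state_and_cycle(self, rare_model):
        m = copy_model(rare_model)
        for r in m.rules:
            if r.strategy == "3DCRT" and r.to_state == "pe_g3":
                r.probability = 0.9  # row already carries ~0.62 elsewhere
        with pytest.raises(ValueError, match="no_late_ae"):
            build_matrix(m, "3DCRT", 1)

    def test_cycle_outside_horizon_rejected(self, rare_model):
        with pytest.raises(ValueError, match="cycle"):
            build_matrix(rare_model, "PBT", 0)
        with pytest.raises(ValueError, match="cycle"):
            build_matrix(rare_model, "PBT", 21)


class TestRunCohort:
    def test_occupancy_conserved_and_death_monotone(self, rare_model):
        for arm in ("PBT", "3DCRT"):
            trace = run_cohort(rare_model, arm)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            death = trace.occupancy[:, trace.state_ids.index("death")]
            assert (np.diff(death) >= -1e-15).all()
            assert trace.occupancy[0, trace.state_ids.index("no_late_ae")] == 1.0

    def test_stay_only_model_keeps_cohort_in_start_state(self):
        # all transition probabilities zero: degenerate but simulable
        # (fails the death-reachability validation, hence check=False)
        m = single_alive_state_model(utility=0.9, hazard=0.0)
        trace = run_cohort(m, "A", check=False)
        start = trace.state_ids.index("start")
        assert (trace.occupancy[:, start] == 1.0).all()

    def test_certain_terminal_care_hazard_empties_cohort_in_two_cycles(self):
        m = single_alive_state_model(utility=0.9, hazard=1.0)
        trace = run_cohort(m, "A")
        assert trace.occupancy[1, trace.state_ids.index("bsc")] == 1.0
        death = trace.occupancy[:, trace.state_ids.index("death")]
        assert (death[2:] == 1.0).all()

    def test_inflow_tracks_entries_not_stayers(self):
        m = single_alive_state_model(utility=0.9, hazard=0.25)
        trace = run_cohort(m, "A")
        bsc = trace.state_ids.index("bsc")
        # entering mass each cycle = hazard times surviving start-state mass
        np.testing.assert_allclose(
            trace.inflow[1:6, bsc], 0.25 * 0.75 ** np.arange(5), atol=1e-12
        )

    def test_trace_export_is_tidy(self, rare_model):
        frame = run_cohort(rare_model, "PBT").to_frame()
        assert list(frame.columns) == ["cycle", "state", "occupancy", "inflow"]
        assert len(frame) == 21 * len(rare_model.states)


class TestAccumulate:
    def test_perfect_utility_undiscounted_gives_horizon_qalys(self):
        m = single_alive_state_model(utility=1.0)
        out = run_strategy(m, "A", check=False)  # no exit hazard at all
        assert out.total_qaly == pytest.approx(5.0)  # 20 cycles x 0.25 y
        assert out.undiscounted_ly == pytest.approx(5.0)

    def test_constant_utility_scales_linearly(self):
        m = single_alive_state_model(utility=0.91)
        out = run_strategy(m, "A", check=False)
        assert out.total_qaly == pytest.approx(0.91 * 5.0)

    def test_discounting_strictly_reduces_outcomes(self, rare_model):
        qalys, tail_costs = [], []
        for rate in (0.0, 0.03, 0.08):
            m = copy_model(rare_model)
            m.settings.annual_discount_rate = rate
            out = run_strategy(m, "3DCRT")
            qalys.append(out.total_qaly)
            tail_costs.append(out.total_cost - m.upfront_cost("3DCRT"))
        assert qalys[0] > qalys[1] > qalys[2]
        assert tail_costs[0] > tail_costs[1] > tail_costs[2]

    def test_equalized_arms_differ_only_by_fee(self, rare_model):
        m = copy_model(rare_model)
        photon = {
            (r.from_state, r.to_state): r.probability
            for r in m.rules
            if r.strategy == "3DCRT"
        }
        for r in m.rules:
            if r.strategy == "PBT":
                r.probability = photon[(r.from_state, r.to_state)]
        out_p = run_strategy(m, "PBT")
        out_x = run_strategy(m, "3DCRT")
        assert out_p.total_qaly == pytest.approx(out_x.total_qaly, abs=1e-12)
        fee_diff = m.upfront_cost("PBT") - m.upfront_cost("3DCRT")
        assert out_p.total_cost - out_x.total_cost == pytest.approx(fee_diff, abs=1e-6)

    def test_total_cost_bounded_below_by_upfront(self, rare_result):
        for out, arm in ((rare_result.comparator, "PBT"), (rare_result.reference, "3DCRT")):
            assert out.total_cost >= 727_600 + 1_325_370
            assert out.total_qaly <= out.undiscounted_ly <= 5.0

    def test_mismatched_trace_rejected(self, rare_model):
        trace = run_cohort(rare_model, "PBT")
        other = minimal_model()
        with pytest.raises(ValueError, match="match"):
            accumulate(other, trace)

    def test_entry_costs_charged_once_per_entering_fraction(self):
        m = single_alive_state_model(utility=0.9, hazard=0.5)
        m.state("bsc").entry_cost = 100_000.0
        m.strategies[0].treatment_fee = 0.0
        m.settings.followup_cost_year1 = 0.0
        m.settings.followup_cost_later = 0.0
        out = run_strategy(m, "A")
        # undiscounted: everyone passes through terminal care exactly once
        total_entering = sum(0.5 * 0.5**k for k in range(20))
        assert out.total_cost == pytest.approx(100_000 * total_entering, rel=1e-6)


class TestCumulativeIncidence:
    def test_severe_toxicity_matches_photon_trial_rates(self, rare_model):
        """Cumulative Grade 3 incidence under 3D-CRT: pneumonitis ~4%,
        pleural effusion ~9%, pericardial effusion (incl. overlap) ~16%."""
        trace = run_cohort(rare_model, "3DCRT")
        ids = trace.state_ids
        cum = lambda sid: trace.inflow[1:, ids.index(sid)].sum()
        assert cum("rp_g3") == pytest.approx(0.04, abs=0.02)
        assert cum("pe_g3") == pytest.approx(0.09, abs=0.02)
        assert cum("pce_g3") + cum("pce_g3_pe_g2") == pytest.approx(0.16, abs=0.02)

    def test_proton_arm_severe_toxicity_is_rare(self, rare_model):
        trace = run_cohort(rare_model, "PBT")
        ids = trace.state_ids
        cum = lambda sid: trace.inflow[1:, ids.index(sid)].sum()
        assert cum("rp_g3") == pytest.approx(0.005, abs=0.005)
        assert cum("pe_g3") == 0.0
        assert cum("pce_g3") + cum("pce_g3_pe_g2") == pytest.approx(0.01, abs=0.01)
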