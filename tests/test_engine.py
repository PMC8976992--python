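"""Markov cohort engine: matrices, traces, discounting, reward accrual."""

import numpy as np
import pytest

import esocea as e
from _oracles import microsim


def immortal(stage1):
    """A strategy with no exits: full cohort stays in no-recurrence."""
    return stage1.strategies["EMR"].replace(
        p_complication_init=0.0, p_death_init=0.0,
        p_nr_to_lr=0.0, p_nr_to_met=0.0, p_nr_to_dead=0.0,
        u_nr=1.0, u_comp=1.0, u_lr=1.0, u_met=1.0,
    )


class TestInitialDistribution:
    def test_esophagectomy_stage1(self, stage1):
        dist = e.initial_distribution(stage1.strategies["esophagectomy"])
        assert dist == pytest.approx([0.826, 0.0, 0.0, 0.119, 0.055])

    def test_no_treatment_death_for_emr(self, stage1):
        assert e.initial_distribution(stage1.strategies["EMR"])[4] == 0.0

    def test_degenerate_all_mass_on_no_recurrence(self, stage1):
        p = stage1.strategies["EMR"].replace(p_complication_init=0.0, p_death_init=0.0)
        assert e.initial_distribution(p) == pytest.approx([1.0, 0, 0, 0, 0])


class TestTransitionMatrix:
    def test_emr_no_recurrence_row(self, stage1):
        m = e.build_transition_matrix(stage1.strategies["EMR"]).entries
        assert m[0] == pytest.approx([0.8879, 0.0188, 0.0233, 0.0, 0.07])

    def test_dead_row_absorbing(self, stage1):
        m = e.build_transition_matrix(stage1.strategies["EMR"]).entries
        assert list(m[4]) == [0.0, 0.0, 0.0, 0.0, 1.0]

    def test_all_zero_transitions_freeze_every_persistent_state(self, stage1):
        # complication stays transient by design: with every probability 0
        # its occupants still return to no-recurrence after one cycle
        m = e.build_transition_matrix(
            immortal(stage1).replace(p_lr_to_met=0, p_lr_to_dead=0, p_met_to_dead=0)
        ).entries
        for row in (0, 1, 2, 4):
            assert np.array_equal(m[row], np.eye(5)[row])
        assert list(m[3]) == [1.0, 0.0, 0.0, 0.0, 0.0]

    def test_rows_sum_to_one(self, all_strategies):
        for p in all_strategies:
            m = e.build_transition_matrix(p).entries
            assert np.abs(m.sum(axis=1) - 1).max() < 1e-12

    def test_row_sum_above_one_rejected(self, stage1):
        p = stage1.strategies["EMR"].replace(p_lr_to_met=0.7, p_lr_to_dead=0.7)
        with pytest.raises(e.ValidationError):
            e.build_transition_matrix(p)


class TestDiscounting:
    def test_factor_values(self, settings):
        assert e.discount_factor(0, settings) == 1.0
        assert e.discount_factor(2, settings) == pytest.approx(1 / 1.03)
        # closed form verified independently: 1.03**-15
        assert e.discount_factor(30, settings) == pytest.approx(0.641861947, abs=1e-9)

    def test_negative_index_rejected(self, settings):
        with pytest.raises(ValueError):
            e.discount_factor(-1, settings)

    def test_zero_rate_makes_discounted_equal_undiscounted(self, stage23):
        s = stage23.settings.replace(annual_discount_rate=0.0)
        for p in stage23:
            o = e.run_strategy(p, s)
            assert o.total_cost_disc == pytest.approx(o.total_cost_undisc, abs=1e-12)
            assert o.ly_disc == pytest.approx(o.ly_undisc, abs=1e-12)
            assert o.qaly_disc == pytest.approx(o.qaly_undisc, abs=1e-12)


class TestCohortTrace:
    def test_rows_conserve_mass(self, all_strategies, settings):
        for p in all_strategies:
            occ = e.run_cohort(p, settings).occupancy
            assert np.abs(occ.sum(axis=1) - 1).max() < 1e-10

    def test_dead_occupancy_non_decreasing(self, all_strategies, settings):
        for p in all_strategies:
            dead = e.run_cohort(p, settings).occupancy[:, 4]
            assert (np.diff(dead) >= -1e-12).all()

    def test_geometric_decay_without_complication_reflux(self, stage1, settings):
        # complication made fatal so nothing flows back into no-recurrence;
        # the no-recurrence state then decays geometrically from 0.931
        p = stage1.strategies["EMR"].replace(p_comp_to_dead=1.0)
        trace = e.run_cohort(p, settings)
        for t in (1, 10, 30):
            assert trace.occupancy[t, 0] == pytest.approx(0.931 * 0.8879**t, abs=1e-12)
        # frozen value computed independently by repeated squaring
        assert trace.occupancy[30, 0] == pytest.approx(0.0262949, abs=1e-7)

    def test_all_mass_dead_is_constant(self, stage1, settings):
        p = stage1.strategies["EMR"].replace(p_complication_init=0.0, p_death_init=1.0)
        occ = e.run_cohort(p, settings).occupancy
        assert (occ[:, 4] == 1.0).all()

    def test_row_zero_is_initial_distribution(self, stage1, settings):
        p = stage1.strategies["esophagectomy"]
        occ = e.run_cohort(p, settings).occupancy
        assert occ[0] == pytest.approx(e.initial_distribution(p))


class TestAccumulation:
    def test_immortal_cohort_life_years(self, stage1, settings):
        o = e.run_strategy(immortal(stage1), settings)
        assert o.ly_undisc == pytest.approx(15.0, abs=1e-12)
        # discounted annuity: 0.5 * (1 - 1.03^-15) / (1 - 1.03^-0.5)
        assert o.ly_disc == pytest.approx(12.205877, abs=1e-5)
        assert o.qaly_disc == pytest.approx(o.ly_disc, abs=1e-12)

    def test_treatment_cost_only(self, stage1, settings):
        o = e.run_strategy(stage1.strategies["EMR"], settings)
        assert o.total_cost_disc == 1788.0
        assert o.total_cost_undisc == 1788.0

    def test_discounted_below_undiscounted(self, all_strategies, settings):
        for p in all_strategies:
            o = e.run_strategy(p.replace(cost_cycle_nr=100.0), settings)
            assert o.total_cost_disc <= o.total_cost_undisc
            assert o.ly_disc <= o.ly_undisc
            assert o.qaly_disc <= o.qaly_undisc

    def test_qaly_below_ly(self, all_strategies, settings):
        for p in all_strategies:
            o = e.run_strategy(p, settings)
            assert o.qaly_disc <= o.ly_disc + 1e-12
            assert o.qaly_undisc <= o.ly_undisc + 1e-12

    def test_terminal_cost_charges_all_deaths(self, stage1, settings):
        p = stage1.strategies["esophagectomy"].replace(cost_terminal=1000.0)
        s = settings.replace(annual_discount_rate=0.0)
        o = e.run_strategy(p, s)
        trace = e.run_cohort(p, s)
        expected = p.cost_treatment + 1000.0 * trace.occupancy[-1, 4]
        assert o.total_cost_undisc == pytest.approx(expected, abs=1e-9)

    def test_trace_settings_mismatch_rejected(self, stage1, settings):
        trace = e.run_cohort(stage1.strategies["EMR"], settings)
        short = settings.replace(horizon_years=10.0)
        with pytest.raises(e.ValidationError):
            e.accumulate_outcomes(trace, stage1.strategies["EMR"], short)

    def test_half_cycle_correction_brackets_default(self, stage1, settings):
        p = stage1.strategies["EMR"]
        default = e.run_strategy(p, settings)
        corrected = e.run_strategy(p, settings.replace(half_cycle_correction=True))
        # occupancy declines over time, so mid-cycle accrual gives less
        assert corrected.ly_disc < default.ly_disc
        assert corrected.qaly_disc < default.qaly_disc


class TestMonotonicity:
    @pytest.mark.parametrize("field", ["p_nr_to_dead", "p_lr_to_dead", "p_met_to_dead", "p_comp_to_dead"])
    def test_raising_death_probability_never_gains_life(self, all_strategies, settings, field):
        for p in all_strategies:
            base = e.run_strategy(p, settings)
            for bump in (0.02, 0.1):
                raised = p.replace(**{field: min(getattr(p, field) + bump, 1.0)})
                if e.validate_params(raised):
                    continue
                worse = e.run_strategy(raised, settings)
                assert worse.ly_disc <= base.ly_disc + 1e-12
                assert worse.qaly_disc <= base.qaly_disc + 1e-12


class TestMicrosimulationOracle:
    def test_trace_and_life_years_agree_with_path_sampling(self, stage23, settings):
        p = stage23.strategies["CRT_surgery"]
        n = 60_000
        occ_sim, ly_sim, ly_se = microsim(p, settings, n, seed=20240917)
        trace = e.run_cohort(p, settings)
        se = np.sqrt(np.clip(trace.occupancy * (1 - trace.occupancy), 1e-12, None) / n)
        assert (np.abs(occ_sim - trace.occupancy) <= 3 * se + 1e-9).all()
        o = e.run_strategy(p, settings.replace(annual_discount_rate=0.0))
        assert abs(o.ly_undisc - ly_sim) <= 3 * ly_se


class TestRateConversion:
    def test_round_trip(self):
        r = e.prob_to_rate(0.07, 0.5)
        assert e.rate_to_prob(r, 0.5) == pytest.approx(0.07, abs=1e-12)

    def test_rescaling_cycle_length(self):
        # a 6-month probability re-expressed over 12 months via rates
        p12 = e.rate_to_prob(e.prob_to_rate(0.1, 0.5), 1.0)
        assert p12 == pytest.approx(1 - 0.9**2, abs=1e-12)
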