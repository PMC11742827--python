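import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfcea import (
    ArmSpec,
    GompertzParams,
    HazardRatio,
    ParameterSet,
    cycle_transition,
    cycle_utility,
    escalate_hosp_prob,
    run_cohort,
    synthesize_life_table,
)

# a background table whose mortality is numerically negligible, for isolating
# the event mechanics from ageing
NEGLIGIBLE_MORTALITY = synthesize_life_table(
    GompertzParams(alpha=1e-15, beta=0.0))

# a table whose quarterly death probability is 1 at every age
CERTAIN_DEATH = synthesize_life_table(GompertzParams(alpha=1e6, beta=0.0))


def event_free_params(**over) -> ParameterSet:
    base = dict(p_urgent=0.0, p_hosp=0.0, p_readmit=0.0,
                utility_decrement_per_cycle=0.0, discount_rate=0.0)
    base.update(over)
    return ParameterSet(**base)


class TestCycleTransition:
    def test_no_events_leave_occupancy_unchanged(self):
        params = event_free_params()
        arm = ArmSpec.standard(params)
        occ, events = cycle_transition((1.0, 0.0, 0.0), 0, arm, params,
                                       NEGLIGIBLE_MORTALITY)
        assert occ == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in events.values())

    def test_unreadmitted_post_state_returns_to_stable(self):
        params = event_free_params()
        arm = ArmSpec.standard(params)
        occ, _ = cycle_transition((0.7, 0.3, 0.0), 0, arm, params,
                                  NEGLIGIBLE_MORTALITY)
        assert occ == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)

    def test_certain_death_absorbs_cohort_in_one_cycle(self):
        params = ParameterSet()
        arm = ArmSpec.standard(params)
        (s, p, d), _ = cycle_transition((1.0, 0.0, 0.0), 0, arm, params,
                                        CERTAIN_DEATH)
        assert (s, p, d) == pytest.approx((0.0, 0.0, 1.0), abs=1e-12)

    def test_hospitalization_flow_split_by_case_fatality(self):
        # stable cohort, no background death: p_hosp = 0.024 with 9%
        # in-hospital fatality splits into 0.02184 post-hosp and 0.00216 dead
        params = ParameterSet(p_urgent=0.0)
        arm = ArmSpec.standard(params)
        (s, p, d), ev = cycle_transition((1.0, 0.0, 0.0), 0, arm, params,
                                         NEGLIGIBLE_MORTALITY)
        assert p == pytest.approx(0.024 * 0.91, abs=1e-9)
        assert d == pytest.approx(0.024 * 0.09, abs=1e-9)
        assert ev["admissions"] == pytest.approx(0.024, abs=1e-9)
        assert ev["in_hosp_deaths"] == pytest.approx(0.00216, abs=1e-9)

    def test_readmission_keeps_patient_in_post_state(self):
        params = ParameterSet(p_hosp=0.0, p_urgent=0.0)
        arm = ArmSpec.standard(params)
        (s, p, d), ev = cycle_transition((0.0, 1.0, 0.0), 0, arm, params,
                                         NEGLIGIBLE_MORTALITY)
        assert ev["readmissions"] == pytest.approx(0.246, abs=1e-9)
        assert p == pytest.approx(0.246 * 0.91, abs=1e-9)   # readmitted, survived
        assert s == pytest.approx(0.754, abs=1e-9)          # back to stable
        assert d == pytest.approx(0.246 * 0.09, abs=1e-9)

    def test_occupancy_must_sum_to_one(self):
        params = ParameterSet()
        with pytest.raises(ValueError):
            cycle_transition((0.5, 0.0, 0.0), 0, ArmSpec.standard(params),
                             params, NEGLIGIBLE_MORTALITY)


class TestHospitalizationEscalation:
    def test_no_escalation_in_first_cycle(self):
        assert escalate_hosp_prob(0.024, 0, 1.16) == pytest.approx(0.024, rel=1e-12)

    def test_one_year_escalation_value(self):
        # 1 - exp(-(-ln 0.976) * 1.16), evaluated independently
        assert escalate_hosp_prob(0.024, 4, 1.16) == pytest.approx(
            0.027786183976681533)

    def test_unit_factor_is_identity(self):
        assert escalate_hosp_prob(0.024, 4, 1.0) == pytest.approx(0.024, rel=1e-12)

    def test_monotone_in_elapsed_time_and_capped(self):
        probs = [escalate_hosp_prob(0.024, k, 1.16) for k in range(0, 400, 4)]
        assert np.all(np.diff(probs) >= 0)
        assert probs[-1] <= 1.0


class TestCycleUtility:
    @pytest.mark.parametrize(
        "base, k, expected",
        [(0.78, 0, 0.78), (0.78, 1, 0.7786428), (0.0, 100, 0.0)],
    )
    def test_relative_decrement(self, base, k, expected):
        assert cycle_utility(base, k) == pytest.approx(expected, rel=1e-9)

    def test_decrement_compounds_multiplicatively(self):
        assert cycle_utility(0.78, 8) == pytest.approx(
            0.78 * (1 - 0.00174) ** 8, rel=1e-12)


class TestRunCohort:
    def test_event_free_year_accrues_baseline_utility(self):
        # no mortality, no events, utility held at 0.78, no discounting:
        # one year of follow-up is worth exactly 0.78 QALYs per patient
        params = event_free_params(cohort_size=1)
        trace = run_cohort(ArmSpec.standard(params), params,
                           NEGLIGIBLE_MORTALITY, horizon_years=1.0)
        assert trace.total_qaly == pytest.approx(0.78, abs=1e-9)
        assert trace.total_ly == pytest.approx(1.0, abs=1e-9)

    def test_constant_mortality_matches_geometric_series(self):
        # with constant quarterly death probability p and no other events,
        # undiscounted life-years follow the geometric closed form
        # sum_k (1-p)^(k+1) * 0.25
        alpha = 0.4
        table = synthesize_life_table(GompertzParams(alpha=alpha, beta=0.0))
        params = event_free_params(cohort_size=1, mortality_rate_ratio=1.0)
        n = 120
        trace = run_cohort(ArmSpec.standard(params), params, table,
                           horizon_years=n / 4)
        p = -math.expm1(-alpha * 0.25)
        closed_form = sum((1 - p) ** (k + 1) * 0.25 for k in range(n))
        assert trace.total_ly == pytest.approx(closed_form, rel=1e-9)

    def test_discount_factor_compounds_quarterly(self, base_params, synth_table):
        trace = run_cohort(ArmSpec.standard(base_params), base_params,
                           synth_table, horizon_years=3.0)
        # at cycle 4 (one year in) the discount factor is 1.05^-1
        assert trace.qaly_disc[4] / trace.qaly[4] == pytest.approx(
            1.05 ** -1, rel=1e-12)
        assert trace.cost_med_disc[8] / trace.cost_med[8] == pytest.approx(
            1.05 ** -2, rel=1e-12)

    @given(
        p_hosp=st.floats(0.0, 0.5),
        p_readmit=st.floats(0.0, 0.9),
        p_inhosp=st.floats(0.0, 0.5),
        hr_death=st.floats(0.2, 2.0),
        hr_hosp=st.floats(0.2, 2.0),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_occupancy_conserved_and_death_monotone(self, synth_table, p_hosp,
                                                    p_readmit, p_inhosp,
                                                    hr_death, hr_hosp):
        params = ParameterSet(p_hosp=p_hosp, p_readmit=p_readmit,
                              p_inhosp_death=p_inhosp)
        arm = ArmSpec("x", hr_death=hr_death, hr_hosp=hr_hosp,
                      med_cost_per_cycle=100.0)
        trace = run_cohort(arm, params, synth_table)
        total = trace.stable + trace.post_hosp + trace.dead
        assert np.abs(total - 1.0).max() < 1e-12
        assert np.all(np.diff(trace.dead) >= -1e-15)
        for col in (trace.admissions, trace.readmissions, trace.urgent_visits,
                    trace.in_hosp_deaths):
            assert np.all(col >= 0)

    def test_identical_arms_give_bit_identical_traces(self, base_params,
                                                      synth_table):
        std = ArmSpec.standard(base_params)
        neutral = ArmSpec("dapagliflozin",
                          med_cost_per_cycle=std.med_cost_per_cycle)
        t1 = run_cohort(std, base_params, synth_table)
        t2 = run_cohort(neutral, base_params, synth_table)
        assert np.array_equal(t1.qaly_disc, t2.qaly_disc)
        assert np.array_equal(t1.cost_med_disc, t2.cost_med_disc)
        assert np.array_equal(t1.dead, t2.dead)

    def test_protective_arm_dominates_clinically(self, base_params, synth_table):
        dapa = run_cohort(ArmSpec.dapagliflozin(base_params), base_params,
                          synth_table)
        std = run_cohort(ArmSpec.standard(base_params), base_params,
                         synth_table)
        assert dapa.total_ly_disc >= std.total_ly_disc
        assert dapa.total_qaly_disc >= std.total_qaly_disc
        assert dapa.total_hospitalizations <= std.total_hospitalizations

    def test_qalys_bounded_by_life_years(self, base_params, synth_table):
        trace = run_cohort(ArmSpec.standard(base_params), base_params,
                           synth_table)
        assert trace.total_qaly_disc <= trace.total_ly_disc
        assert trace.total_qaly <= trace.total_ly

    def test_removing_discount_increases_totals(self, synth_table):
        p5 = ParameterSet()
        p0 = ParameterSet(discount_rate=0.0)
        t5 = run_cohort(ArmSpec.standard(p5), p5, synth_table)
        t0 = run_cohort(ArmSpec.standard(p0), p0, synth_table)
        assert t0.total_qaly_disc > t5.total_qaly_disc
        assert t0.total_cost_disc > t5.total_cost_disc

    def test_half_cycle_correction_raises_person_time(self, synth_table):
        base = ParameterSet()
        hcc = ParameterSet(half_cycle_correction=True)
        t_base = run_cohort(ArmSpec.standard(base), base, synth_table)
        t_hcc = run_cohort(ArmSpec.standard(hcc), hcc, synth_table)
        # start-of-cycle occupancy is never below end-of-cycle occupancy
        assert t_hcc.total_ly_disc > t_base.total_ly_disc

    def test_lifetime_run_extinguishes_cohort(self, base_params, synth_table):
        trace = run_cohort(ArmSpec.standard(base_params), base_params,
                           synth_table)
        assert trace.dead[-1] > 1.0 - 1e-6
        assert trace.age[-1] <= base_params.max_age

    def test_nonpositive_horizon_rejected(self, base_params, synth_table):
        with pytest.raises(ValueError):
            run_cohort(ArmSpec.standard(base_params), base_params, synth_table,
                       horizon_years=0.0)

    def test_trace_csv_columns(self, base_params, synth_table, tmp_path):
        trace = run_cohort(ArmSpec.standard(base_params), base_params,
                           synth_table, horizon_years=2.0)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "cycle", "age", "stable", "post_hosp", "dead", "hospitalizations",
            "urgent_visits", "readmissions", "in_hosp_deaths", "ly_disc",
            "qaly_disc", "cost_med_disc", "cost_hosp_disc", "cost_urgent_disc",
        ]
        assert len(df) == 8
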