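"""Decision tree, cohort engine, conservation and the microsim oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmvr_cea.markov import (
    cumulative_mortality,
    is_treated,
    p_severe_for,
    run_cohort,
    run_decision_tree,
    transition_matrix_for,
)
from pmvr_cea.mortality import NYHA_III, cycle_death_probability, cycle_death_vector


def _zero_mortality_params(params):
    return params.replace(p_periop_death=0.0, p6_excess_death_nyha2=0.0,
                          p6_excess_death_nyha3=0.0, p6_excess_death_nyha4=0.0)


# ---------------------------------------------------------------- decision tree

def test_pmvr_cycle1_deaths_are_periprocedural(params, life_table):
    occ, cost, qaly, deaths = run_decision_tree("PMVR", params, life_table)
    assert deaths == pytest.approx(params.p_periop_death)
    assert deaths >= 0.019
    assert occ.sum() == pytest.approx(1.0 - deaths, abs=1e-12)


def test_pmvr_cycle1_splits_by_implantation_success(params, life_table):
    occ, *_ = run_decision_tree("PMVR", params, life_table)
    implanted, recaptured = occ
    alive = 1.0 - params.p_periop_death
    pmvr_row = params.transitions.matrix("PMVR", "cycle1")[NYHA_III]
    omt_row = params.transitions.matrix("OMT", "cycle1")[NYHA_III]
    np.testing.assert_allclose(
        implanted, alive * (1 - params.p_unsuccessful) * pmvr_row, atol=1e-12)
    np.testing.assert_allclose(
        recaptured, alive * params.p_unsuccessful * omt_row, atol=1e-12)


def test_pmvr_cycle1_all_successful_leaves_recaptured_empty(params, life_table):
    p = params.replace(p_unsuccessful=0.0)
    occ, *_ = run_decision_tree("PMVR", p, life_table)
    assert occ[1] == pytest.approx([0, 0, 0, 0])


def test_pmvr_cycle1_cost_covers_device_for_all_attempts(params, life_table):
    _, cost, _, _ = run_decision_tree("PMVR", params, life_table)
    assert cost >= params.cost_device + params.cost_procedure


def test_omt_cycle1_mortality_and_transition(params, life_table):
    occ, _, _, deaths = run_decision_tree("OMT", params, life_table)
    expected = cycle_death_probability(
        NYHA_III, params.age_start, params.p_severe_baseline, params, life_table)
    assert deaths == pytest.approx(expected)
    omt_row = params.transitions.matrix("OMT", "cycle1")[NYHA_III]
    np.testing.assert_allclose(occ[0], (1 - deaths) * omt_row, atol=1e-12)


# ---------------------------------------------------------- regime resolution

def test_transition_matrix_regimes(params):
    m = transition_matrix_for("OMT", "omt", 5, params)
    assert m[NYHA_III] == pytest.approx([0, 0.17, 0.83, 0])
    m12 = transition_matrix_for("PMVR", "implanted", 12, params)
    assert m12[NYHA_III] == pytest.approx([0, 0.40, 0.60, 0])
    with pytest.raises(ValueError):
        transition_matrix_for("OMT", "omt", 1, params)


def test_recaptured_follow_medical_treatment_matrices(params):
    np.testing.assert_array_equal(
        transition_matrix_for("PMVR", "recaptured", 5, params),
        transition_matrix_for("OMT", "omt", 5, params))


def test_fadeout_reverts_implanted_to_omt_dynamics(params):
    faded = transition_matrix_for("PMVR", "implanted", 40, params, scenario="fadeout")
    np.testing.assert_array_equal(faded, params.transitions.matrix("OMT", "cycle12plus"))
    kept = transition_matrix_for("PMVR", "implanted", 30, params, scenario="fadeout")
    np.testing.assert_array_equal(kept, params.transitions.matrix("PMVR", "cycle12plus"))
    assert not is_treated("PMVR", "implanted", 40, "fadeout")
    assert is_treated("PMVR", "implanted", 30, "fadeout")
    assert p_severe_for("PMVR", "implanted", 40, params, "fadeout") == \
        params.p_severe_baseline


@pytest.mark.parametrize("arm, sub, cycle, expected_attr", [
    ("PMVR", "implanted", 1, "p_severe_baseline"),
    ("PMVR", "implanted", 3, "p_severe_pmvr_1to5"),
    ("PMVR", "implanted", 8, "p_severe_pmvr_6plus"),
    ("PMVR", "recaptured", 8, "p_severe_baseline"),
    ("OMT", "omt", 60, "p_severe_baseline"),
])
def test_severe_mr_trajectory(params, arm, sub, cycle, expected_attr):
    assert p_severe_for(arm, sub, cycle, params) == params.values[expected_attr]


# ----------------------------------------------------------------- invariants

def test_conservation_and_monotone_mortality(base_traces):
    for trace in base_traces.values():
        alive = trace.occupancy.sum(axis=(1, 2))
        np.testing.assert_allclose(alive + trace.cum_dead, 1.0, atol=1e-9)
        assert np.all(np.diff(trace.cum_dead) >= -1e-15)
        np.testing.assert_allclose(trace.cycle_ly, alive / 12.0, atol=1e-12)


def test_zero_mortality_preserves_cohort(params, zero_life_table):
    p = _zero_mortality_params(params)
    for arm in ("PMVR", "OMT"):
        trace = run_cohort(arm, p, zero_life_table)
        np.testing.assert_allclose(trace.occupancy.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert cumulative_mortality(trace, trace.n_cycles) == pytest.approx(0.0)


@given(p6_2=st.floats(0, 0.5), p6_3=st.floats(0, 0.5), p6_4=st.floats(0, 0.9),
       p_periop=st.floats(0, 0.2), p_unsucc=st.floats(0, 1),
       rr=st.floats(0.5, 3.0))
@settings(max_examples=25, deadline=None)
def test_conservation_for_random_parameters(params, life_table, p6_2, p6_3,
                                            p6_4, p_periop, p_unsucc, rr):
    p = params.replace(horizon_months=24, p6_excess_death_nyha2=p6_2,
                       p6_excess_death_nyha3=p6_3, p6_excess_death_nyha4=p6_4,
                       p_periop_death=p_periop, p_unsuccessful=p_unsucc,
                       rr_mortality_severe_mr=rr)
    for arm in ("PMVR", "OMT"):
        trace = run_cohort(arm, p, life_table)
        alive = trace.occupancy.sum(axis=(1, 2))
        np.testing.assert_allclose(alive + trace.cum_dead, 1.0, atol=1e-9)
        assert np.all(np.diff(trace.cum_dead) >= -1e-12)


def test_stripped_treatment_makes_arms_identical(params, zero_life_table):
    """With OMT matrices everywhere, no procedural mortality and certain
    recapture, the arms differ only in first-cycle cost and utility."""
    p = _zero_mortality_params(params).replace(p_unsuccessful=1.0)
    omt_m = params.transitions.to_dict()["OMT"]
    p = type(p)(p.values, p.transitions.copy())
    for regime, rows in omt_m.items():
        p.transitions.matrices[("PMVR", regime)] = np.array(rows)
    t_pmvr = run_cohort("PMVR", p, zero_life_table)
    t_omt = run_cohort("OMT", p, zero_life_table)
    np.testing.assert_allclose(t_pmvr.occupancy.sum(axis=1), t_omt.occupancy[:, 0],
                               atol=1e-12)
    np.testing.assert_allclose(t_pmvr.cum_dead, t_omt.cum_dead, atol=1e-12)
    np.testing.assert_allclose(t_pmvr.cycle_cost[1:], t_omt.cycle_cost[1:], atol=1e-9)
    np.testing.assert_allclose(t_pmvr.cycle_qaly[1:], t_omt.cycle_qaly[1:], atol=1e-12)
    assert t_pmvr.cycle_cost[0] > t_omt.cycle_cost[0]  # device + procedure
    assert t_pmvr.cycle_qaly[0] < t_omt.cycle_qaly[0]  # procedural decrement


def test_cumulative_mortality_bounds(base_traces):
    trace = base_traces["OMT"]
    assert cumulative_mortality(trace, 12) == pytest.approx(trace.cum_dead[11])
    with pytest.raises(ValueError):
        cumulative_mortality(trace, 0)
    with pytest.raises(ValueError):
        cumulative_mortality(trace, trace.n_cycles + 1)


def test_lifetime_scenario_runs_to_extinction(params, life_table):
    trace = run_cohort("OMT", params, life_table, scenario="lifetime")
    assert trace.n_cycles > params.horizon_months
    assert trace.alive(trace.n_cycles) < 0.001


def test_trace_export_shape(base_traces, params):
    df = base_traces["PMVR"].to_frame(params)
    # one row per (cycle, sub-cohort, state) plus a summary row per cycle
    assert len(df) == 120 * (2 * 4 + 1)
    summary = df[df.sub_cohort == "summary"]
    assert summary.cum_dead.is_monotonic_increasing


# ------------------------------------------------------------ microsim oracle

def _microsimulate(arm, params, life_table, n, months, seed):
    """Independent patient-level simulation of the same per-cycle rules."""
    rng = np.random.default_rng(seed)
    DEAD = 4
    state = np.full(n, NYHA_III, dtype=np.int8)
    treated_flag = np.zeros(n, dtype=bool)
    if arm == "PMVR":
        u = rng.random(n)
        state[u < params.p_periop_death] = DEAD
        alive = state != DEAD
        treated_flag[alive] = rng.random(alive.sum()) >= params.p_unsuccessful
        rows = {True: params.transitions.matrix("PMVR", "cycle1")[NYHA_III],
                False: params.transitions.matrix("OMT", "cycle1")[NYHA_III]}
        for flag, row in rows.items():
            mask = alive & (treated_flag == flag)
            state[mask] = rng.choice(4, size=mask.sum(), p=row / row.sum())
    else:
        d1 = cycle_death_probability(NYHA_III, params.age_start,
                                     params.p_severe_baseline, params, life_table)
        state[rng.random(n) < d1] = DEAD
        alive = state != DEAD
        row = params.transitions.matrix("OMT", "cycle1")[NYHA_III]
        state[alive] = rng.choice(4, size=alive.sum(), p=row / row.sum())
    occ_hist, dead_hist = [], []

    def snapshot():
        occ_hist.append(np.array([(state == s).mean() for s in range(4)]))
        dead_hist.append((state == DEAD).mean())

    snapshot()
    for m in range(2, months + 1):
        age = params.age_start + (m - 1) / 12
        for flag in (True, False):
            p_sev = (params.p_severe_pmvr_1to5 if m <= 5 else params.p_severe_pmvr_6plus) \
                if flag else params.p_severe_baseline
            d = cycle_death_vector(age, p_sev, params, life_table, treated=flag)
            group = (state != DEAD) & (treated_flag == flag)
            if not group.any():
                continue
            dies = group & (rng.random(n) < d[np.minimum(state, 3)])
            state[dies] = DEAD
            group &= state != DEAD
            regime = "cycles2to11" if m <= 11 else "cycle12plus"
            mat = params.transitions.matrix("PMVR" if (arm == "PMVR" and flag)
                                            else "OMT", regime)
            cum = np.cumsum(mat, axis=1)
            u = rng.random(n)
            prev = state.copy()
            for s in range(4):
                mask = group & (prev == s)
                if mask.any():
                    state[mask] = np.searchsorted(cum[s], u[mask], side="right")
        snapshot()
    return np.array(occ_hist), np.array(dead_hist)


@pytest.mark.parametrize("arm", ["OMT", "PMVR"])
def test_cohort_engine_agrees_with_microsimulation(params, life_table, arm):
    n = 100_000
    occ_ms, dead_ms = _microsimulate(arm, params, life_table, n, 120, seed=20_250)
    trace = run_cohort(arm, params, life_table)
    for month in (12, 60, 120):
        occ_cohort = trace.occupancy[month - 1].sum(axis=0)
        for s in range(4):
            p = occ_cohort[s]
            se = max(np.sqrt(p * (1 - p) / n), 1e-4)
            assert abs(occ_ms[month - 1, s] - p) < 3 * se, (arm, month, s)
        p = trace.cum_dead[month - 1]
        se = max(np.sqrt(p * (1 - p) / n), 1e-4)
        assert abs(dead_ms[month - 1] - p) < 3 * se, (arm, month, "dead")
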