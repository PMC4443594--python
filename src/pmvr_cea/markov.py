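"""First-cycle decision tree and monthly NYHA Markov cohort engine.

The model runs a closed cohort, all entering in NYHA class III, through
one of two strategies:

* **PMVR** — percutaneous annuloplasty.  In cycle 1 a fraction
  ``p_periop_death`` dies peri-procedurally; survivors split into an
  *implanted* sub-cohort (successful implantation) distributed over NYHA
  classes by the PMVR cycle-1 row, and a *recaptured* sub-cohort (device
  removed intra-operatively) that follows the medical-treatment dynamics
  from then on (intention-to-treat).
* **OMT** — optimal medical treatment; cycle 1 applies the ordinary
  combined mortality and the OMT cycle-1 transition row.

From cycle 2 each sub-cohort is stepped monthly: state-specific death
first (background + NYHA excess + severe-MR mixture), then transition
among survivors under the regime-appropriate matrix (cycles 2-11 versus
12 onwards).  Severe-MR prevalence in the implanted sub-cohort falls
from baseline to its post-procedure plateau; recaptured and OMT patients
keep the baseline prevalence throughout.  Hospitalizations are expected
cost-only events.  Under the fade-out scenario the whole treatment
effect of the implanted sub-cohort — transition matrices, severe-MR
trajectory and the protective relative-risk modifier — reverts to the
medical-treatment dynamics after month 36.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import economics
from .mortality import (
    NYHA_III,
    LifeTable,
    cycle_death_probability,
    cycle_death_vector,
    cycle_hospitalization_vector,
)
from .parameters import NYHA_STATES, ParameterSet

FADEOUT_MONTHS = 36  # observed follow-up horizon of the device studies
MAX_AGE = 100.0
EXTINCTION = 1e-9

SCENARIOS = (None, "fadeout", "lifetime")


@dataclasses.dataclass
class CohortTrace:
    """Per-cycle record of one arm's cohort.

    ``occupancy[m, s, k]`` is the proportion of the original cohort alive
    in sub-cohort ``s`` and NYHA state ``k`` at the end of cycle ``m+1``.
    Cost, QALY and life-year streams are undiscounted; discounting is
    applied by :func:`pmvr_cea.economics.aggregate`.
    """

    arm: str
    sub_cohorts: tuple[str, ...]
    occupancy: np.ndarray      # (n_cycles, n_sub, 4)
    cum_dead: np.ndarray       # (n_cycles,)
    hospitalizations: np.ndarray  # (n_cycles,) expected events
    cycle_cost: np.ndarray     # (n_cycles,) euros
    cycle_qaly: np.ndarray     # (n_cycles,)
    cycle_ly: np.ndarray       # (n_cycles,) years

    @property
    def n_cycles(self) -> int:
        return len(self.cum_dead)

    def alive(self, month: int) -> float:
        return float(self.occupancy[month - 1].sum())

    def to_frame(self, params: ParameterSet | None = None) -> pd.DataFrame:
        """Long-format export: one row per (cycle, sub_cohort, state),
        plus one ``summary`` row per cycle."""
        rows = []
        rate = params.discount_rate_annual if params is not None else 0.0
        for m in range(1, self.n_cycles + 1):
            for s, sub in enumerate(self.sub_cohorts):
                for k, state in enumerate(NYHA_STATES):
                    rows.append({
                        "cycle": m, "sub_cohort": sub, "state": state,
                        "occupancy": self.occupancy[m - 1, s, k],
                        "cum_dead": "", "hospitalizations": "",
                        "cost": "", "cost_discounted": "",
                        "qaly": "", "qaly_discounted": "", "ly": "",
                    })
            d = economics.discount_factor(m, rate)
            rows.append({
                "cycle": m, "sub_cohort": "summary", "state": "",
                "occupancy": self.occupancy[m - 1].sum(),
                "cum_dead": self.cum_dead[m - 1],
                "hospitalizations": self.hospitalizations[m - 1],
                "cost": self.cycle_cost[m - 1],
                "cost_discounted": self.cycle_cost[m - 1] * d,
                "qaly": self.cycle_qaly[m - 1],
                "qaly_discounted": self.cycle_qaly[m - 1] * d,
                "ly": self.cycle_ly[m - 1],
            })
        return pd.DataFrame(rows)


def is_treated(arm: str, sub_cohort: str, cycle: int,
               scenario: str | None = None) -> bool:
    """Whether a sub-cohort carries the implantation treatment effect.

    Only the successfully implanted sub-cohort is treated, from cycle 2
    onwards (cycle 1 mortality is the peri-procedural risk); under the
    fade-out scenario the effect ends after month 36.
    """
    if arm != "PMVR" or sub_cohort != "implanted" or cycle < 2:
        return False
    if scenario == "fadeout" and cycle > FADEOUT_MONTHS:
        return False
    return True


def p_severe_for(arm: str, sub_cohort: str, cycle: int, params: ParameterSet,
                 scenario: str | None = None) -> float:
    """Severe-MR prevalence for a sub-cohort at a given cycle."""
    if cycle < 1:
        raise ValueError("cycle index starts at 1")
    if arm == "PMVR" and sub_cohort == "implanted":
        if scenario == "fadeout" and cycle > FADEOUT_MONTHS:
            return params.p_severe_baseline
        if cycle == 1:
            return params.p_severe_baseline
        if cycle <= 5:
            return params.p_severe_pmvr_1to5
        return params.p_severe_pmvr_6plus
    return params.p_severe_baseline


def transition_matrix_for(arm: str, sub_cohort: str, cycle: int,
                          params: ParameterSet, scenario: str | None = None) -> np.ndarray:
    """Regime-appropriate 4x4 transition matrix for cycles >= 2.

    The implanted sub-cohort uses the PMVR matrices (reverting to OMT
    matrices after month 36 under the fade-out scenario); recaptured
    patients and the OMT arm use the OMT matrices.
    """
    if cycle < 2:
        raise ValueError("transition matrices apply from cycle 2 onwards")
    regime = "cycles2to11" if cycle <= 11 else "cycle12plus"
    matrix_arm = "PMVR" if (arm == "PMVR" and sub_cohort == "implanted") else "OMT"
    if scenario == "fadeout" and matrix_arm == "PMVR" and cycle > FADEOUT_MONTHS:
        matrix_arm = "OMT"
    return params.transitions.matrix(matrix_arm, regime)


def run_decision_tree(arm: str, params: ParameterSet, life_table: LifeTable):
    """Cycle 1: procedural outcomes (PMVR) or first-month OMT dynamics.

    Returns ``(occupancy, cycle_cost, cycle_qaly, deaths)`` where
    ``occupancy`` is (n_sub, 4) at the end of cycle 1.
    """
    omt_row1 = params.transitions.matrix("OMT", "cycle1")[NYHA_III]
    if arm == "PMVR":
        deaths = params.p_periop_death
        alive = 1.0 - deaths
        pmvr_row1 = params.transitions.matrix("PMVR", "cycle1")[NYHA_III]
        occ = np.vstack([
            alive * (1.0 - params.p_unsuccessful) * pmvr_row1,   # implanted
            alive * params.p_unsuccessful * omt_row1,            # recaptured
        ])
        total = occ.sum(axis=0)
        cost = economics.cycle_cost(total, 0.0, 1, params, pmvr_cycle1=True)
        qaly = economics.cycle_qaly(total, 1, "PMVR", params)
    else:
        deaths = cycle_death_probability(
            NYHA_III, params.age_start, params.p_severe_baseline, params, life_table)
        occ = ((1.0 - deaths) * omt_row1)[np.newaxis, :]
        hosp = float(occ[0] @ cycle_hospitalization_vector(params.p_severe_baseline, params))
        cost = economics.cycle_cost(occ[0], hosp, 1, params)
        qaly = economics.cycle_qaly(occ[0], 1, "OMT", params)
    return occ, cost, qaly, deaths


def run_cohort(arm: str, params: ParameterSet, life_table: LifeTable,
               scenario: str | None = None) -> CohortTrace:
    """Run one arm's cohort to the model horizon and return its trace.

    ``scenario`` is ``None`` (base case, fixed horizon), ``"fadeout"``
    (implanted sub-cohort loses its transition benefit after month 36) or
    ``"lifetime"`` (run to cohort extinction or age 100).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario: {scenario!r}")
    sub_cohorts = ("implanted", "recaptured") if arm == "PMVR" else ("omt",)
    n_sub = len(sub_cohorts)

    if scenario == "lifetime":
        horizon = max(1, int(np.ceil((MAX_AGE - params.age_start) * 12.0)))
    else:
        horizon = int(params.horizon_months)

    occ_hist, cum_dead, hosp_hist = [], [], []
    cost_hist, qaly_hist, ly_hist = [], [], []

    occ, cost1, qaly1, dead = run_decision_tree(arm, params, life_table)
    if arm == "PMVR":
        hosp1 = 0.0  # cycle 1 is the procedural admission itself
    else:
        hosp1 = float(occ[0] @ cycle_hospitalization_vector(
            p_severe_for(arm, "omt", 1, params), params))
    occ_hist.append(occ.copy())
    cum_dead.append(dead)
    hosp_hist.append(hosp1)
    cost_hist.append(cost1)
    qaly_hist.append(qaly1)
    ly_hist.append(occ.sum() / 12.0)

    # Per-sub-cohort caches: death/hospitalization vectors change only when
    # the integer age or the severe-MR regime changes; matrices change at
    # regime boundaries.
    cache_key = [None] * n_sub
    d_vec = [None] * n_sub
    h_vec = [None] * n_sub
    m_key = [None] * n_sub
    mat = [None] * n_sub

    for m in range(2, horizon + 1):
        age = params.age_start + (m - 1) / 12.0
        age_floor = int(age)
        deaths_m = 0.0
        hosp_m = 0.0
        for s, sub in enumerate(sub_cohorts):
            p_sev = p_severe_for(arm, sub, m, params, scenario)
            treated = is_treated(arm, sub, m, scenario)
            key = (age_floor, p_sev, treated)
            if key != cache_key[s]:
                d_vec[s] = cycle_death_vector(age, p_sev, params, life_table, treated)
                h_vec[s] = cycle_hospitalization_vector(p_sev, params, treated)
                cache_key[s] = key
            regime_key = ("cycles2to11" if m <= 11 else "cycle12plus",
                          scenario == "fadeout" and m > FADEOUT_MONTHS)
            if regime_key != m_key[s]:
                mat[s] = transition_matrix_for(arm, sub, m, params, scenario)
                m_key[s] = regime_key
            row = occ[s]
            dead_s = float(row @ d_vec[s])
            deaths_m += dead_s
            occ[s] = (row * (1.0 - d_vec[s])) @ mat[s]
            hosp_m += float(occ[s] @ h_vec[s])
        total = occ.sum(axis=0)
        occ_hist.append(occ.copy())
        cum_dead.append(cum_dead[-1] + deaths_m)
        hosp_hist.append(hosp_m)
        cost_hist.append(economics.cycle_cost(total, hosp_m, m, params))
        qaly_hist.append(economics.cycle_qaly(total, m, arm, params))
        ly_hist.append(total.sum() / 12.0)
        if scenario == "lifetime" and total.sum() < EXTINCTION:
            break

    return CohortTrace(
        arm=arm,
        sub_cohorts=sub_cohorts,
        occupancy=np.array(occ_hist),
        cum_dead=np.array(cum_dead),
        hospitalizations=np.array(hosp_hist),
        cycle_cost=np.array(cost_hist),
        cycle_qaly=np.array(qaly_hist),
        cycle_ly=np.array(ly_hist),
    )


def cumulative_mortality(trace: CohortTrace, month: int) -> float:
    """Cumulative all-cause mortality (proportion) at the end of a month."""
    if not 1 <= month <= trace.n_cycles:
        raise ValueError(f"month {month} outside trace horizon {trace.n_cycles}")
    return float(trace.cum_dead[month - 1])


def run_cea(params: ParameterSet, life_table: LifeTable,
            scenario: str | None = None) -> economics.CEAResult:
    """Run both arms and return the incremental cost-utility result."""
    trace_pmvr = run_cohort("PMVR", params, life_table, scenario)
    trace_omt = run_cohort("OMT", params, life_table, scenario)
    return economics.compare(
        economics.aggregate(trace_pmvr, params),
        economics.aggregate(trace_omt, params),
    )
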