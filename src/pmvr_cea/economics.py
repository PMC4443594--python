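"""Cost and QALY accrual, discounting, and incremental cost-effectiveness.

Costs comprise NYHA-specific routine heart-failure management (annual
tariffs accrued monthly on surviving occupancy), expected hospitalization
events priced at the DRG-mix average admission cost, and — in the first
cycle of the PMVR arm only — the device, the placement procedure and the
expected cost of vessel perforation.  Utilities are NYHA-specific and
accrue monthly on surviving occupancy; the PMVR arm carries a one-month
procedural utility decrement.  Discounting is annual-step at 3%/year with
the first model year exempt.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .parameters import ParameterSet

DOMINANT = "dominant"
DOMINATED = "dominated"


def expected_hospitalization_cost(params: ParameterSet) -> float:
    """Mean cost of one hospitalization under the DRG admission mix.

    The published mix proportions are used verbatim (they sum to 0.982
    after rounding); a gross normalization violation is an error.
    """
    mix = params.hosp_mix
    if abs(mix.sum() - 1.0) > 0.02:
        raise ValueError("hospitalization mix must sum to 1")
    return float(mix @ params.hosp_costs)


def cycle_cost(occupancy: np.ndarray, hosp_events: float, cycle: int,
               params: ParameterSet, pmvr_cycle1: bool = False) -> float:
    """Expected cost of one cycle given end-of-cycle occupancy.

    ``occupancy`` is the 4-vector of surviving cohort proportions over
    NYHA I-IV; ``hosp_events`` the expected hospitalizations this cycle.
    With ``pmvr_cycle1`` the device + procedure cost (borne for every
    attempted implantation, successful or not) and the expected
    perforation-management cost are added.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    cost = float(occupancy @ params.annual_mgmt_costs) / 12.0
    cost += hosp_events * expected_hospitalization_cost(params)
    if pmvr_cycle1:
        cost += params.cost_device + params.cost_procedure
        cost += params.p_perforation * params.cost_perforation
    return cost


def cycle_qaly(occupancy: np.ndarray, cycle: int, arm: str,
               params: ParameterSet) -> float:
    """Expected QALYs accrued in one cycle (1/12 of annual utility).

    Cycle 1 of the PMVR arm subtracts the procedural utility decrement
    for every surviving procedure patient.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    q = float(occupancy @ params.utilities) / 12.0
    if cycle == 1 and arm == "PMVR":
        q -= params.utility_decrement_procedure * float(occupancy.sum()) / 12.0
    return q


def discount_factor(cycle: int, rate: float) -> float:
    """Annual-step discount factor for a monthly cycle; year 1 is exempt."""
    if cycle < 1:
        raise ValueError("cycle index starts at 1")
    if cycle <= 12 or rate == 0.0:
        return 1.0
    return float((1.0 + rate) ** (-((cycle - 1) // 12)))


@dataclasses.dataclass(frozen=True)
class ArmTotals:
    """Discounted and undiscounted totals for one arm."""

    arm: str
    total_cost: float
    total_ly: float
    total_qaly: float
    total_cost_undiscounted: float
    total_ly_undiscounted: float
    total_qaly_undiscounted: float


def aggregate(trace, params: ParameterSet) -> ArmTotals:
    """Sum a cohort trace into discounted / undiscounted arm totals."""
    cycles = np.arange(1, trace.n_cycles + 1)
    disc = np.array([discount_factor(int(m), params.discount_rate_annual) for m in cycles])
    return ArmTotals(
        arm=trace.arm,
        total_cost=float(disc @ trace.cycle_cost),
        total_ly=float(disc @ trace.cycle_ly),
        total_qaly=float(disc @ trace.cycle_qaly),
        total_cost_undiscounted=float(trace.cycle_cost.sum()),
        total_ly_undiscounted=float(trace.cycle_ly.sum()),
        total_qaly_undiscounted=float(trace.cycle_qaly.sum()),
    )


def icer(result_a: ArmTotals, result_b: ArmTotals) -> float | str:
    """Incremental cost-effectiveness ratio of a versus comparator b.

    Returns ``"dominant"`` when a is cheaper and more effective,
    ``"dominated"`` when costlier and less effective, NaN when the QALY
    difference is zero while the cost difference is not.
    """
    dc = result_a.total_cost - result_b.total_cost
    dq = result_a.total_qaly - result_b.total_qaly
    if dq > 0 and dc < 0:
        return DOMINANT
    if dq < 0 and dc > 0:
        return DOMINATED
    if dq == 0:
        return 0.0 if dc == 0 else math.nan
    return dc / dq


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB = WTP * dQALY - dCost; positive means cost-effective at WTP."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


@dataclasses.dataclass(frozen=True)
class CEAResult:
    """Incremental cost-utility result of intervention versus comparator."""

    intervention: ArmTotals
    comparator: ArmTotals
    incremental_cost: float
    incremental_ly: float
    incremental_qaly: float
    icer: float | str

    def nmb(self, wtp: float) -> float:
        return net_monetary_benefit(self.incremental_cost, self.incremental_qaly, wtp)

    def to_rows(self) -> list[dict]:
        """Table-shaped rows (comparator first) for CSV export."""
        rows = [{
            "arm": self.comparator.arm,
            "cost": self.comparator.total_cost,
            "incremental_cost": "",
            "ly": self.comparator.total_ly,
            "incremental_ly": "",
            "qaly": self.comparator.total_qaly,
            "incremental_qaly": "",
            "icer": "",
        }, {
            "arm": self.intervention.arm,
            "cost": self.intervention.total_cost,
            "incremental_cost": self.incremental_cost,
            "ly": self.intervention.total_ly,
            "incremental_ly": self.incremental_ly,
            "qaly": self.intervention.total_qaly,
            "incremental_qaly": self.incremental_qaly,
            "icer": self.icer,
        }]
        return rows


def compare(totals_intervention: ArmTotals, totals_comparator: ArmTotals) -> CEAResult:
    """Assemble the incremental comparison of two arms' totals."""
    return CEAResult(
        intervention=totals_intervention,
        comparator=totals_comparator,
        incremental_cost=totals_intervention.total_cost - totals_comparator.total_cost,
        incremental_ly=totals_intervention.total_ly - totals_comparator.total_ly,
        incremental_qaly=totals_intervention.total_qaly - totals_comparator.total_qaly,
        icer=icer(totals_intervention, totals_comparator),
    )
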