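"""Per-cycle death and hospitalization probabilities.

Monthly mortality in each NYHA state combines three ingredients as
independent competing risks:

* background mortality from an age- and sex-specific period life table,
  mixed over the cohort's male fraction;
* NYHA-specific excess mortality, published as six-month probabilities
  and converted to monthly under a constant-hazard assumption;
* a severe-MR adjustment built from the mixture multiplier
  ``(1 - p_severe) + p_severe * rr``.

The referent conventions differ by risk, matching the provenance of the
published baselines.  The excess-*mortality* baselines describe the
trial-average heart-failure cohort (63.9% severe MR), so the mortality
multiplier is the mixture ratio against that baseline severity and
equals 1 for the untreated cohort.  The *hospitalization* baselines are
taken as a non-severe referent, so the full mixture multiplier applies.
Successful implantation is modelled as removing the excess risk
attributable to severe MR: the treated sub-cohort's multiplier is
additionally divided by the relative risk, on top of its lower severe-MR
prevalence.  NYHA class I carries no excess mortality.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ParameterSet

NYHA_I, NYHA_II, NYHA_III, NYHA_IV = 0, 1, 2, 3


@dataclasses.dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by integer age and sex.

    Ages must be contiguous; lookups above the last row clamp to it,
    lookups below the first row are a domain error.
    """

    age: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.age) != 1):
            raise ValueError("life-table ages must increase by exactly 1")
        for q in (self.q_male, self.q_female):
            if np.any((q < 0) | (q > 1)):
                raise ValueError("life-table q values must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "q_male", "q_female"} - set(df.columns)
        if missing:
            raise ValueError(f"life-table CSV missing columns: {sorted(missing)}")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(dtype=int),
                   df["q_male"].to_numpy(dtype=float),
                   df["q_female"].to_numpy(dtype=float))

    @classmethod
    def bundled_german(cls) -> "LifeTable":
        """The packaged German period life table, ages 50-100."""
        ref = importlib.resources.files("pmvr_cea") / "data" / "life_table_de.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)

    def annual_q(self, age: float, male_fraction: float) -> float:
        """Sex-mixed annual death probability at floor(age)."""
        a = int(np.floor(age))
        if a < self.age[0]:
            raise ValueError(f"age {age} below life-table start {self.age[0]}")
        i = min(a - int(self.age[0]), len(self.age) - 1)
        return male_fraction * self.q_male[i] + (1.0 - male_fraction) * self.q_female[i]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.age, "q_male": self.q_male,
                      "q_female": self.q_female}).to_csv(path, index=False)


def period_to_monthly(p: float, k: int) -> float:
    """Convert a k-month probability to monthly assuming constant hazard.

    ``1 - (1 - p)**(1/k)``; the inverse transform recovers ``p`` exactly.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if k < 1:
        raise ValueError("period length must be >= 1 month")
    return 1.0 - (1.0 - p) ** (1.0 / k)


def monthly_background_q(life_table: LifeTable, age: float, male_fraction: float) -> float:
    """Monthly background death probability at the cohort's current age."""
    return period_to_monthly(life_table.annual_q(age, male_fraction), 12)


def severe_mix_multiplier(p_severe: float, rr: float) -> float:
    """Cohort-average risk multiplier when a fraction has severe MR.

    A fraction ``p_severe`` of the cohort carries relative risk ``rr``
    against a non-severe referent, so the cohort-average multiplier is
    ``(1 - p_severe) + p_severe*rr``.
    """
    if not 0.0 <= p_severe <= 1.0:
        raise ValueError(f"p_severe {p_severe} outside [0, 1]")
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    return (1.0 - p_severe) + p_severe * rr


def severe_adjustment(p_severe: float, rr: float, p_referent: float | None = None,
                      treated: bool = False) -> float:
    """Severe-MR risk adjustment for a (sub-)cohort.

    The mixture multiplier at prevalence ``p_severe`` is renormalized by
    the multiplier at ``p_referent`` when the published baseline risk
    describes a cohort with that average severity (pass ``None`` for a
    non-severe referent).  For the successfully implanted sub-cohort
    (``treated``) the adjustment is further divided by ``rr``: the
    procedure is modelled as removing the excess risk attributable to
    severe regurgitation in addition to lowering its prevalence.
    """
    mult = severe_mix_multiplier(p_severe, rr)
    if p_referent is not None:
        mult /= severe_mix_multiplier(p_referent, rr)
    if treated:
        mult /= rr
    return mult


def cycle_death_probability(nyha: int, cycle_age: float, p_severe: float,
                            params: ParameterSet, life_table: LifeTable,
                            treated: bool = False) -> float:
    """Monthly all-cause death probability for one NYHA state.

    Background and NYHA excess mortality combine as independent risks:
    ``1 - (1 - p_bg)(1 - p_excess)``.  NYHA I has zero excess mortality.
    The excess-mortality baselines describe the baseline-severity cohort,
    so the severe-MR adjustment is renormalized to ``p_severe_baseline``.
    """
    p_bg = monthly_background_q(life_table, cycle_age, params.male_fraction)
    if nyha == NYHA_I:
        return p_bg
    p6 = params.p6_excess_death[nyha]
    p_excess = period_to_monthly(p6, 6) * severe_adjustment(
        p_severe, params.rr_mortality_severe_mr,
        p_referent=params.p_severe_baseline, treated=treated)
    p_excess = min(p_excess, 1.0)
    return 1.0 - (1.0 - p_bg) * (1.0 - p_excess)


def cycle_death_vector(cycle_age: float, p_severe: float,
                       params: ParameterSet, life_table: LifeTable,
                       treated: bool = False) -> np.ndarray:
    """Vectorized :func:`cycle_death_probability` over NYHA I-IV."""
    p_bg = monthly_background_q(life_table, cycle_age, params.male_fraction)
    mult = severe_adjustment(p_severe, params.rr_mortality_severe_mr,
                             p_referent=params.p_severe_baseline, treated=treated)
    p6 = params.p6_excess_death
    p_excess = np.minimum((1.0 - (1.0 - p6) ** (1.0 / 6.0)) * mult, 1.0)
    p_excess[NYHA_I] = 0.0
    return 1.0 - (1.0 - p_bg) * (1.0 - p_excess)


def cycle_hospitalization_probability(nyha: int, p_severe: float,
                                      params: ParameterSet,
                                      treated: bool = False) -> float:
    """Monthly hospitalization probability for one NYHA state.

    The published monthly probabilities are the non-severe referent, so
    the full mixture multiplier applies (divided by the relative risk
    for the treated sub-cohort).
    """
    mult = severe_adjustment(p_severe, params.rr_hosp_severe_mr, treated=treated)
    return min(params.p_month_hosp[nyha] * mult, 1.0)


def cycle_hospitalization_vector(p_severe: float, params: ParameterSet,
                                 treated: bool = False) -> np.ndarray:
    """Vectorized :func:`cycle_hospitalization_probability` over NYHA I-IV."""
    mult = severe_adjustment(p_severe, params.rr_hosp_severe_mr, treated=treated)
    return np.minimum(params.p_month_hosp * mult, 1.0)
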