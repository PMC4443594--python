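"""Deterministic and probabilistic sensitivity analysis and scenarios.

One-way DSA re-runs both arms at each parameter's published low/high
bound (tornado diagram).  PSA draws every uncertain parameter from its
published distribution — Beta for probabilities and utilities, Gamma for
routine-management costs, log-normal for the severe-MR relative risks,
truncated normal for age, Dirichlet for transition-matrix rows and the
hospitalization mix — and summarizes the draw-level incremental pairs as
an ICER of means and a cost-effectiveness acceptability curve (CEAC).
DRG tariffs and the device/procedure costs are fixed (no uncertainty).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import economics
from .markov import run_cea
from .mortality import LifeTable
from .parameters import (
    ARMS,
    PARAM_SPECS,
    REGIMES,
    SPEC_BY_NAME,
    DistSpec,
    ParameterSet,
)

_HOSP_MIX_FIELDS = ("hosp_mix_icu", "hosp_mix_ccu", "hosp_mix_cabg",
                    "hosp_mix_ptca", "hosp_mix_transplant", "hosp_mix_none")

#: Willingness-to-pay grid for the CEAC, euros/QALY.
CEAC_GRID = np.arange(0, 100_001, 1_000)


@dataclasses.dataclass(frozen=True)
class TornadoEntry:
    """One-way DSA result for a single parameter."""

    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _numeric_icer(result: economics.CEAResult) -> float:
    """ICER as a plain ratio for tornado plotting (dominance included)."""
    if isinstance(result.icer, str):
        return result.incremental_cost / result.incremental_qaly
    return result.icer


def one_way(param_name: str, params: ParameterSet, life_table: LifeTable,
            bounds: tuple[float, float] | None = None) -> TornadoEntry:
    """Re-run both arms at a parameter's low and high published bound.

    ``bounds`` overrides the registry range (e.g. for custom intervals).
    """
    spec = SPEC_BY_NAME.get(param_name)
    if spec is None:
        raise KeyError(f"unknown parameter: {param_name}")
    if bounds is None:
        if spec.dsa is None:
            raise ValueError(f"parameter {param_name} has no published range")
        bounds = spec.dsa
    lo, hi = bounds
    icer_lo = _numeric_icer(run_cea(params.replace(**{param_name: lo}), life_table))
    icer_hi = _numeric_icer(run_cea(params.replace(**{param_name: hi}), life_table))
    return TornadoEntry(param_name, icer_lo, icer_hi)


def tornado(params: ParameterSet, life_table: LifeTable,
            parameters: list[str] | None = None) -> list[TornadoEntry]:
    """One entry per ranged parameter, sorted by span descending."""
    if parameters is None:
        parameters = [s.name for s in PARAM_SPECS if s.dsa is not None]
    entries = [one_way(name, params, life_table) for name in parameters]
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def _draw_scalar(base: float, dist: DistSpec, rng: np.random.Generator,
                 lo_support: float | None = None) -> float:
    if dist.family == "fixed":
        return base
    if dist.family == "beta":
        a, b = dist.args
        return float(rng.beta(a, b))
    if dist.family == "gamma":
        shape, scale = dist.args
        return float(rng.gamma(shape) * scale)
    if dist.family == "lognormal":
        (se_log,) = dist.args
        return float(base * np.exp(rng.normal(0.0, se_log)))
    if dist.family == "truncnormal":
        sd, lo, hi = dist.args
        if lo_support is not None:
            lo = max(lo, lo_support)
        for _ in range(1000):
            x = rng.normal(base, sd)
            if lo <= x <= hi:
                return float(x)
        return float(min(max(base, lo), hi))
    raise ValueError(f"unknown distribution family: {dist.family}")


def _dirichlet_row(row: np.ndarray, n_eff: float, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw with concentration row * n_eff; zero entries stay zero."""
    out = np.zeros_like(row)
    pos = row > 0
    if pos.sum() <= 1 or n_eff <= 0:
        return row.copy()
    out[pos] = rng.dirichlet(row[pos] * n_eff)
    return out


def sample_parameters(params: ParameterSet, rng: np.random.Generator,
                      scalar_dists: dict[str, DistSpec] | None = None,
                      life_table: LifeTable | None = None) -> ParameterSet:
    """One PSA draw of the full parameter set.

    Scalar parameters follow their registry distribution (overridable via
    ``scalar_dists``, e.g. to replace every distribution by a point mass);
    the hospitalization mix and every data-carrying transition row are
    Dirichlet draws with effective counts ``psa_hosp_mix_n`` and
    ``psa_transition_n_{pmvr,omt}`` (zero disables resampling).  Age draws
    are truncated to the life table's supported range when one is given.
    """
    values = dict(params.values)
    age_floor = float(life_table.age[0]) if life_table is not None else None
    for spec in PARAM_SPECS:
        dist = spec.psa
        if scalar_dists is not None and spec.name in scalar_dists:
            dist = scalar_dists[spec.name]
        if dist.family == "fixed" or spec.name in _HOSP_MIX_FIELDS:
            continue
        lo_support = age_floor if spec.name == "age_start" else None
        values[spec.name] = _draw_scalar(values[spec.name], dist, rng, lo_support)

    mix_n = params.psa_hosp_mix_n
    if mix_n > 0:
        mix = _dirichlet_row(params.hosp_mix, mix_n, rng)
        for f, v in zip(_HOSP_MIX_FIELDS, mix):
            values[f] = float(v)

    transitions = params.transitions.copy()
    n_eff = {"PMVR": params.psa_transition_n_pmvr, "OMT": params.psa_transition_n_omt}
    for arm in ARMS:
        if n_eff[arm] <= 0:
            continue
        for regime in REGIMES:
            mat = transitions.matrices[(arm, regime)]
            for i in np.flatnonzero(transitions.data_rows[(arm, regime)]):
                mat[i] = _dirichlet_row(mat[i], n_eff[arm], rng)
    return ParameterSet(values, transitions)


@dataclasses.dataclass
class PSAResult:
    """Draw-level incremental pairs with CEAC and summary statistics."""

    draws: np.ndarray  # (n, 2): incremental cost, incremental QALY
    seed: int
    mean_incremental_cost: float = dataclasses.field(init=False)
    mean_incremental_qaly: float = dataclasses.field(init=False)
    icer_of_means: float = dataclasses.field(init=False)
    ceac: list[tuple[float, float]] = dataclasses.field(init=False)

    def __post_init__(self):
        self.mean_incremental_cost = float(self.draws[:, 0].mean())
        self.mean_incremental_qaly = float(self.draws[:, 1].mean())
        self.icer_of_means = self.mean_incremental_cost / self.mean_incremental_qaly
        self.ceac = [(float(w), self.probability_cost_effective(float(w)))
                     for w in CEAC_GRID]

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def probability_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with positive net monetary benefit at WTP."""
        nmb = wtp * self.draws[:, 1] - self.draws[:, 0]
        return float(np.mean(nmb > 0))


def run_psa(params: ParameterSet, life_table: LifeTable, n_draws: int,
            seed: int, scalar_dists: dict[str, DistSpec] | None = None) -> PSAResult:
    """Monte-Carlo PSA: sample, run both arms, record incremental pairs.

    Bit-reproducible for a fixed ``seed`` and ``n_draws``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, 2))
    for i in range(n_draws):
        drawn = sample_parameters(params, rng, scalar_dists, life_table)
        res = run_cea(drawn, life_table)
        draws[i] = (res.incremental_cost, res.incremental_qaly)
    return PSAResult(draws=draws, seed=seed)


def scenario_fadeout(params: ParameterSet, life_table: LifeTable) -> economics.CEAResult:
    """Treatment effect limited to the observed 3-year follow-up."""
    return run_cea(params, life_table, scenario="fadeout")


def scenario_lifetime(params: ParameterSet, life_table: LifeTable) -> economics.CEAResult:
    """Run to cohort extinction (age cap 100) instead of 10 years."""
    return run_cea(params, life_table, scenario="lifetime")
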