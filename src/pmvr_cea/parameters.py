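"""Model inputs for the PMVR-vs-OMT cost-utility model.

Every scalar input of the model (cohort demographics, procedural
probabilities, NYHA-specific excess mortality and hospitalization,
severe-MR relative risks, German DRG tariffs, routine-management costs,
utilities, discounting and horizon) lives in :class:`ParameterSet`,
together with its one-way sensitivity range and the distribution used in
probabilistic sensitivity analysis.  The six NYHA transition matrices
(arm x cycle regime) live in :class:`TransitionMatrixSet`.

The default values are the German base case: a cohort aged 62, 77% male,
all in NYHA class III at entry, 63.9% with severe functional mitral
regurgitation, evaluated from the statutory-health-insurance perspective
in 2013 euros over a 10-year horizon with 3% annual discounting.
"""

from __future__ import annotations

import dataclasses
import io
from typing import NamedTuple

import numpy as np
import yaml

ARMS = ("OMT", "PMVR")
REGIMES = ("cycle1", "cycles2to11", "cycle12plus")
NYHA_STATES = ("I", "II", "III", "IV")

#: |row sum - 1| tolerated in a loaded transition row before it is a hard
#: error; rows inside the band are renormalized (two-decimal rounding of
#: published rows can leave sums such as 1.01).
ROW_SUM_TOLERANCE = 0.02


class Finding(NamedTuple):
    """One validation finding: ``level`` is ``ERROR`` or ``WARNING``."""

    level: str
    field: str
    message: str


class DistSpec(NamedTuple):
    """PSA distribution spec: family plus its parameters.

    Families: ``fixed`` (no sampling), ``beta(a, b)``, ``gamma(shape,
    scale)``, ``lognormal(se_log)`` centred at the log of the base value,
    ``truncnormal(sd, lo, hi)`` centred at the base value.
    """

    family: str
    args: tuple = ()


FIXED = DistSpec("fixed")


class ParamSpec(NamedTuple):
    name: str
    base: float
    kind: str  # prob | utility | cost | rr | age | rate | count
    dsa: tuple | None  # (low, high) or None if no published range
    psa: DistSpec


def _beta(a, b):
    return DistSpec("beta", (a, b))


def _gamma(shape, scale):
    return DistSpec("gamma", (shape, scale))


def _lognorm(se_log):
    return DistSpec("lognormal", (se_log,))


# Effective sample size behind the male-gender proportion (implanted +
# recaptured patients of the source trial); Table-style inputs publish no
# Beta parameters for it.
_TRIAL_N = 53

#: Registry of every scalar input: base value, one-way range, PSA family.
PARAM_SPECS: tuple[ParamSpec, ...] = (
    ParamSpec("age_start", 62.0, "age", (50.0, 80.0), DistSpec("truncnormal", (12.0, 18.0, 100.0))),
    ParamSpec("male_fraction", 0.77, "prob", (0.0, 1.0), _beta(0.77 * _TRIAL_N, 0.23 * _TRIAL_N)),
    ParamSpec("p_severe_baseline", 0.639, "prob", (0.511, 0.766), _beta(23, 13)),
    ParamSpec("p_severe_pmvr_1to5", 0.35, "prob", (0.28, 0.42), _beta(12, 22)),
    ParamSpec("p_severe_pmvr_6plus", 0.258, "prob", (0.206, 0.309), _beta(8, 23)),
    ParamSpec("p_periop_death", 0.019, "prob", (0.01, 0.03), _beta(1, 52)),
    ParamSpec("p_mi_pci", 0.04, "prob", (0.02, 0.06), _beta(2, 51)),
    ParamSpec("p_perforation", 0.02, "prob", (0.0, 0.03), _beta(1, 52)),
    ParamSpec("p_unsuccessful", 0.32, "prob", (0.05, 0.40), _beta(17, 36)),
    ParamSpec("p_arrhythmia", 0.04, "prob", (0.02, 0.06), _beta(2, 51)),
    ParamSpec("p6_excess_death_nyha2", 0.04, "prob", (0.02, 0.06), _beta(4, 96)),
    ParamSpec("p6_excess_death_nyha3", 0.07, "prob", (0.035, 0.105), _beta(7, 93)),
    ParamSpec("p6_excess_death_nyha4", 0.28, "prob", (0.14, 0.42), _beta(28, 72)),
    ParamSpec("p_month_hosp_nyha1", 0.015, "prob", (0.008, 0.023), _beta(1.5, 98.5)),
    ParamSpec("p_month_hosp_nyha2", 0.024, "prob", (0.012, 0.036), _beta(2.4, 97.6)),
    ParamSpec("p_month_hosp_nyha3", 0.024, "prob", (0.012, 0.036), _beta(2.4, 97.6)),
    ParamSpec("p_month_hosp_nyha4", 0.154, "prob", (0.077, 0.231), _beta(15.4, 84.6)),
    ParamSpec("rr_mortality_severe_mr", 1.5, "rr", (1.1, 1.9), _lognorm(0.26)),
    ParamSpec("rr_hosp_severe_mr", 1.7, "rr", (1.3, 2.1), _lognorm(0.33)),
    ParamSpec("cost_device", 18000.0, "cost", (12600.0, 23400.0), FIXED),
    ParamSpec("cost_procedure", 4844.0, "cost", (3391.0, 6297.0), FIXED),
    ParamSpec("cost_perforation", 1998.0, "cost", (1399.0, 2597.0), FIXED),
    ParamSpec("hosp_mix_icu", 0.072, "prob", None, FIXED),
    ParamSpec("hosp_mix_ccu", 0.256, "prob", None, FIXED),
    ParamSpec("hosp_mix_cabg", 0.003, "prob", None, FIXED),
    ParamSpec("hosp_mix_ptca", 0.002, "prob", None, FIXED),
    ParamSpec("hosp_mix_transplant", 0.026, "prob", None, FIXED),
    ParamSpec("hosp_mix_none", 0.623, "prob", None, FIXED),
    ParamSpec("hosp_cost_icu", 5004.0, "cost", (3503.0, 6506.0), FIXED),
    ParamSpec("hosp_cost_ccu", 5004.0, "cost", (3503.0, 6506.0), FIXED),
    ParamSpec("hosp_cost_cabg", 15056.0, "cost", (10539.0, 19573.0), FIXED),
    ParamSpec("hosp_cost_ptca", 3793.0, "cost", (2655.0, 4931.0), FIXED),
    ParamSpec("hosp_cost_transplant", 86337.0, "cost", (60436.0, 112239.0), FIXED),
    ParamSpec("hosp_cost_none", 2740.0, "cost", (1918.0, 3562.0), FIXED),
    ParamSpec("annual_mgmt_cost_nyha1", 495.0, "cost", (258.0, 1031.0), _gamma(1, 516)),
    ParamSpec("annual_mgmt_cost_nyha2", 874.0, "cost", (455.0, 1821.0), _gamma(1, 910)),
    ParamSpec("annual_mgmt_cost_nyha3", 864.0, "cost", (450.0, 1800.0), _gamma(1, 900)),
    ParamSpec("annual_mgmt_cost_nyha4", 929.0, "cost", (484.0, 1935.0), _gamma(1, 967)),
    ParamSpec("utility_nyha1", 0.815, "utility", (0.652, 0.978), _beta(395, 90)),
    ParamSpec("utility_nyha2", 0.720, "utility", (0.576, 0.864), _beta(662, 257)),
    ParamSpec("utility_nyha3", 0.590, "utility", (0.472, 0.708), _beta(360, 250)),
    ParamSpec("utility_nyha4", 0.508, "utility", (0.406, 0.609), _beta(52, 50)),
    ParamSpec("utility_decrement_procedure", 0.043, "utility", (0.034, 0.051), _beta(96, 2129)),
    ParamSpec("discount_rate_annual", 0.03, "rate", None, FIXED),
    ParamSpec("horizon_months", 120, "count", None, FIXED),
    ParamSpec("wtp_threshold", 35000.0, "cost", None, FIXED),
    # Dirichlet effective counts used when sampling transition rows and the
    # hospitalization mix in PSA (source-trial arm sizes; CARE-HF mix n).
    ParamSpec("psa_transition_n_pmvr", 36, "count", None, FIXED),
    ParamSpec("psa_transition_n_omt", 17, "count", None, FIXED),
    ParamSpec("psa_hosp_mix_n", 813, "count", None, FIXED),
)

SPEC_BY_NAME: dict[str, ParamSpec] = {s.name: s for s in PARAM_SPECS}

_HOSP_MIX_FIELDS = ("hosp_mix_icu", "hosp_mix_ccu", "hosp_mix_cabg",
                    "hosp_mix_ptca", "hosp_mix_transplant", "hosp_mix_none")
_HOSP_COST_FIELDS = ("hosp_cost_icu", "hosp_cost_ccu", "hosp_cost_cabg",
                     "hosp_cost_ptca", "hosp_cost_transplant", "hosp_cost_none")

# Published transition rows (conditional on surviving the cycle).  Cycle-1
# matrices only define the NYHA III row because the whole cohort enters in
# class III; other cycle-1 rows are structural identity rows.
_RAW_MATRICES: dict[tuple[str, str], list[list[float] | None]] = {
    ("OMT", "cycle1"): [None, None, [0.00, 0.17, 0.75, 0.08], None],
    ("PMVR", "cycle1"): [None, None, [0.10, 0.73, 0.13, 0.03], None],
    ("OMT", "cycles2to11"): [
        [0.00, 0.00, 0.00, 0.00],
        [0.00, 0.67, 0.00, 0.33],
        [0.00, 0.17, 0.83, 0.00],
        [0.00, 0.00, 0.17, 0.83],
    ],
    ("PMVR", "cycles2to11"): [
        [0.25, 0.75, 0.00, 0.00],
        [0.11, 0.63, 0.26, 0.00],
        [0.00, 0.50, 0.50, 0.00],
        [0.00, 0.00, 0.50, 0.50],
    ],
    ("OMT", "cycle12plus"): [
        [0.00, 0.00, 0.00, 0.00],
        [0.00, 0.50, 0.50, 0.00],
        [0.00, 0.67, 0.33, 0.00],
        [0.00, 0.00, 0.67, 0.33],
    ],
    ("PMVR", "cycle12plus"): [
        [0.67, 0.33, 0.00, 0.00],
        [0.12, 0.71, 0.18, 0.00],  # published row sums to 1.01; renormalized
        [0.00, 0.40, 0.60, 0.00],
        [0.00, 0.00, 0.40, 0.60],
    ],
}


@dataclasses.dataclass
class TransitionMatrixSet:
    """The six 4x4 NYHA transition matrices, row-stochastic among survivors.

    ``matrices[(arm, regime)]`` is a (4, 4) array over NYHA I-IV.
    ``data_rows[(arm, regime)]`` flags which rows carry observed data (and
    are therefore resampled in PSA); identity-substituted and structural
    rows are fixed.  ``findings`` records the load-time substitutions.
    """

    matrices: dict[tuple[str, str], np.ndarray]
    data_rows: dict[tuple[str, str], np.ndarray]
    findings: list[Finding] = dataclasses.field(default_factory=list)

    def matrix(self, arm: str, regime: str) -> np.ndarray:
        return self.matrices[(arm, regime)]

    def copy(self) -> "TransitionMatrixSet":
        return TransitionMatrixSet(
            {k: v.copy() for k, v in self.matrices.items()},
            {k: v.copy() for k, v in self.data_rows.items()},
            list(self.findings),
        )

    def to_dict(self) -> dict:
        out: dict = {}
        for arm in ARMS:
            out[arm] = {}
            for regime in REGIMES:
                out[arm][regime] = [
                    [float(x) for x in row] for row in self.matrices[(arm, regime)]
                ]
        return out


def _build_matrix_set(raw: dict[tuple[str, str], list]) -> TransitionMatrixSet:
    """Assemble matrices from (possibly rounded) published rows.

    All-zero rows are replaced by the identity row with a WARNING (the state
    is unreachable under that arm, so the substitution adds no dynamics);
    rows whose sum is off by at most ``ROW_SUM_TOLERANCE`` are renormalized
    with a WARNING; larger deviations raise at validation time via an ERROR
    finding.
    """
    matrices: dict[tuple[str, str], np.ndarray] = {}
    data_rows: dict[tuple[str, str], np.ndarray] = {}
    findings: list[Finding] = []
    for (arm, regime), rows in raw.items():
        mat = np.zeros((4, 4))
        is_data = np.zeros(4, dtype=bool)
        for i, row in enumerate(rows):
            label = f"transitions.{arm}.{regime}.NYHA_{NYHA_STATES[i]}"
            if row is None:
                mat[i, i] = 1.0
                continue
            r = np.asarray(row, dtype=float)
            if np.any(r < 0) or np.any(r > 1):
                findings.append(Finding("ERROR", label, "entries outside [0, 1]"))
                mat[i] = r
                continue
            s = r.sum()
            if s == 0:
                mat[i, i] = 1.0
                findings.append(Finding(
                    "WARNING", label,
                    "all-zero row replaced by identity (state unreachable in this arm)"))
            elif abs(s - 1.0) <= 1e-9:
                mat[i] = r
                is_data[i] = True
            elif abs(s - 1.0) <= ROW_SUM_TOLERANCE:
                mat[i] = r / s
                is_data[i] = True
                findings.append(Finding(
                    "WARNING", label,
                    f"row sum {s:.4f} renormalized to 1 (printed rounding)"))
            else:
                findings.append(Finding("ERROR", label, f"row sum {s:.4f} not 1"))
                mat[i] = r
        matrices[(arm, regime)] = mat
        data_rows[(arm, regime)] = is_data
    return TransitionMatrixSet(matrices, data_rows, findings)


def _default_field_values() -> dict:
    return {s.name: s.base for s in PARAM_SPECS}


def _coerce(name: str, value) -> float | int:
    spec = SPEC_BY_NAME.get(name)
    if spec is not None and spec.kind == "count":
        return int(value)
    return float(value)


@dataclasses.dataclass
class ParameterSet:
    """Full model configuration: every scalar input plus the transition set.

    Scalar values are attributes named exactly as in :data:`PARAM_SPECS`;
    per-parameter metadata (range, PSA distribution) stays in the registry
    so overridden values keep their spec.
    """

    values: dict = dataclasses.field(default_factory=_default_field_values)
    transitions: TransitionMatrixSet = dataclasses.field(
        default_factory=lambda: _build_matrix_set(_RAW_MATRICES))

    def __getattr__(self, name):
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)

    # -- convenience views -------------------------------------------------
    @property
    def hosp_mix(self) -> np.ndarray:
        return np.array([self.values[f] for f in _HOSP_MIX_FIELDS])

    @property
    def hosp_costs(self) -> np.ndarray:
        return np.array([self.values[f] for f in _HOSP_COST_FIELDS])

    @property
    def utilities(self) -> np.ndarray:
        return np.array([self.values[f"utility_nyha{i}"] for i in (1, 2, 3, 4)])

    @property
    def annual_mgmt_costs(self) -> np.ndarray:
        return np.array([self.values[f"annual_mgmt_cost_nyha{i}"] for i in (1, 2, 3, 4)])

    @property
    def p6_excess_death(self) -> np.ndarray:
        """Six-month excess-mortality probabilities by NYHA I-IV (I is 0)."""
        return np.array([0.0] + [self.values[f"p6_excess_death_nyha{i}"] for i in (2, 3, 4)])

    @property
    def p_month_hosp(self) -> np.ndarray:
        return np.array([self.values[f"p_month_hosp_nyha{i}"] for i in (1, 2, 3, 4)])

    def replace(self, **overrides) -> "ParameterSet":
        """Return a copy with named scalar values replaced."""
        for k in overrides:
            if k not in self.values:
                raise KeyError(f"unknown parameter: {k}")
        new = dict(self.values)
        new.update({k: _coerce(k, v) for k, v in overrides.items()})
        return ParameterSet(new, self.transitions.copy())

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {name: self.values[name] for name in (s.name for s in PARAM_SPECS)}
        out["transitions"] = self.transitions.to_dict()
        return out

    def to_yaml(self) -> str:
        buf = io.StringIO()
        yaml.safe_dump(self.to_dict(), buf, sort_keys=False, default_flow_style=None)
        return buf.getvalue()


def default_parameters() -> ParameterSet:
    """The base-case configuration with all published values embedded."""
    return ParameterSet()


def load_parameters(config_text: str | dict | None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a YAML/JSON override document.

    Only keys present in the document are overridden; unknown keys are
    rejected.  Transition matrices may be overridden wholesale under the
    ``transitions`` key as ``{arm: {regime: [[...], ...]}}``.  The result
    is fully validated; ERROR findings raise ``ValueError``.
    """
    if config_text is None:
        doc: dict = {}
    elif isinstance(config_text, dict):
        doc = dict(config_text)
    else:
        doc = yaml.safe_load(config_text) or {}
        if not isinstance(doc, dict):
            raise ValueError("config must be a mapping")

    raw_trans = doc.pop("transitions", None)
    unknown = [k for k in doc if k not in SPEC_BY_NAME]
    if unknown:
        raise ValueError(f"unknown parameter keys: {', '.join(sorted(unknown))}")

    values = _default_field_values()
    for k, v in doc.items():
        values[k] = _coerce(k, v)

    if raw_trans is None:
        transitions = _build_matrix_set(_RAW_MATRICES)
    else:
        raw = {k: list(v) for k, v in _RAW_MATRICES.items()}
        for arm, regimes in raw_trans.items():
            if arm not in ARMS:
                raise ValueError(f"unknown arm in transitions: {arm}")
            for regime, rows in regimes.items():
                if regime not in REGIMES:
                    raise ValueError(f"unknown regime in transitions: {regime}")
                raw[(arm, regime)] = rows
        transitions = _build_matrix_set(raw)

    params = ParameterSet(values, transitions)
    errors = [f for f in validate(params) if f.level == "ERROR"]
    if errors:
        msgs = "; ".join(f"{f.field}: {f.message}" for f in errors)
        raise ValueError(f"invalid configuration: {msgs}")
    return params


def validate(params: ParameterSet) -> list[Finding]:
    """Check every invariant; return findings rather than raising.

    The default set yields WARNINGs only (identity-substituted all-zero
    rows, the renormalized published row); any bound violation is an ERROR.
    """
    findings: list[Finding] = []
    for spec in PARAM_SPECS:
        v = params.values[spec.name]
        if spec.kind in ("prob", "utility") and not (0.0 <= v <= 1.0):
            findings.append(Finding("ERROR", spec.name, f"value {v} outside [0, 1]"))
        elif spec.kind == "cost" and v < 0:
            findings.append(Finding("ERROR", spec.name, f"negative cost {v}"))
        elif spec.kind == "rr" and v <= 0:
            findings.append(Finding("ERROR", spec.name, f"relative risk {v} must be > 0"))
        elif spec.kind in ("age", "count") and v <= 0:
            findings.append(Finding("ERROR", spec.name, f"value {v} must be > 0"))
        if spec.dsa is not None:
            lo, hi = spec.dsa
            base = SPEC_BY_NAME[spec.name].base
            if not (lo <= base <= hi):
                findings.append(Finding(
                    "ERROR", spec.name, f"range ({lo}, {hi}) does not bracket base {base}"))
    mix_sum = params.hosp_mix.sum()
    if abs(mix_sum - 1.0) > ROW_SUM_TOLERANCE:
        findings.append(Finding(
            "ERROR", "hosp_mix", f"hospitalization mix sums to {mix_sum:.6f}, not 1"))
    elif abs(mix_sum - 1.0) > 1e-9:
        findings.append(Finding(
            "WARNING", "hosp_mix",
            f"hospitalization mix sums to {mix_sum:.6f} (printed rounding); used verbatim"))
    findings.extend(params.transitions.findings)
    for (arm, regime), mat in params.transitions.matrices.items():
        for i, row in enumerate(mat):
            label = f"transitions.{arm}.{regime}.NYHA_{NYHA_STATES[i]}"
            if np.any(row < 0) or np.any(row > 1):
                findings.append(Finding("ERROR", label, "entries outside [0, 1]"))
            elif abs(row.sum() - 1.0) > 1e-9:
                findings.append(Finding("ERROR", label, f"row sum {row.sum():.6f} not 1"))
    return findings
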