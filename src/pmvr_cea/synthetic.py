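"""Synthetic inputs for end-to-end testing without external data.

Two generators: a Gompertz-style period life table, and patient-level
monthly NYHA trajectories with absorbing death, simulated under the same
death-then-transition cycle order as the cohort engine so that the
row-wise transition estimator is unbiased by construction.  The
estimator recovers a transition matrix from a trajectory panel by
empirical row proportions among survivors, which closes the loop:
simulate under known matrices, re-estimate, re-run the economic model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .mortality import LifeTable
from .parameters import TransitionMatrixSet

DEAD = 4  # absorbing state appended after NYHA I-IV (0..3)


def synth_life_table(q50_male: float, q50_female: float,
                     annual_growth_rate: float, max_age: int = 100) -> LifeTable:
    """Gompertz-style table: q(age) = min(1, q50 * growth**(age - 50)).

    ``annual_growth_rate`` is the multiplicative increase of the annual
    death probability per year of age (typically ~1.09 for adults).
    """
    for q in (q50_male, q50_female):
        if not 0.0 < q < 1.0:
            raise ValueError(f"q50 {q} must lie strictly in (0, 1)")
    if annual_growth_rate <= 0:
        raise ValueError("annual growth rate must be positive")
    if max_age < 50:
        raise ValueError("max_age must be at least 50")
    ages = np.arange(50, max_age + 1)
    growth = annual_growth_rate ** (ages - 50.0)
    return LifeTable(
        age=ages,
        q_male=np.minimum(1.0, q50_male * growth),
        q_female=np.minimum(1.0, q50_female * growth),
    )


@dataclasses.dataclass
class TrajectoryPanel:
    """Patient-level monthly NYHA state sequences with absorbing death.

    ``states[i, m]`` is patient ``i``'s state after month ``m+1`` (0..3
    for NYHA I-IV, 4 for dead); every patient starts month 1 in NYHA III.
    The generating matrices and seed are recorded for recovery tests.
    """

    states: np.ndarray  # (n_patients, months) int8
    arm: str
    seed: int
    true_matrices: TransitionMatrixSet | None = None

    @property
    def n_patients(self) -> int:
        return self.states.shape[0]

    @property
    def months(self) -> int:
        return self.states.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n, m = self.states.shape
        return pd.DataFrame({
            "patient_id": np.repeat(np.arange(n), m),
            "month": np.tile(np.arange(1, m + 1), n),
            "state": self.states.ravel(),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, arm: str = "", seed: int = 0) -> "TrajectoryPanel":
        df = pd.read_csv(path).sort_values(["patient_id", "month"])
        n = df["patient_id"].nunique()
        states = df["state"].to_numpy(dtype=np.int8).reshape(n, -1)
        return cls(states=states, arm=arm, seed=seed)


def _regime_for(month: int) -> str:
    if month == 1:
        return "cycle1"
    return "cycles2to11" if month <= 11 else "cycle12plus"


def simulate_trajectories(matrix_set: TransitionMatrixSet, death_model,
                          n_patients: int, months: int, seed: int,
                          arm: str = "OMT") -> TrajectoryPanel:
    """Step patients monthly: state-specific death, then transition.

    ``death_model`` gives the monthly death probability per NYHA state:
    ``None`` (no deaths), a length-4 array, or a callable
    ``month -> length-4 array``.  Patients start in NYHA III and use the
    regime-appropriate matrix of ``matrix_set`` for ``arm``.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    rng = np.random.default_rng(seed)
    current = np.full(n_patients, 2, dtype=np.int8)  # NYHA III
    out = np.empty((n_patients, months), dtype=np.int8)
    for month in range(1, months + 1):
        if death_model is None:
            d = np.zeros(4)
        elif callable(death_model):
            d = np.asarray(death_model(month), dtype=float)
        else:
            d = np.asarray(death_model, dtype=float)
        alive = current != DEAD
        u = rng.random(n_patients)
        dying = alive & (u < d[np.minimum(current, 3)])
        current[dying] = DEAD
        mat = matrix_set.matrix(arm, _regime_for(month))
        cum = np.cumsum(mat, axis=1)
        u2 = rng.random(n_patients)
        survivors = current != DEAD
        prev = current.copy()
        for s in range(4):
            mask = survivors & (prev == s)
            if mask.any():
                current[mask] = np.searchsorted(cum[s], u2[mask], side="right").astype(np.int8)
        np.clip(current, 0, DEAD, out=current)
        out[:, month - 1] = current
    return TrajectoryPanel(states=out, arm=arm, seed=seed,
                           true_matrices=matrix_set.copy())


def estimate_transition_matrix(panel: TrajectoryPanel,
                               regime_window: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise empirical transition proportions among survivors.

    ``regime_window = (lo, hi)`` selects months ``lo..hi`` (transitions
    into those months); entry (i, j) is the fraction of patients in state
    ``i`` at the previous month that survived the month and are in state
    ``j``.  Rows never at risk are returned as identity with count 0.
    Returns ``(matrix, row_counts)`` where ``row_counts[i]`` is the
    number of surviving at-risk transitions from state ``i``.
    """
    if panel.n_patients == 0:
        raise ValueError("empty panel")
    lo, hi = regime_window
    if not (2 <= lo <= hi <= panel.months):
        raise ValueError(f"window {regime_window} outside panel months 2..{panel.months}")
    counts = np.zeros((4, 4))
    for month in range(lo, hi + 1):
        prev = panel.states[:, month - 2]
        cur = panel.states[:, month - 1]
        ok = (prev != DEAD) & (cur != DEAD)
        if ok.any():
            np.add.at(counts, (prev[ok], cur[ok]), 1)
    row_counts = counts.sum(axis=1)
    mat = np.eye(4)
    for i in range(4):
        if row_counts[i] > 0:
            mat[i] = counts[i] / row_counts[i]
    return mat, row_counts
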