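"""Closed-cohort Markov engine.

Propagates a cohort through an annual state-transition matrix and exposes
the per-cycle occupancy trace.  The engine knows nothing about costs or
utilities; it only guarantees the Markov invariants (row-stochastic
matrix, mass conservation, absorbing death, tunnel pass-through).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import StateSpace

__all__ = ["assemble_matrix", "CohortTrace", "run_cohort", "prevalence_by_ageband"]

_ROW_TOL = 1e-12


def assemble_matrix(transitions, state_space: StateSpace) -> np.ndarray:
    """Build a row-stochastic annual transition matrix from edge entries.

    Unspecified diagonal entries take the complement of the specified
    outgoing mass; the death row is forced absorbing; tunnel states get a
    zero self-transition (their whole row must be specified to sum to 1).

    Raises ``ValueError`` naming the state when specified outgoing
    probabilities exceed 1.
    """
    n = state_space.n_states
    mat = np.zeros((n, n))
    specified_diag = np.zeros(n, dtype=bool)
    for t in transitions:
        i = state_space.index(t.from_state)
        j = state_space.index(t.to_state)
        mat[i, j] = t.probability
        if i == j:
            specified_diag[i] = True

    for i, sid in enumerate(state_space.ids):
        out = mat[i].sum() - mat[i, i]
        if out > 1.0 + 1e-9:
            raise ValueError(
                f"state {sid}: specified outgoing probabilities sum to {out:.6f} > 1"
            )
        if not specified_diag[i]:
            mat[i, i] = max(0.0, 1.0 - out)
        if sid in state_space.tunnel_states:
            # single-cycle pass-through: no self retention
            mat[i, i] = 0.0
        row = mat[i].sum()
        if abs(row - 1.0) > 1e-9:
            raise ValueError(f"state {sid}: row sums to {row:.9f}, expected 1")
        # exact renormalization to keep downstream 1e-12 row checks honest
        mat[i] /= row

    d = state_space.index(state_space.death_state)
    mat[d] = 0.0
    mat[d, d] = 1.0
    return mat


def _check_stochastic(matrix: np.ndarray, death_index: int | None = None) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(matrix < -_ROW_TOL) or np.any(matrix > 1 + 1e-9):
        raise ValueError("transition probabilities must lie in [0, 1]")
    rows = matrix.sum(axis=1)
    bad = np.where(np.abs(rows - 1.0) > 1e-9)[0]
    if bad.size:
        raise ValueError(
            f"rows {bad.tolist()} are not stochastic (sums {rows[bad].tolist()})"
        )
    if death_index is not None:
        unit = np.zeros(matrix.shape[0])
        unit[death_index] = 1.0
        if not np.allclose(matrix[death_index], unit, atol=1e-12):
            raise ValueError("death row must be the unit vector on death")


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy (in persons) of each state at each cycle boundary.

    ``occupancy[t, j]`` is the mass in state ``j`` at the end of cycle
    ``t`` (row 0 is the initial distribution), so the array has
    ``n_cycles + 1`` rows.
    """

    occupancy: np.ndarray
    state_space: StateSpace

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())

    def column(self, state_id: str) -> np.ndarray:
        return self.occupancy[:, self.state_space.index(state_id)]

    def deaths_per_cycle(self) -> np.ndarray:
        """New death-state entrants per cycle (length ``n_cycles``).

        Valid because death is absorbing: entrants in cycle t equal the
        increase of death occupancy from t-1 to t.
        """
        z = self.column(self.state_space.death_state)
        return np.diff(z)

    def to_frame(self, start_age: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=self.state_space.ids)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        if start_age is not None:
            df.insert(1, "age", start_age + df["cycle"])
        return df


def run_cohort(matrix, initial, n_cycles: int, state_space: StateSpace) -> CohortTrace:
    """Propagate ``initial`` occupancy through ``matrix`` for ``n_cycles``.

    ``matrix`` may be a single square array (cycle-constant, the base
    model) or a sequence of ``n_cycles`` arrays for age-dependent
    extensions.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (state_space.n_states,):
        raise ValueError("initial occupancy must have one entry per state")
    if np.any(initial < 0):
        raise ValueError("initial occupancies must be >= 0")

    matrices = np.asarray(matrix, dtype=float)
    death = state_space.index(state_space.death_state)
    if matrices.ndim == 2:
        _check_stochastic(matrices, death)
        per_cycle = [matrices] * n_cycles
    else:
        if len(matrices) != n_cycles:
            raise ValueError("need one matrix per cycle")
        per_cycle = list(matrices)
        for m in per_cycle:
            _check_stochastic(m, death)

    occ = np.empty((n_cycles + 1, state_space.n_states))
    occ[0] = initial
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ per_cycle[t]
    return CohortTrace(occupancy=occ, state_space=state_space)


def prevalence_by_ageband(
    trace: CohortTrace,
    start_age: float,
    states_of_interest,
    age_lo: float,
    age_hi: float,
) -> float:
    """Mean prevalence of ``states_of_interest`` among the living, over the
    cycles whose attained age lies in ``[age_lo, age_hi)``.

    Used to compare model-predicted latent-RHD prevalence in school-age
    bands (e.g. 11–13.9 and 14–18) against observed screening prevalence.
    """
    ages = start_age + np.arange(trace.occupancy.shape[0])
    mask = (ages >= age_lo) & (ages < age_hi)
    if not mask.any():
        raise ValueError(
            f"age band [{age_lo}, {age_hi}) does not overlap the trace "
            f"(ages {ages[0]}..{ages[-1]})"
        )
    death = trace.state_space.index(trace.state_space.death_state)
    idx = [trace.state_space.index(s) for s in states_of_interest]
    alive = trace.occupancy[mask].sum(axis=1) - trace.occupancy[mask, death]
    sick = trace.occupancy[mask][:, idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(alive > 0, sick / alive, 0.0)
    return float(frac.mean())
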