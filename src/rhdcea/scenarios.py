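"""Strategy construction: standard care vs one-time echo screening.

Both strategies share a single transition matrix in which the treated
states' progression rows already carry the secondary-prophylaxis effect
(treated and untreated disease are distinct states, so "treated-arm"
probabilities are simply the treated-state rows).  The strategies differ
in their cycle-0 distribution — screening moves detected latent cases
into the diagnosed/treated states — and in one-time costs (scans, and
follow-up of false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import assemble_matrix
from .params import ParameterSet
from .states import StateSpace

__all__ = [
    "Strategy",
    "apply_prophylaxis_effect",
    "base_matrix",
    "build_standard_care",
    "build_screening",
]


@dataclass(frozen=True)
class Strategy:
    """One arm of the comparison: initial occupancy, matrix, one-time costs."""

    name: str
    initial_occupancy: np.ndarray
    transition_matrix: np.ndarray
    one_time_costs: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if np.any(self.initial_occupancy < 0):
            raise ValueError("initial occupancy must be >= 0")


def apply_prophylaxis_effect(
    matrix: np.ndarray,
    state_space: StateSpace,
    reduction_definite: float,
    reduction_mild: float,
) -> np.ndarray:
    """Scale treated-state progression by the secondary-prophylaxis effect.

    Progression out of treated asymptomatic definite disease toward
    clinical states (and surgery) is multiplied by ``1 - reduction_definite``;
    treated mild-to-severe progression by ``1 - reduction_mild``.  The
    freed probability mass returns to the source state's self-transition,
    so rows stay stochastic.
    """
    for name, r in (("definite", reduction_definite), ("mild", reduction_mild)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"prophylaxis reduction ({name}) must lie in [0, 1]")
    out = np.array(matrix, dtype=float, copy=True)

    def scale(row_state: str, col_states, factor: float) -> None:
        i = state_space.index(row_state)
        for cs in col_states:
            j = state_space.index(cs)
            freed = out[i, j] * (1.0 - factor)
            out[i, j] *= factor
            out[i, i] += freed
            if not 0.0 <= out[i, j] <= 1.0 or not 0.0 <= out[i, i] <= 1.0 + 1e-12:
                raise ValueError(
                    f"prophylaxis adjustment left {row_state} row outside [0, 1]"
                )

    g = state_space.role("treated_definite")
    clinical_targets = [
        s
        for s in (
            state_space.roles.get("treated_mild"),
            state_space.roles.get("surgery"),
        )
        if s is not None and out[state_space.index(g), state_space.index(s)] > 0
    ]
    scale(g, clinical_targets, 1.0 - reduction_definite)
    h = state_space.role("treated_mild")
    i_state = state_space.roles.get("treated_severe")
    if i_state is not None and out[state_space.index(h), state_space.index(i_state)] > 0:
        scale(h, [i_state], 1.0 - reduction_mild)
    return out


def base_matrix(params: ParameterSet) -> np.ndarray:
    """Assemble the shared matrix with prophylaxis-adjusted treated rows."""
    mat = assemble_matrix(params.transitions, params.state_space)
    return apply_prophylaxis_effect(
        mat,
        params.state_space,
        params.prophylaxis_effect_definite,
        params.prophylaxis_effect_mild,
    )


def build_standard_care(params: ParameterSet) -> Strategy:
    """Standard care: initial distribution as observed, no screening costs."""
    return Strategy(
        name="standard_care",
        initial_occupancy=params.initial_vector(),
        transition_matrix=base_matrix(params),
        one_time_costs=(),
    )


def build_screening(params: ParameterSet) -> Strategy:
    """One-time echo screening at cycle 0.

    Of the screened undiagnosed borderline occupants, a fraction
    ``sensitivity_borderline`` moves to diagnosed borderline; of the
    screened untreated asymptomatic definite occupants,
    ``sensitivity_definite`` moves to treated definite.  Disease-free
    screened children test falsely positive with probability
    ``1 - specificity`` and incur a one-time follow-up cost while staying
    disease-free.  Scans themselves cost
    ``cohort_size x screened_fraction x cost_per_scan`` at cycle 0.
    """
    sp = params.state_space
    scr = params.screening
    init = params.initial_vector().copy()

    def move(src_role: str, dst_role: str, fraction: float) -> None:
        i = sp.index(sp.role(src_role))
        j = sp.index(sp.role(dst_role))
        moved = init[i] * scr.screened_fraction * fraction
        init[i] -= moved
        init[j] += moved

    move("undiagnosed_borderline", "diagnosed_borderline", scr.sensitivity_borderline)
    move("untreated_definite", "treated_definite", scr.sensitivity_definite)

    healthy = init[sp.index(sp.role("healthy"))]
    n_false_positive = healthy * scr.screened_fraction * (1.0 - scr.specificity)

    scan_cost = params.cohort_size * scr.screened_fraction * scr.cost_per_scan
    one_time = []
    if scan_cost > 0:
        one_time.append((0, scan_cost, "screening scans"))
    fp_cost = n_false_positive * scr.false_positive_followup_cost
    if fp_cost > 0:
        one_time.append((0, fp_cost, "false-positive follow-up"))

    return Strategy(
        name="screening",
        initial_occupancy=init,
        transition_matrix=base_matrix(params),
        one_time_costs=tuple(one_time),
    )
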