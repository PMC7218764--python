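"""Discounted costs, DALYs (YLD + YLL) and incremental decision measures.

Conventions
-----------
Accrual defaults to end-of-cycle: the state occupied during cycle ``t``
(t = 1..n) is the trace row ``t`` and is discounted with exponent ``t``;
one-time amounts sit at their own cycle (cycle 0 undiscounted).  A
begin-of-cycle switch is provided.

Years of life lost at a death in cycle ``t`` are, by default, a stream of
the remaining life-expectancy years starting the year after death, each
discounted to time 0, with the fractional final year pro-rated
(``yll_mode="stream"``); ``"lump"`` instead discounts the undiscounted
remaining expectancy as a lump sum at the cycle of death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CohortTrace
from .params import LifeTable, ParameterSet

__all__ = [
    "discount_factor",
    "accrue_costs",
    "accrue_dalys",
    "ScenarioResult",
    "ComparisonResult",
    "compare",
    "evaluate_strategy",
]


def discount_factor(rate: float, cycle: float) -> float:
    """Present-value multiplier ``(1 + rate)**(-cycle)``."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return (1.0 + rate) ** (-cycle)


@dataclass(frozen=True)
class ScenarioResult:
    """Discounted totals for one strategy over the model horizon."""

    name: str
    total_cost: float
    total_dalys: float
    one_time_costs: float
    yld: float
    yll: float
    per_cycle: pd.DataFrame = field(default=None, compare=False, repr=False)

    @property
    def recurring_costs(self) -> float:
        return self.total_cost - self.one_time_costs


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental measures of an intervention against a comparator.

    ``delta_effect`` is DALYs averted (comparator minus intervention, so
    positive means the intervention improves health).  ``icer`` is
    incremental cost per DALY averted when that ratio is meaningful;
    otherwise ``label`` carries a dominance verdict.
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str
    nmb: float
    threshold: float

    @property
    def cost_effective(self) -> bool:
        return self.nmb > 0


def compare(
    standard: ScenarioResult, intervention: ScenarioResult, threshold: float
) -> ComparisonResult:
    """Combine two scenario results into ICER / net-monetary-benefit terms."""
    delta_cost = intervention.total_cost - standard.total_cost
    delta_effect = standard.total_dalys - intervention.total_dalys
    nmb = threshold * delta_effect - delta_cost

    if delta_cost <= 0 and delta_effect > 0:
        label, icer = "dominant", delta_cost / delta_effect
    elif delta_cost >= 0 and delta_effect < 0:
        label, icer = "dominated", None
    elif delta_effect == 0:
        label, icer = ("equivalent" if delta_cost == 0 else "undefined"), None
    else:
        label, icer = "icer", delta_cost / delta_effect
    return ComparisonResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        label=label,
        nmb=nmb,
        threshold=threshold,
    )


def _accrual_rows(n_cycles: int, accrual: str, half_cycle: bool = False):
    """(trace row index, discount exponent, weight) per accruing cycle.

    With the half-cycle correction the occupancy stream is integrated by
    the trapezoid rule over rows 0..n (endpoint weights 0.5), which is
    the usual compromise between the begin and end conventions.
    """
    if half_cycle:
        return [
            (t, t, 0.5 if t in (0, n_cycles) else 1.0)
            for t in range(0, n_cycles + 1)
        ]
    if accrual == "end":
        return [(t, t, 1.0) for t in range(1, n_cycles + 1)]
    if accrual == "begin":
        return [(t - 1, t - 1, 1.0) for t in range(1, n_cycles + 1)]
    raise ValueError(f"unknown cycle accrual {accrual!r}")


def accrue_costs(
    trace: CohortTrace,
    cost_vector: np.ndarray,
    one_time,
    rate: float,
    accrual: str = "end",
    detail: bool = True,
    half_cycle: bool = False,
) -> tuple[float, float, pd.DataFrame | None]:
    """Total discounted cost of a trace.

    Returns ``(total, one_time_total, per_cycle_frame)``.  ``one_time`` is
    a list of ``(cycle, amount, label)`` (amount in USD at that cycle,
    discounted like any flow at its cycle).  ``detail=False`` skips the
    per-cycle frame (used inside probabilistic loops).
    """
    cost_vector = np.asarray(cost_vector, dtype=float)
    if cost_vector.shape != (trace.state_space.n_states,):
        raise ValueError("need one annual cost per state")
    rows = [] if detail else None
    total = 0.0
    for row, exponent, weight in _accrual_rows(trace.n_cycles, accrual, half_cycle):
        df = discount_factor(rate, exponent)
        amount = float(trace.occupancy[row] @ cost_vector) * df * weight
        total += amount
        if detail:
            rows.append({"cycle": row, "discounted_cost": amount})
    one_time_total = 0.0
    for cycle, amount, _label in one_time:
        one_time_total += amount * discount_factor(rate, cycle)
    total += one_time_total
    return total, one_time_total, (pd.DataFrame(rows) if detail else None)


def _discounted_le_stream(le: float, rate: float, death_cycle: int) -> float:
    """Present value (at time 0) of ``le`` years of life starting the year
    after a death at cycle ``death_cycle``; fractional final year pro-rated."""
    whole = int(math.floor(le))
    frac = le - whole
    pv = sum(
        discount_factor(rate, death_cycle + k) for k in range(1, whole + 1)
    )
    if frac > 0:
        pv += frac * discount_factor(rate, death_cycle + whole + 1)
    return pv


def accrue_dalys(
    trace: CohortTrace,
    daly_weights: np.ndarray,
    life_table: LifeTable,
    start_age: float,
    rate: float,
    accrual: str = "end",
    yll_mode: str = "stream",
    detail: bool = True,
    half_cycle: bool = False,
) -> tuple[float, float, float, pd.DataFrame | None]:
    """Total discounted DALYs = YLD + YLL.

    YLD: per-cycle occupancy weighted by disability weights, discounted
    like costs.  YLL: for the new death-state entrants of each cycle, the
    remaining life expectancy at the attained age, discounted per
    ``yll_mode``.

    Returns ``(total, yld, yll, per_cycle_frame)``.
    """
    daly_weights = np.asarray(daly_weights, dtype=float)
    if daly_weights.shape != (trace.state_space.n_states,):
        raise ValueError("need one disability weight per state")

    rows = [] if detail else None
    yld = 0.0
    for row, exponent, weight in _accrual_rows(trace.n_cycles, accrual, half_cycle):
        df = discount_factor(rate, exponent)
        amount = float(trace.occupancy[row] @ daly_weights) * df * weight
        yld += amount
        if detail:
            rows.append({"cycle": row, "discounted_yld": amount, "discounted_yll": 0.0})

    deaths = trace.deaths_per_cycle()
    yll = 0.0
    for t, d in enumerate(deaths, start=1):
        if d <= 0:
            continue
        age = start_age + t
        le = life_table.expectancy(age)
        if yll_mode == "stream":
            unit = _discounted_le_stream(le, rate, t)
        elif yll_mode == "lump":
            unit = le * discount_factor(rate, t)
        else:
            raise ValueError(f"unknown yll_mode {yll_mode!r}")
        amount = float(d) * unit
        yll += amount
        if detail:
            idx = t if half_cycle else (t - 1)
            rows[idx]["discounted_yll"] += amount
    return yld + yll, yld, yll, (pd.DataFrame(rows) if detail else None)


def evaluate_strategy(
    strategy,
    params: ParameterSet,
    cost_vector: np.ndarray | None = None,
    daly_weights: np.ndarray | None = None,
    detail: bool = True,
) -> ScenarioResult:
    """Run one strategy's cohort and accrue its discounted totals.

    ``cost_vector`` / ``daly_weights`` override the point estimates in
    ``params`` (used by sensitivity analyses); ``detail=False`` skips the
    per-cycle breakdown.
    """
    from .engine import run_cohort  # local to avoid cycle at import time

    trace = run_cohort(
        strategy.transition_matrix,
        strategy.initial_occupancy,
        params.n_cycles,
        params.state_space,
    )
    cost_total, one_time_total, cost_frame = accrue_costs(
        trace,
        params.cost_vector() if cost_vector is None else cost_vector,
        strategy.one_time_costs,
        params.discount_rate,
        params.cycle_accrual,
        detail=detail,
        half_cycle=params.half_cycle_correction,
    )
    daly_total, yld, yll, daly_frame = accrue_dalys(
        trace,
        params.daly_weight_vector() if daly_weights is None else daly_weights,
        params.life_table,
        params.start_age,
        params.discount_rate,
        params.cycle_accrual,
        params.yll_mode,
        detail=detail,
        half_cycle=params.half_cycle_correction,
    )
    per_cycle = (
        cost_frame.merge(daly_frame, on="cycle", how="outer") if detail else None
    )
    return ScenarioResult(
        name=strategy.name,
        total_cost=cost_total,
        total_dalys=daly_total,
        one_time_costs=one_time_total,
        yld=yld,
        yll=yll,
        per_cycle=per_cycle,
    )
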