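"""Synthetic parameter bundles.

:func:`generate_bundle` emits a complete, validated bundle with the full
15-state screening topology: transition probabilities drawn from broad,
clinically plausible annual ranges, gamma cost descriptors anchored on the
2017 DataSUS-derived cost table, triangular disability-weight intervals,
a monotone life table, and an initial distribution that splits the latent
RHD prevalence between borderline and definite lesions.  The generator
aims at *structural* fidelity — every invariant of the real bundle holds —
not at reproducing any published estimate; ranges are documented inline.

:func:`generate_toy_bundle` builds a minimal three-state (Healthy, Sick,
Dead) bundle whose discounted totals have closed geometric-series forms,
used as independent oracles in the outcome tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import (
    LifeTable,
    ParameterSet,
    ScreeningParameters,
    StateEconomics,
    TransitionEntry,
    UncertaintyDescriptor,
)
from .states import StateSpace, canonical_state_space

__all__ = ["GeneratorConfig", "generate_bundle", "generate_toy_bundle", "TABLE_COSTS"]

#: Annual per-state costs, 2017 USD (DataSUS reimbursement data; the
#: resolved states assume the cost of the stage they resolved from).
TABLE_COSTS: dict[str, float] = {
    "A": 0.0,
    "B": 0.0,
    "C": 0.0,
    "D": 0.0,
    "E": 0.0,
    "F": 25.84,
    "G": 93.93,
    "H": 337.47,
    "I": 854.00,
    "RG": 93.93,
    "RH": 337.47,
    "RI": 854.00,
    "K": 854.00,
    "X": 4120.51,
    "Z": 0.0,
}

# Disability weights (GBD-style point, 95% lower, upper).  Latent disease
# carries no physical disability; diagnosed latent states carry a small
# "disutility of knowing" plus injection burden; clinical states scale
# with severity; the surgery year is weighted like severe disease plus
# procedural morbidity.  Synthetic stand-ins, not published estimates.
_DALY_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "A": (0.0, 0.0, 0.0),
    "B": (0.0, 0.0, 0.0),
    "C": (0.0, 0.0, 0.0),
    "D": (0.049, 0.031, 0.072),
    "E": (0.233, 0.157, 0.320),
    "F": (0.012, 0.006, 0.018),
    "G": (0.012, 0.006, 0.018),
    "H": (0.049, 0.031, 0.072),
    "I": (0.233, 0.157, 0.320),
    "RG": (0.0, 0.0, 0.0),
    "RH": (0.0, 0.0, 0.0),
    "RI": (0.0, 0.0, 0.0),
    "K": (0.049, 0.031, 0.072),
    "X": (0.324, 0.219, 0.442),
    "Z": (0.0, 0.0, 0.0),
}

# Broad uniform ranges for the annual transition probabilities (documented
# generator choices, drawn once per bundle).  Scales multiply progression
# and mortality draws.
_TRANSITION_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("A", "Z"): (0.0005, 0.002),       # background mortality, ages 11-41
    ("B", "A"): (0.10, 0.30),          # borderline regression
    ("B", "C"): (0.02, 0.08),          # borderline -> definite progression
    ("B", "Z"): (0.0005, 0.002),
    ("C", "D"): (0.04, 0.12),          # definite -> mild clinical
    ("C", "X"): (0.005, 0.02),         # direct to surgery
    ("C", "Z"): (0.002, 0.010),
    ("D", "E"): (0.08, 0.20),          # mild -> severe clinical
    ("D", "H"): (0.10, 0.30),          # care seeking once symptomatic
    ("D", "X"): (0.01, 0.04),
    ("D", "Z"): (0.010, 0.030),
    ("E", "I"): (0.20, 0.40),
    ("E", "X"): (0.10, 0.25),
    ("E", "Z"): (0.05, 0.15),
    ("F", "A"): (0.10, 0.30),
    ("F", "G"): (0.02, 0.08),
    ("F", "Z"): (0.0005, 0.002),
    ("G", "RG"): (0.02, 0.10),         # resolution under prophylaxis
    ("H", "RH"): (0.02, 0.08),
    ("I", "X"): (0.10, 0.25),
    ("I", "RI"): (0.01, 0.05),
    ("I", "Z"): (0.04, 0.12),
    ("RG", "Z"): (0.0005, 0.002),
    ("RH", "Z"): (0.0005, 0.002),
    ("RI", "Z"): (0.0005, 0.002),
    ("K", "X"): (0.01, 0.03),          # reoperation
    ("K", "Z"): (0.01, 0.03),
    ("X", "Z"): (0.03, 0.08),          # peri-operative mortality
}

_PROGRESSION_EDGES = {("C", "D"), ("D", "E"), ("B", "C"), ("F", "G")}
_MORTALITY_EDGES = {
    (a, "Z") for a in ("A", "B", "C", "D", "E", "F", "RG", "RH", "RI", "K", "X", "I")
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic bundle generator.

    ``disease_prevalence`` is the latent-RHD fraction of the cohort at
    enrolment (school-age screening prevalence), split
    ``borderline_definite_ratio``:1 between borderline and definite
    lesions.  ``life_table_shape`` is (expectancy at age 0, decline per
    year of age) for the linear synthetic life table.
    """

    seed: int = 0
    disease_prevalence: float = 0.042
    borderline_definite_ratio: float = 3.0
    progression_scale: float = 1.0
    mortality_scale: float = 1.0
    cost_scale: float = 1.0
    life_table_shape: tuple[float, float] = (70.0, 0.78)
    surgery_cost_cv: float = 0.30
    beta_effective_n: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.disease_prevalence <= 1.0:
            raise ValueError("disease prevalence must lie in [0, 1]")
        for name in ("progression_scale", "mortality_scale", "cost_scale",
                     "borderline_definite_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _life_table(shape: tuple[float, float]) -> LifeTable:
    e0, decline = shape
    ages = np.arange(0, 71, dtype=float)
    ex = e0 - decline * ages
    if ex[-1] <= 0:
        raise ValueError("life table shape yields non-positive expectancy")
    return LifeTable(ages, ex)


def generate_bundle(config: GeneratorConfig | None = None) -> ParameterSet:
    """Draw a complete validated bundle; deterministic given the seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    sp = canonical_state_space()

    draws: dict[tuple[str, str], float] = {}
    for edge in sorted(_TRANSITION_RANGES):  # sorted: draw order fixed
        lo, hi = _TRANSITION_RANGES[edge]
        p = rng.uniform(lo, hi)
        if edge in _PROGRESSION_EDGES:
            p *= config.progression_scale
        if edge in _MORTALITY_EDGES:
            p *= config.mortality_scale
        draws[edge] = min(p, 0.95)

    # treated states progress like their untreated counterparts; the
    # prophylaxis reduction is applied by the scenario builder, not here
    draws[("G", "H")] = draws[("C", "D")]
    draws[("G", "X")] = draws[("C", "X")]
    draws[("G", "Z")] = draws[("C", "Z")]
    draws[("H", "I")] = draws[("D", "E")]
    draws[("H", "Z")] = draws[("D", "Z")]
    # surgery is a tunnel: survivors all reach post-surgery
    draws[("X", "K")] = 1.0 - draws[("X", "Z")]

    n = config.beta_effective_n
    transitions = []
    for (frm, to), p in sorted(draws.items()):
        transitions.append(
            TransitionEntry(
                from_state=frm,
                to_state=to,
                probability=p,
                uncertainty=UncertaintyDescriptor.beta(p, n),
            )
        )

    surgery_cost = TABLE_COSTS["X"] * config.cost_scale
    shared_var = (config.surgery_cost_cv * surgery_cost) ** 2
    economics = []
    for sid in sp.ids:
        cost = TABLE_COSTS[sid] * config.cost_scale
        w, lo, hi = _DALY_WEIGHTS[sid]
        economics.append(
            StateEconomics(
                state=sid,
                annual_cost=cost,
                daly_weight=w,
                daly_lower=lo,
                daly_upper=hi,
            )
        )

    prev = config.disease_prevalence
    r = config.borderline_definite_ratio
    b = prev * r / (r + 1.0)
    c = prev - b
    initial = (("A", 1.0 - prev), ("B", b), ("C", c))

    ps = ParameterSet(
        state_space=sp,
        transitions=tuple(transitions),
        economics=tuple(economics),
        life_table=_life_table(config.life_table_shape),
        initial_distribution=initial,
        screening=ScreeningParameters(),
        shared_cost_variance=shared_var,
    )
    return ps.validate()


# ---------------------------------------------------------------------------
# Toy bundle with closed-form behaviour
# ---------------------------------------------------------------------------

_TOY_EDGES = frozenset([("H", "Z"), ("S", "H"), ("S", "Z")])


def generate_toy_bundle(
    stay_sick: float = 0.6,
    mortality: float = 0.0,
    sick_cost: float = 100.0,
    sick_weight: float = 0.25,
    discount_rate: float = 0.03,
    n_cycles: int = 30,
    cohort_size: float = 1.0,
) -> ParameterSet:
    """Three-state bundle (Healthy, Sick, Dead), everyone initially sick.

    With mortality 0, sick occupancy at cycle t is ``stay_sick**t``, so
    the discounted sick-cost total is the geometric series
    ``sick_cost * sum_t stay_sick**t (1+r)**-t`` — the closed form the
    outcome tests check the engine against.
    """
    if stay_sick + mortality > 1.0:
        raise ValueError("stay_sick + mortality must not exceed 1")
    sp = StateSpace(
        states=(("H", "Healthy"), ("S", "Sick"), ("Z", "Dead")),
        death_state="Z",
        roles={
            # screening roles all collapse onto the sick state so the
            # scenario builder is a no-op reallocation on this bundle
            "healthy": "H",
            "undiagnosed_borderline": "S",
            "diagnosed_borderline": "S",
            "untreated_definite": "S",
            "treated_definite": "S",
            "treated_mild": "S",
            "death": "Z",
        },
    )
    transitions = (
        TransitionEntry("S", "H", 1.0 - stay_sick - mortality),
        TransitionEntry("S", "Z", mortality),
    )
    economics = (
        StateEconomics("H", 0.0),
        StateEconomics("S", sick_cost, sick_weight, sick_weight, sick_weight),
        StateEconomics("Z", 0.0),
    )
    ps = ParameterSet(
        state_space=sp,
        transitions=transitions,
        economics=economics,
        life_table=_life_table((70.0, 0.5)),
        initial_distribution=(("S", 1.0),),
        screening=ScreeningParameters(
            cost_per_scan=0.0,
            sensitivity_borderline=0.0,
            sensitivity_definite=0.0,
            specificity=1.0,
            false_positive_followup_cost=0.0,
        ),
        cohort_size=cohort_size,
        n_cycles=n_cycles,
        discount_rate=discount_rate,
        allowed_edges=_TOY_EDGES,
    )
    return ps.validate()
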