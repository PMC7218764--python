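"""Parameter bundle: domain types, validation, and file I/O.

A *bundle* is one structured-text config (``bundle.yaml``) plus three CSV
tables (``transitions.csv``, ``economics.csv``, ``lifetable.csv``) in a
directory.  :func:`load_bundle` reads and fully validates it;
:func:`save_bundle` writes it back such that load(save(p)) == p.

Monetary amounts are 2017 USD; probabilities are annual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .states import StateSpace, canonical_state_space, CANONICAL_EDGES

__all__ = [
    "UncertaintyDescriptor",
    "TransitionEntry",
    "StateEconomics",
    "LifeTable",
    "ScreeningParameters",
    "ParameterSet",
    "BundleValidationError",
    "validate_edges",
    "load_bundle",
    "save_bundle",
]


class BundleValidationError(ValueError):
    """A parameter bundle violated one of its invariants."""


_KINDS = ("point", "gamma_mean_var", "triangular_95ui", "beta_mean_n", "uniform_bounds")


@dataclass(frozen=True)
class UncertaintyDescriptor:
    """Second-order uncertainty attached to a single model input.

    ``kind`` selects the sampling family used in probabilistic analysis:

    - ``point`` — no uncertainty; ``value``.
    - ``gamma_mean_var`` — gamma with ``mean``/``variance`` (costs).
    - ``triangular_95ui`` — triangular on ``[lower, upper]`` with ``mode``
      at the point estimate (disability weights with 95% uncertainty
      intervals).
    - ``beta_mean_n`` — beta with ``mean`` and effective sample size ``n``
      (probabilities).
    - ``uniform_bounds`` — uniform on ``[lower, upper]``.
    """

    kind: str
    params: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise BundleValidationError(f"unknown uncertainty kind {self.kind!r}")
        p = self.as_dict()
        if self.kind == "gamma_mean_var":
            if p["variance"] < 0:
                raise BundleValidationError("gamma variance must be >= 0")
            if p["mean"] < 0:
                raise BundleValidationError("gamma mean must be >= 0")
        elif self.kind == "triangular_95ui":
            if not p["lower"] <= p["mode"] <= p["upper"]:
                raise BundleValidationError(
                    f"triangular bounds must satisfy lower <= mode <= upper, "
                    f"got {p['lower']}, {p['mode']}, {p['upper']}"
                )
        elif self.kind == "beta_mean_n":
            if not 0.0 <= p["mean"] <= 1.0:
                raise BundleValidationError("beta mean must lie in [0, 1]")
            if p["n"] <= 0:
                raise BundleValidationError("beta effective sample size must be > 0")
        elif self.kind == "uniform_bounds":
            if p["lower"] > p["upper"]:
                raise BundleValidationError("uniform bounds must be ordered")

    # -- constructors -------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "UncertaintyDescriptor":
        return cls("point", (("value", float(value)),))

    @classmethod
    def gamma(cls, mean: float, variance: float) -> "UncertaintyDescriptor":
        return cls("gamma_mean_var", (("mean", float(mean)), ("variance", float(variance))))

    @classmethod
    def triangular(cls, lower: float, mode: float, upper: float) -> "UncertaintyDescriptor":
        return cls(
            "triangular_95ui",
            (("lower", float(lower)), ("mode", float(mode)), ("upper", float(upper))),
        )

    @classmethod
    def beta(cls, mean: float, n: float) -> "UncertaintyDescriptor":
        return cls("beta_mean_n", (("mean", float(mean)), ("n", float(n))))

    @classmethod
    def uniform(cls, lower: float, upper: float) -> "UncertaintyDescriptor":
        return cls("uniform_bounds", (("lower", float(lower)), ("upper", float(upper))))

    # -- accessors ----------------------------------------------------
    def as_dict(self) -> dict:
        return dict(self.params)

    @property
    def is_degenerate(self) -> bool:
        """True when every draw equals the point estimate."""
        p = self.as_dict()
        if self.kind == "point":
            return True
        if self.kind == "gamma_mean_var":
            return p["variance"] == 0.0
        if self.kind == "triangular_95ui":
            return p["lower"] == p["upper"]
        if self.kind == "uniform_bounds":
            return p["lower"] == p["upper"]
        if self.kind == "beta_mean_n":
            return p["mean"] in (0.0, 1.0)
        return False

    def point_estimate(self) -> float:
        p = self.as_dict()
        if self.kind == "point":
            return p["value"]
        if self.kind in ("gamma_mean_var", "beta_mean_n"):
            return p["mean"]
        if self.kind == "triangular_95ui":
            return p["mode"]
        return 0.5 * (p["lower"] + p["upper"])

    def bounds95(self) -> tuple[float, float] | None:
        """Approximate 95% interval, used by one-way sensitivity sweeps.

        Returns None for point descriptors (nothing to sweep).
        """
        p = self.as_dict()
        if self.is_degenerate:
            return None
        if self.kind == "gamma_mean_var":
            sd = math.sqrt(p["variance"])
            return (max(0.0, p["mean"] - 1.96 * sd), p["mean"] + 1.96 * sd)
        if self.kind in ("triangular_95ui", "uniform_bounds"):
            return (p["lower"], p["upper"])
        if self.kind == "beta_mean_n":
            m, n = p["mean"], p["n"]
            sd = math.sqrt(m * (1 - m) / (n + 1))
            return (max(0.0, m - 1.96 * sd), min(1.0, m + 1.96 * sd))
        return None


@dataclass(frozen=True)
class TransitionEntry:
    """One annual transition probability with its uncertainty."""

    from_state: str
    to_state: str
    probability: float
    uncertainty: UncertaintyDescriptor | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise BundleValidationError(
                f"transition {self.from_state}->{self.to_state}: probability "
                f"{self.probability} outside [0, 1]"
            )

    @property
    def descriptor(self) -> UncertaintyDescriptor:
        if self.uncertainty is not None:
            return self.uncertainty
        return UncertaintyDescriptor.point(self.probability)


@dataclass(frozen=True)
class StateEconomics:
    """Per-state annual cost (2017 USD) and disability (DALY) weight."""

    state: str
    annual_cost: float
    daly_weight: float = 0.0
    daly_lower: float = 0.0
    daly_upper: float = 0.0
    cost_uncertainty: UncertaintyDescriptor | None = None

    def __post_init__(self) -> None:
        if self.annual_cost < 0:
            raise BundleValidationError(f"state {self.state}: cost must be >= 0")
        for name, v in (
            ("daly_weight", self.daly_weight),
            ("daly_lower", self.daly_lower),
            ("daly_upper", self.daly_upper),
        ):
            if not 0.0 <= v <= 1.0:
                raise BundleValidationError(
                    f"state {self.state}: {name} {v} outside [0, 1]"
                )
        if not self.daly_lower <= self.daly_weight <= self.daly_upper:
            raise BundleValidationError(
                f"state {self.state}: DALY interval must bracket the weight"
            )

    @property
    def daly_descriptor(self) -> UncertaintyDescriptor:
        return UncertaintyDescriptor.triangular(
            self.daly_lower, self.daly_weight, self.daly_upper
        )


class LifeTable:
    """Remaining life expectancy by age, with linear interpolation."""

    def __init__(self, ages, expectancies, monotonicity_tol: float = 0.0):
        ages = np.asarray(ages, dtype=float)
        ex = np.asarray(expectancies, dtype=float)
        if ages.ndim != 1 or ages.shape != ex.shape or ages.size == 0:
            raise BundleValidationError("life table needs matching non-empty columns")
        if not np.all(np.diff(ages) > 0):
            raise BundleValidationError("life table ages must be strictly increasing")
        if np.any(ex <= 0):
            raise BundleValidationError("life expectancies must be > 0")
        if np.any(np.diff(ex) > monotonicity_tol):
            raise BundleValidationError(
                "life expectancy must be non-increasing with age "
                f"(tolerance {monotonicity_tol})"
            )
        self.ages = ages
        self.expectancies = ex

    def expectancy(self, age: float) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            raise BundleValidationError(
                f"age {age} outside life table range "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(np.interp(age, self.ages, self.expectancies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "expectancy": self.expectancies})

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.expectancies, other.expectancies)
        )


@dataclass(frozen=True)
class ScreeningParameters:
    """One-time echocardiographic screening test characteristics and costs.

    ``sensitivity_*_range`` are the one-way sensitivity-analysis endpoints
    (borderline lesions are harder to call than definite ones, hence the
    wider, lower band).
    """

    cost_per_scan: float = 6.60
    sensitivity_borderline: float = 0.65
    sensitivity_definite: float = 0.90
    specificity: float = 0.95
    false_positive_followup_cost: float = 25.84
    screened_fraction: float = 1.0
    sensitivity_borderline_range: tuple[float, float] = (0.50, 0.80)
    sensitivity_definite_range: tuple[float, float] = (0.80, 1.00)

    def __post_init__(self) -> None:
        for name in (
            "sensitivity_borderline",
            "sensitivity_definite",
            "specificity",
            "screened_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BundleValidationError(f"screening {name} {v} outside [0, 1]")
        for name in ("cost_per_scan", "false_positive_followup_cost"):
            if getattr(self, name) < 0:
                raise BundleValidationError(f"screening {name} must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """Everything needed to evaluate both strategies for one scenario.

    ``initial_distribution`` holds per-state proportions summing to 1;
    occupancies in persons are obtained by scaling with ``cohort_size``.
    ``shared_cost_variance`` is the single cost variance applied to every
    gamma cost descriptor that does not carry its own (the surgery-state
    variance in the canonical bundle, the only one with primary data).
    """

    state_space: StateSpace
    transitions: tuple[TransitionEntry, ...]
    economics: tuple[StateEconomics, ...]
    life_table: LifeTable
    initial_distribution: tuple[tuple[str, float], ...]
    screening: ScreeningParameters = ScreeningParameters()
    cohort_size: float = 1000.0
    n_cycles: int = 30
    start_age: float = 11.0
    discount_rate: float = 0.03
    threshold: float = 25_949.85
    prophylaxis_effect_definite: float = 0.50
    prophylaxis_effect_mild: float = 0.50
    shared_cost_variance: float = 0.0
    allowed_edges: frozenset = field(default_factory=lambda: frozenset(CANONICAL_EDGES))
    cycle_accrual: str = "end"      # {"begin", "end"}
    yll_mode: str = "stream"        # {"stream", "lump"}
    half_cycle_correction: bool = False

    # -- validation ---------------------------------------------------
    def validate(self) -> "ParameterSet":
        sp = self.state_space
        if self.n_cycles < 1:
            raise BundleValidationError("n_cycles must be >= 1")
        if self.discount_rate < 0:
            raise BundleValidationError("discount rate must be >= 0")
        if self.cohort_size <= 0:
            raise BundleValidationError("cohort size must be > 0")
        if self.cycle_accrual not in ("begin", "end"):
            raise BundleValidationError(f"unknown cycle_accrual {self.cycle_accrual!r}")
        if self.yll_mode not in ("stream", "lump"):
            raise BundleValidationError(f"unknown yll_mode {self.yll_mode!r}")
        for name in ("prophylaxis_effect_definite", "prophylaxis_effect_mild"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise BundleValidationError(f"{name} {v} outside [0, 1]")

        seen = set()
        outgoing: dict[str, float] = {}
        for t in self.transitions:
            for s in (t.from_state, t.to_state):
                if s not in sp:
                    raise BundleValidationError(
                        f"transition {t.from_state}->{t.to_state} references "
                        f"unknown state {s!r}"
                    )
            key = (t.from_state, t.to_state)
            if key in seen:
                raise BundleValidationError(f"duplicate transition {key[0]}->{key[1]}")
            seen.add(key)
            if t.from_state != t.to_state:
                outgoing[t.from_state] = outgoing.get(t.from_state, 0.0) + t.probability
        for state, total in outgoing.items():
            if total > 1.0 + 1e-9:
                raise BundleValidationError(
                    f"state {state}: outgoing probabilities sum to {total:.6f} > 1"
                )
        violations = validate_edges(self.transitions, self.allowed_edges)
        if violations:
            raise BundleValidationError(
                "transitions outside the allowed edge list: "
                + ", ".join(f"{a}->{b}" for a, b in violations)
            )

        econ_states = [e.state for e in self.economics]
        if len(set(econ_states)) != len(econ_states):
            raise BundleValidationError("duplicate economics rows")
        for e in self.economics:
            if e.state not in sp:
                raise BundleValidationError(f"economics references unknown state {e.state!r}")
        death = sp.death_state
        for e in self.economics:
            if e.state == death and (e.annual_cost != 0 or e.daly_weight != 0):
                raise BundleValidationError(
                    "death state must carry zero cost and zero disability weight"
                )

        init = dict(self.initial_distribution)
        for s in init:
            if s not in sp:
                raise BundleValidationError(f"initial distribution references unknown state {s!r}")
        total = sum(init.values())
        if abs(total - 1.0) > 1e-9:
            raise BundleValidationError(
                f"initial distribution sums to {total!r}, expected 1"
            )
        if any(v < 0 for v in init.values()):
            raise BundleValidationError("initial distribution proportions must be >= 0")
        # life table must cover every attained age in the horizon
        end_age = self.start_age + self.n_cycles
        if self.life_table.ages[0] > self.start_age or self.life_table.ages[-1] < end_age:
            raise BundleValidationError(
                f"life table must cover ages {self.start_age}..{end_age}"
            )
        return self

    # -- convenience --------------------------------------------------
    def economics_for(self, state: str) -> StateEconomics:
        for e in self.economics:
            if e.state == state:
                return e
        raise BundleValidationError(f"no economics entry for state {state!r}")

    def initial_vector(self) -> np.ndarray:
        """Initial occupancy in persons, ordered like the state space."""
        init = dict(self.initial_distribution)
        return np.array(
            [init.get(s, 0.0) * self.cohort_size for s in self.state_space.ids]
        )

    def cost_vector(self) -> np.ndarray:
        econ = {e.state: e.annual_cost for e in self.economics}
        return np.array([econ.get(s, 0.0) for s in self.state_space.ids])

    def daly_weight_vector(self) -> np.ndarray:
        econ = {e.state: e.daly_weight for e in self.economics}
        return np.array([econ.get(s, 0.0) for s in self.state_space.ids])

    def transition_for(self, from_state: str, to_state: str) -> TransitionEntry:
        for t in self.transitions:
            if t.from_state == from_state and t.to_state == to_state:
                return t
        raise KeyError(f"no transition {from_state}->{to_state} in bundle")


def validate_edges(
    transitions, allowed_edges
) -> list[tuple[str, str]]:
    """Return the ``(from, to)`` pairs not permitted by the model diagram.

    Self-loops are always allowed.  Violations come back as data, not
    exceptions, so callers can report them all at once.
    """
    allowed = set(allowed_edges)
    out = []
    for t in transitions:
        if t.from_state == t.to_state:
            continue
        if (t.from_state, t.to_state) not in allowed:
            out.append((t.from_state, t.to_state))
    return out


# ---------------------------------------------------------------------------
# Bundle I/O: bundle.yaml + transitions.csv + economics.csv + lifetable.csv
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "states", "death_state", "tunnel_states", "roles", "allowed_edges",
    "initial_distribution", "cohort_size", "n_cycles", "start_age",
    "discount_rate", "threshold", "prophylaxis_effect_definite",
    "prophylaxis_effect_mild", "shared_cost_variance", "screening",
    "cycle_accrual", "yll_mode", "half_cycle_correction",
    "transitions_file", "economics_file", "lifetable_file",
}

_SCREENING_KEYS = {
    "cost_per_scan", "sensitivity_borderline", "sensitivity_definite",
    "specificity", "false_positive_followup_cost", "screened_fraction",
    "sensitivity_borderline_range", "sensitivity_definite_range",
}


def _descriptor_from_row(kind: str, raw: str) -> UncertaintyDescriptor | None:
    if not kind or kind == "none" or (isinstance(kind, float) and math.isnan(kind)):
        return None
    values = [float(x) for x in str(raw).split(";") if x != ""]
    names = {
        "point": ("value",),
        "gamma_mean_var": ("mean", "variance"),
        "triangular_95ui": ("lower", "mode", "upper"),
        "beta_mean_n": ("mean", "n"),
        "uniform_bounds": ("lower", "upper"),
    }
    if kind not in names:
        raise BundleValidationError(f"unknown distribution kind {kind!r}")
    if len(values) != len(names[kind]):
        raise BundleValidationError(
            f"distribution {kind} expects {len(names[kind])} parameters, got {len(values)}"
        )
    return UncertaintyDescriptor(kind, tuple(zip(names[kind], values)))


def _descriptor_to_row(d: UncertaintyDescriptor | None) -> tuple[str, str]:
    if d is None:
        return "none", ""
    return d.kind, ";".join(repr(v) for _, v in d.params)


def load_bundle(path) -> ParameterSet:
    """Read and validate a parameter bundle directory.

    Raises :class:`BundleValidationError` naming the offending field on any
    invariant violation, and rejects unknown config keys by name.
    """
    root = Path(path)
    config_path = root / "bundle.yaml" if root.is_dir() else root
    root = config_path.parent
    if not config_path.exists():
        raise BundleValidationError(f"no bundle config at {config_path}")
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise BundleValidationError(f"unknown config keys: {sorted(unknown)}")
    if "screening" in cfg:
        bad = set(cfg["screening"]) - _SCREENING_KEYS
        if bad:
            raise BundleValidationError(f"unknown screening keys: {sorted(bad)}")

    sp = StateSpace(
        states=tuple((s["id"], s["label"]) for s in cfg["states"]),
        death_state=cfg["death_state"],
        tunnel_states=tuple(cfg.get("tunnel_states", [])),
        roles=dict(cfg.get("roles", {})),
    )

    tdf = pd.read_csv(
        root / cfg.get("transitions_file", "transitions.csv"),
        float_precision="round_trip",
    )
    transitions = tuple(
        TransitionEntry(
            from_state=str(r["from"]),
            to_state=str(r["to"]),
            probability=float(r["probability"]),
            uncertainty=_descriptor_from_row(r.get("dist_kind", ""), r.get("dist_params", "")),
        )
        for r in tdf.to_dict("records")
    )

    edf = pd.read_csv(
        root / cfg.get("economics_file", "economics.csv"),
        float_precision="round_trip",
    )
    economics = tuple(
        StateEconomics(
            state=str(r["state"]),
            annual_cost=float(r["cost"]),
            daly_weight=float(r.get("daly_weight", 0.0)),
            daly_lower=float(r.get("daly_lo", r.get("daly_weight", 0.0))),
            daly_upper=float(r.get("daly_hi", r.get("daly_weight", 0.0))),
            cost_uncertainty=_descriptor_from_row(
                r.get("cost_dist", ""), r.get("cost_dist_params", "")
            ),
        )
        for r in edf.to_dict("records")
    )

    ldf = pd.read_csv(
        root / cfg.get("lifetable_file", "lifetable.csv"),
        float_precision="round_trip",
    )
    life = LifeTable(ldf["age"].to_numpy(), ldf["expectancy"].to_numpy())

    screening = ScreeningParameters(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg.get("screening", {}).items()
        }
    )
    allowed = cfg.get("allowed_edges")
    ps = ParameterSet(
        state_space=sp,
        transitions=transitions,
        economics=economics,
        life_table=life,
        initial_distribution=tuple(
            (str(k), float(v)) for k, v in cfg["initial_distribution"].items()
        ),
        screening=screening,
        cohort_size=float(cfg.get("cohort_size", 1000)),
        n_cycles=int(cfg.get("n_cycles", 30)),
        start_age=float(cfg.get("start_age", 11)),
        discount_rate=float(cfg.get("discount_rate", 0.03)),
        threshold=float(cfg.get("threshold", 25_949.85)),
        prophylaxis_effect_definite=float(cfg.get("prophylaxis_effect_definite", 0.5)),
        prophylaxis_effect_mild=float(cfg.get("prophylaxis_effect_mild", 0.5)),
        shared_cost_variance=float(cfg.get("shared_cost_variance", 0.0)),
        allowed_edges=(
            frozenset(tuple(e) for e in allowed)
            if allowed is not None
            else frozenset(CANONICAL_EDGES)
        ),
        cycle_accrual=cfg.get("cycle_accrual", "end"),
        yll_mode=cfg.get("yll_mode", "stream"),
        half_cycle_correction=bool(cfg.get("half_cycle_correction", False)),
    )
    return ps.validate()


def save_bundle(params: ParameterSet, path) -> Path:
    """Write a bundle directory; inverse of :func:`load_bundle`."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    sp = params.state_space

    tdf = pd.DataFrame(
        [
            {
                "from": t.from_state,
                "to": t.to_state,
                "probability": repr(t.probability),
                "dist_kind": _descriptor_to_row(t.uncertainty)[0],
                "dist_params": _descriptor_to_row(t.uncertainty)[1],
            }
            for t in params.transitions
        ]
    )
    tdf.to_csv(root / "transitions.csv", index=False)

    edf = pd.DataFrame(
        [
            {
                "state": e.state,
                "cost": repr(e.annual_cost),
                "cost_dist": _descriptor_to_row(e.cost_uncertainty)[0],
                "cost_dist_params": _descriptor_to_row(e.cost_uncertainty)[1],
                "daly_weight": repr(e.daly_weight),
                "daly_lo": repr(e.daly_lower),
                "daly_hi": repr(e.daly_upper),
            }
            for e in params.economics
        ]
    )
    edf.to_csv(root / "economics.csv", index=False)

    params.life_table.to_frame().to_csv(root / "lifetable.csv", index=False)

    cfg = {
        "states": [{"id": s, "label": l} for s, l in sp.states],
        "death_state": sp.death_state,
        "tunnel_states": list(sp.tunnel_states),
        "roles": dict(sp.roles),
        "allowed_edges": sorted([list(e) for e in params.allowed_edges]),
        "initial_distribution": {k: v for k, v in params.initial_distribution},
        "cohort_size": params.cohort_size,
        "n_cycles": params.n_cycles,
        "start_age": params.start_age,
        "discount_rate": params.discount_rate,
        "threshold": params.threshold,
        "prophylaxis_effect_definite": params.prophylaxis_effect_definite,
        "prophylaxis_effect_mild": params.prophylaxis_effect_mild,
        "shared_cost_variance": params.shared_cost_variance,
        "cycle_accrual": params.cycle_accrual,
        "yll_mode": params.yll_mode,
        "half_cycle_correction": params.half_cycle_correction,
        "screening": {
            "cost_per_scan": params.screening.cost_per_scan,
            "sensitivity_borderline": params.screening.sensitivity_borderline,
            "sensitivity_definite": params.screening.sensitivity_definite,
            "specificity": params.screening.specificity,
            "false_positive_followup_cost": params.screening.false_positive_followup_cost,
            "screened_fraction": params.screening.screened_fraction,
            "sensitivity_borderline_range": list(params.screening.sensitivity_borderline_range),
            "sensitivity_definite_range": list(params.screening.sensitivity_definite_range),
        },
    }
    with open(root / "bundle.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return root
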