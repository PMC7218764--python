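"""Probabilistic and one-way deterministic sensitivity analysis.

Probabilistic sensitivity analysis (PSA) redraws every uncertain input —
transition probabilities, per-state annual costs, disability weights —
from its descriptor, reruns both strategies, and records the incremental
``(delta cost, DALYs averted)`` pair per iteration.  The cost-effectiveness
acceptability curve (CEAC) is the fraction of iterations with positive net
monetary benefit along a threshold grid.

One-way analysis sweeps a single addressable parameter between bounds with
everything else at base values, recording the two ICERs; a batch sweep over
all registered parameters yields the tornado table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .outcomes import compare, evaluate_strategy
from .params import (
    BundleValidationError,
    ParameterSet,
    StateEconomics,
    TransitionEntry,
    UncertaintyDescriptor,
)
from .scenarios import build_screening, build_standard_care

__all__ = [
    "sample_parameter",
    "PsaResult",
    "run_psa",
    "CeacCurve",
    "ceac",
    "TornadoRow",
    "one_way_sweep",
    "tornado",
    "default_threshold_grid",
]

logger = logging.getLogger(__name__)

_REDRAW_CAP = 100


# ---------------------------------------------------------------------------
# Parameter sampling
# ---------------------------------------------------------------------------

def sample_parameter(descriptor: UncertaintyDescriptor, rng: np.random.Generator) -> float:
    """Draw one value from an uncertainty descriptor.

    Gamma draws use shape = mean^2/variance and scale = variance/mean
    (moment matching); zero variance degenerates to the mean.  Triangular
    draws span the 95% uncertainty interval with the mode at the point
    estimate.  Beta draws use alpha = mean*n, beta = (1-mean)*n.
    """
    p = descriptor.as_dict()
    kind = descriptor.kind
    if kind == "point":
        return p["value"]
    if kind == "gamma_mean_var":
        mean, var = p["mean"], p["variance"]
        if var < 0:
            raise BundleValidationError("gamma variance must be >= 0")
        if var == 0.0 or mean == 0.0:
            return mean
        shape = mean * mean / var
        scale = var / mean
        return float(rng.gamma(shape, scale))
    if kind == "triangular_95ui":
        lo, mode, hi = p["lower"], p["mode"], p["upper"]
        if lo == hi:
            return mode
        return float(rng.triangular(lo, mode, hi))
    if kind == "beta_mean_n":
        mean, n = p["mean"], p["n"]
        if mean in (0.0, 1.0):
            return mean
        return float(rng.beta(mean * n, (1.0 - mean) * n))
    if kind == "uniform_bounds":
        lo, hi = p["lower"], p["upper"]
        if lo == hi:
            return lo
        return float(rng.uniform(lo, hi))
    raise BundleValidationError(f"unknown uncertainty kind {kind!r}")


def _cost_descriptor(econ: StateEconomics, shared_variance: float) -> UncertaintyDescriptor:
    """Gamma descriptor for a state's annual cost.

    States without their own variance share one cost variance (in the
    canonical bundle, the surgery state's — the only state with primary
    variance data).  Zero-cost states stay at zero.
    """
    if econ.cost_uncertainty is not None:
        return econ.cost_uncertainty
    if econ.annual_cost == 0.0:
        return UncertaintyDescriptor.point(0.0)
    return UncertaintyDescriptor.gamma(econ.annual_cost, shared_variance)


def _sample_transitions(
    params: ParameterSet, rng: np.random.Generator
) -> tuple[TransitionEntry, ...]:
    """Sample every transition, clip to [0, 1], renormalize rows whose
    sampled outgoing mass exceeds 1 (the self-loop remainder absorbs the
    rest, as in the deterministic matrix)."""
    by_row: dict[str, list[tuple[TransitionEntry, float]]] = {}
    changed = False
    for t in params.transitions:
        draw = min(1.0, max(0.0, sample_parameter(t.descriptor, rng)))
        changed = changed or draw != t.probability
        by_row.setdefault(t.from_state, []).append((t, draw))
    if not changed:  # degenerate descriptors: keep the base entries bit-for-bit
        return params.transitions

    tunnels = set(params.state_space.tunnel_states)
    out: list[TransitionEntry] = []
    for state, entries in by_row.items():
        total = sum(d for e, d in entries if e.from_state != e.to_state)
        # tunnel rows have no self-loop remainder, so they renormalize to
        # exactly 1; ordinary rows only rescale when they overflow
        if state in tunnels and total > 0:
            scale = 1.0 / total
        else:
            scale = 1.0 / total if total > 1.0 else 1.0
        for e, d in entries:
            p = d * scale if e.from_state != e.to_state else d
            out.append(replace(e, probability=p))
    return tuple(out)


def _sampled_vectors(params: ParameterSet, rng: np.random.Generator):
    ids = params.state_space.ids
    costs = {e.state: sample_parameter(_cost_descriptor(e, params.shared_cost_variance), rng)
             for e in params.economics}
    weights = {e.state: min(1.0, max(0.0, sample_parameter(e.daly_descriptor, rng)))
               for e in params.economics}
    cost_vec = np.array([costs.get(s, 0.0) for s in ids])
    weight_vec = np.array([weights.get(s, 0.0) for s in ids])
    return cost_vec, weight_vec


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsaResult:
    """Per-iteration incremental pairs from a probabilistic analysis.

    ``iterations[:, 0]`` is the incremental cost (USD),
    ``iterations[:, 1]`` the DALYs averted.
    """

    iterations: np.ndarray
    seed: int
    n_iterations: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if self.iterations.shape != (self.n_iterations, 2):
            raise ValueError("iterations must be an (n, 2) array")
        if not np.all(np.isfinite(self.iterations)):
            raise ValueError("PSA iterations must be finite")

    @property
    def delta_cost(self) -> np.ndarray:
        return self.iterations[:, 0]

    @property
    def delta_effect(self) -> np.ndarray:
        return self.iterations[:, 1]

    def acceptance_probability(self, threshold: float) -> float:
        """Fraction of iterations with positive net monetary benefit at
        the given willingness-to-pay threshold."""
        return float(
            np.mean(threshold * self.delta_effect - self.delta_cost > 0)
        )


def _evaluate_pair(params: ParameterSet, cost_vec=None, weight_vec=None):
    standard = build_standard_care(params)
    screening = build_screening(params)
    res_s = evaluate_strategy(standard, params, cost_vec, weight_vec, detail=False)
    res_i = evaluate_strategy(screening, params, cost_vec, weight_vec, detail=False)
    return res_s, res_i


def run_psa(params: ParameterSet, n_iterations: int, seed: int) -> PsaResult:
    """Rerun the whole pipeline ``n_iterations`` times with all uncertain
    parameters redrawn; fully reproducible given ``seed``.

    Iterations whose sampled transitions cannot form a valid stochastic
    matrix are rejected and redrawn (cap 100 per iteration), with the
    total redraw count reported on the result.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = np.empty((n_iterations, 2))
    n_redrawn = 0
    for i in range(n_iterations):
        for attempt in range(_REDRAW_CAP + 1):
            try:
                sampled = replace(params, transitions=_sample_transitions(params, rng))
                cost_vec, weight_vec = _sampled_vectors(params, rng)
                res_s, res_i = _evaluate_pair(sampled, cost_vec, weight_vec)
                break
            except (ValueError, BundleValidationError):
                n_redrawn += 1
                if attempt == _REDRAW_CAP:
                    raise RuntimeError(
                        f"PSA iteration {i}: {_REDRAW_CAP} consecutive invalid draws"
                    )
        pairs[i, 0] = res_i.total_cost - res_s.total_cost
        pairs[i, 1] = res_s.total_dalys - res_i.total_dalys
    if n_redrawn:
        logger.info("PSA redrew %d invalid iterations", n_redrawn)
    return PsaResult(
        iterations=pairs, seed=seed, n_iterations=n_iterations, n_redrawn=n_redrawn
    )


# ---------------------------------------------------------------------------
# Cost-effectiveness acceptability curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CeacCurve:
    """Acceptance probability as a function of the threshold."""

    thresholds: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        if self.thresholds.size == 0:
            raise ValueError("threshold grid must be non-empty")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("threshold grid must be strictly increasing")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("acceptance probabilities must lie in [0, 1]")

    def at(self, threshold: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        return float(self.probabilities[idx])


def default_threshold_grid(threshold: float, n: int = 200) -> np.ndarray:
    """0 to twice the decision threshold in ``n`` steps."""
    return np.linspace(0.0, 2.0 * threshold, n + 1)[1:]


def ceac(psa: PsaResult, thresholds) -> CeacCurve:
    """Acceptance probability at each threshold λ: the fraction of
    iterations with λ·ΔE − ΔC > 0."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid must be non-empty")
    nmb = thresholds[:, None] * psa.delta_effect[None, :] - psa.delta_cost[None, :]
    probs = (nmb > 0).mean(axis=1)
    return CeacCurve(thresholds=thresholds, probabilities=probs)


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoRow:
    """ICERs at the two endpoints of one parameter sweep."""

    parameter: str
    low_value: float
    high_value: float
    low_icer: float
    high_icer: float

    @property
    def spread(self) -> float:
        return abs(self.high_icer - self.low_icer)


def _set_parameter(params: ParameterSet, pid: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with the addressed parameter replaced.

    Addresses: ``discount_rate``, ``prophylaxis_effect_definite``,
    ``prophylaxis_effect_mild``, ``cost:<state>``, ``daly:<state>``,
    ``transition:<from>-><to>``, ``screening:<field>``.
    """
    try:
        if pid == "discount_rate":
            if value < 0:
                raise BundleValidationError("discount rate must be >= 0")
            return replace(params, discount_rate=value)
        if pid in ("prophylaxis_effect_definite", "prophylaxis_effect_mild"):
            if not 0.0 <= value <= 1.0:
                raise BundleValidationError("prophylaxis effect must lie in [0, 1]")
            return replace(params, **{pid: value})
        if pid.startswith("cost:"):
            state = pid.split(":", 1)[1]
            econ = params.economics_for(state)
            new = replace(econ, annual_cost=value)
            return replace(
                params,
                economics=tuple(new if e.state == state else e for e in params.economics),
            )
        if pid.startswith("daly:"):
            state = pid.split(":", 1)[1]
            econ = params.economics_for(state)
            new = replace(
                econ,
                daly_weight=value,
                daly_lower=min(econ.daly_lower, value),
                daly_upper=max(econ.daly_upper, value),
            )
            return replace(
                params,
                economics=tuple(new if e.state == state else e for e in params.economics),
            )
        if pid.startswith("transition:"):
            edge = pid.split(":", 1)[1]
            frm, to = edge.split("->")
            entry = params.transition_for(frm, to)
            updated = {(frm, to): replace(entry, probability=value)}
            if frm in params.state_space.tunnel_states:
                # tunnel rows have no self-loop: the other outgoing edges
                # share the complement in their base proportions
                others = [
                    t for t in params.transitions
                    if t.from_state == frm and (t.from_state, t.to_state) != (frm, to)
                ]
                other_sum = sum(t.probability for t in others)
                if other_sum > 0:
                    for t in others:
                        updated[(t.from_state, t.to_state)] = replace(
                            t, probability=(1.0 - value) * t.probability / other_sum
                        )
            return replace(
                params,
                transitions=tuple(
                    updated.get((t.from_state, t.to_state), t)
                    for t in params.transitions
                ),
            )
        if pid.startswith("screening:"):
            fieldname = pid.split(":", 1)[1]
            if not hasattr(params.screening, fieldname):
                raise KeyError(pid)
            return replace(
                params, screening=replace(params.screening, **{fieldname: value})
            )
    except (BundleValidationError, ValueError) as exc:
        raise BundleValidationError(f"parameter {pid!r}: {exc}") from exc
    raise KeyError(f"unknown parameter id {pid!r}")


def one_way_sweep(
    params: ParameterSet, parameter_id: str, low: float, high: float
) -> TornadoRow:
    """Deterministic ICERs with one parameter at its low / high bound."""
    if low > high:
        raise ValueError(f"parameter {parameter_id!r}: low {low} > high {high}")

    def icer_at(value: float) -> float:
        p = _set_parameter(params, parameter_id, value)
        res_s, res_i = _evaluate_pair(p)
        c = compare(res_s, res_i, p.threshold)
        return c.icer if c.icer is not None else float("nan")

    return TornadoRow(
        parameter=parameter_id,
        low_value=low,
        high_value=high,
        low_icer=icer_at(low),
        high_icer=icer_at(high),
    )


def _transition_headroom(params: ParameterSet, entry: TransitionEntry) -> float:
    """Largest probability the edge can take with its row still stochastic."""
    others = sum(
        t.probability
        for t in params.transitions
        if t.from_state == entry.from_state
        and t.from_state != t.to_state
        and (t.from_state, t.to_state) != (entry.from_state, entry.to_state)
    )
    return max(0.0, 1.0 - others)


def sweep_bounds(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Registered sweepable parameters and their endpoint values.

    Transitions and costs use the 95% interval implied by their
    descriptors (transition highs capped at the row's stochastic
    headroom); disability weights their uncertainty intervals; screening
    sensitivities their stated ranges; the discount rate 0–5%; the
    prophylaxis effects 0–50% (definite) and 25–75% (clinical).
    Parameters without usable bounds are skipped with a warning.
    """
    bounds: dict[str, tuple[float, float]] = {}
    bounds["discount_rate"] = (0.0, 0.05)
    bounds["prophylaxis_effect_definite"] = (0.0, params.prophylaxis_effect_definite)
    bounds["prophylaxis_effect_mild"] = (0.25, 0.75)
    scr = params.screening
    bounds["screening:sensitivity_borderline"] = scr.sensitivity_borderline_range
    bounds["screening:sensitivity_definite"] = scr.sensitivity_definite_range

    for t in params.transitions:
        pid = f"transition:{t.from_state}->{t.to_state}"
        b = t.descriptor.bounds95()
        if b is None:
            logger.warning("no bounds for %s; skipped in tornado", pid)
            continue
        cap = _transition_headroom(params, t)
        lo = min(max(0.0, b[0]), 1.0)
        hi = min(b[1], cap, 1.0)
        if hi > lo:
            bounds[pid] = (lo, hi)
    for e in params.economics:
        pid = f"cost:{e.state}"
        b = _cost_descriptor(e, params.shared_cost_variance).bounds95()
        if b is not None:
            bounds[pid] = b
        elif e.annual_cost > 0:
            logger.warning("no bounds for %s; skipped in tornado", pid)
        if e.daly_upper > e.daly_lower:
            bounds[f"daly:{e.state}"] = (e.daly_lower, e.daly_upper)
    return bounds


def tornado(
    params: ParameterSet, parameters: dict[str, tuple[float, float]] | None = None
) -> list[TornadoRow]:
    """Sweep every registered parameter; rows sorted by descending spread."""
    bounds = sweep_bounds(params) if parameters is None else parameters
    rows = [one_way_sweep(params, pid, lo, hi) for pid, (lo, hi) in bounds.items()]
    return sorted(rows, key=lambda r: (np.nan_to_num(-r.spread), r.parameter))
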