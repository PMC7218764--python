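"""Model facade: build once from a parameter bundle, then evaluate.

:class:`ScreeningCEA` wraps the whole pipeline the way statistical
modelling packages wrap an estimator: construct it from a
:class:`~rhdcea.params.ParameterSet` (or ``from_bundle`` on a bundle
directory), then call :meth:`run` for the deterministic cost-utility
comparison, :meth:`run_psa` for the probabilistic analysis, and
:meth:`tornado` for the one-way sweeps.  Each call returns a results
object with the numbers, a ``summary()`` table, and export/plot helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sensitivity as sens
from .engine import CohortTrace, prevalence_by_ageband, run_cohort
from .outcomes import ComparisonResult, ScenarioResult, compare, evaluate_strategy
from .params import ParameterSet, load_bundle
from .scenarios import Strategy, build_screening, build_standard_care

__all__ = ["ScreeningCEA", "CEAResults", "PsaResults", "TornadoResults"]

#: Echo lesion classes mapped onto model states, for prevalence validation.
STATE_CLASSES: dict[str, tuple[str, ...]] = {
    "borderline": ("B", "F"),
    "definite": ("C", "G"),
}


def _usd(x: float) -> str:
    return f"${x:,.2f}"


@dataclass(frozen=True)
class CEAResults:
    """Deterministic cost-utility comparison of screening vs standard care."""

    standard: ScenarioResult
    screening: ScenarioResult
    comparison: ComparisonResult
    params: ParameterSet = field(repr=False, compare=False)
    traces: dict = field(repr=False, compare=False, default_factory=dict)

    @property
    def icer(self) -> float | None:
        return self.comparison.icer

    def to_dict(self) -> dict:
        c = self.comparison
        return {
            "cost_standard": self.standard.total_cost,
            "cost_screening": self.screening.total_cost,
            "dalys_standard": self.standard.total_dalys,
            "dalys_screening": self.screening.total_dalys,
            "delta_cost": c.delta_cost,
            "dalys_averted": c.delta_effect,
            "icer": c.icer,
            "label": c.label,
            "nmb": c.nmb,
            "threshold": c.threshold,
        }

    def summary(self) -> str:
        c = self.comparison
        lines = [
            "Cost-utility analysis: one-time echo screening vs standard care",
            f"  cohort {self.params.cohort_size:,.0f}, {self.params.n_cycles} annual "
            f"cycles from age {self.params.start_age:.0f}, "
            f"discount {self.params.discount_rate:.1%}",
            "",
            f"  {'strategy':<16}{'cost':>16}{'DALYs':>12}",
            f"  {'standard care':<16}{_usd(self.standard.total_cost):>16}"
            f"{self.standard.total_dalys:>12.2f}",
            f"  {'screening':<16}{_usd(self.screening.total_cost):>16}"
            f"{self.screening.total_dalys:>12.2f}",
            "",
            f"  incremental cost      {_usd(c.delta_cost)}",
            f"  DALYs averted         {c.delta_effect:.2f}",
        ]
        if c.icer is not None:
            lines.append(f"  ICER                  {_usd(c.icer)} per DALY averted")
        lines.append(f"  decision              {c.label}")
        lines.append(
            f"  NMB at {_usd(c.threshold)}: {_usd(c.nmb)}"
            f" ({'cost-effective' if c.nmb > 0 else 'not cost-effective'})"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class PsaResults:
    """Probabilistic sensitivity analysis results with CEAC access."""

    psa: sens.PsaResult
    threshold: float

    @property
    def acceptance_probability(self) -> float:
        return self.psa.acceptance_probability(self.threshold)

    def ceac(self, thresholds=None) -> sens.CeacCurve:
        grid = (
            sens.default_threshold_grid(self.threshold)
            if thresholds is None
            else thresholds
        )
        return sens.ceac(self.psa, grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.psa.n_iterations),
                "delta_cost": self.psa.delta_cost,
                "delta_effect": self.psa.delta_effect,
            }
        )

    def summary(self) -> str:
        dc, de = self.psa.delta_cost, self.psa.delta_effect
        return "\n".join(
            [
                f"Probabilistic sensitivity analysis ({self.psa.n_iterations:,} "
                f"iterations, seed {self.psa.seed})",
                f"  mean incremental cost  {_usd(float(dc.mean()))}",
                f"  mean DALYs averted     {float(de.mean()):.2f}",
                f"  P(cost-effective at {_usd(self.threshold)}): "
                f"{self.acceptance_probability:.1%}",
                f"  invalid draws redrawn  {self.psa.n_redrawn}",
            ]
        )

    def plot_ceac(self, ax=None, thresholds=None):
        """Acceptability curve: acceptance probability vs threshold."""
        import matplotlib.pyplot as plt

        curve = self.ceac(thresholds)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.thresholds, curve.probabilities)
        ax.axvline(self.threshold, linestyle="--", color="grey")
        ax.set_xlabel("cost-effectiveness threshold (USD per DALY averted)")
        ax.set_ylabel("probability cost-effective")
        ax.set_ylim(0, 1)
        return ax

    def plot_ce_plane(self, ax=None):
        """Incremental cost-effectiveness plane scatter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.psa.delta_effect, self.psa.delta_cost, s=4, alpha=0.3)
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("DALYs averted")
        ax.set_ylabel("incremental cost (USD)")
        return ax


@dataclass(frozen=True)
class TornadoResults:
    """One-way sensitivity sweep of every registered parameter."""

    rows: tuple[sens.TornadoRow, ...]
    base_icer: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": r.parameter,
                    "low_value": r.low_value,
                    "high_value": r.high_value,
                    "low_icer": r.low_icer,
                    "high_icer": r.high_icer,
                    "spread": r.spread,
                }
                for r in self.rows
            ]
        )

    def summary(self, top: int = 10) -> str:
        lines = [
            f"One-way sensitivity analysis (base ICER {_usd(self.base_icer)})",
            f"  {'parameter':<34}{'low ICER':>14}{'high ICER':>14}{'spread':>14}",
        ]
        for r in self.rows[:top]:
            lines.append(
                f"  {r.parameter:<34}{r.low_icer:>14,.2f}"
                f"{r.high_icer:>14,.2f}{r.spread:>14,.2f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, top: int = 10):
        """Tornado diagram of the largest ICER spreads."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rows = list(self.rows[:top])[::-1]
        names = [r.parameter for r in rows]
        lows = np.array([min(r.low_icer, r.high_icer) for r in rows])
        highs = np.array([max(r.low_icer, r.high_icer) for r in rows])
        ax.barh(names, highs - lows, left=lows, color="steelblue")
        ax.axvline(self.base_icer, linestyle=":", color="black")
        ax.set_xlabel("ICER (USD per DALY averted)")
        return ax


class ScreeningCEA:
    """Cost-utility model of one-time echocardiographic RHD screening.

    Parameters
    ----------
    params
        A fully validated :class:`~rhdcea.params.ParameterSet`.

    Examples
    --------
    >>> from rhdcea import ScreeningCEA, reference_bundle
    >>> model = ScreeningCEA(reference_bundle())
    >>> res = model.run()
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(self, params: ParameterSet):
        self.params = params.validate()

    @classmethod
    def from_bundle(cls, path) -> "ScreeningCEA":
        """Build the model from a bundle directory on disk."""
        return cls(load_bundle(path))

    # -- strategies ---------------------------------------------------
    def strategies(self) -> tuple[Strategy, Strategy]:
        return build_standard_care(self.params), build_screening(self.params)

    def trace(self, strategy: Strategy) -> CohortTrace:
        return run_cohort(
            strategy.transition_matrix,
            strategy.initial_occupancy,
            self.params.n_cycles,
            self.params.state_space,
        )

    # -- analyses -----------------------------------------------------
    def run(self) -> CEAResults:
        """Deterministic evaluation of both strategies."""
        standard, screening = self.strategies()
        res_s = evaluate_strategy(standard, self.params)
        res_i = evaluate_strategy(screening, self.params)
        return CEAResults(
            standard=res_s,
            screening=res_i,
            comparison=compare(res_s, res_i, self.params.threshold),
            params=self.params,
            traces={
                "standard_care": self.trace(standard),
                "screening": self.trace(screening),
            },
        )

    def run_psa(self, n_iterations: int = 10_000, seed: int = 0) -> PsaResults:
        """Probabilistic sensitivity analysis; reproducible given seed."""
        psa = sens.run_psa(self.params, n_iterations, seed)
        return PsaResults(psa=psa, threshold=self.params.threshold)

    def tornado(self, parameters=None) -> TornadoResults:
        """One-way sweeps over all registered parameters (or a given
        ``{parameter_id: (low, high)}`` mapping)."""
        base = self.run().comparison
        rows = sens.tornado(self.params, parameters)
        return TornadoResults(
            rows=tuple(rows),
            base_icer=base.icer if base.icer is not None else float("nan"),
        )

    def validate_prevalence(self, observed: pd.DataFrame) -> pd.DataFrame:
        """Compare model-predicted latent-RHD prevalence per age band with
        observed screening prevalence.

        ``observed`` needs columns ``age_lo``, ``age_hi``, ``state_class``
        (``"borderline"`` or ``"definite"``, or a comma-separated state
        list) and ``prevalence``.  Returns the table with predicted
        values and absolute / relative differences appended.
        """
        standard, _ = self.strategies()
        trace = self.trace(standard)
        rows = []
        for rec in observed.to_dict("records"):
            cls_ = rec["state_class"]
            states = STATE_CLASSES.get(cls_, tuple(str(cls_).split(",")))
            pred = prevalence_by_ageband(
                trace,
                self.params.start_age,
                states,
                float(rec["age_lo"]),
                float(rec["age_hi"]),
            )
            obs = float(rec["prevalence"])
            rows.append(
                {
                    **rec,
                    "predicted": pred,
                    "abs_diff": pred - obs,
                    "rel_diff": (pred - obs) / obs if obs != 0 else float("nan"),
                }
            )
        return pd.DataFrame(rows)
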