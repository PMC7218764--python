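"""Canonical reference bundle and published headline results.

The reference bundle carries the verbatim 2017 USD per-state cost table
(DataSUS / SUS reimbursement data) and the study design constants: a
1,000-child cohort enrolled at age 11, 30 annual cycles, 3% discounting,
a $25,949.85-per-DALY-averted threshold (three times 2015 GDP per
capita), $6.60 per screening scan, and 50% prophylaxis reductions.

Transition probabilities, disability weights, the life table and the
initial distribution are NOT public in the main study text; the reference
bundle fills them with fixed-seed synthetic stand-ins from
:mod:`rhdcea.synthetic` so that the full pipeline runs out of the box.
Anyone holding the primary estimates can overwrite those blocks via
:func:`rhdcea.params.save_bundle` / ``load_bundle``.
"""

from __future__ import annotations

from .params import ParameterSet
from .synthetic import GeneratorConfig, generate_bundle, TABLE_COSTS

__all__ = ["reference_bundle", "PUBLISHED_RESULTS", "TABLE_COSTS"]

#: Headline deterministic totals of the original Brazilian evaluation
#: (2017 USD and discounted DALYs for 1,000 children over 30 cycles),
#: usable as comparator inputs for consistency checks.
PUBLISHED_RESULTS: dict[str, float] = {
    "cost_standard": 34_249.72,
    "cost_screening": 49_828.52,
    "dalys_standard": 726.63,
    "dalys_screening": 725.09,
    "icer": 10_148.38,
    "threshold": 25_949.85,
    "psa_acceptance_at_threshold": 0.70,
}

_FIXTURE_SEED = 20170  # fixed: the reference bundle is one specific bundle


def reference_bundle() -> ParameterSet:
    """The canonical 15-state bundle (verbatim cost table + design
    constants; synthetic stand-ins for the non-public blocks)."""
    return generate_bundle(GeneratorConfig(seed=_FIXTURE_SEED))
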