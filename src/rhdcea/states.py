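"""Health-state space for the rheumatic heart disease (RHD) screening model.

The canonical state space follows the cost table of the Brazilian
screening cost-utility model: fifteen mutually exclusive states covering
latent (borderline / definite) RHD under the World Heart Federation
echocardiographic criteria, clinical disease by severity, treated and
untreated arms, resolution under secondary prophylaxis, valve surgery as
a single-cycle tunnel, post-surgical follow-up, and absorbing death.

The engine itself is state-space-agnostic: any :class:`StateSpace` with a
death state works.  Role annotations (which identifier plays "undiagnosed
borderline", "treated definite", ...) are what the scenario builder uses,
so alternative topologies only need to declare their roles.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class StateSpace:
    """Ordered collection of named health states with one absorbing death state.

    Parameters
    ----------
    states
        Ordered ``(identifier, human label)`` pairs.
    death_state
        Identifier of the absorbing death state.
    tunnel_states
        States the cohort may occupy for at most one cycle (their
        self-transition is forced to zero), e.g. surgery.
    roles
        Optional mapping of semantic roles (``"healthy"``,
        ``"undiagnosed_borderline"``, ``"treated_definite"``, ...) to state
        identifiers, used by the scenario builder.
    """

    states: tuple[tuple[str, str], ...]
    death_state: str
    tunnel_states: tuple[str, ...] = ()
    roles: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.states]
        if not ids:
            raise ValueError("state space must contain at least one state")
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate state identifiers: {dup}")
        if self.death_state not in ids:
            raise ValueError(f"death state {self.death_state!r} not in state list")
        for t in self.tunnel_states:
            if t not in ids:
                raise ValueError(f"tunnel state {t!r} not in state list")

    @property
    def ids(self) -> list[str]:
        return [s for s, _ in self.states]

    @property
    def labels(self) -> dict[str, str]:
        return dict(self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state_id: str) -> int:
        try:
            return self.ids.index(state_id)
        except ValueError:
            raise KeyError(f"unknown state {state_id!r}") from None

    def __contains__(self, state_id: str) -> bool:
        return state_id in self.ids

    def role(self, name: str) -> str:
        if name not in self.roles:
            raise KeyError(f"state space declares no role {name!r}")
        return self.roles[name]


#: The fifteen states of the canonical cost table, single-letter identifiers.
CANONICAL_STATES: tuple[tuple[str, str], ...] = (
    ("A", "No RHD"),
    ("B", "Undiagnosed Asymptomatic Borderline RHD"),
    ("C", "Untreated Asymptomatic Definite RHD"),
    ("D", "Untreated Mild Clinical RHD"),
    ("E", "Untreated Severe Clinical RHD"),
    ("F", "Diagnosed Borderline RHD"),
    ("G", "Treated Asymptomatic Definite RHD"),
    ("H", "Treated Mild Clinical RHD"),
    ("I", "Treated Severe Clinical RHD"),
    ("RG", "Resolved RHD (after treated asymptomatic definite)"),
    ("RH", "Resolved RHD (after treated mild clinical)"),
    ("RI", "Resolved RHD (after treated severe clinical)"),
    ("K", "Post Surgery"),
    ("X", "Surgery"),
    ("Z", "Death"),
)

CANONICAL_ROLES: dict = {
    "healthy": "A",
    "undiagnosed_borderline": "B",
    "untreated_definite": "C",
    "untreated_mild": "D",
    "untreated_severe": "E",
    "diagnosed_borderline": "F",
    "treated_definite": "G",
    "treated_mild": "H",
    "treated_severe": "I",
    "surgery": "X",
    "post_surgery": "K",
    "death": "Z",
}

# Directed edges of the model diagram (self-loops are always permitted and
# not listed; the surgery tunnel has no self-loop).  Death is reachable from
# every state and absorbing.  Care-seeking moves untreated clinical states to
# their treated counterparts; secondary prophylaxis can resolve treated
# disease; severe disease and post-surgical deterioration can require
# (re-)operation.
CANONICAL_EDGES: frozenset[tuple[str, str]] = frozenset(
    [
        ("A", "Z"),
        ("B", "A"), ("B", "C"), ("B", "Z"),
        ("C", "D"), ("C", "X"), ("C", "Z"),
        ("D", "E"), ("D", "H"), ("D", "X"), ("D", "Z"),
        ("E", "I"), ("E", "X"), ("E", "Z"),
        ("F", "A"), ("F", "G"), ("F", "Z"),
        ("G", "H"), ("G", "RG"), ("G", "X"), ("G", "Z"),
        ("H", "I"), ("H", "RH"), ("H", "Z"),
        ("I", "X"), ("I", "RI"), ("I", "Z"),
        ("RG", "Z"), ("RH", "Z"), ("RI", "Z"),
        ("K", "X"), ("K", "Z"),
        ("X", "K"), ("X", "Z"),
    ]
)


def canonical_state_space() -> StateSpace:
    """The 15-state space used by the shipped parameter bundles."""
    return StateSpace(
        states=CANONICAL_STATES,
        death_state="Z",
        tunnel_states=("X",),
        roles=dict(CANONICAL_ROLES),
    )
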