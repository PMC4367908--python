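"""Synthetic multi-valued networks and independent oracles.

The attractor engine assumes one structural class: deterministic synchronous
networks over nodes with small per-node level cardinalities, some of which
are self-held inputs.  This module generates random members of that class as
explicit lookup tables, for property-testing the engine against an
independent brute-force oracle, and carries the hand-derived 11-state
cell-cycle time series used as a fixture.

The brute-force oracle follows the trajectory from every state with a
visited-set until it closes a cycle; it shares no code with the engine's
in-degree-peeling method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RandomNetworkSpec",
    "TabularModel",
    "generate_random_model",
    "brute_force_attractors",
    "expected_cell_cycle_series",
    "ExpectedTimeSeries",
]

MAX_SYNTHETIC_STATES = 2**16


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Shape of a random synchronous multi-valued network."""

    cardinalities: tuple[int, ...]
    input_mask: tuple[bool, ...] = ()
    seed: int = 0
    zero_bias: float = 0.0  # extra probability mass on output level 0

    def __post_init__(self) -> None:
        if not self.input_mask:
            object.__setattr__(self, "input_mask", (False,) * len(self.cardinalities))
        if len(self.input_mask) != len(self.cardinalities):
            raise ValueError("input_mask length must match cardinalities")
        if any(c < 2 for c in self.cardinalities):
            raise ValueError("every node needs at least two levels")
        if not 0 <= self.zero_bias < 1:
            raise ValueError("zero_bias must lie in [0, 1)")
        if int(np.prod(self.cardinalities)) > MAX_SYNTHETIC_STATES:
            raise ValueError(
                f"synthetic state space exceeds {MAX_SYNTHETIC_STATES} states"
            )


@dataclass(frozen=True)
class TabularModel:
    """A synchronous network given by one full lookup table per node.

    ``tables[i][s]`` is node *i*'s next level when the network is in the
    state with mixed-radix index ``s``.  Implements the same engine protocol
    as the 14-node model, so :func:`vulvanet.dynamics.find_attractors`
    applies unchanged.
    """

    cardinalities: tuple[int, ...]
    tables: tuple[tuple[int, ...], ...]
    input_mask: tuple[bool, ...] = ()
    node_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.node_names:
            object.__setattr__(
                self,
                "node_names",
                tuple(f"n{i}" for i in range(len(self.cardinalities))),
            )
        n = self.n_states
        for i, (tab, card) in enumerate(zip(self.tables, self.cardinalities)):
            if len(tab) != n:
                raise ValueError(f"table for node {i} is not total")
            if any(not 0 <= v < card for v in tab):
                raise ValueError(f"table for node {i} has out-of-range outputs")

    @property
    def n_states(self) -> int:
        return int(np.prod(self.cardinalities))

    def successor_table(self) -> np.ndarray:
        cards = np.asarray(self.cardinalities, dtype=np.int64)
        weights = np.ones(len(cards), dtype=np.int64)
        for i in range(len(cards) - 2, -1, -1):
            weights[i] = weights[i + 1] * cards[i + 1]
        succ = np.zeros(self.n_states, dtype=np.int64)
        for i, tab in enumerate(self.tables):
            succ += np.asarray(tab, dtype=np.int64) * weights[i]
        return succ


def generate_random_model(spec: RandomNetworkSpec) -> TabularModel:
    """A reproducible random network; input nodes receive identity rules.

    Output levels are uniform per configuration, except that ``zero_bias``
    moves probability mass to level 0 (uniform tables almost never
    oscillate; biased, sparse ones do).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(np.prod(spec.cardinalities))
    cards = np.asarray(spec.cardinalities, dtype=np.int64)
    weights = np.ones(len(cards), dtype=np.int64)
    for i in range(len(cards) - 2, -1, -1):
        weights[i] = weights[i + 1] * cards[i + 1]
    idx = np.arange(n, dtype=np.int64)
    tables = []
    for i, card in enumerate(spec.cardinalities):
        if spec.input_mask[i]:
            col = (idx // weights[i]) % cards[i]  # identity: inputs hold their level
        else:
            col = rng.integers(0, card, size=n)
            if spec.zero_bias:
                col[rng.random(n) < spec.zero_bias] = 0
        tables.append(tuple(int(v) for v in col))
    return TabularModel(
        cardinalities=spec.cardinalities,
        tables=tuple(tables),
        input_mask=spec.input_mask,
    )


def brute_force_attractors(model) -> list[tuple[tuple[int, ...], ...]]:
    """Independent oracle: trajectory-following attractor search.

    Walks the successor map from every state, detecting the cycle with a
    visited-set, and returns each attractor as its canonically rotated tuple
    of state-level tuples, sorted.  Intentionally shares no machinery with
    the engine's in-degree-peeling enumeration.
    """
    if model.n_states > MAX_SYNTHETIC_STATES:
        raise ValueError("brute-force oracle limited to small state spaces")
    succ = [int(v) for v in model.successor_table()]
    cards = model.cardinalities
    weights = [1] * len(cards)
    for i in range(len(cards) - 2, -1, -1):
        weights[i] = weights[i + 1] * cards[i + 1]

    def decode(s: int) -> tuple[int, ...]:
        return tuple((s // w) % c for w, c in zip(weights, cards))

    found: set[tuple[tuple[int, ...], ...]] = set()
    resolved: dict[int, bool] = {}
    for start in range(model.n_states):
        if start in resolved:
            continue
        order: dict[int, int] = {}
        x = start
        while x not in order and x not in resolved:
            order[x] = len(order)
            x = succ[x]
        if x in order:  # fresh cycle closed
            cycle_idx = [s for s, k in order.items() if k >= order[x]]
            states = [decode(s) for s in cycle_idx]
            m = states.index(min(states))
            found.add(tuple(states[m:] + states[:m]))
        for s in order:
            resolved[s] = True
    return sorted(found)


@dataclass(frozen=True)
class ExpectedTimeSeries:
    """The 11-state cell-cycle progression with its stage names."""

    node_names: tuple[str, ...]
    states: tuple[tuple[int, ...], ...]
    stage_labels: tuple[str, ...]
    phase_labels: tuple[str, ...]


# Hand-derived once from the eight cell-cycle rules with MPK-1 = 0 and
# LIN-39 = 1: the unique cycle of the module, starting at the quiescent
# G1 state.  Node order: CKI-1, EFL-1, LIN-35, SCF, APC, CYD, CYE, CYB.
_SERIES_STATES: tuple[tuple[int, ...], ...] = (
    (1, 0, 1, 0, 1, 0, 0, 0),  # G1-1: the inhibitors CKI-1, LIN-35, APC are on
    (1, 0, 1, 0, 0, 0, 0, 0),  # G1-2: APC switches off
    (0, 0, 1, 0, 0, 0, 0, 0),  # G1-3: CKI-1 inactivated
    (0, 0, 1, 0, 0, 1, 0, 0),  # G1-4: CDK-4/CYD-1 activates (G1 progression)
    (0, 0, 0, 0, 0, 1, 0, 0),  # G1-5: LIN-35 inhibited
    (0, 1, 0, 0, 0, 1, 0, 0),  # G1-6: EFL-1 activates
    (0, 1, 0, 0, 0, 1, 1, 0),  # S1:   CDK-2/CYE-1 on (S marker)
    (0, 1, 0, 1, 0, 1, 1, 0),  # S2:   SCF turns on
    (0, 1, 0, 1, 0, 0, 0, 0),  # G2:   only EFL-1 and SCF active
    (0, 1, 1, 0, 0, 0, 0, 1),  # M1:   LIN-35 and CDK-1/CYB-3 (M marker) on
    (1, 0, 1, 0, 1, 0, 0, 1),  # M2:   EFL-1 off, APC on; then back to G1-1
)
_SERIES_STAGES = ("G1-1", "G1-2", "G1-3", "G1-4", "G1-5", "G1-6", "S1", "S2", "G2", "M1", "M2")
_SERIES_PHASES = ("G1",) * 6 + ("S", "S", "G2", "M", "M")


def expected_cell_cycle_series() -> ExpectedTimeSeries:
    """The reference 11-step cell-cycle time series of the isolated module."""
    from .squad import CELL_CYCLE_NODES

    return ExpectedTimeSeries(
        node_names=CELL_CYCLE_NODES,
        states=_SERIES_STATES,
        stage_labels=_SERIES_STAGES,
        phase_labels=_SERIES_PHASES,
    )
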