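"""Exhaustive state-space analysis: attractors, basins, phases, fates, transitions.

The synchronous update is a total function on a finite state space, so its
transition structure is a functional graph: every connected component is a
single cycle (the attractor) with in-trees hanging off it (the basin).  The
engine finds all cycles by iteratively peeling states of in-degree zero
(vectorized Kahn elimination); what survives is exactly the set of states on
cycles.  Basins are then filled in by propagating attractor labels backwards
through the successor map.

Phase labels follow the marker reading used for this network: CDK-1/CYB-3
marks M, CDK-2/CYE-1 marks S, SCF alone marks G2, and a state with all three
off is in G1.  Fate calls use LIN-39 level 2 (primary), LIN-12i activity
(secondary), LIN-39 silenced throughout (fusion with the hypodermis), and
tertiary otherwise, with precedence primary > secondary > fusion > tertiary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Model

__all__ = [
    "Attractor",
    "BasinSummary",
    "Trajectory",
    "FateTransition",
    "StateSpaceTooLarge",
    "find_attractors",
    "basin_summary",
    "simulate_trajectory",
    "label_phase",
    "g1_length",
    "classify_fate",
    "simulate_fate_transition",
    "wildtype_attractor_for_inputs",
]

DEFAULT_STATE_BOUND = 2**24

PHASES = ("G1", "S", "G2", "M")
FATES = ("primary", "secondary", "tertiary", "fusion", "other")


class StateSpaceTooLarge(ValueError):
    """Exhaustive enumeration refused: the state space exceeds the bound."""


@dataclass(frozen=True)
class Attractor:
    """A cycle of the synchronous map, in canonical rotation.

    ``states`` starts at the lexicographically smallest state of the cycle;
    ``inputs`` is the constant (LIN-3, LS) pair for the full model and
    ``None`` for models without input nodes (e.g. the isolated cell-cycle
    module).
    """

    states: tuple[tuple[int, ...], ...]
    period: int
    inputs: tuple[int, int] | None
    fate: str
    g1_length: int | None
    phase_labels: tuple[str, ...] | None

    def __len__(self) -> int:
        return self.period


@dataclass(frozen=True)
class BasinSummary:
    """Basin sizes per attractor and the attractor grouping per input slice."""

    sizes: tuple[int, ...]
    by_inputs: dict[tuple[int, int], tuple[int, ...]]  # (LIN-3, LS) -> attractor ids
    assignment: np.ndarray  # state index -> attractor id

    @property
    def total(self) -> int:
        return int(sum(self.sizes))


@dataclass(frozen=True)
class Trajectory:
    """States visited from an initial condition, ending at the first revisit.

    ``entry_index`` is the position at which the trajectory enters its cycle;
    ``states[entry_index:]`` is one full traversal of the attractor.
    """

    states: tuple[tuple[int, ...], ...]
    entry_index: int

    @property
    def transient_length(self) -> int:
        return self.entry_index

    @property
    def period(self) -> int:
        return len(self.states) - self.entry_index


@dataclass(frozen=True)
class FateTransition:
    """Outcome of shifting an attractor into a new microenvironment."""

    destinations: tuple[Attractor, ...]
    unique: bool

    @property
    def attractor(self) -> Attractor:
        return self.destinations[0]

    @property
    def fate(self) -> str:
        return self.attractor.fate


# --------------------------------------------------------------------------
# Phase and fate annotation


def _node_pos(model) -> dict[str, int]:
    return {name: i for i, name in enumerate(model.node_names)}


def label_phase(state: Sequence[int], pos: dict[str, int] | None = None) -> str:
    """Cell-cycle phase of a single state by marker precedence M > S > G2 > G1."""
    if pos is None:
        pos = {name: i for i, name in enumerate(Model().node_names)}
    if state[pos["CDK-1/CYB-3"]] == 1:
        return "M"
    if state[pos["CDK-2/CYE-1"]] == 1:
        return "S"
    if state[pos["SCF"]] == 1:
        return "G2"
    return "G1"


def g1_length(attractor: Attractor) -> int | None:
    """Number of G1 states in the cycle; ``None`` marks a quiescent (no-S) attractor."""
    if attractor.phase_labels is None or "S" not in attractor.phase_labels:
        return None
    return sum(1 for p in attractor.phase_labels if p == "G1")


def classify_fate(states: Sequence[Sequence[int]], pos: dict[str, int]) -> str:
    """Vulval fate of a cycle from its marker expression."""
    if "LIN-39" not in pos:
        return "other"
    max_lin39 = max(s[pos["LIN-39"]] for s in states)
    if max_lin39 == 2:
        return "primary"
    if any(s[pos["LIN-12i"]] == 1 for s in states):
        return "secondary"
    if max_lin39 == 0:
        return "fusion"
    return "tertiary"


# --------------------------------------------------------------------------
# Attractor enumeration


def _decode_matrix(model, indices: np.ndarray) -> np.ndarray:
    cards = np.asarray(model.cardinalities, dtype=np.int64)
    weights = np.ones(len(cards), dtype=np.int64)
    for i in range(len(cards) - 2, -1, -1):
        weights[i] = weights[i + 1] * cards[i + 1]
    return (indices[:, None] // weights[None, :]) % cards[None, :]


def _decode_one(model, index: int) -> tuple[int, ...]:
    return tuple(int(v) for v in _decode_matrix(model, np.asarray([index]))[0])


def _cycle_states(T: np.ndarray) -> np.ndarray:
    """Boolean mask of states lying on cycles, via vectorized in-degree peeling."""
    n = len(T)
    alive = np.ones(n, dtype=bool)
    indeg = np.bincount(T, minlength=n)
    frontier = np.flatnonzero(indeg == 0)
    while frontier.size:
        alive[frontier] = False
        dec = np.bincount(T[frontier], minlength=n)
        indeg -= dec
        nxt = np.flatnonzero((indeg == 0) & alive)
        frontier = nxt
    return alive


def _annotate(model, cycle_idx: list[int]) -> Attractor:
    pos = _node_pos(model)
    states = tuple(_decode_one(model, i) for i in cycle_idx)
    has_inputs = "LIN-3" in pos and "LS" in pos
    inputs = (
        (states[0][pos["LIN-3"]], states[0][pos["LS"]]) if has_inputs else None
    )
    phases = tuple(label_phase(s, pos) for s in states) if "SCF" in pos else None
    fate = classify_fate(states, pos)
    att = Attractor(
        states=states,
        period=len(states),
        inputs=inputs,
        fate=fate,
        g1_length=None,
        phase_labels=phases,
    )
    return Attractor(
        states=states,
        period=len(states),
        inputs=inputs,
        fate=fate,
        g1_length=g1_length(att),
        phase_labels=phases,
    )


def find_attractors(model, max_states: int = DEFAULT_STATE_BOUND) -> list[Attractor]:
    """All cycles of the synchronous successor map, in canonical rotation.

    Refuses (rather than samples) when the state space exceeds ``max_states``.
    Attractors are sorted by their smallest state index, which for the full
    model orders them by (LIN-3, LS) input slice.
    """
    if model.n_states > max_states:
        raise StateSpaceTooLarge(
            f"state space of {model.n_states} states exceeds bound {max_states}"
        )
    T = model.successor_table()
    on_cycle = _cycle_states(T)
    seen = np.zeros(len(T), dtype=bool)
    attractors: list[list[int]] = []
    for s in np.flatnonzero(on_cycle):
        if seen[s]:
            continue
        cyc = [int(s)]
        seen[s] = True
        x = int(T[s])
        while x != s:
            cyc.append(x)
            seen[x] = True
            x = int(T[x])
        # canonical rotation: start at the smallest state index, which is the
        # lexicographically smallest state under the mixed-radix order
        m = cyc.index(min(cyc))
        attractors.append(cyc[m:] + cyc[:m])
    attractors.sort(key=lambda c: c[0])
    return [_annotate(model, c) for c in attractors]


def _encode_states(model, states: Sequence[Sequence[int]]) -> list[int]:
    cards = model.cardinalities
    weights = [1] * len(cards)
    for i in range(len(cards) - 2, -1, -1):
        weights[i] = weights[i + 1] * cards[i + 1]
    return [sum(int(v) * w for v, w in zip(s, weights)) for s in states]


def basin_summary(model, attractors: list[Attractor]) -> BasinSummary:
    """Assign every state to its attractor and tabulate basin sizes."""
    T = model.successor_table()
    n = len(T)
    assignment = np.full(n, -1, dtype=np.int64)
    for k, att in enumerate(attractors):
        assignment[_encode_states(model, att.states)] = k
    while True:
        unknown = assignment < 0
        if not unknown.any():
            break
        assignment[unknown] = assignment[T[unknown]]
    sizes = tuple(int(c) for c in np.bincount(assignment, minlength=len(attractors)))
    by_inputs: dict[tuple[int, int], list[int]] = {}
    for k, att in enumerate(attractors):
        if att.inputs is not None:
            by_inputs.setdefault(att.inputs, []).append(k)
    return BasinSummary(
        sizes=sizes,
        by_inputs={k: tuple(v) for k, v in sorted(by_inputs.items())},
        assignment=assignment,
    )


def simulate_trajectory(model, initial: Sequence[int], max_steps: int = 10**6) -> Trajectory:
    """Iterate the synchronous update from ``initial`` until a state repeats."""
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    T = model.successor_table()
    start = _encode_states(model, [initial])[0]
    visited: dict[int, int] = {}
    path: list[int] = []
    x = start
    for _ in range(max_steps + 1):
        if x in visited:
            return Trajectory(
                states=tuple(_decode_one(model, i) for i in path),
                entry_index=visited[x],
            )
        visited[x] = len(path)
        path.append(x)
        x = int(T[x])
    raise RuntimeError("no repeat within max_steps (state space larger than bound?)")


def wildtype_attractor_for_inputs(
    attractors: list[Attractor], lin3: int, ls: int
) -> Attractor:
    """The unique attractor of a given (LIN-3, LS) microenvironment slice."""
    matches = [a for a in attractors if a.inputs == (lin3, ls)]
    if len(matches) != 1:
        raise ValueError(
            f"expected exactly one attractor for inputs ({lin3},{ls}), found {len(matches)}"
        )
    return matches[0]


def simulate_fate_transition(
    model, source: Attractor, new_inputs: tuple[int, int]
) -> FateTransition:
    """Move a differentiated cell into a new microenvironment.

    Every state of the source cycle has its input nodes overwritten with
    ``new_inputs`` and is relaxed to its attractor.  In the wild-type model
    the destination is unique regardless of which cycle state the change
    hits; if variants ever diverge, all destinations are reported with
    ``unique=False``.
    """
    pos = _node_pos(model)
    lin3, ls = new_inputs
    destinations: list[Attractor] = []
    seen: set[tuple[tuple[int, ...], ...]] = set()
    for s in source.states:
        shifted = list(s)
        shifted[pos["LIN-3"]] = lin3
        shifted[pos["LS"]] = ls
        traj = simulate_trajectory(model, shifted)
        cycle = traj.states[traj.entry_index :]
        m = cycle.index(min(cycle))
        canon = tuple(cycle[m:] + cycle[:m])
        if canon not in seen:
            seen.add(canon)
            destinations.append(_annotate(model, _encode_states(model, canon)))
    return FateTransition(destinations=tuple(destinations), unique=len(destinations) == 1)
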