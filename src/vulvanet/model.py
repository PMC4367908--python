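"""The 14-node multi-valued logical network of VPC fate determination and the cell cycle.

The network couples the Ras/MAPK and Notch signalling cascades that decide the
fate of a *C. elegans* vulval precursor cell (VPC) with the CDK/cyclin
machinery that drives its cell cycle.  Two nodes are held inputs describing
the extracellular microenvironment: the inductive EGF-like signal LIN-3
(four levels, 0-3) and the Notch-ligand lateral signal LS (Boolean).  MPK-1
and LIN-39 carry three levels each; the remaining ten nodes are Boolean.

States evolve under a deterministic synchronous update: every node reads the
time-*t* configuration and all nodes switch together.  The full state space
has 4 * 3 * 3 * 2**11 = 73,728 configurations.

Model variants cover the in-silico experiments performed on the network:

* ``clamps`` pin a node to a fixed level (loss/gain-of-function mutants),
* ``removed_interactions`` delete a single regulator->target arrow by
  substituting the regulator's inactive level (0) inside that target's rule
  only, and
* ``lin39_basal`` switches the basal LIN-39 level from 1 to 0, emulating the
  loss of Wnt input (the "fusion" background).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NODES",
    "CARDINALITIES",
    "INPUT_NODES",
    "N_STATES",
    "REGULATORS",
    "NodeSpec",
    "Model",
    "InvalidStateError",
    "ConfigurationError",
    "build_wildtype_model",
    "build_cell_cycle_module",
    "apply_variant",
    "update_state",
    "encode_state",
    "decode_state",
    "state_to_text",
    "state_from_text",
]

# Canonical node order; also the serialization and mixed-radix digit order
# (most significant first).
NODES: tuple[str, ...] = (
    "LIN-3",
    "MPK-1",
    "LIN-39",
    "LS",
    "LIN-12m",
    "LIN-12i",
    "CKI-1",
    "EFL-1",
    "LIN-35",
    "SCF",
    "APC",
    "CDK-4/CYD-1",
    "CDK-2/CYE-1",
    "CDK-1/CYB-3",
)
CARDINALITIES: tuple[int, ...] = (4, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2)
INPUT_NODES: tuple[str, ...] = ("LIN-3", "LS")
N_STATES: int = 73728  # product of the cardinalities

_INDEX: dict[str, int] = {name: i for i, name in enumerate(NODES)}

# Regulators actually read by each node's update rule (the rule-level
# dependency structure; includes self-dependencies and the input identities).
REGULATORS: dict[str, tuple[str, ...]] = {
    "LIN-3": ("LIN-3",),
    "MPK-1": ("LIN-3", "MPK-1", "LIN-12i"),
    "LIN-39": ("MPK-1", "LIN-39"),
    "LS": ("LS",),
    "LIN-12m": ("LIN-39", "LIN-12i", "MPK-1", "CDK-4/CYD-1"),
    "LIN-12i": ("LS", "LIN-12m", "LIN-12i", "LIN-3", "CDK-2/CYE-1", "CDK-1/CYB-3"),
    "CKI-1": ("MPK-1", "CDK-4/CYD-1", "APC", "CDK-1/CYB-3"),
    "EFL-1": ("LIN-35",),
    "LIN-35": ("CDK-4/CYD-1", "CDK-2/CYE-1"),
    "SCF": ("LIN-39", "APC", "CDK-2/CYE-1"),
    "APC": ("SCF", "CDK-1/CYB-3"),
    "CDK-4/CYD-1": ("CKI-1", "SCF", "CDK-1/CYB-3"),
    "CDK-2/CYE-1": ("EFL-1", "LIN-35", "CKI-1", "SCF"),
    "CDK-1/CYB-3": ("CKI-1", "APC", "EFL-1", "CDK-4/CYD-1", "CDK-1/CYB-3"),
}

MODEL_VERSION = "vpc-cc-14node-v1"


class InvalidStateError(ValueError):
    """A state vector has the wrong length or an out-of-range level."""


class ConfigurationError(ValueError):
    """A variant refers to an unknown node, level, or interaction."""


@dataclass(frozen=True)
class NodeSpec:
    """One network component: name, level cardinality, and input/internal role."""

    name: str
    levels: int
    role: str  # "input" | "internal"


def _node_specs() -> tuple[NodeSpec, ...]:
    return tuple(
        NodeSpec(n, c, "input" if n in INPUT_NODES else "internal")
        for n, c in zip(NODES, CARDINALITIES)
    )


# --------------------------------------------------------------------------
# Update rules.
#
# Each rule is written against a resolver ``g(regulator)`` so that
# interaction removal can substitute a constant 0 for one regulator inside
# one target's rule without touching any other rule.  All rules are
# vectorized: ``g`` returns integer arrays and the rule returns an array of
# the same shape.

Resolver = Callable[[str], np.ndarray]


def _rule_mpk1(g: Resolver) -> np.ndarray:
    lin3, mpk1, lin12i = g("LIN-3"), g("MPK-1"), g("LIN-12i")
    high = ((lin3 == 3) & (mpk1 > 0)) | ((lin3 == 2) & (lin12i == 0) & (mpk1 > 0))
    off = (mpk1 < 2) & (((lin3 == 1) & (lin12i == 1)) | (lin3 == 0))
    return np.where(high, 2, np.where(off, 0, 1))


def _rule_lin39(g: Resolver, basal: int) -> np.ndarray:
    return np.where((g("MPK-1") == 2) & (g("LIN-39") > 0), 2, basal)


def _rule_lin12m(g: Resolver) -> np.ndarray:
    on = ((g("LIN-39") > 0) | (g("LIN-12i") == 1)) & (
        (g("MPK-1") <= 1) | (g("CDK-4/CYD-1") == 1)
    )
    return on.astype(np.int64)


def _rule_lin12i(g: Resolver) -> np.ndarray:
    lateral = (g("LS") == 1) & (g("LIN-12m") == 1)
    sustained = ((g("LIN-12i") == 1) | (g("LIN-3") == 1)) & (
        (g("CDK-2/CYE-1") == 1) | (g("CDK-1/CYB-3") == 0)
    )
    return (lateral | sustained).astype(np.int64)


# The eight cell-cycle rules, parameterized on the fate-module context
# (MPK-1 and LIN-39 levels) so the isolated module can reuse them.
def _rule_cki1(g: Resolver) -> np.ndarray:
    # CYD=0 AND (APC=1 OR CYB=1): the grouping that matches the continuous
    # counterpart min(1 - CYD, max(APC, CYB)).
    on = (
        (g("MPK-1") == 0)
        & (g("CDK-4/CYD-1") == 0)
        & ((g("APC") == 1) | (g("CDK-1/CYB-3") == 1))
    )
    return on.astype(np.int64)


def _rule_efl1(g: Resolver) -> np.ndarray:
    return (g("LIN-35") == 0).astype(np.int64)


def _rule_lin35(g: Resolver) -> np.ndarray:
    return ((g("CDK-4/CYD-1") == 0) & (g("CDK-2/CYE-1") == 0)).astype(np.int64)


def _rule_scf(g: Resolver) -> np.ndarray:
    on = (g("LIN-39") > 0) & (g("APC") == 0) & (g("CDK-2/CYE-1") == 1)
    return on.astype(np.int64)


def _rule_apc(g: Resolver) -> np.ndarray:
    return ((g("SCF") == 0) & (g("CDK-1/CYB-3") == 1)).astype(np.int64)


def _rule_cyd(g: Resolver) -> np.ndarray:
    on = (g("CKI-1") == 0) & (g("SCF") == 0) & (g("CDK-1/CYB-3") == 0)
    return on.astype(np.int64)


def _rule_cye(g: Resolver) -> np.ndarray:
    on = (
        (g("EFL-1") == 1)
        & (g("LIN-35") == 0)
        & (g("CKI-1") == 0)
        & (g("SCF") == 0)
    )
    return on.astype(np.int64)


def _rule_cyb(g: Resolver) -> np.ndarray:
    on = (
        (g("CKI-1") == 0)
        & (g("APC") == 0)
        & (g("EFL-1") == 1)
        & ((g("CDK-4/CYD-1") == 0) | (g("CDK-1/CYB-3") == 1))
    )
    return on.astype(np.int64)


_CELL_CYCLE_RULES: dict[str, Callable[[Resolver], np.ndarray]] = {
    "CKI-1": _rule_cki1,
    "EFL-1": _rule_efl1,
    "LIN-35": _rule_lin35,
    "SCF": _rule_scf,
    "APC": _rule_apc,
    "CDK-4/CYD-1": _rule_cyd,
    "CDK-2/CYE-1": _rule_cye,
    "CDK-1/CYB-3": _rule_cyb,
}


@dataclass(frozen=True)
class Model:
    """The network plus a variant (clamps, removed interactions, LIN-39 basal level).

    Instances are immutable; derive variants with :func:`apply_variant`.
    """

    nodes: tuple[NodeSpec, ...] = field(default_factory=_node_specs)
    lin39_basal: int = 1
    clamps: frozenset[tuple[str, int]] = frozenset()
    removed_interactions: frozenset[tuple[str, str]] = frozenset()
    version: str = MODEL_VERSION

    # -- engine protocol ---------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(spec.name for spec in self.nodes)

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(spec.levels for spec in self.nodes)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.cardinalities))

    def __post_init__(self) -> None:
        clamp_targets = [n for n, _ in self.clamps]
        if len(clamp_targets) != len(set(clamp_targets)):
            raise ConfigurationError("a node is clamped to two different levels")
        for node, level in self.clamps:
            if node not in _INDEX:
                raise ConfigurationError(f"unknown node in clamp: {node!r}")
            if not 0 <= level < CARDINALITIES[_INDEX[node]]:
                raise ConfigurationError(f"clamp level {level} out of range for {node}")
        for reg, tgt in self.removed_interactions:
            if tgt not in REGULATORS or reg not in REGULATORS[tgt]:
                raise ConfigurationError(
                    f"({reg} -> {tgt}) is not a regulatory interaction of the model"
                )

    def _resolver(self, levels: Mapping[str, np.ndarray], target: str) -> Resolver:
        removed = self.removed_interactions

        def g(regulator: str) -> np.ndarray:
            if (regulator, target) in removed:
                return np.zeros_like(levels[regulator])
            return levels[regulator]

        return g

    def _update_levels(self, levels: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Synchronous image of a (vectorized) configuration, honouring the variant."""
        out: dict[str, np.ndarray] = {}
        out["LIN-3"] = np.asarray(levels["LIN-3"]).copy()
        out["MPK-1"] = _rule_mpk1(self._resolver(levels, "MPK-1"))
        out["LIN-39"] = _rule_lin39(self._resolver(levels, "LIN-39"), self.lin39_basal)
        out["LS"] = np.asarray(levels["LS"]).copy()
        out["LIN-12m"] = _rule_lin12m(self._resolver(levels, "LIN-12m"))
        out["LIN-12i"] = _rule_lin12i(self._resolver(levels, "LIN-12i"))
        for name, rule in _CELL_CYCLE_RULES.items():
            out[name] = rule(self._resolver(levels, name))
        for node, level in self.clamps:
            out[node] = np.full_like(out[node], level)
        return out

    def successor_table(self) -> np.ndarray:
        """Successor index for every state, as an ``int64`` array of length 73,728."""
        return _successor_table_cached(self._key())

    def _key(self) -> tuple:
        return (self.lin39_basal, tuple(sorted(self.clamps)), tuple(sorted(self.removed_interactions)))


_RADIX_WEIGHTS = np.ones(len(NODES), dtype=np.int64)
for _i in range(len(NODES) - 2, -1, -1):
    _RADIX_WEIGHTS[_i] = _RADIX_WEIGHTS[_i + 1] * CARDINALITIES[_i + 1]


def _decoded_level_arrays() -> dict[str, np.ndarray]:
    idx = np.arange(N_STATES, dtype=np.int64)
    return {
        name: (idx // _RADIX_WEIGHTS[i]) % CARDINALITIES[i]
        for i, name in enumerate(NODES)
    }


@lru_cache(maxsize=256)
def _successor_table_cached(key: tuple) -> np.ndarray:
    lin39_basal, clamps, removed = key
    model = Model(
        lin39_basal=lin39_basal,
        clamps=frozenset(clamps),
        removed_interactions=frozenset(removed),
    )
    levels = _decoded_level_arrays()
    out = model._update_levels(levels)
    succ = np.zeros(N_STATES, dtype=np.int64)
    for i, name in enumerate(NODES):
        succ += np.asarray(out[name], dtype=np.int64) * _RADIX_WEIGHTS[i]
    succ.setflags(write=False)
    return succ


# --------------------------------------------------------------------------
# Public constructors and operations


def build_wildtype_model() -> Model:
    """The wild-type network: no clamps, no removals, LIN-39 basal level 1."""
    return Model()


def apply_variant(
    model: Model,
    clamps: Iterable[tuple[str, int]] = (),
    removed_interactions: Iterable[tuple[str, str]] = (),
    lin39_basal: int | None = None,
) -> Model:
    """Derive a variant model: clamped nodes, removed interactions, or a
    changed LIN-39 basal level.  The arguments extend the base model's variant."""
    return replace(
        model,
        clamps=model.clamps | frozenset(clamps),
        removed_interactions=model.removed_interactions | frozenset(removed_interactions),
        lin39_basal=model.lin39_basal if lin39_basal is None else lin39_basal,
    )


def _validate_state(model: Model, state: Sequence[int]) -> None:
    cards = model.cardinalities
    if len(state) != len(cards):
        raise InvalidStateError(f"state has {len(state)} levels, expected {len(cards)}")
    for lvl, card, name in zip(state, cards, model.node_names):
        if not 0 <= int(lvl) < card:
            raise InvalidStateError(f"level {lvl} out of range [0, {card}) for {name}")


def update_state(model: Model, state: Sequence[int]) -> tuple[int, ...]:
    """The unique synchronous successor of ``state`` under ``model``."""
    _validate_state(model, state)
    levels = {n: np.asarray([int(v)]) for n, v in zip(model.node_names, state)}
    out = model._update_levels(levels)
    return tuple(int(out[n][0]) for n in model.node_names)


def encode_state(state: Sequence[int]) -> int:
    """Mixed-radix index of a full 14-node state (canonical order, MSD first)."""
    _validate_state(Model(), state)
    return int(sum(int(v) * w for v, w in zip(state, _RADIX_WEIGHTS)))


def decode_state(index: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_state`."""
    if not 0 <= index < N_STATES:
        raise InvalidStateError(f"state index {index} outside [0, {N_STATES})")
    return tuple(
        int((index // _RADIX_WEIGHTS[i]) % CARDINALITIES[i]) for i in range(len(NODES))
    )


def state_to_text(state: Sequence[int]) -> str:
    return ",".join(str(int(v)) for v in state)


def state_from_text(text: str) -> tuple[int, ...]:
    return tuple(int(tok) for tok in text.strip().split(","))


# --------------------------------------------------------------------------
# The isolated cell-cycle module


@dataclass(frozen=True)
class CellCycleModule:
    """The eight Boolean cell-cycle nodes with the fate module frozen.

    MPK-1 and LIN-39 are held at the tertiary/VPC context (0 and 1 by
    default); the Notch nodes are absent.  Exposes the same engine protocol
    as :class:`Model` so the attractor machinery applies unchanged.
    """

    mpk1: int = 0
    lin39: int = 1

    node_names: tuple[str, ...] = (
        "CKI-1",
        "EFL-1",
        "LIN-35",
        "SCF",
        "APC",
        "CDK-4/CYD-1",
        "CDK-2/CYE-1",
        "CDK-1/CYB-3",
    )

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return (2,) * 8

    @property
    def n_states(self) -> int:
        return 256

    def successor_table(self) -> np.ndarray:
        n = self.n_states
        idx = np.arange(n, dtype=np.int64)
        levels: dict[str, np.ndarray] = {
            name: (idx >> (7 - i)) & 1 for i, name in enumerate(self.node_names)
        }
        levels["MPK-1"] = np.full(n, self.mpk1, dtype=np.int64)
        levels["LIN-39"] = np.full(n, self.lin39, dtype=np.int64)
        g = levels.__getitem__
        succ = np.zeros(n, dtype=np.int64)
        for i, name in enumerate(self.node_names):
            succ += np.asarray(_CELL_CYCLE_RULES[name](g), dtype=np.int64) << (7 - i)
        return succ


def build_cell_cycle_module(mpk1: int = 0, lin39: int = 1) -> CellCycleModule:
    """The 8-node Boolean cell-cycle oscillator on its own state space."""
    return CellCycleModule(mpk1=mpk1, lin39=lin39)


# --------------------------------------------------------------------------
# Serialization (rules are code-defined; only structure + variant travel)


def model_to_dict(model: Model) -> dict:
    return {
        "version": model.version,
        "nodes": [
            {"name": s.name, "levels": s.levels, "role": s.role} for s in model.nodes
        ],
        "variant": {
            "lin39_basal": model.lin39_basal,
            "clamps": sorted([list(c) for c in model.clamps]),
            "removed_interactions": sorted(
                [list(e) for e in model.removed_interactions]
            ),
        },
    }


def model_from_dict(payload: Mapping) -> Model:
    if payload.get("version") != MODEL_VERSION:
        raise ConfigurationError(f"unsupported model version: {payload.get('version')!r}")
    variant = payload.get("variant", {})
    return Model(
        lin39_basal=int(variant.get("lin39_basal", 1)),
        clamps=frozenset((n, int(l)) for n, l in variant.get("clamps", [])),
        removed_interactions=frozenset(
            (r, t) for r, t in variant.get("removed_interactions", [])
        ),
    )
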