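"""Signed interaction graph and feedback-circuit enumeration.

Interaction signs follow the discrete-derivative definition: regulator *i*
activates target *j* if raising *i* (all else fixed) can raise *f_j*, and
inhibits it if raising *i* can lower *f_j*.  An interaction where both occur
is *ambiguous*; in this network exactly one is, LIN-3 -> LIN-12i (moving
LIN-3 from 0 to 1 enables the sustaining clause of the LIN-12i rule, moving
it from 1 to 2 disables it again).

Two graphs coexist:

* the **rule-derived** graph, computed exhaustively from the update rules
  (includes the input identity self-loops and a positive MPK-1
  self-influence that the curated map omits), and
* the **curated** 38-edge graph, the network map used for the interaction-
  removal screen and the feedback-loop census (three genuine self-loops
  included; input identities and the MPK-1 self-influence excluded).

Feedback circuits are simple directed cycles; a circuit is negative iff it
contains an odd number of inhibitions.  A packaged catalogue of the loop
census as originally published for this network is used to cross-validate
cycle memberships; its printed glyphs disagree with the rule-derived sign of
LIN-35 -> CDK-2/CYE-1 in a handful of rows, which
:func:`compare_circuits_to_catalogue` reports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np

from .model import CARDINALITIES, NODES, Model, _decoded_level_arrays

__all__ = [
    "SignedEdge",
    "Circuit",
    "derive_signed_graph",
    "curated_edge_list",
    "enumerate_circuits",
    "circuit_counts",
    "compare_graphs",
    "published_loop_catalogue",
    "compare_circuits_to_catalogue",
    "to_sif",
    "to_graphml",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SignedEdge:
    regulator: str
    target: str
    sign: str  # activation | inhibition | ambiguous
    provenance: str = "curated"  # curated | rule-derived


@dataclass(frozen=True)
class Circuit:
    """A simple directed cycle, canonically rotated to its smallest node."""

    nodes: tuple[str, ...]
    sign: str  # positive | negative

    @property
    def length(self) -> int:
        return len(self.nodes)


def _f_with_override(model: Model, target: str, regulator: str, level: int) -> np.ndarray:
    """Target rule evaluated over the whole state space with one regulator pinned."""
    levels = dict(_decoded_level_arrays())
    levels[regulator] = np.full_like(levels[regulator], level)
    return np.asarray(model._update_levels(levels)[target], dtype=np.int64)


def derive_signed_graph(model: Model | None = None) -> list[SignedEdge]:
    """Classify every rule dependency by exhaustive configuration scanning.

    For each (regulator, target) pair and each level pair a > b of the
    regulator, the target rule is evaluated over all configurations with the
    regulator pinned at a and at b; any positive difference witnesses
    activation, any negative one inhibition.
    """
    model = model or Model()
    edges: list[SignedEdge] = []
    for target in NODES:
        for regulator in NODES:
            card = CARDINALITIES[NODES.index(regulator)]
            values = [_f_with_override(model, target, regulator, a) for a in range(card)]
            acts = inhs = False
            for a in range(card):
                for b in range(a):
                    diff = values[a] - values[b]
                    acts = acts or bool((diff > 0).any())
                    inhs = inhs or bool((diff < 0).any())
            if acts and inhs:
                sign = AMBIGUOUS
            elif acts:
                sign = ACTIVATION
            elif inhs:
                sign = INHIBITION
            else:
                continue
            edges.append(SignedEdge(regulator, target, sign, provenance="rule-derived"))
    return edges


def curated_edge_list() -> list[SignedEdge]:
    """The fixed 38-edge curated interaction map (packaged table)."""
    with resources.files("vulvanet.data").joinpath("curated_interactions.tsv").open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            SignedEdge(row["regulator"], row["target"], row["sign"], provenance="curated")
            for row in reader
        ]


def enumerate_circuits(edges: list[SignedEdge]) -> tuple[list[Circuit], list[tuple[str, ...]]]:
    """All simple directed cycles of the signed graph, signed by inhibition parity.

    Returns ``(signed_circuits, unsigned_cycles)``; a cycle through an
    ambiguous edge cannot be signed and is reported separately.
    """
    graph = nx.DiGraph()
    sign_of: dict[tuple[str, str], str] = {}
    for e in edges:
        graph.add_edge(e.regulator, e.target)
        sign_of[(e.regulator, e.target)] = e.sign
    signed: list[Circuit] = []
    unsigned: list[tuple[str, ...]] = []
    for cyc in nx.simple_cycles(graph):
        m = cyc.index(min(cyc))
        nodes = tuple(cyc[m:] + cyc[:m])
        steps = [sign_of[(nodes[i], nodes[(i + 1) % len(nodes)])] for i in range(len(nodes))]
        if AMBIGUOUS in steps:
            unsigned.append(nodes)
            continue
        parity = sum(1 for s in steps if s == INHIBITION) % 2
        signed.append(Circuit(nodes=nodes, sign="negative" if parity else "positive"))
    signed.sort(key=lambda c: (c.length, c.nodes))
    unsigned.sort()
    return signed, unsigned


def circuit_counts(circuits: list[Circuit]) -> tuple[int, int]:
    """(positive, negative) counts."""
    pos = sum(1 for c in circuits if c.sign == "positive")
    return pos, len(circuits) - pos


@dataclass(frozen=True)
class GraphComparison:
    only_in_first: tuple[tuple[str, str, str], ...]
    only_in_second: tuple[tuple[str, str, str], ...]
    sign_disagreements: tuple[tuple[str, str, str, str], ...]  # reg, tgt, sign1, sign2


def compare_graphs(first: list[SignedEdge], second: list[SignedEdge]) -> GraphComparison:
    """Edges present in only one list, and sign disagreements on shared edges."""
    a = {(e.regulator, e.target): e.sign for e in first}
    b = {(e.regulator, e.target): e.sign for e in second}
    return GraphComparison(
        only_in_first=tuple(sorted((r, t, a[(r, t)]) for r, t in set(a) - set(b))),
        only_in_second=tuple(sorted((r, t, b[(r, t)]) for r, t in set(b) - set(a))),
        sign_disagreements=tuple(
            sorted(
                (r, t, a[(r, t)], b[(r, t)])
                for r, t in set(a) & set(b)
                if a[(r, t)] != b[(r, t)]
            )
        ),
    )


# --------------------------------------------------------------------------
# Published loop catalogue


@dataclass(frozen=True)
class CatalogueEntry:
    catalogue: str  # positive | negative (as published)
    entry: int
    nodes: tuple[str, ...]
    printed_signs: tuple[str, ...]  # per-step glyph signs as published


def published_loop_catalogue() -> list[CatalogueEntry]:
    """The feedback-loop census as originally published for this network."""
    with resources.files("vulvanet.data").joinpath("published_feedback_loops.tsv").open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            CatalogueEntry(
                catalogue=row["catalogue"],
                entry=int(row["entry"]),
                nodes=tuple(row["nodes"].split("|")),
                printed_signs=tuple(row["printed_signs"].split("|")),
            )
            for row in reader
        ]


def _canon(nodes: tuple[str, ...]) -> tuple[str, ...]:
    m = nodes.index(min(nodes))
    return tuple(nodes[m:] + nodes[:m])


@dataclass(frozen=True)
class CatalogueComparison:
    membership_matches: bool
    missing_from_enumeration: tuple[tuple[str, ...], ...]
    missing_from_catalogue: tuple[tuple[str, ...], ...]
    sign_discrepancies: tuple[tuple[str, int, tuple[str, ...], str, str], ...]
    # (catalogue, entry, nodes, published class, parity class from curated signs)


def compare_circuits_to_catalogue(circuits: list[Circuit]) -> CatalogueComparison:
    """Cross-validate enumerated circuits against the published census.

    Memberships are expected to agree exactly.  Sign classes can disagree
    where the published glyphs conflict with the rule-derived edge signs
    (all known cases involve LIN-35 -> CDK-2/CYE-1 printed as activation).
    """
    catalogue = published_loop_catalogue()
    by_nodes = {_canon(c.nodes): c for c in circuits}
    cat_by_nodes = {_canon(e.nodes): e for e in catalogue}
    missing_enum = tuple(sorted(set(cat_by_nodes) - set(by_nodes)))
    missing_cat = tuple(sorted(set(by_nodes) - set(cat_by_nodes)))
    discrepancies = []
    for key in sorted(set(by_nodes) & set(cat_by_nodes)):
        ours = "positive" if by_nodes[key].sign == "positive" else "negative"
        entry = cat_by_nodes[key]
        if ours != entry.catalogue:
            discrepancies.append((entry.catalogue, entry.entry, entry.nodes, entry.catalogue, ours))
    return CatalogueComparison(
        membership_matches=not missing_enum and not missing_cat,
        missing_from_enumeration=missing_enum,
        missing_from_catalogue=missing_cat,
        sign_discrepancies=tuple(discrepancies),
    )


# --------------------------------------------------------------------------
# Export


def to_sif(edges: list[SignedEdge]) -> str:
    """SIF text: ``source<TAB>activates|inhibits|ambiguous<TAB>target``."""
    verb = {ACTIVATION: "activates", INHIBITION: "inhibits", AMBIGUOUS: "ambiguous"}
    lines = [f"{e.regulator}\t{verb[e.sign]}\t{e.target}" for e in edges]
    return "\n".join(lines) + "\n"


def to_graphml(edges: list[SignedEdge]) -> str:
    graph = nx.DiGraph()
    for e in edges:
        graph.add_edge(e.regulator, e.target, sign=e.sign)
    return "\n".join(nx.generate_graphml(graph))
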