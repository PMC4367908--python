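"""In-silico perturbation screens: single mutants and interaction removals.

Two systematic screens probe the network's robustness and its mutant
phenotypes:

* the **mutant screen** clamps one node at one of its levels — all 32
  (node, level) combinations, the sum of the node cardinalities — and
  recomputes the full attractor landscape; and
* the **removal screen** deletes one of the 38 curated regulatory
  interactions by substituting the regulator's inactive level (0) inside the
  target's update rule, again recomputing the landscape.

Each perturbed landscape is summarized by a fate map over the eight
(LIN-3, LS) microenvironments and a cell-cycle behaviour class.  Two
comparisons against wild type are reported: ``attractors_identical``
(state-by-state equality of the canonical attractor sets) and the weaker
``no_effect`` (the attractor *landscape* — per-microenvironment attractor
counts, periods and fates — is unchanged even if single marker states within
a cycle differ).  The landscape reading is the operational meaning of
"no effect on the dynamics" used throughout the screen summaries; twelve of
the 38 removals are neutral under it, ten of them already under strict
state-by-state equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .circuits import curated_edge_list
from .dynamics import Attractor, find_attractors
from .model import CARDINALITIES, INPUT_NODES, NODES, Model, apply_variant

__all__ = [
    "Perturbation",
    "ScreenResult",
    "enumerate_single_mutants",
    "enumerate_interaction_removals",
    "run_mutant_screen",
    "run_removal_screen",
    "classify_cell_cycle_behavior",
    "mutant_name",
]

MICROENVIRONMENTS: tuple[tuple[int, int], ...] = tuple(
    (lin3, ls) for lin3 in range(4) for ls in range(2)
)

CYCLE_BEHAVIORS = ("normal", "quiescent", "endoreplication", "short_cycle", "long_cycle", "other")

# Paper-style mutant notation: gene names lower-case, complex names verbatim.
_GENE_STYLE = {"LIN-3", "MPK-1", "LIN-39", "LIN-12m", "LIN-12i", "CKI-1", "EFL-1", "LIN-35"}


def mutant_name(node: str, level: int) -> str:
    stem = node.lower() if node in _GENE_STYLE else node
    return f"{stem}({level})"


@dataclass(frozen=True)
class Perturbation:
    kind: str  # "clamp" | "removal"
    clamp: tuple[str, int] | None = None
    removal: tuple[str, str] | None = None

    @property
    def name(self) -> str:
        if self.kind == "clamp":
            return mutant_name(*self.clamp)
        reg, tgt = self.removal
        return f"remove({reg}->{tgt})"


@dataclass(frozen=True)
class ScreenResult:
    perturbation: Perturbation
    attractors: tuple[Attractor, ...]
    fate_map: dict[tuple[int, int], tuple[str, ...]]  # microenv -> sorted fates
    periods: dict[tuple[int, int], tuple[int, ...]]  # microenv -> sorted periods
    cycle_behavior: str
    attractors_identical: bool  # exact canonical attractor-set equality with wild type
    no_effect: bool  # attractor landscape (counts, periods, fates) unchanged


def enumerate_single_mutants(model: Model) -> list[Perturbation]:
    """One clamp per (node, level) pair; 32 in total for the full network."""
    perts = []
    for node, card in zip(model.node_names, model.cardinalities):
        for level in range(card):
            perts.append(Perturbation(kind="clamp", clamp=(node, level)))
    return perts


def enumerate_interaction_removals(model: Model) -> list[Perturbation]:
    """One removal per curated interaction; 38 in total."""
    return [
        Perturbation(kind="removal", removal=(e.regulator, e.target))
        for e in curated_edge_list()
    ]


def _landscape(attractors: Iterable[Attractor]):
    """Per-microenvironment multiset of (period, fate): the attractor landscape."""
    table: dict[tuple[int, int] | None, list[tuple[int, str]]] = {}
    for att in attractors:
        table.setdefault(att.inputs, []).append((att.period, att.fate))
    return {k: tuple(sorted(v)) for k, v in table.items()}


def _fate_map(attractors: Iterable[Attractor]) -> dict[tuple[int, int], tuple[str, ...]]:
    fm: dict[tuple[int, int], set[str]] = {}
    for att in attractors:
        if att.inputs is not None:
            fm.setdefault(att.inputs, set()).add(att.fate)
    return {env: tuple(sorted(fm[env])) for env in sorted(fm)}


def _periods(attractors: Iterable[Attractor]) -> dict[tuple[int, int], tuple[int, ...]]:
    pm: dict[tuple[int, int], list[int]] = {}
    for att in attractors:
        if att.inputs is not None:
            pm.setdefault(att.inputs, []).append(att.period)
    return {env: tuple(sorted(pm[env])) for env in sorted(pm)}


def classify_cell_cycle_behavior(
    attractors: list[Attractor], reference: list[Attractor]
) -> str:
    """Cell-cycle behaviour class of a perturbed attractor set.

    quiescent: no oscillation at all, or neither S- nor M-markers ever fire;
    endoreplication: S-marker (CDK-2/CYE-1) oscillates but the M-marker
    (CDK-1/CYB-3) never fires; short/long: every microenvironment still runs
    a complete G1-S-G2-M cycle but faster/slower than wild type; other: any
    remaining alteration (mixed speeds, extra attractors, incomplete phase
    coverage).
    """

    def cyb_on(atts):
        return any(p == "M" for a in atts for p in (a.phase_labels or ()))

    def cye_on(atts):
        return any(p == "S" for a in atts for p in (a.phase_labels or ()))

    if all(a.period == 1 for a in attractors):
        return "quiescent"
    if not cyb_on(attractors) and not cye_on(attractors):
        return "quiescent"
    if not cyb_on(attractors):
        oscillating = [a for a in attractors if a.period > 1]
        if cye_on(oscillating):
            return "endoreplication"
        return "quiescent"

    ours, ref = _landscape(attractors), _landscape(reference)
    # input clamps restrict the attainable microenvironments; compare on the
    # slices the perturbed model can reach
    if all(k in ref and ours[k] == ref[k] for k in ours):
        return "normal"
    complete = all(
        set(a.phase_labels or ()) == {"G1", "S", "G2", "M"} for a in attractors
    )
    if complete and set(ours) <= set(ref) and all(len(v) == 1 for v in ours.values()):
        deltas = [ours[k][0][0] - ref[k][0][0] for k in ours]
        if any(d < 0 for d in deltas) and not any(d > 0 for d in deltas):
            return "short_cycle"
        if any(d > 0 for d in deltas) and not any(d < 0 for d in deltas):
            return "long_cycle"
    return "other"


def _screen(model: Model, perturbations: list[Perturbation]) -> list[ScreenResult]:
    wild = find_attractors(model)
    wild_set = {a.states for a in wild}
    wild_land = _landscape(wild)
    results = []
    for pert in perturbations:
        if pert.kind == "clamp":
            variant = apply_variant(model, clamps=[pert.clamp])
        else:
            variant = apply_variant(model, removed_interactions=[pert.removal])
        atts = find_attractors(variant)
        land = _landscape(atts)
        results.append(
            ScreenResult(
                perturbation=pert,
                attractors=tuple(atts),
                fate_map=_fate_map(atts),
                periods=_periods(atts),
                cycle_behavior=classify_cell_cycle_behavior(atts, wild),
                attractors_identical={a.states for a in atts} == wild_set,
                no_effect=land == wild_land,
            )
        )
    return results


def run_mutant_screen(model: Model) -> list[ScreenResult]:
    """Attractor landscapes of all 32 single gain/loss-of-function clamps."""
    return _screen(model, enumerate_single_mutants(model))


def run_removal_screen(model: Model) -> list[ScreenResult]:
    """Attractor landscapes of all 38 single interaction removals."""
    return _screen(model, enumerate_interaction_removals(model))
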