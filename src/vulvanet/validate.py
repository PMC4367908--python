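"""Recomputation of the model's headline quantities, with expectations.

Shared by ``vulvanet validate`` and the repository's acceptance script: every
quantity is recomputed from scratch by running the library.  The two
published circuit-census counts are knowingly not reproduced — the published
loop catalogue signs LIN-35 -> CDK-2/CYE-1 inconsistently and files one row
against its own glyphs, and the parity counts under the rule-derived
(inhibitory) sign are 59 positive / 52 negative rather than the published
60 / 51; `vulvanet circuits` reports the five affected catalogue rows.
"""

from __future__ import annotations

from .circuits import circuit_counts, curated_edge_list, derive_signed_graph, enumerate_circuits
from .dynamics import basin_summary, find_attractors, wildtype_attractor_for_inputs
from .model import build_cell_cycle_module, build_wildtype_model
from .screens import enumerate_single_mutants, run_removal_screen

__all__ = ["compute_headline_quantities", "run_validation"]


def compute_headline_quantities() -> dict[str, float]:
    """All headline numbers, recomputed by running the model."""
    model = build_wildtype_model()
    atts = find_attractors(model)
    basins = basin_summary(model, atts)

    signed, _ = enumerate_circuits(curated_edge_list())
    pos, neg = circuit_counts(signed)

    module = build_cell_cycle_module()
    module_atts = find_attractors(module)
    module_basins = basin_summary(module, module_atts)

    removals = run_removal_screen(model)

    quantities = {
        "n_attractors": len(atts),
        "basin_size_each": basins.sizes[0] if len(set(basins.sizes)) == 1 else -1,
        "positive_circuits": pos,
        "negative_circuits": neg,
        "period_low_ras": wildtype_attractor_for_inputs(atts, 1, 0).period,
        "period_primary": wildtype_attractor_for_inputs(atts, 3, 0).period,
        "g1_primary": wildtype_attractor_for_inputs(atts, 3, 0).g1_length,
        "g1_tertiary": wildtype_attractor_for_inputs(atts, 0, 0).g1_length,
        "module_period": module_atts[0].period if len(module_atts) == 1 else -1,
        "module_basin": module_basins.sizes[0] if len(module_atts) == 1 else -1,
        "n_single_mutants": len(enumerate_single_mutants(model)),
        "neutral_removals": sum(r.no_effect for r in removals),
        "neutral_removals_strict": sum(r.attractors_identical for r in removals),
        "n_nodes": len(model.nodes),
        "n_ambiguous_rule_interactions": sum(
            e.sign == "ambiguous" for e in derive_signed_graph(model)
        ),
    }
    return quantities


_EXPECTATIONS: tuple[tuple[str, int], ...] = (
    ("n_attractors", 8),
    ("basin_size_each", 9216),
    ("positive_circuits", 60),
    ("negative_circuits", 51),
    ("period_low_ras", 10),
    ("period_primary", 9),
    ("g1_primary", 4),
    ("g1_tertiary", 6),
    ("module_period", 11),
    ("module_basin", 256),
    ("n_single_mutants", 32),
    ("neutral_removals", 12),
    ("n_nodes", 14),
    ("n_ambiguous_rule_interactions", 1),
)


def run_validation() -> list[tuple[str, bool, str]]:
    values = compute_headline_quantities()
    checks = []
    for name, expected in _EXPECTATIONS:
        got = values[name]
        checks.append((name, got == expected, f"computed {got}, expected {expected}"))
    return checks
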