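"""Text/TSV renderings of attractors, screens and circuits.

All emitters iterate in sorted, deterministic order and use fixed float
formats so repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .dynamics import Attractor, BasinSummary
from .screens import ScreenResult

__all__ = [
    "attractor_summary_frame",
    "attractor_states_frame",
    "render_attractor_report",
    "screen_frame",
    "screen_results_json",
    "basin_map_frame",
]

FLOAT_FORMAT = "%.9g"


def attractor_summary_frame(
    attractors: list[Attractor], basins: BasinSummary | None = None
) -> pd.DataFrame:
    rows = []
    for k, att in enumerate(attractors):
        rows.append(
            {
                "attractor": k,
                "lin3": att.inputs[0] if att.inputs else None,
                "ls": att.inputs[1] if att.inputs else None,
                "period": att.period,
                "fate": att.fate,
                "g1_length": att.g1_length,
                "basin_size": basins.sizes[k] if basins else None,
            }
        )
    return pd.DataFrame(rows)


def attractor_states_frame(attractors: list[Attractor], node_names: Iterable[str]) -> pd.DataFrame:
    node_names = list(node_names)
    rows = []
    for k, att in enumerate(attractors):
        for step, state in enumerate(att.states):
            row = {"attractor": k, "step": step}
            row.update({n: v for n, v in zip(node_names, state)})
            row["phase"] = att.phase_labels[step] if att.phase_labels else ""
            rows.append(row)
    return pd.DataFrame(rows)


def render_attractor_report(attractors: list[Attractor], node_names: Iterable[str]) -> str:
    """Per-attractor state-by-step grid with a phase row and fate annotation."""
    node_names = list(node_names)
    if not attractors:
        return "# warning: no attractors to report\n"
    width = max(len(n) for n in node_names)
    blocks = []
    for k, att in enumerate(attractors):
        head = f"attractor {k}: period={att.period} fate={att.fate}"
        if att.inputs is not None:
            head += f" inputs=(LIN-3={att.inputs[0]}, LS={att.inputs[1]})"
        if att.g1_length is not None:
            head += f" g1={att.g1_length}"
        lines = [head]
        for i, name in enumerate(node_names):
            lines.append(
                f"  {name.ljust(width)} " + " ".join(f"{s[i]:>2}" for s in att.states)
            )
        if att.phase_labels:
            lines.append(
                f"  {'phase'.ljust(width)} " + " ".join(f"{p:>2}" for p in att.phase_labels)
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def screen_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Long-form screen table: one row per (perturbation, microenvironment)."""
    rows = []
    for res in results:
        envs = sorted(res.fate_map) or [None]
        for env in envs:
            rows.append(
                {
                    "perturbation": res.perturbation.name,
                    "lin3": env[0] if env else None,
                    "ls": env[1] if env else None,
                    "fates": "+".join(res.fate_map.get(env, ())) if env else "",
                    "periods": ",".join(map(str, res.periods.get(env, ()))) if env else "",
                    "cycle_behavior": res.cycle_behavior,
                    "attractors_identical": res.attractors_identical,
                    "no_effect": res.no_effect,
                }
            )
    return pd.DataFrame(rows)


def screen_results_json(results: list[ScreenResult]) -> str:
    payload = []
    for res in results:
        payload.append(
            {
                "perturbation": res.perturbation.name,
                "kind": res.perturbation.kind,
                "fate_map": {
                    f"{env[0]},{env[1]}": list(f) for env, f in sorted(res.fate_map.items())
                },
                "periods": {
                    f"{env[0]},{env[1]}": list(p) for env, p in sorted(res.periods.items())
                },
                "cycle_behavior": res.cycle_behavior,
                "attractors_identical": res.attractors_identical,
                "no_effect": res.no_effect,
            }
        )
    return json.dumps(payload, indent=2, sort_keys=True)


def basin_map_frame(basins: BasinSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {"state_index": range(len(basins.assignment)), "attractor": basins.assignment}
    )
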