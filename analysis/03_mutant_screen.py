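#!/usr/bin/env python
"""Single-mutant screen: every node clamped at every one of its levels.

The 32 clamps (the sum of the node cardinalities) emulate complete loss- and
gain-of-function alleles.  Each mutant's full attractor landscape is
recomputed and summarized as a per-microenvironment fate map plus a
cell-cycle behaviour class.

Findings include: lin-39(2) drives every microenvironment to the primary
fate (a Muv-like landscape); efl-1(0) arrests the cycle between G1 and S
(fixed points, no S-marker); SCF(0) arrests with the S-marker CDK-2/CYE-1
locked on; lin-12i(0) abolishes the secondary fate while primary and
tertiary remain attainable; a constitutive lateral signal LS(1) removes the
tertiary fate.
"""

from pathlib import Path

from vulvanet.model import build_wildtype_model
from vulvanet.reporting import screen_frame, screen_results_json
from vulvanet.screens import run_mutant_screen

OUT = Path(__file__).resolve().parent.parent / "results" / "mutant_screen"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    results = run_mutant_screen(build_wildtype_model())
    frame = screen_frame(results)
    frame.to_csv(OUT / "mutant_screen.tsv", sep="\t", index=False)
    (OUT / "mutant_screen.json").write_text(screen_results_json(results) + "\n")

    print(f"{len(results)} single mutants screened")
    by_behavior: dict[str, list[str]] = {}
    for res in results:
        by_behavior.setdefault(res.cycle_behavior, []).append(res.perturbation.name)
    for behavior in sorted(by_behavior):
        names = by_behavior[behavior]
        print(f"  {behavior:16s} {len(names):2d}: {', '.join(sorted(names))}")

    def fates(res):
        return sorted({f for fs in res.fate_map.values() for f in fs})

    for res in results:
        if res.perturbation.name in {"lin-39(2)", "efl-1(0)", "SCF(0)", "lin-12i(0)", "LS(1)"}:
            print(
                f"  {res.perturbation.name}: fates={fates(res)} "
                f"cycle={res.cycle_behavior}"
            )


if __name__ == "__main__":
    main()
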