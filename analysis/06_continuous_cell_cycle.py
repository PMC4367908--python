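#!/usr/bin/env python
"""Continuous (sigmoidal ODE) validation of the cell-cycle oscillator.

Integrates the eight SQUAD-style equations of the cell-cycle module from the
quiescent G1 corner state (CKI-1 = LIN-35 = APC = 1, rest 0) for 200 time
units and tests the trajectory for sustained oscillation; the thresholded
limit cycle is read back as discrete phases.

Findings: the module oscillates indefinitely (all eight components keep
peak-to-trough amplitudes above 0.4 in the trailing half of the run; period
about 9.7 time units, against 11 synchronous steps in the discrete module)
and visits the phases in the discrete order G1 -> S -> G2 -> M.  The
oscillation is therefore a property of the regulatory logic, not an
artifact of synchronous updating.  An overdamped control (gamma = 10)
collapses to a fixed point near the origin, as expected.
"""

from pathlib import Path

import pandas as pd

from vulvanet.squad import (
    CELL_CYCLE_NODES,
    ContinuousParams,
    detect_oscillation,
    g1_corner_state,
    integrate,
    phase_sequence,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "continuous"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    traj = integrate(g1_corner_state(), t_end=200.0)
    frame = pd.DataFrame({"t": traj.t})
    for i, name in enumerate(CELL_CYCLE_NODES):
        frame[name] = traj.x[i]
    frame.to_csv(OUT / "trajectory.csv", index=False, float_format="%.9g")

    report = detect_oscillation(traj)
    order = phase_sequence(traj)
    print(f"sustained oscillation: {report.oscillating}")
    print("tail amplitudes:", [round(a, 3) for a in report.amplitudes])
    print(f"period estimate: {report.period_estimate:.2f} time units")
    print("thresholded phase order:", " -> ".join(order))

    damped = integrate(g1_corner_state(), t_end=60.0, params=ContinuousParams(gamma=10.0))
    damped_report = detect_oscillation(damped)
    print(f"overdamped control oscillates: {damped_report.oscillating} "
          f"(final max activity {damped.x[:, -1].max():.3f})")


if __name__ == "__main__":
    main()
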