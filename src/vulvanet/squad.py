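"""Continuous sigmoidal (SQUAD-style) model of the eight-node cell-cycle module.

Each Boolean cell-cycle rule is relaxed to a differential equation

    dX_i/dt = A_h(omega_i(X)) - gamma * X_i,        X_i in [0, 1],

where ``omega_i`` is the fuzzy (min/max) reading of the discrete rule's
logic and ``A_h`` is the normalized sigmoid with gain ``h``:

    A_h(w) = (-e^{h/2} + e^{-h(w - 1/2)}) / ((1 - e^{h/2}) (1 + e^{-h(w - 1/2)})).

``A_h`` satisfies A_h(0) = 0, A_h(1/2) = 1/2 and A_h(1) = 1 exactly, so a
node with fully active input relaxes towards 1/gamma.  Defaults: h = 10,
gamma = 0.95.  An alternative algebraic form with the opposite exponent sign
in the denominator is available behind the ``legacy_denominator`` flag for
comparison; it is not normalized (A(1) != 1) and is not used by default.

The continuous module exists to confirm that the discrete oscillation is a
property of the regulatory logic, not an artifact of synchronous updating:
integrated from the quiescent G1 corner state the module settles into a
sustained limit cycle whose thresholded reading visits G1, S, G2 and M in
the discrete order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CELL_CYCLE_NODES",
    "ContinuousParams",
    "squad_activation",
    "squad_rate",
    "omega_vector",
    "integrate",
    "detect_oscillation",
    "phase_sequence",
    "g1_corner_state",
    "ContinuousTrajectory",
    "OscillationReport",
]

CELL_CYCLE_NODES: tuple[str, ...] = (
    "CKI-1",
    "EFL-1",
    "LIN-35",
    "SCF",
    "APC",
    "CDK-4/CYD-1",
    "CDK-2/CYE-1",
    "CDK-1/CYB-3",
)


@dataclass(frozen=True)
class ContinuousParams:
    h: float = 10.0  # sigmoid gain (dimensionless)
    gamma: float = 0.95  # first-order decay rate per node (1/time)
    legacy_denominator: bool = False  # printed-form sigmoid variant, for comparison

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("sigmoid gain h must be positive")
        if not 0 < self.gamma:
            raise ValueError("decay rate gamma must be positive")


def squad_activation(omega, params: ContinuousParams = ContinuousParams()):
    """Normalized sigmoid A_h(omega) on [0, 1]."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < -1e-12) or np.any(omega > 1 + 1e-12):
        raise ValueError("omega outside [0, 1]")
    h = params.h
    e_half = np.exp(0.5 * h)
    if params.legacy_denominator:
        return (-e_half + np.exp(-h * (omega - 0.5))) / (
            (1 - e_half) * (1 + np.exp(h * (omega - 0.5)))
        )
    expo = np.exp(-h * (omega - 0.5))
    return (-e_half + expo) / ((1 - e_half) * (1 + expo))


def squad_rate(x, omega, params: ContinuousParams = ContinuousParams()):
    """dX/dt for one node: sigmoid drive minus linear decay."""
    return squad_activation(omega, params) - params.gamma * np.asarray(x, dtype=float)


def omega_vector(state: np.ndarray) -> np.ndarray:
    """Fuzzy-logic input omega_i for the eight nodes, in CELL_CYCLE_NODES order."""
    cki, efl, l35, scf, apc, cyd, cye, cyb = state
    return np.array(
        [
            min(1 - cyd, max(apc, cyb)),  # CKI-1
            1 - l35,  # EFL-1
            min(1 - cyd, 1 - cye),  # LIN-35
            min(1 - apc, cye),  # SCF
            min(1 - scf, cyb),  # APC
            min(1 - cki, 1 - scf, 1 - cyb),  # CDK-4/CYD-1
            min(efl, 1 - l35, 1 - cki, 1 - scf),  # CDK-2/CYE-1
            min(1 - cki, 1 - apc, efl, max(1 - cyd, cyb)),  # CDK-1/CYB-3
        ]
    )


@dataclass(frozen=True)
class ContinuousTrajectory:
    t: np.ndarray  # sample times
    x: np.ndarray  # shape (8, len(t)), CELL_CYCLE_NODES order
    params: ContinuousParams


def g1_corner_state() -> np.ndarray:
    """The quiescent G1 corner: CKI-1, LIN-35 and APC fully on, all else off."""
    x = np.zeros(8)
    x[[0, 2, 4]] = 1.0
    return x


def integrate(
    initial: np.ndarray,
    t_end: float = 200.0,
    params: ContinuousParams = ContinuousParams(),
    n_samples: int = 4001,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ContinuousTrajectory:
    """Adaptive Runge-Kutta solution of the eight coupled SQUAD equations."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (8,):
        raise ValueError("initial state must have 8 components")

    def rhs(_t, x):
        # fuzzy min/max need arguments inside [0,1]; tiny solver overshoots
        # are clipped before evaluating the logic
        return squad_rate(x, omega_vector(np.clip(x, 0.0, 1.0)), params)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        initial,
        rtol=rtol,
        atol=atol,
        dense_output=True,
        max_step=1.0,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    t = np.linspace(0.0, t_end, n_samples)
    return ContinuousTrajectory(t=t, x=sol.sol(t), params=params)


@dataclass(frozen=True)
class OscillationReport:
    oscillating: bool
    period_estimate: float | None
    amplitudes: tuple[float, ...]
    inconclusive: bool = False


def detect_oscillation(
    trajectory: ContinuousTrajectory,
    tail_fraction: float = 0.5,
    amplitude_min: float = 0.2,
) -> OscillationReport:
    """Sustained-oscillation test on the trailing part of a trajectory.

    Oscillating iff at least two components keep a peak-to-trough amplitude
    of ``amplitude_min`` within the trailing ``tail_fraction`` of the run.
    The period is estimated from successive maxima of CDK-1/CYB-3.
    """
    n = trajectory.t.size
    if n < 10:
        return OscillationReport(False, None, (), inconclusive=True)
    start = int(n * (1 - tail_fraction))
    tail = trajectory.x[:, start:]
    t_tail = trajectory.t[start:]
    amplitudes = tuple(float(a) for a in tail.max(axis=1) - tail.min(axis=1))
    oscillating = sum(a >= amplitude_min for a in amplitudes) >= 2
    period = None
    if oscillating:
        cyb = tail[CELL_CYCLE_NODES.index("CDK-1/CYB-3")]
        peaks = [
            t_tail[i]
            for i in range(1, len(cyb) - 1)
            if cyb[i] > cyb[i - 1] and cyb[i] >= cyb[i + 1] and cyb[i] > 0.5
        ]
        if len(peaks) >= 2:
            period = float(np.mean(np.diff(peaks)))
    return OscillationReport(oscillating, period, amplitudes)


def phase_sequence(
    trajectory: ContinuousTrajectory,
    threshold: float = 0.5,
    tail_fraction: float = 0.5,
) -> tuple[str, ...]:
    """Order of first phase visits within one period of the thresholded limit cycle.

    The tail of the trajectory is thresholded to Boolean patterns and read
    with the discrete markers (M: CDK-1/CYB-3, S: CDK-2/CYE-1, G2: SCF, else
    G1).  Successive M episodes delimit periods; within a period, phases are
    recorded in order of first appearance.  The continuous cycle shows a
    brief sub-threshold dip between its two S/G2 excursions, so first-visit
    order (rather than the raw episode string) is the faithful reading of
    the discrete phase progression.
    """
    n = trajectory.t.size
    start = int(n * (1 - tail_fraction))
    boolean = trajectory.x[:, start:] > threshold
    idx = {name: i for i, name in enumerate(CELL_CYCLE_NODES)}

    def phase(col) -> str:
        if col[idx["CDK-1/CYB-3"]]:
            return "M"
        if col[idx["CDK-2/CYE-1"]]:
            return "S"
        if col[idx["SCF"]]:
            return "G2"
        return "G1"

    labels = [phase(boolean[:, i]) for i in range(boolean.shape[1])]
    # delimit one full period between the end of an M episode and the end of
    # the following one
    m_ends = [
        i for i in range(1, len(labels)) if labels[i - 1] == "M" and labels[i] != "M"
    ]
    if len(m_ends) < 2:
        return ()
    window = labels[m_ends[0] : m_ends[1]]
    order: list[str] = []
    for lab in window:
        if lab not in order:
            order.append(lab)
    return tuple(order)
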