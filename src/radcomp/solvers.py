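"""Steady-state solution and transient integration of the tracer system.

Kinetic adsorption rates exceed the biological turnover rates by orders
of magnitude, making the system stiff, so transient runs use an implicit
multistep method (BDF) with the exact (constant) Jacobian and adaptive
steps.  The steady state is obtained directly from the linear system
M A* = -s; quasi-stationarity of a trajectory is measured against that
direct solution rather than by successive-difference heuristics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .tracer import TracerState, TracerSystem, trapped_compartments


class SingularSystemError(ValueError):
    """The steady-state problem is singular: some compartments trap tracer."""


class SolverError(RuntimeError):
    """Transient integration failed or violated the balance invariant."""


@dataclass
class Trajectory:
    """Dense output of a transient run: one state per output time."""

    times: np.ndarray
    values: np.ndarray  # (n_times, n_live + n_sinks)
    compartments: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def state_at(self, i: int) -> TracerState:
        return TracerState(self.values[i].copy(), self.compartments)

    @property
    def final(self) -> TracerState:
        return self.state_at(len(self.times) - 1)

    def series(self, compartment: str) -> np.ndarray:
        return self.values[:, self.compartments.index(compartment)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time, compartment, activity_Bq)."""
        frames = []
        for j, c in enumerate(self.compartments):
            frames.append(
                pd.DataFrame(
                    {
                        "time_years": self.times,
                        "compartment": c,
                        "activity_Bq": self.values[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def solve_steady(system: TracerSystem) -> TracerState:
    """Direct steady state A* of M A + s = 0 over the live compartments.

    Sink rows are returned as 0 (they grow without bound under constant
    forcing and have no steady value).  Raises
    :class:`SingularSystemError` naming the trapped compartments when some
    part of the system has no pathway to export, burial or decay.
    """
    trapped = trapped_compartments(system)
    if trapped:
        raise SingularSystemError(
            "no loss pathway from compartments: " + ", ".join(trapped)
        )
    try:
        a_star = np.linalg.solve(system.matrix, -system.source)
        # one step of iterative refinement sharpens the residual
        r = system.matrix @ a_star + system.source
        a_star -= np.linalg.solve(system.matrix, r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught above
        raise SingularSystemError(str(exc)) from exc
    s_norm = np.linalg.norm(system.source)
    residual = np.linalg.norm(system.matrix @ a_star + system.source)
    # the evaluation floor of M@A itself bounds the attainable residual
    attainable = max(
        s_norm, float(np.linalg.norm(np.abs(system.matrix) @ np.abs(a_star)))
    )
    if s_norm > 0 and residual > 1e-12 * attainable:
        raise SingularSystemError(
            f"steady-state residual {residual:.3e} too large (ill-conditioned)"
        )
    values = np.concatenate([a_star, np.zeros(len(system.sinks))])
    return TracerState(values, system.all_compartments)


def integrate(
    system: TracerSystem,
    initial: TracerState | None = None,
    duration: float = 100.0,
    output_step: float = 1.0,
    rtol: float = 1e-8,
    check_balance: bool = True,
) -> Trajectory:
    """Integrate dA/dt = M A + s from ``initial`` (default: all zero).

    The cumulative sinks are carried alongside the live compartments, so
    for a conservative system (decay off) the total of all rows equals the
    cumulative source input; this balance is verified at every output time
    to 1e-6 relative and a :class:`SolverError` reports the worst time if
    it fails.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if initial is None:
        initial = system.zero_state()
    y0 = np.asarray(initial.values, dtype=float)
    n_ext = system.n + len(system.sinks)
    if y0.shape != (n_ext,):
        raise ValueError("initial state dimension mismatch")

    m_ext = system.extended_matrix
    s_ext = system.extended_source
    t_eval = np.arange(0.0, duration + 0.5 * output_step, output_step)
    t_eval = t_eval[t_eval <= duration]
    if t_eval[-1] < duration:
        t_eval = np.append(t_eval, duration)

    scale = max(
        float(np.abs(s_ext).sum()) * max(duration, 1.0), float(np.abs(y0).max()), 1e-30
    )
    sol = solve_ivp(
        lambda t, y: m_ext @ y + s_ext,
        (0.0, duration),
        y0,
        method="BDF",
        t_eval=t_eval,
        jac=lambda t, y: m_ext,
        rtol=rtol,
        atol=1e-12 * scale,
    )
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}")

    traj = Trajectory(
        times=sol.t,
        values=sol.y.T,
        compartments=system.all_compartments,
        metadata={"rtol": rtol, "n_steps": int(sol.t.size), "nfev": int(sol.nfev)},
    )

    if check_balance and system.conservative:
        total0 = float(y0.sum())
        expected = total0 + system.total_source_rate() * sol.t
        got = traj.values.sum(axis=1)
        denom = np.maximum(np.abs(expected), scale * 1e-12)
        rel = np.abs(got - expected) / denom
        worst = int(np.argmax(rel))
        if rel[worst] > 1e-6:
            raise SolverError(
                f"balance violated at t={sol.t[worst]:g} y: "
                f"relative error {rel[worst]:.3e}"
            )
        traj.metadata["max_balance_error"] = float(rel.max())
    return traj


def time_to_quasi_stationary(
    trajectory: Trajectory,
    system: TracerSystem,
    threshold: float = 0.01,
) -> float:
    """First time every live compartment is within ``threshold`` (relative)
    of the direct steady state.

    The crossing is located by linear interpolation between the bracketing
    output samples; compartments whose steady value is negligible
    (< 1e-12 of the largest) are compared absolutely against that floor.
    Returns ``math.inf`` with a warning when the trajectory never settles.
    """
    steady = solve_steady(system)
    a_star = steady.values[: system.n]
    floor = 1e-12 * max(float(np.abs(a_star).max()), 1e-300)
    denom = np.maximum(np.abs(a_star), floor)

    live = trajectory.values[:, : system.n]
    dev = np.max(np.abs(live - a_star[None, :]) / denom[None, :], axis=1)
    ok = dev <= threshold
    if not ok.any():
        warnings.warn(
            "quasi-stationarity not reached within the trajectory "
            f"(final deviation {dev[-1]:.3g} > threshold {threshold:g})",
            stacklevel=2,
        )
        return math.inf
    k = int(np.argmax(ok))
    if k == 0:
        return float(trajectory.times[0])
    # linear interpolation of the max-deviation curve across the crossing
    t0, t1 = trajectory.times[k - 1], trajectory.times[k]
    d0, d1 = dev[k - 1], dev[k]
    if d0 == d1:
        return float(t1)
    frac = (d0 - threshold) / (d0 - d1)
    return float(t0 + frac * (t1 - t0))
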