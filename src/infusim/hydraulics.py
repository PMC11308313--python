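"""Transient pressure/flow solver for the N-branch infusion network.

Each pump branch is lumped into an ideal flow source (the pump drive)
feeding a single compliance C (syringe plunger and other compressible
elements) behind the branch-line resistance R.  All branches meet at a
zero-volume junction node that drains through the catheter resistance
into a constant venous back-pressure:

    C_i dP_i/dt = Q_set,i(t) - (P_i - P_j)/R_i
    sum_i (P_i - P_j)/R_i = (P_j - P_ven)/R_cath     (junction balance)

The junction pressure P_j is algebraic (no storage at the node), so
branch inflows sum to the catheter outflow at every instant.  Branches
with C = 0 are rigid and deliver their set flow exactly; they enter the
junction balance as fixed sources.

The linear ODE is integrated with backward Euler, which is
unconditionally stable.  That matters because a thin high-resistance
catheter combined with a small plunger compliance produces a stiff
system (time constants of seconds against simulated spans of hours).
Negative branch flows are physical: a pressure surge from one pump can
transiently push mixed fluid back up another pump's line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .components import (
    CatheterSpec,
    InvalidParameterError,
    MixingPointSpec,
    SyringeSpec,
    TubeGeometry,
    poiseuille_resistance,
    tube_volume,
)
from .grid import SimulationGrid

__all__ = [
    "FlowSchedule",
    "PumpBranch",
    "InfusionNetwork",
    "PressureState",
    "BranchFlows",
    "junction_pressure",
    "step_pressures",
    "steady_state",
    "solve_flows",
]

#: resistance floor, mbar*h/mL, to avoid degenerate zero-resistance branches
RESISTANCE_FLOOR = 1e-9


class SingularNetworkError(ValueError):
    """The junction balance has no finite solution."""


class IntegrationError(RuntimeError):
    """The pressure integration produced non-finite values."""


@dataclass(frozen=True)
class FlowSchedule:
    """Piecewise-constant pump set-flow schedule.

    ``events`` is an ordered list of ``(time_h, set_flow_ml_h)``; the
    first event must be at t = 0 and times must strictly increase.
    Set flows are non-negative: pumps infuse, they do not aspirate.
    """

    events: tuple[tuple[float, float], ...]
    duration_h: float | None = None

    def __post_init__(self) -> None:
        events = tuple((float(t), float(q)) for t, q in self.events)
        object.__setattr__(self, "events", events)
        if not events:
            raise InvalidParameterError("schedule needs at least one event")
        if events[0][0] != 0.0:
            raise InvalidParameterError("first schedule event must be at t=0")
        times = [t for t, _ in events]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise InvalidParameterError("event times must strictly increase")
        if any(q < 0 for _, q in events):
            raise InvalidParameterError("set flows must be >= 0")

    def flow_at(self, t_h: float) -> float:
        """Set flow in effect at time ``t_h`` (left-continuous steps)."""
        flow = self.events[0][1]
        for t_ev, q in self.events:
            if t_ev <= t_h:
                flow = q
            else:
                break
        return flow

    @staticmethod
    def constant(flow_ml_h: float) -> "FlowSchedule":
        return FlowSchedule(events=((0.0, flow_ml_h),))

    @staticmethod
    def step(flow_before: float, flow_after: float, at_h: float) -> "FlowSchedule":
        return FlowSchedule(events=((0.0, flow_before), (at_h, flow_after)))


@dataclass(frozen=True)
class PumpBranch:
    """One syringe pump with its line up to the mixing point."""

    syringe: SyringeSpec
    line: TubeGeometry
    drug: str
    schedule: FlowSchedule
    viscosity_mpas: float = 1.0
    line_resistance_mbar_h_per_ml: float | None = None  # None: from geometry

    @property
    def resistance(self) -> float:
        if self.line_resistance_mbar_h_per_ml is not None:
            r = self.line_resistance_mbar_h_per_ml
        else:
            r = poiseuille_resistance(self.line, self.viscosity_mpas)
        return max(r, RESISTANCE_FLOOR)

    @property
    def compliance(self) -> float:
        return self.syringe.compliance_ml_per_mbar

    @property
    def line_volume_ml(self) -> float:
        return tube_volume(self.line)


@dataclass(frozen=True)
class InfusionNetwork:
    """Branches + mixing point + catheter + venous back-pressure."""

    branches: tuple[PumpBranch, ...]
    mixing_point: MixingPointSpec
    catheter: CatheterSpec
    venous_pressure_mbar: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))
        if len(self.branches) < 1:
            raise InvalidParameterError("network needs at least one branch")

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def drugs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.branches:
            if b.drug not in seen:
                seen.append(b.drug)
        return tuple(seen)

    @property
    def shared_volume_ml(self) -> float:
        """Dead volume plus catheter internal volume (the mixed segment)."""
        return self.mixing_point.dead_volume_ml + self.catheter.volume_ml

    @property
    def catheter_resistance(self) -> float:
        return max(self.catheter.resistance_mbar_h_per_ml, RESISTANCE_FLOOR)

    def with_compliance_scale(self, scale: float) -> "InfusionNetwork":
        """Copy of the network with every syringe compliance multiplied
        by ``scale`` (0 gives the rigid ablation)."""
        branches = tuple(
            replace(
                b,
                syringe=replace(
                    b.syringe,
                    compliance_ml_per_mbar=b.syringe.compliance_ml_per_mbar * scale,
                ),
            )
            for b in self.branches
        )
        return replace(self, branches=branches)


@dataclass
class PressureState:
    """Per-branch syringe-side pressures (mbar) at a given time."""

    branch_pressures: np.ndarray
    time_h: float

    def __post_init__(self) -> None:
        self.branch_pressures = np.asarray(self.branch_pressures, dtype=float)
        if not np.all(np.isfinite(self.branch_pressures)):
            raise InvalidParameterError("pressures must be finite")


@dataclass
class BranchFlows:
    """Flow solution on a time grid.

    ``branch_flows[i, k]`` is branch i's flow into the junction at time
    ``times[k]`` (mL/h, negative = backflow up the branch line);
    ``outflow`` is the catheter flow toward the patient.
    """

    times: np.ndarray
    branch_flows: np.ndarray
    outflow: np.ndarray
    set_flows: np.ndarray
    junction_pressure: np.ndarray
    branch_pressures: np.ndarray
    drugs: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self):
        """Tidy long-format table (time_h, branch, set/actual flow)."""
        import pandas as pd

        n_b, n_t = self.branch_flows.shape
        records = []
        for i in range(n_b):
            records.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "branch": i,
                        "drug": self.drugs[i] if self.drugs else str(i),
                        "set_flow_ml_h": self.set_flows[i],
                        "actual_flow_ml_h": self.branch_flows[i],
                    }
                )
            )
        return pd.concat(records, ignore_index=True)


def _set_flow_vector(network: InfusionNetwork, t_h: float) -> np.ndarray:
    return np.array([b.schedule.flow_at(t_h) for b in network.branches])


def junction_pressure(
    state: PressureState, network: InfusionNetwork, t_h: float | None = None
) -> float:
    """Pressure at the mixing point solving the junction flow balance.

    Compliant branches contribute through their line resistances; rigid
    (C = 0) branches contribute their set flow directly.
    """
    t = state.time_h if t_h is None else t_h
    q_set = _set_flow_vector(network, t)
    compliant = np.array([b.compliance > 0 for b in network.branches])
    r = np.array([b.resistance for b in network.branches])
    a = np.where(compliant, 1.0 / r, 0.0)
    a_cath = 1.0 / network.catheter_resistance
    g = a.sum() + a_cath
    if not np.isfinite(g) or g <= 0:
        raise SingularNetworkError("all paths have infinite resistance")
    b_src = q_set[~compliant].sum() + a_cath * network.venous_pressure_mbar
    return float((a @ state.branch_pressures + b_src) / g)


def steady_state(network: InfusionNetwork, t_h: float = 0.0) -> PressureState:
    """Pressures for which every branch delivers its set flow at ``t_h``."""
    q_set = _set_flow_vector(network, t_h)
    p_j = network.venous_pressure_mbar + network.catheter_resistance * q_set.sum()
    r = np.array([b.resistance for b in network.branches])
    return PressureState(branch_pressures=p_j + r * q_set, time_h=t_h)


def _step(
    state: PressureState, network: InfusionNetwork, dt: float
) -> tuple[PressureState, np.ndarray, float, float]:
    """One backward-Euler step.

    Returns (new state, branch flows, junction pressure, outflow), all
    evaluated at the end of the step.  Set flows are sampled at the end
    of the step so an event at t* first acts on the step landing at t*.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    t_new = state.time_h + dt
    q_set = _set_flow_vector(network, t_new)
    c = np.array([b.compliance for b in network.branches])
    r = np.array([b.resistance for b in network.branches])
    compliant = c > 0
    a = np.where(compliant, 1.0 / r, 0.0)
    a_cath = 1.0 / network.catheter_resistance
    g = a.sum() + a_cath
    if not np.isfinite(g) or g <= 0:
        raise SingularNetworkError("all paths have infinite resistance")
    b_src = q_set[~compliant].sum() + a_cath * network.venous_pressure_mbar

    p = state.branch_pressures.copy()
    if compliant.any():
        idx = np.flatnonzero(compliant)
        a_s = a[idx]
        c_s = c[idx]
        m = np.diag(c_s / dt + a_s) - np.outer(a_s, a_s) / g
        rhs = c_s / dt * p[idx] + q_set[idx] + a_s * b_src / g
        p_new_s = np.linalg.solve(m, rhs)
        p[idx] = p_new_s
    p_j = float((a @ p + b_src) / g)
    # rigid branches sit at the pressure implied by their set flow
    rigid = ~compliant
    p[rigid] = p_j + r[rigid] * q_set[rigid]

    if not np.all(np.isfinite(p)):
        raise IntegrationError(
            f"pressure integration diverged at t={t_new:.6g} h; "
            f"reduce dt below {dt:.3g} h"
        )

    q = np.where(compliant, a * (p - p_j), q_set)
    q_out = a_cath * (p_j - network.venous_pressure_mbar)
    return PressureState(branch_pressures=p, time_h=t_new), q, p_j, float(q_out)


def step_pressures(
    state: PressureState, network: InfusionNetwork, dt: float
) -> PressureState:
    """Advance the compliance ODE by one backward-Euler step of ``dt``."""
    new_state, _, _, _ = _step(state, network, dt)
    return new_state


def solve_flows(
    network: InfusionNetwork,
    grid: SimulationGrid,
    initial_state: PressureState | None = None,
) -> BranchFlows:
    """Integrate the network over the grid and return all flow series.

    The network is initialized at the steady state of the t = 0 set
    flows unless ``initial_state`` is given (e.g. a cold start at venous
    pressure).  At every step the branch inflows sum to the catheter
    outflow exactly: the junction node stores no volume.
    """
    n_steps = grid.n_steps
    n_b = network.n_branches
    state = initial_state or steady_state(network, 0.0)

    times = np.empty(n_steps + 1)
    q = np.empty((n_b, n_steps + 1))
    q_set = np.empty((n_b, n_steps + 1))
    q_out = np.empty(n_steps + 1)
    p_all = np.empty((n_b, n_steps + 1))
    p_j_all = np.empty(n_steps + 1)

    # step 0: algebraic evaluation of the initial state
    times[0] = state.time_h
    q_set[:, 0] = _set_flow_vector(network, state.time_h)
    p_j0 = junction_pressure(state, network)
    compliant = np.array([b.compliance > 0 for b in network.branches])
    r = np.array([b.resistance for b in network.branches])
    q[:, 0] = np.where(
        compliant, (state.branch_pressures - p_j0) / r, q_set[:, 0]
    )
    q_out[0] = (p_j0 - network.venous_pressure_mbar) / network.catheter_resistance
    p_all[:, 0] = state.branch_pressures
    p_j_all[0] = p_j0

    for k in range(1, n_steps + 1):
        state, q_k, p_j, q_out_k = _step(state, network, grid.dt_h)
        times[k] = state.time_h
        q[:, k] = q_k
        q_set[:, k] = _set_flow_vector(network, state.time_h)
        q_out[k] = q_out_k
        p_all[:, k] = state.branch_pressures
        p_j_all[k] = p_j

    return BranchFlows(
        times=times,
        branch_flows=q,
        outflow=q_out,
        set_flows=q_set,
        junction_pressure=p_j_all,
        branch_pressures=p_all,
        drugs=tuple(b.drug for b in network.branches),
    )
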