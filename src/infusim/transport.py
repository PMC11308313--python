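"""Drug transport through the shared dead volume and catheter.

The mixed segment (mixing-point dead volume + catheter lumen) is
modelled as a shift register of volume slices, each carrying per-drug
volume fractions.  Every time step the junction mixture is pushed onto
the proximal end and an equal volume is emitted from the distal end, so
plug-flow advection of composition fronts is exact up to the averaging
over one step's throughput.  This time-stepped slice chain is the
discrete-time realization of a Z-transform description of the catheter
contents: each slice is one delay element and advection is the shift.

On top of plug transport two physical refinements are applied:

* **Backflow buffering** — when a pressure surge drives a branch flow
  negative, the junction mixture entering that branch line is stored in
  a last-in-first-out buffer (laminar flow at these Reynolds numbers is
  reversible, so plug reversal is the right model) and re-emerges ahead
  of fresh stock solution when the branch recovers.

* **Poiseuille washout kernel** — laminar flow in a cylindrical tube
  has a parabolic velocity profile with centerline velocity twice the
  cross-sectional average and no radial mixing, so a composition front
  is smeared: the first new fluid arrives after half the mean transit
  time and the washout tail decays as (V/2v)^2 in emitted volume v.
  The kernel is applied to the plug effluent in cumulative-volume
  coordinates, which generalizes the classical constant-flow washout
  curve to time-varying flow.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .components import InvalidParameterError
from .grid import SimulationGrid
from .hydraulics import BranchFlows, InfusionNetwork, PressureState, solve_flows

__all__ = [
    "SliceChain",
    "LineBuffer",
    "DoseTimeSeries",
    "advect",
    "handle_backflow",
    "poiseuille_breakthrough",
    "breakthrough_volume_fraction",
    "first_arrival_time",
    "apply_poiseuille_kernel",
    "simulate_doses",
]

logger = logging.getLogger(__name__)

_FRACTION_TOL = 1e-9


class UnsupportedRegimeError(RuntimeError):
    """Net aspiration from the patient (negative catheter outflow)."""


class SliceChain:
    """Ordered volume slices with per-drug volume fractions.

    Index 0 is the proximal (junction) end; the last slice is at the
    distal (patient) end.  Total volume is invariant under advection.
    """

    def __init__(self, volume_ml: float, fractions: np.ndarray):
        fractions = np.asarray(fractions, dtype=float)
        if volume_ml <= 0:
            raise InvalidParameterError("chain volume must be > 0")
        if abs(fractions.sum() - 1.0) > _FRACTION_TOL or np.any(fractions < 0):
            raise InvalidParameterError("fractions must be >= 0 and sum to 1")
        self._slices: deque[list] = deque([[float(volume_ml), fractions.copy()]])
        self.n_drugs = fractions.size

    @property
    def total_volume(self) -> float:
        return sum(v for v, _ in self._slices)

    @property
    def n_slices(self) -> int:
        return len(self._slices)

    def distal_fractions(self) -> np.ndarray:
        return self._slices[-1][1].copy()

    def push(self, volume_ml: float, fractions: np.ndarray) -> None:
        """Add a slice of junction mixture at the proximal end."""
        if volume_ml <= 0:
            return
        fractions = np.asarray(fractions, dtype=float)
        head = self._slices[0] if self._slices else None
        if head is not None and np.array_equal(head[1], fractions):
            head[0] += volume_ml  # coalesce: keeps steady phases O(1) slices
        else:
            self._slices.appendleft([float(volume_ml), fractions.copy()])

    def emit(self, volume_ml: float) -> np.ndarray:
        """Remove ``volume_ml`` from the distal end.

        Returns the volume-weighted mean composition of the removed
        fluid.  Volume is conserved exactly: the chain shrinks by
        precisely the emitted volume.
        """
        if volume_ml <= 0:
            return self.distal_fractions()
        if volume_ml > self.total_volume + 1e-12:
            raise InvalidParameterError(
                "cannot emit more than the chain holds in one call"
            )
        removed = np.zeros(self.n_drugs)
        remaining = volume_ml
        while remaining > 0 and self._slices:
            vol, frac = self._slices[-1]
            if vol <= remaining + 1e-18:
                removed += vol * frac
                remaining -= vol
                self._slices.pop()
                if not self._slices and remaining > 1e-15:
                    raise InvalidParameterError("chain exhausted during emit")
                if not self._slices:
                    break
            else:
                removed += remaining * frac
                self._slices[-1][0] = vol - remaining
                remaining = 0.0
        return removed / volume_ml

    def composition_profile(self) -> list[tuple[float, np.ndarray]]:
        """Proximal-to-distal list of (volume, fractions) slices."""
        return [(v, f.copy()) for v, f in self._slices]

    def validate(self) -> None:
        for v, f in self._slices:
            assert v > 0
            assert abs(f.sum() - 1.0) < 1e-9, "slice fractions must sum to 1"


def advect(
    chain: SliceChain,
    mixture_fractions: np.ndarray,
    outflow_volume_ml: float,
    slice_volume_ml: float | None = None,
) -> np.ndarray:
    """Advance the chain by one throughput of junction mixture.

    Pushes ``outflow_volume_ml`` of fluid with composition
    ``mixture_fractions`` onto the proximal end and emits the same
    volume from the distal end, returning the emitted composition.
    Plug-flow advection is exact for any step volume; the emitted
    composition is the average over the step's throughput, so the
    caller keeps the step volume at or below the slice volume to
    resolve fronts (``slice_volume_ml`` only triggers a log message
    when exceeded — accuracy, not stability, is at stake).
    """
    if outflow_volume_ml < 0:
        raise UnsupportedRegimeError(
            "negative catheter outflow (net aspiration) is not modelled"
        )
    if outflow_volume_ml == 0:
        return chain.distal_fractions()
    if slice_volume_ml is not None and outflow_volume_ml > 4 * slice_volume_ml:
        logger.debug(
            "advection step volume %.3g mL exceeds 4x slice volume %.3g mL",
            outflow_volume_ml,
            slice_volume_ml,
        )
    chain.push(outflow_volume_ml, mixture_fractions)
    return chain.emit(outflow_volume_ml)


class LineBuffer:
    """LIFO buffer of mixed fluid pushed back up a branch line.

    Plug reversal: the last mixture pushed in is the first to return
    when the branch flow turns positive again.  ``capacity_ml`` is the
    branch-line internal volume; buffered mixture beyond it would
    physically displace fluid toward the syringe, which is tolerated
    with a warning.
    """

    def __init__(self, capacity_ml: float, n_drugs: int):
        self.capacity_ml = capacity_ml
        self.n_drugs = n_drugs
        self._stack: list[list] = []
        self._warned = False

    @property
    def stored_volume(self) -> float:
        return sum(v for v, _ in self._stack)

    def push(self, volume_ml: float, fractions: np.ndarray) -> None:
        if volume_ml <= 0:
            return
        if self.stored_volume + volume_ml > self.capacity_ml and not self._warned:
            warnings.warn(
                "backflow exceeds branch line volume; overflow treated as "
                "displacing toward the syringe",
                stacklevel=2,
            )
            self._warned = True
        fractions = np.asarray(fractions, dtype=float)
        if self._stack and np.array_equal(self._stack[-1][1], fractions):
            self._stack[-1][0] += volume_ml
        else:
            self._stack.append([float(volume_ml), fractions.copy()])

    def draw(self, volume_ml: float, stock_fractions: np.ndarray) -> np.ndarray:
        """Withdraw ``volume_ml`` toward the junction.

        Buffered mixture returns first (last-in-first-out); any
        shortfall is fresh stock solution.  Returns the per-drug volume
        vector (sums to ``volume_ml``).
        """
        drawn = np.zeros(self.n_drugs)
        remaining = volume_ml
        while remaining > 0 and self._stack:
            vol, frac = self._stack[-1]
            take = min(vol, remaining)
            drawn += take * frac
            remaining -= take
            if take >= vol:
                self._stack.pop()
            else:
                self._stack[-1][0] = vol - take
        if remaining > 0:
            drawn += remaining * np.asarray(stock_fractions, dtype=float)
        return drawn


def handle_backflow(
    buffer: LineBuffer, mixture_fractions: np.ndarray, backflow_volume_ml: float
) -> LineBuffer:
    """Store junction mixture pushed back up a branch line.

    No-op for zero volume.  The buffer is modified in place and
    returned for convenience.
    """
    if backflow_volume_ml < 0:
        raise InvalidParameterError("backflow volume must be >= 0")
    buffer.push(backflow_volume_ml, mixture_fractions)
    return buffer


# ---------------------------------------------------------------------------
# Laminar (Poiseuille) washout
# ---------------------------------------------------------------------------


def first_arrival_time(tube_volume_ml: float, flow_ml_h: float) -> float:
    """Time for the first new fluid to reach the tube outlet, in hours.

    The centerline velocity of laminar pipe flow is twice the
    cross-sectional average, so the leading edge of a composition front
    arrives after half the mean transit time: (V/Q)/2.
    """
    if flow_ml_h <= 0:
        raise InvalidParameterError("flow must be > 0")
    if tube_volume_ml < 0:
        raise InvalidParameterError("tube volume must be >= 0")
    return 0.5 * tube_volume_ml / flow_ml_h


def poiseuille_breakthrough(
    tube_volume_ml: float, flow_ml_h: float, t_since_front_h: float
) -> float:
    """Fraction of new fluid in the effluent after a composition step.

    For laminar flow with no radial mixing, an annulus at relative
    radius rho travels at 2*(1 - rho^2) times the mean velocity, giving
    the classical washout curve with mean transit tau = V/Q:

        f(t) = 0                  for t <  tau/2
        f(t) = 1 - (tau/(2 t))^2  for t >= tau/2

    Monotone non-decreasing, reaching 1 only asymptotically.
    """
    if flow_ml_h <= 0:
        raise InvalidParameterError("flow must be > 0")
    if t_since_front_h < 0:
        raise InvalidParameterError("time must be >= 0")
    if tube_volume_ml == 0:
        return 1.0
    tau = tube_volume_ml / flow_ml_h
    if t_since_front_h < 0.5 * tau:
        return 0.0
    return 1.0 - (0.5 * tau / t_since_front_h) ** 2


def breakthrough_volume_fraction(tube_volume_ml: float, emitted_ml) -> np.ndarray:
    """Washout curve in cumulative-volume coordinates.

    Fraction of new fluid in the effluent once ``emitted_ml`` has
    passed since the front entered the tube:  0 below V/2, then
    1 - (V/(2 v))^2.  Valid for time-varying flow because the laminar
    profile rescales with the instantaneous flow (quasi-static).
    """
    if tube_volume_ml < 0:
        raise InvalidParameterError("tube volume must be >= 0")
    v = np.asarray(emitted_ml, dtype=float)
    if tube_volume_ml == 0:
        return np.where(v > 0, 1.0, 0.0)
    with np.errstate(divide="ignore"):
        frac = 1.0 - (tube_volume_ml / (2.0 * v)) ** 2
    return np.where(v < 0.5 * tube_volume_ml, 0.0, frac)


def _kernel_survival(lag_ml, tube_volume_ml: float) -> np.ndarray:
    """P(volume lag relative to the plug front >= lag).

    The laminar effluent at cumulative volume v mixes plug-coordinate
    fluid with lags u in [-V/2, inf): the fastest streamline runs half
    a tube volume ahead of the plug front, the near-wall tail lags
    behind.  S(u) = V^2 / (4 (u + V)^2) for u >= -V/2, else 1; the lag
    distribution has mean zero, so plug and laminar transport share the
    same mean residence volume V (mean residence time V/Q).
    """
    u = np.asarray(lag_ml, dtype=float)
    v_t = tube_volume_ml
    s = np.ones_like(u)
    ahead = u >= -0.5 * v_t
    s[ahead] = v_t**2 / (4.0 * (u[ahead] + v_t) ** 2)
    return s


def apply_poiseuille_kernel(
    plug_fractions: np.ndarray,
    cumulative_volume_ml: np.ndarray,
    tube_volume_ml: float,
) -> np.ndarray:
    """Smear a plug-flow effluent composition series by laminar washout.

    Parameters
    ----------
    plug_fractions
        (n_steps + 1, n_drugs); row k is the composition emitted under
        plug flow during the k-th step (row 0 = composition at t = 0).
    cumulative_volume_ml
        (n_steps + 1,) non-decreasing cumulative emitted volume; entry
        0 is 0.
    tube_volume_ml
        Internal volume of the laminar segment.

    The plug series is treated as piecewise constant in cumulative
    volume and extended by its first/last row outside the simulated
    span (the pre-existing steady composition before t = 0, and a
    settled composition after the end).  Conserves a constant
    composition exactly and reduces to the closed-form breakthrough
    curve for a single step at constant flow.
    """
    c = np.asarray(plug_fractions, dtype=float)
    v = np.asarray(cumulative_volume_ml, dtype=float)
    if c.shape[0] != v.shape[0]:
        raise InvalidParameterError("series lengths must match")
    if np.any(np.diff(v) < -1e-12):
        raise InvalidParameterError("cumulative volume must be non-decreasing")
    if tube_volume_ml <= 0:
        return c.copy()

    n = v.size
    out = np.empty_like(c)
    # far-field pads; V/2 of lead and a long lag tail are enough support
    lo_edge = v[0] - 10.0 * tube_volume_ml
    hi_edge = v[-1] + 0.5 * tube_volume_ml
    edges = np.concatenate(([lo_edge], v, [hi_edge]))
    comps = np.vstack([c[0], c, c[-1]])  # composition on (edges[j-1], edges[j]]
    for k in range(n):
        s = _kernel_survival(v[k] - edges, tube_volume_ml)
        # weight of plug fluid in (edges[j-1], edges[j]] is S(v-e_j)-S(v-e_{j-1})
        w = s[1:] - s[:-1]
        w_tail = 1.0 - s[-1]  # fluid beyond the simulated end
        out[k] = w @ comps[1:] + w_tail * comps[-1]
        norm = w.sum() + w_tail + s[0]
        out[k] += s[0] * comps[0]  # fluid before the padded start
        out[k] /= norm
    return out


# ---------------------------------------------------------------------------
# End-to-end dose simulation
# ---------------------------------------------------------------------------


@dataclass
class DoseTimeSeries:
    """Per-drug dose rates at the vascular access point.

    ``delivered[d, k]`` is the flow of drug d's stock solution reaching
    the patient at ``times[k]`` (mL/h); ``set_rates`` is the reference
    implied by the pump settings.  Delivered rates are non-negative and
    sum to the catheter outflow at every time.
    """

    times: np.ndarray
    drugs: tuple[str, ...]
    delivered: np.ndarray
    set_rates: np.ndarray
    outflow: np.ndarray

    def to_frame(self):
        import pandas as pd

        frames = []
        for d, drug in enumerate(self.drugs):
            frames.append(
                pd.DataFrame(
                    {
                        "time_h": self.times,
                        "drug": drug,
                        "set_rate_ml_h": self.set_rates[d],
                        "delivered_rate_ml_h": self.delivered[d],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class TransportTrace:
    """Diagnostics from a dose simulation (mainly for testing)."""

    flows: BranchFlows
    plug_fractions: np.ndarray
    effluent_fractions: np.ndarray
    cumulative_volume_ml: np.ndarray
    injected_volume_ml: np.ndarray  # per drug, cumulative at the junction side
    emitted_volume_ml: np.ndarray  # per drug, cumulative plug emission
    initial_chain_content_ml: np.ndarray  # per drug
    final_chain_content_ml: np.ndarray  # per drug
    max_buffered_ml: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _drug_index(network: InfusionNetwork, extra: tuple[str, ...]) -> tuple[str, ...]:
    drugs = list(network.drugs)
    for d in extra:
        if d not in drugs:
            drugs.append(d)
    return tuple(drugs)


def simulate_doses(
    network: InfusionNetwork,
    grid: SimulationGrid,
    kernel: str = "poiseuille",
    initial_mixture: dict[str, float] | None = None,
    initial_state: PressureState | None = None,
    return_trace: bool = False,
):
    """Simulate delivered per-drug dose rates at the access point.

    Runs the hydraulic network over the grid, feeds the resulting
    branch flows through the junction (with LIFO backflow buffering on
    each branch line) and advects the mixture through the shared-volume
    slice chain.  With ``kernel='poiseuille'`` the plug effluent is
    additionally smeared by the laminar washout kernel over the shared
    volume; ``kernel='plug'`` gives pure piston transport.

    ``initial_mixture`` sets the composition filling the shared volume
    at t = 0 (drug label -> volume fraction); by default it is the
    steady-state junction mixture of the t = 0 set flows.  Drugs that
    appear only in the initial fill (a previously infused medicine) are
    tracked alongside the pumped drugs.
    """
    if kernel not in ("poiseuille", "plug"):
        raise InvalidParameterError(f"unknown kernel {kernel!r}")

    flows = solve_flows(network, grid, initial_state=initial_state)
    n_steps = grid.n_steps
    n_b = network.n_branches

    extra = tuple(initial_mixture) if initial_mixture else ()
    drugs = _drug_index(network, extra)
    n_d = len(drugs)
    d_of_branch = [drugs.index(b.drug) for b in network.branches]

    stock = np.zeros((n_b, n_d))
    for i, di in enumerate(d_of_branch):
        stock[i, di] = 1.0

    if initial_mixture is not None:
        init = np.zeros(n_d)
        for name, f in initial_mixture.items():
            init[drugs.index(name)] = f
        if abs(init.sum() - 1.0) > _FRACTION_TOL or np.any(init < 0):
            raise InvalidParameterError("initial_mixture must be fractions summing to 1")
    else:
        q0 = flows.set_flows[:, 0]
        if q0.sum() > 0:
            init = (stock.T @ q0) / q0.sum()
        else:
            init = stock.mean(axis=0)

    shared_v = network.shared_volume_ml
    slice_v = grid.resolve_slice_volume(shared_v)
    chain = SliceChain(shared_v, init)
    buffers = [LineBuffer(b.line_volume_ml, n_d) for b in network.branches]

    plug_frac = np.empty((n_steps + 1, n_d))
    plug_frac[0] = chain.distal_fractions()
    emitted = np.zeros(n_steps + 1)
    injected = np.zeros((n_steps + 1, n_d))
    emitted_per_drug = np.zeros((n_steps + 1, n_d))
    initial_content = shared_v * init
    max_buffered = np.zeros(n_b)

    for k in range(1, n_steps + 1):
        dt = flows.times[k] - flows.times[k - 1]
        q = flows.branch_flows[:, k]
        vols = q * dt
        out_vol = vols.sum()
        if out_vol < -1e-12:
            raise UnsupportedRegimeError(
                f"net aspiration at t={flows.times[k]:.6g} h is not modelled"
            )
        out_vol = max(out_vol, 0.0)

        # junction mixture from the branches currently flowing forward
        supplied = np.zeros(n_d)
        total_in = 0.0
        for i in range(n_b):
            if vols[i] > 0:
                supplied += buffers[i].draw(vols[i], stock[i])
                total_in += vols[i]
        if total_in > 0:
            mixture = supplied / total_in
        else:
            mixture = chain.distal_fractions()  # nothing moves this step

        # backflow: junction mixture pushed up the reversed branch lines
        for i in range(n_b):
            if vols[i] < 0:
                handle_backflow(buffers[i], mixture, -vols[i])
                max_buffered[i] = max(max_buffered[i], buffers[i].stored_volume)

        injected[k] = injected[k - 1] + mixture * out_vol
        plug_frac[k] = advect(chain, mixture, out_vol, slice_v)
        emitted_per_drug[k] = emitted_per_drug[k - 1] + plug_frac[k] * out_vol
        emitted[k] = emitted[k - 1] + out_vol

    if kernel == "poiseuille":
        effluent = apply_poiseuille_kernel(plug_frac, emitted, shared_v)
    else:
        effluent = plug_frac

    delivered = effluent.T * np.maximum(flows.outflow, 0.0)

    set_rates = np.zeros((n_d, n_steps + 1))
    for i, di in enumerate(d_of_branch):
        set_rates[di] += flows.set_flows[i]

    series = DoseTimeSeries(
        times=flows.times.copy(),
        drugs=drugs,
        delivered=delivered,
        set_rates=set_rates,
        outflow=flows.outflow.copy(),
    )
    if return_trace:
        final_content = np.zeros(n_d)
        for vol, frac in chain.composition_profile():
            final_content += vol * frac
        trace = TransportTrace(
            flows=flows,
            plug_fractions=plug_frac,
            effluent_fractions=effluent,
            cumulative_volume_ml=emitted,
            injected_volume_ml=injected.T,
            emitted_volume_ml=emitted_per_drug.T,
            initial_chain_content_ml=initial_content,
            final_chain_content_ml=final_content,
            max_buffered_ml=max_buffered,
        )
        return series, trace
    return series
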