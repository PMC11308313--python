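"""Built-in scenarios, scenario config files and randomized fixtures.

Four built-in cases cover the canonical teaching situations of
shared-line infusion:

1. **Syringe exchange** — one pump, a 3 mL infusion line at 6 mL/h;
   when does the first bit of the newly loaded medicine reach the
   patient?  (Half the mean transit time, because of the laminar flow
   profile: 15 min, not 30.)
2. **Carrier step-up, wide catheter (7 Fr)** — pump A runs much faster
   than pump B; raising A's set flow transiently overdoses drug B
   (push-out of the old mixing ratio at the new total flow).
3. **Carrier step-down, wide catheter** — the mirror image: lowering
   A's flow transiently underdoses drug B.
4. **Carrier step-up, 1 Fr catheter** — the very high catheter
   resistance makes syringe compliance dominant: drug B is first
   overdosed (push-out) and then underdosed while the pressure surge
   presses mixed fluid back up B's line — a biphasic, counter-intuitive
   deviation.

The numeric flow rates of cases 2-4 (A: 10->20 or 20->10 mL/h against
B at 1 mL/h) are illustrative defaults for the "A much faster than B"
regime and are fully configurable via scenario files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .components import (
    CatheterSpec,
    InvalidParameterError,
    MixingPointSpec,
    SyringeSpec,
    TubeGeometry,
    catalog_lookup,
)
from .dose_error import decompose, deviation, integrate_error
from .grid import SimulationGrid
from .hydraulics import FlowSchedule, InfusionNetwork, PumpBranch
from .transport import first_arrival_time, simulate_doses

__all__ = [
    "Scenario",
    "builtin_case",
    "run_scenario",
    "generate_fixture",
    "load_scenario",
    "scenario_from_config",
]

logger = logging.getLogger(__name__)

#: deviation below this fraction of the peak counts as "recovered"
_RECOVERY_REL_TOL = 0.02


class UnknownCaseError(ValueError):
    pass


@dataclass
class Scenario:
    """A fully parameterized simulation scenario."""

    name: str
    network: InfusionNetwork
    grid: SimulationGrid
    kernel: str = "poiseuille"
    initial_mixture: dict[str, float] | None = None
    events: str = ""
    expected_qualitative: str = ""
    critical_drug: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kernel not in ("poiseuille", "plug"):
            raise InvalidParameterError(f"unknown kernel {self.kernel!r}")
        # fail fast: validate the network against the grid
        if self.grid.n_steps < 1:
            raise InvalidParameterError("grid shorter than one step")


def _branch(
    drug: str,
    schedule: FlowSchedule,
    syringe: SyringeSpec | None = None,
    line: TubeGeometry | None = None,
) -> PumpBranch:
    return PumpBranch(
        syringe=syringe or catalog_lookup("Omnifix 50mL"),
        line=line or catalog_lookup("Standard line 1m"),
        drug=drug,
        schedule=schedule,
    )


def _two_pump_network(catheter_name: str, sched_a: FlowSchedule) -> InfusionNetwork:
    return InfusionNetwork(
        branches=(
            _branch("drug A", sched_a),
            _branch("drug B", FlowSchedule.constant(1.0)),
        ),
        mixing_point=catalog_lookup("Discofix C 3-gang"),
        catheter=catalog_lookup(catheter_name),
    )


def builtin_case(case_id: int) -> Scenario:
    """One of the four built-in scenarios (see module docstring)."""
    if case_id == 1:
        catheter = catalog_lookup("Careflow 7Fr")
        # the stated 3 mL infusion-line volume is the whole shared path
        # from pump to patient; the manifold entry absorbs the remainder
        line_volume = 3.0
        mixing = MixingPointSpec(
            name="line volume (case 1)",
            dead_volume_ml=line_volume - catheter.volume_ml,
        )
        network = InfusionNetwork(
            branches=(_branch("new medicine", FlowSchedule.constant(6.0)),),
            mixing_point=mixing,
            catheter=catheter,
        )
        return Scenario(
            name="case1-syringe-exchange",
            network=network,
            grid=SimulationGrid(dt_h=1e-3, duration_h=1.5),
            initial_mixture={"old medicine": 1.0},
            events="syringe exchanged at t=0; set flow constant at 6 mL/h",
            expected_qualitative="first-arrival-at-half-mean-transit",
            critical_drug="new medicine",
        )
    if case_id == 2:
        return Scenario(
            name="case2-step-up-7Fr",
            network=_two_pump_network("Careflow 7Fr", FlowSchedule.step(10.0, 20.0, 0.25)),
            grid=SimulationGrid(dt_h=2.5e-4, duration_h=1.0),
            events="Q_A raised 10 -> 20 mL/h at t=0.25 h",
            expected_qualitative="overdose-then-recovery",
            critical_drug="drug B",
        )
    if case_id == 3:
        return Scenario(
            name="case3-step-down-7Fr",
            network=_two_pump_network("Careflow 7Fr", FlowSchedule.step(20.0, 10.0, 0.25)),
            grid=SimulationGrid(dt_h=2.5e-4, duration_h=1.0),
            events="Q_A lowered 20 -> 10 mL/h at t=0.25 h",
            expected_qualitative="underdose-then-recovery",
            critical_drug="drug B",
        )
    if case_id == 4:
        return Scenario(
            name="case4-step-up-1Fr",
            network=_two_pump_network("Premicath 1Fr", FlowSchedule.step(10.0, 20.0, 0.25)),
            grid=SimulationGrid(dt_h=2.5e-4, duration_h=1.0),
            events="Q_A raised 10 -> 20 mL/h at t=0.25 h, 1 Fr catheter",
            expected_qualitative="biphasic",
            critical_drug="drug B",
        )
    raise UnknownCaseError(f"unknown case {case_id!r}; valid ids are 1-4")


# ---------------------------------------------------------------------------
# Scenario analysis and output bundle
# ---------------------------------------------------------------------------


def _first_arrival_from_series(series, drug: str) -> float | None:
    """First time the delivered fraction of ``drug`` becomes positive."""
    d = series.drugs.index(drug)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(series.outflow > 0, series.delivered[d] / series.outflow, 0.0)
    idx = np.flatnonzero(frac > 1e-9)
    if idx.size == 0:
        return None
    return float(series.times[idx[0]])


def analyze_scenario(scenario: Scenario):
    """Run a scenario and summarize it.

    Returns ``(summary, series, decomposition, trace)``; used by
    run_scenario and directly by tests.
    """
    series, trace = simulate_doses(
        scenario.network,
        scenario.grid,
        kernel=scenario.kernel,
        initial_mixture=scenario.initial_mixture,
        return_trace=True,
    )
    deco = decompose(
        scenario.network, scenario.grid, initial_mixture=scenario.initial_mixture
    )
    dev = deviation(series)

    summary: dict = {
        "scenario": scenario.name,
        "events": scenario.events,
        "kernel": scenario.kernel,
        "n_steps": scenario.grid.n_steps,
        "drugs": {},
    }
    for d, drug in enumerate(series.drugs):
        per = dict(deco.integrated.get(drug, integrate_error(series.times, dev[d])))
        peak = float(np.max(np.abs(dev[d]))) if dev[d].size else 0.0
        tol = max(_RECOVERY_REL_TOL * peak, 1e-12)
        above = np.flatnonzero(np.abs(dev[d]) > tol)
        per["peak_deviation_ml_h"] = peak
        per["max_overdose_ml_h"] = float(dev[d].max())
        per["max_underdose_ml_h"] = float(-dev[d].min())
        per["time_to_recovery_h"] = (
            float(series.times[above[-1]]) if above.size else 0.0
        )
        per["biphasic"] = bool(
            dev[d].max() > 0.05 * peak and -dev[d].min() > 0.05 * peak and peak > 0
        )
        summary["drugs"][drug] = per

    if scenario.initial_mixture is not None and scenario.critical_drug:
        v = scenario.network.shared_volume_ml
        q = scenario.network.branches[0].schedule.flow_at(0.0)
        summary["first_arrival_h"] = first_arrival_time(v, q)
        summary["mean_transit_h"] = v / q
        summary["first_arrival_simulated_h"] = _first_arrival_from_series(
            series, scenario.critical_drug
        )
    return summary, series, deco, trace


def run_scenario(scenario: Scenario, outdir: str | Path) -> dict:
    """Run a scenario and write the result bundle to ``outdir``.

    Writes flows.csv, doses.csv, decomposition.csv, summary.json and a
    run log with the full parameter echo.  Re-running the same scenario
    produces byte-identical CSVs: the core simulation has no random
    element.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("running scenario %s: %s", scenario.name, scenario.events)

    summary, series, deco, trace = analyze_scenario(scenario)

    trace.flows.to_frame().to_csv(outdir / "flows.csv", index=False, float_format="%.10g")
    series.to_frame().to_csv(outdir / "doses.csv", index=False, float_format="%.10g")
    deco.to_frame().to_csv(
        outdir / "decomposition.csv", index=False, float_format="%.10g"
    )
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "run.log").write_text(_parameter_echo(scenario))
    logger.info("wrote result bundle to %s", outdir)
    return summary


def _parameter_echo(scenario: Scenario) -> str:
    net = scenario.network
    lines = [
        f"scenario: {scenario.name}",
        f"events: {scenario.events}",
        f"kernel: {scenario.kernel}",
        f"seed: {scenario.seed}",
        f"grid: dt={scenario.grid.dt_h} h, duration={scenario.grid.duration_h} h, "
        f"slice_volume={scenario.grid.resolve_slice_volume(net.shared_volume_ml):.6g} mL",
        f"catheter: {net.catheter.name} ({net.catheter.french_size} Fr, "
        f"R={net.catheter_resistance:.6g} mbar*h/mL, V={net.catheter.volume_ml:.6g} mL)",
        f"mixing point: {net.mixing_point.name} "
        f"(dead volume {net.mixing_point.dead_volume_ml:.6g} mL)",
        f"venous pressure: {net.venous_pressure_mbar} mbar",
        f"initial mixture: {scenario.initial_mixture}",
    ]
    for i, b in enumerate(net.branches):
        lines.append(
            f"branch {i}: drug={b.drug!r}, syringe={b.syringe.name} "
            f"(C={b.compliance:.6g} mL/mbar), line R={b.resistance:.6g} mbar*h/mL, "
            f"line V={b.line_volume_ml:.6g} mL, schedule={list(b.schedule.events)}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Randomized fixtures for property-based testing
# ---------------------------------------------------------------------------


def generate_fixture(
    seed: int,
    n_branches: tuple[int, int] = (1, 3),
    flow_range: tuple[float, float] = (1.0, 10.0),
    dead_volume_range: tuple[float, float] = (0.2, 1.0),
    rigid: bool = True,
    kernel: str = "plug",
) -> Scenario:
    """Random but physically valid scenario, reproducible per seed.

    One branch receives a set-flow step at t = 0.05 h; all others run
    constant.  ``rigid=True`` zeroes every syringe compliance so the
    plug-flow push-out closed form applies exactly; the grid is sized
    so each transport step moves at most one slice volume and the run
    covers the step plus two full flushes of the shared volume.
    """
    lo, hi = n_branches
    if not (1 <= lo <= hi):
        raise InvalidParameterError("invalid n_branches range")
    if flow_range[0] <= 0 or flow_range[0] > flow_range[1]:
        raise InvalidParameterError("invalid flow range")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(lo, hi + 1))
    catheter = catalog_lookup(
        "Careflow 7Fr" if (rigid or rng.random() < 0.5) else "Premicath 1Fr"
    )
    mixing = MixingPointSpec(
        name="fixture manifold",
        dead_volume_ml=float(rng.uniform(*dead_volume_range)),
    )

    step_branch = int(rng.integers(0, n))
    t_step = 0.05
    branches = []
    for i in range(n):
        q1 = float(rng.uniform(*flow_range))
        if i == step_branch:
            q2 = float(rng.uniform(*flow_range))
            schedule = FlowSchedule.step(q1, q2, t_step)
        else:
            schedule = FlowSchedule.constant(q1)
        compliance = 0.0 if rigid else float(rng.uniform(1e-4, 3e-3))
        syringe = SyringeSpec(
            name=f"fixture syringe {i}",
            nominal_volume_ml=50.0,
            compliance_ml_per_mbar=compliance,
        )
        branches.append(
            _branch(f"drug_{i}", schedule, syringe=syringe)
        )
    network = InfusionNetwork(
        branches=tuple(branches), mixing_point=mixing, catheter=catheter
    )

    v_shared = network.shared_volume_ml
    q_tot_after = sum(b.schedule.flow_at(t_step + 1.0) for b in branches)
    q_tot_max = max(
        sum(b.schedule.flow_at(t) for b in branches) for t in (0.0, t_step + 1.0)
    )
    slice_v = v_shared / 200.0
    dt = min(slice_v / q_tot_max, 2e-3)
    duration = t_step + 2.0 * v_shared / q_tot_after + 10.0 * dt
    grid = SimulationGrid(dt_h=dt, duration_h=duration, slice_volume_ml=slice_v)
    return Scenario(
        name=f"fixture-{seed}",
        network=network,
        grid=grid,
        kernel=kernel,
        events=f"Q step on branch {step_branch} at t={t_step} h",
        expected_qualitative="push-out",
        critical_drug=f"drug_{step_branch}",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Declarative scenario files
# ---------------------------------------------------------------------------


def _resolve(value, expected_type, inline_builder):
    """Catalog label or inline mapping -> validated component spec."""
    if isinstance(value, str):
        spec = catalog_lookup(value)
        if not isinstance(spec, expected_type):
            raise InvalidParameterError(
                f"catalog entry {value!r} is not a {expected_type.__name__}"
            )
        return spec
    return inline_builder(value)


def scenario_from_config(cfg: dict) -> Scenario:
    """Build a Scenario from a parsed config mapping.

    Schema (YAML): ``name``, ``grid {dt_h, duration_h[, slice_volume_ml]}``,
    optional ``kernel``, ``venous_pressure_mbar``, ``initial_mixture``;
    ``catheter`` / ``mixing_point`` as catalog labels or inline specs;
    ``branches`` as a list of ``{drug, schedule: [[t, q], ...][, syringe,
    line]}``.
    """
    catheter = _resolve(
        cfg["catheter"],
        CatheterSpec,
        lambda c: CatheterSpec(
            name=c.get("name", "custom catheter"),
            french_size=c["french_size"],
            geometry=TubeGeometry(c["length_m"], c["inner_diameter_mm"]),
        ),
    )
    mixing = _resolve(
        cfg["mixing_point"],
        MixingPointSpec,
        lambda m: MixingPointSpec(
            name=m.get("name", "custom mixing point"),
            dead_volume_ml=m["dead_volume_ml"],
        ),
    )
    branches = []
    for bcfg in cfg["branches"]:
        syringe = _resolve(
            bcfg.get("syringe", "Omnifix 50mL"),
            SyringeSpec,
            lambda s: SyringeSpec(
                name=s.get("name", "custom syringe"),
                nominal_volume_ml=s["nominal_volume_ml"],
                compliance_ml_per_mbar=s["compliance_ml_per_mbar"],
            ),
        )
        line = _resolve(
            bcfg.get("line", "Standard line 1m"),
            TubeGeometry,
            lambda g: TubeGeometry(g["length_m"], g["inner_diameter_mm"]),
        )
        schedule = FlowSchedule(tuple((t, q) for t, q in bcfg["schedule"]))
        branches.append(
            PumpBranch(
                syringe=syringe,
                line=line,
                drug=bcfg["drug"],
                schedule=schedule,
                viscosity_mpas=bcfg.get("viscosity_mpas", 1.0),
            )
        )
    network = InfusionNetwork(
        branches=tuple(branches),
        mixing_point=mixing,
        catheter=catheter,
        venous_pressure_mbar=cfg.get("venous_pressure_mbar", 0.0),
    )
    gcfg = cfg["grid"]
    grid = SimulationGrid(
        dt_h=gcfg["dt_h"],
        duration_h=gcfg["duration_h"],
        slice_volume_ml=gcfg.get("slice_volume_ml"),
    )
    return Scenario(
        name=cfg.get("name", "scenario"),
        network=network,
        grid=grid,
        kernel=cfg.get("kernel", "poiseuille"),
        initial_mixture=cfg.get("initial_mixture"),
        events=cfg.get("events", ""),
        critical_drug=cfg.get("critical_drug"),
    )


def load_scenario(path: str | Path) -> Scenario:
    """Read a scenario from a YAML file (see scenario_from_config)."""
    cfg = yaml.safe_load(Path(path).read_text())
    return scenario_from_config(cfg)
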