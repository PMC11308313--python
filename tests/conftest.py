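"""Shared fixtures: small networks built from catalog components."""

import pytest

from infusim import (
    FlowSchedule,
    InfusionNetwork,
    MixingPointSpec,
    PumpBranch,
    SyringeSpec,
    TubeGeometry,
    catalog_lookup,
)


def make_branch(drug, schedule, compliance=2e-3, line=None):
    return PumpBranch(
        syringe=SyringeSpec("test syringe", 50.0, compliance),
        line=line or TubeGeometry(1.0, 1.0),
        drug=drug,
        schedule=schedule,
    )


def make_network(branches, dead_volume=0.5, catheter="Careflow 7Fr"):
    return InfusionNetwork(
        branches=tuple(branches),
        mixing_point=MixingPointSpec("test manifold", dead_volume),
        catheter=catalog_lookup(catheter),
    )


@pytest.fixture
def two_pump_7fr():
    """Carrier A (10 mL/h) + critical drug B (1 mL/h), wide catheter."""
    return make_network(
        [
            make_branch("A", FlowSchedule.constant(10.0)),
            make_branch("B", FlowSchedule.constant(1.0)),
        ]
    )


@pytest.fixture
def step_up_7fr():
    """A steps 10 -> 20 mL/h at t=0.05 h against B at 1 mL/h."""
    return make_network(
        [
            make_branch("A", FlowSchedule.step(10.0, 20.0, 0.05)),
            make_branch("B", FlowSchedule.constant(1.0)),
        ]
    )


@pytest.fixture
def step_up_1fr():
    """Same step on the thin high-resistance catheter."""
    return make_network(
        [
            make_branch("A", FlowSchedule.step(10.0, 20.0, 0.05)),
            make_branch("B", FlowSchedule.constant(1.0)),
        ],
        catheter="Premicath 1Fr",
    )
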