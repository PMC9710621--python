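"""Shared fixtures: small agents, grown colonies, render configs."""

from __future__ import annotations

import numpy as np
import pytest

from colonysim.agents import CellAgent, HomeostasisModel
from colonysim.engine import SimulationConfig, init_world, run, step
from colonysim.geometry import ShapeParams
from colonysim.render import RenderConfig


def make_agent(
    id: int = 0,
    position=(0.0, 0.0),
    angle: float = 0.0,
    length: float = 2.0,
    width: float = 0.8,
    kind: str = "rod",
    growth_rate: float = float(np.log(2.0)),
    division_trigger: float = 3.0,
    parent_id=None,
    birth_time: float = 0.0,
    fluorescence: float = 0.0,
) -> CellAgent:
    return CellAgent(
        id=id,
        parent_id=parent_id,
        birth_time=birth_time,
        position=tuple(position),
        angle=angle,
        shape=ShapeParams(kind=kind, length=length, width=length if kind == "coccoid" else width),
        growth_rate=growth_rate,
        division_trigger=division_trigger,
        birth_length=length,
        fluorescence=fluorescence,
    )


@pytest.fixture(scope="session")
def contact_colony():
    """A ~64-cell colony grown to tight contact (sizer, mild heterogeneity)."""
    config = SimulationConfig(
        seed=5,
        dt=0.1,
        duration=100.0,  # stepping is explicit below
        model=HomeostasisModel(kind="sizer", trigger_mean=3.0, trigger_cv=0.1, rate_cv=0.08),
    )
    world = init_world(config)
    while world.count() < 64:
        world = step(world, config)
    return world


@pytest.fixture(scope="session")
def small_colony():
    """A ~20-cell colony snapshot plus its full trajectory."""
    config = SimulationConfig(
        seed=9,
        dt=0.1,
        duration=4.5,
        fluorescence=1.0,
        model=HomeostasisModel(kind="sizer", trigger_mean=3.0, trigger_cv=0.12, rate_cv=0.1),
    )
    return run(config)


@pytest.fixture()
def render_config():
    return RenderConfig(image_size=(256, 256))
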