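"""The agent-based simulation loop.

A :class:`World` holds the colony at one instant; :func:`step` advances it
by one time step in the fixed order grow -> divide -> place -> advance
clock, and :func:`run` drives the loop, delivering snapshots to output
emitters.  Time is in hours throughout, lengths in µm.

Randomness is fully reproducible: the world owns a root seed, founder
parameters come from a generator derived from it, and each division draws
from a generator keyed on (root seed, division step, mother id), so results
do not depend on iteration order.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .agents import CellAgent, HomeostasisModel, divide, grow, sample_lognormal, should_divide
from .geometry import ShapeParams
from .placement import PlacementConfig, resolve_overlaps

__all__ = ["World", "SimulationConfig", "init_world", "step", "run"]

logger = logging.getLogger(__name__)

Emitter = Callable[["World", int], None]


@dataclass
class World:
    """The colony at one instant: clock, agents, id counter, RNG root."""

    time: float
    agents: list[CellAgent]
    next_id: int
    seed: int
    step_index: int = 0

    def count(self) -> int:
        return len(self.agents)


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation parameters.

    dt defaults to 1 min (1/60 h), a typical time-lapse cadence.  Founder
    cells start at the sizer steady-state birth length (trigger/2) unless
    ``founder_length`` overrides it; for the timer rule ``founder_length``
    defaults to 1.5 µm.  Founders are scattered uniformly in a disc of
    radius ``5 x founder length`` around the origin.
    """

    seed: int = 0
    dt: float = 1.0 / 60.0
    duration: float = 2.0
    n_founders: int = 1
    model: HomeostasisModel = field(
        default_factory=lambda: HomeostasisModel(kind="sizer", trigger_mean=3.0)
    )
    placement: PlacementConfig = field(default_factory=PlacementConfig)
    emit_every: int = 1
    shape_kind: str = "rod"
    cell_width: float = 0.8  # µm
    bend: float = 0.0
    n_vertices: int = 32
    founder_length: float | None = None
    fluorescence: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if self.emit_every < 1:
            raise ValueError("emit_every must be >= 1")

    def initial_length(self) -> float:
        if self.founder_length is not None:
            return self.founder_length
        if self.model.kind == "sizer":
            return self.model.trigger_mean / 2.0
        return 1.5


def _founder_shape(config: SimulationConfig, length: float) -> ShapeParams:
    kind = config.shape_kind
    width = length if kind == "coccoid" else config.cell_width
    return ShapeParams(
        kind=kind,
        length=length,
        width=width,
        bend=config.bend if kind == "bent_rod" else 0.0,
        n_vertices=config.n_vertices,
    )


def init_world(config: SimulationConfig) -> World:
    """Seed ``n_founders`` cells in a small disc around the origin."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    length = config.initial_length()
    radius = 5.0 * length
    agents = []
    for i in range(config.n_founders):
        # uniform in the disc via sqrt-radius transform
        r = radius * math.sqrt(rng.uniform()) if config.n_founders > 1 else 0.0
        theta = rng.uniform(0, 2 * np.pi) if config.n_founders > 1 else 0.0
        agents.append(
            CellAgent(
                id=i,
                parent_id=None,
                birth_time=0.0,
                position=(r * math.cos(theta), r * math.sin(theta)),
                angle=float(rng.uniform(0, 2 * np.pi)) if config.n_founders > 1 else 0.0,
                shape=_founder_shape(config, length),
                growth_rate=sample_lognormal(config.model.rate_mean, config.model.rate_cv, rng),
                division_trigger=sample_lognormal(
                    config.model.trigger_mean, config.model.trigger_cv, rng
                ),
                birth_length=length,
                fluorescence=config.fluorescence,
            )
        )
    return World(time=0.0, agents=agents, next_id=config.n_founders, seed=config.seed)


def step(world: World, config: SimulationConfig) -> World:
    """Advance one time step: grow all, divide the eligible, resolve overlaps.

    Divisions are processed in ascending agent id; daughters created this
    step are not re-examined.  The cell count never decreases.
    """
    dt = config.dt
    now = world.time + dt
    grown = [grow(a, dt) for a in world.agents]

    next_id = world.next_id
    survivors: list[CellAgent] = []
    for agent in sorted(grown, key=lambda a: a.id):
        if should_divide(agent, config.model, now):
            rng = np.random.default_rng(
                np.random.SeedSequence([world.seed, 1 + world.step_index, agent.id])
            )
            d1, d2 = divide(agent, config.model, rng, now, next_id)
            next_id += 2
            survivors.extend([d1, d2])
        else:
            survivors.append(agent)

    history: list[float] = []
    placed = resolve_overlaps(survivors, config.placement, history=history)
    logger.info(
        "t=%.3f h  cells=%d  overlap=%.4g µm²",
        now,
        len(placed),
        history[-1] if history else 0.0,
    )
    return World(
        time=now,
        agents=placed,
        next_id=next_id,
        seed=world.seed,
        step_index=world.step_index + 1,
    )


def run(
    config: SimulationConfig,
    emitters: Sequence[Emitter] = (),
) -> list[World]:
    """Run the full simulation; return the trajectory of world snapshots.

    ``ceil(duration / dt)`` steps are executed.  Snapshots (including the
    initial world) are handed to every emitter every ``emit_every`` steps;
    emitter exceptions abort the run with context.
    """
    n_steps = math.ceil(config.duration / config.dt - 1e-9)
    world = init_world(config)
    trajectory = [copy.deepcopy(world)]
    _emit(emitters, world, 0)
    for k in range(1, n_steps + 1):
        world = step(world, config)
        trajectory.append(copy.deepcopy(world))
        if k % config.emit_every == 0:
            _emit(emitters, world, k)
    return trajectory


def _emit(emitters: Sequence[Emitter], world: World, step_index: int) -> None:
    for emitter in emitters:
        try:
            emitter(world, step_index)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(
                f"output emitter {emitter!r} failed at step {step_index} (t={world.time:.3f} h)"
            ) from exc
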