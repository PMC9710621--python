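"""Cell agents: state, exponential growth, and size-homeostasis division.

Each cell is an agent carrying identity/lineage, pose, shape parameters and
its own growth/division parameters.  Division follows one of two
phenomenological size-homeostasis rules:

* ``timer`` -- divide once a fixed time has elapsed since birth;
* ``sizer`` -- divide once the cell reaches a threshold length.

Elongation is exponential in length (dL/dt = k L), the standard law for
single bacterial cells, so the length after a step of duration dt is
``L * exp(k * dt)``.  Cell-to-cell heterogeneity in rates and triggers is
modelled with lognormal distributions parametrized by arithmetic mean and
coefficient of variation (CV); CV = 0 collapses to the exact mean, which
yields closed-form colony dynamics used throughout the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .geometry import PolygonChain, ShapeParams, make_shape, place

__all__ = [
    "CellAgent",
    "HomeostasisModel",
    "grow",
    "should_divide",
    "divide",
    "sample_lognormal",
]

# Relative slack on trigger comparisons: floating-point growth products such
# as (2**(1/m))**m land a few ulp below the exact threshold and would
# otherwise postpone division by a whole step.
_TRIGGER_RTOL = 1e-12


@dataclass(frozen=True)
class CellAgent:
    """One cell's full state.

    ``division_trigger`` is in hours for the timer rule and in µm for the
    sizer rule.  ``fluorescence`` is an emission density per unit area
    (arbitrary intensity units / µm²).
    """

    id: int
    parent_id: int | None
    birth_time: float  # h
    position: tuple[float, float]  # µm
    angle: float  # rad
    shape: ShapeParams
    growth_rate: float  # 1/h
    division_trigger: float  # h (timer) or µm (sizer)
    birth_length: float  # µm
    fluorescence: float = 0.0

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if self.division_trigger <= 0:
            raise ValueError("division_trigger must be positive")
        if self.fluorescence < 0:
            raise ValueError("fluorescence must be >= 0")

    @property
    def length(self) -> float:
        return self.shape.length

    @property
    def width(self) -> float:
        return self.shape.width

    def polygon(self) -> PolygonChain:
        """The cell outline placed at its world pose."""
        return place(make_shape(self.shape), self.position, self.angle)


@dataclass(frozen=True)
class HomeostasisModel:
    """Population-level parameters of a size-homeostasis rule.

    trigger_mean is hours (timer) or µm (sizer); rate_mean is the mean
    exponential elongation rate in 1/h.  CVs are dimensionless; 0 means no
    cell-to-cell variability.  ``division_angle_sigma`` (rad) perturbs each
    daughter's orientation at division; ``division_noise_cv`` jitters the
    split fraction around 1/2 while conserving total length.
    """

    kind: Literal["timer", "sizer"]
    trigger_mean: float
    trigger_cv: float = 0.0
    rate_mean: float = np.log(2.0)  # doubling time of 1 h
    rate_cv: float = 0.0
    division_angle_sigma: float = 0.05
    division_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("timer", "sizer"):
            raise ValueError(f"unknown homeostasis model kind {self.kind!r}")
        if self.trigger_mean <= 0 or self.rate_mean <= 0:
            raise ValueError("trigger_mean and rate_mean must be positive")
        if self.trigger_cv < 0 or self.rate_cv < 0:
            raise ValueError("CVs must be >= 0")


def grow(agent: CellAgent, dt: float) -> CellAgent:
    """Advance one cell by ``dt`` hours of exponential elongation.

    Only the length changes: L' = L * exp(k dt).  Width, pose, lineage and
    division state are untouched.  dt = 0 returns the agent unchanged.
    """
    if dt < 0:
        raise ValueError(f"time step must be >= 0, got {dt}")
    if dt == 0:
        return agent
    new_length = agent.shape.length * float(np.exp(agent.growth_rate * dt))
    new_shape = _resize(agent.shape, new_length)
    return dataclasses.replace(agent, shape=new_shape)


def _resize(shape: ShapeParams, new_length: float) -> ShapeParams:
    """New shape of the given length; a coccoid grows isotropically."""
    if shape.kind == "coccoid":
        return dataclasses.replace(shape, length=new_length, width=new_length)
    return dataclasses.replace(shape, length=new_length)


def should_divide(agent: CellAgent, model: HomeostasisModel, now: float) -> bool:
    """Division test: age >= trigger (timer) or length >= trigger (sizer).

    The comparison is inclusive with a tiny relative tolerance so exact
    closed-form trajectories (CV = 0) divide on the intended step.
    """
    if now < agent.birth_time:
        raise ValueError("now precedes the agent's birth time")
    if model.kind == "timer":
        value = now - agent.birth_time
    elif model.kind == "sizer":
        value = agent.length
    else:  # pragma: no cover - guarded in HomeostasisModel
        raise ValueError(f"unknown homeostasis model kind {model.kind!r}")
    return value >= agent.division_trigger * (1.0 - _TRIGGER_RTOL)


def sample_lognormal(mean: float, cv: float, rng: np.random.Generator) -> float:
    """Lognormal draw with arithmetic mean ``mean`` and coefficient of variation ``cv``.

    cv = 0 returns the mean exactly (degenerate distribution).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return float(mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))


def divide(
    agent: CellAgent,
    model: HomeostasisModel,
    rng: np.random.Generator,
    now: float,
    id_start: int,
) -> tuple[CellAgent, CellAgent]:
    """Split a mother into two daughters placed end-to-end along her axis.

    The split is symmetric at the centerline midpoint (optionally jittered
    by ``division_noise_cv``); daughter lengths always sum to the mother's
    length.  Daughters inherit width and fluorescence density, get the
    mother's angle perturbed by a Gaussian of ``division_angle_sigma``, and
    sample fresh growth rates and triggers from the model distributions.

    ``id_start`` and ``id_start + 1`` become the daughters' ids.
    """
    if not should_divide(agent, model, now):
        raise RuntimeError(
            f"divide() called on agent {agent.id} that does not satisfy its division rule"
        )
    L = agent.length
    frac = 0.5
    if model.division_noise_cv > 0:
        frac = float(np.clip(0.5 * (1.0 + model.division_noise_cv * rng.standard_normal()), 0.2, 0.8))
    len_a = frac * L
    len_b = L - len_a

    # mother's centerline spans [-L/2, +L/2] along her axis; each daughter
    # keeps the centre of her own segment
    axis = np.array([np.cos(agent.angle), np.sin(agent.angle)])
    pos = np.asarray(agent.position, dtype=float)
    centre_a = pos + axis * (L * (frac - 1.0) / 2.0)
    centre_b = pos + axis * (L * frac / 2.0)

    daughters = []
    for child_id, child_len, child_pos in (
        (id_start, len_a, centre_a),
        (id_start + 1, len_b, centre_b),
    ):
        d_angle = agent.angle
        if model.division_angle_sigma > 0:
            d_angle += model.division_angle_sigma * float(rng.standard_normal())
        shape = _resize(agent.shape, child_len)
        daughters.append(
            CellAgent(
                id=child_id,
                parent_id=agent.id,
                birth_time=now,
                position=(float(child_pos[0]), float(child_pos[1])),
                angle=d_angle,
                shape=shape,
                growth_rate=sample_lognormal(model.rate_mean, model.rate_cv, rng),
                division_trigger=sample_lognormal(model.trigger_mean, model.trigger_cv, rng),
                birth_length=child_len,
                fluorescence=agent.fluorescence,
            )
        )
    return daughters[0], daughters[1]
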