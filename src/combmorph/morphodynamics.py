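"""Time-dependent rules layered on the Potts engine.

Epithelial cells do not sit at a fixed target area: every ``dt`` mcs the
target of each EP cell relaxes toward a type-specific terminal value,

    a_target(t + dt) = a_target(t) * (1 + (a_term / a_target(t) - 1) * dt/tau),

the Euler discretization of da/dt = (a_term - a)/tau.  Because the update is
exactly linear in a_target, the iterate has the closed form

    a_target(t) = a_term + (a0 - a_term) * (1 - dt/tau)^(t/dt),

which serves as the analytic oracle.  Each update also resets the target
length to ceil(sqrt(a_target)).  Types may start expanding late
(``expansion_delay``), the mechanism behind the delayed-EP1 rescue of long
combs.  Proximal EP3 cells squeezed below 3 pixels are extruded: their
target area and length collapse to 0 under a very large stiffness, so they
vanish from the epithelium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from ._kernels import EP3
from .cpm_core import TYPE_CODE, LatticeState


@dataclass(frozen=True)
class TypeParams:
    """Per-type mechanical parameters.

    ``a_target0_policy`` is either the string ``"initial-area"`` (the target
    starts at the cell's seeded area) or a fixed pixel count.  ``tau`` is the
    expansion (contraction) time constant in mcs; ``epsilon`` the axial
    preference strength; ``expansion_delay`` holds the type's target frozen
    until that time.  ``updates_enabled`` is False for SCT and BA, whose
    targets never change.
    """

    a_target0_policy: str | float = "initial-area"
    a_term: float = 0.0
    lambda_a: float = 0.0
    tau: float = math.inf
    epsilon: float = 0.0
    lambda_l: float = 0.0
    expansion_delay: int = 0
    updates_enabled: bool = False

    def __post_init__(self):
        if self.updates_enabled and not self.tau > 0:
            raise ValueError("tau must be positive for updatable types")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must lie in [0, 1)")

    def a_target0(self, initial_area: float) -> float:
        if self.a_target0_policy == "initial-area":
            return float(initial_area)
        return float(self.a_target0_policy)


@dataclass(frozen=True)
class ExpansionSchedule:
    """Update cadence and per-type parameters for one simulation."""

    type_params: Mapping[str, TypeParams]
    dt: int = 10
    extrusion_threshold: int = 3
    large_lambda: float = 1e6

    def __post_init__(self):
        if self.dt < 1:
            raise ValueError("dt must be >= 1 mcs")
        for name, tp in self.type_params.items():
            if tp.updates_enabled and not self.dt / tp.tau < 1:
                raise ValueError(
                    f"dt/tau must be < 1 for monotone convergence ({name})"
                )

    def with_delay(self, type_name: str, delay: int) -> "ExpansionSchedule":
        tp = dict(self.type_params)
        tp[type_name] = replace(tp[type_name], expansion_delay=int(delay))
        return replace(self, type_params=tp)


def closed_form_target(a0: float, a_term: float, tau: float, dt: float, t: float) -> float:
    """Exact solution of the target-area recurrence after t/dt updates."""
    if t % dt:
        raise ValueError("t must be a multiple of dt")
    if not dt / tau < 1:
        raise ValueError("dt/tau must be < 1")
    return a_term + (a0 - a_term) * (1.0 - dt / tau) ** (t / dt)


def update_targets(lattice: LatticeState, schedule: ExpansionSchedule, t: int) -> LatticeState:
    """One scheduled target update at time t (a multiple of dt), in place.

    Applies the Euler growth step to every live, non-extruded cell whose type
    has updates enabled and whose type's expansion_delay <= t, then resets
    l_target to ceil(sqrt(a_target)).  SCT and BA are never updated.
    """
    if t % schedule.dt:
        raise ValueError("update_targets must be called at multiples of dt")
    for name, tp in schedule.type_params.items():
        if not tp.updates_enabled or tp.expansion_delay > t:
            continue
        code = TYPE_CODE[name]
        mask = (lattice.ctype == code) & (lattice.area > 0) & ~lattice.extruded
        if not mask.any():
            continue
        a = lattice.a_target[mask]
        if np.any(a <= 0):
            raise ValueError(f"non-positive a_target for updatable type {name}")
        a = a * (1.0 + (tp.a_term / a - 1.0) * schedule.dt / tp.tau)
        lattice.a_target[mask] = a
        lattice.l_target[mask] = np.ceil(np.sqrt(a))
    return lattice


def apply_extrusion(lattice: LatticeState, schedule: ExpansionSchedule) -> LatticeState:
    """Mark EP3 cells whose area dropped strictly below the threshold as
    extruded: a_target = l_target = 0 under ``large_lambda`` stiffness.
    Marking is irreversible and removes the cell from future target updates.
    """
    mask = (
        (lattice.ctype == EP3)
        & (lattice.area > 0)
        & (lattice.area < schedule.extrusion_threshold)
        & ~lattice.extruded
    )
    if mask.any():
        lattice.a_target[mask] = 0.0
        lattice.l_target[mask] = 0.0
        lattice.lambda_a[mask] = schedule.large_lambda
        lattice.lambda_l[mask] = schedule.large_lambda
        lattice.extruded[mask] = True
    return lattice
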