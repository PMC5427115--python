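"""Pareto trade-off between two reaction objectives.

Secondary-metabolite synthesis competes with biomass assembly for the
same precursor pool; the trade-off is summarised by the Pareto front of
(growth rate μ, production rate q_p) pairs where neither flux can be
improved without degrading the other.  The front is traced stepwise:

1. the span [min, max] of objective *a* is found by flux variability,
2. *a* is clamped (lb = ub) at evenly spaced values across that span,
3. objective *b* is maximized at each clamp.

Sweeping with the objectives exchanged traces the same boundary from the
other side and is available through the ``direction`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fba import fba, fix_flux, fva
from .model import MetabolicModel


@dataclass
class ParetoPoint:
    fixed_value: float
    max_value: float | None
    status: str


@dataclass
class ParetoFront:
    objective_a_id: str  # the clamped objective
    objective_b_id: str  # the maximized objective
    direction: str  # "a_fixed" | "b_fixed"
    points: list[ParetoPoint] = field(default_factory=list)

    @property
    def feasible_points(self) -> list[ParetoPoint]:
        return [p for p in self.points if p.status == "optimal"]


def compute_pareto(
    model: MetabolicModel,
    objective_a_id: str,
    objective_b_id: str,
    n_steps: int = 20,
    direction: str = "a_fixed",
) -> ParetoFront:
    """Trace the front by clamping one objective and maximizing the other.

    ``n_steps`` clamp values are evenly spaced over the clamped
    objective's feasible [min, max] (endpoints included; ``n_steps=2``
    gives exactly the two single-objective extremes).  A clamp that makes
    the model infeasible is recorded as an infeasible point, never
    dropped silently.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if direction == "a_fixed":
        fixed_id, free_id = objective_a_id, objective_b_id
    elif direction == "b_fixed":
        fixed_id, free_id = objective_b_id, objective_a_id
    else:
        raise ValueError(f"unknown direction {direction!r}")
    model.reaction(fixed_id)
    model.reaction(free_id)

    span = fva(model, [fixed_id], fix_objective_fraction=0.0, objective_id=fixed_id)
    lo, hi = span[fixed_id]
    points = []
    for value in np.linspace(lo, hi, n_steps):
        clamped = fix_flux(model, fixed_id, float(value))
        res = fba(clamped, free_id, "max")
        points.append(
            ParetoPoint(
                fixed_value=float(value),
                max_value=res.objective_value if res.ok else None,
                status=res.status,
            )
        )
    return ParetoFront(
        objective_a_id=objective_a_id,
        objective_b_id=objective_b_id,
        direction=direction,
        points=points,
    )
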