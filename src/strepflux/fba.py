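"""Steady-state flux optimization: FBA, parsimonious FBA, FVA.

All problems share the constraint set S·v = 0, lb ≤ v ≤ ub and are solved
with the HiGHS simplex/IPM through scipy.  Flux units are
mmol·gDW⁻¹·h⁻¹ (h⁻¹ for the biomass pseudo-reaction).  Exchange fluxes
follow the usual sign convention: negative = uptake, positive = secretion.

Alternate optima are the rule, not the exception, in genome-scale LPs;
whenever a *flux vector* (not just an objective value) feeds a downstream
decision, the parsimonious representative from :func:`pfba_fluxes` —
minimum total |v| among the optima — is used so results are deterministic
and solver-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoich_matrix

#: solver feasibility / optimality tolerance
SOLVER_TOL = 1e-9
#: fluxes below this magnitude are treated as zero downstream
ZERO_FLUX_THRESHOLD = 1e-6


class FBAError(RuntimeError):
    """Raised when an optimization cannot be carried out or is not optimal."""


@dataclass
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_id: Optional[str] = None
    method: str = "fba"

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class MediumSpec:
    """A growth medium as exchange-reaction uptake capacities.

    ``components`` maps exchange reaction id -> maximum uptake (positive
    magnitude); applying the medium sets that exchange's lower bound to
    the negated magnitude.  With ``closed_default`` every exchange not
    listed has its uptake blocked (lb = 0) while secretion stays open.
    """

    components: dict[str, float]
    closed_default: bool = True

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.components.items() if v < 0}
        if bad:
            raise ValueError(f"uptake magnitudes must be >= 0: {bad}")


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of the model with the medium's uptake bounds applied."""
    exch = {r.id for r in model.exchange_reactions}
    unknown = sorted(set(medium.components) - exch)
    if unknown:
        raise KeyError(f"unknown exchange reactions in medium: {unknown}")
    out = model.copy()
    for r in out.reactions:
        if not r.is_exchange:
            continue
        if r.id in medium.components:
            r.lower_bound = -abs(medium.components[r.id])
        elif medium.closed_default:
            r.lower_bound = 0.0
    return out


def fix_flux(model: MetabolicModel, reaction_id: str, value: float) -> MetabolicModel:
    """Return a copy with the reaction clamped to lb = ub = value."""
    r = model.reaction(reaction_id)
    if not (r.lower_bound - 1e-12 <= value <= r.upper_bound + 1e-12):
        raise ValueError(
            f"cannot fix {reaction_id} at {value}: outside bounds "
            f"[{r.lower_bound}, {r.upper_bound}]"
        )
    out = model.copy()
    out.set_bounds(reaction_id, value, value)
    return out


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )
    return res


def _problem_arrays(model: MetabolicModel):
    sm = build_stoich_matrix(model)
    S = sm.matrix
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return sm, S, bounds


def fba(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    sense: str = "max",
) -> FluxResult:
    """Maximize (or minimize) one reaction's flux at steady state.

    The objective value is unique even when the flux vector is degenerate;
    the returned vector is one optimal basic solution.  Infeasibility and
    unboundedness are reported in ``status``, never silently.
    """
    objective_id = objective_id or model.objective_reaction_id
    if objective_id is None:
        raise ValueError("no objective reaction given and none set on the model")
    sm, S, bounds = _problem_arrays(model)
    if objective_id not in sm.reaction_index:
        raise KeyError(objective_id)
    n = len(model.reactions)
    c = np.zeros(n)
    sgn = -1.0 if sense == "max" else 1.0
    c[sm.reaction_index[objective_id]] = sgn
    res = _solve_lp(c, S, np.zeros(S.shape[0]), bounds)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        return FluxResult(status=status, objective_value=None,
                          objective_id=objective_id)
    fluxes = {r.id: float(res.x[sm.reaction_index[r.id]]) for r in model.reactions}
    return FluxResult(
        status="optimal",
        objective_value=float(sgn * res.fun) if sense == "min" else float(-res.fun),
        fluxes=fluxes,
        objective_id=objective_id,
    )


def pfba_fluxes(model: MetabolicModel, objective_id: Optional[str] = None) -> FluxResult:
    """Parsimonious FBA: among flux vectors attaining the FBA optimum
    (within 1e-9 relative), return one minimizing Σ|v_j|.

    Fluxes are split v = f − r with f, r ≥ 0 and Σ(f + r) minimized while
    the objective flux is pinned to its optimum; futile cycles that carry
    flux only because the LP tolerates them are driven to zero.
    """
    objective_id = objective_id or model.objective_reaction_id
    base = fba(model, objective_id, "max")
    if not base.ok:
        return base
    opt = base.objective_value
    sm, S, bounds = _problem_arrays(model)
    n = len(model.reactions)
    j_obj = sm.reaction_index[objective_id]
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])

    # variables [f; r], v = f - r
    S2 = sparse.hstack([S, -S]).tocsc()
    split_bounds = [(0.0, max(u, 0.0)) for u in ub] + [(0.0, max(-l, 0.0)) for l in lb]
    # original box on v = f - r (only needed where lb > 0 or ub < 0)
    rows, b_ub_rows = [], []
    eye = sparse.identity(n, format="csr")
    V = sparse.hstack([eye, -eye]).tocsr()
    A_ub = sparse.vstack([V, -V]).tocsc()
    b_ub = np.concatenate([ub, -lb])
    # pin the objective flux to its optimum (tiny relative slack)
    tol = max(SOLVER_TOL, abs(opt) * 1e-9)
    row = np.zeros(2 * n)
    row[j_obj] = 1.0
    row[n + j_obj] = -1.0
    A_ub = sparse.vstack([A_ub, sparse.csr_matrix(row), sparse.csr_matrix(-row)])
    b_ub = np.concatenate([b_ub, [opt + tol, -(opt - tol)]])

    c = np.ones(2 * n)
    res = _solve_lp(c, S2, np.zeros(S.shape[0]), split_bounds,
                    A_ub=A_ub.tocsc(), b_ub=b_ub)
    if res.status != 0:
        raise FBAError(f"pFBA step failed with status {_STATUS.get(res.status)}")
    v = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(v[sm.reaction_index[r.id]]) for r in model.reactions}
    return FluxResult(
        status="optimal",
        objective_value=opt,
        fluxes=fluxes,
        objective_id=objective_id,
        method="pfba",
    )


def fva(
    model: MetabolicModel,
    reaction_ids: Optional[Sequence[str]] = None,
    fix_objective_fraction: float = 0.0,
    objective_id: Optional[str] = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux subject to steady state, bounds, and
    objective ≥ fraction × optimum."""
    objective_id = objective_id or model.objective_reaction_id
    reaction_ids = list(reaction_ids) if reaction_ids is not None else model.reaction_ids
    sm, S, bounds = _problem_arrays(model)
    n = len(model.reactions)
    A_ub = None
    b_ub = None
    base = fba(model, objective_id, "max")
    if not base.ok:
        raise FBAError(f"model is {base.status}; cannot run FVA")
    row = np.zeros(n)
    row[sm.reaction_index[objective_id]] = -1.0
    A_ub = sparse.csr_matrix(row)
    b_ub = np.array([-fix_objective_fraction * base.objective_value])

    out: dict[str, tuple[float, float]] = {}
    zeros = np.zeros(S.shape[0])
    for rid in reaction_ids:
        j = sm.reaction_index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve_lp(c, S, zeros, bounds, A_ub=A_ub, b_ub=b_ub)
        hi = _solve_lp(-c, S, zeros, bounds, A_ub=A_ub, b_ub=b_ub)
        if lo.status != 0 or hi.status != 0:
            raise FBAError(f"FVA subproblem for {rid} not optimal")
        out[rid] = (float(lo.fun), float(-hi.fun))
    return out


def mass_balance_residual(model: MetabolicModel, fluxes: dict[str, float]) -> float:
    """max_i |Σ_j S_ij v_j| for a candidate flux vector."""
    sm = build_stoich_matrix(model)
    v = np.array([fluxes[r.id] for r in model.reactions])
    return float(np.max(np.abs(sm.matrix @ v))) if len(v) else 0.0
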