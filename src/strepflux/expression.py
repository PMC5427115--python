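"""Transcriptome integration: quartile thresholds, reaction classes, iMAT.

Per time point, the first and third quartiles of the RPKM distribution
split genes into lowly (< Q1) and highly (> Q3) expressed.  Gene levels
map onto reactions through the GPR (min over AND — a complex is as
expressed as its scarcest subunit; max over OR — isozymes substitute),
yielding HIGH / LOW / MODERATE reaction classes.  iMAT then searches,
by MILP, for a steady-state flux distribution maximally consistent with
the classes: a HIGH reaction scores when it carries at least ε flux in
either direction, a LOW reaction scores when it carries none, and any
experimentally measured rates (growth, product secretion) are clamped
before the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import ZERO_FLUX_THRESHOLD, apply_medium, fix_flux
from .media import SimulationConstraints
from .model import MetabolicModel, build_stoich_matrix

#: default minimum flux for a HIGH reaction to count as active
DEFAULT_EPSILON = 0.001

HIGH, LOW, MODERATE = "HIGH", "LOW", "MODERATE"


class ImatError(RuntimeError):
    pass


@dataclass
class ExpressionProfile:
    """RPKM values, genes × time points, thin wrapper over a DataFrame."""

    data: pd.DataFrame  # index: gene id; columns: time-point labels

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.data.columns)

    def values_at(self, timepoint: str) -> pd.Series:
        return self.data[timepoint].dropna()

    def model_overlap(self, model: MetabolicModel) -> float:
        """Fraction of model genes measured in the profile."""
        mg = model.genes
        if not mg:
            return 0.0
        return len(mg & set(self.genes)) / len(mg)

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionProfile":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if (df.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")
        return cls(data=df)

    def to_tsv(self, path: str) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def compute_thresholds(
    profile: ExpressionProfile, timepoint: str
) -> tuple[float, float]:
    """(Q1, Q3) of the RPKM distribution at one time point, using
    linear-interpolation quantiles over all genes in the table."""
    values = profile.values_at(timepoint).to_numpy()
    if len(values) < 4:
        raise ValueError(
            f"need >= 4 genes with values at {timepoint!r}, got {len(values)}"
        )
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return float(q1), float(q3)


def classify_reactions(
    model: MetabolicModel,
    profile: ExpressionProfile,
    thresholds: tuple[float, float],
    timepoint: str,
) -> dict[str, str]:
    """HIGH if the GPR-mapped expression exceeds Q3, LOW if below Q1,
    MODERATE otherwise.  Reactions with an empty GPR, or whose rule
    cannot be evaluated because a required gene is unmeasured, are
    MODERATE."""
    q1, q3 = thresholds
    if q1 > q3:
        raise ValueError(f"Q1 {q1} above Q3 {q3}")
    levels = profile.values_at(timepoint).to_dict()
    classes = {}
    for r in model.reactions:
        value = r.gpr.evaluate(levels) if not r.gpr.is_empty else None
        if value is None:
            classes[r.id] = MODERATE
        elif value > q3:
            classes[r.id] = HIGH
        elif value < q1:
            classes[r.id] = LOW
        else:
            classes[r.id] = MODERATE
    return classes


@dataclass
class ImatResult:
    status: str
    consistency_score: int
    fluxes: dict[str, float] = field(default_factory=dict)
    active: dict[str, bool] = field(default_factory=dict)
    constraints_used: Optional[SimulationConstraints] = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _apply_constraints(
    model: MetabolicModel, constraints: Optional[SimulationConstraints]
) -> MetabolicModel:
    work = model
    if constraints is None:
        return model.copy()
    if constraints.medium is not None:
        work = apply_medium(work, constraints.medium)
    else:
        work = work.copy()
    if constraints.growth_rate_fix is not None:
        work = fix_flux(work, work.objective_reaction_id, constraints.growth_rate_fix)
    if constraints.product_rate_fix is not None:
        if constraints.product_reaction_id is None:
            raise ValueError("product_rate_fix given without product_reaction_id")
        work = fix_flux(
            work, constraints.product_reaction_id, constraints.product_rate_fix
        )
    return work


def imat(
    model: MetabolicModel,
    classes: dict[str, str],
    constraints: Optional[SimulationConstraints] = None,
    epsilon: float = DEFAULT_EPSILON,
    zero_threshold: float = ZERO_FLUX_THRESHOLD,
) -> ImatResult:
    """Maximize the number of satisfied expression calls by MILP.

    For each HIGH reaction two binaries select forward (v ≥ ε) or
    reverse (v ≤ −ε) activation; for each LOW reaction one binary forces
    v = 0.  The score is the count of satisfied HIGH-active plus
    LOW-inactive calls subject to S·v = 0, bounds and any clamped rates.
    Big-M coefficients come from each reaction's own bounds; an
    infeasible problem (usually over-tight clamps) raises
    :class:`ImatError` naming the fixed rates.
    """
    work = _apply_constraints(model, constraints)
    sm = build_stoich_matrix(work)
    n = len(work.reactions)
    lb = np.array([r.lower_bound for r in work.reactions])
    ub = np.array([r.upper_bound for r in work.reactions])

    high_idx = [sm.reaction_index[rid] for rid, c in classes.items() if c == HIGH]
    low_idx = [sm.reaction_index[rid] for rid, c in classes.items() if c == LOW]
    n_bin = 2 * len(high_idx) + len(low_idx)
    n_var = n + n_bin

    rows, lo_list, hi_list = [], [], []

    def add_row(cols, coefs, lo, hi):
        row = np.zeros(n_var)
        row[cols] = coefs
        rows.append(row)
        lo_list.append(lo)
        hi_list.append(hi)

    # steady state
    S = sm.matrix.tocoo()
    A_eq = sparse.hstack(
        [sm.matrix, sparse.csr_matrix((S.shape[0], n_bin))]
    ).tocsr()

    b = n  # next free binary column
    obj = np.zeros(n_var)
    for j in high_idx:
        yf, yr = b, b + 1
        b += 2
        # yf = 1 -> v_j >= eps   (v_j + (lb_j - eps) * yf >= lb_j)
        add_row([j, yf], [1.0, lb[j] - epsilon], lb[j], np.inf)
        # yr = 1 -> v_j <= -eps  (v_j + (ub_j + eps) * yr <= ub_j)
        add_row([j, yr], [1.0, ub[j] + epsilon], -np.inf, ub[j])
        add_row([yf, yr], [1.0, 1.0], -np.inf, 1.0)
        obj[yf] = obj[yr] = -1.0  # milp minimizes
    for j in low_idx:
        z = b
        b += 1
        # z = 1 -> v_j = 0
        add_row([j, z], [1.0, ub[j]], -np.inf, ub[j])
        add_row([j, z], [1.0, lb[j]], lb[j], np.inf)
        obj[z] = -1.0

    constraints_list = [
        LinearConstraint(A_eq, np.zeros(A_eq.shape[0]), np.zeros(A_eq.shape[0]))
    ]
    if rows:
        constraints_list.append(
            LinearConstraint(np.vstack(rows), np.array(lo_list), np.array(hi_list))
        )
    bounds = Bounds(
        np.concatenate([lb, np.zeros(n_bin)]),
        np.concatenate([ub, np.ones(n_bin)]),
    )
    integrality = np.concatenate([np.zeros(n), np.ones(n_bin)])
    res = milp(
        c=obj,
        constraints=constraints_list,
        bounds=bounds,
        integrality=integrality,
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0:
        fixed = []
        if constraints is not None:
            if constraints.growth_rate_fix is not None:
                fixed.append(f"growth={constraints.growth_rate_fix}")
            if constraints.product_rate_fix is not None:
                fixed.append(
                    f"{constraints.product_reaction_id}={constraints.product_rate_fix}"
                )
        raise ImatError(
            "iMAT MILP has no feasible solution"
            + (f" under fixed rates ({', '.join(fixed)})" if fixed else "")
        )
    v = res.x[:n]
    fluxes = {r.id: float(v[sm.reaction_index[r.id]]) for r in work.reactions}
    active = {rid: abs(f) > zero_threshold for rid, f in fluxes.items()}
    return ImatResult(
        status="optimal",
        consistency_score=int(round(-res.fun)),
        fluxes=fluxes,
        active=active,
        constraints_used=constraints,
    )


@dataclass
class ActivityCensus:
    n_active: int
    per_subsystem: dict[str, int]


def census_active(
    result: ImatResult,
    model: MetabolicModel,
    zero_threshold: float = ZERO_FLUX_THRESHOLD,
) -> ActivityCensus:
    """Count flux-carrying reactions (|v| > threshold), overall and per
    subsystem (pathway-level activity summary)."""
    per_subsystem: dict[str, int] = {}
    n_active = 0
    for r in model.reactions:
        if abs(result.fluxes.get(r.id, 0.0)) > zero_threshold:
            n_active += 1
            key = r.subsystem or "(unassigned)"
            per_subsystem[key] = per_subsystem.get(key, 0) + 1
    return ActivityCensus(n_active=n_active, per_subsystem=per_subsystem)


def census_summary(counts: list[int]) -> tuple[float, float]:
    """Mean and (sample) standard deviation of per-time-point active
    reaction counts."""
    arr = np.asarray(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd
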