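"""In-memory representation of genome-scale metabolic models.

A model is a set of metabolites, a set of reactions carrying stoichiometry,
flux bounds (mmol·gDW⁻¹·h⁻¹) and an optional GPR rule, plus an objective
reaction (typically biomass assembly, whose flux is the specific growth
rate μ in h⁻¹).  Mass balance at pseudo-steady state is expressed through
the m×n stoichiometric matrix S: S·v = 0 with lb ≤ v ≤ ub per reaction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
from scipy import sparse

from .gpr import EMPTY_GPR, GPRNode, parse_gpr

# COBRA-convention default bounds when a file does not state them
DEFAULT_UB = 1000.0
DEFAULT_LB_REVERSIBLE = -1000.0


class ValidationError(ValueError):
    """Raised when a model violates its structural invariants."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None


@dataclass
class Reaction:
    """A reaction with stoichiometry, bounds and gene association.

    ``stoichiometry`` maps metabolite id -> coefficient (negative =
    consumed).  ``is_exchange`` marks boundary reactions that exchange a
    single metabolite with the environment (negative flux = uptake).
    ``is_gap_fill`` marks reactions added without gene evidence to make
    the network functional; by construction their GPR is empty.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UB
    gpr: GPRNode = EMPTY_GPR
    name: str = ""
    subsystem: str = ""
    is_exchange: bool = False
    is_gap_fill: bool = False

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes

    @property
    def is_gene_associated(self) -> bool:
        return not self.gpr.is_empty

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    name: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction_id: Optional[str] = None

    # -- lookups ----------------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    # -- mutation helpers (return new reaction objects, never shared) ----
    def set_bounds(self, rxn_id: str, lb: float, ub: float) -> None:
        r = self.reaction(rxn_id)
        r.lower_bound = lb
        r.upper_bound = ub


@dataclass
class StoichMatrix:
    """Sparse m×n stoichiometric matrix with id -> index maps."""

    matrix: sparse.csc_matrix
    metabolite_index: dict[str, int]
    reaction_index: dict[str, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def column(self, rxn_id: str) -> dict[str, float]:
        """Reconstruct a reaction's stoichiometry map from its column."""
        j = self.reaction_index[rxn_id]
        col = self.matrix.getcol(j).tocoo()
        inv = {v: k for k, v in self.metabolite_index.items()}
        return {inv[i]: float(x) for i, x in zip(col.row, col.data)}


def detect_exchanges(model: MetabolicModel) -> None:
    """Flag single-metabolite boundary reactions as exchanges, in place."""
    for r in model.reactions:
        if len(r.stoichiometry) == 1:
            r.is_exchange = True


def flag_gap_fills(model: MetabolicModel) -> None:
    """A reaction is gap-fill iff its GPR is empty and it is not an
    exchange/sink; in-place annotation used when a file carries no
    explicit gap-fill markup."""
    for r in model.reactions:
        r.is_gap_fill = r.gpr.is_empty and not r.is_exchange


def validate(model: MetabolicModel) -> MetabolicModel:
    """Check structural invariants, raising ValidationError on the first
    class of violation found (with every offending element listed)."""
    if not model.reactions:
        raise ValidationError("empty model: no reactions")
    dup_m = _duplicates(model.metabolite_ids)
    if dup_m:
        raise ValidationError(f"duplicate metabolite ids: {sorted(dup_m)}")
    dup_r = _duplicates(model.reaction_ids)
    if dup_r:
        raise ValidationError(f"duplicate reaction ids: {sorted(dup_r)}")
    met_ids = set(model.metabolite_ids)
    dangling = []
    for r in model.reactions:
        for mid in r.stoichiometry:
            if mid not in met_ids:
                dangling.append(f"{r.id}->{mid}")
    if dangling:
        raise ValidationError(f"dangling metabolite references: {dangling}")
    bad_bounds = [r.id for r in model.reactions if r.lower_bound > r.upper_bound]
    if bad_bounds:
        raise ValidationError(f"lower bound above upper bound: {bad_bounds}")
    bad_exch = [
        r.id for r in model.reactions if r.is_exchange and len(r.stoichiometry) != 1
    ]
    if bad_exch:
        raise ValidationError(f"exchange reactions with >1 metabolite: {bad_exch}")
    if model.objective_reaction_id is not None:
        if model.objective_reaction_id not in set(model.reaction_ids):
            raise ValidationError(
                f"objective reaction {model.objective_reaction_id!r} not in model"
            )
    return model


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for i in ids:
        if i in seen:
            dups.add(i)
        seen.add(i)
    return dups


def build_stoich_matrix(model: MetabolicModel) -> StoichMatrix:
    """Assemble S with rows in metabolite order and columns in reaction
    order; entry (i, j) is the coefficient of metabolite i in reaction j."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
    rows, cols, data = [], [], []
    for r in model.reactions:
        j = rxn_index[r.id]
        for mid, coef in r.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(float(coef))
    mat = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return StoichMatrix(matrix=mat, metabolite_index=met_index, reaction_index=rxn_index)


def model_stats(model: MetabolicModel) -> dict[str, int]:
    """Summary counts in the style of a reconstruction's features table."""
    gene_assoc = sum(1 for r in model.reactions if r.is_gene_associated)
    n_rxn = len(model.reactions)
    return {
        "n_genes": len(model.genes),
        "n_reactions": n_rxn,
        "n_gene_associated": gene_assoc,
        "n_non_gene_associated": n_rxn - gene_assoc,
        "n_exchange": sum(1 for r in model.reactions if r.is_exchange),
        "n_metabolites": len(model.metabolites),
    }
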