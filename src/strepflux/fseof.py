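"""FSEOF — flux scanning with enforced objective flux.

Candidate overexpression targets for product overproduction are the
reactions whose flux rises as product formation is forced upward while
the cell still maximizes growth.  The scan:

1. baseline — product flux clamped at its measured rate, biomass
   maximized, parsimonious fluxes recorded (step 0);
2. the theoretical maximum product rate v* is computed;
3. the product clamp is ramped in n evenly spaced steps from the
   measured rate up to v* (endpoint included, baseline excluded),
   biomass re-maximized and parsimonious fluxes recorded at each step.

A reaction is *selected* when its |flux| exceeds the baseline in at
least one enforcement step and every non-zero flux in its profile keeps
one sign (the reaction never reverses direction).  Selected reactions
then pass three engineering filters: no gap-filled (gene-less)
reactions, no exchange reactions, and no reactions whose GPR involves
more than one gene (complexes or paralogs) — only single-gene reactions
give an unambiguous amplification target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fba import (
    FBAError,
    MediumSpec,
    ZERO_FLUX_THRESHOLD,
    apply_medium,
    fba,
    fix_flux,
    pfba_fluxes,
)
from .model import MetabolicModel


@dataclass
class FseofConfig:
    product_reaction_id: str
    base_product_rate: float  # the measured rate, mmol·gDW⁻¹·h⁻¹
    n_enforced_steps: int = 10
    medium: Optional[MediumSpec] = None
    zero_threshold: float = ZERO_FLUX_THRESHOLD

    def __post_init__(self) -> None:
        if self.base_product_rate < 0:
            raise ValueError("base product rate must be >= 0")
        if self.n_enforced_steps < 2:
            raise ValueError("need at least 2 enforcement steps")


@dataclass
class FseofTarget:
    reaction_id: str
    flux_profile: np.ndarray  # length n_enforced_steps + 1, index 0 = baseline
    selected: bool
    genes: frozenset[str]
    exclusion_reason: Optional[str] = None  # gap_fill | exchange | multi_gene

    @property
    def slope(self) -> float:
        """Mean increase of |flux| per enforcement step."""
        prof = np.abs(self.flux_profile)
        return float((prof[-1] - prof[0]) / (len(prof) - 1))


def fseof_scan(model: MetabolicModel, config: FseofConfig) -> list[FseofTarget]:
    """Run the enforced-objective scan; returns one (unfiltered) target
    per model reaction with its full flux profile and selection verdict.

    Parsimonious fluxes are recorded at every step so the profile — and
    hence the selected set — does not depend on which alternate optimum
    a solver happens to return.
    """
    biomass_id = model.objective_reaction_id
    if biomass_id is None:
        raise ValueError("model has no objective (biomass) reaction")
    work = apply_medium(model, config.medium) if config.medium else model.copy()
    work.reaction(config.product_reaction_id)

    vmax_res = fba(work, config.product_reaction_id, "max")
    if not vmax_res.ok:
        raise FBAError(f"product maximization is {vmax_res.status}")
    v_star = vmax_res.objective_value
    base = config.base_product_rate
    if base > v_star + 1e-9:
        raise FBAError(
            f"base product rate {base} exceeds the theoretical maximum {v_star}"
        )

    n = config.n_enforced_steps
    enforced = [base + k * (v_star - base) / n for k in range(n + 1)]
    profiles = np.zeros((len(work.reactions), n + 1))
    for k, rate in enumerate(enforced):
        step_model = fix_flux(work, config.product_reaction_id, rate)
        sol = pfba_fluxes(step_model, biomass_id)
        if not sol.ok:
            raise FBAError(f"enforcement step {k} ({rate:g}) is {sol.status}")
        profiles[:, k] = [sol.fluxes[r.id] for r in work.reactions]

    thr = config.zero_threshold
    targets = []
    for i, r in enumerate(work.reactions):
        prof = profiles[i]
        nonzero = prof[np.abs(prof) > thr]
        same_sign = len(nonzero) == 0 or (nonzero > 0).all() or (nonzero < 0).all()
        increased = np.abs(prof[1:]).max(initial=0.0) > abs(prof[0]) + thr
        targets.append(
            FseofTarget(
                reaction_id=r.id,
                flux_profile=prof.copy(),
                selected=bool(increased and same_sign),
                genes=r.genes,
            )
        )
    return targets


def filter_targets(
    targets: list[FseofTarget], model: MetabolicModel
) -> tuple[list[FseofTarget], list[str]]:
    """Apply the engineering filters to the selected targets.

    Excluded targets get their ``exclusion_reason`` set (gap_fill,
    exchange, or multi_gene); returns the surviving targets and the
    sorted union of their (single) genes.
    """
    kept = []
    for t in targets:
        if not t.selected:
            continue
        r = model.reaction(t.reaction_id)
        if r.is_gap_fill:
            t.exclusion_reason = "gap_fill"
        elif r.is_exchange:
            t.exclusion_reason = "exchange"
        elif r.gpr.has_and or r.gpr.has_or or len(r.genes) >= 2:
            t.exclusion_reason = "multi_gene"
        else:
            kept.append(t)
    genes = sorted({g for t in kept for g in t.genes})
    return kept, genes


def report_targets(
    filtered: list[FseofTarget], model: MetabolicModel
) -> pd.DataFrame:
    """Tabulate surviving targets ranked by flux-increase slope
    (Δ|v| per enforcement step), ties broken by reaction id."""
    rows = []
    for t in filtered:
        r = model.reaction(t.reaction_id)
        rows.append(
            {
                "reaction_id": t.reaction_id,
                "name": r.name,
                "subsystem": r.subsystem,
                "genes": ";".join(sorted(t.genes)),
                "slope": t.slope,
                "baseline_flux": float(t.flux_profile[0]),
                "max_enforced_flux": float(np.abs(t.flux_profile).max()),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "reaction_id",
            "name",
            "subsystem",
            "genes",
            "slope",
            "baseline_flux",
            "max_enforced_flux",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["slope", "reaction_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
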