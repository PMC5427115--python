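"""Reading and writing metabolic models.

Two on-disk dialects are supported:

* **SBML** — Level 3 with the fbc package preferred, with the usual
  Level-2 notes-field fallbacks for bounds and GPR.  Parsing and
  serialisation are delegated to cobrapy's SBML layer, which handles
  both dialects; models are converted to/from the package's own types.
* **native TSV** — a hand-writable reactions table (id, name, equation,
  lower_bound, upper_bound, gpr, subsystem) with an optional metabolites
  table, intended for small hand-built fixtures.

Identifiers are taken verbatim; duplicate ids are errors.
"""

from __future__ import annotations

import csv
import os
import re
from typing import Optional

from .gpr import parse_gpr
from .model import (
    DEFAULT_LB_REVERSIBLE,
    DEFAULT_UB,
    MetabolicModel,
    Metabolite,
    Reaction,
    ValidationError,
    detect_exchanges,
    flag_gap_fills,
    validate,
)


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


REACTION_COLUMNS = [
    "id",
    "name",
    "equation",
    "lower_bound",
    "upper_bound",
    "gpr",
    "subsystem",
]
METABOLITE_COLUMNS = ["id", "name", "compartment", "formula"]


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_model(path: str, format: Optional[str] = None) -> MetabolicModel:
    """Load and validate a model from SBML or the native TSV format.

    ``format`` is ``"sbml"`` or ``"tsv"``; when None it is inferred from
    the extension (``.xml``/``.sbml`` -> sbml, ``.tsv`` or a directory ->
    tsv).  Exchange reactions are detected (single-metabolite boundary
    reactions) and gap-fill status is derived from GPR absence when the
    file does not state it.
    """
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        model = _read_sbml(path)
    elif fmt == "tsv":
        model = _read_tsv(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    detect_exchanges(model)
    flag_gap_fills(model)
    return validate(model)


def write_model(model: MetabolicModel, path: str, format: Optional[str] = None) -> None:
    """Serialise a model to SBML (L3-fbc) or the native TSV format."""
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "tsv":
        _write_tsv(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def _infer_format(path: str) -> str:
    if os.path.isdir(path) or path.endswith(".tsv"):
        return "tsv"
    if path.endswith((".xml", ".sbml")):
        return "sbml"
    raise ValueError(f"cannot infer model format from path {path!r}")


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _read_sbml(path: str) -> MetabolicModel:
    import cobra.io

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        cm = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises its own hierarchy
        raise ParseError(f"cannot parse SBML file {path!r}: {exc}") from exc
    return from_cobra(cm)


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), path)


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model into the package's own representation."""
    from cobra.util.solver import linear_reaction_coefficients

    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            formula=m.formula or None,
        )
        for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        rxns.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule or ""),
                subsystem=r.subsystem or "",
                is_exchange=bool(r.boundary),
            )
        )
    objective_id = None
    coeffs = linear_reaction_coefficients(cm)
    if coeffs:
        objective_id = max(coeffs, key=lambda r: abs(coeffs[r])).id
    return MetabolicModel(
        name=cm.id or cm.name or "model",
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=objective_id,
    )


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML output and as the bridge
    to independent LP cross-checks)."""
    import cobra

    cm = cobra.Model(model.name)
    cmets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c",
                               formula=m.formula)
        for m in model.metabolites
    }
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        cr.add_metabolites({cmets[mid]: c for mid, c in r.stoichiometry.items()})
        cr.subsystem = r.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    # GPR assignment needs the reactions to be in the model already
    for r in model.reactions:
        rule = r.gpr.to_string()
        if rule:
            cm.reactions.get_by_id(r.id).gene_reaction_rule = rule
    if model.objective_reaction_id:
        cm.objective = model.objective_reaction_id
    return cm


# ---------------------------------------------------------------------------
# native TSV
# ---------------------------------------------------------------------------

_ARROWS = ["<->", "<=>", "-->", "->", "=>"]


def _read_tsv(path: str) -> MetabolicModel:
    if os.path.isdir(path):
        rxn_path = os.path.join(path, "reactions.tsv")
        met_path = os.path.join(path, "metabolites.tsv")
    else:
        rxn_path = path
        met_path = os.path.join(os.path.dirname(path), "metabolites.tsv")
    if not os.path.exists(rxn_path):
        raise FileNotFoundError(rxn_path)

    mets: dict[str, Metabolite] = {}
    if os.path.exists(met_path):
        with open(met_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                mid = row["id"].strip()
                mets[mid] = Metabolite(
                    id=mid,
                    name=(row.get("name") or "").strip(),
                    compartment=(row.get("compartment") or "c").strip() or "c",
                    formula=(row.get("formula") or "").strip() or None,
                )

    rxns: list[Reaction] = []
    objective_id = None
    with open(rxn_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ParseError(f"{rxn_path!r}: missing header with an 'id' column")
        for row in reader:
            rid = row["id"].strip()
            if not rid:
                continue
            try:
                stoich, reversible = _parse_equation(row.get("equation", ""))
            except ValueError as exc:
                raise ParseError(f"{rxn_path!r}, reaction {rid!r}: {exc}") from exc
            lb = _parse_bound(row.get("lower_bound"),
                              DEFAULT_LB_REVERSIBLE if reversible else 0.0)
            ub = _parse_bound(row.get("upper_bound"), DEFAULT_UB)
            rxns.append(
                Reaction(
                    id=rid,
                    name=(row.get("name") or "").strip(),
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    gpr=parse_gpr(row.get("gpr") or ""),
                    subsystem=(row.get("subsystem") or "").strip(),
                )
            )
            if (row.get("objective") or "").strip() in ("1", "true", "yes"):
                objective_id = rid

    # metabolites not declared explicitly are inferred from equations,
    # compartment taken from a short trailing _x tag when present
    for r in rxns:
        for mid in r.stoichiometry:
            if mid not in mets:
                mets[mid] = Metabolite(id=mid, compartment=_infer_compartment(mid))

    name = os.path.splitext(os.path.basename(rxn_path))[0]
    return MetabolicModel(
        name=name,
        metabolites=list(mets.values()),
        reactions=rxns,
        objective_reaction_id=objective_id,
    )


def _parse_bound(raw: Optional[str], default: float) -> float:
    raw = (raw or "").strip()
    return float(raw) if raw else default


def _infer_compartment(met_id: str) -> str:
    m = re.search(r"_([a-z]{1,2})$", met_id)
    return m.group(1) if m else "c"


def _parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A_c + B_c --> C_c"``; ``<->``/``<=>`` mark reversibility.
    One side may be empty (exchange/sink)."""
    text = text.strip()
    if not text:
        raise ValueError("empty equation")
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ValueError(f"no arrow in equation {text!r}")
    reversible = arrow in ("<->", "<=>")
    left, right = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, mid = 1.0, parts[0]
            elif len(parts) == 2:
                coef, mid = float(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if not stoich:
        raise ValueError(f"equation {text!r} cancels to nothing")
    return stoich, reversible


def _format_equation(r: Reaction) -> str:
    def fmt(coef: float) -> str:
        c = abs(coef)
        return "" if c == 1.0 else (f"{c:g} ")

    left = " + ".join(
        f"{fmt(c)}{mid}" for mid, c in sorted(r.stoichiometry.items()) if c < 0
    )
    right = " + ".join(
        f"{fmt(c)}{mid}" for mid, c in sorted(r.stoichiometry.items()) if c > 0
    )
    arrow = "<->" if r.reversible else "-->"
    return f"{left} {arrow} {right}".strip()


def _write_tsv(model: MetabolicModel, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "reactions.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REACTION_COLUMNS + ["objective"])
        for r in model.reactions:
            w.writerow(
                [
                    r.id,
                    r.name,
                    _format_equation(r),
                    f"{r.lower_bound:g}",
                    f"{r.upper_bound:g}",
                    r.gpr.to_string(),
                    r.subsystem,
                    "1" if r.id == model.objective_reaction_id else "",
                ]
            )
    with open(os.path.join(path, "metabolites.tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(METABOLITE_COLUMNS)
        for m in model.metabolites:
            w.writerow([m.id, m.name, m.compartment, m.formula or ""])
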