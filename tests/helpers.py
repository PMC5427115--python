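"""Independent oracles and random-instance generators for the test suite.

Nothing here calls back into the package's LP/MILP code paths: the FBA
oracle enumerates polytope vertices directly, and the iMAT oracle checks
LP feasibility of every activity pattern with a plain scipy call on
explicitly assembled arrays.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog

from strepflux import MetabolicModel, Metabolite, Reaction
from strepflux.gpr import parse_gpr
from strepflux.model import detect_exchanges, flag_gap_fills, validate


def build_model(
    reactions: dict[str, dict],
    objective: str | None = None,
    name: str = "test",
) -> MetabolicModel:
    """Compact model builder: {rid: {"stoich": {...}, "lb":, "ub":, "gpr":}}."""
    mets: dict[str, Metabolite] = {}
    rxns = []
    for rid, spec in reactions.items():
        stoich = spec["stoich"]
        for mid in stoich:
            if mid not in mets:
                comp = "e" if mid.endswith("_e") else "c"
                mets[mid] = Metabolite(mid, compartment=comp)
        rxns.append(
            Reaction(
                rid,
                dict(stoich),
                lower_bound=spec.get("lb", 0.0),
                upper_bound=spec.get("ub", 1000.0),
                gpr=parse_gpr(spec.get("gpr", "")),
                subsystem=spec.get("subsystem", ""),
            )
        )
    model = MetabolicModel(
        name=name,
        metabolites=list(mets.values()),
        reactions=rxns,
        objective_reaction_id=objective,
    )
    detect_exchanges(model)
    flag_gap_fills(model)
    return validate(model)


def model_arrays(model: MetabolicModel):
    """Dense S, lb, ub assembled directly from reaction dicts (no call
    into the package's matrix builder)."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    n = len(model.reactions)
    S = np.zeros((len(model.metabolites), n))
    for j, r in enumerate(model.reactions):
        for mid, c in r.stoichiometry.items():
            S[met_index[mid], j] = c
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub


def vertex_enumeration_max(S, lb, ub, c, tol=1e-8):
    """Exhaustive maximum of c·v over {S v = 0, lb ≤ v ≤ ub}.

    With all bounds finite, the optimum is attained at a vertex where
    n − rank(S) variables sit at a bound; every such choice is
    enumerated and solved for the remaining (basic) variables.
    Infeasible or inconsistent choices are discarded.
    """
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    best = None
    for nonbasic in combinations(range(n), n - r):
        basic = [j for j in range(n) if j not in nonbasic]
        B = S[:, basic]
        for vals in product(*[(lb[j], ub[j]) for j in nonbasic]):
            rhs = -S[:, nonbasic] @ np.array(vals)
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v = np.zeros(n)
            v[list(nonbasic)] = vals
            v[basic] = sol
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    return best


def random_lp_model(rng: np.random.Generator, max_reactions: int = 8):
    """A random small mass-balanced network with finite bounds that
    always admits v = 0, so the LP is feasible and bounded."""
    n = int(rng.integers(3, max_reactions + 1))
    m = int(rng.integers(2, min(n, 4) + 1))
    while True:
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        S[rng.random(size=S.shape) < 0.4] = 0.0
        if (np.abs(S).sum(axis=0) > 0).all() and (np.abs(S).sum(axis=1) > 0).all():
            break
    lb = -rng.integers(0, 11, size=n).astype(float)
    ub = rng.integers(1, 11, size=n).astype(float)
    mets = [Metabolite(f"m{i}_c") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {f"m{i}_c": S[i, j] for i in range(m) if S[i, j] != 0.0}
        rxns.append(Reaction(f"r{j}", stoich, lower_bound=lb[j], upper_bound=ub[j]))
    model = MetabolicModel(name="random_lp", metabolites=mets, reactions=rxns)
    validate(model)
    return model, S, lb, ub


def brute_force_imat_score(model, classes, constraints_fixed, epsilon):
    """Best consistency score over all HIGH/LOW activity patterns.

    Each HIGH reaction is tried inactive, forward-active (v ≥ ε) or
    reverse-active (v ≤ −ε); each LOW reaction inactive-scored (v = 0)
    or unscored.  Every pattern is checked for LP feasibility on
    explicitly assembled arrays; the score is the number of satisfied
    calls in the best feasible pattern.
    """
    S, lb, ub = model_arrays(model)
    lb, ub = lb.copy(), ub.copy()
    rid_index = {r.id: j for j, r in enumerate(model.reactions)}
    for rid, value in constraints_fixed.items():
        lb[rid_index[rid]] = ub[rid_index[rid]] = value
    high = [rid_index[rid] for rid, c in classes.items() if c == "HIGH"]
    low = [rid_index[rid] for rid, c in classes.items() if c == "LOW"]
    n = S.shape[1]
    best = -1
    for hi_pattern in product((0, 1, -1), repeat=len(high)):
        for lo_pattern in product((0, 1), repeat=len(low)):
            score = sum(1 for h in hi_pattern if h) + sum(lo_pattern)
            if score <= best:
                continue
            l, u = lb.copy(), ub.copy()
            ok = True
            for j, h in zip(high, hi_pattern):
                if h == 1:
                    l[j] = max(l[j], epsilon)
                elif h == -1:
                    u[j] = min(u[j], -epsilon)
                if l[j] > u[j]:
                    ok = False
            for j, z in zip(low, lo_pattern):
                if z:
                    l[j] = max(l[j], 0.0)
                    u[j] = min(u[j], 0.0)
                if l[j] > u[j]:
                    ok = False
            if not ok:
                continue
            res = linprog(
                np.zeros(n),
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(l, u)),
                method="highs",
            )
            if res.status == 0:
                best = score
    return max(best, 0)


def random_imat_instance(rng: np.random.Generator):
    """A random tiny model plus random HIGH/LOW calls (≤ 6 classified
    reactions so the pattern enumeration stays cheap)."""
    model, S, lb, ub = random_lp_model(rng, max_reactions=7)
    ids = [r.id for r in model.reactions]
    k = min(len(ids), 6)
    chosen = rng.choice(ids, size=k, replace=False)
    classes = {}
    for rid in ids:
        if rid in chosen:
            classes[rid] = "HIGH" if rng.random() < 0.5 else "LOW"
        else:
            classes[rid] = "MODERATE"
    return model, classes


def chain_model(uptake: float = 10.0) -> MetabolicModel:
    """∅ ↔ A, A → B, B → biomass drain at 1:1:1; optimum = uptake."""
    return build_model(
        {
            "EX_A": {"stoich": {"A_e": -1}, "lb": -uptake, "ub": 1000},
            "R1": {"stoich": {"A_e": -1, "B_c": 1}},
            "BIO": {"stoich": {"B_c": -1}},
        },
        objective="BIO",
    )
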