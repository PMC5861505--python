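"""Cofactor modification analysis (CMA): NAD(H) <-> NADP(H) specificity swaps.

Many oxidoreductases can in principle be engineered to prefer the other
nicotinamide cofactor.  CMA asks: which (at most *k*) reactions, when their
NAD(H)/NADP(H) specificity is swapped, most increase the attainable product
yield while biomass production stays above a floor?  Formally each eligible
reaction *j* gets a *cofactor-modified* twin whose stoichiometry equals the
original except that the NAD(H) and NADP(H) coefficients are exchanged
(``S^cMod_NADP(H),j = S_NAD(H),j`` and vice versa); a binary ``y_j`` routes
flux through either the original or the twin but not both::

    (1 - y_j) v_min <= v_j      <= (1 - y_j) v_max
         y_j  v_min <= v_j^cMod <=      y_j  v_max
    sum_j y_j <= k

The product objective is the turnover (flux-sum) of the product metabolite,
which for a product with a single secretion route reduces to its exchange
flux — the linear form used here.

Two interchangeable solution routes are provided: exhaustive enumeration over
swap sets (the default, exact for the small ``k`` used in practice) and a
single-level MILP with the binaries above.  They are required to agree and
are cross-checked in the test suite.

The growth side-condition is imposed as ``v_biomass >= v_biomass_min``
(``inner="floor"``, default).  A strict lexicographic mode — maximize biomass
first, then the product among growth-optimal states — is available via
``inner="lexicographic"`` for the enumeration route.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from cobra import Model, Reaction

from .fba import ConditionConstraints, applied_constraints, optimize, quiet_optimize

__all__ = [
    "CofactorPairs",
    "CofactorSwapResult",
    "DEFAULT_PAIRS",
    "swap_eligible_reactions",
    "build_swapped_model",
    "cma_optimize",
    "enumerate_swaps_oracle",
]

_TOL = 1e-9
TWIN_SUFFIX = "_cmod"

#: (nad, nadh, nadp, nadph) metabolite ids per compartment.
CofactorPairs = Sequence[tuple[str, str, str, str]]

DEFAULT_PAIRS: CofactorPairs = (("nad_c", "nadh_c", "nadp_c", "nadph_c"),)


@dataclass
class CofactorSwapResult:
    """Outcome of a CMA run."""

    swapped: tuple[str, ...]
    product_yield_baseline: float
    product_yield_swapped: float
    k_used: int
    biomass_floor: float
    tied: list[tuple[str, ...]] = field(default_factory=list)
    fluxes: pd.Series | None = None

    @property
    def improvement(self) -> float:
        return self.product_yield_swapped - self.product_yield_baseline


def _swap_map(model: Model, pairs: CofactorPairs) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for nad, nadh, nadp, nadph in pairs:
        for mid in (nad, nadh, nadp, nadph):
            if mid not in model.metabolites:
                raise ValueError(f"cofactor species {mid!r} missing from model")
        mapping[nad] = nadp
        mapping[nadp] = nad
        mapping[nadh] = nadph
        mapping[nadph] = nadh
    return mapping


def _is_biomass_like(model: Model, rxn: Reaction) -> bool:
    from cobra.util.solver import linear_reaction_coefficients

    return "biomass" in rxn.id.lower() or rxn in linear_reaction_coefficients(model)


def swap_eligible_reactions(
    model: Model,
    pairs: CofactorPairs = DEFAULT_PAIRS,
    direction: str = "both",
) -> list[str]:
    """Reactions touching NAD(H)/NADP(H) in a listed compartment, excluding
    exchanges/sinks and the biomass reaction.

    ``direction="both"`` lists every cofactor-coupled reaction;
    ``direction="nad_to_nadp"`` restricts to reactions that involve NAD(H),
    i.e. candidates for re-engineering toward NADP specificity (the
    NADPH-supply direction the strain-design question asks for; purely
    NADP(H)-dependent reactions such as fatty-acid synthases are then not
    candidates)."""
    if direction not in ("both", "nad_to_nadp"):
        raise ValueError("direction must be 'both' or 'nad_to_nadp'")
    mapping = _swap_map(model, pairs)
    nad_side = {pair[0] for pair in pairs} | {pair[1] for pair in pairs}
    out = []
    for rxn in model.reactions:
        if len(rxn.metabolites) <= 1 or _is_biomass_like(model, rxn):
            continue
        if rxn.id.endswith(TWIN_SUFFIX):
            continue
        met_ids = {met.id for met in rxn.metabolites}
        if direction == "nad_to_nadp":
            if met_ids & nad_side:
                out.append(rxn.id)
        elif met_ids & set(mapping):
            out.append(rxn.id)
    return sorted(out)


def _swapped_stoichiometry(
    model: Model, rxn: Reaction, mapping: dict[str, str]
) -> dict[str, float]:
    stoich: dict[str, float] = {}
    for met, coeff in rxn.metabolites.items():
        stoich[mapping.get(met.id, met.id)] = float(coeff)
    return stoich


def build_swapped_model(
    model: Model,
    pairs: CofactorPairs = DEFAULT_PAIRS,
    direction: str = "both",
) -> tuple[Model, dict[str, str]]:
    """Extend a copy of ``model`` with a cofactor-modified twin per eligible
    reaction.

    Twins carry the original's bounds; exclusivity between a reaction and its
    twin is *not* enforced here — it is imposed by the CMA optimizers (via
    binaries or by closing bounds during enumeration).

    Returns the extended model and a mapping original id -> twin id.
    """
    eligible = swap_eligible_reactions(model, pairs, direction)
    out = model.copy()
    mapping = _swap_map(out, pairs)
    twin_map: dict[str, str] = {}
    twins = []
    for rid in eligible:
        rxn = out.reactions.get_by_id(rid)
        twin = Reaction(rid + TWIN_SUFFIX, name=f"{rxn.name} (cofactor swapped)")
        twin.bounds = rxn.bounds
        twin.add_metabolites(
            {
                out.metabolites.get_by_id(mid): coeff
                for mid, coeff in _swapped_stoichiometry(out, rxn, mapping).items()
            }
        )
        if rxn.gene_reaction_rule:
            twin.gene_reaction_rule = rxn.gene_reaction_rule
        twins.append(twin)
        twin_map[rid] = twin.id
    out.add_reactions(twins)
    return out, twin_map


def _resolve_floor(
    model: Model,
    biomass_id: str | None,
    biomass_floor: float | None,
    floor_fraction: float,
    constraints: ConditionConstraints | None,
) -> float:
    if biomass_floor is not None:
        return float(biomass_floor)
    if biomass_id is None:
        return 0.0
    state = optimize(model, objective=biomass_id, constraints=constraints)
    if not state.optimal:
        raise RuntimeError(f"biomass LP for floor not optimal: {state.status}")
    return floor_fraction * state.objective_value


def _product_with_floor(
    model: Model,
    product_exchange: str,
    biomass_id: str | None,
    floor: float,
    constraints: ConditionConstraints | None,
    inner: str,
) -> tuple[float | None, pd.Series | None]:
    with applied_constraints(model, constraints):
        if biomass_id is not None and floor > 0:
            bio = model.reactions.get_by_id(biomass_id)
            iface = model.problem
            model.add_cons_vars(
                [iface.Constraint(bio.flux_expression, lb=floor - 1e-9, name="_cma_floor")]
            )
        if inner == "lexicographic" and biomass_id is not None:
            model.objective = biomass_id
            model.objective_direction = "max"
            sol = quiet_optimize(model)
            if sol.status != "optimal":
                return None, None
            iface = model.problem
            bio = model.reactions.get_by_id(biomass_id)
            model.add_cons_vars(
                [
                    iface.Constraint(
                        bio.flux_expression,
                        lb=float(sol.objective_value) - 1e-7,
                        name="_cma_lexi",
                    )
                ]
            )
        model.objective = product_exchange
        model.objective_direction = "max"
        sol = quiet_optimize(model)
        if sol.status != "optimal":
            return None, None
        return float(sol.objective_value), sol.fluxes.copy()


def cma_optimize(
    model: Model,
    product_exchange: str,
    k: int = 1,
    biomass_floor: float | None = None,
    floor_fraction: float = 0.1,
    constraints: ConditionConstraints | None = None,
    pairs: CofactorPairs = DEFAULT_PAIRS,
    biomass_id: str | None = None,
    method: str = "enumerate",
    inner: str = "floor",
    direction: str = "nad_to_nadp",
) -> CofactorSwapResult:
    """Find the best set of at most ``k`` cofactor swaps for a product.

    ``biomass_floor`` defaults to ``floor_fraction`` times the biomass
    optimum under the given constraints (0 when no biomass id is known).
    ``method="enumerate"`` (default) searches swap sets exhaustively and is
    exact; ``method="milp"`` solves the single-level MILP with binary swap
    indicators.  Ties within tolerance are broken by the lexicographically
    smallest swap set and all tied sets are reported.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if product_exchange not in model.reactions:
        raise ValueError(f"unknown product exchange {product_exchange!r}")
    biomass_id = biomass_id or (constraints.biomass_id if constraints else None)
    floor = _resolve_floor(model, biomass_id, biomass_floor, floor_fraction, constraints)

    baseline, _ = _product_with_floor(
        model, product_exchange, biomass_id, floor, constraints, inner
    )
    if baseline is None:
        raise RuntimeError("baseline product LP infeasible under the biomass floor")
    if k == 0:
        return CofactorSwapResult((), baseline, baseline, 0, floor)

    if method == "enumerate":
        return _cma_enumerate(
            model, product_exchange, k, floor, constraints, pairs, biomass_id,
            baseline, inner, direction,
        )
    if method == "milp":
        if inner != "floor":
            raise ValueError("the MILP route supports inner='floor' only")
        return _cma_milp(
            model, product_exchange, k, floor, constraints, pairs, biomass_id,
            baseline, direction,
        )
    raise ValueError(f"unknown method {method!r}")


def _cma_enumerate(
    model: Model,
    product_exchange: str,
    k: int,
    floor: float,
    constraints: ConditionConstraints | None,
    pairs: CofactorPairs,
    biomass_id: str | None,
    baseline: float,
    inner: str,
    direction: str,
) -> CofactorSwapResult:
    ext, twin_map = build_swapped_model(model, pairs, direction)
    # twins closed unless selected
    for twin_id in twin_map.values():
        ext.reactions.get_by_id(twin_id).bounds = (0.0, 0.0)
    original_bounds = {
        rid: model.reactions.get_by_id(rid).bounds for rid in twin_map
    }
    candidates = sorted(twin_map)

    def _evaluate(combo: tuple[str, ...]):
        with ext:
            for rid in combo:
                ext.reactions.get_by_id(rid).bounds = (0.0, 0.0)
                ext.reactions.get_by_id(twin_map[rid]).bounds = original_bounds[rid]
            return _product_with_floor(
                ext, product_exchange, biomass_id, floor, constraints, inner
            )

    results: list[tuple[float, tuple[str, ...]]] = []
    for size in range(1, k + 1):
        for combo in itertools.combinations(candidates, size):
            value, _ = _evaluate(combo)
            if value is not None:
                results.append((value, combo))
    best_value = max([baseline] + [v for v, _ in results])
    if best_value <= baseline + _TOL:
        tied: list[tuple[str, ...]] = [()]
        best_value = baseline
    else:
        tied = sorted(c for v, c in results if v >= best_value - _TOL)
    chosen = tied[0]
    _, best_fluxes = _evaluate(chosen) if chosen else (baseline, None)
    return CofactorSwapResult(
        swapped=chosen,
        product_yield_baseline=baseline,
        product_yield_swapped=best_value,
        k_used=k,
        biomass_floor=floor,
        tied=tied,
        fluxes=best_fluxes,
    )


def _cma_milp(
    model: Model,
    product_exchange: str,
    k: int,
    floor: float,
    constraints: ConditionConstraints | None,
    pairs: CofactorPairs,
    biomass_id: str | None,
    baseline: float,
    direction: str,
) -> CofactorSwapResult:
    ext, twin_map = build_swapped_model(model, pairs, direction)
    with applied_constraints(ext, constraints):
        iface = ext.problem
        cons_vars = []
        ys = {}
        for rid, twin_id in twin_map.items():
            orig = ext.reactions.get_by_id(rid)
            twin = ext.reactions.get_by_id(twin_id)
            lb, ub = orig.lower_bound, orig.upper_bound
            y = iface.Variable(f"_cma_y_{rid}", type="binary")
            ys[rid] = y
            cons_vars += [
                y,
                # v <= (1-y) ub  and  v >= (1-y) lb
                iface.Constraint(orig.flux_expression + ub * y, ub=ub),
                iface.Constraint(orig.flux_expression + lb * y, lb=lb),
                # v_twin <= y ub  and  v_twin >= y lb
                iface.Constraint(twin.flux_expression - ub * y, ub=0.0),
                iface.Constraint(twin.flux_expression - lb * y, lb=0.0),
            ]
        cons_vars.append(
            iface.Constraint(sum(ys.values()), ub=float(k), name="_cma_k")
        )
        if biomass_id is not None and floor > 0:
            bio = ext.reactions.get_by_id(biomass_id)
            cons_vars.append(
                iface.Constraint(bio.flux_expression, lb=floor - 1e-9, name="_cma_floor")
            )
        ext.add_cons_vars(cons_vars)
        ext.objective = product_exchange
        ext.objective_direction = "max"
        sol = quiet_optimize(ext)
        if sol.status != "optimal":
            raise RuntimeError(f"CMA MILP failed with status {sol.status}")
        value = float(sol.objective_value)
        swapped = tuple(sorted(rid for rid, y in ys.items() if y.primal > 0.5))
        fluxes = sol.fluxes.copy()
    if value < baseline - 1e-6:
        raise RuntimeError(
            "CMA MILP optimum below the no-swap baseline — reformulation gap"
        )
    if value <= baseline + _TOL:
        swapped = ()
        value = max(value, baseline)
    return CofactorSwapResult(
        swapped=swapped,
        product_yield_baseline=baseline,
        product_yield_swapped=value,
        k_used=k,
        biomass_floor=floor,
        tied=[swapped],
        fluxes=fluxes,
    )


def enumerate_swaps_oracle(
    model: Model,
    product_exchange: str,
    k: int = 1,
    biomass_floor: float | None = None,
    floor_fraction: float = 0.1,
    constraints: ConditionConstraints | None = None,
    pairs: CofactorPairs = DEFAULT_PAIRS,
    biomass_id: str | None = None,
    inner: str = "floor",
    direction: str = "nad_to_nadp",
) -> CofactorSwapResult:
    """Brute-force single-swap oracle.

    Independently of :func:`cma_optimize`, edits each eligible reaction's
    stoichiometry in place (no twin reactions, no binaries), re-solves the
    product LP under the biomass floor, and returns the argmax.  Scope is
    ``k = 1``; ties are reported with lexicographic tie-breaking.
    """
    if k != 1:
        raise ValueError("the brute-force oracle covers k = 1 only")
    if product_exchange not in model.reactions:
        raise ValueError(f"unknown product exchange {product_exchange!r}")
    biomass_id = biomass_id or (constraints.biomass_id if constraints else None)
    floor = _resolve_floor(model, biomass_id, biomass_floor, floor_fraction, constraints)
    baseline, _ = _product_with_floor(
        model, product_exchange, biomass_id, floor, constraints, inner
    )
    if baseline is None:
        raise RuntimeError("baseline product LP infeasible under the biomass floor")
    mapping_ids = swap_eligible_reactions(model, pairs, direction)
    best_value = baseline
    best_sets: list[tuple[str, ...]] = [()]
    for rid in mapping_ids:
        mutant = model.copy()
        mapping = _swap_map(mutant, pairs)
        rxn = mutant.reactions.get_by_id(rid)
        new_stoich = _swapped_stoichiometry(mutant, rxn, mapping)
        rxn.subtract_metabolites(dict(rxn.metabolites))
        rxn.add_metabolites(
            {mutant.metabolites.get_by_id(mid): c for mid, c in new_stoich.items()}
        )
        value, _ = _product_with_floor(
            mutant, product_exchange, biomass_id, floor, constraints, inner
        )
        if value is None:
            continue
        if value > best_value + _TOL:
            best_value, best_sets = value, [(rid,)]
        elif abs(value - best_value) <= _TOL and best_value > baseline + _TOL:
            best_sets.append((rid,))
    best_sets = sorted(set(best_sets))
    return CofactorSwapResult(
        swapped=best_sets[0],
        product_yield_baseline=baseline,
        product_yield_swapped=best_value,
        k_used=1,
        biomass_floor=floor,
        tied=best_sets,
    )
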