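"""Growth-coupled knockout search, transcriptomics-restoration scanning and
amino-acid supplementation analysis.

Three complementary strain-design strategies:

* :func:`knockout_local_search` — a local search over reaction-deletion sets
  (up to ``max_ko``) whose score is the product secretion guaranteed at
  growth-maximal states.  The inner response is pessimistic (the *minimum*
  product flux among growth-optimal states), so a positive score certifies
  growth coupling rather than reflecting an arbitrary solver vertex.
* :func:`build_context_model` / :func:`restoration_scan` — integrate an
  expression profile through the GPR rules (AND -> min, OR -> max), close the
  reactions whose expression falls below a percentile threshold to obtain a
  context-specific model, then ask which single closed reaction, when
  restored, most improves the product optimum.  Restored reactions are
  overexpression candidates: the cell has transcriptionally switched them
  off in the production condition even though the network could use them.
* :func:`supplementation_scan` — open an amino-acid uptake at a fixed
  C-mmol budget (the budget divided by the supplement's carbon number gives
  its molar rate), maximize the product, and report resolved fluxes plus the
  flux-sum turnover of a metabolite panel against a no-supplement baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cobra import Model

from .core import parse_formula
from .fba import (
    ConditionConstraints,
    FluxState,
    FluxSumProfile,
    applied_constraints,
    flux_sum,
    optimize,
    quiet_optimize,
    resolve_unique,
)
from .toys import ExpressionProfile

__all__ = [
    "KnockoutDesign",
    "RestorationTarget",
    "SupplementationReport",
    "knockout_local_search",
    "eligible_knockouts",
    "build_context_model",
    "reaction_expression",
    "restoration_scan",
    "supplementation_scan",
]

_TOL = 1e-6

#: Carbon numbers used when a supplement metabolite has no formula.
FALLBACK_CARBONS = {"leu": 6, "ile": 6, "val": 5}


@dataclass
class KnockoutDesign:
    deleted: tuple[str, ...]
    production_at_max_growth: float
    growth: float
    coupled: bool


@dataclass
class RestorationTarget:
    reaction_id: str
    yield_context: float
    yield_restored: float
    improvement_pct: float  # inf when the context yield is zero ("from zero")
    from_zero: bool = False


@dataclass
class SupplementationReport:
    """Per-supplement resolved state, product optimum and panel flux-sums."""

    conditions: dict[str, dict] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def product_optimum(self, condition: str) -> float:
        return self.conditions[condition]["product_optimum"]

    def fluxsum(self, condition: str, metabolite_id: str) -> float:
        return float(self.conditions[condition]["flux_sums"][metabolite_id])

    def heatmap_table(self) -> pd.DataFrame:
        """Rows = panel metabolites (flux-sum), columns = conditions."""
        data = {
            cond: info["flux_sums"] for cond, info in self.conditions.items()
        }
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Growth-coupled knockout local search


def eligible_knockouts(
    model: Model,
    biomass_id: str,
    maintenance_id: str | None = None,
    require_gpr: bool = True,
) -> list[str]:
    """Deletion candidates: non-exchange, non-biomass, non-maintenance
    reactions, by default only those with a gene association (spontaneous
    reactions cannot be knocked out)."""
    out = []
    for rxn in model.reactions:
        if len(rxn.metabolites) <= 1:
            continue
        if rxn.id == biomass_id or "biomass" in rxn.id.lower():
            continue
        if maintenance_id is not None and rxn.id == maintenance_id:
            continue
        if require_gpr and not rxn.gene_reaction_rule:
            continue
        out.append(rxn.id)
    return sorted(out)


def score_deletion_set(
    model: Model,
    deletions: Sequence[str],
    product_exchange: str,
    biomass_id: str,
    constraints: ConditionConstraints | None = None,
) -> tuple[float, float] | None:
    """Pessimistic score of a deletion set.

    Returns ``(min product flux at growth-maximal states, max growth)`` or
    ``None`` when the deletions make the model infeasible.
    """
    with applied_constraints(model, constraints):
        for rid in deletions:
            model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        model.objective = biomass_id
        model.objective_direction = "max"
        sol = quiet_optimize(model)
        if sol.status != "optimal":
            return None
        mu = float(sol.objective_value)
        iface = model.problem
        bio = model.reactions.get_by_id(biomass_id)
        model.add_cons_vars(
            [iface.Constraint(bio.flux_expression, lb=mu - 1e-7, name="_ko_mu")]
        )
        model.objective = product_exchange
        model.objective_direction = "min"
        sol = quiet_optimize(model)
        if sol.status != "optimal":
            return None
        return float(sol.objective_value), mu


def knockout_local_search(
    model: Model,
    product_exchange: str,
    max_ko: int = 5,
    neighborhood: int = 1,
    constraints: ConditionConstraints | None = None,
    biomass_id: str | None = None,
    maintenance_id: str | None = None,
    eligible: Iterable[str] | None = None,
) -> KnockoutDesign:
    """Iterated local search over reaction-deletion sets.

    Starting from no deletions, all neighbors within ``neighborhood``
    single-element moves (add, drop, or swap one deletion) are scored; the
    search moves to the best strictly improving neighbor and stops at a local
    optimum.  Candidate ordering is lexicographic, making the search
    deterministic.
    """
    biomass_id = biomass_id or (constraints.biomass_id if constraints else None)
    if biomass_id is None:
        raise ValueError("knockout search needs a biomass reaction id")
    if eligible is None:
        eligible = eligible_knockouts(model, biomass_id, maintenance_id)
    candidates = sorted(eligible)
    if neighborhood < 1:
        raise ValueError("neighborhood must be >= 1")

    current: tuple[str, ...] = ()
    base = score_deletion_set(model, current, product_exchange, biomass_id, constraints)
    if base is None:
        raise RuntimeError("wild-type model infeasible under the given constraints")
    current_score = base

    def _neighbors(dels: tuple[str, ...]):
        dset = set(dels)
        if len(dels) < max_ko:
            for rid in candidates:
                if rid not in dset:
                    yield tuple(sorted(dset | {rid}))
        for rid in dels:
            yield tuple(sorted(dset - {rid}))
        for old in dels:
            for new in candidates:
                if new not in dset:
                    yield tuple(sorted((dset - {old}) | {new}))

    while True:
        best_move: tuple[str, ...] | None = None
        best_score = current_score
        for cand in sorted(set(_neighbors(current))):
            score = score_deletion_set(
                model, cand, product_exchange, biomass_id, constraints
            )
            if score is None:
                continue
            if score[0] > best_score[0] + _TOL:
                best_move, best_score = cand, score
        if best_move is None:
            break
        current, current_score = best_move, best_score

    production, growth = current_score
    return KnockoutDesign(
        deleted=current,
        production_at_max_growth=production,
        growth=growth,
        coupled=production > _TOL,
    )


# ---------------------------------------------------------------------------
# Context-specific model and restoration scan


def reaction_expression(rxn, values: Mapping[str, float]) -> float | None:
    """Evaluate a GPR rule on expression values: AND -> min, OR -> max.

    Genes missing from ``values`` are ignored inside their clause; ``None``
    when nothing in the rule is evaluable (or there is no rule).
    """
    import ast

    if not rxn.gene_reaction_rule:
        return None
    body = rxn.gpr.body

    def _eval(node):
        if isinstance(node, ast.Name):
            return values.get(node.id)
        if isinstance(node, ast.BoolOp):
            parts = [_eval(v) for v in node.values]
            parts = [p for p in parts if p is not None]
            if not parts:
                return None
            return min(parts) if isinstance(node.op, ast.And) else max(parts)
        if isinstance(node, ast.Expression):  # pragma: no cover
            return _eval(node.body)
        raise ValueError(f"unsupported GPR node {type(node).__name__}")

    return _eval(body)


def build_context_model(
    model: Model,
    expr: ExpressionProfile,
    threshold_percentile: float = 25,
    biomass_id: str | None = None,
) -> tuple[Model, set[str], set[str]]:
    """Close lowly expressed reactions to obtain a context-specific model.

    Reaction expression is the GPR evaluation of the profile; reactions whose
    expression falls strictly below the given percentile of all evaluable
    reaction expressions are closed (bounds 0) in ascending-expression order,
    except that a closure breaking biomass feasibility is rolled back and the
    reaction flagged instead.  Reactions with no GPR (or no measured gene)
    are kept.

    Returns ``(context model, removed ids, kept-but-flagged ids)``.
    """
    model_genes = {g.id for g in model.genes}
    if not model_genes & set(expr.values):
        raise ValueError("expression profile shares no genes with the model")
    levels: dict[str, float] = {}
    for rxn in model.reactions:
        value = reaction_expression(rxn, expr.values)
        if value is not None:
            levels[rxn.id] = value
    if not levels:
        raise ValueError("no reaction expression could be evaluated")
    threshold = float(np.percentile(list(levels.values()), threshold_percentile))
    candidates = sorted(
        (rid for rid, v in levels.items() if v < threshold), key=lambda r: levels[r]
    )
    context = model.copy()
    removed: set[str] = set()
    flagged: set[str] = set()
    for rid in candidates:
        rxn = context.reactions.get_by_id(rid)
        saved = rxn.bounds
        rxn.bounds = (0.0, 0.0)
        if biomass_id is not None:
            state = optimize(context, objective=biomass_id, sense="max")
            if not state.optimal or state.objective_value < _TOL:
                rxn.bounds = saved
                flagged.add(rid)
                continue
        removed.add(rid)
    return context, removed, flagged


def restoration_scan(
    context_model: Model,
    removed: Iterable[str],
    product_exchange: str,
    constraints: ConditionConstraints | None = None,
    original_bounds: Mapping[str, tuple[float, float]] | None = None,
    improvement_tol: float = _TOL,
) -> list[RestorationTarget]:
    """Restore each removed reaction alone and rank by product improvement.

    ``original_bounds`` supplies the bounds a restored reaction reopens to
    (defaulting to the conventional ±1000 for reversible-unknown cases is
    avoided by requiring the caller — typically :func:`build_context_model`'s
    input model — to provide them).  Targets whose improvement is within
    ``improvement_tol`` are omitted.  A context yield of zero reports the
    improvement as infinite with ``from_zero=True``.
    """
    removed = sorted(set(removed))
    for rid in removed:
        if rid not in context_model.reactions:
            raise ValueError(f"removed reaction {rid!r} not in the context model")
    base_state = optimize(context_model, objective=product_exchange, sense="max",
                          constraints=constraints)
    if not base_state.optimal:
        raise RuntimeError(f"context product LP not optimal: {base_state.status}")
    yield_context = base_state.objective_value
    targets: list[RestorationTarget] = []
    for rid in removed:
        rxn = context_model.reactions.get_by_id(rid)
        if original_bounds is not None and rid in original_bounds:
            reopened = original_bounds[rid]
        else:
            raise ValueError(
                f"no original bounds supplied for removed reaction {rid!r}"
            )
        with context_model:
            rxn.bounds = reopened
            state = optimize(
                context_model, objective=product_exchange, sense="max",
                constraints=constraints,
            )
        if not state.optimal:
            continue
        restored = state.objective_value
        gain = restored - yield_context
        if gain <= improvement_tol:
            continue
        if yield_context <= _TOL:
            targets.append(
                RestorationTarget(rid, yield_context, restored, float("inf"), True)
            )
        else:
            targets.append(
                RestorationTarget(
                    rid, yield_context, restored, 100.0 * gain / yield_context
                )
            )
    targets.sort(key=lambda t: (-t.improvement_pct, t.reaction_id))
    return targets


# ---------------------------------------------------------------------------
# Amino-acid supplementation


def _carbon_count(model: Model, exchange_id: str) -> int | None:
    rxn = model.reactions.get_by_id(exchange_id)
    met = next(iter(rxn.metabolites))
    if met.formula:
        carbons = parse_formula(met.formula).get("C", 0)
        if carbons > 0:
            return carbons
    for key, n in FALLBACK_CARBONS.items():
        if key in met.id.lower():
            return n
    return None


def supplementation_scan(
    model: Model,
    product_exchange: str,
    substrate_exchange: str,
    supplements: Mapping[str, str],
    uptake: float = 10.0,
    c_mmol_budget: float = 10.0,
    panel: Sequence[str] = (),
    constraints: ConditionConstraints | None = None,
    carbon_counts: Mapping[str, int] | None = None,
) -> SupplementationReport:
    """Product maximization with amino-acid co-feeding at a fixed carbon budget.

    ``supplements`` maps condition names (e.g. ``"leucine"``) to their
    exchange-reaction ids.  Each supplement's molar uptake bound is
    ``c_mmol_budget / carbon number`` (formula carbon count, with documented
    fallbacks).  The primary substrate uptake is fixed at ``uptake``.  For
    every condition — a no-supplement baseline always included — the product
    is maximized, fluxes are parsimoniously resolved, and flux-sums are
    computed on the metabolite panel.  A supplement whose uptake cannot be
    metabolized (no degradation route) is skipped with a warning.
    """
    report = SupplementationReport()

    def _run(condition: str, extra_bounds: dict[str, tuple[float, float]]):
        cc = ConditionConstraints(
            exchange_bounds={
                substrate_exchange: (-uptake, -uptake),
                **(constraints.exchange_bounds if constraints else {}),
                **extra_bounds,
            },
            biomass_id=constraints.biomass_id if constraints else None,
            label=condition,
        )
        state = resolve_unique(
            model, objective=product_exchange, constraints=cc, sense="max"
        )
        if not state.optimal:
            return None
        sums = flux_sum(model, state)
        panel_sums = sums.values.reindex(list(panel)) if panel else sums.values
        report.conditions[condition] = {
            "state": state,
            "product_optimum": state.objective_value,
            "flux_sums": panel_sums,
        }
        return state

    if _run("baseline", {}) is None:
        raise RuntimeError("baseline product LP infeasible")
    base_opt = report.conditions["baseline"]["product_optimum"]

    for condition, exchange_id in supplements.items():
        if exchange_id not in model.reactions:
            report.skipped[condition] = "missing exchange"
            warnings.warn(
                f"supplement {condition!r}: exchange {exchange_id!r} missing; skipped",
                stacklevel=2,
            )
            continue
        carbons = (
            carbon_counts.get(condition)
            if carbon_counts and condition in carbon_counts
            else _carbon_count(model, exchange_id)
        )
        if not carbons:
            report.skipped[condition] = "unknown carbon number"
            warnings.warn(
                f"supplement {condition!r}: carbon number unknown; skipped",
                stacklevel=2,
            )
            continue
        rate = c_mmol_budget / carbons
        if rate <= _TOL:
            # zero budget: identical to baseline by construction, still reported
            if _run(condition, {exchange_id: (0.0, 0.0)}) is None:
                report.skipped[condition] = "infeasible"
            continue
        # verify a consuming path exists: can the supplement be taken up?
        probe = optimize(
            model,
            objective=exchange_id,
            sense="min",
            constraints=ConditionConstraints(
                exchange_bounds={
                    substrate_exchange: (-uptake, -uptake),
                    exchange_id: (-rate, 0.0),
                }
            ),
        )
        if not probe.optimal or probe.objective_value > -_TOL:
            report.skipped[condition] = "no degradation path"
            warnings.warn(
                f"supplement {condition!r} cannot be metabolized; skipped",
                stacklevel=2,
            )
            continue
        if _run(condition, {exchange_id: (-rate, 0.0)}) is None:
            report.skipped[condition] = "infeasible"
    for condition, info in report.conditions.items():
        if condition != "baseline" and info["product_optimum"] < base_opt - _TOL:
            raise RuntimeError(
                "supplementation decreased the product optimum — "
                "this contradicts LP relaxation and indicates a solver failure"
            )
    return report
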