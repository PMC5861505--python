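"""Flux-activity analysis: MILP scanning for up/down-regulation targets.

The *flux activity* of reaction *j* is the absolute value of its flux,
``f_j = |v_j|``.  Scanning proceeds in four steps:

1. **Wild type** — solve biomass-maximizing FBA, resolve the flux vector
   parsimoniously, and take ``f_j^WT = |v_j|``.
2. **Feasible range** — for each reaction solve the MILP
   ``max/min f_j`` where ``v_j = f_j+ - f_j-``, ``f_j± >= 0``,
   ``f_j± <= I_j±·M``, ``I_j+ + I_j- = 1`` with binary indicators and a
   big-M constant, giving ``f_j^min`` and ``f_j^max``.  (For a reaction whose
   feasible flux interval straddles zero, ``f_j^min = 0``.)
3. **Perturbed growth** — maximize biomass subject to a graded activity
   constraint: downregulation (attenuation, level ``k_att``)
   ``f_j+ + f_j- <= f_j^min + k_att (f_j^WT - f_j^min)``, or upregulation
   (intensification, level ``k_int``)
   ``f_j+ + f_j- >= f_j^WT + k_int (f_j^max - f_j^WT)``, with ``k`` on a
   0..1 grid.  The optimum is ``B_{j,k}``.
4. **Product response** — re-solve with the targeted product exchange as
   objective subject to ``v_biomass >= B_{j,k}`` plus the same activity
   constraint.

A reaction is classified *coupled-overexpression* when the product optimum is
non-decreasing and strictly increases somewhere along increasing ``k_int``
(and analogously *coupled-downregulation* along increasing attenuation);
otherwise it is neutral.  Only the scanned reaction's flux is decomposed in
each MILP — the remaining reactions' decompositions are unconstrained, so the
optimum is unchanged while the problems stay small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from cobra import Model

from .fba import (
    ConditionConstraints,
    applied_constraints,
    quiet_optimize,
    resolve_unique,
)

__all__ = [
    "ActivityRecord",
    "PerturbationCell",
    "FluxActivityScan",
    "wildtype_activity",
    "activity_range",
    "perturbation_growth",
    "product_at_perturbation",
    "scan_targets",
]

_TOL = 1e-6


@dataclass
class ActivityRecord:
    """Wild-type and feasible-range activities of one reaction."""

    reaction_id: str
    f_wt: float
    f_min: float | None = None
    f_max: float | None = None


@dataclass
class PerturbationCell:
    """One (reaction, mode, level) cell of the perturbation grid."""

    reaction_id: str
    mode: str  # "up" (k_int) or "down" (k_att)
    k: float
    growth: float | None  # B_jk; None when the perturbation is infeasible
    product_opt: float | None
    status: str = "optimal"


@dataclass
class FluxActivityScan:
    """Full scan result: activity records, grid cells and classifications."""

    records: dict[str, ActivityRecord]
    cells: list[PerturbationCell]
    classification: dict[str, str]
    product_exchange: str
    wildtype_growth: float

    def targets(self, kind: str) -> list[str]:
        return sorted(r for r, c in self.classification.items() if c == kind)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "reaction": c.reaction_id,
                    "mode": c.mode,
                    "k": c.k,
                    "growth": c.growth,
                    "product_opt": c.product_opt,
                    "status": c.status,
                    "classification": self.classification.get(
                        c.reaction_id, "neutral"
                    ),
                }
                for c in self.cells
            ]
        )


def big_m(model: Model) -> float:
    """Big-M constant: 10x the largest bound magnitude in the model."""
    cap = max(
        (max(abs(r.lower_bound), abs(r.upper_bound)) for r in model.reactions),
        default=1.0,
    )
    return 10.0 * max(cap, 1.0)


def _add_decomposition(model: Model, reaction_id: str, M: float):
    """Attach ``v_j = f+ - f-`` with binary complementarity to the problem."""
    rxn = model.reactions.get_by_id(reaction_id)
    iface = model.problem
    fp = iface.Variable(f"_fa_fp_{reaction_id}", lb=0.0)
    fm = iface.Variable(f"_fa_fm_{reaction_id}", lb=0.0)
    ip = iface.Variable(f"_fa_ip_{reaction_id}", type="binary")
    im = iface.Variable(f"_fa_im_{reaction_id}", type="binary")
    cons = [
        iface.Constraint(
            rxn.flux_expression - fp + fm, lb=0.0, ub=0.0, name=f"_fa_split_{reaction_id}"
        ),
        iface.Constraint(fp - M * ip, ub=0.0, name=f"_fa_capp_{reaction_id}"),
        iface.Constraint(fm - M * im, ub=0.0, name=f"_fa_capm_{reaction_id}"),
        iface.Constraint(ip + im, lb=1.0, ub=1.0, name=f"_fa_one_{reaction_id}"),
    ]
    model.add_cons_vars([fp, fm, ip, im, *cons])
    return fp, fm


def _milp_value(model: Model) -> tuple[float | None, str]:
    solution = quiet_optimize(model)
    if solution.status != "optimal":
        return None, solution.status
    return float(solution.objective_value), "optimal"


def wildtype_activity(
    model: Model,
    constraints: ConditionConstraints | None = None,
    biomass_id: str | None = None,
) -> dict[str, ActivityRecord]:
    """Wild-type activities ``f_j^WT`` from the parsimoniously resolved
    biomass-optimal state."""
    objective = biomass_id or (constraints.biomass_id if constraints else None)
    state = resolve_unique(model, objective=objective, constraints=constraints)
    if not state.optimal:
        raise RuntimeError(f"wild-type FBA not optimal: {state.status}")
    return {
        rxn.id: ActivityRecord(rxn.id, abs(float(state.fluxes[rxn.id])))
        for rxn in model.reactions
    }


def activity_range(
    model: Model,
    reaction_id: str,
    constraints: ConditionConstraints | None = None,
) -> tuple[float, float]:
    """MILP extrema ``(f_j^min, f_j^max)`` of one reaction's flux activity."""
    if reaction_id not in model.reactions:
        raise ValueError(f"unknown reaction {reaction_id!r}")
    with applied_constraints(model, constraints):
        M = big_m(model)
        fp, fm = _add_decomposition(model, reaction_id, M)
        iface = model.problem
        model.objective = iface.Objective(fp + fm, direction="max")
        f_max, status = _milp_value(model)
        if f_max is None:
            raise RuntimeError(f"activity max MILP failed: {status}")
        model.objective = iface.Objective(fp + fm, direction="min")
        f_min, status = _milp_value(model)
        if f_min is None:
            raise RuntimeError(f"activity min MILP failed: {status}")
    f_min = max(0.0, f_min)
    f_max = max(f_min, f_max)
    return f_min, f_max


def _activity_constraint(
    model: Model,
    fp,
    fm,
    mode: str,
    k: float,
    record: ActivityRecord,
) -> None:
    if not 0.0 <= k <= 1.0:
        raise ValueError("perturbation level k must lie in [0, 1]")
    iface = model.problem
    if mode == "down":
        bound = record.f_min + k * (record.f_wt - record.f_min)
        cons = iface.Constraint(fp + fm, ub=bound, name="_fa_level")
    elif mode == "up":
        bound = record.f_wt + k * (record.f_max - record.f_wt)
        cons = iface.Constraint(fp + fm, lb=bound, name="_fa_level")
    else:
        raise ValueError("mode must be 'up' or 'down'")
    model.add_cons_vars([cons])


def perturbation_growth(
    model: Model,
    reaction_id: str,
    mode: str,
    k: float,
    record: ActivityRecord,
    constraints: ConditionConstraints | None = None,
    biomass_id: str | None = None,
) -> float | None:
    """Maximum biomass ``B_jk`` under a graded activity constraint.

    Returns ``None`` when the perturbation is infeasible (recorded, never
    silently zero).
    """
    if record.f_min is None or record.f_max is None:
        raise ValueError("activity record lacks f_min/f_max; run activity_range")
    with applied_constraints(model, constraints):
        M = big_m(model)
        fp, fm = _add_decomposition(model, reaction_id, M)
        _activity_constraint(model, fp, fm, mode, k, record)
        objective = biomass_id or (constraints.biomass_id if constraints else None)
        if objective is not None:
            model.objective = objective
        model.objective_direction = "max"
        value, _status = _milp_value(model)
    return value


def product_at_perturbation(
    model: Model,
    reaction_id: str,
    mode: str,
    k: float,
    record: ActivityRecord,
    growth_floor: float,
    product_exchange: str,
    constraints: ConditionConstraints | None = None,
    biomass_id: str | None = None,
    sense: str = "max",
) -> float | None:
    """Product optimum subject to ``v_biomass >= B_jk`` and the activity
    constraint (the scan's fourth step)."""
    with applied_constraints(model, constraints):
        M = big_m(model)
        fp, fm = _add_decomposition(model, reaction_id, M)
        _activity_constraint(model, fp, fm, mode, k, record)
        objective = biomass_id or (constraints.biomass_id if constraints else None)
        if objective is not None:
            iface = model.problem
            bio = model.reactions.get_by_id(objective)
            model.add_cons_vars(
                [
                    iface.Constraint(
                        bio.flux_expression,
                        lb=growth_floor - 1e-6,
                        name="_fa_growth_floor",
                    )
                ]
            )
        model.objective = product_exchange
        model.objective_direction = sense
        value, _status = _milp_value(model)
    return value


def _grid(step: float) -> list[float]:
    n = int(round(1.0 / step))
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError("grid step must divide 1.0")
    return [round(i * step, 10) for i in range(n + 1)]


def _series_classifies(values: Sequence[float | None]) -> bool:
    """Non-decreasing within tolerance and strictly increasing somewhere."""
    if any(v is None for v in values) or len(values) < 2:
        return False
    arr = np.asarray(values, dtype=float)
    if np.any(np.diff(arr) < -_TOL):
        return False
    return bool(arr[-1] > arr[0] + _TOL)


def scan_targets(
    model: Model,
    product_exchange: str,
    constraints: ConditionConstraints | None = None,
    grid_step: float = 0.1,
    biomass_id: str | None = None,
    reactions: Iterable[str] | None = None,
    objective_sense: str = "max",
    anchor: str = "per-cell",
) -> FluxActivityScan:
    """Scan every candidate reaction over the perturbation grid.

    Parameters
    ----------
    objective_sense
        Direction of the fourth-step product objective; ``"max"`` targets the
        product exchange itself (the documented default).
    anchor
        ``"per-cell"`` anchors growth at ``B_jk`` of each cell; ``"wildtype"``
        anchors at the unperturbed biomass optimum for every cell.
    reactions
        Candidate reaction ids; default is all non-exchange reactions.

    Per-cell solver failures are recorded in the cell status without aborting
    the scan.
    """
    if product_exchange not in model.reactions:
        raise ValueError(f"unknown product exchange {product_exchange!r}")
    biomass_id = biomass_id or (constraints.biomass_id if constraints else None)
    if biomass_id is None:
        raise ValueError("scan_targets needs a biomass reaction id")
    if reactions is None:
        candidates = [r.id for r in model.reactions if len(r.metabolites) > 1]
    else:
        candidates = list(reactions)

    records = wildtype_activity(model, constraints, biomass_id)
    b_wt = resolve_unique(
        model, objective=biomass_id, constraints=constraints
    ).objective_value

    cells: list[PerturbationCell] = []
    classification: dict[str, str] = {}
    ks = _grid(grid_step)
    for rid in candidates:
        record = records[rid]
        try:
            record.f_min, record.f_max = activity_range(model, rid, constraints)
        except RuntimeError as exc:  # pragma: no cover - solver hiccup
            warnings.warn(f"activity range failed for {rid}: {exc}", stacklevel=2)
            classification[rid] = "neutral"
            continue
        series: dict[str, list[float | None]] = {}
        for mode in ("up", "down"):
            values: list[float | None] = []
            for k in ks:
                growth = perturbation_growth(
                    model, rid, mode, k, record, constraints, biomass_id
                )
                if growth is None:
                    cells.append(
                        PerturbationCell(rid, mode, k, None, None, "infeasible")
                    )
                    values.append(None)
                    continue
                floor = b_wt if anchor == "wildtype" else growth
                product = product_at_perturbation(
                    model,
                    rid,
                    mode,
                    k,
                    record,
                    floor,
                    product_exchange,
                    constraints,
                    biomass_id,
                    sense=objective_sense,
                )
                status = "optimal" if product is not None else "infeasible"
                cells.append(
                    PerturbationCell(rid, mode, k, growth, product, status)
                )
                values.append(product)
            series[mode] = values
        if record.f_max <= _TOL:
            classification[rid] = "neutral"
        elif _series_classifies(series["up"]):
            classification[rid] = "coupled-overexpression"
        elif _series_classifies(list(reversed(series["down"]))):
            classification[rid] = "coupled-downregulation"
        else:
            classification[rid] = "neutral"
    return FluxActivityScan(
        records=records,
        cells=cells,
        classification=classification,
        product_exchange=product_exchange,
        wildtype_growth=b_wt,
    )
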