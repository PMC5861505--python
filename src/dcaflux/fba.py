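"""Constraint-based flux analysis: FBA, deterministic flux resolution,
flux-sum turnover, growth validation and theoretical product yields.

The linear program solved throughout is

.. math::

    \\max\\; Z_1 = \\sum_j c_j v_j
    \\quad\\text{s.t.}\\quad
    \\sum_j S_{ij} v_j = 0 \\;\\forall i,\\qquad
    v_j^{min} \\le v_j \\le v_j^{max},

with :math:`S` the stoichiometric matrix, :math:`v` the flux vector in
mmol/gDCW/h and :math:`c` the objective weights (biomass for growth
simulation, a product exchange for yield questions).  Because LP optima are
usually degenerate, :func:`resolve_unique` fixes the objective at its optimum
and then minimizes total absolute flux (parsimonious resolution), producing a
solver-order-independent representative used for flux activities and
flux-sums.

The flux-sum of metabolite *i* at a flux state is half the total absolute
stoichiometry-weighted flux through it,
:math:`\\Phi_i = 0.5 \\sum_j |S_{ij} v_j|`, i.e. its turnover rate; at steady
state production and consumption halves are equal.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from cobra import Model
from cobra.util import create_stoichiometric_matrix
from cobra.util.solver import set_objective

__all__ = [
    "FluxState",
    "ConditionConstraints",
    "FluxSumProfile",
    "applied_constraints",
    "optimize",
    "resolve_unique",
    "flux_sum",
    "steady_state_residual",
    "validate_growth",
    "theoretical_max_yield",
]

FEASIBILITY_TOL = 1e-9


@dataclass
class FluxState:
    """A flux vector with its objective value and solver status."""

    fluxes: pd.Series
    objective_value: float
    status: str  # optimal | infeasible | unbounded | ...

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])


@dataclass
class ConditionConstraints:
    """Culture-condition constraints layered on top of model bounds.

    ``exchange_bounds`` maps exchange-reaction ids to ``(lb, ub)`` pairs;
    uptake is a negative flux (an uptake rate of 10 mmol/gDCW/h on glucose is
    ``("EX_glc", (-10, -10))`` when fixed, ``(-10, 0)`` when an upper limit
    on uptake).  ``biomass_id`` selects the active biomass equation for this
    condition.  ``measured_growth`` carries an experimental specific growth
    rate for validation tables.
    """

    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    biomass_id: str | None = None
    label: str = ""
    measured_growth: float | None = None

    def validate(self, model: Model) -> None:
        for rid, (lb, ub) in self.exchange_bounds.items():
            if rid not in model.reactions:
                raise ValueError(f"constraint names unknown exchange {rid!r}")
            if lb > ub:
                raise ValueError(f"lb > ub for {rid!r}: ({lb}, {ub})")


@dataclass
class FluxSumProfile:
    """Per-metabolite turnover rates Phi_i (mmol/gDCW/h)."""

    values: pd.Series

    def __getitem__(self, metabolite_id: str) -> float:
        return float(self.values[metabolite_id])

    def top(self, n: int = 10) -> pd.Series:
        return self.values.sort_values(ascending=False).head(n)


@contextmanager
def applied_constraints(
    model: Model, constraints: ConditionConstraints | None
) -> Iterator[Model]:
    """Temporarily apply condition constraints inside a ``with model`` scope."""
    with model:
        if constraints is not None:
            constraints.validate(model)
            for rid, (lb, ub) in constraints.exchange_bounds.items():
                model.reactions.get_by_id(rid).bounds = (lb, ub)
            if constraints.biomass_id is not None:
                model.objective = constraints.biomass_id
        yield model


def quiet_optimize(model: Model):
    """``model.optimize(raise_error=False)`` without the solver-status warning."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Solver status")
        return model.optimize(raise_error=False)


def _solve(model: Model) -> FluxState:
    solution = quiet_optimize(model)
    status = solution.status
    if status != "optimal":
        return FluxState(
            fluxes=pd.Series(dtype=float), objective_value=float("nan"), status=status
        )
    return FluxState(
        fluxes=solution.fluxes.copy(),
        objective_value=float(solution.objective_value),
        status="optimal",
    )


def optimize(
    model: Model,
    objective: Mapping[str, float] | str | None = None,
    sense: str = "max",
    constraints: ConditionConstraints | None = None,
) -> FluxState:
    """Solve the flux-balance LP for the given objective and conditions.

    ``objective`` is a reaction id or a mapping of reaction ids to weights
    ``c_j``; ``None`` keeps the model's current objective.  Infeasibility or
    unboundedness is reported in :attr:`FluxState.status`, never as zeros.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    with applied_constraints(model, constraints):
        if objective is not None:
            _set_linear_objective(model, objective)
        model.objective_direction = sense
        return _solve(model)


def _set_linear_objective(model: Model, objective: Mapping[str, float] | str) -> None:
    if isinstance(objective, str):
        objective = {objective: 1.0}
    coeffs = {}
    for rid, weight in objective.items():
        if rid not in model.reactions:
            raise ValueError(f"objective names unknown reaction {rid!r}")
        coeffs[model.reactions.get_by_id(rid)] = float(weight)
    set_objective(model, coeffs, additive=False)


def resolve_unique(
    model: Model,
    objective: Mapping[str, float] | str | None = None,
    constraints: ConditionConstraints | None = None,
    sense: str = "max",
) -> FluxState:
    """Deterministic representative among alternate optima.

    First optimizes the objective, then fixes it at the optimum (within the
    solver feasibility tolerance) and minimizes total absolute flux
    ``sum_j |v_j|`` using the solver's forward/reverse variable split.  The
    reported ``objective_value`` is the original optimum.
    """
    with applied_constraints(model, constraints):
        if objective is not None:
            _set_linear_objective(model, objective)
        model.objective_direction = sense
        first = _solve(model)
        if not first.optimal:
            return first
        opt = first.objective_value
        iface = model.problem
        fix = iface.Constraint(
            model.objective.expression,
            lb=opt - 1e-7 if sense == "max" else None,
            ub=opt + 1e-7 if sense == "min" else None,
            name="_fix_objective",
        )
        model.add_cons_vars([fix])
        pfba_expr = sum(
            rxn.forward_variable + rxn.reverse_variable for rxn in model.reactions
        )
        model.objective = iface.Objective(pfba_expr, direction="min")
        second = _solve(model)
        if not second.optimal:  # pragma: no cover - fixed optimum is feasible
            return first
        return FluxState(
            fluxes=second.fluxes, objective_value=opt, status="optimal"
        )


def steady_state_residual(model: Model, fluxes: pd.Series) -> float:
    """Largest absolute metabolite imbalance ``max_i |sum_j S_ij v_j|``."""
    matrix = create_stoichiometric_matrix(model)
    v = fluxes.reindex([r.id for r in model.reactions]).fillna(0.0).to_numpy()
    return float(np.abs(matrix @ v).max()) if len(v) else 0.0


def flux_sum(model: Model, state: FluxState) -> FluxSumProfile:
    """Compute Phi_i = 0.5 * sum_j |S_ij v_j| for every metabolite."""
    if not state.optimal:
        raise ValueError("flux_sum requires an optimal flux state")
    matrix = create_stoichiometric_matrix(model)
    v = (
        state.fluxes.reindex([r.id for r in model.reactions])
        .fillna(0.0)
        .to_numpy()
    )
    phi = 0.5 * np.abs(matrix * v[np.newaxis, :]).sum(axis=1)
    return FluxSumProfile(
        values=pd.Series(phi, index=[m.id for m in model.metabolites])
    )


def validate_growth(
    model: Model,
    datasets: Sequence[ConditionConstraints],
    biomass_id: str | None = None,
) -> pd.DataFrame:
    """Predict maximum growth for each culture dataset and compare to data.

    Each dataset constrains its carbon-source uptake (and optionally the CO2
    evolution rate) through ``exchange_bounds``; predicted growth is the FBA
    biomass maximum under those constraints.  Deviations are reported signed
    (predicted - measured) and relative.
    """
    rows = []
    for ds in datasets:
        objective = ds.biomass_id or biomass_id
        state = optimize(model, objective=objective, sense="max", constraints=ds)
        mu = state.objective_value if state.optimal else float("nan")
        measured = ds.measured_growth
        deviation = mu - measured if measured is not None else float("nan")
        relative = (
            deviation / measured
            if measured not in (None, 0) and np.isfinite(deviation)
            else float("nan")
        )
        rows.append(
            {
                "dataset": ds.label,
                "status": state.status,
                "predicted_growth": mu,
                "measured_growth": measured,
                "deviation": deviation,
                "relative_deviation": relative,
            }
        )
    return pd.DataFrame(rows)


def theoretical_max_yield(
    model: Model,
    product_exchange: str,
    substrate_exchange: str,
    uptake: float,
    constraints: ConditionConstraints | None = None,
    release_reactions: Sequence[str] = (),
) -> float:
    """Maximum product exchange flux at a fixed substrate uptake rate.

    ``uptake`` is a positive magnitude; the substrate exchange is fixed at
    ``-uptake``.  Reactions in ``release_reactions`` (typically biomass and
    ATP maintenance) have their lower bounds released to 0 so the whole
    carbon budget is available to the product.
    """
    for rid in (product_exchange, substrate_exchange):
        if rid not in model.reactions:
            raise ValueError(f"unknown exchange {rid!r}")
    if uptake < 0:
        raise ValueError("uptake is a positive magnitude")
    with applied_constraints(model, constraints):
        model.reactions.get_by_id(substrate_exchange).bounds = (-uptake, -uptake)
        for rid in release_reactions:
            rxn = model.reactions.get_by_id(rid)
            rxn.lower_bound = min(rxn.lower_bound, 0.0)
        state = optimize(model, objective=product_exchange, sense="max")
    if not state.optimal:
        raise RuntimeError(
            f"yield LP not optimal (status {state.status}) for {product_exchange}"
        )
    return state.objective_value
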