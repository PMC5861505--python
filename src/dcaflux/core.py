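"""Model representation, SBML I/O, curation-ledger application and model statistics.

The in-memory container for a genome-scale metabolic model (GSMM) is a
:class:`cobra.Model`: metabolites indexed by id with compartment and elemental
formula, reactions with signed stoichiometry, flux bounds in mmol/gDCW/h,
boolean gene-protein-reaction (GPR) rules, and a linear objective.  This module
adds the operations the strain-design pipeline needs around that container:

* reading/writing SBML (Level 2, or Level 3 with the FBC package),
* applying a manual-curation ledger (add / remove / modify reactions) given as
  a TSV of reaction-equation strings,
* assembling a biomass synthesis reaction from a macromolecular composition
  with growth-associated maintenance (GAM) ATP, plus the non-growth-associated
  maintenance (NGAM) reaction,
* elemental mass-balance checking.

Reaction-equation grammar used by the ledger and the toy network::

    2 A[c] + B[c] -> C[e]        irreversible
    A[c] <=> B[c]                reversible (bounds -1000..1000 by default)

Metabolite tokens are ``name[compartment]``; internally they map to ids of the
form ``name_compartment``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
from cobra import Metabolite, Model, Reaction
from cobra.util.solver import linear_reaction_coefficients

__all__ = [
    "DEFAULT_BOUND",
    "ModelStats",
    "BiomassComposition",
    "CurationEntry",
    "CurationLedger",
    "CurationSummary",
    "MassBalanceReport",
    "read_sbml",
    "write_sbml",
    "model_stats",
    "parse_equation",
    "reaction_from_equation",
    "read_curation_ledger",
    "apply_curation",
    "build_biomass_reaction",
    "select_biomass",
    "check_mass_balance",
    "parse_formula",
]

#: Default flux capacity (mmol/gDCW/h) used when a file declares no bounds —
#: the usual COBRA convention.
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ModelStats:
    """Counts of distinct reactions, metabolites and genes in a model."""

    n_reactions: int
    n_metabolites: int
    n_genes: int


@dataclass
class BiomassComposition:
    """Macromolecular biomass composition for one culture condition.

    Parameters
    ----------
    macromolecule_fractions
        Precursor metabolite id -> demand in mmol per gDCW.
    gam
        Growth-associated maintenance, mmol ATP per gDCW, hydrolysed inside
        the biomass reaction.
    ngam
        Non-growth-associated maintenance, mmol ATP per gDCW per h, imposed as
        the fixed lower bound of a dedicated ATP-hydrolysis reaction.
    condition_label
        Typically ``"C-limited"`` or ``"N-limited"``.
    """

    macromolecule_fractions: dict[str, float]
    gam: float
    ngam: float
    condition_label: str = "C-limited"

    def validate(self) -> None:
        bad = {m: f for m, f in self.macromolecule_fractions.items() if f < 0}
        if bad:
            raise ValueError(f"negative biomass fractions: {bad}")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("GAM and NGAM must be non-negative")


@dataclass
class CurationEntry:
    """One ledger row: an action plus the reaction payload it refers to."""

    action: str  # add | remove | modify_bounds | modify_stoichiometry
    reaction_id: str
    equation: str = ""
    lower_bound: float | None = None
    upper_bound: float | None = None
    gpr: str = ""
    note: str = ""


@dataclass
class CurationLedger:
    entries: list[CurationEntry] = field(default_factory=list)


@dataclass(frozen=True)
class CurationSummary:
    n_added: int
    n_removed: int
    n_modified: int


@dataclass
class MassBalanceReport:
    """Per-reaction elemental residuals plus the reactions that were skipped."""

    imbalanced: dict[str, dict[str, float]]
    unchecked: list[str]

    def imbalanced_ids(self) -> list[str]:
        return sorted(self.imbalanced)


# ---------------------------------------------------------------------------
# SBML I/O


def read_sbml(path: str) -> Model:
    """Read an SBML file (L2 or L3/FBC) into a :class:`cobra.Model`.

    Reversibility is encoded as a negative lower bound.  Reactions without
    declared bounds receive ``±DEFAULT_BOUND`` (a warning is emitted by the
    reader in that case).
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of error types
        raise IOError(f"could not parse SBML file {path!r}: {exc}") from exc
    return model


def write_sbml(model: Model, path: str) -> None:
    """Write ``model`` as SBML Level 3 Version 1 with the FBC package."""
    try:
        cobra.io.write_sbml_model(model, str(path))
    except Exception as exc:
        raise IOError(f"could not write SBML to {path!r}: {exc}") from exc


def model_stats(model: Model) -> ModelStats:
    return ModelStats(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
    )


# ---------------------------------------------------------------------------
# Reaction-equation grammar

_ARROWS = ("<=>", "->", "=>", "-->")
_MET_TOKEN = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(.+?)\[(\w+)\]$")


def parse_equation(equation: str) -> tuple[dict[tuple[str, str], float], bool]:
    """Parse ``"2 A[c] + B[c] -> C[e]"`` into stoichiometry and reversibility.

    Returns
    -------
    stoichiometry
        ``(metabolite name, compartment) -> signed coefficient``.
    reversible
        True when the arrow is ``<=>``.
    """
    equation = equation.strip()
    arrow = None
    for cand in _ARROWS:
        if cand in equation:
            arrow = cand
            break
    if arrow is None:
        raise ValueError(f"no reaction arrow in equation {equation!r}")
    lhs, rhs = equation.split(arrow, 1)
    stoich: dict[tuple[str, str], float] = {}

    def _consume(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _MET_TOKEN.match(term)
            if m is None:
                raise ValueError(
                    f"cannot parse metabolite term {term!r} in {equation!r}"
                )
            coeff = float(m.group(1)) if m.group(1) else 1.0
            key = (m.group(2).strip(), m.group(3))
            stoich[key] = stoich.get(key, 0.0) + sign * coeff

    _consume(lhs, -1.0)
    _consume(rhs, +1.0)
    return stoich, arrow == "<=>"


def _met_id(name: str, compartment: str) -> str:
    return f"{name}_{compartment}"


def reaction_from_equation(
    model: Model,
    reaction_id: str,
    equation: str,
    lower_bound: float | None = None,
    upper_bound: float | None = None,
    gpr: str = "",
    name: str = "",
) -> Reaction:
    """Build a :class:`cobra.Reaction` from an equation string.

    Metabolites missing from ``model`` are created on the fly (compartment
    taken from the bracket suffix).  Default bounds follow reversibility:
    ``(-DEFAULT_BOUND, DEFAULT_BOUND)`` for ``<=>`` and ``(0, DEFAULT_BOUND)``
    otherwise.
    """
    stoich, reversible = parse_equation(equation)
    if lower_bound is None:
        lower_bound = -DEFAULT_BOUND if reversible else 0.0
    if upper_bound is None:
        upper_bound = DEFAULT_BOUND
    rxn = Reaction(reaction_id, name=name or reaction_id)
    rxn.bounds = (lower_bound, upper_bound)
    mets = {}
    for (mname, comp), coeff in stoich.items():
        mid = _met_id(mname, comp)
        if mid in model.metabolites:
            met = model.metabolites.get_by_id(mid)
        else:
            met = Metabolite(mid, name=mname, compartment=comp)
        mets[met] = coeff
    rxn.add_metabolites(mets)
    if gpr:
        rxn.gene_reaction_rule = gpr
    return rxn


# ---------------------------------------------------------------------------
# Curation ledger

_LEDGER_COLUMNS = (
    "action",
    "reaction_id",
    "equation",
    "lower_bound",
    "upper_bound",
    "gpr",
    "note",
)


def read_curation_ledger(path: str) -> CurationLedger:
    """Read a TSV curation ledger (columns: action, reaction_id, equation,
    lower_bound, upper_bound, gpr, note)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_LEDGER_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"curation ledger missing columns: {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            CurationEntry(
                action=row["action"].strip(),
                reaction_id=row["reaction_id"].strip(),
                equation=row.get("equation", ""),
                lower_bound=float(row["lower_bound"])
                if row.get("lower_bound", "") != ""
                else None,
                upper_bound=float(row["upper_bound"])
                if row.get("upper_bound", "") != ""
                else None,
                gpr=row.get("gpr", ""),
                note=row.get("note", ""),
            )
        )
    return CurationLedger(entries=entries)


def apply_curation(
    model: Model, ledger: CurationLedger
) -> tuple[Model, CurationSummary]:
    """Apply a curation ledger, in order, to a copy of ``model``.

    Returns the curated model and a summary of how many reactions were added,
    removed and modified.  Removing or modifying a reaction id that does not
    exist at application time is a :class:`ValueError`.
    """
    out = model.copy()
    n_added = n_removed = n_modified = 0
    for entry in ledger.entries:
        action = entry.action
        if action == "add":
            if entry.reaction_id in out.reactions:
                raise ValueError(f"cannot add existing reaction {entry.reaction_id!r}")
            rxn = reaction_from_equation(
                out,
                entry.reaction_id,
                entry.equation,
                entry.lower_bound,
                entry.upper_bound,
                entry.gpr,
            )
            out.add_reactions([rxn])
            n_added += 1
        elif action == "remove":
            if entry.reaction_id not in out.reactions:
                raise ValueError(
                    f"cannot remove unknown reaction {entry.reaction_id!r}"
                )
            out.remove_reactions([entry.reaction_id], remove_orphans=True)
            n_removed += 1
        elif action == "modify_bounds":
            if entry.reaction_id not in out.reactions:
                raise ValueError(
                    f"cannot modify unknown reaction {entry.reaction_id!r}"
                )
            rxn = out.reactions.get_by_id(entry.reaction_id)
            lb = entry.lower_bound if entry.lower_bound is not None else rxn.lower_bound
            ub = entry.upper_bound if entry.upper_bound is not None else rxn.upper_bound
            rxn.bounds = (lb, ub)
            n_modified += 1
        elif action == "modify_stoichiometry":
            if entry.reaction_id not in out.reactions:
                raise ValueError(
                    f"cannot modify unknown reaction {entry.reaction_id!r}"
                )
            rxn = out.reactions.get_by_id(entry.reaction_id)
            rxn.subtract_metabolites(dict(rxn.metabolites))
            new = reaction_from_equation(out, "__tmp__", entry.equation)
            rxn.add_metabolites(dict(new.metabolites))
            if entry.lower_bound is not None or entry.upper_bound is not None:
                rxn.bounds = (
                    entry.lower_bound
                    if entry.lower_bound is not None
                    else rxn.lower_bound,
                    entry.upper_bound
                    if entry.upper_bound is not None
                    else rxn.upper_bound,
                )
            n_modified += 1
        else:
            raise ValueError(f"unknown curation action {action!r}")
    return out, CurationSummary(n_added, n_removed, n_modified)


# ---------------------------------------------------------------------------
# Biomass assembly


def build_biomass_reaction(
    comp: BiomassComposition,
    biomass_metabolite_id: str = "biomass_c",
    atp_id: str = "atp_c",
    adp_id: str = "adp_c",
    pi_id: str = "pi_c",
    h2o_id: str = "h2o_c",
    reaction_id: str | None = None,
    maintenance_id: str = "ATPM",
) -> tuple[Reaction, Reaction]:
    """Assemble biomass and maintenance reactions from a composition.

    The biomass reaction consumes every precursor at its fraction plus
    ``gam`` mmol ATP (with water), releases ADP and phosphate, and produces
    one unit of a biomass pseudo-metabolite.  The second returned reaction is
    ATP hydrolysis whose *fixed lower bound* is ``ngam`` — the conventional
    non-growth maintenance encoding.
    """
    comp.validate()
    if not any(f > 0 for f in comp.macromolecule_fractions.values()) and comp.gam == 0:
        warnings.warn(
            "degenerate biomass composition: no precursor demand and zero GAM",
            stacklevel=2,
        )
    label = comp.condition_label.replace("-", "_").replace(" ", "_")
    rid = reaction_id or f"BIOMASS_{label}"
    compartment = biomass_metabolite_id.rsplit("_", 1)[-1]

    def _met(mid: str) -> Metabolite:
        return Metabolite(mid, compartment=mid.rsplit("_", 1)[-1])

    rxn = Reaction(rid, name=f"Biomass synthesis ({comp.condition_label})")
    rxn.bounds = (0.0, DEFAULT_BOUND)
    stoich: dict[str, float] = {
        mid: -frac for mid, frac in comp.macromolecule_fractions.items()
    }
    for mid, coeff in (
        (atp_id, -comp.gam),
        (h2o_id, -comp.gam),
        (adp_id, comp.gam),
        (pi_id, comp.gam),
    ):
        stoich[mid] = stoich.get(mid, 0.0) + coeff
    stoich[biomass_metabolite_id] = stoich.get(biomass_metabolite_id, 0.0) + 1.0
    rxn.add_metabolites(
        {Metabolite(mid, compartment=mid.rsplit("_", 1)[-1]): c for mid, c in stoich.items() if c != 0}
    )

    atpm = Reaction(maintenance_id, name="ATP maintenance (NGAM)")
    atpm.add_metabolites(
        {
            _met(atp_id): -1.0,
            _met(h2o_id): -1.0,
            _met(adp_id): 1.0,
            _met(pi_id): 1.0,
        }
    )
    atpm.bounds = (comp.ngam, DEFAULT_BOUND)
    # silence unused warning for compartment; kept for clarity of intent
    del compartment
    return rxn, atpm


def select_biomass(model: Model, biomass_id: str, others: Iterable[str] = ()) -> None:
    """Make ``biomass_id`` the single active biomass equation.

    Sets it as the objective with open bounds and closes any other listed
    biomass reactions, so exactly one equation backs a given simulation.
    """
    if biomass_id not in model.reactions:
        raise ValueError(f"unknown biomass reaction {biomass_id!r}")
    for rid in others:
        if rid != biomass_id and rid in model.reactions:
            model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    rxn = model.reactions.get_by_id(biomass_id)
    rxn.bounds = (0.0, DEFAULT_BOUND)
    model.objective = biomass_id


# ---------------------------------------------------------------------------
# Mass balance


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a chemical formula string into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos or not match.group(0):
            break
        counts[match.group(1)] = counts.get(match.group(1), 0) + int(
            match.group(2) or 1
        )
        pos = match.end()
    return counts


def _is_boundary_like(rxn: Reaction) -> bool:
    return len(rxn.metabolites) <= 1


def _is_biomass_like(model: Model, rxn: Reaction) -> bool:
    if "biomass" in rxn.id.lower():
        return True
    return rxn in linear_reaction_coefficients(model)


def check_mass_balance(
    model: Model,
    elements: Sequence[str] | None = None,
    tol: float = 1e-6,
) -> MassBalanceReport:
    """Flag elementally imbalanced reactions.

    A reaction is imbalanced when, for any checked element, the net
    stoichiometry-weighted element count differs from zero by more than
    ``tol``.  Exchange/sink reactions (a single metabolite) and biomass
    pseudo-reactions are excluded; a reaction containing any metabolite with
    no formula cannot be checked and is reported as unchecked instead.

    Parameters
    ----------
    elements
        Restrict the check to these elements (e.g. ``["C"]`` for a
        carbon-only audit of a lumped network); default is all elements seen.
    """
    imbalanced: dict[str, dict[str, float]] = {}
    unchecked: list[str] = []
    for rxn in model.reactions:
        if _is_boundary_like(rxn) or _is_biomass_like(model, rxn):
            continue
        if any(not met.formula for met in rxn.metabolites):
            unchecked.append(rxn.id)
            continue
        residual: dict[str, float] = {}
        for met, coeff in rxn.metabolites.items():
            for element, count in parse_formula(met.formula).items():
                residual[element] = residual.get(element, 0.0) + coeff * count
        if elements is not None:
            residual = {e: r for e, r in residual.items() if e in elements}
        residual = {e: r for e, r in residual.items() if abs(r) > tol}
        if residual:
            imbalanced[rxn.id] = residual
    return MassBalanceReport(imbalanced=imbalanced, unchecked=unchecked)
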