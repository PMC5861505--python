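"""Deterministic toy network (``YL-mini``) and synthetic expression profiles.

``YL-mini`` is a deliberately small, lumped model of the central carbon
metabolism relevant to dodecanedioic acid (DDDA) production in an oleaginous
yeast: glucose uptake, lumped glycolysis, a lumped oxidative pentose-phosphate
pathway (the NADPH source), pyruvate dehydrogenase, acetyl-CoA carboxylase,
fatty-acid synthesis to dodecanoate (DDCA), omega-oxidation of DDCA to DDDA,
respiration, ATP maintenance, a biomass reaction drawing acetyl-CoA and ATP,
and a (closed by default) lumped leucine-degradation route to acetyl-CoA.

The lumped stoichiometry is chosen so the standard scenarios have closed-form
optima by carbon/NADPH accounting; they are recorded in :data:`TOY_MANIFEST`
and serve as exact oracles for the LP/MILP machinery:

* one DDDA requires 6 acetyl-CoA (3 glucose through glycolysis + PDH) and
  11 NADPH (11/12 glucose through the PPP), i.e. 47/12 glucose per DDDA, so
  the maximum DDDA rate at 10 mmol/gDCW/h glucose is ``120/47 ~ 2.553``;
* opening leucine uptake at 10 C-mmol/gDCW/h (1.667 mmol of C6 leucine,
  degraded to 5 mmol acetyl-CoA) raises that optimum to ``150/47 ~ 3.191``;
* swapping the glycolytic dehydrogenase's cofactor from NAD to NADP supplies
  6 NADPH per DDDA from glycolysis, leaving 5 for the PPP: 41/12 glucose per
  DDDA, maximum ``120/41 ~ 2.927`` (the PDH swap attains the same optimum;
  ties are broken lexicographically);
* biomass (1 unit = 10 acetyl-CoA + 30 ATP) is carbon-limited at glucose 10:
  maximum growth ``2.0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from cobra import Model

from .core import DEFAULT_BOUND, reaction_from_equation

__all__ = [
    "TOY_MANIFEST",
    "ToyManifest",
    "ExpressionProfile",
    "toy_model",
    "random_expression_profile",
    "plant_bottleneck",
    "write_expression_tsv",
    "read_expression_tsv",
]


@dataclass
class ExpressionProfile:
    """Gene-expression snapshot: gene id -> non-negative level."""

    values: dict[str, float]
    label: str = ""
    planted_high: set[str] | None = None  # ground truth when synthetic

    def low_genes(self) -> set[str]:
        if self.planted_high is None:
            raise ValueError("profile carries no planted partition")
        return set(self.values) - self.planted_high


@dataclass(frozen=True)
class ToyManifest:
    """Documented reaction list and analytic optima of the toy network."""

    reactions: tuple[tuple[str, str, float, float, str], ...]
    formulas: dict[str, str]
    optima: dict[str, float]
    biomass_id: str = "BIOMASS"
    maintenance_id: str = "ATPM"
    product_exchange: str = "EX_ddda"
    substrate_exchange: str = "EX_glc"
    cofactor_pairs: tuple[tuple[str, str, str, str], ...] = (
        ("nad_c", "nadh_c", "nadp_c", "nadph_c"),
    )

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        mets = set()
        from .core import parse_equation

        for _, eq, *_ in self.reactions:
            stoich, _ = parse_equation(eq)
            mets.update(f"{n}_{c}" for (n, c) in stoich)
        return len(mets)

    @property
    def n_genes(self) -> int:
        return sum(1 for *_rest, gpr in self.reactions if gpr)


_B = DEFAULT_BOUND

# (id, equation, lower_bound, upper_bound, gpr)
_TOY_REACTIONS: tuple[tuple[str, str, float, float, str], ...] = (
    ("EX_glc", "glc[e] <=> ", -10.0, _B, ""),
    ("EX_o2", "o2[e] <=> ", -_B, _B, ""),
    ("EX_co2", "co2[e] <=> ", 0.0, _B, ""),
    ("EX_ddda", "ddda[e] <=> ", 0.0, _B, ""),
    ("EX_leu", "leu[e] <=> ", 0.0, _B, ""),  # uptake closed by default
    ("DM_biomass", "biomass[c] <=> ", 0.0, _B, ""),
    ("GLCt", "glc[e] -> glc[c]", 0.0, _B, "g_GLCt"),
    ("O2t", "o2[e] -> o2[c]", 0.0, _B, "g_O2t"),
    ("CO2t", "co2[c] -> co2[e]", 0.0, _B, "g_CO2t"),
    ("LEUt", "leu[e] -> leu[c]", 0.0, _B, "g_LEUt"),
    # lumped glycolysis (GAPD analog carries the NAD couple)
    (
        "GLYC",
        "glc[c] + 2 nad[c] + 2 adp[c] + 2 pi[c] -> "
        "2 pyr[c] + 2 nadh[c] + 2 atp[c]",
        0.0,
        _B,
        "g_GLYC",
    ),
    # lumped oxidative pentose-phosphate pathway: the NADPH source
    ("PPP", "glc[c] + 12 nadp[c] -> 6 co2[c] + 12 nadph[c]", 0.0, _B, "g_PPP"),
    ("PDH", "pyr[c] + nad[c] -> accoa[c] + co2[c] + nadh[c]", 0.0, _B, "g_PDH"),
    (
        "ACC",
        "accoa[c] + atp[c] + co2[c] -> malcoa[c] + adp[c] + pi[c]",
        0.0,
        _B,
        "g_ACC",
    ),
    (
        "FAS",
        "6 malcoa[c] + 10 nadph[c] -> ddca[c] + 10 nadp[c] + 6 co2[c]",
        0.0,
        _B,
        "g_FAS",
    ),
    # lumped omega-oxidation: hydroxylase (NADPH, O2) + aldehyde
    # dehydrogenase (NAD) in one step
    (
        "OMEGA",
        "ddca[c] + o2[c] + nadph[c] + nad[c] -> ddda[c] + nadp[c] + nadh[c]",
        0.0,
        _B,
        "g_OMEGA",
    ),
    ("DDDAt", "ddda[c] -> ddda[e]", 0.0, _B, "g_DDDAt"),
    (
        "RESP",
        "nadh[c] + 0.5 o2[c] + 2 adp[c] + 2 pi[c] -> nad[c] + 2 atp[c]",
        0.0,
        _B,
        "g_RESP",
    ),
    ("ATPM", "atp[c] -> adp[c] + pi[c]", 1.0, _B, ""),
    # lumped leucine degradation to acetyl-CoA; closed until supplementation
    ("LEUDEG", "leu[c] -> 3 accoa[c]", 0.0, 0.0, "g_LEUDEG"),
    (
        "BIOMASS",
        "10 accoa[c] + 30 atp[c] -> 30 adp[c] + 30 pi[c] + biomass[c]",
        0.0,
        _B,
        "",
    ),
)

# Carbon counts are exact (the manifest's carbon audit relies on them);
# hydrogen/oxygen of the lumped steps and the CoA moiety are not tracked, and
# cofactors use carbon-free placeholder cores.
_TOY_FORMULAS = {
    "glc_e": "C6H12O6",
    "glc_c": "C6H12O6",
    "pyr_c": "C3H4O3",
    "accoa_c": "C2H3O",
    "malcoa_c": "C3H3O3",
    "ddca_c": "C12H24O2",
    "ddda_c": "C12H22O4",
    "ddda_e": "C12H22O4",
    "co2_c": "CO2",
    "co2_e": "CO2",
    "o2_c": "O2",
    "o2_e": "O2",
    "leu_e": "C6H13NO2",
    "leu_c": "C6H13NO2",
    "nad_c": "R",
    "nadh_c": "RH",
    "nadp_c": "RP",
    "nadph_c": "RHP",
    "atp_c": "RP3",
    "adp_c": "RP2",
    "pi_c": "HO4P",
    "biomass_c": "",
}

TOY_MANIFEST = ToyManifest(
    reactions=_TOY_REACTIONS,
    formulas=dict(_TOY_FORMULAS),
    optima={
        # glucose 10, biomass and maintenance lower bounds released to 0
        "max_ddda_glc10": float(Fraction(120, 47)),
        # additionally 10 C-mmol/gDCW/h leucine (1.667 mmol, -> 5 acetyl-CoA)
        "max_ddda_glc10_leu": float(Fraction(150, 47)),
        # best single NAD->NADP specificity swap (GLYC, tied with PDH)
        "max_ddda_glc10_swap": float(Fraction(120, 41)),
        # growth at glucose 10 (carbon-limited; ATP is in excess)
        "max_growth_glc10": 2.0,
        # flux-sum of acetyl-CoA in the resolved max-DDDA state: 6 per DDDA
        "fluxsum_accoa_max_ddda": 6.0 * float(Fraction(120, 47)),
    },
)


def toy_model() -> Model:
    """Construct the fixed ``YL-mini`` network described by the manifest."""
    model = Model("YL_mini", name="YL-mini toy network")
    for rid, equation, lb, ub, gpr in TOY_MANIFEST.reactions:
        # adding one at a time lets reaction_from_equation reuse metabolites
        # already attached to the model
        rxn = reaction_from_equation(model, rid, equation, lb, ub, gpr)
        model.add_reactions([rxn])
    for mid, formula in TOY_MANIFEST.formulas.items():
        if formula:
            model.metabolites.get_by_id(mid).formula = formula
    model.objective = TOY_MANIFEST.biomass_id
    return model


def random_expression_profile(
    model: Model,
    seed: int,
    active_fraction: float = 0.75,
    label: str = "synthetic",
) -> ExpressionProfile:
    """Draw a synthetic expression profile with a planted active/inactive split.

    Approximately ``active_fraction`` of the model's genes are sampled from a
    high-expression lognormal component (median 1000) and the rest from a low
    one (median 1), separated widely enough that percentile thresholding
    recovers the planted partition.  Fully determined by ``seed``.
    """
    if not 0 < active_fraction <= 1:
        raise ValueError("active_fraction must lie in (0, 1]")
    genes = sorted(g.id for g in model.genes)
    if not genes:
        raise ValueError("model has no genes")
    rng = np.random.default_rng(seed)
    n_high = int(round(active_fraction * len(genes)))
    n_high = max(1, n_high)
    high = set(rng.choice(genes, size=n_high, replace=False).tolist())
    values = {}
    for g in genes:
        mu = np.log(1000.0) if g in high else 0.0
        values[g] = float(rng.lognormal(mean=mu, sigma=0.5))
    return ExpressionProfile(values=values, label=label, planted_high=high)


def plant_bottleneck(model: Model, reaction_id: str, cap: float) -> Model:
    """Return a copy of ``model`` with ``|flux|`` through a reaction capped."""
    if cap < 0:
        raise ValueError("cap must be non-negative")
    if reaction_id not in model.reactions:
        raise ValueError(f"unknown reaction {reaction_id!r}")
    out = model.copy()
    rxn = out.reactions.get_by_id(reaction_id)
    rxn.bounds = (max(rxn.lower_bound, -cap), min(rxn.upper_bound, cap))
    return out


def write_expression_tsv(profile: ExpressionProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gene in sorted(profile.values):
            fh.write(f"{gene}\t{profile.values[gene]:.6g}\n")


def read_expression_tsv(path: str, label: str = "") -> ExpressionProfile:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "value"} <= set(df.columns):
        raise ValueError("expression TSV needs columns gene_id and value")
    values = {str(g): float(v) for g, v in zip(df["gene_id"], df["value"])}
    if any(v < 0 for v in values.values()):
        raise ValueError("expression values must be non-negative")
    return ExpressionProfile(values=values, label=label or str(path))
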