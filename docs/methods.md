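# Methods

## Scope and model container

`dcaflux` analyses genome-scale metabolic models (GSMMs) of oleaginous
yeasts for long-chain dicarboxylic-acid (DCA) production.  The in-memory
container is a `cobra.Model`; SBML Level 2 and Level 3/FBC files are read and
written through cobrapy/libSBML, with the COBRA convention of ±1000
mmol/gDCW/h default bounds where a file declares none.  All optimization
(LP and MILP) runs on the GLPK backend that ships with cobrapy's optlang
layer.

Manual curation of a scaffold reconstruction is expressed as a ledger of
`add` / `remove` / `modify_bounds` / `modify_stoichiometry` rows over
reaction-equation strings (`2 A[c] + B[c] -> C[e]`, `<=>` for reversible);
applying a ledger returns a new model plus an added/removed/modified
summary, and a ledger followed by its exact inverse restores the original
model statistics.

Biomass is assembled from a macromolecular composition (mmol precursor per
gDCW): growth-associated maintenance ATP (GAM) is the ATP/ADP/Pi
stoichiometry inside the biomass reaction, while non-growth-associated
maintenance (NGAM) is the fixed lower bound of a dedicated ATP-hydrolysis
reaction — the conventional split.  Two biomass equations (C-limited and
N-limited) may coexist; `select_biomass` activates exactly one per
simulation.  NGAM is interpreted as a rate (mmol ATP/gDCW/h), the only
dimensionally consistent reading for a flux bound.

Mass balance is audited per element from metabolite formulas with a 1e-6
residual tolerance; exchange/sink and biomass pseudo-reactions are excluded,
and a reaction containing any formula-free metabolite is reported as
unchecked rather than silently passed.  Charge and proton balancing are not
enforced.  The audit accepts an element subset, which is how the lumped toy
network is checked for carbon only.

## Flux analysis

The base problem is FBA: maximize a linear objective over the steady-state
flux cone subject to bounds.  Infeasibility and unboundedness are reported
as statuses, never as zero vectors.  Because LP optima are degenerate, any
flux vector that downstream steps consume is resolved parsimoniously: the
objective is fixed at its optimum (tolerance 1e-7) and total absolute flux
is minimized over the solver's forward/reverse variable split.  This zeroes
futile cycles and closed pathways and makes flux activities and flux-sums
solver-order independent.

The flux-sum of metabolite *i* at a flux state is
Φᵢ = 0.5 Σⱼ |Sᵢⱼ vⱼ| — its turnover rate; production and consumption halves
are equal at steady state and this identity is asserted in the tests.

Growth validation takes per-dataset culture constraints (carbon-source
uptake, optionally a CO₂ evolution rate as an upper bound on the CO₂
exchange) and reports predicted vs measured growth with signed and relative
deviations.  Measured values are user configuration; none are shipped.
Uptake rates are positive magnitudes in all interfaces and are negated
internally (exchanges are written outward).

## Flux-activity scanning

Flux activity is fⱼ = |vⱼ|.  The scan follows four steps: (1) wild-type
activities from the parsimonious biomass optimum; (2) per-reaction activity
ranges [fⱼᵐⁱⁿ, fⱼᵐᵃˣ] from a MILP that decomposes vⱼ = fⱼ⁺ − fⱼ⁻ with binary
indicators Iⱼ⁺ + Iⱼ⁻ = 1 and big-M coupling (M = 10× the largest bound
magnitude); (3) maximum biomass B₍ⱼ,ₖ₎ under a graded activity constraint —
attenuation fⱼ⁺+fⱼ⁻ ≤ fⱼᵐⁱⁿ + k_att(fⱼᵂᵀ−fⱼᵐⁱⁿ) or intensification
fⱼ⁺+fⱼ⁻ ≥ fⱼᵂᵀ + k_int(fⱼᵐᵃˣ−fⱼᵂᵀ) — on a 0..1 grid with step 0.1 by
default; (4) the product exchange optimized subject to v_biomass ≥ B₍ⱼ,ₖ₎
and the same activity constraint.

Design choices worth noting:

* Only the scanned reaction is decomposed in each MILP.  Decomposing every
  reaction, as the formulation displays, adds unconstrained variable pairs
  that cannot change the optimum but multiply the problem size.
* The growth anchor is B₍ⱼ,ₖ₎ per cell (an inequality, not an equality, to
  avoid spurious infeasibility); anchoring every cell at the unperturbed
  optimum is selectable (`anchor="wildtype"`).
* The fourth-step objective sense is a parameter defaulting to maximizing
  the targeted product exchange.
* Classification is purely grid-based: a reaction is a coupled
  overexpression target iff its product series along increasing k_int is
  non-decreasing (tolerance 1e-6) with a strict increase somewhere;
  analogously for downregulation along increasing attenuation; everything
  else, including blocked reactions (fⱼᵐᵃˣ ≈ 0), is neutral.
* Activity ranges agree with a signed-interval FVA oracle (fold the FVA
  interval through |·|; intervals straddling zero give fⱼᵐⁱⁿ = 0); this
  equivalence is asserted over every toy reaction.

## Cofactor modification analysis

CMA asks which ≤ k reactions, with their NAD(H)/NADP(H) specificity
swapped, most raise the product yield.  Each eligible reaction gets a
cofactor-modified twin (NAD↔NADP, NADH↔NADPH coefficients exchanged; a
reaction touching both pairs has both exchanged simultaneously); a binary
yⱼ lets flux pass through the original or the twin but not both, with
Σyⱼ ≤ k.  Exchanges and biomass are never swap-eligible.

Two solution routes are implemented and cross-checked: exhaustive
enumeration over swap sets (default; exact for the small k used in
practice, deterministic lexicographic tie-breaking with all tied sets
reported) and a single-level MILP over the twin-extended network.  The
enumeration route additionally edits nothing — it toggles bounds on a
twin-extended copy — while the test oracle mutates stoichiometry in place,
keeping the two routes genuinely independent.

Two deliberate interpretation choices:

* **Growth side-condition.**  Read literally as a bilevel program (inner:
  maximize biomass; outer: product among inner optima), the product would be
  pinned near zero whenever growth is substrate-limited, which contradicts
  the near-theoretical-maximum yields such analyses report.  The default is
  therefore the floor semantics — maximize product subject to
  v_biomass ≥ v_biomass_min, with the floor defaulting to 10% of the biomass
  optimum (configurable; 0 reproduces the pure theoretical yield).  A strict
  lexicographic mode is available on the enumeration route.
* **Swap direction.**  The engineering question is NADPH supply, so the
  optimizers default to candidates that involve NAD(H)
  (`direction="nad_to_nadp"`): enzymes re-specified *toward* NADP.  With
  symmetric eligibility (`direction="both"`) the mathematically optimal
  move is often to make a big NADPH *consumer* (e.g. fatty-acid synthase)
  NADH-dependent instead — a different, far harder protein-engineering
  proposition that the directional default excludes by design.

## Knockout search, restoration scan, supplementation

**Knockout local search.**  Deletion sets (≤ max_ko, default 5) over
eligible reactions — non-exchange, non-biomass, non-maintenance, and by
default only gene-associated reactions — are scored pessimistically: maximize
growth, then *minimize* the product at that growth optimum.  A positive
score therefore certifies growth coupling independent of solver vertex
choice.  The search moves to the best strictly improving neighbor
(add/drop/swap one deletion, lexicographic candidate order, hence
deterministic) and stops at a local optimum; on the toy testbed it matches
exhaustive enumeration up to two deletions.

**Context model and restoration.**  Reaction expression is the GPR
evaluation of a profile (AND→min, OR→max; unmeasured genes are ignored
within their clause).  Reactions below the given percentile (default 25) of
evaluable reaction expressions are closed in ascending order, except that a
closure destroying biomass feasibility is rolled back and flagged.  This
percentile-threshold scheme is this package's own documented integration
rule — a deliberately simple stand-in for published
transcriptome-integration algorithms, sufficient to drive the restoration
principle: reopen each closed reaction alone, recompute the product optimum,
and rank by improvement.  A context yield of zero reports the improvement as
"from zero" (infinite percentage) rather than dividing.  Improvements are
non-negative by construction (reopening bounds only relaxes the LP).

**Supplementation.**  Amino-acid co-feeding at a fixed carbon budget
(default 10 C-mmol/gDCW/h): the molar uptake bound is the budget divided by
the supplement's carbon number (from its formula, with fallbacks leucine 6,
isoleucine 6, valine 5).  For each condition — a no-supplement baseline
always included — the product is maximized at fixed primary-substrate
uptake, fluxes are resolved parsimoniously, and flux-sums are reported on a
metabolite panel (acetyl-CoA, NADPH, the product, …) as a heat-map-ready
table.  A supplement with no consuming route is skipped with a warning, and
supplementation can never lower the product optimum (pure LP relaxation —
asserted).

## The toy network

`YL-mini` is a 21-reaction, 22-metabolite, 13-gene lumped model of the
pathway structure the real analysis navigates: glucose uptake, lumped
glycolysis (carrying the NAD couple of the GAPD step), a lumped oxidative
PPP as the NADPH source, PDH, acetyl-CoA carboxylase, fatty-acid synthesis
to dodecanoate, ω-oxidation to DDDA (NADPH- and NAD-coupled), respiration,
ATP maintenance (lower bound 1 mmol/gDCW/h), a biomass reaction (10
acetyl-CoA + 30 ATP per unit), and a leucine-degradation route (closed
until supplementation).  Stoichiometry was lumped so the standard scenarios
have closed-form optima by carbon/NADPH accounting (120/47, 150/47, 120/41,
growth 2.0 — derivations in the `toys` module docstring), which the LP/MILP
machinery must reproduce to 1e-6.  Carbon formulas are exact and audited;
hydrogen/oxygen of lumped steps and the CoA moiety are not tracked, and the
nitrogen of the lumped leucine route is deliberately unbalanced.

The synthetic expression generator draws each gene from one of two
lognormal components (medians 1000 and 1, σ = 0.5 in log space), with the
active fraction planted and recorded; the separation is wide enough that
percentile thresholding recovers the planted partition essentially always,
which is measured, not assumed.  What the toy does **not** emulate:
realistic network redundancy (isozymes, parallel pathways, compartmental
duplicates), GPR complexity beyond one gene per reaction, noise correlation
structure in expression, or thermodynamic constraints — so green tests here
demonstrate algorithmic correctness, not predictive accuracy on a real
transcriptome.

## Numerical conventions

* Solver: GLPK; feasibility/optimality at solver defaults; package-level
  comparisons use 1e-6, fixing tolerances 1e-7, and strict identities 1e-9.
* Big-M: 10× the largest bound magnitude of the model in force.
* Ties: lexicographic by reaction id everywhere (CMA swap sets, knockout
  neighbors), with ties reported rather than hidden where they carry
  information.
* Degenerate inputs: empty curation ledgers are identities; an all-zero
  biomass composition is accepted with a warning; a zero supplementation
  budget reproduces the baseline; blocked reactions scan as neutral.
* Reported numbers are rounded only at output, never internally.

## Problem sizes

The shipped tests and the acceptance script run entirely on the toy network:
full-model flux-activity scans use a 0.25 grid (the 0.1 default remains the
production setting; grid nesting is asserted so coarse and fine grids agree
cell-for-cell), knockout enumeration is exhaustive to two deletions, and
partition recovery uses 100 seeded profiles.  On a genome-scale model the
same code paths apply unchanged; the per-reaction MILP scan is the dominant
cost and scales linearly in reactions × grid points.

## Known limitations

* The bilevel CMA is solved by enumeration or a single-level MILP under the
  floor semantics; the strict lexicographic bilevel is available only via
  enumeration.
* The knockout search is a local search: it inherits the usual
  local-optimum caveat (mitigated by determinism and the enumeration
  cross-check at small sizes).
* The expression-integration rule is a percentile threshold, not a
  published integration algorithm; results on real transcriptomes should be
  read as restoration-principle rankings, not as context-model fidelity.
* No thermodynamic or enzyme-capacity constraints; no dynamic FBA; no
  gap-filling.
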