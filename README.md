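# dcaflux

Constraint-based strain design for long-chain **dicarboxylic acid (DCA)**
overproduction in oleaginous yeast, aimed at metabolic engineers who want to
rank overexpression, knockout and cofactor-specificity targets from a
genome-scale metabolic model (GSMM) before going to the bench.

*Yarrowia lipolytica* secretes dodecanedioic acid (DDDA, the C12 DCA) through
its ω-oxidation pathway — a strongly NADPH-demanding oxidative route fed by
acetyl-CoA-derived fatty acids.  `dcaflux` wraps the whole *in silico* design
workflow around a cobrapy model:

1. **FBA** — `max Z₁ = Σⱼ cⱼvⱼ  s.t.  Σⱼ Sᵢⱼvⱼ = 0,  vⱼᵐⁱⁿ ≤ vⱼ ≤ vⱼᵐᵃˣ`,
   with parsimonious resolution of alternate optima, growth validation
   against culture data, and theoretical product yields.
2. **Flux-activity scanning** — the activity of reaction *j* is `fⱼ = |vⱼ|`,
   decomposed as `vⱼ = fⱼ⁺ − fⱼ⁻` with binary complementarity in a MILP.
   Graded up-/down-regulation constraints
   (`fⱼ⁺+fⱼ⁻ ≥ fⱼᵂᵀ + k·(fⱼᵐᵃˣ−fⱼᵂᵀ)` and the attenuation analogue) are
   swept over a 0–1 grid; reactions whose forced activity monotonically
   raises the product optimum at the perturbed biomass ceiling are
   growth-compatible overexpression (or downregulation) targets.
3. **Cofactor modification analysis (CMA)** — choose ≤ *k* reactions whose
   NAD(H)/NADP(H) specificity is swapped
   (`S^cMod_NADP(H),j = S_NAD(H),j` and vice versa, a binary `yⱼ` routing flux
   through the original or the modified twin but never both) to maximize
   product yield above a biomass floor.
4. **Growth-coupled knockout search** — local search over ≤ 5 reaction
   deletions scored by the product flux *guaranteed* at growth-optimal
   states.
5. **Expression-restoration scanning** — integrate a transcriptome through
   GPR rules (AND→min, OR→max), close lowly expressed reactions, and rank
   the closed reactions by the product-yield gain their restoration brings.
6. **Flux-sum turnover** — `Φᵢ = 0.5 Σⱼ |Sᵢⱼvⱼ|`, the turnover rate of
   metabolite *i* — used e.g. to follow the acetyl-CoA pool under
   branched-chain amino-acid co-feeding at a fixed C-mmol budget.

Everything runs on a bundled, fully documented toy network (`YL-mini`) with
closed-form optima, and equally on any SBML GSMM (e.g. a published
*Y. lipolytica* reconstruction) supplied by the user.

## Worked example

```python
from dcaflux import toy_model, theoretical_max_yield, cma_optimize, flux_sum, resolve_unique
from dcaflux.fba import ConditionConstraints

model = toy_model()
yield_wt = theoretical_max_yield(
    model, "EX_ddda", "EX_glc", uptake=10.0,
    release_reactions=("BIOMASS", "ATPM"),
)
print(f"max DDDA on 10 mmol/gDCW/h glucose: {yield_wt:.3f} mmol/gDCW/h")

state = resolve_unique(
    model, "EX_ddda",
    ConditionConstraints({"EX_glc": (-10.0, -10.0)}),
)
print(f"acetyl-CoA turnover at that optimum: {flux_sum(model, state)['accoa_c']:.2f}")

cc = ConditionConstraints({"EX_glc": (-10.0, -10.0)}, biomass_id="BIOMASS")
swap = cma_optimize(model, "EX_ddda", k=1, biomass_floor=0.0, constraints=cc)
print(f"best NAD->NADP swap: {swap.swapped[0]} "
      f"({swap.product_yield_baseline:.3f} -> {swap.product_yield_swapped:.3f})")
```

prints

```
max DDDA on 10 mmol/gDCW/h glucose: 2.553 mmol/gDCW/h
acetyl-CoA turnover at that optimum: 15.32
best NAD->NADP swap: GLYC (2.553 -> 2.927)
```

The 2.553 is the exact 120/47: each DDDA costs 3 glucose through glycolysis
(6 acetyl-CoA) plus 11/12 glucose through the oxidative PPP (11 NADPH), so
10 glucose supports 120/47 DDDA.  Re-specifying the glycolytic dehydrogenase
(the GAPD analogue) from NAD to NADP supplies 6 of those 11 NADPH for free,
cutting the cost to 41/12 glucose and lifting the ceiling to 120/41 ≈ 2.927.
The acetyl-CoA flux-sum is 6 × 120/47 ≈ 15.32 — six acetyl-CoA turned over
per secreted DDDA.

A `dcaflux` console command exposes the same stages
(`stats`, `curate`, `validate`, `fseof`, `cma`, `knockout`, `tsot`,
`supplement`, `run-all`); try `dcaflux --model toy cma`.

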