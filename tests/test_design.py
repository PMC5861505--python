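"""Knockout local search, context-model restoration and supplementation."""

import itertools

import pytest

from dcaflux import (
    build_context_model,
    knockout_local_search,
    random_expression_profile,
    restoration_scan,
    supplementation_scan,
    toy_model,
)
from dcaflux.core import reaction_from_equation
from dcaflux.design import eligible_knockouts, reaction_expression, score_deletion_set
from dcaflux.fba import ConditionConstraints
from dcaflux.toys import ExpressionProfile

from conftest import MAX_DDDA, MAX_DDDA_LEU


def _coupling_testbed():
    """Toy + a beta-oxidation-like DDCA degradation route, fixed glucose
    uptake and a capped biomass ceiling, so that surplus carbon must leave
    through either the degradation route or the product."""
    model = toy_model()
    betaox = reaction_from_equation(
        model, "BETAOX", "ddca[c] -> 6 accoa[c]", 0, 1000, gpr="g_BETAOX"
    )
    model.add_reactions([betaox])
    model.reactions.BIOMASS.upper_bound = 1.0
    constraints = ConditionConstraints(
        {"EX_glc": (-10.0, -10.0)}, biomass_id="BIOMASS"
    )
    return model, constraints


class TestKnockoutSearch:
    def test_degradation_route_is_deleted_and_production_coupled(self):
        model, cc = _coupling_testbed()
        wild = score_deletion_set(model, (), "EX_ddda", "BIOMASS", cc)
        design = knockout_local_search(
            model, "EX_ddda", max_ko=2, constraints=cc,
            biomass_id="BIOMASS", maintenance_id="ATPM",
        )
        assert "BETAOX" in design.deleted
        assert design.coupled
        assert design.production_at_max_growth > wild[0] + 1e-6

    def test_matches_exhaustive_enumeration_up_to_two_deletions(self):
        model, cc = _coupling_testbed()
        candidates = eligible_knockouts(model, "BIOMASS", "ATPM")
        best_score, best_sets = -1.0, []
        for n in range(3):
            for combo in itertools.combinations(candidates, n):
                score = score_deletion_set(model, combo, "EX_ddda", "BIOMASS", cc)
                if score is None:
                    continue
                if score[0] > best_score + 1e-6:
                    best_score, best_sets = score[0], [set(combo)]
                elif abs(score[0] - best_score) <= 1e-6:
                    best_sets.append(set(combo))
        design = knockout_local_search(
            model, "EX_ddda", max_ko=2, constraints=cc,
            biomass_id="BIOMASS", maintenance_id="ATPM",
        )
        assert design.production_at_max_growth == pytest.approx(best_score, abs=1e-6)
        assert any(set(design.deleted) <= s or set(design.deleted) == s
                   for s in best_sets)

    def test_max_ko_zero_returns_wild_type(self):
        model, cc = _coupling_testbed()
        design = knockout_local_search(
            model, "EX_ddda", max_ko=0, constraints=cc,
            biomass_id="BIOMASS", maintenance_id="ATPM",
        )
        assert design.deleted == ()

    def test_biomass_maintenance_and_exchanges_ineligible(self, toy):
        candidates = eligible_knockouts(toy, "BIOMASS", "ATPM")
        assert "BIOMASS" not in candidates
        assert "ATPM" not in candidates
        assert not any(c.startswith("EX_") or c.startswith("DM_") for c in candidates)


class TestContextModel:
    def test_planted_low_ppp_is_removed(self, toy):
        values = {g.id: 1000.0 for g in toy.genes}
        values["g_PPP"] = 0.5
        profile = ExpressionProfile(values, planted_high=set(values) - {"g_PPP"})
        _, removed, flagged = build_context_model(
            toy, profile, threshold_percentile=25, biomass_id="BIOMASS"
        )
        assert removed == {"PPP"}
        assert flagged == set()

    def test_zero_percentile_removes_nothing(self, toy):
        profile = random_expression_profile(toy, seed=7)
        _, removed, flagged = build_context_model(
            toy, profile, threshold_percentile=0, biomass_id="BIOMASS"
        )
        assert removed == set() and flagged == set()

    def test_unrelated_genes_rejected(self, toy):
        profile = ExpressionProfile({"not_a_gene": 1.0})
        with pytest.raises(ValueError, match="no genes"):
            build_context_model(toy, profile, biomass_id="BIOMASS")

    def test_essential_reactions_kept_and_flagged(self, toy):
        values = {g.id: 1000.0 for g in toy.genes}
        values["g_GLCt"] = 0.1  # closing glucose transport kills growth
        profile = ExpressionProfile(values)
        _, removed, flagged = build_context_model(
            toy, profile, threshold_percentile=25, biomass_id="BIOMASS"
        )
        assert "GLCt" in flagged and "GLCt" not in removed

    def test_gpr_evaluation_and_or(self, toy):
        toy.reactions.PPP.gene_reaction_rule = "(gA and gB) or gC"
        values = {"gA": 5.0, "gB": 2.0, "gC": 3.0}
        assert reaction_expression(toy.reactions.PPP, values) == 3.0
        assert reaction_expression(toy.reactions.PPP, {"gA": 5.0, "gB": 2.0}) == 2.0

    def test_partition_recovery_across_seeds(self, toy):
        """Percentile thresholding recovers the planted partition in almost
        every random profile (20-seed spot check; the acceptance suite runs
        the full 100)."""
        hits = 0
        for seed in range(20):
            profile = random_expression_profile(toy, seed=seed, active_fraction=0.75)
            low = profile.low_genes()
            planted = {
                r.id for r in toy.reactions
                if r.gene_reaction_rule and set(g.id for g in r.genes) <= low
            }
            _, removed, flagged = build_context_model(
                toy, profile, threshold_percentile=25, biomass_id="BIOMASS"
            )
            if removed | flagged == planted:
                hits += 1
        assert hits >= 19


class TestRestorationScan:
    def test_restoring_ppp_recovers_full_yield_from_zero(self, toy):
        values = {g.id: 1000.0 for g in toy.genes}
        values["g_PPP"] = 0.5
        profile = ExpressionProfile(values)
        context, removed, _ = build_context_model(
            toy, profile, threshold_percentile=25, biomass_id="BIOMASS"
        )
        assert removed == {"PPP"}
        bounds = {rid: toy.reactions.get_by_id(rid).bounds for rid in removed}
        targets = restoration_scan(
            context, removed, "EX_ddda",
            constraints=ConditionConstraints({"EX_glc": (-10.0, -10.0)}),
            original_bounds=bounds,
        )
        assert [t.reaction_id for t in targets] == ["PPP"]
        top = targets[0]
        assert top.from_zero
        assert top.yield_context == pytest.approx(0.0, abs=1e-9)
        assert top.yield_restored == pytest.approx(MAX_DDDA, abs=1e-6)

    def test_improvements_nonnegative_and_joint_restoration_dominates(self, toy):
        from dcaflux import optimize

        values = {g.id: 1000.0 for g in toy.genes}
        values["g_PPP"] = 0.5
        values["g_ACC"] = 0.6
        profile = ExpressionProfile(values)
        context, removed, _ = build_context_model(
            toy, profile, threshold_percentile=25, biomass_id="BIOMASS"
        )
        bounds = {rid: toy.reactions.get_by_id(rid).bounds for rid in removed}
        cc = ConditionConstraints({"EX_glc": (-10.0, -10.0)})
        targets = restoration_scan(
            context, removed, "EX_ddda", constraints=cc, original_bounds=bounds
        )
        assert all(t.yield_restored >= t.yield_context - 1e-9 for t in targets)
        with context:
            for rid in removed:
                context.reactions.get_by_id(rid).bounds = bounds[rid]
            joint = optimize(context, "EX_ddda", constraints=cc).objective_value
        best_single = max((t.yield_restored for t in targets), default=0.0)
        assert joint >= best_single - 1e-6

    def test_unknown_removed_reaction_rejected(self, toy):
        with pytest.raises(ValueError, match="not in the context model"):
            restoration_scan(toy, ["NOPE"], "EX_ddda")


class TestSupplementation:
    def test_leucine_raises_ddda_optimum(self, toy):
        toy.reactions.LEUDEG.bounds = (0.0, 1000.0)
        report = supplementation_scan(
            toy, "EX_ddda", "EX_glc", {"leucine": "EX_leu"},
            panel=["accoa_c", "ddda_c", "nadph_c"],
        )
        assert report.product_optimum("baseline") == pytest.approx(MAX_DDDA, abs=1e-6)
        assert report.product_optimum("leucine") == pytest.approx(
            MAX_DDDA_LEU, abs=1e-6
        )

    def test_acetyl_coa_turnover_increases_with_leucine(self, toy):
        toy.reactions.LEUDEG.bounds = (0.0, 1000.0)
        report = supplementation_scan(
            toy, "EX_ddda", "EX_glc", {"leucine": "EX_leu"}, panel=["accoa_c"]
        )
        assert report.fluxsum("leucine", "accoa_c") > report.fluxsum(
            "baseline", "accoa_c"
        ) + 1e-6

    def test_zero_budget_is_baseline(self, toy):
        toy.reactions.LEUDEG.bounds = (0.0, 1000.0)
        report = supplementation_scan(
            toy, "EX_ddda", "EX_glc", {"leucine": "EX_leu"}, c_mmol_budget=0.0
        )
        assert report.product_optimum("leucine") == pytest.approx(
            report.product_optimum("baseline"), abs=1e-9
        )

    def test_missing_degradation_path_skipped(self, toy):
        # LEUDEG stays closed: leucine cannot be metabolized
        with pytest.warns(UserWarning, match="cannot be metabolized"):
            report = supplementation_scan(
                toy, "EX_ddda", "EX_glc", {"leucine": "EX_leu"}
            )
        assert report.skipped == {"leucine": "no degradation path"}
        assert "leucine" not in report.conditions

    def test_molar_rate_uses_carbon_number(self, toy):
        toy.reactions.LEUDEG.bounds = (0.0, 1000.0)
        report = supplementation_scan(
            toy, "EX_ddda", "EX_glc", {"leucine": "EX_leu"}, c_mmol_budget=10.0
        )
        state = report.conditions["leucine"]["state"]
        # leucine is C6: 10 C-mmol -> 10/6 mmol uptake, fully consumed
        assert state["EX_leu"] == pytest.approx(-10.0 / 6.0, abs=1e-6)
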