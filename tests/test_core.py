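"""Model container, SBML round trips, curation ledger and mass balance."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcaflux.core import (
    BiomassComposition,
    CurationEntry,
    CurationLedger,
    apply_curation,
    build_biomass_reaction,
    check_mass_balance,
    model_stats,
    parse_equation,
    parse_formula,
    read_curation_ledger,
    read_sbml,
    reaction_from_equation,
    write_sbml,
)


class TestEquationGrammar:
    @pytest.mark.parametrize(
        "equation, stoich, reversible",
        [
            ("2 A[c] + B[c] -> C[e]", {("A", "c"): -2, ("B", "c"): -1, ("C", "e"): 1}, False),
            ("A[c] <=> B[m]", {("A", "c"): -1, ("B", "m"): 1}, True),
            ("glc[e] <=> ", {("glc", "e"): -1}, True),
            ("0.5 o2[c] + nadh[c] -> nad[c]", {("o2", "c"): -0.5, ("nadh", "c"): -1, ("nad", "c"): 1}, False),
        ],
    )
    def test_parse(self, equation, stoich, reversible):
        got, rev = parse_equation(equation)
        assert got == stoich
        assert rev is reversible

    def test_no_arrow_rejected(self):
        with pytest.raises(ValueError, match="arrow"):
            parse_equation("A[c] + B[c]")

    def test_bad_term_rejected(self):
        with pytest.raises(ValueError, match="term"):
            parse_equation("A -> B[c]")


class TestSbmlRoundTrip:
    def test_stats_bounds_and_stoichiometry_survive(self, toy, tmp_path):
        path = tmp_path / "toy.xml"
        write_sbml(toy, str(path))
        back = read_sbml(str(path))
        assert model_stats(back) == model_stats(toy)
        for rxn in toy.reactions:
            other = back.reactions.get_by_id(rxn.id)
            assert other.lower_bound == pytest.approx(rxn.lower_bound, abs=1e-9)
            assert other.upper_bound == pytest.approx(rxn.upper_bound, abs=1e-9)
            assert {m.id: c for m, c in other.metabolites.items()} == {
                m.id: c for m, c in rxn.metabolites.items()
            }

    def test_negative_lower_bound_preserved(self, toy, tmp_path):
        toy.reactions.GLYC.bounds = (-1000.0, 1000.0)
        path = tmp_path / "rev.xml"
        write_sbml(toy, str(path))
        back = read_sbml(str(path))
        assert back.reactions.GLYC.lower_bound == -1000.0

    def test_parse_failure_is_io_error(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("not sbml at all")
        with pytest.raises(IOError):
            read_sbml(str(bad))


class TestCuration:
    def _ledger(self):
        return CurationLedger(
            entries=[
                CurationEntry("add", "NEWRXN", "pyr[c] -> 3 co2[c]", 0, 1000, "g_NEW"),
                CurationEntry("remove", "LEUDEG"),
                CurationEntry("modify_bounds", "ATPM", lower_bound=2.5),
            ]
        )

    def test_apply_reports_summary(self, toy):
        curated, summary = apply_curation(toy, self._ledger())
        assert (summary.n_added, summary.n_removed, summary.n_modified) == (1, 1, 1)
        assert "NEWRXN" in curated.reactions
        assert "LEUDEG" not in curated.reactions
        assert curated.reactions.ATPM.lower_bound == 2.5
        # input untouched
        assert "NEWRXN" not in toy.reactions

    def test_empty_ledger_is_identity(self, toy):
        curated, summary = apply_curation(toy, CurationLedger())
        assert model_stats(curated) == model_stats(toy)
        assert (summary.n_added, summary.n_removed, summary.n_modified) == (0, 0, 0)

    def test_remove_unknown_reaction_rejected(self, toy):
        ledger = CurationLedger(entries=[CurationEntry("remove", "NOPE")])
        with pytest.raises(ValueError, match="NOPE"):
            apply_curation(toy, ledger)

    def test_inverse_ledger_restores_stats(self, toy):
        forward = CurationLedger(
            entries=[
                CurationEntry("add", "NEWRXN", "pyr[c] -> 3 co2[c]", 0, 1000),
                CurationEntry("remove", "LEUDEG"),
            ]
        )
        leudeg = toy.reactions.LEUDEG
        inverse = CurationLedger(
            entries=[
                CurationEntry(
                    "add",
                    "LEUDEG",
                    "leu[c] -> 3 accoa[c]",
                    leudeg.lower_bound,
                    leudeg.upper_bound,
                    leudeg.gene_reaction_rule,
                ),
                CurationEntry("remove", "NEWRXN"),
            ]
        )
        curated, _ = apply_curation(toy, forward)
        restored, _ = apply_curation(curated, inverse)
        assert model_stats(restored) == model_stats(toy)

    def test_tsv_round_trip(self, toy, tmp_path):
        path = tmp_path / "ledger.tsv"
        path.write_text(
            "action\treaction_id\tequation\tlower_bound\tupper_bound\tgpr\tnote\n"
            "add\tNEWRXN\tpyr[c] -> 3 co2[c]\t0\t1000\tg_NEW\tx\n"
            "modify_bounds\tATPM\t\t2.5\t\t\t\n"
        )
        ledger = read_curation_ledger(str(path))
        assert [e.action for e in ledger.entries] == ["add", "modify_bounds"]
        _, summary = apply_curation(toy, ledger)
        assert (summary.n_added, summary.n_modified) == (1, 1)


class TestBiomassAssembly:
    def test_gam_becomes_atp_coefficient(self):
        comp = BiomassComposition({"accoa_c": 10.0}, gam=23.09, ngam=5.03)
        biomass, _ = build_biomass_reaction(comp)
        coeffs = {m.id: c for m, c in biomass.metabolites.items()}
        assert coeffs["atp_c"] == pytest.approx(-23.09)
        assert coeffs["adp_c"] == pytest.approx(23.09)
        assert coeffs["accoa_c"] == pytest.approx(-10.0)
        assert coeffs["biomass_c"] == pytest.approx(1.0)

    def test_ngam_becomes_maintenance_lower_bound(self):
        comp = BiomassComposition({"accoa_c": 1.0}, gam=23.09, ngam=5.03)
        _, maintenance = build_biomass_reaction(comp)
        assert maintenance.lower_bound == pytest.approx(5.03)

    def test_negative_fraction_rejected(self):
        comp = BiomassComposition({"accoa_c": -1.0}, gam=1.0, ngam=0.0)
        with pytest.raises(ValueError, match="negative"):
            build_biomass_reaction(comp)

    def test_degenerate_composition_warns(self):
        comp = BiomassComposition({"accoa_c": 0.0}, gam=0.0, ngam=0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            build_biomass_reaction(comp)


class TestMassBalance:
    def test_hydrogen_imbalance_flagged(self, toy):
        # glc (C6H12O6) -> 2 pyr (C3H4O3): carbon balances, hydrogen does not
        rxn = reaction_from_equation(toy, "BADGLYC", "glc[c] -> 2 pyr[c]")
        toy.add_reactions([rxn])
        report = check_mass_balance(toy, elements=["H"])
        assert "BADGLYC" in report.imbalanced
        assert report.imbalanced["BADGLYC"]["H"] == pytest.approx(-4.0)

    def test_balanced_carbon_audit_is_clean(self, toy):
        report = check_mass_balance(toy, elements=["C"])
        assert report.imbalanced == {}
        assert report.unchecked == []

    def test_missing_formulas_reported_unchecked(self, toy):
        for met in toy.metabolites:
            met.formula = ""
        report = check_mass_balance(toy)
        assert report.imbalanced == {}
        # every non-boundary, non-biomass reaction is now uncheckable
        assert "GLYC" in report.unchecked and "PPP" in report.unchecked

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_verdict_invariant_under_positive_scaling(self, scale):
        from dcaflux import toy_model

        model = toy_model()
        rxn = reaction_from_equation(model, "BADGLYC", "glc[c] -> 2 pyr[c]")
        model.add_reactions([rxn])
        rxn.add_metabolites(
            {m: c * (scale - 1) for m, c in rxn.metabolites.items()}
        )
        report = check_mass_balance(model, elements=["C", "H"])
        assert "BADGLYC" in report.imbalanced
        assert "H" in report.imbalanced["BADGLYC"]
        assert "C" not in report.imbalanced["BADGLYC"]

    def test_formula_parser(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
        assert parse_formula("CO2") == {"C": 1, "O": 2}
        assert parse_formula("") == {}
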