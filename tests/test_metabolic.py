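"""GPR rules, FBA against an independent solver, TAG/biomass splitting,
knockdown bounds, the rho score and the precursor/overlap utilities."""

import math

import numpy as np
import pytest

from lipidtrn.metabolic import (
    GprRule,
    KnockdownConfig,
    MetabolicModel,
    ModelError,
    Reaction,
    affected_reactions,
    classify_condition_overlap,
    fba,
    gene_knockdown_bounds,
    load_model,
    precursor_genes,
    rho,
    screen_targets,
    split_tag_from_biomass,
)
from lipidtrn.synthetic import random_toy_network, simulate_toy_metabolic_model


def cobra_objective(model: MetabolicModel, objective_id: str) -> float:
    """Independent LP oracle: rebuild the network in cobrapy and optimize."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {m: cobra.Metabolite(m) for m in model.metabolites}
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = -1e6 if math.isinf(r.lb) else r.lb
        cr.upper_bound = 1e6 if math.isinf(r.ub) else r.ub
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
    cm.objective = objective_id
    return float(cm.slim_optimize())


class TestGprRules:
    def test_tree_leaves_and_genes(self):
        rule = GprRule("(g1 and g2) or g3")
        assert rule.genes == frozenset({"g1", "g2", "g3"})

    @pytest.mark.parametrize(
        "rule,knocked,expected",
        [
            ("g1 or g2", {"g1"}, True),  # isozyme rescues
            ("g1 and g2", {"g1"}, False),  # complex subunit loss disables
            ("(g1 and g2) or g3", {"g1"}, True),
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("Cre02.g082750", {"Cre02.g082750"}, False),  # dotted locus ids parse
            ("", {"g1"}, True),  # no rule: reaction unaffected by any gene
        ],
    )
    def test_evaluation_under_knockouts(self, rule, knocked, expected):
        assert GprRule(rule).evaluate(knocked) is expected

    @pytest.mark.parametrize("bad", ["g1 or", "(g1 and g2", "and g1", "g1 g2 or"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(ModelError):
            GprRule(bad)


class TestFba:
    def test_linear_chain_objective(self, chain_model):
        model, _ = chain_model
        assert fba(model, "BM_TAG").objective_value == pytest.approx(10.0, abs=1e-9)

    def test_two_to_one_stoichiometry_halves_yield(self):
        model = MetabolicModel(
            id="half",
            metabolites=["A", "B"],
            reactions=[
                Reaction("SRC_A", {"A": 1.0}, 0, 10.0),
                Reaction("R1", {"A": -2.0, "B": 1.0}, 0, math.inf),
                Reaction("BM_TAG", {"B": -1.0}, 0, math.inf),
            ],
        )
        assert fba(model, "BM_TAG").objective_value == pytest.approx(5.0, abs=1e-9)

    def test_agreement_with_independent_cobra_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            model = random_toy_network(rng)
            ours = fba(model, "OBJ", parsimonious=False).objective_value
            theirs = cobra_objective(model, "OBJ")
            assert ours == pytest.approx(theirs, abs=1e-6)

    def test_every_solution_is_mass_balanced(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            model = random_toy_network(rng)
            sol = fba(model, "OBJ")
            S = model.stoichiometric_matrix()
            v = np.array([sol.fluxes[r] for r in model.reaction_ids])
            assert np.abs(S @ v).max() <= 1e-6

    def test_infeasible_model_signals_not_raises(self):
        model = MetabolicModel(
            id="inf",
            metabolites=["A", "B"],
            reactions=[
                Reaction("SRC_A", {"A": 1.0}, 5.0, 10.0),  # forced uptake
                Reaction("BM", {"B": -1.0}, 0, math.inf),  # nothing consumes A
            ],
        )
        assert fba(model, "BM").status == "infeasible"


class TestSplitTag:
    def _biomass_model(self):
        return MetabolicModel(
            id="bm",
            metabolites=["protein", "tag"],
            reactions=[
                Reaction("SRC_P", {"protein": 1.0}, 0, 10.0),
                Reaction("SRC_T", {"tag": 1.0}, 0, 10.0),
                Reaction("BIOMASS", {"protein": -1.0, "tag": -0.2}, 0, math.inf),
            ],
            biomass_id="BIOMASS",
        )

    def test_split_moves_tag_species_to_exchange(self):
        out = split_tag_from_biomass(self._biomass_model(), ["tag"])
        bm = out.reaction("BM_TAG")
        ex = out.reaction("EX_TAG")
        assert bm.stoich == {"protein": -1.0}
        assert ex.stoich == {"tag": -0.2}
        out.require_designated()

    def test_empty_species_list_rejected(self):
        with pytest.raises(ModelError, match="non-empty"):
            split_tag_from_biomass(self._biomass_model(), [])

    def test_double_split_rejected(self):
        once = split_tag_from_biomass(self._biomass_model(), ["tag"])
        with pytest.raises(ModelError, match="not consumed"):
            split_tag_from_biomass(once, ["tag"])

    def test_missing_designated_reaction_detected(self):
        model = self._biomass_model()
        model.biomass_id = None
        with pytest.raises(ModelError):
            split_tag_from_biomass(model, ["tag"])
        plain = self._biomass_model()
        with pytest.raises(ModelError, match="EX_TAG"):
            plain.tag_exchange_id = None
            plain.require_designated()


class TestKnockdownBounds:
    def test_single_gene_reaction_capped_at_sixteenth(self, chain_model):
        model, _ = chain_model
        wt = fba(model, "BM_TAG")
        wt.fluxes["R1"] = 8.0  # exercise the stated bound arithmetic directly
        pert = gene_knockdown_bounds(model, wt, "g1")
        assert (pert.reaction("R1").lb, pert.reaction("R1").ub) == (0.0, 0.5)

    def test_isozyme_rescues_under_boolean_gpr(self, isozyme_model):
        model, _ = isozyme_model
        assert affected_reactions(model, "g1", "boolean") == []
        assert affected_reactions(model, "g1", "any-association") == ["R1"]

    def test_complex_subunit_loss_constrains(self):
        model = MetabolicModel(
            id="cx",
            metabolites=["A", "B"],
            reactions=[
                Reaction("SRC_A", {"A": 1.0}, 0, 10.0),
                Reaction("R1", {"A": -1.0, "B": 1.0}, 0, math.inf, "g1 and g2"),
                Reaction("BM_TAG", {"B": -1.0}, 0, math.inf),
            ],
        )
        assert affected_reactions(model, "g1", "boolean") == ["R1"]

    def test_absent_gene_is_noop_with_warning(self, chain_model):
        model, _ = chain_model
        wt = fba(model, "BM_TAG")
        with pytest.warns(UserWarning, match="no-op"):
            pert = gene_knockdown_bounds(model, wt, "ghost")
        assert [(r.lb, r.ub) for r in pert.reactions] == [(r.lb, r.ub) for r in model.reactions]

    def test_zero_flux_reaction_pinned_to_zero(self, branch_model):
        model, _ = branch_model
        wt = fba(model, "BM_TAG")
        pert = gene_knockdown_bounds(model, wt, "gD")
        assert (pert.reaction("R_D").lb, pert.reaction("R_D").ub) == (0.0, 0.0)


class TestRho:
    def test_untouched_gene_scores_exactly_one(self, branch_model):
        model, _ = branch_model
        res = rho(model, "ghost_gene")
        assert res.rho == 1.0 and res.viable

    @pytest.mark.parametrize("kind", ["chain", "branch", "isozyme"])
    def test_hand_solved_fixture_outcomes(self, kind):
        model, truth = simulate_toy_metabolic_model(kind)
        for gene, by_factor in truth.items():
            for factor, expected in by_factor.items():
                res = rho(model, gene, KnockdownConfig(kd_factor=factor))
                assert res.viable is expected["viable"], (kind, gene, factor)
                assert res.bm_ratio == pytest.approx(expected["bm_ratio"], abs=1e-8)
                assert res.tag_ratio == pytest.approx(expected["tag_ratio"], abs=1e-8)
                if expected["rho"] is None:
                    assert res.rho is None
                else:
                    assert res.rho == pytest.approx(expected["rho"], abs=1e-8)

    def test_chain_full_knockdown_is_inviable(self, chain_model):
        model, _ = chain_model
        res = rho(model, "g1", KnockdownConfig(kd_factor=16.0))
        assert res.bm_ratio == pytest.approx(0.0625, abs=1e-9)
        assert not res.viable and res.rho is None

    def test_deeper_knockdown_never_increases_perturbed_fluxes(self, branch_model):
        model, _ = branch_model
        prev_bm, prev_tag = math.inf, math.inf
        for factor in (2.0, 4.0, 8.0, 16.0):
            res = rho(model, "gB", KnockdownConfig(kd_factor=factor))
            assert res.bm_pert <= prev_bm + 1e-9
            assert res.tag_pert <= prev_tag + 1e-9
            prev_bm, prev_tag = res.bm_pert, res.tag_pert


class TestScreen:
    def test_planted_target_is_the_only_flag(self, branch_model):
        model, _ = branch_model
        results = screen_targets(model, ["gB", "gC", "gD"], KnockdownConfig(kd_factor=2.0))
        flagged = [r.gene for r in results if r.viable and r.rho is not None and r.rho > 1]
        assert flagged == ["gC"]
        assert [r.gene for r in results] == ["gC", "gD", "gB"]  # rho-descending order

    def test_candidates_outside_model_score_neutral(self, branch_model):
        model, _ = branch_model
        results = screen_targets(model, ["nope1", "nope2"], KnockdownConfig(kd_factor=2.0))
        assert all(r.rho == 1.0 for r in results)
        assert not any(r.rho > 1 for r in results)

    def test_result_order_invariant_to_input_order(self, branch_model):
        model, _ = branch_model
        a = screen_targets(model, ["gB", "gC", "gD"], KnockdownConfig(kd_factor=2.0))
        b = screen_targets(model, ["gD", "gB", "gC"], KnockdownConfig(kd_factor=2.0))
        assert [(r.gene, r.rho) for r in a] == [(r.gene, r.rho) for r in b]


class TestPrecursorGenes:
    def test_only_path_gene_found(self, chain_model):
        model, _ = chain_model
        assert precursor_genes(model, ["B"]) == frozenset({"g1"})

    def test_idle_branch_gene_excluded(self, branch_model):
        model, _ = branch_model
        genes = precursor_genes(model, ["B"])
        assert "gB" in genes and "gC" not in genes and "gD" not in genes

    def test_isozyme_pair_both_returned(self, isozyme_model):
        model, _ = isozyme_model
        assert precursor_genes(model, ["B"]) == frozenset({"g1", "g2"})

    def test_unproducible_precursor_warns_empty(self):
        model = MetabolicModel(
            id="dead",
            metabolites=["A", "B"],
            reactions=[
                Reaction("SRC_A", {"A": 1.0}, 0, 10.0),
                Reaction("SINK_A", {"A": -1.0}, 0, math.inf, "g1"),
            ],
        )
        with pytest.warns(UserWarning, match="cannot be produced"):
            assert precursor_genes(model, ["B"]) == frozenset()


class TestConditionOverlap:
    def test_membership_classes(self):
        got = classify_condition_overlap(
            ["a", "b", "c", "d"], s_down={"b", "c"}, p_down={"c", "d"}
        )
        classes = {o.gene: o.overlap_class for o in got}
        assert classes == {"a": "N-only", "b": "N+S", "c": "N+S+P", "d": "N+P"}


class TestModelIO:
    def test_json_roundtrip(self, tmp_path, branch_model):
        model, _ = branch_model
        path = tmp_path / "branch.json"
        model.to_json(path)
        back = load_model(path)
        assert back.reaction_ids == model.reaction_ids
        assert back.genes == model.genes
        assert fba(back, "BM_TAG").objective_value == pytest.approx(5.0, abs=1e-9)

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ModelError, match="unknown metabolites"):
            MetabolicModel(id="x", metabolites=["A"], reactions=[Reaction("R", {"Z": 1.0})])

    def test_sbml_roundtrip_through_cobra(self, tmp_path, chain_model):
        import cobra

        model, _ = chain_model
        cm = cobra.Model("chain")
        mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
        rxns = []
        for r in model.reactions:
            cr = cobra.Reaction(r.id)
            cr.lower_bound, cr.upper_bound = r.lb, min(r.ub, 1e6)
            rxns.append(cr)
        cm.add_reactions(rxns)
        for r, cr in zip(model.reactions, rxns):
            cr.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
            cr.gene_reaction_rule = r.gpr.text
        path = tmp_path / "chain.xml"
        cobra.io.write_sbml_model(cm, str(path))
        back = load_model(path)
        assert set(back.reaction_ids) == set(model.reaction_ids)
        assert back.genes == {"g1"}
        assert fba(back, "BM_TAG").objective_value == pytest.approx(10.0, abs=1e-6)
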