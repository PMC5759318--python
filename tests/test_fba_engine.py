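"""LP core, conditions, screens, essentiality, ATP yields."""

import numpy as np
import pytest

from halogem.fba_engine import (
    ConditionError,
    ConditionSpec,
    apply_condition,
    atp_yield_per_substrate,
    essentiality_comparison,
    optimize,
    screen_carbon_sources,
    set_medium_m63,
    single_gene_deletions,
)
from halogem.network_core import GPRRule, Metabolite, MetabolicModel, Reaction
from halogem.synthetic_data import (
    brute_force_lp_optimum,
    make_condition_pair,
    make_random_network,
    make_toy_core_model,
)


def _chain_model():
    """EX_A (lb -10) -> A; biomass consumes 2 A per unit: optimum 5."""
    return MetabolicModel(
        metabolites=[Metabolite(id="A[c]")],
        reactions=[
            Reaction("EX_A", "", {"A[c]": -1.0}, -10.0, 0.0, kind="exchange"),
            Reaction("BIO", "", {"A[c]": -2.0}, 0.0, 1000.0, kind="biomass"),
        ],
        objective_id="BIO",
    )


class TestOptimize:
    def test_chain_yield(self):
        sol = optimize(_chain_model())
        assert sol.ok
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)
        assert sol.fluxes["EX_A"] == pytest.approx(-10.0, abs=1e-7)

    def test_no_carbon_no_growth(self):
        m = _chain_model()
        m.get_reaction("EX_A").lower_bound = 0.0
        sol = optimize(m)
        assert sol.ok and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_matches_analytic_optimum_on_core_toy(self, toy_core):
        model, truth = toy_core
        sol = optimize(model)
        assert sol.objective_value == pytest.approx(
            float(truth.analytic_optimum), abs=1e-7
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_vertex_enumeration_oracle(self, seed):
        model = make_random_network(4, 6, seed)
        oracle = brute_force_lp_optimum(model)
        sol = optimize(model)
        assert sol.ok and oracle is not None
        assert sol.objective_value == pytest.approx(float(oracle), abs=1e-7)

    def test_optimum_invariant_to_reaction_permutation(self, toy_core):
        model, _ = toy_core
        perm = model.copy()
        rng = np.random.default_rng(3)
        order = rng.permutation(len(perm.reactions))
        perm.reactions = [perm.reactions[i] for i in order]
        perm.metabolites = [perm.metabolites[i]
                            for i in rng.permutation(len(perm.metabolites))]
        assert optimize(perm).objective_value == pytest.approx(
            optimize(model).objective_value, abs=1e-7
        )

    def test_relaxing_bound_never_decreases_optimum(self, toy_core):
        model, _ = toy_core
        base = optimize(model).objective_value
        relaxed = model.copy()
        relaxed.get_reaction("EX_glc").lower_bound = -12.0
        assert optimize(relaxed).objective_value >= base - 1e-9

    def test_unbounded_reported_not_raised(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id="A[c]")],
            reactions=[
                Reaction("in", "", {"A[c]": 1.0}, 0.0, np.inf, kind="exchange"),
                Reaction("out", "", {"A[c]": -1.0}, 0.0, np.inf, kind="exchange"),
            ],
            objective_id="out",
        )
        assert optimize(m).status == "unbounded"


class TestConditions:
    def test_apply_condition_sets_bounds_and_objective(self, toy_core):
        model, _ = toy_core
        cond = ConditionSpec("c", "BIO_H", {"EX_glc": (-6.5, 0.0)}, {"ATPM": 7.6})
        out = apply_condition(model, cond)
        assert out.get_reaction("EX_glc").lower_bound == -6.5
        assert out.objective_id == "BIO_H"
        atpm = out.get_reaction("ATPM")
        assert atpm.lower_bound == atpm.upper_bound == 7.6
        # original untouched
        assert model.get_reaction("EX_glc").lower_bound == -10.0
        assert model.objective_id == "BIO_L"

    def test_apply_condition_idempotent(self, toy_core):
        model, _ = toy_core
        cond = ConditionSpec("c", "BIO_H", {"EX_glc": (-6.5, 0.0)})
        once = apply_condition(model, cond)
        twice = apply_condition(once, cond)
        assert [(r.lower_bound, r.upper_bound) for r in once.reactions] == [
            (r.lower_bound, r.upper_bound) for r in twice.reactions
        ]

    def test_unknown_override_rejected(self, toy_core):
        model, _ = toy_core
        cond = ConditionSpec("c", "BIO_L", {"EX_nope": (-1.0, 0.0)})
        with pytest.raises(ConditionError, match="EX_nope"):
            apply_condition(model, cond)

    def test_override_must_target_exchange(self, toy_core):
        model, _ = toy_core
        cond = ConditionSpec("c", "BIO_L", {"TCA": (0.0, 1.0)})
        with pytest.raises(ConditionError, match="kind"):
            apply_condition(model, cond)

    def test_set_medium_opens_inorganics_closes_organics(self, toy_core):
        model, _ = toy_core
        out = set_medium_m63(model, ["EX_o2", "EX_co2"])
        assert out.get_reaction("EX_o2").lower_bound == -1000.0
        assert out.get_reaction("EX_glc").lower_bound == 0.0  # closed until chosen

    def test_set_medium_missing_exchange_warns(self, toy_core, caplog):
        model, _ = toy_core
        with caplog.at_level("WARNING"):
            set_medium_m63(model, ["EX_o2", "EX_missing"])
        assert any("EX_missing" in rec.message for rec in caplog.records)


class TestScreen:
    def test_glucose_supports_growth(self, toy_core):
        model, _ = toy_core
        table = screen_carbon_sources(model, ["EX_glc"], uptake=10.0)
        assert bool(table.loc["EX_glc", "grows"])

    def test_closed_only_source_means_no_growth(self, toy_core):
        model, _ = toy_core
        # CO2 cannot serve as the sole carbon source here
        table = screen_carbon_sources(
            model, ["EX_co2"], uptake=10.0, glucose_exchange_id="EX_glc"
        )
        assert not bool(table.loc["EX_co2", "grows"])

    def test_non_exchange_id_rejected(self, toy_core):
        model, _ = toy_core
        with pytest.raises(ConditionError):
            screen_carbon_sources(model, ["TCA"])


class TestEssentiality:
    def test_isozymes_rescue_complexes_break(self, toy_core):
        model, truth = toy_core
        report = single_gene_deletions(model)
        assert {"gEmp1", "gEmp2"} & report.essential == set()
        assert {"gPtsA", "gPtsB"} <= report.essential

    def test_matches_generator_truth_both_conditions(self, toy_core):
        model, truth = toy_core
        pair = make_condition_pair(pin_growth=None)
        rep_low = single_gene_deletions(model, pair.low)
        rep_high = single_gene_deletions(model, pair.high)
        assert rep_low.essential == truth.essential_genes
        assert rep_high.essential == truth.essential_genes
        comp = essentiality_comparison(rep_low, rep_high)
        assert comp["shared"] == sorted(truth.essential_genes)
        assert comp["only_a"] == [] and comp["only_b"] == []

    def test_gene_without_gpr_is_inert(self, toy_core):
        model, _ = toy_core
        m = model.copy()
        m.genes = m.genes + ["gOrphan"]
        report = single_gene_deletions(m)
        wt = report.wild_type_growth
        assert report.table.loc["gOrphan", "growth_rate"] == pytest.approx(wt)
        assert "gOrphan" not in report.essential


class TestAtpYield:
    def test_hand_stoichiometry_yield_two(self):
        m = MetabolicModel(
            metabolites=[Metabolite(id=x) for x in ("s[c]", "atp[c]", "adp[c]")],
            reactions=[
                Reaction("EX_s", "", {"s[c]": -1.0}, -10.0, 0.0, kind="exchange"),
                Reaction("CAT", "", {"s[c]": -1.0, "adp[c]": -2.0, "atp[c]": 2.0},
                         0.0, 1000.0),
                Reaction("ATPM", "", {"atp[c]": -1.0, "adp[c]": 1.0},
                         0.0, 1000.0, kind="maintenance"),
            ],
            objective_id="ATPM",
        )
        assert atp_yield_per_substrate(m, None, "EX_s") == pytest.approx(2.0, abs=1e-7)

    def test_anaerobic_yield_not_higher(self, toy_core):
        model, _ = toy_core
        aerobic = atp_yield_per_substrate(model, None, "EX_glc")
        anaerobic_model = model.copy()
        anaerobic_model.get_reaction("EX_o2").lower_bound = 0.0
        anaerobic = atp_yield_per_substrate(anaerobic_model, None, "EX_glc")
        assert anaerobic <= aerobic + 1e-9
        # O2-limited optimum: TCA flux 5, surplus pyruvate burned as osmolyte,
        # net (60 + 9*5 - 2*15) ATP per 10 glucose = 7.5 per glucose
        assert aerobic == pytest.approx(7.5, abs=1e-6)

    def test_missing_maintenance_is_error(self):
        with pytest.raises(ConditionError):
            atp_yield_per_substrate(_chain_model(), None, "EX_A")
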