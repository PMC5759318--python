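"""Model data structures, GPR logic, matrix assembly, and IO round-trips."""

import itertools

import numpy as np
import pytest

from halogem.network_core import (
    GPRRule,
    Metabolite,
    MetabolicModel,
    ModelParseError,
    ModelValidationError,
    Reaction,
    build_S,
    evaluate_gpr,
    format_stoichiometry,
    parse_stoichiometry,
    read_model,
    write_model,
)
from halogem.synthetic_data import make_random_network, make_toy_core_model


def _eval_via_python(rule_str: str, knocked_out: set[str], genes: set[str]) -> bool:
    """Independent GPR oracle: substitute booleans and let Python evaluate."""
    expr = rule_str
    for g in sorted(genes, key=len, reverse=True):
        expr = expr.replace(g, str(g not in knocked_out))
    return eval(expr)  # noqa: S307 - controlled test input


class TestGPR:
    @pytest.mark.parametrize(
        "rule, ko, expected",
        [
            ("g1 or g2", {"g1"}, True),  # isozyme rescues
            ("g1 and g2", {"g2"}, False),  # complex broken
            ("(g1 and g2) or g3", {"g1", "g3"}, False),
            ("(g1 and g2) or g3", {"g1"}, True),
            ("", set(), True),  # no association: always active
        ],
    )
    def test_evaluate(self, rule, ko, expected):
        assert evaluate_gpr(GPRRule.parse(rule), ko) is expected

    def test_truth_table_matches_python_eval(self):
        """Exhaustive knockout enumeration agrees with a Python-eval oracle."""
        rules = [
            "g1",
            "g1 and g2",
            "g1 or g2",
            "(g1 and g2) or g3",
            "g1 and (g2 or g3) and g4",
            "((g1 or g2) and g3) or (g4 and g5)",
            "g1 or g2 and g3",  # precedence: and binds tighter
            "(g1 or g2) and (g3 or g4) and (g5 or g6)",
        ]
        for text in rules:
            rule = GPRRule.parse(text)
            genes = sorted(rule.genes())
            assert len(genes) <= 6
            for r in range(len(genes) + 1):
                for ko in itertools.combinations(genes, r):
                    assert rule.evaluate(set(ko)) == _eval_via_python(
                        text, set(ko), set(genes)
                    ), f"{text} with KO {ko}"

    @pytest.mark.parametrize(
        "text",
        ["g1", "g1 and g2", "(a and b) or c", "a or b or (c and d and (e or f))"],
    )
    def test_parse_print_parse_fixpoint(self, text):
        rule = GPRRule.parse(text)
        assert GPRRule.parse(rule.to_string()).root == rule.root

    def test_parse_errors(self):
        with pytest.raises(ModelParseError):
            GPRRule.parse("(g1 and")
        with pytest.raises(ModelParseError):
            GPRRule.parse("g1 g2")


class TestBuildS:
    def test_two_reaction_chain(self):
        model = MetabolicModel(
            metabolites=[Metabolite(id=x) for x in ("A[c]", "B[c]", "C[c]")],
            reactions=[
                Reaction("r1", "", {"A[c]": -1.0, "B[c]": 1.0}, 0, 1000),
                Reaction("r2", "", {"B[c]": -1.0, "C[c]": 1.0}, 0, 1000),
            ],
        )
        S = build_S(model).toarray()
        assert S.tolist() == [[-1, 0], [1, -1], [0, 1]]

    def test_supply_exchange_column(self):
        model = MetabolicModel(
            metabolites=[Metabolite(id="A[e]")],
            reactions=[Reaction("EX_A", "", {"A[e]": 1.0}, 0, 1000, kind="exchange")],
        )
        S = build_S(model).toarray()
        assert S.tolist() == [[1.0]]

    def test_elemental_conservation_on_balanced_fixture(self):
        """Internal columns of S conserve atoms when reactions are balanced."""
        mets = [
            Metabolite(id="a[c]", formula="C2"),
            Metabolite(id="b[c]", formula="C1"),
            Metabolite(id="c[c]", formula="C1"),
        ]
        model = MetabolicModel(
            metabolites=mets,
            reactions=[
                Reaction("split", "", {"a[c]": -1.0, "b[c]": 1.0, "c[c]": 1.0}, 0, 1000),
                Reaction("iso", "", {"b[c]": -1.0, "c[c]": 1.0}, -1000, 1000),
            ],
        )
        S = build_S(model).toarray()
        carbon = np.array([2.0, 1.0, 1.0])
        rng = np.random.default_rng(0)
        for _ in range(10):
            v = rng.normal(size=2)
            assert abs(carbon @ S @ v) < 1e-12


class TestModelValidation:
    def test_duplicate_reaction_ids_rejected(self):
        model = MetabolicModel(
            metabolites=[Metabolite(id="A[c]")],
            reactions=[
                Reaction("r", "", {"A[c]": 1.0}, 0, 1),
                Reaction("r", "", {"A[c]": -1.0}, 0, 1),
            ],
        )
        with pytest.raises(ModelValidationError, match="duplicate"):
            model.validate()

    def test_unknown_metabolite_rejected(self):
        model = MetabolicModel(
            metabolites=[Metabolite(id="A[c]")],
            reactions=[Reaction("r", "", {"B[c]": 1.0}, 0, 1)],
        )
        with pytest.raises(ModelValidationError, match="unknown metabolites"):
            model.validate()

    def test_compartment_suffix_mismatch_rejected(self):
        with pytest.raises(ModelValidationError):
            Metabolite(id="x[c]", compartment="e")

    def test_summary_counts(self, toy_core):
        model, _ = toy_core
        s = model.summary()
        assert s["n_reactions"] == len(model.reactions)
        assert s["n_metabolites"] == 14
        assert s["reactions_by_kind"]["exchange"] == 4
        assert s["reactions_by_kind"]["biomass"] == 2
        assert s["reactions_multi_compartment"] == 5  # the transporters


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["tsv", "sbml"])
    def test_toy_core_round_trip(self, toy_core, tmp_path, fmt):
        model, _ = toy_core
        path = tmp_path / ("m.xml" if fmt == "sbml" else "m")
        write_model(model, path, format=fmt)
        back = read_model(path, format=fmt)
        assert back.metabolite_ids() == model.metabolite_ids()
        assert back.reaction_ids() == model.reaction_ids()
        assert back.genes == model.genes
        assert back.objective_id == model.objective_id
        for a, b in zip(model.reactions, back.reactions):
            assert a.stoichiometry == b.stoichiometry
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
            assert a.gpr.root == b.gpr.root
            assert (a.kind, a.subsystem, a.name) == (b.kind, b.subsystem, b.name)
        for a, b in zip(model.metabolites, back.metabolites):
            assert (a.id, a.name, a.formula, a.charge, a.compartment) == (
                b.id, b.name, b.formula, b.charge, b.compartment)

    @pytest.mark.parametrize("fmt", ["tsv", "sbml"])
    @pytest.mark.parametrize("seed", [1, 2])
    def test_random_network_round_trip(self, tmp_path, fmt, seed):
        model = make_random_network(5, 9, seed)
        path = tmp_path / ("m.xml" if fmt == "sbml" else "m")
        write_model(model, path, format=fmt)
        back = read_model(path, format=fmt)
        assert back.reaction_ids() == model.reaction_ids()
        for a, b in zip(model.reactions, back.reactions):
            assert a.stoichiometry == b.stoichiometry
            assert a.gpr.root == b.gpr.root

    def test_empty_file_is_parse_error(self, tmp_path):
        d = tmp_path / "m"
        d.mkdir()
        (d / "metabolites.tsv").write_text("")
        (d / "reactions.tsv").write_text("")
        with pytest.raises(ModelParseError):
            read_model(d, format="tsv")

    def test_stoichiometry_string_round_trip(self):
        stoich = {"a[c]": -1.0, "b[c]": 2.5, "c[e]": -0.37}
        assert parse_stoichiometry(format_stoichiometry(stoich)) == stoich

    def test_cobra_reads_our_sbml(self, toy_core, tmp_path):
        """Independent cross-check: cobrapy parses our SBML to the same sizes."""
        cobra_io = pytest.importorskip("cobra.io")
        model, _ = toy_core
        path = tmp_path / "toy.xml"
        write_model(model, path, format="sbml")
        cm = cobra_io.read_sbml_model(str(path))
        assert len(cm.reactions) == len(model.reactions)
        assert len(cm.metabolites) == len(model.metabolites)
        assert len(cm.genes) == len(model.genes)
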