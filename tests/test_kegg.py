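"""KEGG module definition parsing, completeness scoring, KO propagation."""

import itertools

import numpy as np
import pytest

from conftest import make_genome
from oracles import definition_atoms, eval_definition
from orthopan.kegg import (
    Alt,
    Atom,
    Complex,
    CompletenessMatrix,
    Gap,
    KoAssignment,
    KoEntry,
    ModuleParseError,
    Optional,
    StepSeq,
    completeness_matrix,
    module_completeness,
    parse_module_definition,
    propagate_annotations,
)
from orthopan.orthology import OrthogroupSet
from orthopan.synthetic import random_module_definition


class TestParser:
    def test_single_atom(self):
        assert parse_module_definition("K00001").expression == Atom("K00001")

    def test_steps_with_alternative(self):
        d = parse_module_definition("(K00001,K00002) K00003")
        assert d.expression == StepSeq(
            (Alt((Atom("K00001"), Atom("K00002"))), Atom("K00003"))
        )

    def test_complex_with_optional_subunit(self):
        d = parse_module_definition("K00001+K00002-K00003")
        assert d.expression == Complex(
            (Atom("K00001"), Atom("K00002"), Optional(Atom("K00003")))
        )

    def test_gap_token(self):
        d = parse_module_definition("K00001 -- K00002")
        assert d.expression == StepSeq((Atom("K00001"), Gap(), Atom("K00002")))

    @pytest.mark.parametrize(
        "text,pos",
        [
            ("K00001+", 7),       # dangling operator
            ("(K00001", 7),       # unbalanced parentheses
            ("K00001,", 8),       # dangling comma (fails at end of text)
            ("K1", 0),            # illegal token
        ],
    )
    def test_parse_errors_carry_position(self, text, pos):
        with pytest.raises(ModuleParseError) as exc:
            parse_module_definition(text)
        assert exc.value.position <= len(text)

    def test_precedence_plus_over_comma_over_space(self):
        d = parse_module_definition("K00001,K00002+K00003 K00004")
        expr = d.expression
        assert isinstance(expr, StepSeq)
        first, second = expr.children
        assert first == Alt((Atom("K00001"), Complex((Atom("K00002"), Atom("K00003")))))
        assert second == Atom("K00004")

    def test_round_trip_stability_random_corpus(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            text = random_module_definition(rng, max_atoms=6)
            tree = parse_module_definition(text).expression
            reparsed = parse_module_definition(
                parse_module_definition(text).serialize()
            ).expression
            assert reparsed == tree, text


class TestCompleteness:
    @pytest.mark.parametrize(
        "definition,kos,expected",
        [
            ("K00001 K00002", {"K00001"}, 0.5),
            ("K00001+K00002", {"K00001"}, 0.0),
            ("K00001-K00002", {"K00001"}, 1.0),
            ("K00001,K00002", {"K00002"}, 1.0),
            ("K00001 --", {"K00001"}, 1.0),
            ("K00001 K00002 K00003 K00004", {"K00001", "K00003"}, 0.5),
        ],
    )
    def test_stated_semantics(self, definition, kos, expected):
        res = module_completeness(parse_module_definition(definition), kos)
        assert res.completeness == pytest.approx(expected)

    def test_gap_as_missing_option(self):
        d = parse_module_definition("K00001 --")
        res = module_completeness(d, {"K00001"}, gap_satisfied=False)
        assert res.completeness == pytest.approx(0.5)

    def test_matches_string_oracle_over_all_subsets(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            text = random_module_definition(rng, max_atoms=5)
            d = parse_module_definition(text)
            atoms = sorted(definition_atoms(text))
            for r in range(len(atoms) + 1):
                for subset in itertools.combinations(atoms, r):
                    kos = set(subset)
                    assert module_completeness(d, kos).completeness == pytest.approx(
                        eval_definition(text, kos)
                    ), (text, kos)

    def test_monotone_in_ko_set(self):
        rng = np.random.default_rng(88)
        for _ in range(40):
            text = random_module_definition(rng, max_atoms=5)
            d = parse_module_definition(text)
            atoms = sorted(definition_atoms(text))
            kos: set[str] = set()
            prev = module_completeness(d, kos).completeness
            for a in atoms:
                kos.add(a)
                cur = module_completeness(d, kos).completeness
                assert cur >= prev - 1e-12
                prev = cur

    def test_nested_module_reference(self):
        inner = parse_module_definition("K00001 K00002", module_id="M00002")
        outer = parse_module_definition("M00002 K00003", module_id="M00001")
        res = module_completeness(
            outer, {"K00001", "K00002", "K00003"}, nested={"M00002": inner}
        )
        assert res.completeness == 1.0
        partial = module_completeness(outer, {"K00003"}, nested={"M00002": inner})
        assert partial.completeness == pytest.approx(0.5)

    def test_unresolved_module_reference_warns(self):
        outer = parse_module_definition("M00099 K00003")
        with pytest.warns(UserWarning, match="M00099"):
            res = module_completeness(outer, {"K00003"})
        assert res.completeness == pytest.approx(0.5)

    def test_satisfied_atoms_reported(self):
        d = parse_module_definition("K00001 (K00002,K00003)")
        res = module_completeness(d, {"K00001", "K00003", "K99999"})
        assert res.satisfied_atoms == {"K00001", "K00003"}


class TestPropagation:
    def _setup(self):
        ogs = OrthogroupSet(groups={
            "OG0": [("A", "A_1"), ("B", "B_1")],
            "OG1": [("A", "A_2"), ("B", "B_2")],
        })
        assignments = KoAssignment(entries=[
            KoEntry("A", "A_1", "K00001"),
        ])
        return ogs, assignments

    def test_unannotated_member_gains_ko(self):
        ogs, assignments = self._setup()
        out = propagate_annotations(assignments, ogs)
        gained = [e for e in out.entries if e.provenance == "propagated"]
        assert len(gained) == 1
        e = gained[0]
        assert (e.genome_id, e.locus_tag, e.ko) == ("B", "B_1", "K00001")
        assert e.source_orthogroup == "OG0"

    def test_direct_entries_untouched(self):
        ogs, assignments = self._setup()
        out = propagate_annotations(assignments, ogs)
        assert out.direct() == assignments.entries

    def test_no_shared_annotation_noop(self):
        ogs = OrthogroupSet(groups={"OG0": [("A", "A_1")], "OG1": [("B", "B_1")]})
        assignments = KoAssignment(entries=[KoEntry("A", "A_1", "K00001")])
        out = propagate_annotations(assignments, ogs)
        assert out.entries == assignments.entries

    def test_idempotent(self):
        ogs, assignments = self._setup()
        once = propagate_annotations(assignments, ogs)
        twice = propagate_annotations(once, ogs)
        assert sorted(map(repr, once.entries)) == sorted(map(repr, twice.entries))

    def test_unknown_gene_is_error(self):
        ogs, _ = self._setup()
        bad = KoAssignment(entries=[KoEntry("A", "GHOST", "K00001")])
        genome = make_genome("A", [("A_1", 0, 30, 1, "MAA")])
        with pytest.raises(ValueError, match="GHOST"):
            propagate_annotations(bad, ogs, genomes=[genome])

    def test_propagated_entry_requires_source(self):
        with pytest.raises(ValueError):
            KoEntry("A", "A_1", "K00001", provenance="propagated")


class TestCompletenessMatrix:
    def _inputs(self):
        ogs = OrthogroupSet(groups={
            "OG0": [("A", "A_1"), ("B", "B_1")],
        })
        assignments = propagate_annotations(
            KoAssignment(entries=[KoEntry("A", "A_1", "K00001")]), ogs
        )
        defs = [parse_module_definition("K00001 K00002", module_id="M00001")]
        return defs, assignments

    def test_propagation_toggle_changes_predicted_cells_only(self):
        defs, assignments = self._inputs()
        direct = completeness_matrix(defs, assignments, ["A", "B"], use_propagated=False)
        prop = completeness_matrix(defs, assignments, ["A", "B"], use_propagated=True)
        assert direct.results[("M00001", "A")].completeness == pytest.approx(0.5)
        assert direct.results[("M00001", "B")].completeness == 0.0
        assert prop.results[("M00001", "B")].completeness == pytest.approx(0.5)
        assert prop.results[("M00001", "B")].used_propagated
        assert not prop.results[("M00001", "A")].used_propagated
        # cell-wise monotonicity
        for key in direct.results:
            assert prop.results[key].completeness >= direct.results[key].completeness

    def test_full_ko_set_is_complete(self):
        defs = [parse_module_definition("K00001 K00002+K00003", module_id="M1")]
        assignments = KoAssignment(entries=[
            KoEntry("A", "A_1", "K00001"),
            KoEntry("A", "A_2", "K00002"),
            KoEntry("A", "A_3", "K00003"),
        ])
        cm = completeness_matrix(defs, assignments, ["A"])
        assert cm.results[("M1", "A")].completeness == 1.0

    def test_empty_assignment_all_zero(self):
        defs = [parse_module_definition("K00001 K00002", module_id="M1")]
        cm = completeness_matrix(defs, KoAssignment(), ["A", "B"])
        assert all(r.completeness == 0.0 for r in cm.results.values())

    def test_ko_gene_counts(self):
        defs, assignments = self._inputs()
        cm = completeness_matrix(defs, assignments, ["A", "B"], use_propagated=True)
        assert cm.ko_gene_counts[("M00001", "A")] == {"K00001": 1, "K00002": 0}
        assert cm.ko_gene_counts[("M00001", "B")] == {"K00001": 1, "K00002": 0}
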