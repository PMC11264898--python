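"""Core selection, alignment concatenation, distances, neighbor joining."""

import numpy as np
import pandas as pd
import pytest

from orthopan.orthology import PresenceMatrix
from orthopan.phylo import (
    NoCoreError,
    concatenate_alignments,
    distance_matrix,
    nj_tree,
    pad_alignment,
    select_core_orthologs,
    SuperAlignment,
)


def _matrix(data, genomes=None):
    genomes = genomes or [f"g{i}" for i in range(len(data[0]))]
    return PresenceMatrix(df=pd.DataFrame(
        data, index=[f"OG{i}" for i in range(len(data))], columns=genomes
    ))


class TestCoreSelection:
    def test_strict_single_copy_core(self):
        m = _matrix([[1, 1, 1], [1, 1, 0], [2, 1, 1], [0, 1, 1]])
        sel = select_core_orthologs(m, max_missing=0)
        assert sel.og_ids == ["OG0"]

    def test_relaxed_includes_one_missing(self):
        m = _matrix([[1, 1, 1], [1, 1, 0]])
        sel = select_core_orthologs(m, max_missing=1)
        assert sel.og_ids == ["OG0", "OG1"]
        assert sel.coverage == {"OG0": 3, "OG1": 2}

    def test_multicopy_excluded_regardless(self):
        m = _matrix([[2, 1, 1], [1, 1, 1]])
        for mm in (0, 1, 2):
            assert "OG0" not in select_core_orthologs(m, max_missing=mm).og_ids

    def test_nested_inclusion_property(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            m = _matrix(rng.integers(0, 3, size=(15, 5)))
            selections = {}
            for mm in range(5):
                try:
                    selections[mm] = set(select_core_orthologs(m, mm).og_ids)
                except NoCoreError:
                    selections[mm] = set()
            for a in range(4):
                assert selections[a] <= selections[a + 1]

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.integers(0, 3, size=(20, 4)))
        mm = 1
        try:
            got = set(select_core_orthologs(m, mm).og_ids)
        except NoCoreError:
            got = set()
        expected = set()
        for og in m.df.index:
            row = m.df.loc[og]
            if (row > 1).any():
                continue
            if (row == 1).sum() >= 4 - mm:
                expected.add(og)
        assert got == expected

    def test_no_core_error(self):
        m = _matrix([[1, 0, 0], [0, 1, 0]])
        with pytest.raises(NoCoreError, match="max_missing"):
            select_core_orthologs(m, max_missing=0)

    def test_max_missing_bounds(self):
        m = _matrix([[1, 1, 1]])
        with pytest.raises(ValueError):
            select_core_orthologs(m, max_missing=3)


class TestConcatenation:
    def _selection(self, ogs):
        from orthopan.phylo import CoreSelection

        return CoreSelection(og_ids=ogs, max_missing=1, coverage={})

    def test_lengths_and_partitions(self):
        aln = {
            "OG0": {"a": "MK" * 50, "b": "MR" * 50},
            "OG1": {"a": "WC" * 25, "b": "WY" * 25},
        }
        sa = concatenate_alignments(aln, self._selection(["OG0", "OG1"]), ["a", "b"])
        assert sa.length == 150
        assert sa.partitions == [("OG0", 0, 100), ("OG1", 100, 150)]

    def test_missing_genome_padded_with_gaps(self):
        aln = {
            "OG0": {"a": "MKMK", "b": "MRMR"},
            "OG1": {"a": "WCWCW"},
        }
        sa = concatenate_alignments(aln, self._selection(["OG0", "OG1"]), ["a", "b"])
        assert sa.rows["b"][4:] == "-" * 5

    def test_slice_round_trip(self):
        aln = {
            "OG0": {"a": "MKMK", "b": "MRMR"},
            "OG1": {"a": "WCWCW", "b": "WYWYW"},
        }
        sa = concatenate_alignments(aln, self._selection(["OG0", "OG1"]), ["a", "b"])
        assert sa.slice("OG1") == aln["OG1"]

    def test_ragged_alignment_errors(self):
        aln = {"OG0": {"a": "MKMK", "b": "MRM"}}
        with pytest.raises(ValueError, match="OG0"):
            concatenate_alignments(aln, self._selection(["OG0"]), ["a", "b"])

    def test_pad_alignment_fallback(self):
        padded = pad_alignment({"a": "MK", "b": "MKW"})
        assert padded == {"a": "MK-", "b": "MKW"}


class TestDistanceMatrix:
    def test_identical_rows(self):
        sa = SuperAlignment(rows={"a": "MKW", "b": "MKW"}, partitions=[("OG0", 0, 3)])
        assert distance_matrix(sa).loc["a", "b"] == 0.0

    def test_five_of_hundred(self):
        row_a = "A" * 100
        row_b = "A" * 95 + "C" * 5
        sa = SuperAlignment(rows={"a": row_a, "b": row_b}, partitions=[("OG0", 0, 100)])
        assert distance_matrix(sa).loc["a", "b"] == pytest.approx(0.05)

    def test_pairwise_deletion_and_recount_oracle(self):
        rng = np.random.default_rng(10)
        alphabet = np.array(list("ACDEF-"))
        rows = {
            f"t{i}": "".join(rng.choice(alphabet, size=60)) for i in range(4)
        }
        sa = SuperAlignment(rows=rows, partitions=[("OG0", 0, 60)])
        d = distance_matrix(sa)
        for a in rows:
            for b in rows:
                if a == b:
                    assert d.loc[a, b] == 0.0
                    continue
                cols = [
                    (x, y) for x, y in zip(rows[a], rows[b]) if x != "-" and y != "-"
                ]
                expected = 1 - sum(1 for x, y in cols if x == y) / len(cols)
                assert d.loc[a, b] == pytest.approx(expected)

    def test_no_comparable_columns_errors(self):
        sa = SuperAlignment(rows={"a": "MK--", "b": "--MK"}, partitions=[("OG0", 0, 4)])
        with pytest.raises(ValueError, match="comparable"):
            distance_matrix(sa)


def _additive_matrix_4taxa():
    # tree ((A:2,B:3):1,(C:4,D:5)); internal edge 1
    names = list("ABCD")
    return pd.DataFrame(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
        index=names, columns=names, dtype=float,
    )


def _additive_matrix_5taxa():
    # caterpillar tree ((((A:1,B:2):1,C:3):1,D:4):1,E:5) as unrooted distances
    names = list("ABCDE")
    D = pd.DataFrame(0.0, index=names, columns=names)
    # leaf-to-root-path representation: distances computed by hand
    paths = {
        "A": [("e1", 1)], "B": [("e2", 2)], "C": [("e3", 3)],
        "D": [("e4", 4)], "E": [("e5", 5)],
    }
    # pair distances via the known topology
    dist = {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 7, ("A", "E"): 9,
        ("B", "C"): 6, ("B", "D"): 8, ("B", "E"): 10,
        ("C", "D"): 8, ("C", "E"): 10,
        ("D", "E"): 10,
    }
    for (a, b), d in dist.items():
        D.loc[a, b] = D.loc[b, a] = d
    return D


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        names = list("ABC")
        D = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]], index=names, columns=names, dtype=float
        )
        tree = nj_tree(D)
        # closed form: la=(ab+ac-bc)/2=1, lb=(ab+bc-ac)/2=2, lc=(ac+bc-ab)/2=4
        branch = {c.name: bl for c, bl in tree.root.children}
        assert branch == {"A": 1.0, "B": 2.0, "C": 4.0}

    @pytest.mark.parametrize("matrix_fn", [_additive_matrix_4taxa, _additive_matrix_5taxa])
    def test_additive_path_lengths_reproduced(self, matrix_fn):
        D = matrix_fn()
        tree = nj_tree(D)
        paths = tree.leaf_distances()
        assert np.abs(paths.loc[D.index, D.columns].to_numpy() - D.to_numpy()).max() < 1e-9

    def test_taxon_order_invariance(self):
        D = _additive_matrix_4taxa()
        perm = ["C", "A", "D", "B"]
        t1 = nj_tree(D)
        t2 = nj_tree(D.loc[perm, perm])
        assert t1.to_newick() == t2.to_newick()

    def test_agrees_with_reference_nj(self):
        # independent cross-check against scikit-bio's neighbor joining
        skbio = pytest.importorskip("skbio")
        D = _additive_matrix_5taxa()
        ours = nj_tree(D).leaf_distances()
        dm = skbio.DistanceMatrix(D.to_numpy(), ids=list(D.index))
        ref = skbio.tree.nj(dm)
        for a in D.index:
            for b in D.index:
                if a < b:
                    assert ours.loc[a, b] == pytest.approx(
                        ref.find(a).distance(ref.find(b)), abs=1e-9
                    )

    def test_two_taxa_single_edge(self):
        D = pd.DataFrame([[0, 4], [4, 0]], index=["A", "B"], columns=["A", "B"], dtype=float)
        tree = nj_tree(D)
        assert tree.leaf_distances().loc["A", "B"] == pytest.approx(4.0)

    def test_negative_branches_clamped(self):
        names = list("ABCD")
        # deliberately non-additive, triggers a negative NJ branch estimate
        D = pd.DataFrame(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0]],
            index=names, columns=names, dtype=float,
        )
        D.loc["A", "B"] = D.loc["B", "A"] = 8.0  # inconsistent with the rest
        tree = nj_tree(D)

        def branch_lengths(node):
            for c, bl in node.children:
                yield bl
                yield from branch_lengths(c)

        assert all(bl >= 0 for bl in branch_lengths(tree.root))
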