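"""Trimming, information content, p-distances, NJ, and long-branch scores."""

import math

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from cystakit import (
    Alignment,
    InputError,
    column_information,
    long_branch_score,
    nj_tree,
    p_distance_matrix,
    trim_alignment,
)

LOG2_20 = math.log2(20)


def aln(rows):
    return Alignment(rows=[(f"r{i}", s) for i, s in enumerate(rows)])


class TestTrimAlignment:
    def test_flanks_trimmed_at_threshold(self):
        trimmed = trim_alignment(aln(["--QTVAG--", "AAQTVAGAA"]), min_occupancy=0.6)
        assert [g for _, g in trimmed.rows] == ["QTVAG", "QTVAG"]

    def test_fully_occupied_unchanged(self):
        a = aln(["QTVAG", "QTVAA"])
        assert trim_alignment(a).rows == a.rows

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(InputError):
            trim_alignment(aln(["-----", "-----"]))

    def test_internal_columns_untouched(self):
        trimmed = trim_alignment(aln(["AA--AA", "AA--AA"]), min_occupancy=0.5)
        assert trimmed.rows[0][1] == "AA--AA"

    def test_idempotent(self):
        a = aln(["--QTVAG--", "AAQTVAGAA", "-AQTVAGA-"])
        once = trim_alignment(a, 0.6)
        twice = trim_alignment(once, 0.6)
        assert once.rows == twice.rows


class TestColumnInformation:
    def test_constant_column_full_information(self):
        prof = column_information(aln(["Q", "Q", "Q", "Q"]))
        assert prof.information_content[0] == pytest.approx(LOG2_20, abs=1e-9)
        assert prof.consensus[0] == "Q"

    def test_uniform_four_way_column(self):
        prof = column_information(aln(["A", "C", "D", "E"]))
        assert prof.information_content[0] == pytest.approx(LOG2_20 - 2, abs=1e-9)

    def test_gaps_excluded_from_frequencies(self):
        prof = column_information(aln(["Q", "-", "Q", "-"]))
        assert prof.information_content[0] == pytest.approx(LOG2_20, abs=1e-9)
        assert prof.gap_fraction[0] == pytest.approx(0.5)
        assert prof.frequencies[0] == {"Q": 1.0}

    def test_all_gap_column_flagged(self):
        prof = column_information(aln(["Q-", "Q-"]))
        assert np.isnan(prof.information_content[1])
        assert prof.consensus[1] == "-"

    def test_ic_decreases_toward_uniformity(self, rng):
        """Progressively replacing a constant column's residues with distinct
        residues can only lower the information content."""
        residues = list("QQQQQQQQQQ")
        alphabet = list("ACDEFGHIKL")
        last = LOG2_20
        for k in range(10):
            residues[k] = alphabet[k]
            ic = column_information(aln([r for r in residues])).information_content[0]
            assert ic <= last + 1e-12
            last = ic

    def test_small_sample_correction_reduces_ic(self):
        a = aln(["Q", "Q", "Q", "Q"])
        raw = column_information(a).information_content[0]
        corrected = column_information(a, small_sample_correction=True).information_content[0]
        assert corrected < raw


class TestPDistance:
    def test_identical_rows_zero(self):
        d = p_distance_matrix(aln(["QTVAG", "QTVAG"]))
        assert d.iloc[0, 1] == 0

    def test_one_in_five_mismatch(self):
        d = p_distance_matrix(aln(["QTVAG", "QTVAA"]))
        assert d.iloc[0, 1] == pytest.approx(0.2)

    def test_gapped_columns_excluded_from_denominator(self):
        # comparable positions: Q T A G (4); mismatches: 1 -> 0.25
        d = p_distance_matrix(aln(["QT-AG", "QTVAA"]))
        assert d.iloc[0, 1] == pytest.approx(0.25)

    def test_no_comparable_positions_flagged(self):
        with pytest.warns(UserWarning, match="no ungapped"):
            d = p_distance_matrix(aln(["Q----", "-TVAG"]))
        assert np.isnan(d.iloc[0, 1])


def random_additive_tree(n_taxa, rng):
    """Random rooted binary tree with branch lengths; returns (tree, dists)."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0))) for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)), children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    ids = sorted(t.name for t in root.tips())
    dm = root.tip_tip_distances(endpoints=ids)
    return root, pd.DataFrame(dm.data, index=ids, columns=ids)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix(self):
        ids = list("ABCD")
        d = pd.DataFrame(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=ids, columns=ids, dtype=float,
        )
        tree = nj_tree(d)
        # topology AB|CD; tip branches 1, unrooted internal edge 4-1-1 = 2
        got = tree.tip_tip_distances(endpoints=ids)
        assert np.allclose(got.data, d.to_numpy())
        a = tree.find("A")
        b = tree.find("B")
        assert a.parent is b.parent
        assert all(abs(t.length - 1.0) < 1e-9 for t in tree.tips())
        internal = [n.length for n in tree.non_tips() if n.parent is not None]
        assert any(abs(l - 2.0) < 1e-9 for l in internal)

    def test_three_taxa_closed_form(self):
        # three-point formulas: x=(dAB+dAC-dBC)/2 etc.
        ids = list("ABC")
        d = pd.DataFrame(
            [[0, 3, 5], [3, 0, 6], [5, 6, 0]], index=ids, columns=ids, dtype=float
        )
        tree = nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_zero_matrix_zero_lengths(self):
        ids = list("ABCD")
        d = pd.DataFrame(np.zeros((4, 4)), index=ids, columns=ids)
        tree = nj_tree(d)
        assert all((t.length or 0) == pytest.approx(0, abs=1e-12) for t in tree.traverse())

    def test_asymmetric_matrix_rejected(self):
        ids = list("ABC")
        d = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], index=ids, columns=ids)
        with pytest.raises(InputError, match="symmetric"):
            nj_tree(d)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        true_tree, d = random_additive_tree(n, rng)
        est = nj_tree(d)
        got = est.tip_tip_distances(endpoints=list(d.index))
        assert np.allclose(got.data, d.to_numpy(), atol=1e-9)
        assert est.compare_rfd(true_tree) == 0


class TestLongBranchScore:
    def _tree(self, lengths):
        kids = [TreeNode(name=k, length=v) for k, v in lengths.items()]
        return TreeNode(children=kids)

    def test_equal_lengths_ratio_one(self):
        t = self._tree({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        assert long_branch_score(t, ["a", "b"]) == pytest.approx(1.0)

    def test_fast_evolving_subset_scores_high(self):
        t = self._tree({"a": 5.0, "b": 5.0, "c": 1.0, "d": 1.0})
        assert long_branch_score(t, ["a", "b"]) == pytest.approx(5.0)

    def test_full_subset_rejected(self):
        t = self._tree({"a": 1.0, "b": 1.0})
        with pytest.raises(InputError):
            long_branch_score(t, ["a", "b"])

    def test_zero_outside_mean_flagged(self):
        t = self._tree({"a": 1.0, "b": 0.0})
        with pytest.raises(InputError, match="undefined"):
            long_branch_score(t, ["a"])
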