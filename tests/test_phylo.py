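"""Distances, neighbor joining, bootstrap, subfamilies and Wagner parsimony."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

from famsurveyor.align import MultipleAlignment
from famsurveyor.phylo import (
    DistanceMatrix,
    assign_subfamilies,
    bootstrap_support,
    nj_tree,
    parsimony_gain_loss,
    protein_distance,
    size_variability,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_additive_tree(rng, n_taxa):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf distance matrix (path lengths)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    nodes = {lab: {"children": [], "length": None} for lab in labels}
    active = list(labels)
    counter = itertools.count()
    parent = {}
    lengths = {}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        new = f"I{next(counter)}"
        for child in (a, b):
            parent[child] = new
            lengths[child] = float(rng.uniform(0.5, 3.0))
        active = [x for x in active if x not in (a, b)] + [new]
    root = active[0]

    def path_to_root(x):
        out = []
        while x != root:
            out.append(x)
            x = parent[x]
        return out

    D = np.zeros((n_taxa, n_taxa))
    for ii in range(n_taxa):
        for jj in range(ii + 1, n_taxa):
            pa, pb = path_to_root(labels[ii]), path_to_root(labels[jj])
            shared = set(pa) & set(pb)
            d = sum(lengths[x] for x in pa + pb if x not in shared)
            D[ii, jj] = D[jj, ii] = d
    return labels, D, parent, lengths, root


def tree_distance_matrix(tree, labels):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestProteinDistance:
    def _msa(self, rows):
        return MultipleAlignment(rows)

    def test_identical_rows_zero(self):
        d = protein_distance(self._msa({"a": "ACDEF", "b": "ACDEF"}), model="p")
        assert d.d[0, 1] == 0.0

    def test_poisson_closed_form(self):
        # 1 difference in 10 sites: p = 0.1
        rows = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAC"}
        d = protein_distance(self._msa(rows), model="poisson")
        assert d.d[0, 1] == pytest.approx(-math.log(0.9), abs=1e-9)
        assert d.d[0, 1] == pytest.approx(0.10536, abs=1e-5)

    def test_kimura_closed_form(self):
        rows = {"a": "AAAAAAAAAA", "b": "AAAAAAAAAC"}
        d = protein_distance(self._msa(rows), model="kimura")
        assert d.d[0, 1] == pytest.approx(-math.log(1 - 0.1 - 0.01 / 5), abs=1e-9)

    def test_deletion_modes_differ_only_with_gaps(self):
        gapless = {"a": "ACDEF", "b": "ACDEC", "c": "ACDEF"}
        dp = protein_distance(self._msa(gapless), deletion="pairwise")
        dc = protein_distance(self._msa(gapless), deletion="complete")
        np.testing.assert_allclose(dp.d, dc.d)
        gapped = {"a": "ACDEF", "b": "AC-EF", "c": "GCDEF"}
        dp = protein_distance(self._msa(gapped), deletion="pairwise")
        dc = protein_distance(self._msa(gapped), deletion="complete")
        assert not np.allclose(dp.d, dc.d)

    def test_saturation_flagged_infinite(self):
        rows = {"a": "ACDEFGHIKL", "b": "CDEFGHIKLM"}
        d = protein_distance(self._msa(rows), model="poisson")
        assert np.isinf(d.d[0, 1])


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(ids, d))
        got = tree_distance_matrix(tree, ids)
        np.testing.assert_allclose(got, d, atol=1e-9)
        # split AB|CD present
        newick = tree.as_string(schema="newick")
        assert "(A:1.0,B:2.0)" in newick.replace("'", "")

    def test_three_taxa_star_exact(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(ids, d))
        got = tree_distance_matrix(tree, ids)
        np.testing.assert_allclose(got, d, atol=1e-12)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            labels, D, parent, lengths, root = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(labels, D))
            got = tree_distance_matrix(tree, labels)
            np.testing.assert_allclose(got, D, atol=1e-9)

    def test_nonfinite_distance_is_error(self):
        d = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], d))


def _two_clade_msa(noise_cols=0, seed=0):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(list(AAS), size=40))
    b = "".join(rng.choice(list(AAS), size=40))
    rows = {"a1": a, "a2": a, "b1": b, "b2": b}
    return MultipleAlignment(rows)


class TestBootstrap:
    def test_clean_clades_get_full_support(self):
        tree = bootstrap_support(_two_clade_msa(), n_replicates=50, seed=1, model="p")
        supports = [n.support for n in tree.preorder_node_iter() if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_in_range_and_deterministic(self):
        rng = np.random.default_rng(3)
        rows = {f"s{i}": "".join(rng.choice(list(AAS), size=30)) for i in range(6)}
        msa = MultipleAlignment(rows)
        t1 = bootstrap_support(msa, n_replicates=30, seed=5, model="p")
        t2 = bootstrap_support(msa, n_replicates=30, seed=5, model="p")
        s1 = sorted(n.support for n in t1.preorder_node_iter() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.preorder_node_iter() if hasattr(n, "support"))
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)

    def test_leaf_order_permutation_invariant(self):
        msa = _two_clade_msa()
        perm = MultipleAlignment(dict(reversed(list(msa.rows.items()))))
        t1 = bootstrap_support(msa, n_replicates=40, seed=2, model="p")
        t2 = bootstrap_support(perm, n_replicates=40, seed=2, model="p")
        s1 = sorted(n.support for n in t1.preorder_node_iter() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.preorder_node_iter() if hasattr(n, "support"))
        assert s1 == s2


class TestSubfamilies:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_sister_reference_label(self):
        tree = self._tree("((q1:1,r1:1):1,(r2:1,r3:1):1);")
        out = assign_subfamilies(tree, {"r1": "sf25", "r2": "sf7", "r3": "sf7"})
        assert out["q1"] == "sf25"

    def test_equal_representation_is_orphan(self):
        tree = self._tree("((q1:1,(r1:1,r2:1):1):1,(r3:1,r4:1):1);")
        out = assign_subfamilies(tree, {"r1": "A", "r2": "B", "r3": "C", "r4": "C"})
        assert out["q1"] == "orphan"

    def test_planted_clades_fully_recovered(self):
        # three clades, each with one reference and three queries
        parts = []
        labels = {}
        for c, sf in enumerate(["sf1", "sf2", "sf3"]):
            ref = f"r{c}"
            labels[ref] = sf
            leaves = [f"q{c}x{i}" for i in range(3)] + [ref]
            parts.append("(" + ",".join(f"{x}:1" for x in leaves) + "):1")
        tree = self._tree("(" + ",".join(parts) + ");")
        out = assign_subfamilies(tree, labels)
        for c, sf in enumerate(["sf1", "sf2", "sf3"]):
            for i in range(3):
                assert out[f"q{c}x{i}"] == sf

    def test_unknown_reference_is_error(self):
        tree = self._tree("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(KeyError):
            assign_subfamilies(tree, {"nope": "x"})


class TestSizeVariability:
    def test_constant_counts_cv_zero(self):
        counts = pd.DataFrame(
            {"sfA": [10, 10, 10], "sfB": [1, 2, 3], "sfC": [4, 5, 6]},
            index=["sp1", "sp2", "sp3"],
        )
        cv, r, p = size_variability(counts)
        assert cv["sfA"] == 0.0

    def test_hand_computed_cv(self):
        counts = pd.DataFrame(
            {"sfA": [1, 2, 3], "sfB": [2, 2, 2], "sfC": [1, 5, 9]},
            index=["sp1", "sp2", "sp3"],
        )
        cv, _, _ = size_variability(counts)
        assert cv["sfA"] == pytest.approx(50.0)

    def test_proportional_sd_mean_gives_r_one(self):
        counts = pd.DataFrame(
            {"sfA": [1, 3], "sfB": [2, 6], "sfC": [4, 12]},
            index=["sp1", "sp2"],
        )
        _, r, p = size_variability(counts)
        assert r == pytest.approx(1.0)
        assert p < 0.05


def brute_force_parsimony(tree, counts, sub):
    """Minimal total |change| by enumerating every internal-state vector."""
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    smax = int(counts[sub].max())
    best = math.inf
    for states in itertools.product(range(smax + 1), repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, states)}
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = int(counts.loc[leaf.taxon.label, sub])
        cost = 0
        for n in tree.preorder_node_iter():
            if n.parent_node is not None:
                cost += abs(assign[id(n)] - assign[id(n.parent_node)])
        best = min(best, cost)
    return best


class TestParsimony:
    def _tree(self, newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_constant_counts_no_change(self):
        tree = self._tree("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        counts = pd.DataFrame({"sf": [5, 5, 5, 5, 5]}, index=list("abcde"))
        deltas, tallies = parsimony_gain_loss(tree, counts)
        assert (deltas["sf"] == 0).all()

    def test_star_single_expansion(self):
        tree = self._tree("(a:1,b:1,c:1,d:1,e:1);")
        counts = pd.DataFrame({"sf": [6, 5, 5, 5, 5]}, index=list("abcde"))
        deltas, tallies = parsimony_gain_loss(tree, counts)
        assert deltas.loc["a", "sf"] == 1
        assert tallies.loc["a", "expanded"] == 1
        assert tallies["contracted"].sum() == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        tree_str = "((a:1,b:1):1,(c:1,(d:1,e:1):1):1);"
        for _ in range(30):
            tree = self._tree(tree_str)
            counts = pd.DataFrame(
                {"sf": rng.integers(0, 5, size=5)}, index=list("abcde")
            )
            deltas, _ = parsimony_gain_loss(tree, counts)
            got_cost = deltas["sf"].abs().sum()
            assert got_cost == brute_force_parsimony(tree, counts, "sf")

    def test_leaf_mismatch_is_error(self):
        tree = self._tree("(a:1,b:1,c:1);")
        counts = pd.DataFrame({"sf": [1, 2]}, index=["a", "x"])
        with pytest.raises(ValueError):
            parsimony_gain_loss(tree, counts)
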