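"""CNV distances, neighbor joining against oracles, bootstrap consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chocnv import cnv_phylogeny as cp
from chocnv.depth_profiling import GeneDepthTable


def _table(values, sample="s"):
    s = pd.Series(values, dtype=float)
    return GeneDepthTable(sample, raw=s, normalized=s)


def _matrix(d, labels):
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for (a, b), v in d.items():
        mat.loc[a, b] = mat.loc[b, a] = v
    return mat


class TestCnvDistance:
    def test_identity(self):
        t = _table({f"g{i}": 2.0 for i in range(10)})
        assert cp.cnv_distance(t, t) == 0

    def test_counts_genes_over_rule(self):
        a = _table({"g1": 2.0, "g2": 2.0, "g3": 2.0})
        b = _table({"g1": 1.0, "g2": 3.0, "g3": 2.0})
        assert cp.cnv_distance(a, b) == 2

    def test_boundary_strict(self):
        a = _table({"g1": 2.0})
        b = _table({"g1": 2.95})
        assert cp.cnv_distance(a, b) == 0

    def test_symmetric_premetric(self):
        rng = np.random.default_rng(0)
        a = _table({f"g{i}": v for i, v in enumerate(rng.uniform(0, 4, 50))}, "a")
        b = _table({f"g{i}": v for i, v in enumerate(rng.uniform(0, 4, 50))}, "b")
        assert cp.cnv_distance(a, b) == cp.cnv_distance(b, a)
        assert cp.cnv_distance(a, a) == 0

    def test_universe_mismatch(self):
        with pytest.raises(ValueError):
            cp.cnv_distance(_table({"g1": 2.0}), _table({"g2": 2.0}))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        """d(A,B)=2, d(A,C)=4, d(B,C)=4 solves to branches (1, 1, 3)."""
        mat = _matrix({("A", "B"): 2, ("A", "C"): 4, ("B", "C"): 4}, list("ABC"))
        tree = cp.neighbor_joining(mat)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_four_taxon_additive_recovery(self):
        """An additive matrix is fit exactly, and better than the two
        alternative quartet topologies under least squares."""
        # generating tree: ((A:1,B:2):3,C:4,D:5)
        d = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
             ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
        mat = _matrix(d, list("ABCD"))
        tree = cp.neighbor_joining(mat)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (a, b), v in d.items():
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(v)
        assert cp.has_bipartition(tree, {"A", "B"})

    @pytest.mark.parametrize("n_taxa", [5, 6, 8])
    def test_additive_matrices_reproduce_generating_tree(self, n_taxa):
        """NJ on tree-derived (additive) distances returns the tree's own
        path-length matrix for random caterpillar-free topologies."""
        import dendropy

        rng = np.random.default_rng(n_taxa)
        labels = [f"T{i}" for i in range(n_taxa)]
        # random binary tree by sequential attachment, integer branch lengths
        newick = f"({labels[0]}:1,{labels[1]}:1,{labels[2]}:1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        for label in labels[3:]:
            edges = [e for e in tree.preorder_edge_iter() if e.length is not None]
            edge = edges[rng.integers(len(edges))]
            old_head = edge.head_node
            parent = edge.tail_node
            new_internal = parent.new_child(edge_length=float(rng.integers(1, 5)))
            parent.remove_child(old_head)
            new_internal.add_child(old_head)
            old_head.edge.length = float(rng.integers(1, 5))
            new_leaf = new_internal.new_child(edge_length=float(rng.integers(1, 5)))
            new_leaf.taxon = tree.taxon_namespace.new_taxon(label)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace if t.label in labels}
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for a, b in itertools.combinations(labels, 2):
            v = pdm.distance(taxa[a], taxa[b])
            mat.loc[a, b] = mat.loc[b, a] = v
        nj_tree = cp.neighbor_joining(mat)
        nj_pdm = nj_tree.phylogenetic_distance_matrix()
        nj_taxa = {t.label: t for t in nj_tree.taxon_namespace}
        for a, b in itertools.combinations(labels, 2):
            assert nj_pdm.distance(nj_taxa[a], nj_taxa[b]) == pytest.approx(
                mat.loc[a, b]
            ), (a, b)

    def test_matches_independent_library_implementation(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        labels = [f"S{i}" for i in range(6)]
        raw = rng.integers(50, 500, size=(6, 6)).astype(float)
        sym = np.triu(raw, 1)
        sym = sym + sym.T
        mat = pd.DataFrame(sym, index=labels, columns=labels)
        ours = cp.neighbor_joining(mat)
        theirs = skbio_nj(DistanceMatrix(sym, ids=labels))
        # compare unrooted topologies via bipartitions
        def bips(leafsets, all_leaves):
            canon = set()
            for side in leafsets:
                if 1 < len(side) < len(all_leaves) - 1:
                    canon.add(min(side, all_leaves - side, key=sorted))
            return canon

        all_leaves = frozenset(labels)
        ours_sets = [
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in ours.internal_nodes()
        ]
        theirs_sets = [
            frozenset(t.name for t in n.tips()) for n in theirs.non_tips()
        ]
        assert bips(ours_sets, all_leaves) == bips(theirs_sets, all_leaves)

    def test_equidistant_taxa_deterministic(self):
        mat = _matrix({(a, b): 10 for a, b in itertools.combinations("ABCD", 2)},
                      list("ABCD"))
        t1 = cp.neighbor_joining(mat).as_string(schema="newick")
        t2 = cp.neighbor_joining(mat).as_string(schema="newick")
        assert t1 == t2

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            cp.neighbor_joining(_matrix({("A", "B"): 1}, list("AB")))


class TestBootstrap:
    @staticmethod
    def _tables(seed=0, n_genes=400):
        """Three clades separated by large planted CNV blocks."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        base = {g: 2.0 for g in genes}

        def variant(block, jitter_seed):
            r = np.random.default_rng(jitter_seed)
            vals = dict(base)
            for g in block:
                vals[g] = 1.0
            return {g: v + r.normal(0, 0.03) for g, v in vals.items()}

        tables = {
            "X1": _table(variant(genes[:100], 1), "X1"),
            "X2": _table(variant(genes[:110], 2), "X2"),
            "Y1": _table(variant(genes[150:250], 3), "Y1"),
            "Y2": _table(variant(genes[150:260], 4), "Y2"),
            "ref": _table({g: v + rng.normal(0, 0.03) for g, v in base.items()}, "ref"),
        }
        return tables

    def test_single_replicate_equals_consensus(self):
        tables = self._tables()
        tree, _ = cp.bootstrap_consensus(tables, n_replicates=1, seed=9)
        assert len(list(tree.leaf_node_iter())) == 5

    def test_planted_clades_recovered_with_support(self):
        tables = self._tables()
        tree, matrix = cp.bootstrap_consensus(tables, n_replicates=50, seed=9)
        assert cp.support_of_pair(tree, "X1", "X2") >= 90
        assert cp.support_of_pair(tree, "Y1", "Y2") >= 90
        assert matrix.loc["X1", "X2"] < matrix.loc["X1", "Y1"]

    def test_same_seed_identical(self):
        tables = self._tables()
        t1, _ = cp.bootstrap_consensus(tables, n_replicates=20, seed=5)
        t2, _ = cp.bootstrap_consensus(tables, n_replicates=20, seed=5)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_label_permutation_invariance(self):
        """Renaming samples permutes leaves but leaves the support structure
        unchanged."""
        tables = self._tables()
        t1, _ = cp.bootstrap_consensus(tables, n_replicates=30, seed=5)
        renamed = {f"z_{k}": v for k, v in tables.items()}
        t2, _ = cp.bootstrap_consensus(renamed, n_replicates=30, seed=5)
        assert cp.support_of_pair(t1, "X1", "X2") == cp.support_of_pair(
            t2, "z_X1", "z_X2"
        )
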