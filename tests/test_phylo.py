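"""NJ construction, bootstrap support, monophyly scoring, Newick I/O."""

import numpy as np
import pytest

from barcodekit.distmat import DistanceMatrix, pairwise_matrix
from barcodekit.phylo import (
    bipartitions,
    bootstrap_support,
    monophyly_assess,
    nj_tree,
    path_length_matrix,
    read_newick,
    write_newick,
)
from barcodekit.seq_io import MarkerAlignment, SpecimenRecord


def _dm(ids, d):
    d = np.asarray(d, float)
    return DistanceMatrix(ids, d, np.zeros(d.shape, int))


def _random_additive(rng, n_taxa):
    """Random binary tree -> (ids, path-length matrix, cherry sets)."""
    import dendropy

    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [dendropy.Node(taxon=dendropy.Taxon(t)) for t in taxa]
    # random sequential pairwise joins with strictly positive lengths
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.uniform(0.1, 1.0))
        b.edge.length = float(rng.uniform(0.1, 1.0))
        nodes.append(parent)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    for leaf in tree.leaf_node_iter():
        tns.add_taxon(leaf.taxon)
    m = path_length_matrix(tree)
    return tree, m


class TestNJ:
    def test_four_taxon_worked_example(self):
        # additive matrix with known branch lengths A:1 B:2 C:3 D:4, internal 1
        ids = list("ABCD")
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        tree = nj_tree(_dm(ids, d))
        plm = path_length_matrix(tree)
        order = [plm.ids.index(x) for x in ids]
        assert np.allclose(plm.d[np.ix_(order, order)], np.asarray(d, float), atol=1e-10)
        # topology AB|CD
        bips = bipartitions(tree)
        assert frozenset({"C", "D"}) in bips or frozenset({"A", "B"}) in bips
        # leaf branch lengths recovered exactly
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})

    def test_three_taxa_closed_form(self):
        ids = list("ABC")
        d = [[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]]
        tree = nj_tree(_dm(ids, d))
        plm = path_length_matrix(tree)
        order = [plm.ids.index(x) for x in ids]
        assert np.allclose(plm.d[np.ix_(order, order)], np.asarray(d, float), atol=1e-12)

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(10)
        import dendropy

        for _ in range(10):
            n = int(rng.integers(5, 11))
            true_tree, m = _random_additive(rng, n)
            est = nj_tree(m.subset(list(m.ids)))
            plm = path_length_matrix(est)
            order = [plm.ids.index(x) for x in m.ids]
            assert np.allclose(plm.d[np.ix_(order, order)], m.d, atol=1e-8)
            # identical bipartition sets = identical unrooted topology
            assert set(bipartitions(est)) == set(bipartitions(true_tree))

    def test_missing_entries_refused(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(ValueError, match="MISSING|finite"):
            nj_tree(_dm(list("ABC"), d))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(_dm(list("AB"), [[0, 1], [1, 0]]))

    def test_agrees_with_skbio_topology(self):
        # independent implementation cross-check on a K2P matrix
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(8)}
        # make them related: mutate from a base sequence
        base = "".join(rng.choice(list("ACGT"), 200))
        seqs = {}
        for i in range(8):
            s = list(base)
            for p in rng.choice(200, size=5 + 4 * i, replace=False):
                s[p] = "ACGT"[(("ACGT".index(s[p])) + 1 + int(rng.integers(3))) % 4]
            seqs[f"s{i}"] = "".join(s)
        m = pairwise_matrix(MarkerAlignment("mk", seqs), min_overlap=10)
        mine = nj_tree(m)
        ref = skbio.tree.nj(skbio.DistanceMatrix(m.d, m.ids))
        ref_dp = read_newick_from_string(str(ref).strip())
        assert set(bipartitions(mine)) == set(bipartitions(ref_dp))


def read_newick_from_string(s):
    import dendropy

    return dendropy.Tree.get(data=s, schema="newick", suppress_internal_node_taxa=True)


class TestBootstrap:
    def _diagnostic_alignment(self, n_species=4, n_per=3, n_private=30, length=240):
        # each species has `n_private` private diagnostic columns
        rng = np.random.default_rng(0)
        base = rng.choice(list("ACGT"), length)
        seqs = {}
        for s in range(n_species):
            sp_seq = base.copy()
            cols = range(s * n_private, (s + 1) * n_private)
            for c in cols:
                sp_seq[c] = {"A": "G", "C": "T", "G": "A", "T": "C"}[sp_seq[c]]
            for i in range(n_per):
                seqs[f"sp{s}_{i}"] = "".join(sp_seq)
        return MarkerAlignment("mk", seqs)

    def test_private_columns_give_high_support(self):
        aln = self._diagnostic_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=1, min_overlap=10)
        specimens = [
            SpecimenRecord(sid, sid.split("_")[0], site_id="X") for sid in aln.ids
        ]
        rep = monophyly_assess(tree, specimens, min_support=50)
        assert rep.monophyly_pct == 100.0
        sups = rep.table["support"].dropna()
        assert (sups >= 99.0).all()

    def test_same_seed_same_supports(self):
        aln = self._diagnostic_alignment(n_private=5)
        t1 = bootstrap_support(aln, n_reps=50, seed=7, min_overlap=10)
        t2 = bootstrap_support(aln, n_reps=50, seed=7, min_overlap=10)
        s1 = {k: v.support for k, v in bipartitions(t1).items()}
        s2 = {k: v.support for k, v in bipartitions(t2).items()}
        assert s1 == s2

    def test_invalid_reps(self):
        aln = self._diagnostic_alignment(n_private=2)
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap_support(aln, n_reps=0)


class TestMonophyly:
    def _tree(self, newick):
        return read_newick_from_string(newick)

    def _specimens(self, ids):
        return [SpecimenRecord(s, s[0].upper(), site_id="X") for s in ids]

    def test_clean_clades(self):
        t = self._tree("((a1:1,a2:1)100:1,(b1:1,b2:1)100:1,c1:2);")
        rep = monophyly_assess(t, self._specimens(["a1", "a2", "b1", "b2", "c1"]))
        tab = rep.table.set_index("species")
        assert tab.loc["A", "is_monophyletic"] and tab.loc["B", "is_monophyletic"]
        assert rep.monophyly_pct == 100.0
        # singleton C is monophyletic but not counted
        assert tab.loc["C", "is_monophyletic"] and not tab.loc["C", "counted"]

    def test_interleaved_species_fail(self):
        t = self._tree("((a1:1,b1:1):1,(a2:1,b2:1):1,c1:1);")
        rep = monophyly_assess(t, self._specimens(["a1", "b1", "a2", "b2", "c1"]))
        assert rep.monophyly_pct == 0.0

    def test_low_support_fails_strict_rule(self):
        t = self._tree("((a1:1,a2:1)45:1,(b1:1,b2:1)80:1,c1:1);")
        rep = monophyly_assess(
            t, self._specimens(["a1", "a2", "b1", "b2", "c1"]), min_support=50
        )
        tab = rep.table.set_index("species")
        assert not tab.loc["A", "is_monophyletic"]
        assert tab.loc["A", "support"] == 45.0
        assert tab.loc["B", "is_monophyletic"]
        # exactly 50 also fails (strictly greater than)
        t50 = self._tree("((a1:1,a2:1)50:1,(b1:1,b2:1)80:1,c1:1);")
        rep50 = monophyly_assess(
            t50, self._specimens(["a1", "a2", "b1", "b2", "c1"]), min_support=50
        )
        assert not rep50.table.set_index("species").loc["A", "is_monophyletic"]

    def test_invariant_to_rerooting(self):
        from barcodekit.phylo import reroot_at_edge

        rng = np.random.default_rng(4)
        newick = "((a1:1,a2:1)90:1,((b1:1,b2:1)80:1,(c1:1,c2:2)30:1)60:1,d1:3);"
        ids = ["a1", "a2", "b1", "b2", "c1", "c2", "d1"]
        base = monophyly_assess(self._tree(newick), self._specimens(ids))
        for _ in range(5):
            t = self._tree(newick)
            edges = [e for e in t.preorder_edge_iter() if e.length is not None]
            edge = edges[int(rng.integers(len(edges)))]
            reroot_at_edge(t, edge)
            rep = monophyly_assess(t, self._specimens(ids))
            assert rep.monophyly_pct == base.monophyly_pct
            assert list(rep.table["is_monophyletic"]) == list(base.table["is_monophyletic"])

    def test_partitioned_assessment(self):
        t = self._tree("((a1:1,b1:1):1,(a2:1,b2:1):1,c1:1);")
        ids = ["a1", "b1", "a2", "b2", "c1"]
        # A and B share a partition and stay interleaved there; restricting
        # B's test to its own partition makes it trivially monophyletic.
        same = {"A": "ord1", "B": "ord1", "C": "ord2"}
        rep = monophyly_assess(t, self._specimens(ids), partition_of=same)
        tab = rep.table.set_index("species")
        assert not tab.loc["A", "is_monophyletic"]
        assert not tab.loc["B", "is_monophyletic"]
        split = {"A": "ord1", "B": "ord2", "C": "ord1"}
        rep2 = monophyly_assess(t, self._specimens(ids), partition_of=split)
        tab2 = rep2.table.set_index("species")
        assert tab2.loc["B", "is_monophyletic"]  # alone in its partition
        assert tab2.loc["A", "is_monophyletic"]  # b-leaves excluded from scope

    def test_nj_paraphyly_fixture(self, fixtures):
        fx = fixtures["paraphyly"]
        m = pairwise_matrix(fx.dataset.alignments["mk"], min_overlap=1)
        tree = nj_tree(m)
        rep = monophyly_assess(tree, fx.dataset.specimens)
        assert rep.monophyly_pct == fx.expected["monophyly_pct"]
        tab = rep.table.set_index("species")
        for sp in fx.expected["monophyletic"]:
            assert tab.loc[sp, "is_monophyletic"]
        for sp in fx.expected["non_monophyletic"]:
            assert not tab.loc[sp, "is_monophyletic"]


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        newick = "((a1:1.0,a2:2.0)75:0.5,(b1:1.0,b2:1.5)90:0.5,c1:3.0);"
        t = read_newick_from_string(newick)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        t2 = read_newick(p)
        assert set(bipartitions(t)) == set(bipartitions(t2))
        sup = {k: getattr(v, "support", None) for k, v in bipartitions(t2).items()}
        assert sorted(v for v in sup.values() if v is not None) == [75.0, 90.0]

    def test_malformed_newick_errors(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a,b,(c);")
        with pytest.raises(Exception):
            read_newick(p)
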