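"""Neighbor joining, bootstrap supports, Newick I/O, monophyly checks."""

import itertools

import numpy as np
import pytest

from barcodegap import (
    DistanceMatrix,
    SpecimenRecord,
    bipartition_set,
    bootstrap_supports,
    monophyly_report,
    neighbor_joining,
    read_newick,
    tree_path_lengths,
    write_newick,
)
from barcodegap.errors import IncompleteMatrixError, ValidationError
from barcodegap.tree import GROUP_ROW_LABEL



def dm_from(ids, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(tuple(ids), d, np.full(d.shape, 100))


def random_additive_tree(rng, n):
    """Random binary tree with positive branch lengths; returns its splits
    and path-length matrix (the generating truth for NJ consistency)."""
    import dendropy

    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    nodes = [dendropy.Node(taxon=t) for t in tns]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = rng.uniform(0.05, 1.0)
        nodes[j].edge.length = rng.uniform(0.05, 1.0)
        nodes[i] = parent
        del nodes[j]
    center = dendropy.Node()
    for nd in nodes:
        center.add_child(nd)
        nd.edge.length = rng.uniform(0.05, 1.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    ids = [f"t{i}" for i in range(n)]
    return tree, ids, tree_path_lengths(tree, ids)


def enumerate_unrooted_topologies(ids):
    """All unrooted binary topologies over the tips, as bipartition sets.

    Grown by inserting each new tip on every edge of every smaller topology;
    splits are kept canonical (side not containing the reference tip).
    """
    ids = sorted(ids)
    ref = ids[0]
    topos = [frozenset()]
    tips = list(ids[:3])
    for new in ids[3:]:
        nxt = []
        for splits in topos:
            # insert on an internal edge E: the subdivided edge yields splits
            # E and E+new; `new` joins the side of every split containing E
            for E in splits:
                ns = {(s | {new}) if E <= s else s for s in splits}
                ns.add(E)
                nxt.append(frozenset(ns))
            # insert on a tip edge t: new split {t, new}
            for t in tips:
                ns = {(s | {new}) if t in s else s for s in splits}
                pair = {t, new}
                if ref in pair:
                    pair = (set(tips) | {new}) - pair
                ns.add(frozenset(pair))
                nxt.append(frozenset(ns))
        topos = nxt
        tips.append(new)
    return topos


def least_squares_residual(ids, splits, pl):
    """Best least-squares fit of branch lengths for one topology.

    Design matrix: one column per edge (tip edges + internal splits), one
    row per tip pair; entry 1 when the edge separates the pair.  Returns the
    residual sum of squares of the fitted path lengths.
    """
    ids = list(ids)
    full = frozenset(ids)
    edges = [frozenset([t]) for t in ids] + [frozenset(s) for s in splits]
    pairs = list(itertools.combinations(range(len(ids)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([pl[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        for c, e in enumerate(edges):
            if (ids[i] in e) != (ids[j] in e):
                A[r, c] = 1.0
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ coef - y) ** 2).sum())


class TestNeighborJoining:
    def test_additive_four_taxon_example(self):
        # d(A,B)=3 d(A,C)=5 d(A,D)=6 d(B,C)=6 d(B,D)=7 d(C,D)=7
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = neighbor_joining(dm_from("ABCD", d))
        assert bipartition_set(t) == frozenset({frozenset({"C", "D"})})
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        pl = tree_path_lengths(t, "ABCD")
        assert np.abs(pl - np.array(d)).max() <= 1e-9

    def test_three_taxa_three_point_formulas(self):
        t = neighbor_joining(dm_from("abc", [[0, 2, 3], [2, 0, 3], [3, 3, 0]]))
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1, "b": 1, "c": 2})

    def test_two_cluster_ultrametric_split(self):
        d = [[0, 0.01, 0.10, 0.10],
             [0.01, 0, 0.10, 0.10],
             [0.10, 0.10, 0, 0.01],
             [0.10, 0.10, 0.01, 0]]
        t = neighbor_joining(dm_from(["a1", "a2", "b1", "b2"], d))
        assert bipartition_set(t) == frozenset({frozenset({"b1", "b2"})})

    def test_rejects_incomplete_matrix(self):
        d = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        with pytest.raises(IncompleteMatrixError):
            neighbor_joining(DistanceMatrix(("a", "b", "c"), d,
                                            np.full((3, 3), 10)))

    def test_rejects_fewer_than_three_tips(self):
        with pytest.raises(ValidationError):
            neighbor_joining(dm_from("ab", [[0, 1], [1, 0]]))

    @pytest.mark.parametrize("n", [4, 5, 6, 8, 10])
    def test_recovers_random_additive_trees(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(8):
            true_tree, ids, pl = random_additive_tree(rng, n)
            dm = dm_from(ids, pl)
            t = neighbor_joining(dm)
            assert bipartition_set(t) == bipartition_set(true_tree)
            assert np.abs(tree_path_lengths(t, ids) - pl).max() <= 1e-9

    @pytest.mark.parametrize("n", [4, 5])
    def test_exhaustive_topology_enumeration_agrees(self, n):
        """On additive input the NJ topology is the unique zero-residual
        least-squares fit among ALL unrooted topologies (3 for n=4, 15 for
        n=5) — an exhaustive, NJ-independent oracle."""
        rng = np.random.default_rng(7 * n)
        ids = [f"t{i}" for i in range(n)]
        topologies = enumerate_unrooted_topologies(ids)
        assert len(topologies) == {4: 3, 5: 15}[n]
        for _ in range(5):
            true_tree, ids_, pl = random_additive_tree(rng, n)
            nj_splits = bipartition_set(neighbor_joining(dm_from(ids_, pl)))
            residuals = {t: least_squares_residual(ids_, t, pl)
                         for t in topologies}
            zero = [t for t, r in residuals.items() if r <= 1e-12]
            assert zero == [nj_splits]
            assert all(r > 1e-8 for t, r in residuals.items()
                       if t != nj_splits)

    def test_against_independent_library_implementation(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        _, ids, pl = random_additive_tree(rng, 7)
        t = neighbor_joining(dm_from(ids, pl))
        sk = skbio.tree.nj(skbio.DistanceMatrix(pl, ids))
        sk_nwk = str(sk).strip()
        sk_tree = read_newick(sk_nwk)
        assert bipartition_set(t) == bipartition_set(sk_tree)

    def test_clamp_negative_preserves_joined_path(self):
        # a matrix known to give a negative NJ branch
        d = [[0, 5, 9, 9], [5, 0, 8, 8], [9, 8, 0, 1], [9, 8, 1, 0]]
        t = neighbor_joining(dm_from("ABCD", d), clamp_negative=True)
        for lf in t.leaf_node_iter():
            assert lf.edge.length >= 0
        for nd in t.preorder_node_iter():
            if nd.edge.length is not None:
                assert nd.edge.length >= -1e-12

    def test_tip_order_invariance(self):
        rng = np.random.default_rng(9)
        _, ids, pl = random_additive_tree(rng, 6)
        t1 = bipartition_set(neighbor_joining(dm_from(ids, pl)))
        perm = rng.permutation(len(ids))
        ids2 = [ids[i] for i in perm]
        t2 = bipartition_set(neighbor_joining(dm_from(ids2, pl[np.ix_(perm, perm)])))
        assert t1 == t2


class TestNewick:
    def test_single_line_with_terminator(self):
        t = neighbor_joining(dm_from("abc", [[0, 2, 3], [2, 0, 3], [3, 3, 0]]))
        s = write_newick(t)
        assert s.strip().endswith(";")
        assert s.strip().count("\n") == 0

    def test_roundtrip_topology_lengths_supports(self, two_cluster_alignment):
        t = bootstrap_supports(two_cluster_alignment, replicates=20, seed=1)
        s = write_newick(t)
        back = read_newick(s)
        assert bipartition_set(back) == bipartition_set(t)
        pl1 = tree_path_lengths(t, two_cluster_alignment.ids)
        pl2 = tree_path_lengths(back, two_cluster_alignment.ids)
        assert np.abs(pl1 - pl2).max() <= 1e-9

    def test_support_value_appears_as_internal_label(self, two_cluster_alignment):
        t = bootstrap_supports(two_cluster_alignment, replicates=50, seed=1)
        s = write_newick(t)
        assert ")100:" in s.replace(" ", "")


class TestBootstrap:
    def test_clean_clusters_get_full_support(self, two_cluster_alignment):
        t = bootstrap_supports(two_cluster_alignment, replicates=100, seed=3)
        splits = {
            frozenset(s): nd for s, nd in
            __import__("barcodegap").bipartitions(t).items()
        }
        assert frozenset({"b1", "b2"}) in splits
        assert splits[frozenset({"b1", "b2"})].support == 100

    def test_determinism_same_seed(self, two_cluster_alignment):
        t1 = bootstrap_supports(two_cluster_alignment, replicates=30, seed=5)
        t2 = bootstrap_supports(two_cluster_alignment, replicates=30, seed=5)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_bounded_and_tip_order_invariant(self, default_dataset):
        aln, _ = default_dataset
        sub = aln.subset(aln.ids[:12])
        t = bootstrap_supports(sub, replicates=25, seed=2)
        from barcodegap import bipartitions
        sups = [nd.support for nd in bipartitions(t).values()
                if hasattr(nd, "support")]
        assert sups and all(0 <= s <= 100 for s in sups)


class TestMonophyly:
    def _records(self, mapping, roles=None):
        roles = roles or {}
        return [
            SpecimenRecord(sid, sp, roles.get(sid, "ingroup"))
            for sid, sp in mapping.items()
        ]

    def test_clustered_species_are_monophyletic(self):
        d = [[0, 0.01, 0.2, 0.2], [0.01, 0, 0.2, 0.2],
             [0.2, 0.2, 0, 0.01], [0.2, 0.2, 0.01, 0]]
        t = neighbor_joining(dm_from(["a1", "a2", "b1", "b2"], d))
        rep = monophyly_report(t, self._records(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}))
        assert rep.set_index("species")["monophyletic"].all()

    def test_interleaved_species_is_not_monophyletic(self):
        # tree groups (a1,b1) vs (a2,b2): neither species forms a clade
        d = [[0, 0.01, 0.2, 0.2], [0.01, 0, 0.2, 0.2],
             [0.2, 0.2, 0, 0.01], [0.2, 0.2, 0.01, 0]]
        t = neighbor_joining(dm_from(["a1", "b1", "a2", "b2"], d))
        rep = monophyly_report(t, self._records(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}))
        by = rep.set_index("species")["monophyletic"]
        assert not by["A"] and not by["B"]

    def test_single_specimen_species_monophyletic_support_na(self):
        d = [[0, 0.1, 0.2], [0.1, 0, 0.2], [0.2, 0.2, 0]]
        t = neighbor_joining(dm_from(["a1", "b1", "c1"], d))
        rep = monophyly_report(t, self._records({"a1": "A", "b1": "B", "c1": "C"}))
        assert rep["monophyletic"].all()
        assert rep["support"].isna().all()

    def test_group_row_reports_ingroup_monophyly(self, default_dataset):
        aln, _ = default_dataset
        t = bootstrap_supports(aln, replicates=10, seed=4)
        rep = monophyly_report(t, aln.records)
        assert GROUP_ROW_LABEL in set(rep["species"])
        grp = rep.set_index("species").loc[GROUP_ROW_LABEL]
        assert grp["n_tips"] == 44
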