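"""p-distance, neighbor joining, bootstrap and clade assignment."""

import numpy as np
import pytest

from madsfam.phylogeny import (DistanceMatrix, Tree, TreeNode, assign_clades,
                               bootstrap_support, neighbor_joining,
                               p_distance)


# ---------------------------------------------------------------- p-distance

def test_p_distance_examples():
    d = p_distance({"a": "AAAA", "b": "AAAT"}).matrix
    assert d[0, 1] == pytest.approx(0.25)
    d = p_distance({"a": "AA-A", "b": "AAAT"}, deletion="pairwise").matrix
    assert d[0, 1] == pytest.approx(1 / 3)
    d = p_distance({"a": "ACGT", "b": "ACGT"}).matrix
    assert d[0, 1] == 0.0


def test_complete_deletion_uses_globally_ungapped_columns():
    msa = {"a": "AA-A", "b": "AAAT", "c": "CAAA"}
    d = p_distance(msa, deletion="complete").matrix
    # columns 0,1,3 kept; a vs b differ at col 3 only
    assert d[0, 1] == pytest.approx(1 / 3)


def test_disjoint_coverage_is_flagged_missing():
    dm = p_distance({"a": "AA--", "b": "--TT", "c": "AATT"})
    assert frozenset(("a", "b")) in dm.missing
    with pytest.raises(ValueError, match="complete deletion"):
        neighbor_joining(dm)


# ------------------------------------------------------------------------ NJ

def _additive_4taxon():
    # tree ((A:1,B:2),(C:3,D:4)) with internal edge 1
    taxa = ["A", "B", "C", "D"]
    m = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0]], dtype=float)
    return DistanceMatrix(taxa=taxa, matrix=m)


def test_nj_recovers_the_four_taxon_tree_exactly():
    tree = neighbor_joining(_additive_4taxon())
    assert {"A", "B"} in [set(bp) for bp in tree.bipartitions()] or \
           {"C", "D"} in [set(bp) for bp in tree.bipartitions()]
    paths = tree.path_distances()
    dm = _additive_4taxon()
    for i, ti in enumerate(dm.taxa):
        for j, tj in enumerate(dm.taxa):
            if i < j:
                assert paths[frozenset((ti, tj))] == pytest.approx(
                    dm.matrix[i, j])


def test_three_taxa_closed_form():
    dm = DistanceMatrix(taxa=["a", "b", "c"],
                        matrix=np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0.]]))
    tree = neighbor_joining(dm)
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths["a"] == pytest.approx(0.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(3.0)


def _random_additive(rng, n):
    """Random binary tree with positive branch lengths -> (taxa, matrix)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    for nd in nodes:
        nd.length = float(rng.uniform(0.5, 3.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]],
                          length=float(rng.uniform(0.5, 3.0)))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = Tree(root=TreeNode(children=nodes))
    paths = tree.path_distances()
    taxa = sorted(l.name for l in tree.root.leaves())
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = paths[frozenset((taxa[a], taxa[b]))]
    return tree, DistanceMatrix(taxa=taxa, matrix=m)


@pytest.mark.parametrize("n", [4, 5, 6, 8])
def test_nj_is_exact_on_random_additive_matrices(n, rng):
    for _ in range(10):
        true_tree, dm = _random_additive(rng, n)
        est = neighbor_joining(dm)
        paths = est.path_distances()
        for a in range(n):
            for b in range(a + 1, n):
                key = frozenset((dm.taxa[a], dm.taxa[b]))
                assert paths[key] == pytest.approx(dm.matrix[a, b], abs=1e-9)
        assert est.bipartitions() == true_tree.bipartitions()


def test_nj_topology_matches_scikit_bio(rng):
    """Independent cross-check of the NJ implementation."""
    skbio = pytest.importorskip("skbio")
    for _ in range(5):
        _, dm = _random_additive(rng, 6)
        est = neighbor_joining(dm)
        sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.taxa)
        sk_tree = skbio.tree.nj(sk_dm)
        sk_bips = set()
        all_leaves = frozenset(dm.taxa)
        anchor = min(all_leaves)
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                sk_bips.add(side)
        assert est.bipartitions() == sk_bips


def test_nj_is_input_order_invariant(rng):
    _, dm = _random_additive(rng, 6)
    order = list(rng.permutation(len(dm.taxa)))
    dm2 = DistanceMatrix(taxa=[dm.taxa[i] for i in order],
                         matrix=dm.matrix[np.ix_(order, order)])
    t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)
    assert t1.bipartitions() == t2.bipartitions()
    assert t1.newick() == t2.newick() or \
        t1.path_distances() == pytest.approx(t2.path_distances())


# ----------------------------------------------------------------- bootstrap

def _two_group_msa(rng, n_per=3, length=120, between=0.4, within=0.02):
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))

    def mutate(s, rate):
        out = list(s)
        for i in np.nonzero(rng.random(len(s)) < rate)[0]:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + 1) % 4]
        return "".join(out)

    other = mutate(base, between)
    msa = {}
    for k in range(n_per):
        msa[f"g1_{k}"] = mutate(base, within)
        msa[f"g2_{k}"] = mutate(other, within)
    return msa


def test_bootstrap_supports_are_bounded_and_deterministic(rng):
    msa = _two_group_msa(rng)
    t1 = bootstrap_support(msa, n_reps=20, seed=5)
    t2 = bootstrap_support(msa, n_reps=20, seed=5)
    s1 = sorted(n.support for n in t1.internal_nodes() if n.support is not None)
    s2 = sorted(n.support for n in t2.internal_nodes() if n.support is not None)
    assert s1 == s2
    assert all(0 <= s <= 100 for s in s1)


def test_single_replicate_supports_are_all_or_nothing(rng):
    msa = _two_group_msa(rng)
    t = bootstrap_support(msa, n_reps=1, seed=0)
    for n in t.internal_nodes():
        if n.support is not None:
            assert n.support in (0.0, 100.0)


def test_separated_groups_get_full_support(rng):
    msa = _two_group_msa(rng, between=0.5, within=0.01)
    t = bootstrap_support(msa, n_reps=50, seed=3)
    leaves = frozenset(msa)
    anchor = min(leaves)
    g1 = frozenset(k for k in msa if k.startswith("g1"))
    target = g1 if anchor not in g1 else leaves - g1
    supports = {frozenset(n.leaf_names()) if anchor not in n.leaf_names()
                else leaves - n.leaf_names(): n.support
                for n in t.internal_nodes()}
    assert supports.get(target) == pytest.approx(100.0)


# ------------------------------------------------------------------- clades

def _toy_tree():
    # ((ref1:1,g1:1):1,(ref2:1,ref3:1,g2:1):1,g3:1)
    a = TreeNode(children=[TreeNode(name="ref1", length=1),
                           TreeNode(name="g1", length=1)], length=1)
    b = TreeNode(children=[TreeNode(name="ref2", length=1),
                           TreeNode(name="ref3", length=1),
                           TreeNode(name="g2", length=1)], length=1)
    return Tree(root=TreeNode(children=[a, b, TreeNode(name="g3", length=1)]))


def test_gene_sister_to_single_reference_gets_its_subfamily():
    labels = assign_clades(_toy_tree(), {"ref1": "AGL2", "ref2": "SQUA",
                                         "ref3": "SQUA"})
    assert labels["g1"] == "AGL2"
    assert labels["g2"] == "SQUA"


def test_mixed_reference_clade_is_unassigned():
    labels = assign_clades(_toy_tree(), {"ref1": "AGL2", "ref2": "SQUA",
                                         "ref3": "AG"})
    assert labels["g2"] == "unassigned"


def test_planted_clades_recovered_on_synthetic_families(full_run):
    """>= 95% of family genes land in their planted clade."""
    cfg, ctx = full_run
    ds = ctx["dataset"]
    clades = ctx["clades"]
    ok = sum(1 for g, c in clades.items()
             if c == f"clade_{ds.clade_of.get(g)}")
    labelled = [g for g in clades if g in ds.clade_of]
    assert len(labelled) > 0
    assert ok / len(labelled) >= 0.95
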