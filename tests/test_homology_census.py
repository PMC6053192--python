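"""Global identity, RBH anchors, collinear chaining and the origin census."""

import itertools

import numpy as np
import pytest

from madsfam.homology_census import (AnchorPair, OriginParams, best_chain,
                                     chain_collinear, chromosome_census,
                                     classify_origins, global_identity,
                                     reciprocal_best_hits, sister_pairs)

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ------------------------------------------------------------ global identity

def test_identity_examples():
    ident, _ = global_identity("MKRLVW", "MKRLVW")
    assert ident == 100.0
    ident, _ = global_identity("ACDEF", "ACDFF")
    assert ident == pytest.approx(80.0)


def test_identity_is_symmetric(rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(5):
        a = "".join(aas[i] for i in rng.integers(0, 20, size=12))
        b = "".join(aas[i] for i in rng.integers(0, 20, size=10))
        assert global_identity(a, b)[0] == pytest.approx(
            global_identity(b, a)[0])


def test_empty_sequence_raises():
    with pytest.raises(ValueError):
        global_identity("", "MK")


def _brute_force_score(a, b, open_=-10.0, ext=-0.5):
    """Best affine-gap global alignment score by exhaustive enumeration."""
    best = [-np.inf]

    def go(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "m")
        if i < len(a):
            gap = ext if last == "a" else open_  # first gap position: open
            go(i + 1, j, score + gap, "a")
        if j < len(b):
            gap = ext if last == "b" else open_
            go(i, j + 1, score + gap, "b")

    go(0, 0, 0.0, "m")
    return best[0]


def test_alignment_score_matches_exhaustive_oracle(rng):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(6):
        a = "".join(aas[i] for i in rng.integers(0, 20,
                                                 size=rng.integers(3, 8)))
        b = "".join(aas[i] for i in rng.integers(0, 20,
                                                 size=rng.integers(3, 8)))
        _, score = global_identity(a, b)
        assert score == pytest.approx(_brute_force_score(a, b))


# ------------------------------------------------------------------------ RBH

def test_rbh_identical_sets_pair_each_gene_with_its_copy():
    x = {"x1": "MKRLVWAAAA", "x2": "CCDEFGHIKL"}
    y = {"y1": "MKRLVWAAAA", "y2": "CCDEFGHIKL"}
    pairs = {(p.x_gene, p.y_gene) for p in reciprocal_best_hits(x, y)}
    assert pairs == {("x1", "y1"), ("x2", "y2")}


def test_rbh_tie_broken_lexicographically():
    x = {"x1": "MKRLVWAAAA"}
    y = {"y2": "MKRLVWAAAA", "y1": "MKRLVWAAAA"}
    (pair,) = reciprocal_best_hits(x, y)
    assert pair.y_gene == "y1"


def test_rbh_exclude_self():
    prots = {"a": "MKRLVWAAAA", "b": "MKRLVWAAAC", "c": "DDDDDDDDDD"}
    pairs = {(p.x_gene, p.y_gene)
             for p in reciprocal_best_hits(prots, prots, exclude_self=True)}
    assert ("a", "b") in pairs and ("b", "a") in pairs
    assert all(p[0] != p[1] for p in pairs)


# ------------------------------------------------------------------ chaining

def _oracle_best_chain(points, max_gap):
    """Exhaustive maximum-score chain over every subset order."""
    n = len(points)
    best = 0.0
    order = sorted(range(n), key=lambda i: points[i])
    for size in range(1, n + 1):
        for combo in itertools.combinations(order, size):
            ok = True
            skipped = 0
            for u, v in zip(combo, combo[1:]):
                dx = points[v][0] - points[u][0]
                dy = points[v][1] - points[u][1]
                if dx <= 0 or dy <= 0 or dx > max_gap or dy > max_gap:
                    ok = False
                    break
                skipped += (dx - 1) + (dy - 1)
            if ok:
                best = max(best, size - 0.1 * skipped)
    return best


def test_simple_diagonal_is_one_block():
    anchors = [AnchorPair(f"x{i}", f"y{i}", 1.0, 99.0) for i in range(3)]
    ranks_x = {f"x{i}": ("cx", i + 1) for i in range(3)}
    ranks_y = {f"y{i}": ("cy", i + 1) for i in range(3)}
    blocks = chain_collinear(anchors, ranks_x, ranks_y, max_gap=25,
                             min_block=3)
    assert len(blocks) == 1
    assert blocks[0].n_anchors == 3
    assert blocks[0].orientation == "same"


def test_outlier_is_excluded_from_the_block():
    anchors = [AnchorPair(f"x{i}", f"y{i}", 1.0, 99.0) for i in range(4)]
    ranks_x = {"x0": ("cx", 1), "x1": ("cx", 2), "x2": ("cx", 3),
               "x3": ("cx", 10)}
    ranks_y = {"y0": ("cy", 1), "y1": ("cy", 2), "y2": ("cy", 3),
               "y3": ("cy", 1)}
    blocks = chain_collinear(anchors, ranks_x, ranks_y, max_gap=25,
                             min_block=3)
    assert len(blocks) == 1
    assert blocks[0].x_genes() == {"x0", "x1", "x2"}


def test_inverted_blocks_are_found():
    anchors = [AnchorPair(f"x{i}", f"y{i}", 1.0, 99.0) for i in range(4)]
    ranks_x = {f"x{i}": ("cx", i + 1) for i in range(4)}
    ranks_y = {f"y{i}": ("cy", 10 - i) for i in range(4)}
    (block,) = chain_collinear(anchors, ranks_x, ranks_y, 25, 4)
    assert block.orientation == "inverted"
    assert block.n_anchors == 4


def test_best_chain_matches_exhaustive_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(2, 11))
        pts = [(int(rng.integers(1, 15)), int(rng.integers(1, 15)))
               for _ in range(n)]
        pts = list(dict.fromkeys(pts))
        max_gap = int(rng.integers(2, 8))
        score, chain = best_chain(pts, max_gap)
        assert score == pytest.approx(_oracle_best_chain(pts, max_gap))
        # returned chain is valid under the same constraints
        for u, v in zip(chain, chain[1:]):
            dx = pts[v][0] - pts[u][0]
            dy = pts[v][1] - pts[u][1]
            assert 0 < dx <= max_gap and 0 < dy <= max_gap


def test_chaining_is_input_order_invariant(rng):
    anchors = [AnchorPair(f"x{i}", f"y{i}", 1.0, 99.0) for i in range(8)]
    ranks_x = {f"x{i}": ("cx", i + 1) for i in range(8)}
    ranks_y = {f"y{i}": ("cy", i + 1) for i in range(8)}
    b1 = chain_collinear(anchors, ranks_x, ranks_y, 25, 4)
    shuffled = [anchors[i] for i in rng.permutation(8)]
    b2 = chain_collinear(shuffled, ranks_x, ranks_y, 25, 4)
    assert [b.anchors for b in b1] == [b.anchors for b in b2]


# ------------------------------------------------------------- origin labels

def test_origin_labels_partition_the_family(full_run):
    cfg, ctx = full_run
    labels = [l.label for l in ctx["origins"].values()]
    assert len(labels) == len(ctx["origins"])
    valid = {"inherited_A", "inherited_C", "segmental", "tandem", "HE",
             "unassigned"}
    assert set(labels) <= valid


def test_planted_tandem_pairs_are_labeled_tandem(full_run):
    cfg, ctx = full_run
    truth = ctx["dataset"].truth
    tandem_truth = set(truth[truth.origin == "tandem"].gene)
    tandem_called = {g for g, l in ctx["origins"].items()
                     if l.label == "tandem"}
    assert tandem_truth == tandem_called


def test_planted_he_runs_are_labeled_he(full_run):
    cfg, ctx = full_run
    truth = ctx["dataset"].truth
    he_truth = set(truth[truth.origin == "HE"].gene)
    he_called = {g for g, l in ctx["origins"].items() if l.label == "HE"}
    assert he_truth == he_called


def test_missing_family_gene_raises():
    with pytest.raises(ValueError, match="absent"):
        classify_origins({}, {"ghost"}, lambda c: "A", [], [], [],
                         {}, lambda a, b: 0.0, OriginParams())


# --------------------------------------------------------------- sister pairs

def test_identical_duplicates_pair_at_full_identity():
    prots = {"a": "MKRLVWCCDEFGHIKL", "b": "MKRLVWCCDEFGHIKL",
             "c": "WWWWYYYYWWWWYYYY"}
    ranges = {g: (0, 6) for g in prots}
    proms = {g: "ACGTACGTACGT" for g in prots}
    pairs = sister_pairs(prots, ranges, proms)
    assert len(pairs) == 1
    p = pairs[0]
    assert {p["gene1"], p["gene2"]} == {"a", "b"}
    assert p["domain_identity"] == 100.0
    assert p["full_identity"] == 100.0
    assert p["promoter_identity"] == 100.0


def test_unrelated_genes_do_not_pair():
    prots = {"a": "MKRLVWCCDEFGHIKL", "c": "WWWWYYYYWWWWYYYY"}
    ranges = {g: (0, 6) for g in prots}
    assert sister_pairs(prots, ranges) == []


def test_planted_sister_pairs_recovered(full_run):
    cfg, ctx = full_run
    ds = ctx["dataset"]
    found = {frozenset((p["gene1"], p["gene2"]))
             for p in ctx["sister_pairs"]}
    planted = {frozenset((g1, g2)) for _sid, g1, g2 in ds.sister_pairs}
    recovered = planted & found
    assert len(recovered) / len(planted) >= 0.9


# ----------------------------------------------------------- chromosome census

def test_chromosome_counts_and_subgenome_means():
    counts_vec = [12, 11, 18, 12, 13, 10, 12, 7, 18, 8]
    chroms = [f"A{i + 1:02d}" for i in range(10)]
    gene_chroms = {}
    k = 0
    for c, n in zip(chroms, counts_vec):
        for _ in range(n):
            gene_chroms[f"g{k}"] = c
            k += 1
    counts, means = chromosome_census(gene_chroms, chroms, lambda c: c[0])
    assert sum(counts.values()) == 121
    assert means["A"] == 12.1


def test_empty_chromosome_counts_zero():
    counts, means = chromosome_census({"g": "A01"}, ["A01", "A02"],
                                      lambda c: "A")
    assert counts["A02"] == 0
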