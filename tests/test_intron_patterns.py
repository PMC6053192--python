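"""Signature construction, pattern clustering and concordance statistics."""

import itertools

import numpy as np
import pytest

from madsfam.gene_models import GeneModel
from madsfam.domain_scan import DomainHit
from madsfam.intron_patterns import (PatternSignature, make_signature,
                                     clade_pattern_concordance,
                                     cluster_signatures,
                                     cross_set_pattern_presence,
                                     mads_exon1_check, signatures_linked)


def sig(gene, sites):
    return PatternSignature(gene_id=gene, sites=tuple(sites))


# ------------------------------------------------------------ make_signature

def test_window_filter():
    s = make_signature("g", [(5, 1), (40, 0)], (10, 60))
    assert s.sites == ((40, 0),)


def test_empty_signature_outside_window():
    s = make_signature("g", [(5, 1)], (10, 60))
    assert s.sites == ()


def test_invalid_window_raises():
    with pytest.raises(ValueError):
        make_signature("g", [], (60, 10))


# --------------------------------------------------------------- clustering

def test_hand_single_linkage_example():
    sigs = [sig("g1", [(10, 1), (25, 0)]), sig("g2", [(11, 1), (25, 0)]),
            sig("g3", [(40, 2)])]
    classes = cluster_signatures(sigs, column_tol=2,
                                 allow_variable_first=False)
    assert [(c.label, c.size) for c in classes] == [("A", 2), ("B", 1)]
    assert classes[0].frequency == pytest.approx(2 / 3)
    assert classes[1].frequency == pytest.approx(1 / 3)


def test_identical_signatures_form_one_class():
    sigs = [sig(f"g{i}", [(10, 1), (25, 0)]) for i in range(5)]
    (c,) = cluster_signatures(sigs)
    assert c.size == 5 and c.frequency == 1.0
    assert c.consensus == ((10, 1), (25, 0))


def test_variable_first_site_links_length_mismatch():
    a = sig("a", [(10, 1), (25, 0), (40, 2)])
    b = sig("b", [(25, 0), (40, 2)])             # leading site absent
    c = sig("c", [(18, 2), (25, 0), (40, 2)])    # leading site differs
    assert signatures_linked(a, b, 2, True)
    assert signatures_linked(a, c, 2, True)
    assert not signatures_linked(a, b, 2, False)
    assert not signatures_linked(a, c, 2, False)


def test_zero_tolerance_equals_exact_equality_oracle(rng):
    """Brute-force oracle: classes are exact-equality groups."""
    pool = [((10, 1), (25, 0)), ((10, 1), (26, 0)), ((40, 2),),
            ((10, 1), (25, 0), (33, 2))]
    sigs = [sig(f"g{i}", pool[rng.integers(len(pool))]) for i in range(30)]
    classes = cluster_signatures(sigs, column_tol=0,
                                 allow_variable_first=False)
    oracle = {}
    for s in sigs:
        oracle.setdefault(s.sites, set()).add(s.gene_id)
    got = {tuple(c.consensus): set(c.members) for c in classes}
    assert got == {k: v for k, v in oracle.items()}


def test_clustering_is_order_and_shift_invariant(rng):
    pool = [((10, 1), (25, 0)), ((40, 2),), ((12, 1), (25, 0))]
    sigs = [sig(f"g{i}", pool[i % 3]) for i in range(12)]
    base = cluster_signatures(sigs)
    perm = [sigs[i] for i in rng.permutation(len(sigs))]
    assert [(c.label, sorted(c.members)) for c in base] == \
           [(c.label, sorted(c.members)) for c in cluster_signatures(perm)]
    shifted = [sig(s.gene_id, [(c + 100, p) for c, p in s.sites])
               for s in sigs]
    assert [sorted(c.members) for c in base] == \
           [sorted(c.members) for c in cluster_signatures(shifted)]


def test_planted_patterns_recovered_on_synthetic_family(full_run):
    """Recovered class membership matches planted labels for >= 95%."""
    cfg, ctx = full_run
    ds = ctx["dataset"]
    truth = dict(zip(ds.truth.gene, ds.truth.pattern))
    correct = total = 0
    for cls in ctx["pattern_classes"]:
        planted = [truth[g] for g in cls.members if truth.get(g)]
        if not planted:
            continue
        majority = max(set(planted), key=planted.count)
        correct += planted.count(majority)
        total += len(planted)
    assert total >= 40
    assert correct / total >= 0.95


# --------------------------------------------------------------- exon1 rule

def _gene(exon_cds_lens):
    exons, pos = [], 0
    for L in exon_cds_lens:
        exons.append((pos, pos + L))
        pos += L + 90
    return GeneModel(id="g", chromosome="c", strand="+", exons=exons,
                     cds_seq="A" * sum(exon_cds_lens))


def test_single_exon_gene_has_no_downstream_intron():
    hit = DomainHit("g", 0, 30, 1.0, 1.0)
    assert mads_exon1_check(_gene([120]), hit) == (True, None)


def test_downstream_phase_is_reported():
    # hit ends at protein 60, first exon 250 nt, next intron at offset 250
    hit = DomainHit("g", 0, 60, 1.0, 1.0)
    g = _gene([250, 100])
    assert mads_exon1_check(g, hit) == (True, 250 % 3)
    assert 250 % 3 == 1


def test_domain_crossing_exon_boundary_is_flagged():
    hit = DomainHit("g", 0, 60, 1.0, 1.0)
    g = _gene([100, 200])
    in_first, phase = mads_exon1_check(g, hit)
    assert in_first is False
    assert phase is None  # the only intron interrupts the domain itself


# -------------------------------------------------------------- concordance

def test_monomorphic_clades_have_purity_one():
    labels = {f"g{i}": "P1" for i in range(4)} | \
             {f"h{i}": "P2" for i in range(4)}
    clades = {"c1": {f"g{i}" for i in range(4)},
              "c2": {f"h{i}" for i in range(4)}}
    purity, p = clade_pattern_concordance(labels, clades, n_perm=99, seed=0)
    assert purity == 1.0
    assert 0 < p <= 1


def test_random_labels_match_enumeration_oracle():
    """Mean purity over all 2-pattern labelings equals brute-force value."""
    genes = [f"g{i}" for i in range(6)]
    clades = {"c1": set(genes[:3]), "c2": set(genes[3:])}
    purities = []
    for bits in itertools.product("01", repeat=6):
        labels = dict(zip(genes, bits))
        vals = []
        for members in clades.values():
            pats = [labels[g] for g in members]
            vals.append(max(pats.count(x) for x in set(pats)) / len(pats))
        purities.append(np.mean(vals))
    expected = float(np.mean(purities))
    rng = np.random.default_rng(0)
    sampled = []
    for _ in range(4000):
        labels = {g: str(rng.integers(2)) for g in genes}
        obs, _p = clade_pattern_concordance(labels, clades, n_perm=1, seed=1)
        sampled.append(obs)
    assert np.mean(sampled) == pytest.approx(expected, abs=0.02)


def test_planted_concordance_is_significant(full_run):
    cfg, ctx = full_run
    purity, p = ctx["concordance"]
    assert purity == pytest.approx(1.0)
    assert p <= 0.01


def test_gene_in_two_clades_raises():
    with pytest.raises(ValueError):
        clade_pattern_concordance({"g": "P"}, {"a": {"g"}, "b": {"g"}})


# ----------------------------------------------------- cross-species matrix

def test_presence_matrix_reflects_shared_patterns():
    from madsfam.intron_patterns import PatternClass
    c1 = PatternClass("A", ((10, 1), (25, 0)), ["x"], 1.0)
    c2 = PatternClass("A", ((11, 1), (25, 0)), ["y"], 0.5)
    c3 = PatternClass("B", ((40, 2),), ["z"], 0.5)
    m = cross_set_pattern_presence({"sp1": [c1], "sp2": [c2, c3],
                                    "sp3": []})
    assert list(m.columns) == ["sp1", "sp2", "sp3"]
    shared = m.loc[m["sp1"]]
    assert shared["sp2"].all()          # shared pattern present in both
    assert not m["sp3"].any()           # empty species: all-absent column
    assert m["sp2"].sum() == 2
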