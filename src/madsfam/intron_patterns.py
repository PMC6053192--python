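"""Intron-pattern fingerprints of a conserved domain.

Within a window of alignment columns (e.g. the K-box of MIKC-type MADS
proteins), each gene is reduced to a signature: the ordered list of
(alignment column, splicing phase) pairs of its intron insertion sites.
Signatures are clustered into conserved patterns by single linkage — two
signatures are linked when their phase sequences agree and matched columns
differ by at most ``column_tol`` — with an optional allowance for a variable
(or absent) leading site, reflecting that in real families the first intron
of the domain wanders while downstream sites stay put.  Classes are labelled
A, B, C, … by descending size.

Also provided: the first-exon rule check for the DNA-binding domain (domain
fully inside exon 1, first downstream intron phase 2), a permutation test of
clade–pattern concordance, and a cross-species pattern presence matrix.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np

from .domain_scan import DomainHit
from .gene_models import GeneModel, compute_intron_sites

__all__ = [
    "PatternSignature",
    "PatternClass",
    "make_signature",
    "signatures_linked",
    "cluster_signatures",
    "mads_exon1_check",
    "clade_pattern_concordance",
    "cross_set_pattern_presence",
]

Site = tuple[int, int]  # (alignment column, phase)


@dataclass
class PatternSignature:
    gene_id: str
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        cols = [c for c, _ in self.sites]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError(f"{self.gene_id}: columns must strictly increase")
        if any(p not in (0, 1, 2) for _, p in self.sites):
            raise ValueError(f"{self.gene_id}: phases must be 0, 1 or 2")

    @property
    def phases(self) -> tuple[int, ...]:
        return tuple(p for _, p in self.sites)

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.sites)


@dataclass
class PatternClass:
    label: str
    consensus: tuple[Site, ...]
    members: list[str]
    frequency: float = 0.0

    @property
    def size(self) -> int:
        return len(self.members)


def make_signature(gene_id: str, projected_sites: list[Site],
                   window: tuple[int, int]) -> PatternSignature:
    """Restrict projected sites to the domain window (order preserved)."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("window start must be < end")
    kept = tuple((c, p) for c, p in projected_sites if lo <= c < hi)
    return PatternSignature(gene_id=gene_id, sites=kept)


def _match_tail(a: tuple[Site, ...], b: tuple[Site, ...], tol: int) -> bool:
    """Site-by-site match: identical phases, columns within tol."""
    if len(a) != len(b):
        return False
    return all(pa == pb and abs(ca - cb) <= tol
               for (ca, pa), (cb, pb) in zip(a, b))


def signatures_linked(s1: PatternSignature, s2: PatternSignature,
                      column_tol: int = 2,
                      allow_variable_first: bool = True) -> bool:
    """Linkage rule for single-linkage clustering of signatures.

    Equal-length signatures are linked when every paired site matches
    (identical phase, column difference <= ``column_tol``).  With
    ``allow_variable_first`` the leading site may additionally differ freely
    (equal lengths, remaining sites matching) or be absent from the shorter
    signature (lengths differing by one, the longer one matching after
    dropping its leading site).
    """
    a, b = s1.sites, s2.sites
    if not a or not b:
        return False
    if len(a) == len(b):
        if _match_tail(a, b, column_tol):
            return True
        if allow_variable_first and len(a) >= 2:
            return _match_tail(a[1:], b[1:], column_tol)
        return False
    if allow_variable_first and abs(len(a) - len(b)) == 1:
        longer, shorter = (a, b) if len(a) > len(b) else (b, a)
        return _match_tail(longer[1:], shorter, column_tol)
    return False


def _consensus(members: list[PatternSignature]) -> tuple[Site, ...]:
    """Median columns and modal phases over members of the modal length."""
    lengths = [len(m.sites) for m in members]
    modal_len = statistics.mode(sorted(lengths))
    rows = [m for m in members if len(m.sites) == modal_len]
    out = []
    for k in range(modal_len):
        cols = sorted(m.sites[k][0] for m in rows)
        phases = sorted(m.sites[k][1] for m in rows)
        med = cols[len(cols) // 2] if len(cols) % 2 else \
            (cols[len(cols) // 2 - 1] + cols[len(cols) // 2]) // 2
        out.append((med, statistics.mode(phases)))
    return tuple(out)


def cluster_signatures(signatures: list[PatternSignature],
                       column_tol: int = 2,
                       allow_variable_first: bool = True
                       ) -> list[PatternClass]:
    """Single-linkage clustering of non-empty signatures into pattern classes.

    Classes are connected components under :func:`signatures_linked`.
    Labels are letters assigned by descending class size, ties broken by the
    smaller consensus first column.  Frequencies are member shares of all
    classified (non-empty) signatures.
    """
    sigs = [s for s in signatures if s.sites]
    if not sigs:
        raise ValueError("no non-empty signature to cluster")
    n = len(sigs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if signatures_linked(sigs[i], sigs[j], column_tol,
                                 allow_variable_first):
                parent[find(i)] = find(j)

    groups: dict[int, list[PatternSignature]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(sigs[i])

    classes = []
    for members in groups.values():
        cons = _consensus(members)
        classes.append((len(members), cons, sorted(m.gene_id for m in members),
                        members))
    classes.sort(key=lambda t: (-t[0], t[1][0][0] if t[1] else 0))
    out = []
    for rank, (size, cons, ids, _members) in enumerate(classes):
        label = _letter_label(rank)
        out.append(PatternClass(label=label, consensus=cons, members=ids,
                                frequency=size / n))
    return out


def _letter_label(rank: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    label = ""
    rank += 1
    while rank:
        rank, rem = divmod(rank - 1, 26)
        label = letters[rem] + label
    return label


def mads_exon1_check(gene: GeneModel, hit: DomainHit
                     ) -> tuple[bool, int | None]:
    """First-exon rule for the DNA-binding domain.

    Returns ``(domain_in_first_exon, first_downstream_intron_phase)`` where
    the flag is true iff the domain hit ends within the first exon's CDS
    (``3*hit.end <= first exon CDS length``) and the phase is that of the
    first intron at or beyond the domain end (None when there is none).
    """
    first_exon_len = gene.exon_cds_lengths[0]
    in_first = 3 * hit.end <= first_exon_len
    downstream = None
    for site in compute_intron_sites(gene):
        if site.cds_offset >= 3 * hit.end:
            downstream = site.phase
            break
    return in_first, downstream


def clade_pattern_concordance(labels: dict[str, str],
                              clades: dict[str, set],
                              n_perm: int = 999,
                              seed: int | None = None
                              ) -> tuple[float, float]:
    """Permutation test: do clades share patterns more than chance?

    Purity is the mean, over clades with at least one labelled gene, of the
    largest within-clade pattern share.  The p-value is
    ``(1 + #{permuted purity >= observed}) / (n_perm + 1)`` with pattern
    labels permuted over genes.
    """
    gene_order = sorted(g for genes in clades.values() for g in genes
                        if g in labels)
    assignment = {}
    for name, genes in clades.items():
        for g in genes:
            if g in assignment:
                raise ValueError(f"gene {g} appears in more than one clade")
            assignment[g] = name

    def purity(lab: dict[str, str]) -> float:
        vals = []
        for name, genes in clades.items():
            pats = [lab[g] for g in genes if g in lab]
            if not pats:
                warnings.warn(f"clade {name} has no labelled gene; excluded")
                continue
            shares = {p: pats.count(p) / len(pats) for p in set(pats)}
            vals.append(max(shares.values()))
        if not vals:
            raise ValueError("no clade with labelled genes")
        return float(np.mean(vals))

    observed = purity(labels)
    rng = np.random.default_rng(seed)
    lab_list = [labels[g] for g in gene_order]
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(lab_list)
        permuted = dict(zip(gene_order, perm))
        if purity(permuted) >= observed - 1e-12:
            ge += 1
    p = (1 + ge) / (n_perm + 1)
    return observed, p


def cross_set_pattern_presence(tables: dict[str, list[PatternClass]],
                               column_tol: int = 2,
                               allow_variable_first: bool = True):
    """Presence/absence of pattern consensi across species.

    Consensus signatures from all species are deduplicated with the same
    linkage rule used for clustering; the result is a pattern × species
    boolean DataFrame.  A species with no classes yields an all-absent
    column.
    """
    import pandas as pd
    refs: list[tuple[str, PatternSignature]] = []  # (row name, consensus)

    def as_sig(name: str, cons: tuple[Site, ...]) -> PatternSignature:
        return PatternSignature(gene_id=name, sites=cons)

    for species in sorted(tables):
        for cls in tables[species]:
            sig = as_sig(f"{species}:{cls.label}", cls.consensus)
            if not any(signatures_linked(sig, r, column_tol,
                                         allow_variable_first)
                       for _, r in refs):
                refs.append((f"P{len(refs) + 1}", sig))

    data = {}
    for species in sorted(tables):
        col = []
        for _, ref in refs:
            col.append(any(
                signatures_linked(as_sig("q", cls.consensus), ref,
                                  column_tol, allow_variable_first)
                for cls in tables[species]))
        data[species] = col
    return pd.DataFrame(data, index=[name for name, _ in refs])
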