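"""Promoter scanning against an IUPAC cis-element catalog.

Replaces a database lookup (e.g. PlantCARE) with explicit degenerate-pattern
matching: every exact IUPAC match of every catalog motif is reported on both
strands, with reverse-strand hits mapped back to forward-strand coordinates.
Summaries count genes, not hits, so overlapping matches of the same motif do
not inflate them.  Matching is implemented as a direct per-position
character-class comparison (not via the ``re`` module).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

GROUPS = ("A_light", "B_stress", "C_hormone")

__all__ = [
    "MotifCatalogEntry",
    "MotifHit",
    "CatalogError",
    "default_catalog",
    "load_catalog",
    "write_catalog",
    "scan_promoter",
    "summarize_groups",
    "reverse_complement",
]


class CatalogError(ValueError):
    """Raised when a catalog entry is invalid."""


@dataclass
class MotifCatalogEntry:
    motif_id: str
    pattern: str
    group: str
    description: str = ""

    def __post_init__(self) -> None:
        self.pattern = self.pattern.upper()
        bad = [c for c in self.pattern if c not in IUPAC]
        if bad:
            raise CatalogError(
                f"catalog entry {self.motif_id!r}: invalid IUPAC code(s) "
                f"{''.join(sorted(set(bad)))} in pattern {self.pattern!r}")
        if self.group not in GROUPS:
            raise CatalogError(
                f"catalog entry {self.motif_id!r}: group {self.group!r} not "
                f"one of {GROUPS}")


@dataclass
class MotifHit:
    gene_id: str
    motif_id: str
    offset: int        # 0-based, forward strand
    strand: str        # "+" | "-"
    matched_seq: str   # forward-strand sequence at the hit


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def default_catalog() -> list[MotifCatalogEntry]:
    """A small literature-style catalog of named plant cis-elements.

    The patterns are conventional IUPAC renderings of the named elements and
    are meant to be replaced by a user-supplied catalog when exact database
    patterns matter.
    """
    entries = [
        ("G-box", "CACGTG", "A_light", "light-responsive G-box"),
        ("GT1-motif", "GRWAAW", "A_light", "light-responsive GT1 site"),
        ("Box4", "ATTAAT", "A_light", "part of a light-responsive module"),
        ("MBS", "CAACTG", "B_stress", "MYB binding site, drought response"),
        ("HSE", "AGAANNTTCT", "B_stress", "heat shock element"),
        ("TC-rich", "ATTTTCTTCA", "B_stress", "defence/stress repeats"),
        ("CArG", "CCWWWWWWGG", "B_stress",
         "MADS-box protein binding site (CArG box)"),
        ("TCA", "CCATCTTTTT", "C_hormone", "salicylic-acid response"),
        ("GARE", "TCTGTTG", "C_hormone", "gibberellin response"),
        ("CGTCA", "CGTCA", "C_hormone", "MeJA response"),
        ("TGACG", "TGACG", "C_hormone", "MeJA response"),
        ("ABRE", "ACGTGGC", "C_hormone", "abscisic-acid response"),
    ]
    return [MotifCatalogEntry(*e) for e in entries]


def load_catalog(path: str) -> list[MotifCatalogEntry]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [MotifCatalogEntry(str(r["motif_id"]), str(r["pattern"]),
                              str(r["group"]), str(r.get("description", "")))
            for _, r in df.iterrows()]


def write_catalog(catalog: list[MotifCatalogEntry], path: str) -> None:
    pd.DataFrame([vars(e) for e in catalog]).to_csv(path, sep="\t",
                                                    index=False)


def _matches_at(seq: str, pattern: str, pos: int) -> bool:
    for k, code in enumerate(pattern):
        if seq[pos + k] not in IUPAC[code]:
            return False
    return True


def scan_promoter(promoter: str, catalog: list[MotifCatalogEntry],
                  gene_id: str = "") -> list[MotifHit]:
    """All exact IUPAC matches of every catalog motif, both strands.

    Reverse-strand matches are reported at forward-strand coordinates with
    ``strand="-"``; the matched sequence is the forward-strand slice.
    """
    if not promoter:
        raise ValueError("promoter sequence is empty")
    if not catalog:
        raise ValueError("motif catalog is empty")
    promoter = promoter.upper()
    rc = reverse_complement(promoter)
    n = len(promoter)
    hits: list[MotifHit] = []
    for entry in catalog:
        m = len(entry.pattern)
        if m > n:
            continue
        for pos in range(n - m + 1):
            if _matches_at(promoter, entry.pattern, pos):
                hits.append(MotifHit(gene_id, entry.motif_id, pos, "+",
                                     promoter[pos:pos + m]))
        for pos in range(n - m + 1):
            if _matches_at(rc, entry.pattern, pos):
                fwd = n - pos - m
                hits.append(MotifHit(gene_id, entry.motif_id, fwd, "-",
                                     promoter[fwd:fwd + m]))
    hits.sort(key=lambda h: (h.motif_id, h.offset, h.strand))
    return hits


def summarize_groups(hits: list[MotifHit], gene_classes: dict[str, str],
                     catalog: list[MotifCatalogEntry]) -> pd.DataFrame:
    """Gene-level motif-group counts per gene class.

    A gene counts once per motif regardless of hit multiplicity; a group
    total is the number of distinct genes with at least one motif of that
    group.  Returns a groups × classes DataFrame of gene counts.
    """
    group_of = {e.motif_id: e.group for e in catalog}
    classes = sorted(set(gene_classes.values()))
    genes_by_group: dict[str, set] = {g: set() for g in GROUPS}
    for h in hits:
        if h.gene_id not in gene_classes:
            raise ValueError(f"gene {h.gene_id} has no class")
        genes_by_group[group_of[h.motif_id]].add(h.gene_id)
    data = {cls: [sum(1 for g in genes_by_group[grp]
                      if gene_classes[g] == cls) for grp in GROUPS]
            for cls in classes}
    return pd.DataFrame(data, index=list(GROUPS))
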