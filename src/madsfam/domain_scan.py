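"""Position-specific scoring of a conserved protein domain.

A seed alignment of the domain (e.g. the ~58-aa MADS DNA-binding domain) is
turned into an explicit log-odds PSSM; candidate proteins are scanned with a
sliding window and hits are reported with a score normalised by the model's
maximum attainable score.  Intron sites expressed as protein positions can
then be projected into alignment-column coordinates so that insertion sites
are comparable across family members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

__all__ = [
    "DomainModel",
    "DomainHit",
    "build_pssm",
    "scan_protein",
    "project_site_to_alignment",
    "read_alignment",
    "write_hits_table",
]


@dataclass
class DomainModel:
    """Log-odds PSSM over retained alignment columns.

    ``log_odds`` has shape (width, 20) in :data:`AMINO_ACIDS` order;
    ``columns`` are the original alignment column indices that were retained;
    ``max_score`` is the sum of per-column maxima.
    """

    columns: list[int]
    log_odds: np.ndarray
    max_score: float

    @property
    def width(self) -> int:
        return len(self.columns)


@dataclass
class DomainHit:
    gene_id: str
    start: int  # 0-based on the protein
    end: int    # half-open
    score: float
    norm_score: float


def read_alignment(path: str) -> dict[str, str]:
    """Aligned FASTA → {id: row}; raises if rows are not equal length."""
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not rows:
        raise ValueError(f"no sequences in alignment {path!r}")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment {path!r} is not rectangular: {lengths}")
    return rows


def build_pssm(seed_msa: dict[str, str] | str, min_occupancy: float = 0.5,
               pseudocount: float = 1.0) -> DomainModel:
    """Build a log-odds PSSM from a seed alignment.

    Columns with a non-gap fraction below ``min_occupancy`` are dropped.
    Per retained column the score of residue *a* is
    ``log2(((count_a + pseudocount) / (n + 20*pseudocount)) / (1/20))``
    with ``n`` the number of sequences; the background is uniform 1/20.
    """
    if isinstance(seed_msa, str):
        seed_msa = read_alignment(seed_msa)
    rows = list(seed_msa.values())
    if len(rows) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    n = len(rows)
    length = len(rows[0])
    columns: list[int] = []
    scores: list[np.ndarray] = []
    denom = n + 20.0 * pseudocount
    for j in range(length):
        col = [r[j] for r in rows]
        nongap = [c for c in col if c not in "-."]
        if len(nongap) / n < min_occupancy or not nongap:
            continue
        counts = np.zeros(20)
        for c in nongap:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        lo = np.log2(((counts + pseudocount) / denom) * 20.0)
        columns.append(j)
        scores.append(lo)
    if not columns:
        raise ValueError("no alignment column satisfies min_occupancy")
    log_odds = np.vstack(scores)
    return DomainModel(columns=columns, log_odds=log_odds,
                       max_score=float(log_odds.max(axis=1).sum()))


def _window_score(model: DomainModel, window: str) -> float:
    total = 0.0
    for k, c in enumerate(window):
        row = model.log_odds[k]
        total += row[_AA_INDEX[c]] if c in _AA_INDEX else float(row.min())
    return total


def scan_protein(protein: str, model: DomainModel, threshold: float = 0.6,
                 gene_id: str = "") -> list[DomainHit]:
    """Scan a protein with the PSSM; return non-overlapping hits.

    All windows with normalised score >= ``threshold`` are candidates; hits
    are selected greedily best-score-first (ties to the leftmost start) and
    must not overlap an already accepted hit.  A protein shorter than the
    model width yields no hits.
    """
    w = model.width
    if len(protein) < w:
        return []
    candidates = []
    for start in range(len(protein) - w + 1):
        s = _window_score(model, protein[start:start + w])
        ns = s / model.max_score
        if ns >= threshold:
            candidates.append((start, s, ns))
    candidates.sort(key=lambda t: (-t[1], t[0]))
    taken: list[DomainHit] = []
    for start, s, ns in candidates:
        if any(start < h.end and start + w > h.start for h in taken):
            continue
        taken.append(DomainHit(gene_id=gene_id, start=start, end=start + w,
                               score=s, norm_score=ns))
    taken.sort(key=lambda h: h.start)
    return taken


def project_site_to_alignment(msa_row: str, codon_index: int,
                              phase: int) -> tuple[int, int]:
    """Map a protein position to its alignment column; phase passes through.

    Returns the column index of the ``codon_index``-th (0-based) non-gap
    character of ``msa_row``.  Raises ``IndexError`` when the row has fewer
    residues.
    """
    seen = 0
    for col, c in enumerate(msa_row):
        if c in "-.":
            continue
        if seen == codon_index:
            return col, phase
        seen += 1
    raise IndexError(
        f"codon_index {codon_index} beyond the {seen} residues of the row")


def write_hits_table(hits: list[DomainHit], path: str,
                     header_lines: list[str] | None = None) -> None:
    import pandas as pd
    df = pd.DataFrame(
        [{"gene": h.gene_id, "start": h.start, "end": h.end,
          "score": round(h.score, 4), "norm_score": round(h.norm_score, 4)}
         for h in hits],
        columns=["gene", "start", "end", "score", "norm_score"])
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
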