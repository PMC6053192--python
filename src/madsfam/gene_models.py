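"""Gene models from genome FASTA + GFF3: CDS reconstruction and intron sites.

The unit of downstream analysis is the :class:`GeneModel` — one transcript
per locus (longest CDS when several mRNAs exist), with exons in transcription
order — and the :class:`IntronSite`, the position of an intron in CDS
coordinates together with its splicing phase.  Phase follows the standard
intron-phase convention: phase 0 introns fall between codons, phase 1 after
the first base of a codon, phase 2 after the second.  This is distinct from
the GFF3 ``phase`` column (which states where the next codon starts inside a
CDS segment); the latter is validated on input but never used as the intron
phase.

Coordinates are GFF3 1-based inclusive at I/O and 0-based half-open
internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "IntronSite",
    "AnnotationError",
    "parse_annotation",
    "compute_intron_sites",
    "intron_count_summary",
    "write_structure_table",
]


class AnnotationError(ValueError):
    """Raised when GFF3 features are inconsistent with the genome FASTA."""


@dataclass
class IntronSite:
    """An intron insertion point in CDS coordinates.

    ``cds_offset`` is the number of coding nucleotides preceding the intron;
    ``phase = cds_offset mod 3`` and ``codon_index = cds_offset // 3`` (the
    0-based codon containing or immediately following the junction).
    """

    cds_offset: int
    phase: int
    codon_index: int

    @classmethod
    def from_offset(cls, cds_offset: int) -> "IntronSite":
        return cls(cds_offset=cds_offset, phase=cds_offset % 3,
                   codon_index=cds_offset // 3)


@dataclass
class GeneModel:
    """One gene locus: ordered CDS segments and derived sequences.

    ``exons`` are CDS segments as 0-based half-open genomic intervals in
    transcription order (descending genomic coordinates on the minus strand).
    ``cds_seq`` is the spliced coding sequence in reading direction.
    ``partial_orf`` flags genes whose CDS length is not a multiple of 3;
    such genes are kept but excluded from operations needing full proteins.
    """

    id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds_seq: str
    protein_seq: str | None = None
    partial_orf: bool = False
    attributes: dict = field(default_factory=dict)

    @property
    def exon_cds_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate (0-based) of the coding region."""
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        total = sum(self.exon_cds_lengths)
        if total != len(self.cds_seq):
            raise ValueError(
                f"{self.id}: CDS length {len(self.cds_seq)} != sum of exon "
                f"lengths {total}")


def _translate(cds: str) -> str | None:
    if len(cds) % 3 != 0:
        return None
    prot = str(Seq(cds).translate())
    return prot.rstrip("*")


def parse_annotation(gff3: str, fasta: str,
                     keep_partial: bool = True) -> list[GeneModel]:
    """Parse a GFF3 + genome FASTA into :class:`GeneModel` objects.

    When a gene carries several mRNAs the isoform with the longest total CDS
    is kept.  Genes without CDS features are skipped with a warning.  A CDS
    segment outside its chromosome raises :class:`AnnotationError` naming the
    feature.
    """
    db = gffutils.create_db(gff3, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genome = Fasta(fasta, as_raw=True, sequence_always_upper=True)
    models: list[GeneModel] = []

    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        best: tuple[int, list, str, object] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_parts = list(db.children(mrna, featuretype="CDS",
                                         order_by="start"))
            if not cds_parts:
                continue
            total = sum(c.end - c.start + 1 for c in cds_parts)
            if best is None or total > best[0]:
                best = (total, cds_parts, mrna.strand, mrna)
        if best is None:
            warnings.warn(f"gene {gene.id} has no CDS features; skipped")
            continue
        _, cds_parts, strand, _mrna = best
        chrom = gene.seqid
        if chrom not in genome:
            raise AnnotationError(
                f"gene {gene.id}: chromosome {chrom!r} absent from FASTA")
        chrom_len = len(genome[chrom])
        exons: list[tuple[int, int]] = []
        for c in cds_parts:
            s0, e0 = c.start - 1, c.end  # to 0-based half-open
            if s0 < 0 or e0 > chrom_len:
                raise AnnotationError(
                    f"CDS segment of {gene.id} ({c.start}..{c.end}) outside "
                    f"chromosome {chrom} (length {chrom_len})")
            exons.append((s0, e0))
        exons.sort()
        if strand == "-":
            exons = exons[::-1]
        pieces = []
        for s0, e0 in exons:
            seq = genome[chrom][min(s0, e0):max(s0, e0)]
            if strand == "-":
                seq = str(Seq(seq).reverse_complement())
            pieces.append(seq)
        cds_seq = "".join(pieces)
        partial = len(cds_seq) % 3 != 0
        if partial and not keep_partial:
            continue
        models.append(GeneModel(
            id=gene.id, chromosome=chrom, strand=strand, exons=exons,
            cds_seq=cds_seq, protein_seq=_translate(cds_seq),
            partial_orf=partial,
            attributes=dict(gene.attributes)))
    return models


def compute_intron_sites(gene: GeneModel) -> list[IntronSite]:
    """Intron insertion sites of a gene, in CDS coordinates.

    Returns one site per exon junction (``n_exons - 1`` sites), ordered by
    strictly increasing ``cds_offset``.  Single-exon genes yield an empty
    list.
    """
    sites: list[IntronSite] = []
    offset = 0
    for length in gene.exon_cds_lengths[:-1]:
        offset += length
        sites.append(IntronSite.from_offset(offset))
    return sites


def intron_count_summary(genes: list[GeneModel],
                         classes: dict[str, str] | None = None
                         ) -> pd.DataFrame:
    """Per-gene intron counts with an optional per-class mean (2 decimals).

    Returns a table with columns ``gene``, ``introns`` and, when ``classes``
    maps gene id → class label, ``class`` plus an attached per-class mean in
    ``df.attrs['class_means']``.
    """
    rows = [{"gene": g.id, "introns": len(g.exons) - 1} for g in genes]
    df = pd.DataFrame(rows, columns=["gene", "introns"])
    if classes is not None and not df.empty:
        df["class"] = df["gene"].map(classes)
        means = df.groupby("class")["introns"].mean().round(2).to_dict()
        df.attrs["class_means"] = means
    elif not df.empty:
        df.attrs["mean"] = round(float(df["introns"].mean()), 2)
    return df


def write_structure_table(genes: list[GeneModel], path: str,
                          header_lines: list[str] | None = None) -> None:
    """Write per-gene structure TSV: exon lengths, intron offsets and phases."""
    rows = []
    for g in genes:
        sites = compute_intron_sites(g)
        rows.append({
            "gene": g.id,
            "chromosome": g.chromosome,
            "strand": g.strand,
            "exon_cds_lengths": ",".join(map(str, g.exon_cds_lengths)),
            "intron_cds_offsets": ",".join(str(s.cds_offset) for s in sites),
            "intron_phases": ",".join(str(s.phase) for s in sites),
            "partial_orf": int(g.partial_orf),
        })
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
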