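"""Synthetic allotetraploid genome system with planted ground truth.

The generator emulates the data situation of a gene-family study in an
allotetraploid crop: two progenitor genomes (subgenomes "A" and "C") evolve
independently from a common ancestor by per-site substitution; the derived
genome is their union with one further round of substitutions, plus planted
tandem duplications, segmental duplications (a window of genes copied to
another chromosome of the same subgenome) and homologous-exchange events (a
window replaced by its homoeologous progenitor copy).  Family genes carry a
DNA-binding domain in exon 1 followed by a phase-2 intron and a K-box-like
region whose intron insertion sites and phases realise one of the planted
pattern signatures (one pattern per clade, the first site jittered within a
clade).  Promoters of derived family genes carry planted IUPAC motifs;
expression profiles follow one log2 archetype per clade so that homoeologous
sister pairs are correlated at a configurable level.

Every output is a plain-text standard format (FASTA, GFF3, aligned FASTA,
TSV, JSON) and the full ground truth is emitted as a per-gene truth table.
All randomness flows from ``SimConfig.seed``; two runs with the same config
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gene_models import GeneModel
from .promoter_elements import (IUPAC, MotifCatalogEntry, default_catalog,
                                scan_promoter)

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SyntheticDataset",
    "DEFAULT_PATTERN_LIBRARY",
    "simulate_dataset",
    "plant_intron_signature",
    "mutate_cds",
]

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGT", "TGCA")

# family-gene architecture (protein coordinates)
FAMILY_PROTEIN_LEN = 190      # aa
MADS_END = 58                 # DNA-binding domain occupies [0, 58)
KBOX_WINDOW = (70, 170)       # K-box-like region, alignment columns
MADS_INTRON_SITE = (58, 2)    # phase-2 intron right after the domain
BACKGROUND_PROTEIN_LEN = 150  # aa, non-family genes
INTRON_LEN = 90               # bp, canonical GT...AG
SPACER_LEN = 60               # bp between gene cassettes

# a MADS-like DNA-binding domain consensus used as the family seed
MADS_CONSENSUS = ("MGRGRVELKRIENKINRQVTFAKRRNGLLKKAYELSVLCDAEVALIIFSNRGKLYEFA")

# Seven pattern signatures in the K-box window: sites 2-5 are the conserved
# scaffold; the first site is the variable one; one pattern lacks the second
# site and one lacks the fifth.
DEFAULT_PATTERN_LIBRARY: dict[str, list[tuple[int, int]]] = {
    "A": [(78, 1), (115, 2), (140, 0), (162, 0)],
    "B": [(78, 1), (90, 0), (115, 2), (140, 0), (162, 1)],
    "C": [(78, 1), (90, 0), (115, 2), (140, 0), (162, 0)],
    "D": [(78, 1), (90, 0), (115, 2), (140, 0), (155, 0)],
    "E": [(78, 1), (90, 0), (115, 2), (132, 0), (162, 0)],
    "F": [(78, 1), (90, 0), (107, 2), (140, 0), (162, 0)],
    "G": [(78, 1), (90, 0), (115, 2), (140, 0)],
}

DEFAULT_MOTIF_PLANTS = {
    "GT1-motif": 1, "Box4": 1, "CArG": 1, "ABRE": 1, "CGTCA": 1, "TGACG": 1,
}

_CLADE_DIVERGENCE = 0.12   # between-clade substitution rate (ancestor level)
_DOMAIN_CONSERVATION = 0.1  # domain mutates at this fraction of the rate
_POST_POLYPLOIDY = 0.2      # derived-genome rate as a fraction of divergence


class SimConfigError(ValueError):
    """A simulation configuration is infeasible; the message names the
    violated constraint."""


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom_A: int = 3
    n_chrom_C: int = 3
    genes_per_chrom: int = 20
    family_size: int = 21          # family loci per progenitor genome
    divergence: float = 0.05       # per-site substitution probability
    n_tandem: int = 2
    n_segmental: int = 2
    n_HE: int = 2
    pattern_library: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in
                                 DEFAULT_PATTERN_LIBRARY.items()})
    motif_plants: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_PLANTS))
    promoter_len: int = 500
    expr_tissues: int = 50
    expr_noise_sd: float = 0.4
    pair_rho: float = 0.9

    def validate(self) -> None:
        for name in ("n_chrom_A", "n_chrom_C", "genes_per_chrom",
                     "family_size", "n_tandem", "n_segmental", "n_HE",
                     "promoter_len", "expr_tissues"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.divergence < 0.5:
            raise SimConfigError("divergence must be in [0, 0.5)")
        if not 0.0 <= self.pair_rho < 1.0:
            raise SimConfigError("pair_rho must be in [0, 1)")
        for label, sig in self.pattern_library.items():
            cols = [c for c, _ in sig]
            if any(b <= a for a, b in zip(cols, cols[1:])):
                raise SimConfigError(
                    f"pattern {label}: codon indices must strictly increase")
            if any(p not in (0, 1, 2) for _, p in sig):
                raise SimConfigError(f"pattern {label}: phases must be 0/1/2")
            if cols and cols[-1] >= FAMILY_PROTEIN_LEN:
                raise SimConfigError(
                    f"pattern {label}: codon index beyond family protein")
        n_chrom = max(self.n_chrom_A, self.n_chrom_C)
        if n_chrom == 0 and self.family_size > 0:
            raise SimConfigError("family_size > 0 requires chromosomes")
        if self.family_size:
            per = -(-self.family_size // n_chrom)  # ceil
            if 1 + 3 * (per - 1) > self.genes_per_chrom - 1:
                raise SimConfigError(
                    "family_size too large: family loci are spaced 3 ranks "
                    "apart and must fit genes_per_chrom")
        paired = min(self.n_chrom_A, self.n_chrom_C)
        n_events = self.n_tandem + self.n_segmental + self.n_HE
        if n_events > 2 * self.family_size:
            raise SimConfigError(
                "n_tandem + n_segmental + n_HE exceeds the number of derived "
                "family genes")
        if self.n_segmental and (self.n_chrom_A < 2 and self.n_chrom_C < 2):
            raise SimConfigError(
                "segmental events need >= 2 chromosomes in a subgenome")
        if self.n_HE and paired == 0:
            raise SimConfigError(
                "HE events need homoeologous (paired) chromosomes")


@dataclass
class _Cassette:
    gene_id: str
    locus: str
    family: bool
    clade: str | None
    strand: str
    cds: str
    intron_offsets: list[int]
    intron_seqs: list[str]
    promoter: str
    spacer: str
    pattern_label: str = ""
    sister_id: str = ""
    origin: str = ""
    motif_counts: dict[str, int] = field(default_factory=dict)
    expr_key: str = ""


@dataclass
class SyntheticDataset:
    out_dir: str
    config: SimConfig
    paths: dict[str, str]
    truth: pd.DataFrame
    family_ids: dict[str, list[str]]      # genome -> family gene ids
    clade_of: dict[str, str]              # derived family gene -> clade
    sister_pairs: list[tuple[str, str, str]]
    kbox_window: tuple[int, int] = KBOX_WINDOW
    mads_range: tuple[int, int] = (0, MADS_END)


# ---------------------------------------------------------------- sequences

def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


_SENSE_CODONS = sorted(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS)

_CODON_OF: dict[str, str] = {}
for _codon in _SENSE_CODONS:
    from Bio.Seq import Seq as _Seq
    _aa = str(_Seq(_codon).translate())
    _CODON_OF.setdefault(_aa, _codon)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    return _CODON_OF["M"] + "".join(_SENSE_CODONS[i] for i in idx)


def mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution (uniform among the 3 alternatives), with
    substitutions that would create a new in-frame stop codon reverted."""
    if rate <= 0:
        return cds
    s = list(cds)
    hits = np.nonzero(rng.random(len(s)) < rate)[0]
    for i in hits:
        alt = [b for b in BASES if b != s[i]]
        s[i] = alt[int(rng.integers(3))]
    for c in range(0, len(s) - 2, 3):
        codon = "".join(s[c:c + 3])
        if codon in STOP_CODONS and cds[c:c + 3] not in STOP_CODONS:
            s[c:c + 3] = cds[c:c + 3]
    return "".join(s)


def _mutate_family_cds(cds: str, rate: float,
                       rng: np.random.Generator) -> str:
    """Family-gene substitution: the DNA-binding domain evolves under
    purifying selection, at a tenth of the background rate."""
    cut = 3 * MADS_END
    return (mutate_cds(cds[:cut], rate * _DOMAIN_CONSERVATION, rng)
            + mutate_cds(cds[cut:], rate, rng))


def _intron_seq(rng: np.random.Generator) -> str:
    return "GT" + _random_seq(INTRON_LEN - 4, rng) + "AG"


def _signature_to_offsets(cds_len: int,
                          signature: list[tuple[int, int]]) -> list[int]:
    offsets = []
    prev = 0
    for codon_index, phase in signature:
        if phase not in (0, 1, 2):
            raise ValueError(f"invalid phase {phase}")
        off = 3 * codon_index + phase
        if off <= prev:
            raise ValueError("codon indices must strictly increase")
        if not 0 < off < cds_len:
            raise ValueError(
                f"intron site (codon {codon_index}, phase {phase}) outside "
                f"CDS of {cds_len} nt")
        offsets.append(off)
        prev = off
    return offsets


def plant_intron_signature(cds_seq: str,
                           signature: list[tuple[int, int]],
                           gene_id: str = "gene",
                           chromosome: str = "chr",
                           origin: int = 0,
                           strand: str = "+",
                           rng: np.random.Generator | None = None
                           ) -> tuple[GeneModel, str]:
    """Insert introns realising ``signature`` into a CDS.

    ``signature`` is an ordered list of (codon_index, phase) pairs; the
    intron is inserted at CDS offset ``3*codon_index + phase``.  Returns the
    resulting :class:`~madsfam.gene_models.GeneModel` (exon coordinates on a
    virtual plus-strand chromosome starting at ``origin``) together with the
    genomic sequence of the gene body.  Recomputing intron sites from the
    model reproduces the signature exactly.
    """
    rng = rng or np.random.default_rng(0)
    offsets = _signature_to_offsets(len(cds_seq), signature)
    introns = [_intron_seq(rng) for _ in offsets]
    bounds = [0] + offsets + [len(cds_seq)]
    exon_seqs = [cds_seq[a:b] for a, b in zip(bounds, bounds[1:])]
    body = ""
    exons = []
    pos = origin
    for k, exon in enumerate(exon_seqs):
        exons.append((pos, pos + len(exon)))
        body += exon
        pos += len(exon)
        if k < len(introns):
            body += introns[k]
            pos += len(introns[k])
    from Bio.Seq import Seq
    protein = None
    if len(cds_seq) % 3 == 0:
        protein = str(Seq(cds_seq).translate()).rstrip("*")
    model = GeneModel(id=gene_id, chromosome=chromosome, strand=strand,
                      exons=exons, cds_seq=cds_seq, protein_seq=protein,
                      partial_orf=len(cds_seq) % 3 != 0)
    return model, body


# ------------------------------------------------------------- motif plants

def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in pattern)


def _plant_promoter(length: int, plants: dict[str, int],
                    catalog: list[MotifCatalogEntry],
                    rng: np.random.Generator, max_tries: int = 200) -> str:
    """A random promoter whose realized motif presence equals the plan.

    Planted instances are written at non-overlapping random offsets; the
    background is redrawn until no unplanted catalog motif matches anywhere
    (rejection sampling), so gene-level presence is exactly the planted set.
    """
    by_id = {e.motif_id: e for e in catalog}
    for mid in plants:
        if mid not in by_id:
            raise SimConfigError(f"motif_plants names unknown motif {mid!r}")
    want = {m for m, c in plants.items() if c > 0}
    for _ in range(max_tries):
        arr = list(_random_seq(length, rng))
        placed: list[tuple[int, int]] = []
        ok = True
        for mid in sorted(plants):
            pat = by_id[mid].pattern
            for _k in range(plants[mid]):
                inst = _instantiate(pat, rng)
                for _t in range(50):
                    off = int(rng.integers(0, length - len(inst) + 1))
                    if all(off + len(inst) <= s or off >= s + l
                           for s, l in placed):
                        placed.append((off, len(inst)))
                        arr[off:off + len(inst)] = inst
                        break
                else:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        seq = "".join(arr)
        present = {h.motif_id for h in scan_promoter(seq, catalog)}
        if present == want:
            return seq
    raise SimConfigError(
        "could not realize the planted motif presence within "
        f"{max_tries} tries; reduce catalog density or promoter motif load")


# ----------------------------------------------------------------- assembly

def _render_genome(chroms: dict[str, list[_Cassette]], source: str
                   ) -> tuple[dict[str, str], list[str],
                              dict[str, tuple[int, int, str]]]:
    """Assemble chromosome sequences + GFF3 lines; returns promoter spans."""
    fasta: dict[str, str] = {}
    gff: list[str] = ["##gff-version 3"]
    promoters: dict[str, tuple[int, int, str]] = {}  # gene -> (s, e, chrom)
    for chrom in sorted(chroms):
        pieces: list[str] = []
        pos = 0
        for cas in chroms[chrom]:
            bounds = [0] + list(cas.intron_offsets) + [len(cas.cds)]
            exon_seqs = [cas.cds[a:b] for a, b in zip(bounds, bounds[1:])]
            body = ""
            rel: list[tuple[int, int]] = []
            p = 0
            for k, ex in enumerate(exon_seqs):
                rel.append((p, p + len(ex)))
                body += ex
                p += len(ex)
                if k < len(cas.intron_seqs):
                    body += cas.intron_seqs[k]
                    p += len(cas.intron_seqs[k])
            if cas.strand == "+":
                prom_span = (pos, pos + len(cas.promoter))
                body_start = pos + len(cas.promoter)
                exons = [(body_start + a, body_start + b) for a, b in rel]
                pieces.append(cas.promoter + body + cas.spacer)
            else:
                body_start = pos + len(cas.spacer)
                L = len(body)
                exons = [(body_start + L - b, body_start + L - a)
                         for a, b in rel]  # transcription order kept
                prom_span = (body_start + L, body_start + L
                             + len(cas.promoter))
                pieces.append(cas.spacer + _rc(body) + _rc(cas.promoter))
            pos += len(pieces[-1])
            promoters[cas.gene_id] = (prom_span[0], prom_span[1], chrom)
            gmin = min(s for s, _ in exons)
            gmax = max(e for _, e in exons)
            attrs = f"ID={cas.gene_id}"
            gff.append("\t".join([chrom, source, "gene", str(gmin + 1),
                                  str(gmax), ".", cas.strand, ".", attrs]))
            mid = f"{cas.gene_id}.1"
            gff.append("\t".join([chrom, source, "mRNA", str(gmin + 1),
                                  str(gmax), ".", cas.strand, ".",
                                  f"ID={mid};Parent={cas.gene_id}"]))
            cum = 0
            for k, (s, e) in enumerate(exons):
                phase = (3 - cum % 3) % 3
                for ftype in ("exon", "CDS"):
                    gff.append("\t".join(
                        [chrom, source, ftype, str(s + 1), str(e),
                         ".", cas.strand, str(phase) if ftype == "CDS"
                         else ".",
                         f"ID={mid}.{ftype}{k};Parent={mid}"]))
                cum += e - s
        fasta[chrom] = "".join(pieces)
    return fasta, gff, promoters


def _write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _translate(cds: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(cds).translate()).rstrip("*")


# ------------------------------------------------------------------- driver

def simulate_dataset(config: SimConfig, out_dir: str,
                     catalog: list[MotifCatalogEntry] | None = None
                     ) -> SyntheticDataset:
    """Generate the full synthetic dataset and write it under ``out_dir``.

    Outputs: ``progenitorA/C.genome.fasta`` + ``.gff3``, ``derived.genome
    .fasta`` + ``.gff3``, ``derived.promoters.fasta``, ``domain_seed.aln
    .fasta`` (DNA-binding domains of the clade ancestors),
    ``family_proteins.aln.fasta`` (derived family proteins, rectangular),
    ``expression.tsv``, ``truth.tsv`` and ``config.json``.
    """
    config.validate()
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)

    patterns = sorted(config.pattern_library)
    n_chrom = max(config.n_chrom_A, config.n_chrom_C)
    paired = min(config.n_chrom_A, config.n_chrom_C)

    # --- ancestor loci ------------------------------------------------
    # family loci spread over chromosomes, 3 ranks apart
    fam_positions: dict[int, list[int]] = {i: [] for i in range(n_chrom)}
    for f in range(config.family_size):
        fam_positions[f % n_chrom].append(1 + 3 * (f // n_chrom))

    base_family_cds = (
        "".join(_CODON_OF[aa] for aa in MADS_CONSENSUS)
        + _random_cds(FAMILY_PROTEIN_LEN - MADS_END, rng)[3:]
        + _random_cds(2, rng)[:3])
    # exactly FAMILY_PROTEIN_LEN codons
    base_family_cds = base_family_cds[:3 * FAMILY_PROTEIN_LEN]
    clade_cds = {}
    clade_prot = {}
    for label in patterns:
        cds = _mutate_family_cds(base_family_cds, _CLADE_DIVERGENCE, rng)
        clade_cds[label] = cds
        clade_prot[label] = _translate(cds)

    ancestor: dict[int, list[_Cassette]] = {}
    fam_counter = 0
    for ci in range(n_chrom):
        cassettes: list[_Cassette] = []
        fam_at = set(fam_positions[ci])
        for pos in range(config.genes_per_chrom):
            locus = f"{ci:02d}g{pos:02d}"
            strand = "-" if rng.random() < 0.3 else "+"
            if pos in fam_at:
                clade = patterns[fam_counter % len(patterns)]
                fam_counter += 1
                sig = [MADS_INTRON_SITE] + list(
                    config.pattern_library[clade])
                # jitter the first K-box site within the clade
                if len(sig) > 1:
                    c0, p0 = sig[1]
                    nxt = sig[2][0] if len(sig) > 2 else KBOX_WINDOW[1]
                    jit = int(rng.integers(-3, 4))
                    c0 = min(max(c0 + jit, KBOX_WINDOW[0] + 1), nxt - 2)
                    sig[1] = (c0, p0)
                cds = _mutate_family_cds(clade_cds[clade], 0.02, rng)
                offsets = _signature_to_offsets(len(cds), sig)
                cassettes.append(_Cassette(
                    gene_id=locus, locus=locus, family=True, clade=clade,
                    strand=strand, cds=cds, intron_offsets=offsets,
                    intron_seqs=[_intron_seq(rng) for _ in offsets],
                    promoter=_random_seq(config.promoter_len, rng),
                    spacer=_random_seq(SPACER_LEN, rng),
                    pattern_label=clade,
                    sister_id=f"sp_{locus}" if ci < paired else ""))
            else:
                cds = _random_cds(BACKGROUND_PROTEIN_LEN, rng)
                k = int(rng.integers(0, 3))
                codons = sorted(rng.choice(
                    np.arange(10, BACKGROUND_PROTEIN_LEN - 10), size=k,
                    replace=False)) if k else []
                sig = [(int(c), int(rng.integers(0, 3))) for c in codons]
                offsets = _signature_to_offsets(len(cds), sig)
                cassettes.append(_Cassette(
                    gene_id=locus, locus=locus, family=False, clade=None,
                    strand=strand, cds=cds, intron_offsets=offsets,
                    intron_seqs=[_intron_seq(rng) for _ in offsets],
                    promoter=_random_seq(config.promoter_len, rng),
                    spacer=_random_seq(SPACER_LEN, rng)))
        ancestor[ci] = cassettes

    # --- progenitors ----------------------------------------------------
    def derive(cas: _Cassette, gene_id: str, rate: float) -> _Cassette:
        mut = _mutate_family_cds if cas.family else mutate_cds
        return dataclasses.replace(
            cas, gene_id=gene_id, cds=mut(cas.cds, rate, rng),
            motif_counts={})

    prog: dict[str, dict[str, list[_Cassette]]] = {"A": {}, "C": {}}
    for sub, n_sub in (("A", config.n_chrom_A), ("C", config.n_chrom_C)):
        for ci in range(n_sub):
            chrom = f"{sub}{ci + 1:02d}"
            prog[sub][chrom] = [
                derive(cas, f"Pr{sub}_{chrom}_{cas.locus}",
                       config.divergence)
                for cas in ancestor[ci]]

    # --- derived genome -------------------------------------------------
    # the allopolyploid is recent: much less divergence from the
    # progenitors than between the progenitors themselves
    post_rate = config.divergence * _POST_POLYPLOIDY
    derived: dict[str, list[_Cassette]] = {}
    for sub in ("A", "C"):
        for chrom, cassettes in prog[sub].items():
            dchrom = f"{sub}n{chrom[1:]}"
            derived[dchrom] = [
                derive(cas, f"Bn_{dchrom}_{cas.locus.split('_')[-1]}",
                       post_rate)
                for cas in cassettes]
    for chrom in derived:
        for cas in derived[chrom]:
            if cas.family:
                cas.origin = f"inherited_{chrom[0]}"

    # --- events ----------------------------------------------------------
    def sub_of(chrom: str) -> str:
        return chrom[0]

    def fam_indices(chrom: str) -> list[int]:
        return [i for i, c in enumerate(derived[chrom]) if c.family]

    used: set[tuple[str, int]] = set()  # (chrom, index) loci consumed

    # HE: replace a 3-gene window with the homoeologous progenitor copies
    d_chroms = sorted(derived)
    he_candidates = []
    for chrom in d_chroms:
        ci = int(chrom[2:]) - 1
        if ci >= paired:
            continue
        for i in fam_indices(chrom):
            if 1 <= i <= len(derived[chrom]) - 2:
                he_candidates.append((chrom, i))
    if config.n_HE > len(he_candidates):
        raise SimConfigError(
            f"n_HE={config.n_HE} exceeds the {len(he_candidates)} eligible "
            "family loci on paired chromosomes")
    he_pick_idx = rng.choice(len(he_candidates), size=config.n_HE,
                             replace=False) if config.n_HE else []
    for k in sorted(int(i) for i in np.atleast_1d(he_pick_idx)):
        chrom, i = he_candidates[k]
        other_sub = "C" if sub_of(chrom) == "A" else "A"
        src_chrom = f"{other_sub}{chrom[2:]}"
        for j in (i - 1, i, i + 1):
            donor = prog[other_sub][src_chrom][j]
            cas = derived[chrom][j]
            mut = _mutate_family_cds if cas.family else mutate_cds
            cas.cds = mut(donor.cds, post_rate, rng)
            if cas.family:
                cas.origin = "HE"
            used.add((chrom, j))

    def pick_free_family(n: int, need_window: int, what: str
                         ) -> list[tuple[str, int]]:
        cands = []
        for chrom in d_chroms:
            for i in fam_indices(chrom):
                lo, hi = i - need_window, i + need_window
                if lo < 0 or hi >= len(derived[chrom]):
                    continue
                if any((chrom, j) in used for j in range(lo, hi + 1)):
                    continue
                if what == "segmental":
                    sub = sub_of(chrom)
                    n_sub = (config.n_chrom_A if sub == "A"
                             else config.n_chrom_C)
                    if n_sub < 2:
                        continue
                cands.append((chrom, i))
        if n > len(cands):
            raise SimConfigError(
                f"n_{what}={n} exceeds the {len(cands)} available family "
                "loci (windows must not overlap other planted events)")
        idx = rng.choice(len(cands), size=n, replace=False) if n else []
        picked = [cands[int(i)] for i in np.atleast_1d(idx)]
        for chrom, i in picked:
            for j in range(i - need_window, i + need_window + 1):
                used.add((chrom, j))
        return sorted(picked)

    seg_picks = pick_free_family(config.n_segmental, 2, "segmental")
    tan_picks = pick_free_family(config.n_tandem, 1, "tandem")

    # segmental: copy a 5-gene window to another chromosome, same subgenome
    for chrom, i in seg_picks:
        sub = sub_of(chrom)
        sub_chroms = sorted(c for c in d_chroms if sub_of(c) == sub)
        tgt = sub_chroms[(sub_chroms.index(chrom) + 1) % len(sub_chroms)]
        for j in range(i - 2, i + 3):
            src = derived[chrom][j]
            copy = derive(src, src.gene_id + "_s", post_rate)
            copy.sister_id = ""
            if copy.family:
                copy.origin = "segmental"
                copy.expr_key = src.locus  # conserved expression archetype
            derived[tgt].append(copy)

    # tandem: insert a copy immediately after the source gene
    for chrom, i in sorted(tan_picks, key=lambda t: (t[0], -t[1])):
        src = derived[chrom][i]
        copy = derive(src, src.gene_id + "_t", post_rate)
        copy.sister_id = ""
        copy.origin = "tandem"
        copy.expr_key = src.locus
        src.origin = "tandem"
        derived[chrom].insert(i + 1, copy)

    # --- promoters with planted motifs (derived family genes) ----------
    for chrom in d_chroms:
        for cas in derived[chrom]:
            if cas.family:
                cas.promoter = _plant_promoter(
                    config.promoter_len, config.motif_plants, catalog, rng)
                cas.motif_counts = {m: c for m, c in
                                    sorted(config.motif_plants.items()) if c}

    # --- expression ------------------------------------------------------
    t = config.expr_tissues
    clade_category: dict[str, str] = {}
    clade_archetype: dict[str, np.ndarray] = {}
    s_arch = config.expr_noise_sd * float(
        np.sqrt(config.pair_rho / (1 - config.pair_rho))) \
        if config.pair_rho > 0 else 1.0
    for k, label in enumerate(patterns):
        if k == len(patterns) - 1 and len(patterns) > 2:
            clade_category[label] = "not_expressed"
            clade_archetype[label] = np.zeros(t)
        elif k == len(patterns) - 2 and len(patterns) > 2:
            clade_category[label] = "weak"
            clade_archetype[label] = 0.9 + 0.5 * rng.standard_normal(t)
        else:
            clade_category[label] = "expressed"
            clade_archetype[label] = 3.0 + s_arch * rng.standard_normal(t)

    expr_rows = []
    for chrom in d_chroms:
        for cas in derived[chrom]:
            if not cas.family:
                continue
            cat = clade_category[cas.clade]
            if cat == "not_expressed":
                fpkm = np.zeros(t)
            else:
                v = clade_archetype[cas.clade] + \
                    config.expr_noise_sd * rng.standard_normal(t)
                if cat == "weak":
                    v = np.clip(v, 0.0, 2.3)
                    if v.max() < 1.0:
                        v[int(np.argmax(v))] = 1.5
                else:
                    v = np.clip(v, 0.0, None)
                    if v.max() < 2.65:
                        v[int(np.argmax(v))] = 3.5
                fpkm = np.power(2.0, v) - 1.0
                fpkm[fpkm < 0] = 0.0
            cas.expr_key = cat if cat != "expressed" else f"clade_{cas.clade}"
            expr_rows.append((cas.gene_id, np.round(fpkm, 4)))

    # --- write outputs ---------------------------------------------------
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    genomes = {"progenitorA": prog["A"], "progenitorC": prog["C"],
               "derived": derived}
    truth_rows = []
    family_ids: dict[str, list[str]] = {g: [] for g in genomes}
    clade_of: dict[str, str] = {}
    sisters: dict[str, list[str]] = {}
    derived_family_prots: dict[str, str] = {}
    promoter_seqs: dict[str, str] = {}

    for gname, chroms in genomes.items():
        fasta, gff, _spans = _render_genome(chroms, source="madsfam_sim")
        _write_fasta(fasta, p(f"{gname}.genome.fasta"))
        with open(p(f"{gname}.gff3"), "w") as fh:
            fh.write("\n".join(gff) + "\n")
        for chrom in sorted(chroms):
            for rank, cas in enumerate(chroms[chrom]):
                if cas.family:
                    family_ids[gname].append(cas.gene_id)
                truth_rows.append({
                    "gene": cas.gene_id, "genome": gname,
                    "chromosome": chrom, "rank": rank,
                    "family": int(cas.family),
                    "pattern": cas.pattern_label,
                    "signature": ";".join(
                        f"{off // 3}.{off % 3}"
                        for off in cas.intron_offsets),
                    "origin": cas.origin if gname == "derived" else "",
                    "motifs": ";".join(f"{m}={c}" for m, c in
                                       sorted(cas.motif_counts.items())),
                    "sister_pair": cas.sister_id,
                    "expr_archetype": cas.expr_key
                    if gname == "derived" else "",
                })
                if gname == "derived" and cas.family:
                    clade_of[cas.gene_id] = cas.clade
                    derived_family_prots[cas.gene_id] = _translate(cas.cds)
                    promoter_seqs[cas.gene_id] = cas.promoter
                    if cas.sister_id:
                        sisters.setdefault(cas.sister_id, []).append(
                            cas.gene_id)

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(p("truth.tsv"), sep="\t", index=False)

    _write_fasta({f"ref_{l}": clade_prot[l][:MADS_END] for l in patterns},
                 p("domain_seed.aln.fasta"))
    _write_fasta(derived_family_prots, p("family_proteins.aln.fasta"))
    _write_fasta(promoter_seqs, p("derived.promoters.fasta"))
    _write_fasta({f"ref_{l}": clade_prot[l] for l in patterns},
                 p("reference_proteins.fasta"))

    tissues = [f"T{i + 1:02d}" for i in range(t)]
    expr = pd.DataFrame({g: v for g, v in expr_rows}, index=tissues).T
    expr.index.name = "gene"
    expr.columns = tissues
    expr.to_csv(p("expression.tsv"), sep="\t")

    cfg = dataclasses.asdict(config)
    with open(p("config.json"), "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True, default=list)

    sister_pairs = [(sid, genes[0], genes[1])
                    for sid, genes in sorted(sisters.items())
                    if len(genes) == 2]
    return SyntheticDataset(
        out_dir=out_dir, config=config, paths=paths, truth=truth,
        family_ids=family_ids, clade_of=clade_of, sister_pairs=sister_pairs)
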