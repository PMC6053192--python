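"""Pipeline orchestration: run the analysis stages on one dataset.

Stages run in dependency order — gene models → domain scan → phylogeny →
intron patterns → duplication census → promoters → expression → report —
each writing its own TSV outputs (with a header carrying tool version,
config hash and seed) so that partial reruns are possible.  The
:func:`census_report` helper reproduces the family-census percentage
arithmetic (100·n/d, rounded half-up).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from . import __version__
from . import domain_scan, expression, gene_models, homology_census
from . import intron_patterns, phylogeny, promoter_elements, synthetic_data

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_stage",
           "census_report", "pct", "extract_promoters", "STAGES"]

STAGES = ("simulate", "models", "scan", "phylo", "patterns", "census",
          "promoters", "expression", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "madsfam_out"
    seed: int = 0
    # inputs (filled automatically by the simulate stage)
    derived_fasta: str = ""
    derived_gff3: str = ""
    progenitorA_fasta: str = ""
    progenitorA_gff3: str = ""
    progenitorC_fasta: str = ""
    progenitorC_gff3: str = ""
    seed_msa: str = ""
    family_msa: str = ""
    reference_fasta: str = ""
    expression_tsv: str = ""
    catalog_tsv: str = ""
    # parameters
    sim: synthetic_data.SimConfig = field(
        default_factory=synthetic_data.SimConfig)
    min_occupancy: float = 0.5
    pseudocount: float = 1.0
    domain_threshold: float = 0.6
    domain_coverage: float = 0.8
    kbox_window: tuple[int, int] = synthetic_data.KBOX_WINDOW
    column_tol: int = 2
    allow_variable_first: bool = True
    n_perm: int = 999
    bootstrap_reps: int = 100
    promoter_len: int = 500
    origin: homology_census.OriginParams = field(
        default_factory=homology_census.OriginParams)
    t_off: float = 1.0
    t_weak: float = 5.0
    r_same: float = 0.8
    r_div: float = 0.3
    k_blocks: int = 3

    @classmethod
    def from_json(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("sim", {})
        origin = raw.pop("origin", {})
        cfg = cls(**raw)
        if sim:
            sim["pattern_library"] = {
                k: [tuple(s) for s in v]
                for k, v in sim.get(
                    "pattern_library",
                    synthetic_data.DEFAULT_PATTERN_LIBRARY).items()}
            cfg.sim = synthetic_data.SimConfig(**sim)
        if origin:
            cfg.origin = homology_census.OriginParams(**origin)
        cfg.kbox_window = tuple(cfg.kbox_window)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def header(self) -> list[str]:
        return [f"madsfam v{__version__}", f"seed={self.seed}",
                f"config={self.config_hash()}"]


def pct(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100·n/d rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    q = Decimal(1).scaleb(-decimals)
    val = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def census_report(counts: list[tuple[str, int, int]],
                  decimals: int = 2) -> pd.DataFrame:
    """Percentage table from (name, numerator, denominator) rows."""
    rows = [{"name": n, "numerator": a, "denominator": b,
             "pct": pct(a, b, decimals)} for n, a, b in counts]
    return pd.DataFrame(rows)


def extract_promoters(fasta_path: str, models, promoter_len: int
                      ) -> dict[str, str]:
    """Coding-strand promoter (``promoter_len`` bp upstream) per gene."""
    from pyfaidx import Fasta
    genome = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    out = {}
    for g in models:
        chrom = genome[g.chromosome]
        if g.strand == "+":
            s = max(g.start - promoter_len, 0)
            out[g.id] = str(chrom[s:g.start])
        else:
            e = min(g.end + promoter_len, len(chrom))
            seq = str(chrom[g.end:e])
            out[g.id] = synthetic_data._rc(seq)
    return out


def _write_tsv(df: pd.DataFrame, path: str, cfg: RunConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in cfg.header():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


class PipelineContext(dict):
    """Cross-stage scratch: parsed models, hits, trees, labels."""


def run_stage(cfg: RunConfig, stage: str, ctx: PipelineContext | None = None
              ) -> PipelineContext:
    ctx = ctx if ctx is not None else PipelineContext()
    os.makedirs(cfg.out_dir, exist_ok=True)
    fn = _STAGE_FNS[stage]
    fn(cfg, ctx)
    return ctx


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES
                 ) -> PipelineContext:
    """Run stages in dependency order; raises on the first failing stage."""
    for path_attr in ("derived_fasta", "derived_gff3"):
        p = getattr(cfg, path_attr)
        if p and not os.path.exists(p):
            raise PipelineError(f"input file missing: {path_attr}={p!r}")
    ctx = PipelineContext()
    for stage in STAGES:
        if stage in stages:
            run_stage(cfg, stage, ctx)
    return ctx


# ----------------------------------------------------------------- stages

def _stage_simulate(cfg: RunConfig, ctx: PipelineContext) -> None:
    sim_dir = os.path.join(cfg.out_dir, "sim")
    cfg.sim.seed = cfg.seed
    catalog = (promoter_elements.load_catalog(cfg.catalog_tsv)
               if cfg.catalog_tsv else None)
    ds = synthetic_data.simulate_dataset(cfg.sim, sim_dir, catalog=catalog)
    ctx["dataset"] = ds
    cfg.derived_fasta = ds.paths["derived.genome.fasta"]
    cfg.derived_gff3 = ds.paths["derived.gff3"]
    cfg.progenitorA_fasta = ds.paths["progenitorA.genome.fasta"]
    cfg.progenitorA_gff3 = ds.paths["progenitorA.gff3"]
    cfg.progenitorC_fasta = ds.paths["progenitorC.genome.fasta"]
    cfg.progenitorC_gff3 = ds.paths["progenitorC.gff3"]
    cfg.seed_msa = ds.paths["domain_seed.aln.fasta"]
    cfg.family_msa = ds.paths["family_proteins.aln.fasta"]
    cfg.reference_fasta = ds.paths["reference_proteins.fasta"]
    cfg.expression_tsv = ds.paths["expression.tsv"]
    cfg.kbox_window = ds.kbox_window
    cfg.promoter_len = cfg.sim.promoter_len


def _stage_models(cfg: RunConfig, ctx: PipelineContext) -> None:
    models = gene_models.parse_annotation(cfg.derived_gff3, cfg.derived_fasta)
    ctx["models"] = {m.id: m for m in models}
    gene_models.write_structure_table(
        models, os.path.join(cfg.out_dir, "gene_structures.tsv"),
        header_lines=cfg.header())


def _stage_scan(cfg: RunConfig, ctx: PipelineContext) -> None:
    model = domain_scan.build_pssm(cfg.seed_msa, cfg.min_occupancy,
                                   cfg.pseudocount)
    ctx["pssm"] = model
    hits = []
    for gid, gm in sorted(ctx["models"].items()):
        if gm.protein_seq is None:
            continue
        for h in domain_scan.scan_protein(gm.protein_seq, model,
                                          cfg.domain_threshold, gene_id=gid):
            hits.append(h)
    best: dict[str, domain_scan.DomainHit] = {}
    for h in hits:
        if h.gene_id not in best or h.score > best[h.gene_id].score:
            best[h.gene_id] = h
    ctx["hits"] = best
    domain_scan.write_hits_table(
        hits, os.path.join(cfg.out_dir, "domain_hits.tsv"),
        header_lines=cfg.header())


def _stage_phylo(cfg: RunConfig, ctx: PipelineContext) -> None:
    msa = domain_scan.read_alignment(cfg.family_msa)
    refs = {}
    if cfg.reference_fasta:
        refs = domain_scan.read_alignment(cfg.reference_fasta)
        msa = {**msa, **refs}
    ctx["msa"] = msa
    tree = phylogeny.bootstrap_support(msa, n_reps=cfg.bootstrap_reps,
                                       seed=cfg.seed)
    ctx["tree"] = tree
    with open(os.path.join(cfg.out_dir, "family_tree.nwk"), "w") as fh:
        fh.write(tree.newick(with_support=True) + "\n")
    if refs:
        ref_labels = {r: f"clade_{r.split('_', 1)[1]}" for r in refs}
        ctx["clades"] = phylogeny.assign_clades(tree, ref_labels)
        df = pd.DataFrame(sorted(ctx["clades"].items()),
                          columns=["gene", "clade"])
        _write_tsv(df, os.path.join(cfg.out_dir, "clade_assignments.tsv"),
                   cfg)
    dm = phylogeny.p_distance(msa)
    _write_tsv(dm.to_frame().round(6),
               os.path.join(cfg.out_dir, "p_distance.tsv"), cfg, index=True)


def _stage_patterns(cfg: RunConfig, ctx: PipelineContext) -> None:
    if "msa" not in ctx:
        ctx["msa"] = domain_scan.read_alignment(cfg.family_msa)
    msa = {k: v for k, v in ctx["msa"].items() if k in ctx["models"]}
    window = tuple(cfg.kbox_window)
    sigs = []
    exon1_rows = []
    for gid in sorted(msa):
        gm = ctx["models"][gid]
        sites = gene_models.compute_intron_sites(gm)
        projected = [domain_scan.project_site_to_alignment(
            msa[gid], s.codon_index, s.phase) for s in sites]
        sigs.append(intron_patterns.make_signature(gid, projected, window))
        if gid in ctx["hits"]:
            in_first, ph = intron_patterns.mads_exon1_check(gm,
                                                            ctx["hits"][gid])
            exon1_rows.append({"gene": gid, "domain_in_first_exon": in_first,
                               "first_downstream_phase": ph})
    ctx["signatures"] = {s.gene_id: s for s in sigs}
    ctx["exon1"] = exon1_rows
    classes = intron_patterns.cluster_signatures(
        sigs, cfg.column_tol, cfg.allow_variable_first)
    ctx["pattern_classes"] = classes
    label_of = {g: c.label for c in classes for g in c.members}
    ctx["pattern_labels"] = label_of
    _write_tsv(pd.DataFrame(
        [{"gene": s.gene_id,
          "signature": ";".join(f"{c}.{p}" for c, p in s.sites),
          "label": label_of.get(s.gene_id, "")} for s in sigs]),
        os.path.join(cfg.out_dir, "pattern_signatures.tsv"), cfg)
    _write_tsv(pd.DataFrame(
        [{"label": c.label, "size": c.size,
          "frequency": round(c.frequency, 4),
          "consensus": ";".join(f"{a}.{b}" for a, b in c.consensus)}
         for c in classes]),
        os.path.join(cfg.out_dir, "pattern_classes.tsv"), cfg)
    _write_tsv(pd.DataFrame(exon1_rows),
               os.path.join(cfg.out_dir, "exon1_rule.tsv"), cfg)
    if "clades" in ctx:
        clades: dict[str, set] = {}
        for g, c in ctx["clades"].items():
            if c != "unassigned" and g in label_of:
                clades.setdefault(c, set()).add(g)
        if clades:
            purity, p = intron_patterns.clade_pattern_concordance(
                label_of, clades, n_perm=cfg.n_perm, seed=cfg.seed)
            ctx["concordance"] = (purity, p)
            _write_tsv(pd.DataFrame([{"purity": round(purity, 4),
                                      "p_value": p,
                                      "n_perm": cfg.n_perm}]),
                       os.path.join(cfg.out_dir, "concordance.tsv"), cfg)


def _subgenome_of(chrom: str) -> str:
    return chrom[0].upper()


def _ranks(models: dict) -> dict[str, tuple[str, int]]:
    by_chrom: dict[str, list] = {}
    for m in models.values():
        by_chrom.setdefault(m.chromosome, []).append(m)
    out = {}
    for chrom, ms in by_chrom.items():
        for rank, m in enumerate(sorted(ms, key=lambda x: x.start)):
            out[m.id] = (chrom, rank)
    return out


def _stage_census(cfg: RunConfig, ctx: PipelineContext) -> None:
    derived = ctx["models"]
    progA = {m.id: m for m in gene_models.parse_annotation(
        cfg.progenitorA_gff3, cfg.progenitorA_fasta)}
    progC = {m.id: m for m in gene_models.parse_annotation(
        cfg.progenitorC_gff3, cfg.progenitorC_fasta)}

    def prots(models):
        return {gid: m.protein_seq for gid, m in models.items()
                if m.protein_seq}

    pd_, pa, pc = prots(derived), prots(progA), prots(progC)
    ranks_d, ranks_a, ranks_c = _ranks(derived), _ranks(progA), _ranks(progC)

    scoresA = homology_census.pairwise_identity_table(pd_, pa)
    scoresC = homology_census.pairwise_identity_table(pd_, pc)
    scoresD = homology_census.pairwise_identity_table(pd_, pd_)
    # orthology anchors are searched within the expected subgenome: a
    # homologous-exchange copy on the other subgenome must not hijack the
    # progenitor gene's best hit away from its true homoeolog
    pd_a = {g: s for g, s in pd_.items()
            if _subgenome_of(derived[g].chromosome) == "A"}
    pd_c = {g: s for g, s in pd_.items()
            if _subgenome_of(derived[g].chromosome) == "C"}
    rbhA = homology_census.reciprocal_best_hits(pd_a or pd_, pa,
                                                scores=scoresA)
    rbhC = homology_census.reciprocal_best_hits(pd_c or pd_, pc,
                                                scores=scoresC)
    rbhD = [a for a in homology_census.reciprocal_best_hits(
        pd_, pd_, scores=scoresD, exclude_self=True)
        if a.x_gene < a.y_gene]

    op = cfg.origin
    blocksA = homology_census.chain_collinear(rbhA, ranks_d, ranks_a,
                                              op.max_gap, op.min_block)
    blocksC = homology_census.chain_collinear(rbhC, ranks_d, ranks_c,
                                              op.max_gap, op.min_block)
    blocksD = homology_census.chain_collinear(rbhD, ranks_d, ranks_d,
                                              op.max_gap, op.min_block)

    best_identity = {}
    for g in pd_:
        ia = max((scoresA[(g, y)][1] for y in pa), default=0.0)
        ic = max((scoresC[(g, y)][1] for y in pc), default=0.0)
        best_identity[g] = {"A": ia, "C": ic}

    family_ids = {g for g in ctx["hits"] if g in pd_}

    def pair_identity(g, h):
        key = (g, h) if (g, h) in scoresD else (h, g)
        return scoresD[key][1]

    labels = homology_census.classify_origins(
        ranks_d, family_ids, _subgenome_of, blocksA, blocksC, blocksD,
        best_identity, pair_identity, op)
    ctx["origins"] = {l.gene_id: l for l in labels}

    promoters = extract_promoters(cfg.derived_fasta,
                                  [derived[g] for g in sorted(family_ids)],
                                  cfg.promoter_len)
    ctx["promoters"] = promoters
    fam_prots = {g: pd_[g] for g in family_ids}
    dom_ranges = {g: (ctx["hits"][g].start, ctx["hits"][g].end)
                  for g in family_ids}
    pairs = homology_census.sister_pairs(fam_prots, dom_ranges, promoters)
    ctx["sister_pairs"] = pairs

    chroms = sorted({m.chromosome for m in derived.values()})
    counts, means = homology_census.chromosome_census(
        {g: derived[g].chromosome for g in family_ids}, chroms,
        _subgenome_of)
    ctx["chrom_census"] = (counts, means)

    _write_tsv(pd.DataFrame(
        [{"x_gene": a.x_gene, "y_gene": a.y_gene,
          "identity": round(a.identity, 2)} for a in rbhA + rbhC + rbhD]),
        os.path.join(cfg.out_dir, "anchors.tsv"), cfg)
    _write_tsv(pd.DataFrame(
        [{"x_chrom": b.x_chrom, "y_chrom": b.y_chrom,
          "orientation": b.orientation, "n_anchors": b.n_anchors,
          "score": round(b.score, 2)}
         for b in blocksA + blocksC + blocksD]),
        os.path.join(cfg.out_dir, "synteny_blocks.tsv"), cfg)
    _write_tsv(pd.DataFrame(
        [{"gene": l.gene_id, "origin": l.label,
          "evidence": json.dumps(l.evidence, sort_keys=True)}
         for l in labels]),
        os.path.join(cfg.out_dir, "origin_labels.tsv"), cfg)
    _write_tsv(pd.DataFrame(pairs),
               os.path.join(cfg.out_dir, "sister_pairs.tsv"), cfg)


def _stage_promoters(cfg: RunConfig, ctx: PipelineContext) -> None:
    catalog = (promoter_elements.load_catalog(cfg.catalog_tsv)
               if cfg.catalog_tsv else promoter_elements.default_catalog())
    hits = []
    for gid in sorted(ctx.get("promoters", {})):
        hits.extend(promoter_elements.scan_promoter(
            ctx["promoters"][gid], catalog, gene_id=gid))
    ctx["motif_hits"] = hits
    classes = {gid: "type_II" for gid in ctx.get("promoters", {})}
    summary = promoter_elements.summarize_groups(hits, classes, catalog)
    ctx["motif_summary"] = summary
    _write_tsv(pd.DataFrame(
        [{"gene": h.gene_id, "motif": h.motif_id, "offset": h.offset,
          "strand": h.strand, "sequence": h.matched_seq} for h in hits]),
        os.path.join(cfg.out_dir, "motif_hits.tsv"), cfg)
    _write_tsv(summary, os.path.join(cfg.out_dir, "motif_summary.tsv"), cfg,
               index=True)


def _stage_expression(cfg: RunConfig, ctx: PipelineContext) -> None:
    if not cfg.expression_tsv:
        return
    fpkm = expression.read_fpkm(cfg.expression_tsv)
    cats, table = expression.categorize(fpkm, cfg.t_off, cfg.t_weak)
    ctx["categories"] = cats
    ctx["category_table"] = table
    expressed = fpkm.loc[cats == "expressed"]
    if len(expressed) >= cfg.k_blocks:
        blocks, order = expression.cluster_expressed(
            expression.log2_matrix(fpkm.loc[expressed.index]), cfg.k_blocks)
        ctx["blocks"] = blocks
        _write_tsv(blocks.to_frame(),
                   os.path.join(cfg.out_dir, "expression_blocks.tsv"), cfg,
                   index=True)
        _write_tsv(pd.DataFrame({"gene": order}),
                   os.path.join(cfg.out_dir, "expression_order.tsv"), cfg)
    pair_triplets = [(str(p["pair_id"]), p["gene1"], p["gene2"])
                     for p in ctx.get("sister_pairs", [])
                     if p["gene1"] in fpkm.index and p["gene2"] in fpkm.index]
    verdicts = expression.pair_conservation(
        pair_triplets, fpkm, cfg.t_off, cfg.t_weak, cfg.r_same, cfg.r_div)
    ctx["pair_verdicts"] = verdicts
    _write_tsv(pd.DataFrame(
        [{"pair": v.pair_id, "gene1": v.gene1, "gene2": v.gene2,
          "r": None if v.r is None else round(v.r, 4),
          "verdict": v.verdict} for v in verdicts]),
        os.path.join(cfg.out_dir, "pair_conservation.tsv"), cfg)
    _write_tsv(cats.to_frame(),
               os.path.join(cfg.out_dir, "expression_categories.tsv"), cfg,
               index=True)
    _write_tsv(table,
               os.path.join(cfg.out_dir, "expression_percentages.tsv"), cfg)


def _stage_report(cfg: RunConfig, ctx: PipelineContext) -> None:
    rows: list[tuple[str, int, int]] = []
    if "origins" in ctx:
        labels = [l.label for l in ctx["origins"].values()]
        total = len(labels)
        for lab in homology_census.ORIGIN_LABELS:
            rows.append((f"origin_{lab}", labels.count(lab), total))
        inherited = sum(labels.count(l) for l in
                        ("inherited_A", "inherited_C"))
        rows.append(("origin_inherited_total", inherited, total))
    if "categories" in ctx:
        cats = ctx["categories"]
        for cat in expression.CATEGORIES:
            rows.append((f"expression_{cat}", int((cats == cat).sum()),
                         len(cats)))
    report = census_report(rows) if rows else pd.DataFrame()
    ctx["report"] = report
    _write_tsv(report, os.path.join(cfg.out_dir, "census_report.tsv"), cfg)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "models": _stage_models,
    "scan": _stage_scan,
    "phylo": _stage_phylo,
    "patterns": _stage_patterns,
    "census": _stage_census,
    "promoters": _stage_promoters,
    "expression": _stage_expression,
    "report": _stage_report,
}
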