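"""Duplication-origin census of a gene family in an allotetraploid.

Each family gene of the derived genome is assigned one origin label:

* ``inherited_A`` / ``inherited_C`` — syntenic with the expected progenitor
  subgenome (retained through allopolyploidy),
* ``tandem`` — near-adjacent, highly similar pair on one chromosome,
* ``segmental`` — member of an intra-genome collinear block that is not a
  homoeologous (A-vs-C subgenome) relationship,
* ``HE`` — homologous exchange: a syntenic gene whose sequence is closer to
  the *opposite* progenitor than to its own, in a run of consecutive such
  genes (a chromosomal segment replaced by its homoeologous copy),
* ``unassigned`` otherwise.

Synteny is derived from reciprocal-best-hit anchors chained into collinear
blocks by dynamic programming.  Sequence identity comes from global
Needleman–Wunsch alignment (BLOSUM62, affine gaps, via Biopython).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AnchorPair",
    "SyntenyBlock",
    "OriginLabel",
    "OriginParams",
    "global_identity",
    "reciprocal_best_hits",
    "chain_collinear",
    "best_chain",
    "classify_origins",
    "sister_pairs",
    "chromosome_census",
]

ORIGIN_LABELS = ("inherited_A", "inherited_C", "segmental", "tandem", "HE",
                 "unassigned")


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    return a


def _nucleotide_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 5.0
    a.mismatch_score = -4.0
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    return a


_PROT = None
_NUC = None


def global_identity(a: str, b: str, kind: str = "protein"
                    ) -> tuple[float, float]:
    """Percent identity and score of the global alignment of two sequences.

    Identity is matches / alignment length (gap columns included) × 100.
    """
    global _PROT, _NUC
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if kind == "protein":
        if _PROT is None:
            _PROT = _protein_aligner()
        aligner = _PROT
        a = a.replace("*", "X")
        b = b.replace("*", "X")
    else:
        if _NUC is None:
            _NUC = _nucleotide_aligner()
        aligner = _NUC
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    identity = 100.0 * counts.identities / aln.shape[1]
    return identity, float(aln.score)


@dataclass
class AnchorPair:
    x_gene: str
    y_gene: str
    score: float
    identity: float
    reciprocal: bool = True


@dataclass
class SyntenyBlock:
    x_chrom: str
    y_chrom: str
    orientation: str  # "same" | "inverted"
    anchors: list[tuple[str, str, int, int]]  # (x_gene, y_gene, x_rank, y_rank)
    score: float = 0.0

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def x_genes(self) -> set:
        return {a[0] for a in self.anchors}

    def y_genes(self) -> set:
        return {a[1] for a in self.anchors}


@dataclass
class OriginLabel:
    gene_id: str
    label: str
    evidence: dict = field(default_factory=dict)


@dataclass
class OriginParams:
    tandem_rank_gap: int = 2
    tandem_min_id: float = 70.0
    max_gap: int = 25
    min_block: int = 4
    he_margin: float = 2.0
    he_min_genes: int = 2


def pairwise_identity_table(prots_x: dict[str, str], prots_y: dict[str, str],
                            kind: str = "protein"
                            ) -> dict[tuple[str, str], tuple[float, float]]:
    """(score, identity) of the global alignment for every cross pair."""
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for x in sorted(prots_x):
        for y in sorted(prots_y):
            ident, score = global_identity(prots_x[x], prots_y[y], kind)
            out[(x, y)] = (score, ident)
    return out


def reciprocal_best_hits(prots_x: dict[str, str], prots_y: dict[str, str],
                         kind: str = "protein",
                         scores: dict | None = None,
                         exclude_self: bool = False) -> list[AnchorPair]:
    """Reciprocal best hits between two protein sets.

    Best hits maximise alignment score; ties are broken by higher identity,
    then by lexicographically smaller partner id.  ``scores`` may carry a
    precomputed :func:`pairwise_identity_table`; ``exclude_self`` skips the
    trivial self hit when the two sets share ids (intra-genome search).
    """
    if not prots_x or not prots_y:
        raise ValueError("both genomes need at least one protein")
    xs, ys = sorted(prots_x), sorted(prots_y)
    if scores is None:
        scores = pairwise_identity_table(prots_x, prots_y, kind)

    def best(partner_ids, fixed):
        cand = [p for p in partner_ids if not (exclude_self and p == fixed)]
        key = lambda p: (-scores[(fixed, p) if (fixed, p) in scores
                                 else (p, fixed)][0],
                         -scores[(fixed, p) if (fixed, p) in scores
                                 else (p, fixed)][1], p)
        return min(cand, key=key)

    best_y = {x: best(ys, x) for x in xs}
    best_x = {y: best(xs, y) for y in ys}
    out = []
    for x in xs:
        y = best_y[x]
        if best_x[y] == x and not (exclude_self and x == y):
            sc, ident = scores[(x, y)]
            out.append(AnchorPair(x_gene=x, y_gene=y, score=sc,
                                  identity=ident))
    return out


def best_chain(anchors: list[tuple[int, int]], max_gap: int = 25
               ) -> tuple[float, list[int]]:
    """Maximum-score collinear chain over (x_rank, y_rank) anchors.

    A chain is strictly increasing in both ranks with consecutive rank
    differences <= ``max_gap`` on both axes; its score is
    ``n_anchors - 0.1 * skipped ranks`` where skipped ranks are
    ``(dx - 1) + (dy - 1)`` summed over consecutive anchor pairs.  Returns
    the score and the chained anchor indices (into ``anchors``).  Only the
    "same" orientation is considered; callers handle inversion by negating
    y ranks.
    """
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1]))
    dp = [1.0] * n
    back = [-1] * n
    for oi, i in enumerate(order):
        xi, yi = anchors[i]
        for j in (order[k] for k in range(oi)):
            xj, yj = anchors[j]
            dx, dy = xi - xj, yi - yj
            if dx <= 0 or dy <= 0 or dx > max_gap or dy > max_gap:
                continue
            cand = dp[j] + 1.0 - 0.1 * ((dx - 1) + (dy - 1))
            if cand > dp[i] + 1e-12:
                dp[i] = cand
                back[i] = j
    if n == 0:
        return 0.0, []
    besti = max(range(n), key=lambda i: (dp[i],
                                         -anchors[i][0], -anchors[i][1]))
    chain = []
    i = besti
    while i != -1:
        chain.append(i)
        i = back[i]
    return dp[besti], chain[::-1]


def chain_collinear(anchors: list[AnchorPair],
                    ranks_x: dict[str, tuple[str, int]],
                    ranks_y: dict[str, tuple[str, int]],
                    max_gap: int = 25, min_block: int = 4
                    ) -> list[SyntenyBlock]:
    """Chain anchors into collinear synteny blocks.

    ``ranks_x``/``ranks_y`` map gene id → (chromosome, integer rank on that
    chromosome).  Within each chromosome pair, maximum-score chains are
    extracted iteratively (both orientations searched); blocks with fewer
    than ``min_block`` anchors are dropped.  The result is independent of
    anchor input order.
    """
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        cx, _ = ranks_x[a.x_gene]
        cy, _ = ranks_y[a.y_gene]
        groups.setdefault((cx, cy), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (cx, cy), group in sorted(groups.items()):
        group = sorted(group, key=lambda a: (ranks_x[a.x_gene][1],
                                             ranks_y[a.y_gene][1]))
        remaining = list(range(len(group)))
        while remaining:
            pts = [(ranks_x[group[i].x_gene][1], ranks_y[group[i].y_gene][1])
                   for i in remaining]
            s_same, c_same = best_chain(pts, max_gap)
            s_inv, c_inv = best_chain([(x, -y) for x, y in pts], max_gap)
            if s_same >= s_inv:
                score, chain, orient = s_same, c_same, "same"
            else:
                score, chain, orient = s_inv, c_inv, "inverted"
            if len(chain) < min_block:
                break
            idx = [remaining[k] for k in chain]
            blocks.append(SyntenyBlock(
                x_chrom=cx, y_chrom=cy, orientation=orient,
                anchors=[(group[i].x_gene, group[i].y_gene,
                          ranks_x[group[i].x_gene][1],
                          ranks_y[group[i].y_gene][1]) for i in idx],
                score=score))
            taken = set(idx)
            remaining = [i for i in remaining if i not in taken]
    return blocks


def classify_origins(derived_ranks: dict[str, tuple[str, int]],
                     family_ids: set,
                     subgenome_of,
                     blocks_dA: list[SyntenyBlock],
                     blocks_dC: list[SyntenyBlock],
                     blocks_dd: list[SyntenyBlock],
                     best_identity: dict[str, dict[str, float]],
                     pair_identity,
                     params: OriginParams = OriginParams()
                     ) -> list[OriginLabel]:
    """Assign one origin label to every family gene of the derived genome.

    ``derived_ranks`` maps every derived gene → (chromosome, rank);
    ``subgenome_of`` maps a chromosome name to ``"A"`` or ``"C"``;
    ``best_identity`` maps gene → {"A": identity to best progenitor-A hit,
    "C": ...} (0 when absent); ``pair_identity(g, h)`` returns percent
    identity between two derived genes (used for the tandem rule).

    Precedence: tandem, then HE (a syntenic gene whose identity favours the
    opposite progenitor by >= ``he_margin`` inside a run of >=
    ``he_min_genes`` consecutive such genes), then inherited, then
    segmental, then unassigned.
    """
    for g in family_ids:
        if g not in derived_ranks:
            raise ValueError(f"family gene {g} absent from derived genome")

    in_a = set().union(*(b.x_genes() for b in blocks_dA)) if blocks_dA else set()
    in_c = set().union(*(b.x_genes() for b in blocks_dC)) if blocks_dC else set()

    # segmental candidates: members of intra-genome blocks whose two
    # chromosomes are in the same subgenome (not homoeologous A<->C blocks)
    segmental = set()
    for b in blocks_dd:
        if subgenome_of(b.x_chrom) == subgenome_of(b.y_chrom):
            segmental |= b.x_genes() | b.y_genes()

    # HE-like flag over all derived genes, runs per chromosome
    he_like = {}
    for g, ident in best_identity.items():
        own = subgenome_of(derived_ranks[g][0])
        opp = "C" if own == "A" else "A"
        he_like[g] = (ident.get(opp, 0.0) - ident.get(own, 0.0)
                      >= params.he_margin)
    by_chrom: dict[str, list[str]] = {}
    for g, (chrom, rank) in derived_ranks.items():
        by_chrom.setdefault(chrom, []).append(g)
    # an exchanged segment is a run of consecutive HE-like genes anchored to
    # a progenitor by at least one of its members (the family gene itself may
    # lose its anchor to paralogs once its content is replaced)
    he_genes = set()
    syntenic_any = in_a | in_c
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: derived_ranks[g][1])
        run: list[str] = []
        for g in genes + [None]:
            if g is not None and he_like.get(g, False):
                run.append(g)
            else:
                if (len(run) >= params.he_min_genes
                        and any(r in syntenic_any for r in run)):
                    he_genes.update(run)
                run = []

    fam_by_chrom: dict[str, list[str]] = {}
    for g in family_ids:
        fam_by_chrom.setdefault(derived_ranks[g][0], []).append(g)

    out: list[OriginLabel] = []
    for g in sorted(family_ids):
        chrom, rank = derived_ranks[g]
        own = subgenome_of(chrom)
        evidence: dict = {"chromosome": chrom, "rank": rank}
        # 1. tandem
        partner = None
        for h in fam_by_chrom[chrom]:
            if h == g:
                continue
            if abs(derived_ranks[h][1] - rank) <= params.tandem_rank_gap:
                ident = pair_identity(g, h)
                if ident >= params.tandem_min_id:
                    partner = (h, ident)
                    break
        if partner is not None:
            evidence.update(partner_gene=partner[0], identity=partner[1])
            out.append(OriginLabel(g, "tandem", evidence))
            continue
        syntenic = g in in_a or g in in_c
        # 2. HE (a gene inside an anchored exchanged run)
        if g in he_genes:
            evidence.update(identity_A=best_identity[g].get("A", 0.0),
                            identity_C=best_identity[g].get("C", 0.0))
            out.append(OriginLabel(g, "HE", evidence))
            continue
        # 3. inherited on the expected subgenome
        if (own == "A" and g in in_a) or (own == "C" and g in in_c):
            out.append(OriginLabel(g, f"inherited_{own}", evidence))
            continue
        # 4. segmental
        if g in segmental:
            out.append(OriginLabel(g, "segmental", evidence))
            continue
        out.append(OriginLabel(g, "unassigned", evidence))
    return out


def sister_pairs(proteins: dict[str, str],
                 domain_ranges: dict[str, tuple[int, int]],
                 promoters: dict[str, str] | None = None,
                 full_min_id: float = 70.0,
                 domain_min_id: float = 90.0,
                 max_group: int = 4) -> list[dict]:
    """Recent-duplicate (sister) pairs among family proteins.

    Pairs require domain identity >= ``domain_min_id`` and full-protein
    identity >= ``full_min_id``; matching is greedy by descending full
    identity, allowing mutual groups of up to ``max_group`` genes.  Promoter
    identity (nucleotide global alignment) is reported when promoters are
    given.
    """
    ids = sorted(g for g in proteins if g in domain_ranges)
    edges = []
    for i, g in enumerate(ids):
        for h in ids[i + 1:]:
            full_id, _ = global_identity(proteins[g], proteins[h])
            if full_id < full_min_id:
                continue
            ds, de = domain_ranges[g]
            hs, he = domain_ranges[h]
            dom_id, _ = global_identity(proteins[g][ds:de],
                                        proteins[h][hs:he])
            if dom_id >= domain_min_id:
                edges.append((full_id, dom_id, g, h))
    edges.sort(key=lambda e: (-e[0], e[2], e[3]))
    group_of: dict[str, int] = {}
    groups: dict[int, set] = {}
    nxt = 0
    out = []
    for full_id, dom_id, g, h in edges:
        gg, gh = group_of.get(g), group_of.get(h)
        if gg is not None and gh is not None:
            continue  # both already matched
        if gg is None and gh is None:
            gid = nxt
            nxt += 1
            groups[gid] = {g, h}
            group_of[g] = group_of[h] = gid
        else:
            gid = gg if gg is not None else gh
            if len(groups[gid]) >= max_group:
                continue
            newcomer = g if gg is None else h
            groups[gid].add(newcomer)
            group_of[newcomer] = gid
        rec = {"pair_id": gid, "gene1": g, "gene2": h,
               "domain_identity": round(dom_id, 2),
               "full_identity": round(full_id, 2)}
        if promoters and g in promoters and h in promoters:
            prom_id, _ = global_identity(promoters[g], promoters[h],
                                         kind="nucleotide")
            rec["promoter_identity"] = round(prom_id, 2)
        out.append(rec)
    return out


def chromosome_census(gene_chroms: dict[str, str], chromosomes: list[str],
                      subgenome_of) -> tuple[dict[str, int], dict[str, float]]:
    """Per-chromosome family-gene counts and per-subgenome means (1 decimal)."""
    counts = {c: 0 for c in chromosomes}
    for g, c in gene_chroms.items():
        if c in counts:
            counts[c] += 1
    sub: dict[str, list[int]] = {}
    for c in chromosomes:
        sub.setdefault(subgenome_of(c), []).append(counts[c])
    means = {s: round(float(np.mean(v)), 1) for s, v in sorted(sub.items())}
    return counts, means
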