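# Methods

## Scope and model

`madsfam` analyses the evolution of a transcription-factor gene family in an
allotetraploid genome along five axes: (1) intron-insertion fingerprints of a
conserved protein domain, (2) distance phylogeny of the family, (3) the
duplication origin of every family gene (progenitor inheritance, tandem and
segmental duplication, homologous exchange between subgenomes), (4) promoter
cis-element content, and (5) expression conservation between recent
duplicates.  Every component runs on standard inputs (genome FASTA, GFF3,
aligned FASTA, FPKM TSV, motif TSV) and on the bundled synthetic
allotetraploid generator, which carries a complete ground truth.

## Intron sites and pattern fingerprints

An intron site is the pair (CDS offset, phase) at an exon junction; phase is
the offset modulo 3 (0 = between codons).  This is the standard intron-phase
convention and is distinct from the GFF3 CDS `phase` column, which is
validated on input but not used.  Genes whose CDS length is not a multiple
of 3 are kept and flagged `partial_orf`; they are excluded only from
operations requiring full proteins.  When a locus has several mRNAs the
longest-CDS isoform is used.

Sites are projected into alignment columns through each gene's row of the
family protein alignment, then restricted to a configured domain window (the
K-box region).  Two signatures belong to the same pattern when their phase
sequences are identical and paired columns differ by at most `column_tol`
(default 2 columns); with `allow_variable_first` (default on) the leading
site may differ freely or be absent, since in real families the first intron
of the region wanders while the downstream scaffold stays put.  Patterns are
connected components under this relation (single linkage), labelled A, B,
C, … by descending size (ties by smaller first consensus column).  The class
consensus is the per-site median column and modal phase over members of the
class's modal signature length.  Frequencies are reported over classified
(non-empty-signature) genes, and the denominator is printed alongside.

Clade–pattern concordance is scored as purity — the mean over clades of the
largest within-clade pattern share — with a label-permutation p-value
`(1 + #{perm >= obs}) / (n_perm + 1)`.

## Domain detection

A log-odds PSSM replaces database screening: columns with non-gap occupancy
≥ `min_occupancy` (0.5) are retained and scored
`log2(((count + pc) / (n + 20 pc)) / (1/20))` with pseudocount `pc = 1` and a
uniform 1/20 background.  Hits require a normalised score (score / maximum
attainable score) ≥ 0.6 by default and are selected greedily,
best-score-first, non-overlapping, ties to the leftmost start.  All four
knobs are config-exposed; there is no E-value calibration, and the model has
no insert/delete states.

## Phylogeny

Distances are p-distances with pairwise deletion (per-pair comparable
sites); pairs with no comparable site are flagged and abort
neighbor joining with an instruction to rerun under complete deletion rather
than being imputed.  NJ follows Saitou–Nei with Q-matrix ties broken by the
lexicographically smallest pair of subtree labels, making the topology
input-order invariant.  Negative branch-length estimates are clamped to zero
for output with the raw value retained.  Bootstrap resamples alignment
columns with replacement; supports are the percentage of replicate trees
containing each internal bipartition of the full-data tree, mapped back onto
that tree (no majority-rule consensus).  Clades are assigned from reference
taxa: a gene takes the subfamily of the smallest clade containing it and at
least one reference, provided all references inside agree; otherwise it is
unassigned.

## Duplication-origin census

Anchors are reciprocal best hits under global Needleman–Wunsch alignment
(BLOSUM62, gap open −10, extend −0.5; identity = matches / alignment
length).  Derived↔progenitor anchors are searched within the expected
subgenome so that a homologous-exchange copy on the other subgenome cannot
hijack a progenitor gene's best hit away from its true homoeolog.  Anchors
are chained per chromosome pair by dynamic programming: chains are strictly
monotone in both rank orders (both orientations searched), consecutive rank
gaps ≤ `max_gap` (25), score = anchors − 0.1 × skipped ranks, blocks with
< `min_block` (4) anchors dropped; chains are extracted iteratively by
descending score.

Labels are assigned with precedence: **tandem** (same chromosome, rank
difference ≤ 2, identity ≥ 70%), then **HE** — a run of ≥ `he_min_genes` (2)
consecutive genes whose identity to the opposite progenitor exceeds identity
to their own progenitor by ≥ `he_margin` (2 points), provided at least one
run member is block-anchored to a progenitor (the family gene itself may
lose its own anchor to clade paralogs once its content is replaced) — then
**inherited_A/C** (member of a derived↔progenitor block on the expected
subgenome), then **segmental** (member of an intra-genome block whose two
chromosomes lie in the same subgenome, i.e. not a homoeologous A↔C
relationship), else **unassigned**.  Tandem precedes inheritance so local
duplications are not absorbed into large syntenic blocks.

Sister pairs require domain identity ≥ 90% and full-protein identity ≥ 70%
(greedy best-partner matching, mutual groups of up to 4 allowed); promoter
identity is computed by the same global aligner on 500 bp (simulated) or
user-configured upstream sequence (2,000 bp is a common choice for real
genomes).

## Promoter scanning and expression

Motif matching is exact IUPAC matching on both strands, implemented as a
direct character-class scan (the test suite compares it against an
independent regular-expression oracle); reverse-strand hits are reported at
forward coordinates.  All overlapping matches are reported, but summaries
count genes, not hits, so they are robust to that choice.  The bundled
catalog holds literature-style IUPAC renderings of named plant elements
(G-box, GT1, Box4, MBS, HSE, TC-rich, CArG, TCA, GARE, CGTCA/TGACG, ABRE)
and is explicitly replaceable — exact database patterns are versioned and
user-supplied.

Expression categories use `t_off = 1` FPKM (silent: every tissue below) and
`t_weak = 5` FPKM (weak: expressed somewhere but never reaching it); both
are package choices, since "weak expression" has no universal boundary, and
downstream shares other than the silent fraction are threshold-sensitive.
Expressed genes are clustered by average linkage under correlation distance
(1 − Pearson r of log2(FPKM+1)), cut into `k_blocks = 3` groups, with the
dendrogram leaf order exported for heatmaps.  Pair conservation: `same` if
r ≥ 0.8 and categories agree, `divergent` if r < 0.3 or exactly one member
is silent, `similar` otherwise; constant profiles (undefined r) fall back to
category comparison and are logged.

## Synthetic allotetraploid generator

The generator is first-class, tested code and defines the study conditions:

* **Genome**: two progenitors ("A", "C") of 3 chromosomes × 20 genes evolve
  independently from a common ancestor by i.i.d. per-site substitution at
  `divergence` (default 0.05); the derived genome copies both progenitors
  with one further round at 0.2 × `divergence`, reflecting that
  allopolyploidy is recent relative to progenitor divergence.  Substitutions
  creating in-frame stops are reverted; there are no indels, so open reading
  frames and alignment columns stay intact.
* **Family genes** (21 per progenitor, 7 clades): a 58-aa DNA-binding
  domain in exon 1 (mutating at a tenth of the background rate — purifying
  selection), a phase-2 intron immediately after the domain, and a K-box
  region realising one of 7 planted intron patterns (the first site jittered
  by ±3 codons within a clade; one pattern lacks the second site, one the
  fifth).  Introns are 90 bp with canonical GT…AG termini.
* **Events** (defaults 2 each): tandem — a copy inserted at the adjacent
  rank; segmental — a 5-gene window copied to another chromosome of the same
  subgenome; HE — a 3-gene window replaced by its homoeologous progenitor
  copies.  Event windows never overlap; family loci are spaced 3 ranks apart
  so the tandem rule cannot fire between unrelated neighbours.
* **Promoters**: 500 bp upstream on the coding strand.  Family promoters
  carry one planted instance each of six catalog motifs at non-overlapping
  offsets; the background is redrawn (rejection sampling) until no unplanted
  catalog motif matches, so gene-level presence equals the plan exactly.
* **Expression**: one log2 archetype per clade over 50 tissues; a gene's
  profile is archetype + N(0, 0.4) noise, with the archetype spread scaled
  so sister profiles correlate at `pair_rho` (0.9).  One clade is silent
  (exact zeros), one weak, the rest expressed, with small deterministic
  guards keeping realised categories equal to planted ones.

Fixed seed ⇒ byte-identical outputs.  What the generator does **not**
emulate: indels and alignment uncertainty, rate heterogeneity and codon
structure beyond stop avoidance, transposable elements and intergenic
realism, promoter homology between duplicates (event and homoeolog promoters
are regenerated, so synthetic promoter identities sit near the random
baseline), dosage effects in expression.  Passing tests therefore show the
pipeline's rules are implemented correctly and recoverable under clean
conditions, not that they are robust to alignment error or assembly
artefacts in real genomes.

## Numerical and reporting choices

Census percentages are 100·n/d rounded half-up to 2 decimals (1 decimal for
per-chromosome means); every output TSV carries the tool version, a config
hash and the seed.  Problem sizes used by the test suite and the acceptance
script — a ~130-gene derived genome for the full pipeline, 200 family genes
for pattern recovery, ≤ 8 taxa for exact NJ checks, ≤ 10 anchors for the
exhaustive chaining oracle, 1,000 random promoter/catalog instances for the
scanning oracle — were chosen so each check runs in seconds while the
relevant combinatorics (brute-force enumeration) stay exact.  Bootstrap
default in the pipeline config is 100 replicates; 1,000 is typical for
publication-grade support values.

## Known limitations

* The pattern letters are size-ranked, not homology-matched to any published
  A–G scheme; mapping to published labels is a user-supplied table.
* The PSSM has no gap states, so domains with indels relative to the seed
  may score below threshold.
* HE detection is identity-margin-based; where curated exchange blocks
  exist, supplying them directly (interval input) is preferable.
* p-distances may violate the triangle inequality; no correction model is
  offered by design.
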