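# madsfam

Gene-family evolution analysis for allopolyploid genomes: intron-phase
fingerprints of a conserved domain, distance phylogeny with bootstrap,
duplication-origin classification, promoter cis-element scanning and
expression-conservation analysis — plus a synthetic allotetraploid genome
generator with full ground truth for end-to-end validation.

## Who it is for

Comparative genomicists studying large transcription-factor families (the
motivating case is the MIKC-type MADS-box family in an allotetraploid crop
derived from two progenitor genomes).  In such families the intron
insertion sites and splicing phases inside the K-box dimerization domain are
conserved within phylogenetic clades and act as an independent fingerprint
of common descent; at the genome scale, family expansion decomposes into
progenitor inheritance, tandem and segmental duplication, and homologous
exchange (HE) between subgenomes.

## The core quantities

* **Intron site**: (CDS offset, phase) at each exon junction, with
  phase = offset mod 3 (0 between codons, 1 after the first base, 2 after
  the second).  Type-II-like family genes keep the whole DNA-binding domain
  in exon 1, followed by a phase-2 intron.
* **Pattern signature**: the ordered (alignment column, phase) pairs inside
  the K-box window; signatures cluster into conserved patterns (A, B, C, …)
  by single linkage with a column tolerance and a variable-first-intron
  allowance.
* **Phylogeny**: p-distance (pairwise deletion) + Saitou–Nei neighbor
  joining, bootstrap supports mapped onto the full-data tree.
* **Origin labels**: every family gene gets exactly one of
  `inherited_A`, `inherited_C`, `tandem`, `segmental`, `HE`, `unassigned`,
  from reciprocal-best-hit synteny blocks, rank-adjacency + identity
  (tandem), and an identity-margin run test (HE).
* **Expression**: categories (not_expressed / weak / expressed), correlation
  blocks, and sister-pair conservation verdicts on log2(FPKM+1) profiles.

## Worked example

```bash
python examples/03_duplication_census.py
```

prints (seed 1, default synthetic allotetraploid):

```
46 family genes classified:
  inherited_C   20  (43.48%)
  inherited_A   18  (39.13%)
  tandem         4  (8.70%)
  HE             2  (4.35%)
  segmental      2  (4.35%)
mean family genes per chromosome: subgenome A: 7.7, subgenome C: 7.7
28 sister pairs: mean domain identity 98.3%, mean full-length identity 86.4%
```

Inheritance through allopolyploidy dominates the census (83% of the family),
with small tandem/segmental/HE contributions — exactly the planted design.
Sister pairs show near-identical DNA-binding domains but much more diverged
full-length proteins, the signature of purifying selection concentrated on
the domain.  `examples/01_simulate_and_parse.py`,
`examples/02_intron_patterns.py` and
`examples/04_promoters_and_expression.py` walk through the other
capabilities (gene-model parsing, the A–G pattern table with its
clade-concordance test, promoter motif groups and expression verdicts).

A thin CLI wraps the same pipeline:

```bash
madsfam all --seed 1 --out-dir run1          # simulate + analyse everything
madsfam patterns --config my_config.json     # one stage (plus prerequisites)
```

Every stage writes TSV outputs with a header carrying tool version, config
hash and seed.  Real data are supplied by pointing the JSON run config at
your own FASTA/GFF3/alignment/FPKM/catalog files instead of the simulator.

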