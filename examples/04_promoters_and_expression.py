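"""Promoter cis-element scan and expression-conservation analysis.

Scans the family promoters against the bundled IUPAC catalog (light /
stress / hormone groups), then categorises expression profiles and scores
sister-pair conservation.
"""

import collections

from madsfam import pipeline

cfg = pipeline.RunConfig(out_dir="example_out/expr", seed=1)
ctx = pipeline.run_pipeline(cfg)

print("genes with >= 1 motif per cis-element group:")
print(ctx["motif_summary"])

cats = ctx["categories"]
print("\nexpression categories:",
      dict(collections.Counter(cats)))

verdicts = collections.Counter(v.verdict for v in ctx["pair_verdicts"])
print("sister-pair expression verdicts:", dict(verdicts))
# Sister pairs share a planted expression archetype, so most pairs are
# 'same' (r >= 0.8, equal categories); 'divergent' pairs would indicate
# regulatory divergence after duplication.
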