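"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration or via an
unrelated library (``re``), so they stay independent of the implementation
paths they check.
"""

import itertools
import re

import numpy as np
from Bio.Align import substitution_matrices

from madsfam.promoter_elements import IUPAC, reverse_complement

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_alignment_score(a, b, open_=-10.0, ext=-0.5):
    """Best affine-gap global alignment score by exhaustive enumeration.

    The first position of a gap scores ``open_``, every further position
    ``ext`` (the same convention as Biopython's PairwiseAligner).
    """
    best = [-np.inf]

    def go(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "m")
        if i < len(a):
            go(i + 1, j, score + (ext if last == "a" else open_), "a")
        if j < len(b):
            go(i, j + 1, score + (ext if last == "b" else open_), "b")

    go(0, 0, 0.0, "m")
    return best[0]


def oracle_best_chain(points, max_gap):
    """Exhaustive maximum-score collinear chain over all anchor subsets."""
    n = len(points)
    best = 0.0
    order = sorted(range(n), key=lambda i: points[i])
    for size in range(1, n + 1):
        for combo in itertools.combinations(order, size):
            ok = True
            skipped = 0
            for u, v in zip(combo, combo[1:]):
                dx = points[v][0] - points[u][0]
                dy = points[v][1] - points[u][1]
                if dx <= 0 or dy <= 0 or dx > max_gap or dy > max_gap:
                    ok = False
                    break
                skipped += (dx - 1) + (dy - 1)
            if ok:
                best = max(best, size - 0.1 * skipped)
    return best


def regex_motif_hits(promoter, catalog):
    """Overlapping IUPAC matches on both strands via the ``re`` module."""
    out = set()
    n = len(promoter)
    rc = reverse_complement(promoter)
    for e in catalog:
        pat = "".join(f"[{IUPAC[c]}]" for c in e.pattern)
        for m in re.finditer(f"(?=({pat}))", promoter):
            out.add((e.motif_id, m.start(), "+"))
        for m in re.finditer(f"(?=({pat}))", rc):
            out.add((e.motif_id, n - m.start() - len(e.pattern), "-"))
    return out
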