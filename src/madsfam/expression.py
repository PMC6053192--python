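"""Expression categories, heatmap clustering and sister-pair conservation.

Input is an FPKM matrix (genes × tissues).  Genes are categorised as
``not_expressed`` (every tissue below ``t_off``), ``weak`` (expressed
somewhere but never reaching ``t_weak``) or ``expressed``; expressed genes
are grouped into blocks by average-linkage hierarchical clustering of
``log2(FPKM + 1)`` profiles under correlation distance (1 − Pearson r).
Sister-pair conservation compares the log2 profiles of recent duplicates:
``same`` (r >= r_same and equal categories), ``divergent`` (r < r_div or
exactly one member silent), ``similar`` otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

CATEGORIES = ("not_expressed", "weak", "expressed")

__all__ = [
    "PairConservation",
    "read_fpkm",
    "categorize",
    "cluster_expressed",
    "pair_conservation",
]


@dataclass
class PairConservation:
    pair_id: str
    gene1: str
    gene2: str
    r: float | None
    verdict: str  # same | similar | divergent


def read_fpkm(path: str) -> pd.DataFrame:
    """FPKM TSV (genes in rows, tissue codes in the header) → DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.isna().any().any():
        raise ValueError("FPKM matrix has missing values")
    if (df.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if df.columns.duplicated().any():
        raise ValueError("tissue names must be unique")
    return df


def categorize(fpkm: pd.DataFrame, t_off: float = 1.0, t_weak: float = 5.0,
               classes: dict[str, str] | None = None
               ) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene expression category and a per-class percentage table.

    ``not_expressed``: every tissue FPKM < t_off; ``weak``: max FPKM <
    t_weak otherwise; ``expressed`` else.  Percentages are
    100·count/class-size, reported to 2 decimals.
    """
    if fpkm.isna().any().any():
        raise ValueError("FPKM matrix has missing values")
    if (fpkm.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    mx = fpkm.max(axis=1)
    cats = pd.Series(
        np.where(mx < t_off, "not_expressed",
                 np.where(mx < t_weak, "weak", "expressed")),
        index=fpkm.index, name="category")
    cls = pd.Series({g: (classes or {}).get(g, "all") for g in fpkm.index},
                    name="class")
    rows = []
    for c in sorted(cls.unique()):
        sub = cats[cls == c]
        n = len(sub)
        for cat in CATEGORIES:
            k = int((sub == cat).sum())
            rows.append({"class": c, "category": cat, "count": k,
                         "total": n, "pct": round(100.0 * k / n, 2)})
    return cats, pd.DataFrame(rows)


def log2_matrix(fpkm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.log2(fpkm + pseudocount)


def cluster_expressed(log2: pd.DataFrame, k_blocks: int = 3
                      ) -> tuple[pd.Series, list[str]]:
    """Average-linkage clustering of expressed-gene profiles.

    Distance is 1 − Pearson r between log2 profiles.  Returns the block id
    per gene (1..k_blocks) and the dendrogram leaf order for heatmap export.
    Constant profiles (undefined correlation) are placed at maximal distance
    from everything and logged.
    """
    if len(log2) < k_blocks:
        raise ValueError("need at least k_blocks expressed genes")
    x = log2.values.astype(float)
    const = x.std(axis=1) == 0
    if const.any():
        log.warning("%d constant profiles; correlation undefined, distance "
                    "set to maximum", int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(x, metric="correlation")
    d = np.nan_to_num(d, nan=2.0)
    z = hierarchy.linkage(d, method="average")
    blocks = hierarchy.fcluster(z, t=k_blocks, criterion="maxclust")
    order = hierarchy.leaves_list(z)
    genes = list(log2.index)
    return (pd.Series(blocks, index=log2.index, name="block"),
            [genes[i] for i in order])


def pair_conservation(pairs: list[tuple[str, str, str]],
                      fpkm: pd.DataFrame,
                      t_off: float = 1.0, t_weak: float = 5.0,
                      r_same: float = 0.8, r_div: float = 0.3,
                      pseudocount: float = 1.0) -> list[PairConservation]:
    """Expression-conservation verdict for each sister pair.

    ``pairs`` are (pair_id, gene1, gene2) triples; both genes must be in the
    matrix.  With a constant profile Pearson r is undefined and the verdict
    falls back to the categories alone (equal → same, one silent →
    divergent, else similar).
    """
    cats, _ = categorize(fpkm, t_off, t_weak)
    lg = log2_matrix(fpkm, pseudocount)
    out = []
    for pid, g1, g2 in pairs:
        if g1 not in fpkm.index or g2 not in fpkm.index:
            raise ValueError(f"pair {pid}: gene without profile")
        v1, v2 = lg.loc[g1].values, lg.loc[g2].values
        if v1.std() == 0 or v2.std() == 0:
            r = None
            log.warning("pair %s: constant profile, verdict from categories",
                        pid)
        else:
            r = float(np.corrcoef(v1, v2)[0, 1])
        c1, c2 = cats[g1], cats[g2]
        one_silent = (c1 == "not_expressed") != (c2 == "not_expressed")
        if one_silent or (r is not None and r < r_div):
            verdict = "divergent"
        elif (r is None and c1 == c2) or \
                (r is not None and r >= r_same and c1 == c2):
            verdict = "same"
        else:
            verdict = "similar"
        out.append(PairConservation(pid, g1, g2, r, verdict))
    return out
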