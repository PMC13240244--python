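"""Gene overlap and GO-term enrichment for candidate regions.

Overlaps use 1-based inclusive intervals with zero flank (any shared bp
counts).  Enrichment is a per-term hypergeometric upper tail with BH
adjustment; the gene->GO mapping is assumed pre-propagated up the ontology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gl_io import GeneAnnotation, RegionSet


def overlap_genes(regions: RegionSet, genes: GeneAnnotation,
                  ) -> dict[str, list[str]]:
    """Genes overlapping each region (any overlap, zero flank); de-duplicated."""
    out: dict[str, list[str]] = {}
    gt = genes.table
    for _, r in regions.table.iterrows():
        hit = gt[(gt["chrom"] == r["chrom"]) & (gt["start"] <= r["end"])
                 & (gt["end"] >= r["start"])]
        out[r["label"]] = sorted(set(hit["gene_id"]))
    return out


def go_enrichment(selected, universe, gene2go: dict[str, set[str]],
                  alpha: float = 0.05, min_term_size: int = 2) -> pd.DataFrame:
    """Hypergeometric GO enrichment of ``selected`` within ``universe``.

    For a term annotating K of N universe genes with k hits among the n
    selected genes, p = P(X >= k), X ~ Hypergeom(N, K, n).  Terms with fewer
    than ``min_term_size`` universe genes are untestable and skipped.  BH
    adjustment across tested terms; rows sorted by adjusted p.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    n_univ, n_sel = len(universe), len(selected)
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for go in gene2go.get(gene, ()):
            term_genes.setdefault(go, set()).add(gene)
    rows = []
    for go, members in sorted(term_genes.items()):
        size = len(members)
        if size < min_term_size:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, n_univ, size, n_sel))
        rows.append({"go_id": go, "term_size": size, "count_selected": k,
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["go_id", "term_size", "count_selected", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
        df = df.sort_values(["p_adj", "p", "go_id"]).reset_index(drop=True)
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df
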