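"""lncRNA expression filtering, biotype representation and co-expression.

lncRNAs use a lower expression floor than coding genes (RPKM 0.5 instead
of 3, same "at least two replicates at some time point" rule), split into
pre-activation (0 h) and post-activation sets.  Differentially expressed
lncRNAs are the DE calls intersected with the post-activation expressed
set.  Biotype over/under-representation among the DE lncRNAs (antisense,
sense-intronic, lincRNA, ...) is tested per biotype with both
hypergeometric tails against the expressed set as universe.  Each lncRNA
can be tied to protein-coding genes positionally (nearest coding gene by
interval distance) and by co-expression (top positively and negatively
Pearson-correlated DE coding genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import call_de, filter_expressed, standardized_profiles
from .io import TimeCourseMatrix

__all__ = [
    "LncClassStats",
    "lnc_expression_sets",
    "de_lncrnas",
    "biotype_representation",
    "nearest_coding_gene",
    "top_correlated_coding",
]


@dataclass(frozen=True)
class LncClassStats:
    biotype: str
    n_expressed: int
    n_de: int
    p_over: float
    p_under: float


def lnc_expression_sets(matrix_pre: TimeCourseMatrix,
                        matrix_post: TimeCourseMatrix,
                        threshold: float = 0.5,
                        min_replicates: int = 2) -> tuple[set[str], set[str]]:
    """Expressed-lncRNA sets before (0 h) and after activation.

    Applies the same keep rule as :func:`~orthokinetics.de.filter_expressed`
    to the two sample sets independently.
    """
    before = filter_expressed(matrix_pre, threshold, min_replicates)
    after = filter_expressed(matrix_post, threshold, min_replicates)
    return before, after


def de_lncrnas(de_table: pd.DataFrame, expressed_after: set[str],
               fdr_cut: float = 0.05, fc_cut: float = 1.0) -> set[str]:
    """DE lncRNAs: FDR/FC calls restricted to expressed-after lncRNAs."""
    hits = call_de(de_table, fdr_cut=fdr_cut, fc_cut=fc_cut)
    return set(hits["gene_id"]) & set(expressed_after)


def biotype_representation(de_set: set[str], expressed_set: set[str],
                           annotation: pd.DataFrame) -> list[LncClassStats]:
    """Per-biotype hypergeometric representation of DE among expressed.

    For each biotype with at least one expressed member, tests whether its
    count among the DE set is higher (``p_over``, upper tail) or lower
    (``p_under``, lower tail) than expected when drawing |de_set| genes
    from the expressed universe.
    """
    if not de_set:
        raise ValueError("empty query: no differentially expressed lncRNAs")
    if not de_set <= expressed_set:
        raise ValueError("DE set must be a subset of the expressed set")
    biotype = annotation.set_index("gene_id")["biotype"]
    missing = (de_set | expressed_set) - set(biotype.index)
    if missing:
        raise ValueError(
            f"genes missing from annotation: {sorted(missing)[:5]}"
        )
    N = len(expressed_set)
    n = len(de_set)
    stats = []
    universe_biotypes = biotype.loc[sorted(expressed_set)]
    de_biotypes = biotype.loc[sorted(de_set)]
    for bt in sorted(universe_biotypes.unique()):
        K = int((universe_biotypes == bt).sum())
        k = int((de_biotypes == bt).sum())
        stats.append(LncClassStats(
            biotype=bt,
            n_expressed=K,
            n_de=k,
            p_over=float(hypergeom.sf(k - 1, N, K, n)),
            p_under=float(hypergeom.cdf(k, N, K, n)),
        ))
    return stats


def nearest_coding_gene(lnc: str, annotation: pd.DataFrame,
                        coding_biotype: str = "coding"):
    """Nearest coding gene on the lncRNA's chromosome, by interval distance.

    Returns ``(gene_id, distance_bp)`` with distance 0 for overlap; ties
    are broken by the smaller start coordinate.  Returns ``None`` when the
    chromosome has no coding gene.
    """
    ann = annotation.set_index("gene_id")
    if lnc not in ann.index:
        raise ValueError(f"lncRNA {lnc!r} absent from annotation")
    row = ann.loc[lnc]
    coding = annotation[
        (annotation["biotype"] == coding_biotype)
        & (annotation["chrom"] == row["chrom"])
        & (annotation["gene_id"] != lnc)
    ]
    if coding.empty:
        return None
    dist = np.maximum(
        coding["start"].to_numpy() - int(row["end"]),
        int(row["start"]) - coding["end"].to_numpy(),
    )
    dist = np.maximum(dist, 0)
    order = coding.assign(distance=dist).sort_values(["distance", "start"])
    best = order.iloc[0]
    return str(best["gene_id"]), int(best["distance"])


def top_correlated_coding(lnc_matrix: TimeCourseMatrix,
                          coding_matrix: TimeCourseMatrix,
                          lnc_genes, coding_genes,
                          top_n: int = 5) -> pd.DataFrame:
    """Top positively and negatively correlated DE coding genes per lncRNA.

    Correlations are Pearson r over the replicate-averaged log2(RPKM+1)
    time profiles.  Constant profiles are excluded (flagged by omission:
    lncRNAs with a flat profile yield no rows).  Returns a long table
    (lnc_gene, coding_gene, pearson_r, direction, rank).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if list(lnc_matrix.timepoints) != list(coding_matrix.timepoints):
        raise ValueError("matrices must share the time grid")
    prof_l = standardized_profiles(lnc_matrix, lnc_genes)
    prof_c = standardized_profiles(coding_matrix, coding_genes)
    if prof_l.empty or prof_c.empty:
        return pd.DataFrame(columns=["lnc_gene", "coding_gene", "pearson_r",
                                     "direction", "rank"])
    T = prof_l.shape[1]
    # rows are z-scored (population sd) so r = dot / T
    R = prof_l.to_numpy() @ prof_c.to_numpy().T / T
    rows = []
    for i, lnc in enumerate(prof_l.index):
        r = pd.Series(R[i], index=prof_c.index).drop(lnc, errors="ignore")
        r = r.sort_values(ascending=False, kind="mergesort")
        for rank, (gene, val) in enumerate(r.head(top_n).items(), start=1):
            rows.append((lnc, gene, float(val), "positive", rank))
        for rank, (gene, val) in enumerate(
                r.tail(top_n).iloc[::-1].items(), start=1):
            rows.append((lnc, gene, float(val), "negative", rank))
    return pd.DataFrame(rows, columns=["lnc_gene", "coding_gene",
                                       "pearson_r", "direction", "rank"])
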