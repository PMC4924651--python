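"""Window-based SNP-to-gene linking and hypergeometric set enrichment.

Disease lead SNPs with association p < 1e-5 are linked to every gene whose
body (start-end interval) lies within +/-100 kb on the same chromosome;
traits with fewer than two linked genes in the test universe are excluded.
Over-representation of a trait's genes in a query set is scored with the
hypergeometric upper tail, Benjamini-Hochberg adjusted across traits.  The
same machinery serves functional-class enrichment with a user-supplied
term-to-genes map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "link_snps_to_genes",
    "hypergeom_enrich",
    "enrich_gene_sets_vs_traits",
]

ENRICHMENT_COLUMNS = ["term", "k", "K", "n", "N", "p", "fdr", "genes"]


def link_snps_to_genes(snps: pd.DataFrame, annotation: pd.DataFrame,
                       window: int = 100_000,
                       p_cut: float = 1e-5) -> dict[str, set[str]]:
    """Map each trait to the genes within ``window`` bp of its lead SNPs.

    Only SNPs with p-value strictly below ``p_cut`` are used.  A SNP is
    linked to a gene when its distance to the gene body [start, end] is
    <= ``window`` (0 when inside), on the same chromosome.  SNPs on
    chromosomes absent from the annotation are skipped with a warning.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    kept = snps[snps["pvalue"] < p_cut]
    by_chrom = {
        chrom: sub.sort_values("start").reset_index(drop=True)
        for chrom, sub in annotation.groupby("chrom")
    }
    traits: dict[str, set[str]] = {}
    skipped = 0
    for row in kept.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in by_chrom:
            skipped += 1
            continue
        genes = by_chrom[chrom]
        # distance from point to [start, end]; 0 inside
        dist = np.maximum(
            genes["start"].to_numpy() - row.pos,
            row.pos - genes["end"].to_numpy(),
        )
        dist = np.maximum(dist, 0)
        hits = genes.loc[dist <= window, "gene_id"]
        if len(hits):
            traits.setdefault(row.trait, set()).update(hits)
    if skipped:
        warnings.warn(
            f"skipped {skipped} SNP(s) on chromosomes absent from the "
            "annotation",
            stacklevel=2,
        )
    return traits


def hypergeom_enrich(query: set[str], terms: dict[str, set[str]],
                     universe: set[str],
                     min_term_genes: int = 2) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    Term gene sets are intersected with ``universe`` first; terms left with
    fewer than ``min_term_genes`` genes are dropped.  p = P(X >= k) for
    X ~ Hypergeom(N=|universe|, K=|term|, n=|query|); FDR is Benjamini-
    Hochberg across the surviving terms.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query) & set(universe)
    N = len(universe)
    n = len(query)
    rows = []
    for term in sorted(terms):
        term_genes = terms[term] & universe
        K = len(term_genes)
        if K < min_term_genes:
            continue
        overlap = sorted(term_genes & query)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term=term, k=k, K=K, n=n, N=N, p=min(p, 1.0),
                         genes=";".join(overlap)))
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS
                                     if c != "fdr"])
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["fdr"] = pd.Series(dtype=float)
    df = df[ENRICHMENT_COLUMNS]
    return df.sort_values(["p", "term"]).reset_index(drop=True)


@dataclass(frozen=True)
class GeneSetSpec:
    """A query set, its reference universe, and whether its genes live in
    mouse id space (and must be mapped to human via the ortholog map before
    trait lookup)."""

    query: frozenset
    universe: frozenset
    map_to_human: bool = False


def enrich_gene_sets_vs_traits(
    gene_sets: dict[str, GeneSetSpec],
    trait_map: dict[str, set[str]],
    ortholog_map: pd.DataFrame | None = None,
    min_term_genes: int = 2,
) -> dict[str, pd.DataFrame]:
    """Trait enrichment for several query sets with set-specific universes.

    ``trait_map`` is in human gene space (as produced by
    :func:`link_snps_to_genes` on the human annotation).  Sets flagged
    ``map_to_human`` have their query and universe translated through the
    one-to-one ortholog map; members without an ortholog are dropped (the
    drop count is reported as a warning).
    """
    results = {}
    m2h = None
    if ortholog_map is not None:
        m2h = dict(
            zip(ortholog_map["mouse_gene"], ortholog_map["human_gene"])
        )
    for name, spec in gene_sets.items():
        query, universe = set(spec.query), set(spec.universe)
        if spec.map_to_human:
            if m2h is None:
                raise ValueError(
                    f"set {name!r} needs an ortholog map to translate mouse ids"
                )
            dropped = sum(g not in m2h for g in query)
            query = {m2h[g] for g in query if g in m2h}
            universe = {m2h[g] for g in universe if g in m2h}
            if dropped:
                warnings.warn(
                    f"{name}: dropped {dropped} mouse gene(s) without an "
                    "ortholog",
                    stacklevel=2,
                )
        if not query.issubset(universe):
            raise ValueError(f"set {name!r}: query is not within its universe")
        results[name] = hypergeom_enrich(
            query, trait_map, universe, min_term_genes=min_term_genes
        )
    return results
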