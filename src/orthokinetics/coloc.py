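"""Chromosomal co-localization of a gene set with permutation significance.

A *cluster* is a maximal run of query genes, in chromosome gene order, in
which every consecutive pair is separated by at most ``d`` non-query
annotated genes (gap semantics of the Kerfuffle co-localization tool;
default d = 3, minimum cluster size 2).  Significance is empirical: each
permutation re-assigns the |query| labels uniformly without replacement
over all annotation gene slots, and two statistics are tracked —

* the global cluster count, and
* the count of clusters of size >= s for each observed size s —

with add-one p-values p = (1 + #{perm >= observed}) / (1 + n_perm), so the
reporting floor is 1 / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneCluster",
    "ColocResult",
    "find_clusters",
    "permutation_pvalues",
]


@dataclass(frozen=True)
class GeneCluster:
    chromosome: str
    genes: tuple[str, ...]  # ordered by position
    span_bp: int
    max_gap: int  # largest intervening non-query gene count inside the run

    @property
    def size(self) -> int:
        return len(self.genes)


def _ordered_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    return annotation.sort_values(
        ["chrom", "start", "end", "gene_id"]
    ).reset_index(drop=True)


def _cluster_sizes_from_slots(slots: np.ndarray, chrom_codes: np.ndarray,
                              d: int) -> np.ndarray:
    """Sizes of maximal runs among sorted query slot indices.

    ``slots`` are sorted positions in genome gene order; consecutive query
    genes are linked when they share a chromosome and have <= d intervening
    slots.  Returns run sizes (>= 1; callers filter by min size).
    """
    if slots.size == 0:
        return np.zeros(0, dtype=int)
    linked = (np.diff(slots) <= d + 1) & (
        chrom_codes[slots[1:]] == chrom_codes[slots[:-1]]
    )
    # run lengths of consecutive linked genes -> cluster sizes
    breaks = np.flatnonzero(~linked)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(slots) - 1]))
    return (ends - starts + 1).astype(int)


def find_clusters(query: set[str], annotation: pd.DataFrame, d: int = 3,
                  min_size: int = 2) -> list[GeneCluster]:
    """Maximal query-gene runs with inter-gene gaps <= ``d``.

    The result is independent of the iteration order of ``query``.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    ann = _ordered_annotation(annotation)
    known = set(ann["gene_id"])
    missing = set(query) - known
    if missing:
        raise ValueError(
            f"query genes absent from annotation: {sorted(missing)[:5]}"
        )
    is_query = ann["gene_id"].isin(query).to_numpy()
    slots = np.flatnonzero(is_query)
    chrom_codes = pd.factorize(ann["chrom"])[0]
    clusters: list[GeneCluster] = []
    if slots.size == 0:
        return clusters
    linked = (np.diff(slots) <= d + 1) & (
        chrom_codes[slots[1:]] == chrom_codes[slots[:-1]]
    )
    start = 0
    for i in range(len(slots)):
        last = i == len(slots) - 1
        if last or not linked[i]:
            members = slots[start:i + 1]
            if len(members) >= min_size:
                sub = ann.iloc[members]
                gaps = np.diff(members) - 1
                clusters.append(GeneCluster(
                    chromosome=str(sub["chrom"].iloc[0]),
                    genes=tuple(sub["gene_id"]),
                    span_bp=int(sub["end"].max() - sub["start"].min() + 1),
                    max_gap=int(gaps.max()) if len(gaps) else 0,
                ))
            start = i + 1
    return clusters


@dataclass(frozen=True)
class ColocResult:
    clusters: tuple[GeneCluster, ...]
    n_perm: int
    global_count: int
    global_p: float
    per_size_p: dict  # size s -> empirical p of count(size >= s)
    per_size_observed: dict  # size s -> observed count(size >= s)

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            dict(chromosome=c.chromosome, members=";".join(c.genes),
                 size=c.size, span_bp=c.span_bp, max_gap=c.max_gap,
                 p_empirical=self.per_size_p.get(c.size, np.nan))
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows, columns=["chromosome", "members", "size", "span_bp",
                           "max_gap", "p_empirical"]
        )


def permutation_pvalues(query: set[str], annotation: pd.DataFrame,
                        d: int = 3, n_perm: int = 1000,
                        seed: int = 0, min_size: int = 2) -> ColocResult:
    """Empirical significance of the observed clustering.

    Both the global cluster count and, per observed cluster size s, the
    count of clusters of size >= s are compared against ``n_perm`` uniform
    relabelings of the query over all gene slots.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ann = _ordered_annotation(annotation)
    chrom_codes = pd.factorize(ann["chrom"])[0]
    n_genes = len(ann)
    clusters = find_clusters(query, annotation, d=d, min_size=min_size)
    obs_sizes = np.asarray([c.size for c in clusters], dtype=int)
    global_count = len(clusters)
    sizes_of_interest = sorted(set(obs_sizes)) or []
    obs_ge = {s: int((obs_sizes >= s).sum()) for s in sizes_of_interest}

    rng = np.random.default_rng(seed)
    q = len(query)
    exceed_global = 0
    exceed_ge = {s: 0 for s in sizes_of_interest}
    for _ in range(n_perm):
        slots = np.sort(rng.choice(n_genes, size=q, replace=False))
        sizes = _cluster_sizes_from_slots(slots, chrom_codes, d)
        sizes = sizes[sizes >= min_size]
        if len(sizes) >= global_count:
            exceed_global += 1
        for s in sizes_of_interest:
            if int((sizes >= s).sum()) >= obs_ge[s]:
                exceed_ge[s] += 1
    denom = 1 + n_perm
    return ColocResult(
        clusters=tuple(clusters),
        n_perm=n_perm,
        global_count=global_count,
        global_p=(1 + exceed_global) / denom,
        per_size_p={s: (1 + exceed_ge[s]) / denom for s in sizes_of_interest},
        per_size_observed=obs_ge,
    )


def circos_export(clusters, annotation: pd.DataFrame) -> pd.DataFrame:
    """Cluster spans as (chromosome, start, end, cluster_id) for plotting."""
    ann = annotation.set_index("gene_id")
    rows = []
    for i, c in enumerate(clusters, start=1):
        sub = ann.loc[list(c.genes)]
        rows.append(dict(chromosome=c.chromosome,
                         start=int(sub["start"].min()),
                         end=int(sub["end"].max()),
                         cluster_id=f"cluster{i:03d}"))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                       "cluster_id"])
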