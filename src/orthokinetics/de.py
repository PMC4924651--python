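"""Differential-expression filtering, ranking, cross-species concordance,
profile clustering and ortholog expression correlation.

Conventions (mirroring the study design the package targets):

* expression filter — a gene is *expressed* iff at some time point at least
  ``min_replicates`` replicates reach the RPKM threshold (3 for coding
  genes, 0.5 for lncRNAs); genes failing this at every time point are
  removed;
* DE calls — FDR < 0.05 and |log2 FC| > 1, both strict;
* ranking — per time point and direction, candidates with FDR < 0.05 and
  |log2 FC| >= 0.3 are sorted by |log2 FC| (ties broken by gene id) and the
  top ceil(20%) kept; per-species sets are merged over all time points
  before cross-species comparison;
* clustering — replicate-averaged log2(RPKM+1) profiles, z-scored per gene
  across time points, pooled over both species, k-means with k = 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .io import TimeCourseMatrix

__all__ = [
    "RankedSets",
    "filter_expressed",
    "call_de",
    "rank_top20",
    "build_ranked_sets",
    "concordant_pairs",
    "standardized_profiles",
    "cluster_profiles_kmeans",
    "hierarchical_order",
    "correlate_ortholog_expression",
]


def filter_expressed(matrix: TimeCourseMatrix, rpkm_threshold: float = 3.0,
                     min_replicates: int = 2) -> set[str]:
    """Genes with >= ``min_replicates`` replicates at or above the RPKM
    threshold at one or more time points (the complement of the "below
    threshold in at least two replicates at all time points" removal rule).
    """
    if rpkm_threshold <= 0:
        raise ValueError("rpkm_threshold must be positive")
    if min_replicates < 1 or min_replicates > matrix.n_replicates:
        raise ValueError(
            f"min_replicates must be in [1, {matrix.n_replicates}]"
        )
    keep = pd.Series(False, index=matrix.gene_ids)
    for t in matrix.timepoints:
        cols = matrix.columns_for(t)
        n_ok = (matrix.values[cols] >= rpkm_threshold).sum(axis=1)
        keep |= n_ok >= min_replicates
    return set(keep.index[keep])


def call_de(de_table: pd.DataFrame, fdr_cut: float = 0.05,
            fc_cut: float = 1.0) -> pd.DataFrame:
    """Records passing FDR < ``fdr_cut`` and |log2 FC| > ``fc_cut`` (strict),
    with an added ``direction`` column ('up' / 'down').
    """
    hits = de_table[
        (de_table["fdr"] < fdr_cut) & (de_table["log2_fc"].abs() > fc_cut)
    ].copy()
    hits["direction"] = np.where(hits["log2_fc"] > 0, "up", "down")
    return hits.reset_index(drop=True)


def rank_top20(de_table: pd.DataFrame, timepoint: float,
               fdr_cut: float = 0.05, fc_floor: float = 0.3,
               fraction: float = 0.2) -> tuple[list[str], list[str]]:
    """Top-``fraction`` up- and down-regulated genes at one time point.

    Candidates need FDR < ``fdr_cut`` and |log2 FC| >= ``fc_floor``; each
    direction is sorted by |log2 FC| descending with ties broken by gene id
    ascending, and the first ceil(fraction * n) genes are kept.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    sub = de_table[
        (de_table["timepoint"] == float(timepoint))
        & (de_table["fdr"] < fdr_cut)
        & (de_table["log2_fc"].abs() >= fc_floor)
    ]

    def top(direction_sub: pd.DataFrame) -> list[str]:
        n = len(direction_sub)
        if n == 0:
            return []
        k = math.ceil(fraction * n)
        ordered = direction_sub.assign(absfc=direction_sub["log2_fc"].abs())
        ordered = ordered.sort_values(
            ["absfc", "gene_id"], ascending=[False, True]
        )
        return ordered["gene_id"].head(k).tolist()

    up = top(sub[sub["log2_fc"] > 0])
    down = top(sub[sub["log2_fc"] < 0])
    return up, down


@dataclass
class RankedSets:
    """Per (timepoint, direction) ranked gene lists for one species."""

    species: str
    by_timepoint: dict[tuple[float, str], list[str]] = field(default_factory=dict)

    def merged(self, direction: str) -> set[str]:
        """Union over all time points for one direction."""
        return set().union(
            *(genes for (t, d), genes in self.by_timepoint.items()
              if d == direction)
        ) if self.by_timepoint else set()

    def all_genes(self) -> set[str]:
        return self.merged("up") | self.merged("down")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(species=self.species, timepoint=t, direction=d,
                 rank=i + 1, gene_id=g)
            for (t, d), genes in sorted(self.by_timepoint.items())
            for i, g in enumerate(genes)
        ]
        return pd.DataFrame(
            rows, columns=["species", "timepoint", "direction", "rank", "gene_id"]
        )


def build_ranked_sets(de_table: pd.DataFrame, species: str,
                      fdr_cut: float = 0.05, fc_floor: float = 0.3,
                      fraction: float = 0.2) -> RankedSets:
    """Apply :func:`rank_top20` at every time point of a DE table."""
    ranked = RankedSets(species=species)
    for t in sorted(de_table["timepoint"].unique()):
        up, down = rank_top20(de_table, t, fdr_cut, fc_floor, fraction)
        if up:
            ranked.by_timepoint[(float(t), "up")] = up
        if down:
            ranked.by_timepoint[(float(t), "down")] = down
    return ranked


def concordant_pairs(ranked_h: RankedSets, ranked_m: RankedSets,
                     ortholog_map: pd.DataFrame) -> pd.DataFrame:
    """Ortholog pairs regulated in the same direction in both species.

    Time points are merged per species first, so a pair counts as
    concordant when both members are hit in the same direction at *any*
    (not necessarily the same) time point.  A pair can appear for both
    directions.
    """
    rows = []
    for direction in ("up", "down"):
        mh = ranked_h.merged(direction)
        mm = ranked_m.merged(direction)
        for hgene, mgene in ortholog_map.itertuples(index=False):
            if hgene in mh and mgene in mm:
                rows.append((hgene, mgene, direction))
    return pd.DataFrame(rows, columns=["human_gene", "mouse_gene", "direction"])


def standardized_profiles(matrix: TimeCourseMatrix,
                          genes=None) -> pd.DataFrame:
    """Replicate-mean log2(RPKM+1) profiles, z-scored per gene across time.

    Genes with a constant mean profile (zero variance) are dropped — they
    carry no shape information for clustering or correlation.
    """
    prof = matrix.replicate_mean_log2()
    if genes is not None:
        genes = [g for g in genes if g in prof.index]
        prof = prof.loc[genes]
    arr = prof.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    keep = sd > 1e-12  # tolerance: replicate averaging leaves ~1e-16 wobble
    arr = arr[keep]
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(z, index=prof.index[keep], columns=prof.columns)


def cluster_profiles_kmeans(matrix_h: TimeCourseMatrix,
                            matrix_m: TimeCourseMatrix,
                            genes_h, genes_m,
                            ortholog_map: pd.DataFrame,
                            k: int = 30, restarts: int = 10,
                            seed: int = 0):
    """Joint k-means over pooled standardized profiles of both species.

    Returns ``(assignments, co_clustered)``: a DataFrame (species, gene_id,
    cluster) and the ortholog pairs whose two members share a cluster.
    """
    if list(matrix_h.timepoints) != list(matrix_m.timepoints):
        raise ValueError("species matrices must share the time grid")
    prof_h = standardized_profiles(matrix_h, genes_h)
    prof_m = standardized_profiles(matrix_m, genes_m)
    pooled = np.vstack([prof_h.to_numpy(), prof_m.to_numpy()])
    if pooled.shape[0] < k:
        raise ValueError(
            f"need at least k={k} pooled genes, got {pooled.shape[0]}"
        )
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(pooled)
    assignments = pd.DataFrame({
        "species": ["human"] * len(prof_h) + ["mouse"] * len(prof_m),
        "gene_id": list(prof_h.index) + list(prof_m.index),
        "cluster": labels,
    })
    lookup = {
        (row.species, row.gene_id): row.cluster
        for row in assignments.itertuples(index=False)
    }
    rows = []
    for hgene, mgene in ortholog_map.itertuples(index=False):
        ch = lookup.get(("human", hgene))
        cm = lookup.get(("mouse", mgene))
        if ch is not None and ch == cm:
            rows.append((hgene, mgene, ch))
    co_clustered = pd.DataFrame(
        rows, columns=["human_gene", "mouse_gene", "cluster"]
    )
    return assignments, co_clustered


def hierarchical_order(profiles: pd.DataFrame) -> list:
    """Deterministic Ward/Euclidean dendrogram leaf order for heatmaps."""
    if len(profiles) < 2:
        raise ValueError("need at least two rows")
    arr = profiles.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("profiles contain NaN rows")
    Z = hierarchy.linkage(arr, method="ward", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    return [profiles.index[i] for i in leaves]


def correlate_ortholog_expression(matrix_h: TimeCourseMatrix,
                                  matrix_m: TimeCourseMatrix,
                                  pairs: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between replicate-mean log profiles of each ortholog pair.

    Pairs with a constant profile in either species get ``r = NaN`` and
    ``constant_profile = True`` rather than a spurious coefficient.
    """
    if list(matrix_h.timepoints) != list(matrix_m.timepoints):
        raise ValueError("species matrices must share the time grid")
    prof_h = matrix_h.replicate_mean_log2()
    prof_m = matrix_m.replicate_mean_log2()
    rows = []
    for hgene, mgene in pairs[["human_gene", "mouse_gene"]].itertuples(index=False):
        a = prof_h.loc[hgene].to_numpy(dtype=float)
        b = prof_m.loc[mgene].to_numpy(dtype=float)
        if a.std() <= 1e-12 or b.std() <= 1e-12:
            rows.append((hgene, mgene, np.nan, True))
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        rows.append((hgene, mgene, r, False))
    return pd.DataFrame(
        rows, columns=["human_gene", "mouse_gene", "pearson_r",
                       "constant_profile"]
    )
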