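import itertools

import numpy as np
import pandas as pd
import pytest

from orthokinetics.de import (RankedSets, build_ranked_sets, call_de,
                              cluster_profiles_kmeans, concordant_pairs,
                              correlate_ortholog_expression, filter_expressed,
                              hierarchical_order, rank_top20,
                              standardized_profiles)
from orthokinetics.simulate import DEFAULT_TIMEPOINTS

from conftest import make_matrix


class TestFilterExpressed:
    def test_two_replicates_at_threshold_kept(self):
        # 3,3,0 at the first time point, zeros elsewhere: exactly two
        # replicates reach RPKM 3 at one time point -> the gene stays
        vals = np.zeros(30)
        vals[:3] = [3.0, 3.0, 0.0]
        m = make_matrix({"g1": vals})
        assert filter_expressed(m, 3.0) == {"g1"}

    def test_single_replicate_everywhere_removed(self):
        vals = np.zeros((10, 3))
        vals[:, 0] = 10.0  # one replicate high at every time point
        m = make_matrix({"g1": vals})
        assert filter_expressed(m, 3.0) == set()

    def test_lnc_threshold_same_semantics(self):
        vals = np.zeros(30)
        vals[:3] = [0.5, 0.5, 0.1]
        m = make_matrix({"l1": vals})
        assert filter_expressed(m, 0.5) == {"l1"}
        assert filter_expressed(m, 3.0) == set()

    def test_just_below_threshold_removed(self):
        m = make_matrix({"g1": np.full(30, 2.999)})
        assert filter_expressed(m, 3.0) == set()

    def test_min_replicates_validation(self):
        m = make_matrix({"g1": np.ones(30)})
        with pytest.raises(ValueError):
            filter_expressed(m, 3.0, min_replicates=4)


class TestCallDe:
    @pytest.mark.parametrize(
        "fdr,fc,included",
        [
            (0.05, 2.0, False),   # fdr boundary: strict <
            (0.01, 1.0, False),   # fc boundary: strict >
            (0.01, -1.5, True),   # down-regulated passes
            (0.049, 1.001, True),
        ],
    )
    def test_strict_cutoffs(self, fdr, fc, included):
        de = pd.DataFrame(
            [("g1", 4.0, fc, fdr)],
            columns=["gene_id", "timepoint", "log2_fc", "fdr"],
        )
        hits = call_de(de)
        assert (len(hits) == 1) is included
        if included:
            assert hits["direction"].iloc[0] == ("up" if fc > 0 else "down")


class TestRankTop20:
    def _table(self, fcs, timepoint=4.0, fdr=0.01):
        return pd.DataFrame(
            [(f"g{i:02d}", timepoint, fc, fdr) for i, fc in enumerate(fcs)],
            columns=["gene_id", "timepoint", "log2_fc", "fdr"],
        )

    def test_top_fraction_of_ten(self):
        fcs = np.linspace(0.4, 4.0, 10)
        up, down = rank_top20(self._table(fcs), 4.0)
        assert len(up) == 2 and down == []
        assert up == ["g09", "g08"]  # largest |log2FC| first

    def test_ceiling_rule_on_seven(self):
        fcs = -np.linspace(0.5, 3.5, 7)
        up, down = rank_top20(self._table(fcs), 4.0)
        assert up == [] and len(down) == 2  # ceil(0.2 * 7) = 2

    def test_all_high_fdr_empty(self):
        up, down = rank_top20(self._table([1.0, 2.0], fdr=0.5), 4.0)
        assert up == down == []

    def test_fc_floor_inclusive(self):
        up, _ = rank_top20(self._table([0.3]), 4.0)
        assert up == ["g00"]
        up, _ = rank_top20(self._table([0.29]), 4.0)
        assert up == []

    def test_ties_broken_by_gene_id(self):
        de = self._table([1.0, 1.0, 1.0, 1.0, 1.0])
        up, _ = rank_top20(de, 4.0)
        assert up == ["g00"]

    def test_monotone_adding_candidates_never_shrinks(self):
        fcs = list(np.linspace(0.4, 2.0, 9))
        n9 = len(rank_top20(self._table(fcs), 4.0)[0])
        n10 = len(rank_top20(self._table(fcs + [0.35]), 4.0)[0])
        assert n10 >= n9


class TestConcordance:
    def _ranked(self, species, hits):
        rs = RankedSets(species=species)
        for (t, d), genes in hits.items():
            rs.by_timepoint[(t, d)] = genes
        return rs

    def test_different_timepoints_still_concordant(self):
        rh = self._ranked("human", {(4.0, "up"): ["h1"]})
        rm = self._ranked("mouse", {(72.0, "up"): ["m1"]})
        ortho = pd.DataFrame({"human_gene": ["h1"], "mouse_gene": ["m1"]})
        conc = concordant_pairs(rh, rm, ortho)
        assert conc.to_records(index=False).tolist() == [("h1", "m1", "up")]

    def test_opposite_directions_not_concordant(self):
        rh = self._ranked("human", {(4.0, "up"): ["h1"]})
        rm = self._ranked("mouse", {(4.0, "down"): ["m1"]})
        ortho = pd.DataFrame({"human_gene": ["h1"], "mouse_gene": ["m1"]})
        assert concordant_pairs(rh, rm, ortho).empty

    def test_empty_mouse_sets(self):
        rh = self._ranked("human", {(4.0, "up"): ["h1"]})
        rm = RankedSets(species="mouse")
        ortho = pd.DataFrame({"human_gene": ["h1"], "mouse_gene": ["m1"]})
        assert concordant_pairs(rh, rm, ortho).empty

    def test_species_symmetric(self):
        rh = self._ranked("human", {(4.0, "up"): ["h1", "h2"]})
        rm = self._ranked("mouse", {(6.0, "up"): ["m1"]})
        ortho = pd.DataFrame({"human_gene": ["h1", "h2"],
                              "mouse_gene": ["m1", "m2"]})
        fwd = concordant_pairs(rh, rm, ortho)
        swapped = ortho.rename(columns={"human_gene": "mouse_gene",
                                        "mouse_gene": "human_gene"})
        rev = concordant_pairs(rm, rh, swapped[["human_gene", "mouse_gene"]])
        assert len(fwd) == len(rev) == 1


class TestClustering:
    def test_identical_profiles_co_cluster(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(1, 40, 10)
        genes_h, genes_m, data_h, data_m = [], [], {}, {}
        for i in range(6):
            p = rng.uniform(1, 40, 10)
            data_h[f"h{i}"] = np.repeat(p, 3)
            data_m[f"m{i}"] = np.repeat(p if i < 3 else rng.uniform(1, 40, 10), 3)
            genes_h.append(f"h{i}")
            genes_m.append(f"m{i}")
        mh = make_matrix(data_h, species="human")
        mm = make_matrix(data_m, species="mouse")
        ortho = pd.DataFrame({"human_gene": genes_h, "mouse_gene": genes_m})
        _, co = cluster_profiles_kmeans(mh, mm, genes_h, genes_m, ortho,
                                        k=4, restarts=5, seed=0)
        assert {("h0", "m0"), ("h1", "m1"), ("h2", "m2")} <= set(
            zip(co["human_gene"], co["mouse_gene"])
        )

    def test_fewer_genes_than_k_rejected(self):
        mh = make_matrix({"h1": np.arange(30) + 1.0})
        mm = make_matrix({"m1": np.arange(30) + 2.0}, species="mouse")
        ortho = pd.DataFrame({"human_gene": ["h1"], "mouse_gene": ["m1"]})
        with pytest.raises(ValueError, match="k="):
            cluster_profiles_kmeans(mh, mm, ["h1"], ["m1"], ortho, k=30)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(1)
        data = {f"g{i}": rng.uniform(1, 40, 30) for i in range(40)}
        mh = make_matrix(data)
        mm = make_matrix({k.replace("g", "m"): v for k, v in data.items()},
                         species="mouse")
        ortho = pd.DataFrame({"human_gene": list(data),
                              "mouse_gene": [k.replace("g", "m") for k in data]})
        a1, c1 = cluster_profiles_kmeans(mh, mm, list(data), list(ortho["mouse_gene"]),
                                         ortho, k=5, seed=7)
        a2, c2 = cluster_profiles_kmeans(mh, mm, list(data), list(ortho["mouse_gene"]),
                                         ortho, k=5, seed=7)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(c1, c2)


def _brute_force_ward_merge_order(X):
    """Greedy Ward merging oracle: returns the sequence of merged sets."""
    clusters = {i: [i] for i in range(len(X))}
    centroids = {i: X[i].astype(float) for i in range(len(X))}
    sizes = {i: 1 for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            na, nb = sizes[a], sizes[b]
            d2 = ((centroids[a] - centroids[b]) ** 2).sum()
            cost = na * nb / (na + nb) * d2
            if best is None or cost < best[0]:
                best = (cost, a, b)
        _, a, b = best
        merges.append(frozenset(clusters[a] + clusters[b]))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        centroids[next_id] = (sizes[a] * centroids[a] + sizes[b] * centroids[b]) / (
            sizes[a] + sizes[b]
        )
        sizes[next_id] = sizes[a] + sizes[b]
        del centroids[a], centroids[b], sizes[a], sizes[b]
        next_id += 1
    return merges


class TestHierarchicalOrder:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 4))
        X[3] = X[1]
        prof = pd.DataFrame(X, index=[f"r{i}" for i in range(5)])
        order = hierarchical_order(prof)
        assert abs(order.index("r1") - order.index("r3")) == 1

    def test_leaf_order_is_permutation(self):
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(rng.normal(size=(8, 5)),
                            index=[f"r{i}" for i in range(8)])
        assert sorted(hierarchical_order(prof)) == sorted(prof.index)

    def test_first_merge_matches_brute_force_oracle(self):
        from scipy.cluster import hierarchy

        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        oracle = _brute_force_ward_merge_order(X)
        Z = hierarchy.linkage(X, method="ward")
        # reconstruct scipy's merge sets and compare with the oracle's
        sets = {i: frozenset([i]) for i in range(6)}
        for step, (a, b, *_rest) in enumerate(Z):
            merged = sets[int(a)] | sets[int(b)]
            sets[6 + step] = merged
            assert merged == oracle[step]

    def test_nan_rows_rejected(self):
        prof = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="NaN"):
            hierarchical_order(prof)


class TestCorrelation:
    def test_identical_and_negated(self):
        p = np.linspace(1, 30, 10)
        mh = make_matrix({"h1": np.repeat(p, 3)})
        # profile whose log2 values are anti-correlated with h1's
        lh = np.log2(p + 1)
        neg = 2 ** (lh.max() + lh.min() - lh) - 1
        mm = make_matrix({"m1": np.repeat(p, 3), "m2": np.repeat(neg, 3)},
                         species="mouse")
        pairs = pd.DataFrame({"human_gene": ["h1", "h1"],
                              "mouse_gene": ["m1", "m2"]})
        res = correlate_ortholog_expression(mh, mm, pairs)
        assert res["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert res["pearson_r"].iloc[1] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 50, 30)
        b = rng.uniform(0, 50, 30)
        mh = make_matrix({"h1": a})
        mm = make_matrix({"m1": b}, species="mouse")
        pairs = pd.DataFrame({"human_gene": ["h1"], "mouse_gene": ["m1"]})
        r = correlate_ortholog_expression(mh, mm, pairs)["pearson_r"].iloc[0]
        x = mh.replicate_mean_log2().loc["h1"].to_numpy()
        y = mm.replicate_mean_log2().loc["m1"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_profile_flagged(self):
        mh = make_matrix({"h1": np.full(30, 7.0)})
        mm = make_matrix({"m1": np.arange(30) + 1.0}, species="mouse")
        pairs = pd.DataFrame({"human_gene": ["h1"], "mouse_gene": ["m1"]})
        res = correlate_ortholog_expression(mh, mm, pairs)
        assert res["constant_profile"].iloc[0]
        assert np.isnan(res["pearson_r"].iloc[0])


def test_build_ranked_sets_merging(de_table_small):
    ranked = build_ranked_sets(de_table_small, "human")
    # candidates: t=4: up a1 (2.0), a2 down; t=72: a4 up (1.2), a5 down (0.4)
    assert ranked.merged("up") == {"a1", "a4"}
    assert ranked.merged("down") == {"a2", "a5"}
    frame = ranked.to_frame()
    assert set(frame.columns) == {"species", "timepoint", "direction",
                                  "rank", "gene_id"}


def test_standardized_profiles_drop_constant():
    m = make_matrix({"g1": np.repeat(np.linspace(1, 20, 10), 3),
                     "g2": np.full(30, 5.0)})
    prof = standardized_profiles(m)
    assert list(prof.index) == ["g1"]
    assert prof.loc["g1"].mean() == pytest.approx(0.0, abs=1e-12)
    assert prof.loc["g1"].std(ddof=0) == pytest.approx(1.0)
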