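"""Stratified metrics: Pearson, AUC/AUPRC, cross-cell-type correlation,
replicate CV with Mann-Whitney, TSS stratification, precision@k."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ctsbench.stratified_eval import (bh_adjust, cross_celltype_correlation,
                                      mannwhitney_one_sided,
                                      precision_top_celltypes, replicate_cv,
                                      replicate_concordance, stratified_auc_auprc,
                                      stratified_pearson, tss_stratify)


def _cell(table, track, stratum, metric):
    row = table[(table["track"] == track) & (table["stratum"] == stratum)
                & (table["metric"] == metric)]
    assert len(row) == 1
    return row.iloc[0]


class TestStratifiedPearson:
    def test_perfect_and_inverse(self):
        x = np.arange(20, dtype=float)[:, None]
        strata = ["a"] * 10 + ["b"] * 10
        t = stratified_pearson(x, x, strata)
        assert _cell(t, "track0", "a", "pearson_r")["value"] == pytest.approx(1.0)
        t = stratified_pearson(x, -x, strata)
        assert _cell(t, "track0", "b", "pearson_r")["value"] == pytest.approx(-1.0)

    def test_closed_form_three_points(self):
        t = stratified_pearson(np.array([[1.0], [2.0], [3.0]]),
                               np.array([[1.0], [3.0], [2.0]]),
                               ["s"] * 3, min_n=3)
        assert _cell(t, "track0", "s", "pearson_r")["value"] == pytest.approx(0.5)

    def test_small_cells_absent_not_zero(self):
        x = np.arange(5, dtype=float)[:, None]
        t = stratified_pearson(x, x, ["s"] * 5, min_n=10)
        cell = _cell(t, "track0", "s", "pearson_r")
        assert cell["value"] is None or (isinstance(cell["value"], float)
                                         and math.isnan(cell["value"]))
        assert cell["reason"] == "n below minimum"

    def test_zero_variance_absent(self):
        x = np.ones((12, 1))
        t = stratified_pearson(x, np.arange(12.0)[:, None], ["s"] * 12)
        assert _cell(t, "track0", "s", "pearson_r")["reason"] == "zero variance"

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=(30, 2))
        target = pred + rng.normal(scale=0.5, size=(30, 2))
        strata = ["a"] * 15 + ["b"] * 15
        t1 = stratified_pearson(pred, target, strata)
        perm = rng.permutation(30)
        t2 = stratified_pearson(pred[perm], target[perm],
                                [strata[i] for i in perm])
        for tr, s in itertools.product(["track0", "track1"], ["a", "b"]):
            assert _cell(t1, tr, s, "pearson_r")["value"] == pytest.approx(
                _cell(t2, tr, s, "pearson_r")["value"])

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(size=(40, 1))
        target = pred + rng.normal(scale=0.3, size=(40, 1))
        strata = ["s"] * 40
        base = _cell(stratified_pearson(pred, target, strata),
                     "track0", "s", "pearson_r")["value"]
        scaled = _cell(stratified_pearson(3.5 * pred + 2, target, strata),
                       "track0", "s", "pearson_r")["value"]
        assert scaled == pytest.approx(base)


class TestAucAuprc:
    def test_perfect_separation(self):
        scores = np.r_[np.ones(10), np.zeros(10)][:, None]
        labels = np.r_[np.ones(10), np.zeros(10)][:, None].astype(int)
        t = stratified_auc_auprc(scores, labels, ["s"] * 20)
        assert _cell(t, "track0", "s", "auc")["value"] == 1.0
        assert _cell(t, "track0", "s", "auprc")["value"] == 1.0

    def test_pair_counting_matches_enumeration(self):
        scores = np.array([0.9, 0.8, 0.7, 0.95])[:, None]
        labels = np.array([1, 1, 0, 0])[:, None]
        # exhaustive pair enumeration oracle
        pos = scores[labels[:, 0] == 1, 0]
        neg = scores[labels[:, 0] == 0, 0]
        expected = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        t = stratified_auc_auprc(scores, labels, ["s"] * 4, min_n=2)
        assert _cell(t, "track0", "s", "auc")["value"] == pytest.approx(expected)

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(2)
        n = 4000
        scores = rng.normal(size=(n, 1))
        labels = rng.integers(0, 2, size=(n, 1))
        t = stratified_auc_auprc(scores, labels, ["s"] * n)
        assert abs(_cell(t, "track0", "s", "auc")["value"] - 0.5) < 3 / np.sqrt(n)

    def test_single_class_absent(self):
        t = stratified_auc_auprc(np.ones((12, 1)), np.ones((12, 1), int),
                                 ["s"] * 12)
        assert _cell(t, "track0", "s", "auc")["reason"] == "single class"


class TestCrossCelltype:
    def test_identical_columns_all_one(self):
        m = np.tile(np.arange(20.0)[:, None], (1, 3))
        t = cross_celltype_correlation(m)
        assert np.allclose(t["pearson_r"], 1.0)

    def test_two_point_block_design(self):
        m = np.array([[10.0, 0.0]] * 10 + [[0.0, 10.0]] * 10)
        t = cross_celltype_correlation(m)
        assert t["pearson_r"].iloc[0] == pytest.approx(-1.0)

    def test_pair_count(self):
        rng = np.random.default_rng(3)
        for T in (2, 4, 6):
            t = cross_celltype_correlation(rng.normal(size=(15, T)))
            assert len(t) == T * (T - 1) // 2


class TestMannWhitney:
    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            a = rng.normal(size=5)
            b = rng.normal(size=4)
            u, p = mannwhitney_one_sided(a, b)
            # enumeration oracle: all C(9,5) splits of the pooled sample
            pooled = np.concatenate([a, b])
            def u_stat(x, y):
                return sum((xi > yi) + 0.5 * (xi == yi)
                           for xi in x for yi in y)
            observed = u_stat(a, b)
            count = total = 0
            for idx in itertools.combinations(range(9), 5):
                x = pooled[list(idx)]
                y = pooled[[i for i in range(9) if i not in idx]]
                if u_stat(x, y) >= observed:
                    count += 1
                total += 1
            assert p == pytest.approx(count / total, abs=1e-12)

    def test_complete_separation(self):
        a = np.arange(20, 40, dtype=float)
        b = np.arange(0, 20, dtype=float)
        u, p = mannwhitney_one_sided(a, b)
        assert u == 400.0
        assert p < 1e-6


class TestReplicateCV:
    def test_cv_arithmetic(self):
        pred = np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]] * 10)
        labels = (["specific", "ubiquitous"] * 10)
        report = replicate_cv(pred, labels)
        assert report.iloc[0]["median_cv_specific"] == 0.0
        assert report.iloc[0]["median_cv_ubiquitous"] == pytest.approx(0.5)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        spec = np.column_stack([10 + rng.normal(0, 3, (20, 3))[:, i]
                                for i in range(3)])
        ubiq = np.column_stack([10 + rng.normal(0, 0.05, (20, 3))[:, i]
                                for i in range(3)])
        pred = np.vstack([spec, ubiq])
        labels = ["specific"] * 20 + ["ubiquitous"] * 20
        report = replicate_cv(pred, labels)
        assert report.iloc[0]["p"] < 1e-4

    def test_nonpositive_rows_excluded(self):
        pred = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0], [2.0, 2.0, 2.0]])
        labels = ["specific", "specific", "ubiquitous"]
        report = replicate_cv(pred, labels)
        assert report.iloc[0]["n_excluded_nonpositive_mean"] == 1
        assert report.iloc[0]["n_specific"] == 1

    def test_bh_adjust_bounds(self):
        table = pd.DataFrame({"p": [0.001, 0.02, 0.5, 1.0]})
        out = bh_adjust(table)
        assert (out["q"] >= out["p"] - 1e-12).all()
        assert (out["q"] <= 1.0).all()


class TestReplicateConcordance:
    def test_identical_tracks(self):
        h = np.arange(30, dtype=float)
        t = replicate_concordance(h, h, ["s"] * 30)
        assert t.iloc[0]["value"] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(6)
        t = replicate_concordance(rng.normal(size=500), rng.normal(size=500),
                                  ["s"] * 500)
        assert abs(t.iloc[0]["value"]) < 0.15

    def test_simulated_replicates_mild_specificity_effect(self, small_sim):
        """Between-replicate concordance decreases only mildly for specific
        peaks relative to ubiquitous ones."""
        truth = small_sim["truth"]
        tracks = {str(t.track_id): t for t in small_sim["tracks"]}
        a, b = tracks["ct1|rep0|ind0"], tracks["ct1|rep1|ind0"]
        heights_a, heights_b, strata = [], [], []
        for p in truth.peaks:
            b0, b1 = p.start // 128, p.end // 128
            heights_a.append(a.counts[p.chrom][b0:b1].mean())
            heights_b.append(b.counts[p.chrom][b0:b1].mean())
            strata.append("ubiquitous" if p.label == "ubiquitous" else "specific")
        t = stratified_pearson(np.asarray(heights_a)[:, None],
                               np.asarray(heights_b)[:, None], strata,
                               tracks=["pair"])
        r_ub = _cell(t, "pair", "ubiquitous", "pearson_r")["value"]
        r_sp = _cell(t, "pair", "specific", "pearson_r")["value"]
        assert r_ub >= r_sp - 0.15


class TestTssStratify:
    def test_zero_distance_first_bin(self):
        rows = [("c", 100, 200)] + [("c", 1000 * i, 1000 * i + 100)
                                    for i in range(2, 12)]
        tss = [("c", 150)]
        labels, dists, _ = tss_stratify(rows, tss)
        assert dists[0] == 0
        assert labels[0] == "tss_bin1"

    def test_nine_distinct_distances_equal_bins(self):
        rows = [("c", 100 * i, 100 * i + 10) for i in range(1, 10)]
        labels, _, _ = tss_stratify(rows, [("c", 0)])
        from collections import Counter
        assert sorted(Counter(labels).values()) == [3, 3, 3]

    def test_tertile_edges_match_percentile_oracle(self):
        rng = np.random.default_rng(7)
        rows = [("c", int(p), int(p) + 10) for p in
                rng.integers(100, 100_000, 50)]
        labels, dists, edges = tss_stratify(rows, [("c", 0)])
        np.testing.assert_allclose(edges,
                                   np.percentile(dists, [100 / 3, 200 / 3]),
                                   rtol=1e-9)

    def test_requires_tss(self):
        with pytest.raises(ValueError):
            tss_stratify([("c", 0, 10)], [])


class TestPrecisionTopCelltypes:
    def test_perfect_ranking(self):
        pred = np.array([[5.0, 1.0, 1.0, 1.0]])
        truth = np.array([[True, False, False, False]])
        per_row, mean = precision_top_celltypes(pred, truth, k=1)
        assert mean == 1.0

    def test_wrong_top_gives_zero(self):
        pred = np.array([[1.0, 5.0, 1.0, 1.0]])
        truth = np.array([[True, False, False, False]])
        _, mean = precision_top_celltypes(pred, truth, k=1)
        assert mean == 0.0

    def test_random_scores_expectation_quarter(self):
        rng = np.random.default_rng(8)
        n = 10_000
        pred = rng.normal(size=(n, 4))
        truth = np.zeros((n, 4), bool)
        truth[np.arange(n), rng.integers(0, 4, n)] = True
        _, mean = precision_top_celltypes(pred, truth, k=1)
        assert abs(mean - 0.25) < 0.02

    def test_k_validation(self):
        with pytest.raises(ValueError):
            precision_top_celltypes(np.ones((2, 3)), np.ones((2, 3), bool), k=4)
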