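"""Poisson peak calling, presence matrix, specificity schemes and peak
sequence annotations, each checked against brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from ctsbench.peakcall import (LOW_SPECIFICITY_LABEL, NONPEAK_LABEL,
                               PresenceMatrix, SpecificityScheme,
                               assign_specificity_bins, build_presence_matrix,
                               call_peaks, call_peaks_all, cpg_island_flag,
                               define_tissue_peaks, estimate_global_lambda,
                               gc_content, match_by_height, motif_enrichment)
from ctsbench.pwm import random_pwm
from ctsbench.synthetic import BinnedTrack, TrackId


def _track(counts, bin_size=128, tid=None):
    return BinnedTrack(tid or TrackId("ct", 0, 0),
                       {"c1": np.asarray(counts)}, bin_size)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def poisson_upper_tail(x: int, lam: float) -> float:
    """P(X >= x) by explicit pmf summation from x upward (no cancellation)."""
    if x <= 0:
        return 1.0
    return min(1.0, sum_tail(x, lam))


def sum_tail(x: int, lam: float) -> float:
    term = math.exp(-lam)
    for k in range(1, x + 1):
        term *= lam / k
    total, k = term, x
    while term > total * 1e-18:
        k += 1
        term *= lam / k
        total += term
    return total


def textbook_bh(pvals):
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, pvals[idx] * m / rank)
        q[idx] = running
    return q


class TestCallPeaks:
    def test_lambda_is_mean(self):
        assert estimate_global_lambda(_track([1, 2, 3])) == 2.0
        assert estimate_global_lambda(_track([0, 0, 0, 0, 20])) == 4.0

    def test_all_zero_track_floors_lambda(self):
        lam = estimate_global_lambda(_track([0, 0, 0]))
        assert lam == pytest.approx(1e-8)
        res = call_peaks(_track([0, 0, 0]), lam)
        assert (res.pvalues["c1"] == 1.0).all()
        assert not res.is_peak["c1"].any()

    def test_zero_count_never_a_peak(self):
        res = call_peaks(_track([0, 50, 0, 0]), lam=2.0)
        assert res.pvalues["c1"][0] == 1.0
        assert not res.is_peak["c1"][0]

    def test_single_extreme_bin(self):
        res = call_peaks(_track([10]), lam=1.0)
        expected = sum_tail(10, 1.0)   # ~1.1e-7
        assert res.pvalues["c1"][0] == pytest.approx(expected, rel=1e-9)
        assert res.qvalues["c1"][0] == pytest.approx(expected, rel=1e-9)
        assert res.is_peak["c1"][0]

    def test_hand_computed_bh_example(self):
        counts = [1, 1, 1, 1, 1, 40]
        lam = np.mean(counts)
        res = call_peaks(_track(counts), lam=lam, alpha=0.01)
        assert res.is_peak["c1"].sum() == 1
        assert res.is_peak["c1"][5]

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            call_peaks(_track([1, 2]), lam=1.0, alpha=1.5)

    def test_oracle_equivalence_random_bins(self):
        """(p, q, is_peak) match an independent tail-sum + textbook-BH oracle."""
        rng = np.random.default_rng(0)
        for lam in (0.5, 4.2, 11.0):
            counts = rng.poisson(lam, size=2000)
            counts[rng.choice(2000, 20, replace=False)] += rng.integers(10, 40, 20)
            res = call_peaks(_track(counts), lam=lam, alpha=0.01)
            p_oracle = np.array([poisson_upper_tail(int(x), lam) for x in counts])
            q_oracle = textbook_bh(p_oracle)
            np.testing.assert_allclose(res.pvalues["c1"], p_oracle, rtol=1e-10)
            np.testing.assert_allclose(res.qvalues["c1"], q_oracle, rtol=1e-10)
            np.testing.assert_array_equal(res.is_peak["c1"], q_oracle <= 0.01)

    def test_bh_monotonicity_invariant(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, 500)
        res = call_peaks(_track(counts), lam=3.0)
        p, q = res.pvalues["c1"], res.qvalues["c1"]
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_recovery_on_seeded_simulation(self):
        """lambda0=5 with intensity >= 15 gives recall >= 0.95 at FDR <= 0.05."""
        from ctsbench.synthetic import (SimConfig, make_grammar,
                                        simulate_coverage,
                                        simulate_genome_and_peaks)
        rng = np.random.default_rng(2)
        pwms = [random_pwm(f"M{i}", 8, rng) for i in range(4)]
        cfg = SimConfig(n_cell_types=1, chrom_lengths={"c1": 1_000_000,
                                                       "c2": 1_000_000},
                        n_ubiquitous=0, n_specific_per_type=200,
                        depth_lambda0=5.0, overdispersion=0.0,
                        peak_intensity_mean=30.0, intensity_residual_sigma=0.2,
                        n_replicates=1, n_individuals=1, scale_sigma=0.0, seed=3)
        g = make_grammar(1, pwms, 1, 1, seed=3)
        genome, truth = simulate_genome_and_peaks(cfg, g)
        for p in truth.peaks:   # enforce the stated minimum intensity
            p.intensity = {c: max(v, 15.0) for c, v in p.intensity.items()}
        track = simulate_coverage(genome, truth, cfg)[0]
        res = call_peaks(track, estimate_global_lambda(track), alpha=0.01)
        full, partial = set(), set()
        for p in truth.peaks:
            for b in range(p.start // 128, p.end // 128 + 1):
                seg = (b * 128, (b + 1) * 128)
                if seg[0] >= p.start and seg[1] <= p.end:
                    full.add((p.chrom, b))
                elif seg[0] < p.end and seg[1] > p.start:
                    partial.add((p.chrom, b))
        called = {(c, b) for c in res.chroms
                  for b in np.flatnonzero(res.is_peak[c])}
        recall = len(called & full) / len(full)
        fp = {cb for cb in called if cb not in full and cb not in partial}
        fdr = len(fp) / max(len(called), 1)
        assert recall >= 0.95
        assert fdr <= 0.05


class TestPresenceMatrix:
    def _result(self, flags, counts=None, tid=None):
        n = len(flags)
        counts = np.asarray(counts if counts is not None else flags, float)
        track = _track(counts, tid=tid)
        res = call_peaks(track, lam=1.0)
        res.is_peak = {"c1": np.asarray(flags, bool)}
        return res

    def test_merge_adjacent_runs(self):
        flags = np.zeros(12, bool)
        flags[[5, 6, 9]] = True
        res = self._result(flags)
        m = build_presence_matrix([res], collapse="merge_adjacent")
        assert [(r[1] // 128, r[2] // 128) for r in m.rows] == [(5, 7), (9, 10)]

    def test_all_tracks_same_bin_gives_full_N(self):
        results = [self._result(np.eye(1, 8, 3)[0].astype(bool),
                                tid=TrackId("ct", r, 0)) for r in range(4)]
        m = build_presence_matrix(results, collapse="per_bin")
        assert m.N[3] == 4
        assert m.N.sum() == 4

    def test_N_equals_row_sums_random_matrix(self):
        rng = np.random.default_rng(3)
        flags = rng.random((6, 20)) < 0.3
        results = [self._result(flags[t], tid=TrackId("ct", t, 0))
                   for t in range(6)]
        m = build_presence_matrix(results, collapse="per_bin")
        np.testing.assert_array_equal(m.N, flags.sum(axis=0))
        # conservation: sum of N equals total number of calls
        assert m.N.sum() == flags.sum()

    def test_mismatched_grids_rejected(self):
        a = self._result([True, False, True])
        b = self._result([True, False])
        with pytest.raises(ValueError, match="grid"):
            build_presence_matrix([a, b])


class TestSpecificityScheme:
    def scheme(self):
        return SpecificityScheme(edges=[1, 2, 11, 301, 1000],
                                 labels=["1", "2-10", "11-300", ">300"],
                                 low_threshold=300)

    def test_low_specificity_rule_above_300(self):
        assert self.scheme().label_for(301) == LOW_SPECIFICITY_LABEL
        assert self.scheme().label_for(300) == "11-300"

    def test_most_specific_and_nonpeak(self):
        assert self.scheme().label_for(1) == "1"
        assert self.scheme().label_for(0) == NONPEAK_LABEL

    def test_assignment_over_matrix(self):
        m = PresenceMatrix(rows=[("c", 0, 128)] * 3,
                           track_ids=list(range(400)),
                           presence=np.zeros((3, 400), bool),
                           heights=np.zeros((3, 400)))
        m.presence[0, :1] = True
        m.presence[1, :305] = True
        labels = assign_specificity_bins(m, self.scheme())
        assert labels == ["1", LOW_SPECIFICITY_LABEL, NONPEAK_LABEL]


class TestTissuePeaks:
    def _matrix(self, presence):
        presence = np.asarray(presence, bool)
        return PresenceMatrix(rows=[("c", i * 128, (i + 1) * 128)
                                    for i in range(presence.shape[0])],
                              track_ids=list(range(presence.shape[1])),
                              presence=presence,
                              heights=presence.astype(float))

    def test_thirty_percent_rule(self):
        presence = np.zeros((2, 10), bool)
        presence[0, :3] = True     # 3 of 10 tissue tracks -> tissue peak
        presence[1, :2] = True     # 2 of 10 -> not
        m = self._matrix(presence)
        rows, _, _ = define_tissue_peaks(m, list(range(10)), fraction=0.3)
        assert rows.tolist() == [0]

    def test_median_split_halves(self):
        presence = np.zeros((4, 500), bool)
        for i, n in enumerate([2, 5, 100, 400]):
            presence[i, :n] = True
        m = self._matrix(presence)
        rows, high, low = define_tissue_peaks(m, list(range(2)), fraction=0.0001)
        assert rows.tolist() == [0, 1, 2, 3]
        assert high.tolist() == [0, 1]
        assert low.tolist() == [2, 3]

    def test_empty_subset_error(self):
        m = self._matrix(np.ones((2, 4), bool))
        with pytest.raises(ValueError):
            define_tissue_peaks(m, [])


class TestSequenceAnnotations:
    def test_cpg_island_hand_counts(self):
        assert cpg_island_flag("CGCGCGCGCG") is True       # ratio 5/2.5 = 2
        assert cpg_island_flag("ATATATATAT") is False      # GC = 0
        assert cpg_island_flag("GGGGGCCCCC") is False      # observed CG = 0
        assert gc_content("CGCGCGCGCG") == 1.0
        assert gc_content("ATGC") == 0.5

    def test_cpg_n_positions_excluded(self):
        assert cpg_island_flag("NNNN" + "CG" * 10) is True

    def test_match_by_height_nearest(self):
        matched = match_by_height(np.array([10.0]), np.array([9.0, 50.0]))
        assert matched.tolist() == [0]

    def test_match_by_height_permutation_on_identical_multisets(self):
        heights = np.array([3.0, 1.0, 2.0])
        matched = match_by_height(heights, np.array([1.0, 2.0, 3.0]))
        assert sorted(matched.tolist()) == [0, 1, 2]

    def test_match_by_height_reduces_ks_distance(self):
        rng = np.random.default_rng(4)
        specific = rng.lognormal(2.5, 0.5, 80)
        ubiquitous = rng.lognormal(3.2, 0.5, 300)
        matched = ubiquitous[match_by_height(specific, ubiquitous)]
        ks_before = stats.ks_2samp(specific, ubiquitous).statistic
        ks_after = stats.ks_2samp(specific, matched).statistic
        assert ks_after < ks_before

    def test_match_by_height_size_error(self):
        with pytest.raises(ValueError):
            match_by_height(np.arange(3.0), np.arange(2.0))


@pytest.fixture(scope="module")
def enrichment_pwm():
    rng = np.random.default_rng(5)
    return random_pwm("planted", 8, rng, min_dominant=0.9)


class TestMotifEnrichment:

    def _random_seqs(self, n, length, seed):
        rng = np.random.default_rng(seed)
        return ["".join(rng.choice(list("ACGT"), length)) for _ in range(n)]

    def test_perfect_separation(self, enrichment_pwm):
        pwm = enrichment_pwm
        bg = self._random_seqs(50, 60, 6)
        cons = pwm.consensus()
        fg = [s[:20] + cons + s[28:] for s in self._random_seqs(50, 60, 7)]
        table = motif_enrichment(fg, bg, [pwm], logodds_threshold=8.0)
        row = table.iloc[0]
        expected_p = stats.fisher_exact([[50, 0], [0, 50]],
                                        alternative="greater")[1]
        assert row["fg_hit_rate"] == 1.0 and row["bg_hit_rate"] == 0.0
        assert np.isinf(row["odds_ratio"])
        assert row["p"] == pytest.approx(expected_p, rel=1e-9)

    def test_identical_sets_null(self, enrichment_pwm):
        pwm = enrichment_pwm
        seqs = self._random_seqs(30, 60, 8)
        table = motif_enrichment(seqs, seqs, [pwm], logodds_threshold=np.inf)
        assert table.iloc[0]["odds_ratio"] == 1.0
        assert table.iloc[0]["p"] == 1.0

    def test_infinite_threshold_no_hits(self, enrichment_pwm):
        pwm = enrichment_pwm
        fg = self._random_seqs(20, 60, 9)
        bg = self._random_seqs(20, 60, 10)
        table = motif_enrichment(fg, bg, [pwm], logodds_threshold=np.inf)
        assert table.iloc[0]["fg_hit_rate"] == 0.0
        assert table.iloc[0]["p"] == 1.0

    def test_empty_inputs_rejected(self, enrichment_pwm):
        pwm = enrichment_pwm
        with pytest.raises(ValueError):
            motif_enrichment([], ["ACGT"], [pwm], 0.0)
        with pytest.raises(ValueError):
            motif_enrichment(["ACGT"], ["ACGT"], [], 0.0)
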