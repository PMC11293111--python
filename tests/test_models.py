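"""CNN model zoo: encoding, training sets, splits, capacity scaling,
training dynamics, ensembled prediction and transfer learning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctsbench import models as M
from ctsbench import nn


@pytest.fixture(scope="module")
def tiny_genome():
    rng = np.random.default_rng(0)
    return {f"c{i}": "".join(rng.choice(list("ACGT"), 4000)) for i in range(1, 7)}


def _flat_coverage(genome, cell_types, value=3.0, bin_size=128):
    return {ct: {c: np.full(len(s) // bin_size, value) for c, s in genome.items()}
            for ct in cell_types}


class TestOneHot:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=64))
    def test_round_trip(self, seq):
        assert M.decode_one_hot(M.one_hot(seq)) == seq

    def test_columns_sum_to_one_or_zero_for_N(self):
        mat = M.one_hot("ACGNT")
        assert mat.sum(axis=0).tolist() == [1, 1, 1, 0, 1]


class TestTrainingSets:
    def _peaks(self, genome, n=12, width=384):
        peaks = []
        chroms = sorted(genome)
        for i in range(n):
            chrom = chroms[i % len(chroms)]
            start = 600 + (i // len(chroms)) * 1200
            label = "ubiquitous" if i % 3 == 0 else f"specific:ct{i % 2 + 1}"
            peaks.append((chrom, start, start + width, label))
        return peaks

    def test_peaks_only_count(self, tiny_genome):
        peaks = self._peaks(tiny_genome)
        cov = _flat_coverage(tiny_genome, ["ct1"])
        spec = M.TrainingSetSpec(mode="peaks_only")
        out = M.build_training_set(tiny_genome, peaks, cov, ["ct1"], spec, 256, 128)
        assert len(out) == len(peaks)
        assert all(ex.is_peak for ex in out)

    def test_equal_nonpeaks_half_off_peak(self, tiny_genome):
        peaks = self._peaks(tiny_genome)
        cov = _flat_coverage(tiny_genome, ["ct1"])
        spec = M.TrainingSetSpec(mode="peaks_plus_equal_nonpeaks", seed=1)
        out = M.build_training_set(tiny_genome, peaks, cov, ["ct1"], spec, 256, 128)
        assert len(out) == 2 * len(peaks)
        nonpeak = [ex for ex in out if not ex.is_peak]
        assert len(nonpeak) == len(peaks)
        for ex in nonpeak:
            assert not any(p[0] == ex.chrom and p[1] < ex.end and ex.start < p[2]
                           for p in peaks)

    def test_gc_matched_histogram(self, tiny_genome):
        peaks = self._peaks(tiny_genome)
        cov = _flat_coverage(tiny_genome, ["ct1"])
        spec = M.TrainingSetSpec(mode="peaks_plus_gc_matched_nonpeaks", seed=2)
        out = M.build_training_set(tiny_genome, peaks, cov, ["ct1"], spec, 256, 128)
        from collections import Counter
        want = Counter(M._gc_bin(ex.seq) for ex in out if ex.is_peak)
        got = Counter(M._gc_bin(ex.seq) for ex in out if not ex.is_peak)
        for b in set(want) | set(got):
            assert abs(want.get(b, 0) - got.get(b, 0)) <= 1

    def test_nonubiquitous_mode_drops_ubiquitous(self, tiny_genome):
        peaks = self._peaks(tiny_genome)
        cov = _flat_coverage(tiny_genome, ["ct1"])
        spec = M.TrainingSetSpec(mode="nonubiquitous_peaks_only")
        out = M.build_training_set(tiny_genome, peaks, cov, ["ct1"], spec, 256, 128)
        n_nonub = sum(1 for p in peaks if p[3] != "ubiquitous")
        assert len(out) == n_nonub
        assert all(ex.label != "ubiquitous" for ex in out)

    def test_all_genomic_tiles(self, tiny_genome):
        cov = _flat_coverage(tiny_genome, ["ct1"])
        spec = M.TrainingSetSpec(mode="all_genomic", stride=1000)
        out = M.build_training_set(tiny_genome, [], cov, ["ct1"], spec, 256, 128)
        assert len(out) > 0
        assert all(ex.end - ex.start == 256 for ex in out)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            M.TrainingSetSpec(mode="bogus")


class TestSplit:
    def _examples(self):
        return [M.SequenceExample(c, 0, 4, "ACGT", np.zeros(1))
                for c in ["c1", "c2", "c3", "c4", "c5", "c6"]]

    def test_partition(self):
        train, val, test = M.split_by_chromosome(self._examples(), ["c2"], ["c3"])
        assert [ex.chrom for ex in train] == ["c1", "c4", "c5", "c6"]
        assert [ex.chrom for ex in val] == ["c2"]
        assert [ex.chrom for ex in test] == ["c3"]

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="both"):
            M.split_by_chromosome(self._examples(), ["c2"], ["c2", "c3"])

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError):
            M.split_by_chromosome(self._examples(), ["c2"], [])

    def test_paper_default_split_constants(self):
        assert M.DEFAULT_VAL_CHROMS == ["chr7", "chr14", "chr15"]
        assert M.DEFAULT_TEST_CHROMS == ["chr4", "chr5"]
        assert M.DEFAULT_INPUT_LENGTH == 1344


class TestCapacityScaling:
    def test_parameter_count_within_ten_percent_of_m(self):
        base = M.parameter_count(M.ModelSpec(tasks=list("abcd"), capacity=1,
                                             input_length=256))
        for m in (2, 4, 8):
            count = M.parameter_count(M.ModelSpec(tasks=list("abcd"), capacity=m,
                                                  input_length=256))
            assert 0.9 * m <= count / base <= 1.1 * m

    def test_invalid_capacity_rejected(self):
        with pytest.raises(ValueError):
            M.ModelSpec(tasks=["a"], capacity=3)


class TestPoissonLoss:
    def test_minimized_at_target(self):
        y = 3.7
        grid = np.linspace(0.5, 20, 200)
        losses = [nn.poisson_loss(np.array([[g]]), np.array([[y]])) for g in grid]
        assert abs(grid[int(np.argmin(losses))] - y) < 0.1

    def test_rejects_nonpositive_predictions(self):
        with pytest.raises(ValueError):
            nn.poisson_loss(np.array([[0.0]]), np.array([[1.0]]))


def _toy_examples(n, seed, tasks=1):
    """Motif-planted toy dataset: high target iff the motif is present."""
    rng = np.random.default_rng(seed)
    motif = "ACGTAGCA"
    out = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGT"), 128))
        if i % 2 == 0:
            off = int(rng.integers(16, 100))
            seq = seq[:off] + motif + seq[off + 8:]
        y = np.full(tasks, 40.0 if i % 2 == 0 else 5.0)
        out.append(M.SequenceExample("c1", 0, 128, seq, y))
    return out


def _toy_spec(tasks=("t",), seed=0):
    return M.ModelSpec(tasks=list(tasks), capacity=1, input_length=128,
                       conv_channels=(16, 8, 8, 8, 8, 8, 8, 8),
                       conv_pools=(2, 2, 2, 2, 2, 2, 1, 1),
                       fc_units=8, seed=seed)


class TestTraining:
    def test_loss_decreases_all_replicates(self):
        examples = _toy_examples(200, seed=1)
        ens = M.train(_toy_spec(), examples, examples[:40], epochs=20,
                      patience=20, replicate_seeds=(0, 1, 2), lr=1e-2,
                      rc_augment=False)
        for hist in ens.histories:
            assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_deterministic_given_seeds(self):
        examples = _toy_examples(80, seed=2)
        kwargs = dict(epochs=3, patience=3, replicate_seeds=(7,), lr=1e-2)
        a = M.train(_toy_spec(), examples, examples[:20], **kwargs)
        b = M.train(_toy_spec(), examples, examples[:20], **kwargs)
        for wa, wb in zip(a.models[0].get_weights(), b.models[0].get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_replicate_count_enforced(self):
        spec = _toy_spec()
        model = M.build_model(spec)
        with pytest.raises(ValueError):
            M.TrainedEnsemble(spec, [model], [{}], (0, 1))


class TestPredict:
    def test_rc_shift_equals_plain_for_constant_model(self):
        spec = _toy_spec()
        model = M.build_model(spec)
        # zero the final dense weights -> constant output
        head = [l for l in model.layers if isinstance(l, nn.Dense)][-1]
        head.W[...] = 0.0
        head.b[...] = 1.3
        X = M.one_hot_batch(["ACGT" * 32, "TTTT" * 32])
        plain = M.predict_model(model, X, "plain")
        ens = M.predict_model(model, X, "rc_shift")
        np.testing.assert_allclose(plain, ens, rtol=1e-6)
        np.testing.assert_allclose(plain, np.log1p(np.exp(1.3)), rtol=1e-5)

    def test_rc_shift_is_mean_of_six_members(self):
        spec = _toy_spec(seed=3)
        model = M.build_model(spec)
        X = M.one_hot_batch(["ACGTACGT" * 16])
        members = []
        for s in (-1, 0, 1):
            Xs = M._shift(X, s)
            members.append(M.predict_model(model, Xs, "plain"))
            members.append(M.predict_model(model, M._rc(Xs), "plain"))
        np.testing.assert_allclose(M.predict_model(model, X, "rc_shift"),
                                   np.mean(members, axis=0), rtol=1e-5)

    def test_wrong_shape_rejected(self):
        model = M.build_model(_toy_spec())
        with pytest.raises(ValueError):
            M.predict_model(model, np.zeros((2, 3, 128)))

    def test_ensemble_mean_and_members(self):
        examples = _toy_examples(40, seed=4)
        ens = M.train(_toy_spec(), examples, examples[:10], epochs=1,
                      patience=1, replicate_seeds=(0, 1, 2))
        X = M.one_hot_batch([ex.seq for ex in examples[:5]])
        mean, per = M.predict_ensemble(ens, X)
        assert per.shape[0] == 3
        np.testing.assert_allclose(mean, per.mean(axis=0), rtol=1e-6)


class TestTransfer:
    def test_head_reinit_changes_only_final_layer(self):
        spec = _toy_spec(seed=5)
        pre = M.build_model(spec, init_seed=1)
        new = M.transfer_init(pre, spec, head_seed=9)
        src, dst = pre.params(), new.params()
        for s, d in zip(src[:-2], dst[:-2]):
            np.testing.assert_array_equal(s, d)
        assert not np.array_equal(src[-2], dst[-2])

    def test_finetune_same_task_does_not_regress(self):
        examples = _toy_examples(120, seed=6)
        val = examples[:30]
        ens = M.train(_toy_spec(seed=6), examples, val, epochs=8, patience=8,
                      replicate_seeds=(0,), lr=1e-2, rc_augment=False)
        pre_val = ens.histories[0]["best_val_loss"]
        model, hist = M.transfer_finetune(ens.models[0], _toy_spec(seed=6),
                                          examples, val, epochs=8, patience=8,
                                          lr=1e-3, head_seed=2)
        assert hist["best_val_loss"] <= pre_val + 0.5

    def test_shape_mismatch_rejected(self):
        pre = M.build_model(_toy_spec(seed=7))
        other = M.ModelSpec(tasks=["t"], capacity=1, input_length=128,
                            conv_channels=(8, 8, 8, 8, 8, 8, 8, 8),
                            conv_pools=(2, 2, 2, 2, 2, 2, 1, 1), fc_units=8)
        with pytest.raises(ValueError):
            M.transfer_init(pre, other)

    def test_seeded_finetune_reproducible(self):
        examples = _toy_examples(60, seed=8)
        pre = M.build_model(_toy_spec(seed=8))
        a, _ = M.transfer_finetune(pre, _toy_spec(seed=8), examples,
                                   examples[:15], epochs=2, head_seed=3)
        b, _ = M.transfer_finetune(pre, _toy_spec(seed=8), examples,
                                   examples[:15], epochs=2, head_seed=3)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)
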