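"""Accessibility CNN zoo: training sets, chromosome splits, training, prediction.

Models map one-hot DNA windows to per-cell-type continuous accessibility
(normalized read counts in the window's central bins) through a Basset-style
stack of 8 convolutional layers and 2 fully connected layers with a softplus
head, trained with the Poisson regression loss. Capacity-scaled variants
multiply every layer width by a solved factor so total parameter count grows
~m-fold.
Three seed replicates per configuration quantify training variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .synthetic import BinnedTrack

VALID_MODES = ("all_genomic", "peaks_plus_equal_nonpeaks",
               "peaks_plus_gc_matched_nonpeaks", "peaks_only",
               "nonubiquitous_peaks_only")

_COMPLEMENT = np.array([3, 2, 1, 0])


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

def one_hot(seq: str) -> np.ndarray:
    """(4, L) one-hot in ACGT order; N (or any other char) -> zero column."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros((4, len(arr)), dtype=np.float32)
    for i, base in enumerate("ACGT"):
        out[i, arr == ord(base)] = 1.0
    return out


def decode_one_hot(mat: np.ndarray) -> str:
    mat = np.asarray(mat)
    idx = mat.argmax(axis=0)
    present = mat.sum(axis=0) > 0
    return "".join("ACGT"[i] if ok else "N" for i, ok in zip(idx, present))


def one_hot_batch(seqs: list[str]) -> np.ndarray:
    return np.stack([one_hot(s) for s in seqs])


# ---------------------------------------------------------------------------
# Targets: normalized coverage
# ---------------------------------------------------------------------------

def normalized_celltype_coverage(tracks: list[BinnedTrack], cell_types: list[str],
                                 scale_total: float = 1e6,
                                 squash_exponent: float = 0.75) -> dict:
    """Normalized accessibility per cell type: counts-per-`scale_total` per
    track, averaged over the cell type's tracks, then power-squashed
    (default exponent 0.75) to damp the heavy upper tail of peak heights
    before Poisson-loss training. All targets and reference evaluations use
    this one scale."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for ct in cell_types:
        members = [t for t in tracks if t.track_id.cell_type == ct]
        if not members:
            raise ValueError(f"no tracks for cell type {ct!r}")
        acc: dict[str, np.ndarray] = {}
        for t in members:
            total = sum(float(a.sum()) for a in t.counts.values())
            for chrom, arr in t.counts.items():
                norm = arr * (scale_total / max(total, 1.0))
                acc[chrom] = acc.get(chrom, 0) + norm
        out[ct] = {c: (a / len(members)) ** squash_exponent for c, a in acc.items()}
    return out


def window_target(cov: dict[str, np.ndarray], chrom: str, start: int, L: int,
                  bin_size: int) -> float:
    """Mean normalized count over the window's central two-bin-wide segment.

    The segment [mid - bin, mid + bin) need not align with the bin grid, so
    the mean is overlap-weighted; this keeps the target centred on the peak
    regardless of the peak's phase relative to the grid."""
    mid = start + L // 2
    s, e = mid - bin_size, mid + bin_size
    arr = cov[chrom]
    total = weight = 0.0
    for b in range(max(s // bin_size, 0), min((e - 1) // bin_size + 1, len(arr))):
        ov = min(e, (b + 1) * bin_size) - max(s, b * bin_size)
        total += arr[b] * ov
        weight += ov
    if weight == 0:
        raise ValueError(f"window at {chrom}:{start} outside the bin grid")
    return float(total / weight)


# ---------------------------------------------------------------------------
# Training set construction (the five training-set compositions)
# ---------------------------------------------------------------------------

@dataclass
class SequenceExample:
    chrom: str
    start: int
    end: int
    seq: str
    targets: np.ndarray           # one value per task, >= 0
    is_peak: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.float32)
        if (self.targets < 0).any():
            raise ValueError("targets must be non-negative")


@dataclass
class TrainingSetSpec:
    mode: str = "peaks_plus_equal_nonpeaks"
    stride: int = 1344            # for all_genomic tiling
    seed: int = 0
    # window-jitter augmentation: one example per shift (bp) per peak; shifts
    # must stay small enough that the central target segment remains in-peak
    jitter_shifts: tuple = (0,)

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")


def build_training_set(genome: dict, peaks: list[tuple[str, int, int, str]],
                       coverage: dict, cell_types: list[str],
                       spec: TrainingSetSpec, input_length: int,
                       bin_size: int) -> list[SequenceExample]:
    """Assemble examples per the requested training-set composition.

    ``peaks`` rows are (chrom, start, end, label); label 'ubiquitous' marks
    ubiquitously accessible rows (needed for the non-ubiquitous mode).
    """
    L = input_length
    make = lambda chrom, start, is_peak, label="": SequenceExample(
        chrom, start, start + L, genome[chrom][start:start + L],
        np.array([window_target(coverage[ct], chrom, start, L, bin_size)
                  for ct in cell_types]),
        is_peak, label)

    if spec.mode == "all_genomic":
        out = []
        for chrom in sorted(genome):
            for start in range(0, len(genome[chrom]) - L + 1, spec.stride):
                snapped = (start // bin_size) * bin_size
                out.append(make(chrom, snapped, _overlaps_any(peaks, chrom, snapped, snapped + L)))
        return out

    wanted = peaks if spec.mode != "nonubiquitous_peaks_only" else [
        p for p in peaks if p[3] != "ubiquitous"]
    peak_examples = []
    for chrom, start, end, label in wanted:
        for shift in spec.jitter_shifts:
            w_start = _snap_window(chrom, (start + end) // 2 + shift, L,
                                   bin_size, genome)
            peak_examples.append(make(chrom, w_start, True, label))

    if spec.mode in ("peaks_only", "nonubiquitous_peaks_only"):
        return peak_examples

    rng = np.random.default_rng(spec.seed)
    if spec.mode == "peaks_plus_equal_nonpeaks":
        nonpeaks = _sample_nonpeaks(genome, peaks, len(peak_examples), L, bin_size,
                                    rng, make)
    else:  # peaks_plus_gc_matched_nonpeaks
        nonpeaks = _sample_gc_matched_nonpeaks(genome, peaks, peak_examples, L,
                                               bin_size, rng, make)
    return peak_examples + nonpeaks


def _snap_window(chrom: str, center: int, L: int, bin_size: int, genome: dict) -> int:
    """Window start centred on ``center``, clipped to the chromosome."""
    return int(np.clip(center - L // 2, 0, len(genome[chrom]) - L))


def _overlaps_any(peaks, chrom, start, end) -> bool:
    return any(p[0] == chrom and p[1] < end and start < p[2] for p in peaks)


def _random_nonpeak_start(genome, peaks, L, bin_size, rng, max_tries=200):
    chroms = sorted(genome)
    lens = np.array([len(genome[c]) for c in chroms], float)
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
        n_pos = (len(genome[chrom]) - L) // bin_size
        if n_pos <= 0:
            continue
        start = int(rng.integers(0, n_pos + 1)) * bin_size
        if not _overlaps_any(peaks, chrom, start, start + L):
            return chrom, start
    return None


def _sample_nonpeaks(genome, peaks, n, L, bin_size, rng, make):
    out = []
    for _ in range(n):
        hit = _random_nonpeak_start(genome, peaks, L, bin_size, rng)
        if hit is None:
            raise ValueError(
                f"could not sample {n} non-peak windows (short by {n - len(out)}); "
                f"genome too dense with peaks")
        out.append(make(hit[0], hit[1], False))
    return out


def _gc_bin(seq: str) -> int:
    seq = seq.upper()
    n = sum(seq.count(b) for b in "ACGT")
    gc = (seq.count("G") + seq.count("C")) / max(n, 1)
    return min(int(gc / 0.02), 49)


def _sample_gc_matched_nonpeaks(genome, peaks, peak_examples, L, bin_size, rng, make):
    from collections import Counter
    need = Counter(_gc_bin(ex.seq) for ex in peak_examples)
    out = []
    tries, max_tries = 0, 2000 * len(peak_examples) + 10000
    while sum(need.values()) > 0:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"GC matching failed: still short {dict(need)} windows per GC bin")
        hit = _random_nonpeak_start(genome, peaks, L, bin_size, rng)
        if hit is None:
            continue
        ex = make(hit[0], hit[1], False)
        b = _gc_bin(ex.seq)
        if need.get(b, 0) > 0:
            need[b] -= 1
            out.append(ex)
    return out


def jitter_examples(genome: dict, coverage: dict, cell_types: list[str],
                    examples: list[SequenceExample], shifts: tuple,
                    bin_size: int) -> list[SequenceExample]:
    """Augment peak examples with shifted windows (non-peak rows pass through).

    Used on the training split only; shifts must be small enough that the
    central target segment stays inside the peak."""
    out = []
    for ex in examples:
        out.append(ex)
        if not ex.is_peak:
            continue
        L = ex.end - ex.start
        center = ex.start + L // 2
        for shift in shifts:
            if shift == 0:
                continue
            start = _snap_window(ex.chrom, center + shift, L, bin_size, genome)
            out.append(SequenceExample(
                ex.chrom, start, start + L, genome[ex.chrom][start:start + L],
                np.array([window_target(coverage[ct], ex.chrom, start, L, bin_size)
                          for ct in cell_types]),
                True, ex.label))
    return out


def split_by_chromosome(examples: list[SequenceExample], val_chroms: list[str],
                        test_chroms: list[str]):
    """Disjoint, exhaustive partition of examples by chromosome."""
    if not val_chroms or not test_chroms:
        raise ValueError("validation and test chromosome lists must be non-empty")
    overlap = set(val_chroms) & set(test_chroms)
    if overlap:
        raise ValueError(f"chromosomes in both val and test: {sorted(overlap)}")
    known = {ex.chrom for ex in examples}
    missing = (set(val_chroms) | set(test_chroms)) - known
    if missing:
        raise ValueError(f"chromosomes not present in examples: {sorted(missing)}")
    val = [ex for ex in examples if ex.chrom in val_chroms]
    test = [ex for ex in examples if ex.chrom in test_chroms]
    train = [ex for ex in examples
             if ex.chrom not in val_chroms and ex.chrom not in test_chroms]
    return train, val, test


# ---------------------------------------------------------------------------
# Model spec & construction
# ---------------------------------------------------------------------------

# Paper-scale defaults: 1344-bp windows, validation chr7/14/15, test chr4/5.
DEFAULT_INPUT_LENGTH = 1344
DEFAULT_VAL_CHROMS = ["chr7", "chr14", "chr15"]
DEFAULT_TEST_CHROMS = ["chr4", "chr5"]


@dataclass
class ModelSpec:
    tasks: list[str]
    capacity: int = 1                       # m in {1, 2, 4, 8}
    input_length: int = DEFAULT_INPUT_LENGTH
    n_conv: int = 8
    n_fc: int = 2
    conv_channels: tuple = (48, 24, 12, 6, 6, 6, 6, 6)
    conv_kernels: tuple = (11, 5, 5, 5, 3, 3, 3, 3)
    conv_pools: tuple = (4, 2, 2, 2, 2, 2, 1, 1)
    fc_units: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capacity not in (1, 2, 4, 8):
            raise ValueError(f"capacity multiplier must be in {{1,2,4,8}}, got {self.capacity}")
        if not self.tasks:
            raise ValueError("need at least one task")
        if len(self.conv_channels) != self.n_conv:
            raise ValueError("conv_channels length must equal n_conv")

    def _count_with_factor(self, s: float) -> int:
        """Closed-form parameter count when all widths are scaled by s
        (mirrors build_model: conv + BN per conv block, two dense layers
        with one BN, softplus head)."""
        channels = [max(2, round(c * s)) for c in self.conv_channels]
        fc = max(2, round(self.fc_units * s))
        total, c_in, L = 0, 4, self.input_length
        for c_out, k, p in zip(channels, self.conv_kernels, self.conv_pools):
            total += c_in * k * c_out + c_out          # conv W + b
            total += 2 * c_out                          # BN gamma/beta
            c_in = c_out
            L //= p
        total += c_in * L * fc + fc                     # dense 1
        total += 2 * fc                                 # BN
        total += fc * len(self.tasks) + len(self.tasks)  # head
        return total

    def width_factor(self) -> float:
        """Width multiplier giving ~capacity x the baseline parameter count
        (solved numerically; sqrt(m) is only exact when quadratic terms
        dominate)."""
        if self.capacity == 1:
            return 1.0
        base = self._count_with_factor(1.0)
        target = self.capacity * base
        lo, hi = 1.0, 2.0 * self.capacity
        for _ in range(60):
            mid = (lo + hi) / 2
            if self._count_with_factor(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    def scaled_channels(self) -> list[int]:
        s = self.width_factor()
        return [max(2, round(c * s)) for c in self.conv_channels]

    def scaled_fc(self) -> int:
        return max(2, round(self.fc_units * self.width_factor()))


def build_model(spec: ModelSpec, init_seed: int | None = None) -> nn.Sequential:
    rng = np.random.default_rng(spec.seed if init_seed is None else init_seed)
    layers: list[nn.Layer] = []
    channels = spec.scaled_channels()
    c_in, L = 4, spec.input_length
    for c_out, k, p in zip(channels, spec.conv_kernels, spec.conv_pools):
        # pooling directly after the convolution keeps the normalized
        # activations small; BN then ReLU as usual
        layers += [nn.Conv1d(c_in, c_out, k, rng), nn.MaxPool1d(p),
                   nn.BatchNorm(c_out), nn.ReLU()]
        c_in = c_out
        L = L // p
    if L < 1:
        raise ValueError(f"input length {spec.input_length} too short for pooling stack")
    layers[0].need_input_grad = False
    layers += [nn.Flatten(),
               nn.Dense(c_in * L, spec.scaled_fc(), rng),
               nn.BatchNorm(spec.scaled_fc()), nn.ReLU(),
               nn.Dense(spec.scaled_fc(), len(spec.tasks), rng), nn.Softplus()]
    return nn.Sequential(layers)


def parameter_count(spec: ModelSpec) -> int:
    return build_model(spec).n_params()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedEnsemble:
    spec: ModelSpec
    models: list[nn.Sequential]
    histories: list[dict]
    replicate_seeds: tuple

    def __post_init__(self) -> None:
        if len(self.models) != len(self.replicate_seeds):
            raise ValueError("one model per replicate seed required")


def _examples_to_arrays(examples: list[SequenceExample]) -> tuple[np.ndarray, np.ndarray]:
    X = one_hot_batch([ex.seq for ex in examples])
    Y = np.stack([ex.targets for ex in examples]).astype(np.float32)
    return X, Y


def fit_model(model: nn.Sequential, X: np.ndarray, Y: np.ndarray,
              X_val: np.ndarray, Y_val: np.ndarray, epochs: int = 10,
              patience: int = 2, lr: float = 3e-3, batch_size: int = 64,
              shuffle_seed: int = 0, rc_augment: bool = True,
              lr_halflife: int = 10) -> dict:
    """Minibatch Adam on the Poisson loss with early stopping on validation
    loss; with ``rc_augment`` each minibatch is reverse-complemented with
    probability one half (targets unchanged)."""
    # start the positive head near the mean target per task
    head = [l for l in model.layers if isinstance(l, nn.Dense)][-1]
    head.b[...] = np.array([nn.inverse_softplus(m) for m in
                            np.maximum(Y.mean(axis=0), 1e-3)], dtype=np.float32)
    opt = nn.Adam(model.params(), lr=lr)
    rng = np.random.default_rng(shuffle_seed)
    best_val, best_w, bad, stopped = np.inf, model.get_weights(), 0, epochs
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(epochs):
        if lr_halflife:
            opt.lr = lr * 0.5 ** (epoch // lr_halflife)
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb = X[idx]
            if rc_augment and rng.random() < 0.5:
                xb = _rc(xb)
            yhat = model.forward(xb, train=True)
            loss = nn.poisson_loss(yhat, Y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite Poisson loss at epoch {epoch}, batch {i // batch_size}: "
                    f"{loss}; reduce the learning rate")
            model.backward(nn.poisson_loss_grad(yhat, Y[idx]))
            opt.step(model.grads())
            losses.append(loss)
        val_loss = nn.poisson_loss(predict_model(model, X_val), Y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        if val_loss < best_val - 1e-6:
            best_val, best_w, bad = val_loss, model.get_weights(), 0
        else:
            bad += 1
            if bad > patience:
                stopped = epoch + 1
                break
    model.set_weights(best_w)
    history["stopped_epoch"] = stopped
    history["best_val_loss"] = float(best_val)
    return history


def train(spec: ModelSpec, train_examples: list[SequenceExample],
          val_examples: list[SequenceExample], epochs: int = 10, patience: int = 2,
          replicate_seeds: tuple = (0, 1, 2), lr: float = 3e-3,
          batch_size: int = 64, rc_augment: bool = True) -> TrainedEnsemble:
    """Train one model per replicate seed (distinct initialization + shuffling)."""
    X, Y = _examples_to_arrays(train_examples)
    Xv, Yv = _examples_to_arrays(val_examples)
    models, histories = [], []
    for seed in replicate_seeds:
        # dead-start guard: an unlucky initialization can leave the network
        # stuck at a near-constant function whose validation loss looks
        # unremarkable; such replicates are refit with a perturbed seed
        for attempt in range(3):
            salt = () if attempt == 0 else (7919 + attempt,)
            model = build_model(spec, init_seed=_mix_seed(spec.seed, seed, *salt))
            hist = fit_model(model, X, Y, Xv, Yv, epochs=epochs,
                             patience=patience, lr=lr, batch_size=batch_size,
                             rc_augment=rc_augment,
                             shuffle_seed=_mix_seed(spec.seed, seed, 1, *salt))
            preds = predict_model(model, Xv)
            rel_spread = preds.std(axis=0) / np.maximum(preds.mean(axis=0), 1e-6)
            hist["init_attempts"] = attempt + 1
            hist["degenerate"] = bool((rel_spread <= 0.01).all())
            if not hist["degenerate"]:
                break
        models.append(model)
        histories.append(hist)
    return TrainedEnsemble(spec, models, histories, tuple(replicate_seeds))


def _mix_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Prediction (plain and reverse-complement / shift ensembling)
# ---------------------------------------------------------------------------

def _rc(X: np.ndarray) -> np.ndarray:
    return X[:, _COMPLEMENT, ::-1]


def _shift(X: np.ndarray, by: int) -> np.ndarray:
    """Shift along the sequence axis, padding with zero (N) columns."""
    if by == 0:
        return X
    out = np.zeros_like(X)
    if by > 0:
        out[:, :, by:] = X[:, :, :-by]
    else:
        out[:, :, :by] = X[:, :, -by:]
    return out


def predict_model(model: nn.Sequential, X: np.ndarray, mode: str = "plain",
                  batch_size: int = 256) -> np.ndarray:
    """Predictions for a batch of one-hot windows (B, 4, L) -> (B, tasks).

    ``rc_shift`` averages the six predictions {forward, reverse complement}
    x {-1, 0, +1 nt shifts}.
    """
    if X.ndim != 3 or X.shape[1] != 4:
        raise ValueError("X must have shape (batch, 4, L)")
    if mode == "plain":
        variants = [X]
    elif mode == "rc_shift":
        variants = [f(_shift(X, s)) for s in (-1, 0, 1) for f in (lambda a: a, _rc)]
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    acc = None
    for V in variants:
        parts = [model.forward(V[i:i + batch_size])
                 for i in range(0, len(V), batch_size)]
        out = np.concatenate(parts)
        acc = out if acc is None else acc + out
    return acc / len(variants)


def predict_ensemble(ens: TrainedEnsemble, X: np.ndarray, mode: str = "plain"
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(mean over replicates, per-replicate stack of shape (R, B, tasks))."""
    per = np.stack([predict_model(m, X, mode) for m in ens.models])
    return per.mean(axis=0), per


# ---------------------------------------------------------------------------
# Transfer learning
# ---------------------------------------------------------------------------

def transfer_init(pretrained: nn.Sequential, spec: ModelSpec,
                  head_seed: int = 0) -> nn.Sequential:
    """Copy of a pretrained model with only the final head reinitialized
    (shaped for the new task count); the body weights are identical."""
    model = build_model(spec, init_seed=head_seed)
    src, dst = pretrained.params(), model.params()
    if len(src) != len(dst) or any(
            s.shape != d.shape for s, d in zip(src[:-2], dst[:-2])):
        raise ValueError("architectures differ beyond the final head")
    for s, d in zip(src[:-2], dst[:-2]):
        d[...] = s
    return model


def transfer_finetune(pretrained: nn.Sequential, spec: ModelSpec,
                      train_examples: list[SequenceExample],
                      val_examples: list[SequenceExample], epochs: int = 10,
                      patience: int = 2, lr: float = 1e-3, batch_size: int = 64,
                      head_seed: int = 0) -> tuple[nn.Sequential, dict]:
    """Fine-tune a pretrained model on a new task: the final head is
    reinitialized for the new task count, every weight is then updated."""
    model = transfer_init(pretrained, spec, head_seed)
    X, Y = _examples_to_arrays(train_examples)
    Xv, Yv = _examples_to_arrays(val_examples)
    hist = fit_model(model, X, Y, Xv, Yv, epochs=epochs, patience=patience,
                     lr=lr, batch_size=batch_size, shuffle_seed=head_seed)
    hist["provenance"] = {"finetuned_from_tasks": None, "head_seed": head_seed}
    return model, hist
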