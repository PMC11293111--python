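"""Synthetic multi-cell-type ATAC benchmark generator.

Generates a random genome with planted regulatory grammar: a set of shared
("housekeeping") motifs that drive ubiquitously accessible peaks in every
cell type, and per-cell-type private motifs that drive cell type-specific
peaks. Binned read coverage is simulated per (cell type, replicate,
individual) track with Poisson (optionally Gamma-Poisson overdispersed)
counts, and heterozygous variants are planted inside or outside motif
instances with known cell type-restricted effects.

Every quantity downstream stages estimate (peak locations, specificity,
per-cell-type intensity, variant effect sign) is therefore known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pwm import BASES, BASE_INDEX, PWM, best_hit

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryGrammar:
    """Assignment of PWMs to housekeeping (shared) and per-cell-type roles."""

    shared_motifs: list[str]
    specific_motifs: dict[str, list[str]]
    effect_sizes: dict[str, float]
    pwm_set: dict[str, PWM]

    def __post_init__(self) -> None:
        shared = set(self.shared_motifs)
        specific = {m for ms in self.specific_motifs.values() for m in ms}
        if shared & specific:
            raise ValueError(f"shared/specific motif sets overlap: {shared & specific}")
        for mid in shared | specific:
            if mid not in self.pwm_set:
                raise ValueError(f"motif {mid!r} not in pwm_set")
        for mid, eff in self.effect_sizes.items():
            if eff <= 0:
                raise ValueError(f"effect size for {mid!r} must be > 0, got {eff}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.specific_motifs)

    def motifs_for_class(self, label: str) -> list[str]:
        if label == "ubiquitous":
            return list(self.shared_motifs)
        if label.startswith("specific:"):
            return list(self.specific_motifs[label.split(":", 1)[1]])
        raise ValueError(f"unknown peak class {label!r}")

    def carriers(self, motif_id: str, cell_types: list[str]) -> list[str]:
        """Cell types whose grammar contains the motif."""
        if motif_id in self.shared_motifs:
            return list(cell_types)
        return [c for c, ms in self.specific_motifs.items() if motif_id in ms]


@dataclass
class MotifPlacement:
    pwm_id: str
    offset: int           # offset of the instance within the peak
    strand: str           # '+' or '-'
    realization: str      # planted bases, peak-strand orientation
    score: float          # log-odds of the realization under its PWM


@dataclass
class Peak:
    chrom: str
    start: int            # 0-based half-open
    end: int
    label: str            # 'ubiquitous' or 'specific:<cell type>'
    intensity: dict[str, float]   # expected reads/bin above background per cell type
    placements: list[MotifPlacement] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def specificity(self) -> int:
        return sum(1 for v in self.intensity.values() if v > 0)


@dataclass
class Variant:
    chrom: str
    pos: int              # 0-based
    ref: str
    alt: str
    delta: dict[str, float]       # true per-cell-type effect on log intensity odds
    causal: bool
    allelic_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    # track id -> (ref_reads, alt_reads)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        self.causal = any(d != 0 for d in self.delta.values())


@dataclass
class GroundTruth:
    peaks: list[Peak]
    tss: list[tuple[str, int]]
    variants: list[Variant] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)


@dataclass
class SimConfig:
    """Study conditions for one synthetic benchmark run."""

    n_cell_types: int = 4
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 1_500_000 for i in range(1, 9)})
    gc_content: float = 0.41
    n_ubiquitous: int = 1200
    n_specific_per_type: int = 450
    peak_width: int = 384
    bin_size: int = 128
    depth_lambda0: float = 5.0        # background reads/bin
    overdispersion: float = 0.1       # phi; Gamma-Poisson variance phi*mean^2
    n_replicates: int = 2
    n_individuals: int = 2
    peak_intensity_mean: float = 20.0  # reads/bin above background (class mean)
    shared_motif_copies: int = 2       # instances of each shared motif per
                                       # ubiquitous peak (promoter-like peaks
                                       # carry redundant, easily read features)
    intensity_residual_sigma: float = 0.3
    intensity_seq_coupling: float = 0.11  # gamma: log-intensity per unit motif score
    scale_sigma: float = 0.15          # per-(replicate,individual) log-normal depth
    tss_distal_fraction: float = 0.7   # fraction of specific peaks without nearby TSS
    min_peak_gap: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "n_ubiquitous", "peak_width", "bin_size",
                     "n_replicates", "n_individuals"):
            if getattr(self, name) <= 0 and not (name == "n_ubiquitous" and self.n_ubiquitous == 0):
                raise ValueError(f"{name} must be positive")
        if self.depth_lambda0 <= 0:
            raise ValueError("depth_lambda0 must be > 0")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")

    @property
    def cell_types(self) -> list[str]:
        return [f"ct{i + 1}" for i in range(self.n_cell_types)]


@dataclass(frozen=True)
class TrackId:
    cell_type: str
    replicate: int
    individual: int

    def __str__(self) -> str:
        return f"{self.cell_type}|rep{self.replicate}|ind{self.individual}"


@dataclass
class BinnedTrack:
    """Non-negative binned read counts for one (cell type, replicate, individual)."""

    track_id: TrackId
    counts: dict[str, np.ndarray]
    bin_size: int

    def __post_init__(self) -> None:
        for chrom, arr in self.counts.items():
            arr = np.asarray(arr)
            if (arr < 0).any():
                raise ValueError(f"negative counts on {chrom}")
            self.counts[chrom] = arr

    @property
    def n_bins(self) -> int:
        return sum(len(a) for a in self.counts.values())

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in sorted(self.counts)])


Genome = dict  # chrom -> str


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def make_grammar(T: int, pwms: list[PWM], n_shared: int, n_specific_per_type: int,
                 seed: int, specific_effect: float = 1.25,
                 shared_effect: float = 1.0) -> RegulatoryGrammar:
    """Randomly assign PWMs to shared and per-cell-type roles (disjoint)."""
    needed = n_shared + T * n_specific_per_type
    if len(pwms) < needed:
        raise ValueError(
            f"need at least {needed} PWMs ({n_shared} shared + "
            f"{T} x {n_specific_per_type} specific), got {len(pwms)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pwms))
    chosen = [pwms[i] for i in order[:needed]]
    shared = [p.name for p in chosen[:n_shared]]
    specific: dict[str, list[str]] = {}
    k = n_shared
    for t in range(T):
        specific[f"ct{t + 1}"] = [p.name for p in chosen[k:k + n_specific_per_type]]
        k += n_specific_per_type
    effects = {p.name: shared_effect for p in chosen[:n_shared]}
    effects.update({m: specific_effect for ms in specific.values() for m in ms})
    return RegulatoryGrammar(shared, specific, effects, {p.name: p for p in pwms})


def simulate_genome_and_peaks(cfg: SimConfig,
                              grammar: RegulatoryGrammar) -> tuple[Genome, GroundTruth]:
    """Random genome + non-overlapping truth peaks with planted motif instances."""
    rng = np.random.default_rng(cfg.seed)
    base_probs = np.array([(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
                           cfg.gc_content / 2, (1 - cfg.gc_content) / 2])
    genome_arr: dict[str, np.ndarray] = {
        chrom: rng.choice(4, size=length, p=base_probs).astype(np.int8)
        for chrom, length in cfg.chrom_lengths.items()
    }

    labels = (["ubiquitous"] * cfg.n_ubiquitous
              + [f"specific:{c}" for c in cfg.cell_types
                 for _ in range(cfg.n_specific_per_type)])
    total_needed = len(labels) * (cfg.peak_width + cfg.min_peak_gap)
    total_len = sum(cfg.chrom_lengths.values())
    if total_needed > 0.7 * total_len:
        raise ValueError(
            f"genome too small for {len(labels)} peaks of width {cfg.peak_width}: "
            f"need roughly {int(total_needed / 0.7)} bp, have {total_len} bp")

    placements = _place_intervals(cfg, rng, len(labels))
    rng.shuffle(labels)

    peaks: list[Peak] = []
    for (chrom, start), label in zip(placements, labels):
        peak = _plant_peak(genome_arr, chrom, start, label, cfg, grammar, rng)
        peaks.append(peak)
    peaks.sort(key=lambda p: (p.chrom, p.start))

    tss = _place_tss(peaks, cfg, rng)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {c: bytes(lut[arr]).decode("ascii") for c, arr in genome_arr.items()}
    return genome, GroundTruth(peaks=peaks, tss=tss, cell_types=cfg.cell_types)


def _place_intervals(cfg: SimConfig, rng: np.random.Generator,
                     n: int) -> list[tuple[str, int]]:
    """Rejection-sample non-overlapping peak starts (with a minimum gap)."""
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], float)
    probs = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[tuple[str, int]] = []
    max_tries = 200 * n + 1000
    tries = 0
    import bisect
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} peaks of width {cfg.peak_width} after "
                f"{max_tries} draws; increase genome size")
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        limit = cfg.chrom_lengths[chrom] - cfg.peak_width - cfg.min_peak_gap
        if limit <= cfg.min_peak_gap:
            continue
        start = int(rng.integers(cfg.min_peak_gap, limit))
        end = start + cfg.peak_width
        ivs = occupied[chrom]
        i = bisect.bisect_left(ivs, (start, end))
        ok = True
        if i > 0 and ivs[i - 1][1] + cfg.min_peak_gap > start:
            ok = False
        if i < len(ivs) and end + cfg.min_peak_gap > ivs[i][0]:
            ok = False
        if ok:
            bisect.insort(ivs, (start, end))
            out.append((chrom, start))
    return out


def _plant_peak(genome_arr: dict[str, np.ndarray], chrom: str, start: int, label: str,
                cfg: SimConfig, grammar: RegulatoryGrammar,
                rng: np.random.Generator) -> Peak:
    width = cfg.peak_width
    motif_ids = grammar.motifs_for_class(label)
    if label == "ubiquitous" and cfg.shared_motif_copies > 1:
        motif_ids = [m for m in motif_ids for _ in range(cfg.shared_motif_copies)]
    placements: list[MotifPlacement] = []
    used: list[tuple[int, int]] = []
    score_dev = 0.0
    effect_mult = 1.0
    for mid in motif_ids:
        pwm = grammar.pwm_set[mid]
        w = pwm.width
        lo, hi = width // 4, 3 * width // 4 - w
        for _ in range(200):
            off = int(rng.integers(lo, hi + 1))
            if all(off + w <= a or off >= b for a, b in used):
                break
        else:
            raise ValueError(f"cannot place motif {mid} in peak of width {width}")
        used.append((off, off + w))
        realization = pwm.sample(rng)
        score = pwm.score_sequence(realization)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = realization if strand == "+" else reverse_complement(realization)
        enc = np.array([BASE_INDEX[b] for b in planted], dtype=np.int8)
        genome_arr[chrom][start + off:start + off + w] = enc
        placements.append(MotifPlacement(mid, off, strand, planted, score))
        score_dev += score - pwm.expected_score()
        effect_mult *= grammar.effect_sizes[mid]

    log_mu = (math.log(cfg.peak_intensity_mean * effect_mult)
              + cfg.intensity_seq_coupling * score_dev
              + rng.normal(0.0, cfg.intensity_residual_sigma))
    value = math.exp(log_mu)
    if label == "ubiquitous":
        intensity = {c: value for c in cfg.cell_types}
    else:
        target = label.split(":", 1)[1]
        intensity = {c: (value if c == target else 0.0) for c in cfg.cell_types}
    return Peak(chrom, start, start + width, label, intensity, placements)


def _place_tss(peaks: list[Peak], cfg: SimConfig,
               rng: np.random.Generator) -> list[tuple[str, int]]:
    """TSS next to every ubiquitous peak (promoter-like) and near a configurable
    fraction of specific peaks, leaving the rest TSS-distal."""
    tss: list[tuple[str, int]] = []
    for peak in peaks:
        near = peak.label == "ubiquitous" or rng.random() > cfg.tss_distal_fraction
        if near:
            pos = peak.end + int(rng.integers(50, 500))
            pos = min(pos, cfg.chrom_lengths[peak.chrom] - 1)
            tss.append((peak.chrom, pos))
    return tss


def simulate_coverage(genome: Genome, truth: GroundTruth,
                      cfg: SimConfig) -> list[BinnedTrack]:
    """Binned Poisson / Gamma-Poisson coverage, one track per
    (cell type, replicate, individual); last partial bin dropped."""
    if cfg.overdispersion < 0 or cfg.depth_lambda0 <= 0:
        raise ValueError("need overdispersion >= 0 and depth_lambda0 > 0")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    bs = cfg.bin_size
    n_bins = {c: len(seq) // bs for c, seq in genome.items()}

    # expected in-peak contribution per bin per cell type (overlap-weighted)
    base_rate = {c: {chrom: np.zeros(n) for chrom, n in n_bins.items()}
                 for c in truth.cell_types}
    for peak in truth.peaks:
        first, last = peak.start // bs, (peak.end - 1) // bs
        for b in range(first, min(last + 1, n_bins[peak.chrom])):
            ov = (min(peak.end, (b + 1) * bs) - max(peak.start, b * bs)) / bs
            for c, val in peak.intensity.items():
                if val > 0:
                    base_rate[c][peak.chrom][b] += val * ov

    tracks: list[BinnedTrack] = []
    for c in truth.cell_types:
        for r in range(cfg.n_replicates):
            for i in range(cfg.n_individuals):
                s = float(np.exp(rng.normal(0.0, cfg.scale_sigma))) if cfg.scale_sigma > 0 else 1.0
                counts: dict[str, np.ndarray] = {}
                for chrom, n in n_bins.items():
                    rate = (cfg.depth_lambda0 + base_rate[c][chrom]) * s
                    if cfg.overdispersion > 0:
                        shape = 1.0 / cfg.overdispersion
                        rate = rng.gamma(shape, rate / shape)
                    counts[chrom] = rng.poisson(rate)
                tracks.append(BinnedTrack(TrackId(c, r, i), counts, bs))
    return tracks


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def plant_variants(truth: GroundTruth, grammar: RegulatoryGrammar, genome: Genome,
                   n_causal: int, n_neutral: int, het_depth: int, seed: int,
                   track_ids: list[TrackId] | None = None,
                   count_noise: bool = True) -> list[Variant]:
    """Heterozygous variants with known cell type-restricted effects.

    Causal variants sit inside planted motif instances; their per-cell-type
    effect is the PWM log-odds change of the substitution, applied to cell
    types whose grammar carries the motif. Neutral variants sit inside peaks
    but outside every motif instance and have zero effect everywhere.
    Per-track allelic read counts are Binomial(het_depth, sigmoid(delta_c));
    with count_noise=False the counts are the rounded binomial expectation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    instances = [(peak, pl) for peak in truth.peaks for pl in peak.placements]
    if n_causal > 0 and not instances:
        raise ValueError("no planted motif instances available for causal variants")

    variants: list[Variant] = []
    order = rng.permutation(len(instances))
    k = 0
    while len(variants) < n_causal:
        if k >= len(order):
            raise ValueError(f"only found {len(variants)} causal placements "
                             f"of {n_causal} requested")
        peak, pl = instances[order[k]]
        k += 1
        v = _causal_variant(peak, pl, grammar, genome, truth.cell_types, rng)
        if v is not None:
            variants.append(v)

    n_done = 0
    guard = 0
    while n_done < n_neutral:
        guard += 1
        if guard > 100 * n_neutral + 1000:
            raise ValueError("could not place neutral variants outside motifs")
        peak = truth.peaks[rng.integers(len(truth.peaks))]
        pos = int(rng.integers(peak.start, peak.end))
        rel = pos - peak.start
        if any(pl.offset <= rel < pl.offset + len(pl.realization)
               for pl in peak.placements):
            continue
        ref = genome[peak.chrom][pos]
        if ref not in BASES:
            continue
        alt = BASES[(BASE_INDEX[ref] + 1 + int(rng.integers(3))) % 4]
        variants.append(Variant(peak.chrom, pos, ref, alt,
                                {c: 0.0 for c in truth.cell_types}, causal=False))
        n_done += 1

    for v in variants:
        if track_ids is None:
            continue
        for tid in track_ids:
            p_alt = _sigmoid(v.delta.get(tid.cell_type, 0.0))
            if count_noise:
                alt_reads = int(rng.binomial(het_depth, p_alt))
            else:
                alt_reads = int(round(het_depth * p_alt))
            v.allelic_counts[str(tid)] = (het_depth - alt_reads, alt_reads)
    return variants


def _causal_variant(peak: Peak, pl: MotifPlacement, grammar: RegulatoryGrammar,
                    genome: Genome, cell_types: list[str],
                    rng: np.random.Generator) -> Variant | None:
    pwm = grammar.pwm_set[pl.pwm_id]
    lo = pwm.log_odds()
    col = int(rng.integers(pwm.width))
    # instance column in motif orientation
    motif_base = pl.realization if pl.strand == "+" else reverse_complement(pl.realization)
    ref_m = motif_base[col]
    ref_idx = BASE_INDEX[ref_m]
    cons = int(pwm.matrix[:, col].argmax())
    alt_idx = int(pwm.matrix[:, col].argmin()) if ref_idx == cons else cons
    if alt_idx == ref_idx:
        return None
    delta_val = float(lo[alt_idx, col] - lo[ref_idx, col])
    if delta_val == 0.0:
        return None
    # genome coordinates / strand orientation
    if pl.strand == "+":
        pos = peak.start + pl.offset + col
        ref_g, alt_g = BASES[ref_idx], BASES[alt_idx]
    else:
        pos = peak.start + pl.offset + (pwm.width - 1 - col)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref_g, alt_g = comp[BASES[ref_idx]], comp[BASES[alt_idx]]
    if genome[peak.chrom][pos] != ref_g:
        return None  # overlapping plant clobbered this instance; skip
    carriers = grammar.carriers(pl.pwm_id, cell_types)
    delta = {c: (delta_val if c in carriers and peak.intensity.get(c, 0) > 0 else 0.0)
             for c in cell_types}
    if all(d == 0 for d in delta.values()):
        return None
    return Variant(peak.chrom, pos, ref_g, alt_g, delta, causal=True)


# ---------------------------------------------------------------------------
# Recoverability oracle (used by tests and sanity checks)
# ---------------------------------------------------------------------------

def planted_motif_recovered(peak: Peak, genome: Genome, grammar: RegulatoryGrammar,
                            threshold: float = 0.0) -> bool:
    """Does a brute-force PWM scan recover >=1 planted motif above threshold?"""
    seq = genome[peak.chrom][peak.start:peak.end]
    for pl in peak.placements:
        _, score = best_hit(grammar.pwm_set[pl.pwm_id], seq)
        if score >= threshold:
            return True
    return not peak.placements
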