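"""Poisson global-null peak calling, presence matrices and specificity binning.

Peaks are called per 128-bp bin against a single genome-wide null rate
(the mean reads/bin of the track), with an upper-tail Poisson p-value and
Benjamini-Hochberg FDR control across all bins of the track; a bin is a
peak when its q-value is at most the FDR cutoff (default 0.01).

A presence matrix records, for each row (bin or merged interval), which
tracks called it; the row sum N is the cell-type specificity count used to
stratify every downstream evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pwm import PWM, scan_sequence
from .synthetic import BinnedTrack

LAMBDA_FLOOR = 1e-8
NONPEAK_LABEL = "non-peak"
LOW_SPECIFICITY_LABEL = "low specificity"


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

@dataclass
class PeakCallResult:
    track_id: object
    bin_size: int
    chroms: list[str]
    counts: dict[str, np.ndarray]
    pvalues: dict[str, np.ndarray]
    qvalues: dict[str, np.ndarray]
    is_peak: dict[str, np.ndarray]
    global_lambda: float
    fdr_threshold: float

    def concatenated(self, which: str) -> np.ndarray:
        return np.concatenate([getattr(self, which)[c] for c in self.chroms])


def estimate_global_lambda(track: BinnedTrack) -> float:
    """Global null rate: mean count over all bins, floored at 1e-8."""
    if track.n_bins == 0:
        raise ValueError("track has no bins")
    return max(float(track.concatenated().mean()), LAMBDA_FLOOR)


def call_peaks(track: BinnedTrack, lam: float, alpha: float = 0.01) -> PeakCallResult:
    """Upper-tail Poisson test per bin, BH across all bins of the track."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    chroms = sorted(track.counts)
    counts = {c: np.asarray(track.counts[c]) for c in chroms}
    x = np.concatenate([counts[c] for c in chroms])
    # P(X >= x) inclusive upper tail; x=0 -> 1 exactly
    p = stats.poisson.sf(x - 1, lam)
    p = np.clip(p, 0.0, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    peak = q <= alpha
    out_p, out_q, out_peak = {}, {}, {}
    k = 0
    for c in chroms:
        n = len(counts[c])
        out_p[c] = p[k:k + n]
        out_q[c] = q[k:k + n]
        out_peak[c] = peak[k:k + n]
        k += n
    return PeakCallResult(track.track_id, track.bin_size, chroms, counts,
                          out_p, out_q, out_peak, lam, alpha)


def call_peaks_all(tracks: list[BinnedTrack], alpha: float = 0.01) -> list[PeakCallResult]:
    return [call_peaks(t, estimate_global_lambda(t), alpha) for t in tracks]


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Rows (bins or merged peak intervals) x tracks binary calls."""

    rows: list[tuple[str, int, int]]       # (chrom, start, end) in bp, 0-based half-open
    track_ids: list[object]
    presence: np.ndarray                   # bool, rows x tracks
    heights: np.ndarray                    # float, rows x tracks (mean count over row bins)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, bool)
        self.heights = np.asarray(self.heights, float)

    @property
    def N(self) -> np.ndarray:
        """Per-row specificity count: number of tracks calling the row."""
        return self.presence.sum(axis=1)

    @property
    def n_tracks(self) -> int:
        return len(self.track_ids)


def build_presence_matrix(results: list[PeakCallResult],
                          collapse: str = "per_bin") -> PresenceMatrix:
    if not results:
        raise ValueError("no peak call results")
    ref = results[0]
    for r in results[1:]:
        if r.chroms != ref.chroms or r.bin_size != ref.bin_size or any(
                len(r.counts[c]) != len(ref.counts[c]) for c in ref.chroms):
            raise ValueError("tracks do not share a common bin grid")
    bs = ref.bin_size
    track_ids = [r.track_id for r in results]

    if collapse == "per_bin":
        rows = [(c, b * bs, (b + 1) * bs)
                for c in ref.chroms for b in range(len(ref.counts[c]))]
        presence = np.column_stack([r.concatenated("is_peak") for r in results])
        heights = np.column_stack([r.concatenated("counts") for r in results]).astype(float)
        return PresenceMatrix(rows, track_ids, presence, heights)

    if collapse == "merge_adjacent":
        rows: list[tuple[str, int, int]] = []
        presence_rows, height_rows = [], []
        for c in ref.chroms:
            union = np.zeros(len(ref.counts[c]), bool)
            for r in results:
                union |= r.is_peak[c]
            for b0, b1 in _runs(union):
                rows.append((c, b0 * bs, b1 * bs))
                presence_rows.append([r.is_peak[c][b0:b1].any() for r in results])
                height_rows.append([r.counts[c][b0:b1].mean() for r in results])
        presence = (np.array(presence_rows, bool) if presence_rows
                    else np.zeros((0, len(results)), bool))
        heights = (np.array(height_rows, float) if height_rows
                   else np.zeros((0, len(results))))
        return PresenceMatrix(rows, track_ids, presence, heights)

    raise ValueError(f"unknown collapse mode {collapse!r}")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open index ranges."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# Specificity schemes
# ---------------------------------------------------------------------------

@dataclass
class SpecificityScheme:
    """Ordered bins over the specificity count N, plus an optional override
    labelling everything above a threshold L as 'low specificity'."""

    edges: list[int]          # strictly increasing; bin i = [edges[i], edges[i+1])
    labels: list[str]
    low_threshold: int | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("need len(labels) == len(edges) - 1")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    @classmethod
    def quantile_like(cls, n_tracks: int, low_threshold: int | None = None
                      ) -> "SpecificityScheme":
        """A simple geometric binning of [1, n_tracks]."""
        edges = [1]
        while edges[-1] * 2 <= n_tracks:
            edges.append(edges[-1] * 2)
        edges.append(n_tracks + 1)
        edges = sorted(set(edges))
        labels = [f"{a}" if b == a + 1 else f"{a}-{b - 1}"
                  for a, b in zip(edges, edges[1:])]
        return cls(edges, labels, low_threshold)

    def label_for(self, n: int) -> str:
        if n == 0:
            return NONPEAK_LABEL
        if self.low_threshold is not None and n > self.low_threshold:
            return LOW_SPECIFICITY_LABEL
        for a, b, lab in zip(self.edges, self.edges[1:], self.labels):
            if a <= n < b:
                return lab
        if n >= self.edges[-1]:
            return self.labels[-1]
        raise ValueError(f"N={n} below first edge {self.edges[0]}")


def assign_specificity_bins(matrix: PresenceMatrix,
                            scheme: SpecificityScheme) -> list[str]:
    return [scheme.label_for(int(n)) for n in matrix.N]


def define_tissue_peaks(matrix: PresenceMatrix, tissue_tracks: list[object],
                        fraction: float = 0.3
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tissue peaks (called in >= fraction of the tissue's tracks) and their
    high/low cell-type-specificity halves (median split on global N;
    ties go to the low-specificity half)."""
    if not tissue_tracks:
        raise ValueError("tissue track subset is empty")
    col_idx = []
    for t in tissue_tracks:
        try:
            col_idx.append(matrix.track_ids.index(t))
        except ValueError:
            raise ValueError(f"track {t!r} not in presence matrix") from None
    import math
    need = math.ceil(fraction * len(col_idx))
    tissue_count = matrix.presence[:, col_idx].sum(axis=1)
    tissue_rows = np.flatnonzero(tissue_count >= need)
    if tissue_rows.size == 0:
        return tissue_rows, tissue_rows, tissue_rows
    n_global = matrix.N[tissue_rows]
    med = float(np.median(n_global))
    high = tissue_rows[n_global < med]    # fewer tracks -> higher specificity
    low = tissue_rows[n_global >= med]
    return tissue_rows, high, low


# ---------------------------------------------------------------------------
# Sequence-feature annotations
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def cpg_island_flag(seq: str) -> bool:
    """CpG-island rule: GC fraction > 0.5 and observed/expected CpG > 0.6,
    with expected CpG = (#C * #G) / length (N positions excluded)."""
    seq = seq.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    kept = [b for b in seq if b in "ACGT"]
    n = len(kept)
    if n < 2:
        return False
    c, g = kept.count("C"), kept.count("G")
    gc = (c + g) / n
    observed = sum(1 for a, b in zip(seq, seq[1:]) if a == "C" and b == "G")
    expected = c * g / n
    if expected == 0:
        return False
    return gc > 0.5 and observed / expected > 0.6


def match_by_height(specific_heights: np.ndarray, ubiquitous_heights: np.ndarray
                    ) -> np.ndarray:
    """Greedy nearest-height 1:1 matching without replacement.

    Returns indices into ubiquitous_heights, one per specific row, processed
    in stable input order (ties resolved to the earlier candidate).
    """
    specific_heights = np.asarray(specific_heights, float)
    ubiquitous_heights = np.asarray(ubiquitous_heights, float)
    if len(ubiquitous_heights) < len(specific_heights):
        raise ValueError(
            f"need |ubiquitous| >= |specific|, got "
            f"{len(ubiquitous_heights)} < {len(specific_heights)}")
    import bisect
    pool = sorted((float(h), i) for i, h in enumerate(ubiquitous_heights))
    chosen = []
    for h in specific_heights:
        j = bisect.bisect_left(pool, (float(h), -1))
        cands = []
        if j > 0:
            cands.append(j - 1)
        if j < len(pool):
            cands.append(j)
        best = min(cands, key=lambda k: (abs(pool[k][0] - h), pool[k][1]))
        chosen.append(pool[best][1])
        pool.pop(best)
    return np.array(chosen, dtype=int)


def motif_enrichment(fg_seqs: list[str], bg_seqs: list[str], pwms: list[PWM],
                     logodds_threshold: float):
    """Fisher-exact motif hit-rate enrichment of foreground vs background.

    A sequence is a hit for a motif when any scan position on either strand
    scores at least the threshold (log-odds vs. the background sets' base
    frequencies, pseudocount 1e-3). One 2x2 Fisher exact test (one-sided,
    enrichment) per motif, BH-corrected across motifs. Returns a DataFrame.
    """
    import pandas as pd

    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background sets must be non-empty")
    if not pwms:
        raise ValueError("no PWMs given")
    background = _base_frequencies(bg_seqs)
    rows = []
    for pwm in pwms:
        fg_hits = sum(_has_hit(pwm, s, background, logodds_threshold) for s in fg_seqs)
        bg_hits = sum(_has_hit(pwm, s, background, logodds_threshold) for s in bg_seqs)
        a, b = fg_hits, len(fg_seqs) - fg_hits
        c, d = bg_hits, len(bg_seqs) - bg_hits
        if b * c == 0:
            odds = np.inf if a * d > 0 else (1.0 if a == c and b == d else np.nan)
        else:
            odds = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"motif": pwm.name, "fg_hit_rate": a / len(fg_seqs),
                     "bg_hit_rate": c / len(bg_seqs), "odds_ratio": odds,
                     "p": float(p)})
    table = pd.DataFrame(rows)
    _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["q"] = q
    return table


def _base_frequencies(seqs: list[str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs:
        s = s.upper()
        for i, b in enumerate("ACGT"):
            counts[i] += s.count(b)
    total = counts.sum()
    return counts / total if total > 0 else np.full(4, 0.25)


def _has_hit(pwm: PWM, seq: str, background: np.ndarray, threshold: float) -> bool:
    scores = scan_sequence(pwm, seq, background, both_strands=True)
    return bool(scores.size and np.max(scores) >= threshold)
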