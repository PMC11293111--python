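"""Reference-accuracy evaluations stratified by cell-type specificity.

All metrics are reported per (track, stratum) cell with the cell's sample
size; cells with fewer than ``min_n`` rows, or with a degenerate (constant)
vector, are reported as absent rather than as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_N = 10


@dataclass
class MetricCell:
    track: str
    stratum: str
    metric: str
    value: float | None
    n: int
    reason: str = ""


def _cells_to_frame(cells: list[MetricCell]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cells])


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    return float(stats.pearsonr(a, b)[0])


def stratified_pearson(pred: np.ndarray, target: np.ndarray, strata: list[str],
                       tracks: list[str] | None = None,
                       min_n: int = DEFAULT_MIN_N, log1p: bool = False
                       ) -> pd.DataFrame:
    """Pearson R between prediction and measurement per (track, stratum).

    ``pred`` and ``target`` are rows x tracks arrays aligned row-for-row with
    ``strata``. With ``log1p`` both sides are log1p-transformed first.
    """
    pred = np.atleast_2d(np.asarray(pred, float).T).T
    target = np.atleast_2d(np.asarray(target, float).T).T
    if pred.shape != target.shape or pred.shape[0] != len(strata):
        raise ValueError("pred, target and strata must be aligned")
    if log1p:
        pred, target = np.log1p(pred), np.log1p(target)
    tracks = tracks or [f"track{i}" for i in range(pred.shape[1])]
    strata_arr = np.asarray(strata)
    cells = []
    for j, tr in enumerate(tracks):
        for s in dict.fromkeys(strata):
            idx = strata_arr == s
            n = int(idx.sum())
            if n < min_n:
                cells.append(MetricCell(tr, s, "pearson_r", None, n, "n below minimum"))
                continue
            r = _pearson(pred[idx, j], target[idx, j])
            if r is None:
                cells.append(MetricCell(tr, s, "pearson_r", None, n, "zero variance"))
            else:
                cells.append(MetricCell(tr, s, "pearson_r", r, n))
    return _cells_to_frame(cells)


def stratified_auc_auprc(scores: np.ndarray, labels: np.ndarray, strata: list[str],
                         tracks: list[str] | None = None,
                         min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    """AUROC and AUPRC of binary peak labels per (track, stratum)."""
    scores = np.atleast_2d(np.asarray(scores, float).T).T
    labels = np.atleast_2d(np.asarray(labels, int).T).T
    tracks = tracks or [f"track{i}" for i in range(scores.shape[1])]
    strata_arr = np.asarray(strata)
    cells = []
    for j, tr in enumerate(tracks):
        for s in dict.fromkeys(strata):
            idx = strata_arr == s
            n = int(idx.sum())
            y, sc = labels[idx, j], scores[idx, j]
            if n < min_n:
                reason = "n below minimum"
            elif len(np.unique(y)) < 2:
                reason = "single class"
            else:
                cells.append(MetricCell(tr, s, "auc", float(roc_auc_score(y, sc)), n))
                cells.append(MetricCell(tr, s, "auprc",
                                        float(average_precision_score(y, sc)), n))
                continue
            cells.append(MetricCell(tr, s, "auc", None, n, reason))
            cells.append(MetricCell(tr, s, "auprc", None, n, reason))
    return _cells_to_frame(cells)


def cross_celltype_correlation(matrix: np.ndarray, row_subset: np.ndarray | None = None,
                               cell_types: list[str] | None = None,
                               min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    """Pairwise Pearson R of row heights between cell-type columns.

    Returns one row per unordered cell-type pair; constant columns make the
    pair absent. Apply identically to measured and predicted matrices.
    """
    matrix = np.asarray(matrix, float)
    if matrix.shape[1] < 2:
        raise ValueError("need at least two cell types")
    if row_subset is not None:
        matrix = matrix[np.asarray(row_subset)]
    if matrix.shape[0] < min_n:
        raise ValueError(f"row subset has {matrix.shape[0]} rows < min_n={min_n}")
    cell_types = cell_types or [f"ct{i + 1}" for i in range(matrix.shape[1])]
    rows = []
    for i, j in combinations(range(matrix.shape[1]), 2):
        r = _pearson(matrix[:, i], matrix[:, j])
        rows.append({"cell_type_a": cell_types[i], "cell_type_b": cell_types[j],
                     "pearson_r": r, "n": matrix.shape[0]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Replicate variability (coefficient of variation across model replicates)
# ---------------------------------------------------------------------------

def mannwhitney_one_sided(greater: np.ndarray, lesser: np.ndarray
                          ) -> tuple[float, float]:
    """One-sided Mann-Whitney U (alternative: ``greater`` > ``lesser``).

    Exact enumeration for n <= 8 per group without ties, otherwise the
    normal approximation with tie correction.
    """
    greater, lesser = np.asarray(greater, float), np.asarray(lesser, float)
    pooled = np.concatenate([greater, lesser])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(greater) <= 8 and len(lesser) <= 8 and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(greater, lesser, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def replicate_cv(predictions: np.ndarray, group_labels: list[str],
                 specific_label: str = "specific", ubiquitous_label: str = "ubiquitous",
                 comparison_id: str = "all") -> pd.DataFrame:
    """Per-row CV over replicate predictions + one-sided test specific > ubiquitous.

    ``predictions`` is rows x replicates (>= 2 replicates). Rows with
    non-positive mean are excluded (their count is recorded).
    """
    predictions = np.asarray(predictions, float)
    if predictions.ndim != 2 or predictions.shape[1] < 2:
        raise ValueError("need a rows x replicates array with >= 2 replicates")
    means = predictions.mean(axis=1)
    ok = means > 0
    cv = np.full(len(means), np.nan)
    cv[ok] = predictions[ok].std(axis=1, ddof=1) / means[ok]
    groups = np.asarray(group_labels)
    spec_cv = cv[ok & (groups == specific_label)]
    ubiq_cv = cv[ok & (groups == ubiquitous_label)]
    if len(spec_cv) == 0 or len(ubiq_cv) == 0:
        raise ValueError("both groups must be non-empty after exclusions")
    u, p = mannwhitney_one_sided(spec_cv, ubiq_cv)
    return pd.DataFrame([{
        "comparison": comparison_id,
        "median_cv_specific": float(np.median(spec_cv)),
        "median_cv_ubiquitous": float(np.median(ubiq_cv)),
        "n_specific": len(spec_cv), "n_ubiquitous": len(ubiq_cv),
        "n_excluded_nonpositive_mean": int((~ok).sum()),
        "U": u, "p": p,
    }])


def bh_adjust(table: pd.DataFrame, p_col: str = "p", q_col: str = "q") -> pd.DataFrame:
    table = table.copy()
    _, q, _, _ = multipletests(table[p_col].to_numpy(), method="fdr_bh")
    table[q_col] = q
    return table


def replicate_concordance(heights_a: np.ndarray, heights_b: np.ndarray,
                          strata: list[str], min_n: int = DEFAULT_MIN_N,
                          pair_id: str = "pair") -> pd.DataFrame:
    """Pearson R of row heights between two paired tracks, per stratum."""
    return stratified_pearson(np.asarray(heights_a, float)[:, None],
                              np.asarray(heights_b, float)[:, None],
                              strata, tracks=[pair_id], min_n=min_n)


# ---------------------------------------------------------------------------
# TSS-distance stratification & per-peak precision
# ---------------------------------------------------------------------------

def tss_stratify(rows: list[tuple[str, int, int]], tss: list[tuple[str, int]],
                 n_bins: int = 3) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Label each row by empirical tertile (n_bins-tile) of distance to the
    nearest TSS. Returns (labels, distances, bin edges)."""
    if not tss:
        raise ValueError("need at least one TSS")
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss:
        by_chrom.setdefault(chrom, [])
    for chrom, pos in tss:
        by_chrom[chrom].append(pos)
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    dists = []
    for chrom, start, end in rows:
        mid = (start + end) // 2
        sites = by_chrom.get(chrom)
        if sites is None:
            dists.append(np.inf)
            continue
        i = np.searchsorted(sites, mid)
        cands = []
        if i > 0:
            cands.append(abs(mid - sites[i - 1]))
        if i < len(sites):
            cands.append(abs(mid - sites[i]))
        dists.append(min(cands))
    dists = np.asarray(dists, float)
    qs = np.quantile(dists, np.linspace(0, 1, n_bins + 1)[1:-1])
    labels = []
    for d in dists:
        b = int(np.searchsorted(qs, d, side="right"))
        labels.append(f"tss_bin{b + 1}")
    return labels, dists, qs


def precision_top_celltypes(pred: np.ndarray, truth_presence: np.ndarray,
                            k: int = 1) -> tuple[np.ndarray, float]:
    """Precision@k per row: fraction of the top-k predicted cell types that are
    truly present. Ties broken by cell-type index (lower index wins)."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth_presence, bool)
    if k > pred.shape[1]:
        raise ValueError(f"k={k} exceeds number of cell types {pred.shape[1]}")
    if not truth.any(axis=1).all():
        raise ValueError("every row must be present in at least one cell type")
    # stable ties: sort by (-score, index)
    order = np.lexsort((np.arange(pred.shape[1])[None, :].repeat(len(pred), 0),
                        -pred), axis=1)
    topk = order[:, :k]
    hits = np.take_along_axis(truth, topk, axis=1).sum(axis=1)
    per_row = hits / k
    return per_row, float(per_row.mean())
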