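"""Variant effect scoring and evaluation.

SAD (SNP accessibility difference) is the per-task model prediction for the
alt-allele window minus the ref-allele window, for a fixed-length window
centred on the variant. Downstream: high/low |SAD| subsetting, allelic
imbalance sign evaluation, direction-of-effect AUC, and a cross-validated
random-forest classifier of causal vs. neutral variants from per-task |SAD|
feature vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import models as M
from .synthetic import Variant


@dataclass
class SADProfile:
    variant: Variant
    sad: dict[str, float]                  # task -> signed alt - ref
    group_mean_abs: dict[str, float] = field(default_factory=dict)
    window_center_offset: int = 0

    def mean_abs(self, tasks: list[str] | None = None) -> float:
        tasks = tasks or list(self.sad)
        return float(np.mean([abs(self.sad[t]) for t in tasks]))


def variant_windows(genome: dict, variant: Variant, L: int) -> tuple[str, str]:
    """(ref window, alt window) of length L with the variant at position L//2."""
    chrom_seq = genome[variant.chrom]
    start = variant.pos - L // 2
    if start < 0 or start + L > len(chrom_seq):
        raise ValueError(f"variant at {variant.chrom}:{variant.pos} too close to "
                         f"a chromosome edge for window length {L}")
    ref_win = chrom_seq[start:start + L]
    observed = ref_win[L // 2]
    if observed != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: genome has "
            f"{observed!r}, variant says {variant.ref!r}")
    alt_win = ref_win[:L // 2] + variant.alt + ref_win[L // 2 + 1:]
    return ref_win, alt_win


def sad_scores(predict_fn, genome: dict, variants: list[Variant], L: int,
               tasks: list[str], track_groups: dict[str, list[str]] | None = None
               ) -> list[SADProfile]:
    """SAD profiles for a batch of variants.

    ``predict_fn`` maps a one-hot batch (B, 4, L) to predictions (B, tasks);
    pass e.g. ``lambda X: predict_model(model, X, mode="rc_shift")`` so the
    same ensembling is used as in reference evaluation.
    """
    ref_seqs, alt_seqs = [], []
    for v in variants:
        r, a = variant_windows(genome, v, L)
        ref_seqs.append(r)
        alt_seqs.append(a)
    pred_ref = predict_fn(M.one_hot_batch(ref_seqs))
    pred_alt = predict_fn(M.one_hot_batch(alt_seqs))
    diffs = np.asarray(pred_alt) - np.asarray(pred_ref)
    profiles = []
    for v, d in zip(variants, diffs):
        sad = {t: float(x) for t, x in zip(tasks, np.atleast_1d(d))}
        groups = track_groups or {"all": tasks}
        gm = {g: float(np.mean([abs(sad[t]) for t in ts])) for g, ts in groups.items()}
        profiles.append(SADProfile(v, sad, gm))
    return profiles


def subset_by_sad(scores: np.ndarray, rule: str = "median_split",
                  top_fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Partition variant indices into (high, low) by |SAD| magnitude.

    ``median_split`` gives equal sizes (+-1); ``top_fraction`` puts the
    ceil(f*n) largest scores in the high set. Ties are broken by stable
    input order (earlier variants go high first).
    """
    scores = np.asarray(scores, float)
    n = len(scores)
    if n < 2:
        raise ValueError("need at least two variants")
    order = np.lexsort((np.arange(n), -scores))  # descending, stable
    if rule == "median_split":
        k = n // 2
    elif rule == "top_fraction":
        k = math.ceil(top_fraction * n)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    high = np.sort(order[:k])
    low = np.sort(order[k:])
    return high, low


def allelic_imbalance_eval(profiles: list[SADProfile], min_total_reads: int = 10,
                           pseudocount: float = 0.5,
                           task_of_track=lambda track: track.split("|")[0]
                           ) -> pd.DataFrame:
    """Sign concordance between model SAD and measured allelic imbalance.

    Sites are (variant, track) pairs with total reads >= min_total_reads and
    alt fraction != 0.5; label = sign(log((alt+c)/(ref+c))). Accuracy counts
    SAD sign matches, with SAD = 0 ties scored 0.5. AUC scores signed SAD
    against the binary label. Pooled over tracks plus per-track rows.
    """
    rows = []
    for prof in profiles:
        for track, (ref_reads, alt_reads) in prof.variant.allelic_counts.items():
            total = ref_reads + alt_reads
            if total < min_total_reads or ref_reads == alt_reads:
                continue
            label = 1 if alt_reads > ref_reads else -1
            sad = prof.sad.get(task_of_track(track))
            if sad is None:
                continue
            rows.append({"track": track, "label": label, "sad": sad,
                         "logratio": math.log((alt_reads + pseudocount)
                                              / (ref_reads + pseudocount))})
    if not rows:
        raise ValueError("no sites pass the read-depth / imbalance filter")
    df = pd.DataFrame(rows)

    def _summary(sub: pd.DataFrame, name: str) -> dict:
        match = np.where(sub["sad"] == 0, 0.5, (np.sign(sub["sad"]) == sub["label"]))
        out = {"group": name, "n_sites": len(sub), "accuracy": float(np.mean(match))}
        if len(sub["label"].unique()) == 2:
            out["auc"] = float(roc_auc_score((sub["label"] > 0).astype(int), sub["sad"]))
        else:
            out["auc"] = None
        return out

    summaries = [_summary(df, "pooled")]
    summaries += [_summary(g, t) for t, g in df.groupby("track")]
    return pd.DataFrame(summaries)


def direction_of_effect_eval(signed_scores: np.ndarray, true_signs: np.ndarray,
                             groups: list[str] | None = None) -> pd.DataFrame:
    """AUC of signed SAD scores against true effect sign, per group."""
    signed_scores = np.asarray(signed_scores, float)
    true_signs = np.asarray(true_signs)
    groups = np.asarray(groups) if groups is not None else np.array(["all"] * len(true_signs))
    rows = []
    for g in dict.fromkeys(groups.tolist()):
        idx = groups == g
        y = (true_signs[idx] > 0).astype(int)
        if len(np.unique(y)) < 2:
            rows.append({"group": g, "auc": None, "n": int(idx.sum()),
                         "reason": "single class"})
        else:
            rows.append({"group": g, "auc": float(roc_auc_score(y, signed_scores[idx])),
                         "n": int(idx.sum()), "reason": ""})
    return pd.DataFrame(rows)


def variant_classifier(features: np.ndarray, labels: np.ndarray, n_folds: int = 8,
                       seed: int = 0, strata: list[str] | None = None) -> dict:
    """Random-forest causal-vs-neutral classifier, stratified K-fold CV.

    Uses default forest hyperparameters apart from max_features=log2 of the
    feature count. Returns mean/sd AUPRC over folds, per-fold values, and
    (optionally) per-specificity-stratum AUPRC pooled over held-out folds.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    n_folds_eff = min(n_folds, int(np.bincount(y).min()))
    if n_folds_eff < 2:
        raise ValueError("too few minority-class examples for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    fold_auprc, oof_scores = [], np.full(len(y), np.nan)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(max_features="log2", random_state=seed + k)
        clf.fit(X[tr], y[tr])
        scores = clf.predict_proba(X[te])[:, 1]
        oof_scores[te] = scores
        fold_auprc.append(float(average_precision_score(y[te], scores)))
    report = {
        "n_folds": n_folds_eff,
        "requested_folds": n_folds,
        "max_features_rule": "log2",
        "auprc_mean": float(np.mean(fold_auprc)),
        "auprc_sd": float(np.std(fold_auprc, ddof=1)) if len(fold_auprc) > 1 else 0.0,
        "fold_auprc": fold_auprc,
        "prevalence": float(y.mean()),
    }
    if strata is not None:
        strata = np.asarray(strata)
        by = {}
        for s in dict.fromkeys(strata.tolist()):
            idx = strata == s
            if len(np.unique(y[idx])) == 2:
                by[s] = float(average_precision_score(y[idx], oof_scores[idx]))
        report["auprc_by_stratum"] = by
    return report
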