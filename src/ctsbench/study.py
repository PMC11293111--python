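"""The desk-scale study: simulate, train the model zoo, and run every
stratified evaluation.

This module wires the library into the benchmark experiment the analysis
scripts and the acceptance checks run: a four-cell-type synthetic genome
with disjoint specific grammars, a deliberately narrow baseline multi-task
CNN versus per-cell-type single-task CNNs (three seed replicates each), and
the downstream reference-accuracy, variant-effect and motif-level
evaluations, all stratified by cell-type specificity.

Problem sizes here are the package's desk-scale study conditions: 8
chromosomes x 1.5 Mb, 1200 ubiquitous + 4 x 450 specific peaks (60%
cell type-specific), 256-bp input windows, 2 replicates x 2 individuals
per cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models as M
from . import variant_effects as V
from .interpretability import activity_matrix, make_backgrounds
from .pwm import PWM, random_pwm
from .stratified_eval import (bh_adjust, cross_celltype_correlation, replicate_cv,
                              stratified_pearson)
from .synthetic import (GroundTruth, RegulatoryGrammar, SimConfig, Variant,
                        make_grammar, plant_variants, simulate_coverage,
                        simulate_genome_and_peaks)


@dataclass
class StudyProfile:
    """Everything about the desk-scale experiment that is not the simulator."""

    input_length: int = 256
    n_pwms: int = 14              # 10 grammar motifs + 4 distractors
    pwm_width: int = 8
    n_shared: int = 2
    n_specific_per_type: int = 2
    trainset_mode: str = "peaks_only"
    val_chroms: tuple = ("chr7",)
    test_chroms: tuple = ("chr4", "chr5")
    epochs: int = 30
    patience: int = 30
    learning_rate: float = 1.2e-2
    batch_size: int = 96
    single_task_epochs: int = 20
    replicate_seeds: tuple = (0, 1, 2)
    jitter_shifts: tuple = (-64, 64)
    n_causal: int = 200
    n_neutral: int = 200
    het_depth: int = 60
    n_backgrounds: int = 1000
    min_delta_for_imbalance: float = 1.0


@dataclass
class StudyData:
    profile: StudyProfile
    cfg: SimConfig
    pwms: list[PWM]
    grammar: RegulatoryGrammar
    genome: dict
    truth: GroundTruth
    tracks: list
    coverage: dict                      # cell type -> chrom -> normalized bins
    examples: list[M.SequenceExample]
    train: list[M.SequenceExample]
    val: list[M.SequenceExample]
    test_peaks: list[M.SequenceExample]  # peak examples on the test chromosomes

    @property
    def cell_types(self) -> list[str]:
        return self.cfg.cell_types

    def test_strata(self) -> list[str]:
        """'ubiquitous' vs pooled 'specific' labels for the test peak rows."""
        return ["ubiquitous" if ex.label == "ubiquitous" else "specific"
                for ex in self.test_peaks]

    def test_targets(self) -> np.ndarray:
        return np.stack([ex.targets for ex in self.test_peaks])


def simulate_study(seed: int, profile: StudyProfile | None = None,
                   sim_overrides: dict | None = None) -> StudyData:
    """Simulate the study's genome, coverage and training examples."""
    profile = profile or StudyProfile()
    cfg = SimConfig(seed=seed, **(sim_overrides or {}))
    pwm_rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    pwms = [random_pwm(f"SYN{i + 1:02d}", profile.pwm_width, pwm_rng)
            for i in range(profile.n_pwms)]
    grammar = make_grammar(cfg.n_cell_types, pwms, profile.n_shared,
                           profile.n_specific_per_type, seed=seed + 1)
    genome, truth = simulate_genome_and_peaks(cfg, grammar)
    tracks = simulate_coverage(genome, truth, cfg)
    coverage = M.normalized_celltype_coverage(tracks, cfg.cell_types)

    peak_rows = [(p.chrom, p.start, p.end, p.label) for p in truth.peaks]
    tspec = M.TrainingSetSpec(mode=profile.trainset_mode,
                              stride=profile.input_length, seed=seed + 2)
    examples = M.build_training_set(genome, peak_rows, coverage, cfg.cell_types,
                                    tspec, profile.input_length, cfg.bin_size)
    train, val, test = M.split_by_chromosome(examples, list(profile.val_chroms),
                                             list(profile.test_chroms))
    if profile.jitter_shifts:
        train = M.jitter_examples(genome, coverage, cfg.cell_types, train,
                                  profile.jitter_shifts, cfg.bin_size)
    test_peaks = [ex for ex in test if ex.is_peak]
    return StudyData(profile, cfg, pwms, grammar, genome, truth, tracks,
                     coverage, examples, train, val, test_peaks)


# ---------------------------------------------------------------------------
# Model zoo
# ---------------------------------------------------------------------------

def _single_task_examples(examples: list[M.SequenceExample], task_idx: int
                          ) -> list[M.SequenceExample]:
    return [M.SequenceExample(ex.chrom, ex.start, ex.end, ex.seq,
                              ex.targets[task_idx:task_idx + 1], ex.is_peak, ex.label)
            for ex in examples]


def train_zoo(data: StudyData, capacities: tuple = (1,), single_task: bool = True,
              seed: int = 0, single_replicate_seeds: tuple | None = None) -> dict:
    """Train multi-task models at the requested capacities plus (optionally)
    one single-task ensemble per cell type. Returns
    {'multi_m<m>': ensemble, 'single': {cell type: ensemble}}.

    ``single_replicate_seeds`` overrides the profile's replicate seeds for
    the single-task ensembles (e.g. a single replicate when only point
    estimates are needed)."""
    prof = data.profile
    zoo: dict = {}
    for m in capacities:
        spec = M.ModelSpec(tasks=data.cell_types, capacity=m,
                           input_length=prof.input_length, seed=seed + m)
        zoo[f"multi_m{m}"] = M.train(
            spec, data.train, data.val, epochs=prof.epochs, patience=prof.patience,
            replicate_seeds=prof.replicate_seeds, lr=prof.learning_rate,
            batch_size=prof.batch_size)
    if single_task:
        singles = {}
        for i, ct in enumerate(data.cell_types):
            spec = M.ModelSpec(tasks=[ct], capacity=1,
                               input_length=prof.input_length, seed=seed + 100 + i)
            singles[ct] = M.train(
                spec, _single_task_examples(data.train, i),
                _single_task_examples(data.val, i),
                epochs=prof.single_task_epochs,
                patience=prof.single_task_epochs,
                replicate_seeds=single_replicate_seeds or prof.replicate_seeds,
                lr=prof.learning_rate, batch_size=prof.batch_size)
        zoo["single"] = singles
    return zoo


def single_task_prediction_matrix(singles: dict, X: np.ndarray,
                                  cell_types: list[str], replicate: int,
                                  mode: str = "plain") -> np.ndarray:
    """Rows x cell types prediction matrix assembled from per-type models."""
    cols = [M.predict_model(singles[ct].models[replicate], X, mode)[:, 0]
            for ct in cell_types]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Reference-accuracy evaluation (specificity-stratified)
# ---------------------------------------------------------------------------

def reference_eval(data: StudyData, zoo: dict, mode: str = "plain",
                   min_n: int = 10) -> dict:
    """Stratified Pearson R, cross-cell-type over-correlation, and replicate
    CV for every model in the zoo, on the held-out test-chromosome peaks."""
    X = M.one_hot_batch([ex.seq for ex in data.test_peaks])
    target = data.test_targets()
    strata = data.test_strata()
    strata_arr = np.asarray(strata)
    spec_rows = np.flatnonzero(strata_arr == "specific")
    cts = data.cell_types

    pearson_tables, cv_tables, cross_rows = [], [], []
    per_replicate: dict[str, list[np.ndarray]] = {}

    for name, ens in zoo.items():
        if name == "single":
            n_rep = min(len(e.models) for e in ens.values())
            preds = [single_task_prediction_matrix(ens, X, cts, r, mode)
                     for r in range(n_rep)]
        else:
            _, per = M.predict_ensemble(ens, X, mode)
            preds = list(per)
        per_replicate[name] = preds
        for r, pred in enumerate(preds):
            tab = stratified_pearson(pred, target, strata, tracks=cts,
                                     min_n=min_n)
            tab.insert(0, "model", name)
            tab.insert(1, "replicate", r)
            pearson_tables.append(tab)
            cc = cross_celltype_correlation(pred, spec_rows, cts, min_n=min_n)
            cross_rows.append({"model": name, "replicate": r,
                               "mean_pairwise_r": float(cc["pearson_r"].mean())})
        # CV across the replicate models, per cell type (needs >= 2 replicates)
        if len(preds) >= 2:
            for j, ct in enumerate(cts):
                stack = np.column_stack([p[:, j] for p in preds])
                cv_tab = replicate_cv(stack, strata, comparison_id=f"{name}|{ct}")
                cv_tables.append(cv_tab)

    cc_exp = cross_celltype_correlation(target, spec_rows, cts, min_n=min_n)
    cross_rows.append({"model": "experimental", "replicate": -1,
                       "mean_pairwise_r": float(cc_exp["pearson_r"].mean())})

    cv = bh_adjust(pd.concat(cv_tables, ignore_index=True))
    return {"pearson": pd.concat(pearson_tables, ignore_index=True),
            "cross_celltype": pd.DataFrame(cross_rows),
            "replicate_cv": cv,
            "per_replicate_predictions": per_replicate}


def mean_r(pearson: pd.DataFrame, model: str, stratum: str,
           replicate: int | None = None) -> float:
    sub = pearson[(pearson["model"] == model) & (pearson["stratum"] == stratum)]
    if replicate is not None:
        sub = sub[sub["replicate"] == replicate]
    vals = sub["value"].dropna()
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Variant-effect evaluation
# ---------------------------------------------------------------------------

def plant_study_variants(data: StudyData, seed: int,
                         count_noise: bool = True) -> list[Variant]:
    prof = data.profile
    track_ids = [t.track_id for t in data.tracks]
    variants = plant_variants(data.truth, data.grammar, data.genome,
                              prof.n_causal, prof.n_neutral, prof.het_depth,
                              seed=seed, track_ids=track_ids,
                              count_noise=count_noise)
    L = prof.input_length
    # keep only variants with a full prediction window
    return [v for v in variants
            if v.pos - L // 2 >= 0 and v.pos + L // 2 <= len(data.genome[v.chrom])]


def oracle_sad_profiles(variants: list[Variant], cell_types: list[str]
                        ) -> list[V.SADProfile]:
    """Truth-oracle predictor: SAD equals the true per-cell-type effect."""
    return [V.SADProfile(v, {c: v.delta.get(c, 0.0) for c in cell_types})
            for v in variants]


def model_sad_profiles(data: StudyData, zoo: dict, variants: list[Variant],
                       replicate: int = 0, mode: str = "plain",
                       model: str = "single") -> list[V.SADProfile]:
    cts = data.cell_types
    L = data.profile.input_length
    if model == "single":
        fn = lambda X: single_task_prediction_matrix(zoo["single"], X, cts,
                                                     replicate, mode)
    else:
        fn = lambda X: M.predict_model(zoo[model].models[replicate], X, mode)
    return V.sad_scores(fn, data.genome, variants, L, cts)


def variant_eval(data: StudyData, zoo: dict, seed: int) -> dict:
    """Causal-vs-neutral |SAD| separation, classifier AUPRC, allelic imbalance."""
    from .stratified_eval import mannwhitney_one_sided

    variants = plant_study_variants(data, seed=seed, count_noise=True)
    causal_mask = np.array([v.causal for v in variants])
    profs = model_sad_profiles(data, zoo, variants)
    mean_abs = np.array([p.mean_abs() for p in profs])
    u, p = mannwhitney_one_sided(mean_abs[causal_mask], mean_abs[~causal_mask])

    # classifier on truth-separable features (per-cell-type |delta|) and on
    # model-derived per-task |SAD| features
    cts = data.cell_types
    feats_truth = np.array([[abs(v.delta.get(c, 0.0)) for c in cts]
                            for v in variants])
    feats_model = np.array([[abs(pr.sad[c]) for c in cts] for pr in profs])
    clf_truth = V.variant_classifier(feats_truth, causal_mask, seed=seed)
    clf_model = V.variant_classifier(feats_model, causal_mask, seed=seed)
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(causal_mask)
    clf_shuffled = V.variant_classifier(feats_truth, shuffled, seed=seed)

    # allelic imbalance on high-|delta| sites
    noiseless = plant_study_variants(data, seed=seed, count_noise=False)
    thr = data.profile.min_delta_for_imbalance
    high = [v for v in noiseless
            if max(abs(d) for d in v.delta.values()) >= thr or not v.causal]
    oracle = oracle_sad_profiles(high, cts)
    imb_oracle = V.allelic_imbalance_eval(oracle)
    high_noisy = [_restrict_counts_to_carriers(v, thr) for v in variants
                  if max(abs(d) for d in v.delta.values()) >= thr]
    profs_high = model_sad_profiles(data, zoo, high_noisy)
    imb_model = V.allelic_imbalance_eval(profs_high)

    signed = np.array([pr.sad[_max_delta_ct(pr.variant, cts)] for pr in profs
                       if pr.variant.causal])
    true_signs = np.array([pr.variant.delta[_max_delta_ct(pr.variant, cts)]
                           for pr in profs if pr.variant.causal])
    direction = V.direction_of_effect_eval(signed, true_signs)

    return {"n_variants": len(variants),
            "n_causal": int(causal_mask.sum()),
            "sad_mwu_u": u, "sad_mwu_p": p,
            "classifier_truth": clf_truth,
            "classifier_model": clf_model,
            "classifier_shuffled": clf_shuffled,
            "imbalance_oracle": imb_oracle,
            "imbalance_model": imb_model,
            "direction_of_effect": direction}


def _max_delta_ct(variant: Variant, cell_types: list[str]) -> str:
    return max(cell_types, key=lambda c: abs(variant.delta.get(c, 0.0)))


def _restrict_counts_to_carriers(v: Variant, thr: float) -> Variant:
    """Keep allelic counts only for tracks whose cell type truly carries a
    large effect (|delta| >= thr), the sites the sign test is meaningful for."""
    counts = {track: rc for track, rc in v.allelic_counts.items()
              if abs(v.delta.get(track.split("|")[0], 0.0)) >= thr}
    out = Variant(v.chrom, v.pos, v.ref, v.alt, dict(v.delta), v.causal)
    out.allelic_counts = counts
    return out


# ---------------------------------------------------------------------------
# Motif-activity evaluation
# ---------------------------------------------------------------------------

def motif_eval(data: StudyData, zoo: dict, seed: int, replicate: int = 0,
               n_backgrounds: int | None = None) -> dict:
    """Single-task TF activity matrix over all PWMs (grammar + distractors)
    and the fraction of cell types whose top-ranked motif is one of their
    own planted specific motifs."""
    n_bg = n_backgrounds or data.profile.n_backgrounds
    peak_seqs = [ex.seq for ex in data.test_peaks]
    backgrounds = make_backgrounds(peak_seqs, n=n_bg, seed=seed)
    fns = {ct: (lambda X, _m=zoo["single"][ct].models[replicate]:
                M.predict_model(_m, X))
           for ct in data.cell_types}
    acts = activity_matrix(fns, data.pwms, backgrounds, seed=seed)
    hits = {}
    for ct in data.cell_types:
        top = acts.loc[ct].idxmax()
        hits[ct] = top in data.grammar.specific_motifs[ct]
    return {"activity": acts, "top_hit_is_own_specific": hits,
            "recovered_fraction": float(np.mean(list(hits.values()))),
            "n_backgrounds": n_bg}
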