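"""End-to-end orchestration: simulate -> call peaks -> train -> evaluate ->
variants -> interpret, with every intermediate written to a report directory.

The report directory contains only plain-text artifacts (FASTA, BED,
bedGraph, VCF, TSV, JSON) plus a log; reruns with the same configuration
produce identical metric tables.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as io
from . import peakcall as pc
from . import study as st
from .io_formats import RunConfig
from .pwm import write_jaspar

log = logging.getLogger("ctsbench")


def _profile_from_config(config: RunConfig) -> st.StudyProfile:
    t, v, i = config.training, config.variant, config.interpretability
    return st.StudyProfile(
        input_length=config.model.get("input_length", 512),
        trainset_mode=t["mode"],
        val_chroms=tuple(t["val_chroms"]), test_chroms=tuple(t["test_chroms"]),
        epochs=t["epochs"], patience=t["patience"],
        single_task_epochs=t.get("single_task_epochs", t["epochs"]),
        learning_rate=t["learning_rate"], batch_size=t["batch_size"],
        replicate_seeds=tuple(t["replicate_seeds"]),
        n_causal=v["n_causal"], n_neutral=v["n_neutral"],
        het_depth=v["het_depth"], n_backgrounds=i["n_backgrounds"])


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline; returns the summary metrics dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    (outdir / "config.json").write_text(config.to_json())
    summary: dict = {"stages": {}}

    def stage(name, fn):
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", name, time.time() - t0)
        summary["stages"][name] = round(time.time() - t0, 2)
        return result

    profile = _profile_from_config(config)
    sim_overrides = {k: v for k, v in config.simulation.items() if k != "seed"}
    sim_seed = config.simulation.get("seed", config.seed)

    data = stage("simulate", lambda: st.simulate_study(sim_seed, profile,
                                                       sim_overrides))
    stage("write_simulation", lambda: _write_simulation(data, outdir))
    results = stage("callpeaks", lambda: pc.call_peaks_all(
        data.tracks, alpha=config.peakcall["alpha"]))
    matrix = stage("specificity", lambda: _specificity(results, config, data, outdir))
    zoo = stage("train", lambda: st.train_zoo(
        data, capacities=tuple(config.model.get("capacity_grid", (1,))),
        single_task=config.model.get("single_task", True), seed=config.seed))
    ref = stage("evaluate", lambda: _evaluate(data, zoo, config, outdir))
    var = stage("variants", lambda: _variants(data, zoo, config, outdir))
    interp = stage("interpret", lambda: _interpret(data, zoo, config, outdir))

    summary["reference"] = ref
    summary["variants"] = var
    summary["interpretability"] = interp
    summary["n_presence_rows"] = len(matrix.rows)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    log.removeHandler(handler)
    handler.close()
    return summary


def _write_simulation(data: st.StudyData, outdir: Path) -> None:
    io.write_fasta(data.genome, outdir / "genome.fa")
    io.write_truth_peaks_bed(data.truth, outdir / "truth_peaks.bed")
    covdir = outdir / "coverage"
    covdir.mkdir(exist_ok=True)
    for track in data.tracks:
        io.write_bedgraph(track, covdir / f"{track.track_id}.bedGraph".replace("|", "_"))
    write_jaspar(data.pwms, outdir / "motifs.pfm")
    manifest = {
        "cell_types": data.cell_types,
        "shared_motifs": data.grammar.shared_motifs,
        "specific_motifs": data.grammar.specific_motifs,
        "effect_sizes": data.grammar.effect_sizes,
        "n_peaks": len(data.truth.peaks),
        "n_tracks": len(data.tracks),
    }
    (outdir / "grammar.json").write_text(json.dumps(manifest, indent=2))


def _specificity(results, config: RunConfig, data: st.StudyData, outdir: Path):
    matrix = pc.build_presence_matrix(results, collapse=config.peakcall["collapse"])
    io.write_presence_tsv(matrix, outdir / "presence_matrix.tsv")
    scheme = pc.SpecificityScheme.quantile_like(matrix.n_tracks)
    labels = pc.assign_specificity_bins(matrix, scheme)
    called = matrix.N > 0
    pd.DataFrame({"chrom": [r[0] for r in matrix.rows],
                  "start": [r[1] for r in matrix.rows],
                  "end": [r[2] for r in matrix.rows],
                  "N": matrix.N, "label": labels})[called].to_csv(
        outdir / "specificity.tsv", sep="\t", index=False)
    for res in results[:1]:
        io.write_peak_calls_bed(res, outdir / "peak_calls_track0.bed")
    return matrix


def _evaluate(data: st.StudyData, zoo: dict, config: RunConfig,
              outdir: Path) -> dict:
    ref = st.reference_eval(data, zoo, min_n=config.evaluation.get("min_n", 10))
    ref["pearson"].to_csv(outdir / "stratified_pearson.tsv", sep="\t", index=False)
    ref["cross_celltype"].to_csv(outdir / "cross_celltype_correlation.tsv",
                                 sep="\t", index=False)
    ref["replicate_cv"].to_csv(outdir / "replicate_cv.tsv", sep="\t", index=False)
    out = {}
    for name in zoo:
        out[f"{name}_r_ubiquitous"] = st.mean_r(ref["pearson"], name, "ubiquitous")
        out[f"{name}_r_specific"] = st.mean_r(ref["pearson"], name, "specific")
    return out


def _variants(data: st.StudyData, zoo: dict, config: RunConfig, outdir: Path) -> dict:
    var = st.variant_eval(data, zoo, seed=config.variant["seed"])
    var["imbalance_model"].to_csv(outdir / "allelic_imbalance.tsv", sep="\t",
                                  index=False)
    variants = st.plant_study_variants(data, seed=config.variant["seed"])
    io.write_vcf(variants, {c: len(s) for c, s in data.genome.items()},
                 outdir / "variants.vcf")
    io.write_allelic_counts(variants, outdir / "allelic_counts.tsv")
    return {"sad_mwu_p": var["sad_mwu_p"],
            "classifier_auprc": var["classifier_model"]["auprc_mean"],
            "oracle_imbalance_accuracy":
                float(var["imbalance_oracle"].iloc[0]["accuracy"]),
            "model_imbalance_accuracy":
                float(var["imbalance_model"].iloc[0]["accuracy"])}


def _interpret(data: st.StudyData, zoo: dict, config: RunConfig, outdir: Path) -> dict:
    motif = st.motif_eval(data, zoo, seed=config.interpretability["seed"],
                          n_backgrounds=config.interpretability["n_backgrounds"])
    motif["activity"].to_csv(outdir / "motif_activity.tsv", sep="\t")
    return {"recovered_fraction": motif["recovered_fraction"]}
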