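"""Readers/writers for the external formats the pipeline touches, plus the
structured run configuration.

Coordinates are 0-based half-open everywhere inside the package; VCF
positions are converted to/from 1-based at this boundary only. bedGraph
(not bigWig) is the canonical coverage format so every artifact stays plain
text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .synthetic import BinnedTrack, GroundTruth, SimConfig, TrackId, Variant


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: dict, path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def read_fasta(path) -> dict:
    from pyfaidx import Fasta
    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_truth_peaks_bed(truth: GroundTruth, path) -> None:
    """BED6+: name = class label, score = specificity count, extra columns =
    per-cell-type intensity."""
    with open(path, "w") as fh:
        for p in truth.peaks:
            extra = "\t".join(f"{p.intensity[c]:.4f}" for c in truth.cell_types)
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.label}\t"
                     f"{p.specificity}\t.\t{extra}\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates")
            if not 0 <= start < end:
                raise ValueError(f"{path}: line {lineno}: invalid interval "
                                 f"{start}-{end}")
            row = {"chrom": parts[0], "start": start, "end": end}
            for i, name in enumerate(("name", "score", "strand"), start=3):
                if len(parts) > i:
                    row[name] = parts[i]
            row["extra"] = parts[6:] if len(parts) > 6 else []
            rows.append(row)
    return pd.DataFrame(rows)


def write_peak_calls_bed(result, path, score_cap: float = 320.0) -> None:
    """Called peak bins as BED6 with score = -log10 q (capped)."""
    with open(path, "w") as fh:
        bs = result.bin_size
        for chrom in result.chroms:
            q = result.qvalues[chrom]
            for b in np.flatnonzero(result.is_peak[chrom]):
                score = min(-np.log10(max(q[b], 1e-320)), score_cap)
                fh.write(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\t"
                         f"peak\t{score:.3f}\t.\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: BinnedTrack, path) -> None:
    with open(path, "w") as fh:
        bs = track.bin_size
        fh.write(f"track type=bedGraph name=\"{track.track_id}\"\n")
        for chrom in sorted(track.counts):
            for b, v in enumerate(track.counts[chrom]):
                fh.write(f"{chrom}\t{b * bs}\t{(b + 1) * bs}\t{v:g}\n")


def read_bedgraph(path, bin_size: int, track_id: TrackId | None = None) -> BinnedTrack:
    """Fixed-step bedGraph -> BinnedTrack; any step != bin_size is rejected."""
    counts: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph fields")
            chrom, s, e, v = parts
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric field")
            if e - s != bin_size:
                raise ValueError(f"{path}: line {lineno}: step {e - s} != "
                                 f"bin size {bin_size}")
            arr = counts.setdefault(chrom, [])
            if s != len(arr) * bin_size:
                raise ValueError(f"{path}: line {lineno}: bins out of order or gapped")
            arr.append(v)
    return BinnedTrack(track_id or TrackId("unknown", 0, 0),
                       {c: np.asarray(v) for c, v in counts.items()}, bin_size)


# ---------------------------------------------------------------------------
# VCF + allelic counts TSV
# ---------------------------------------------------------------------------

def write_vcf(variants: list[Variant], chrom_lengths: dict, path) -> None:
    """Minimal VCF 4.2; positions written 1-based."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ctsbench-synthetic\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write('##INFO=<ID=CAUSAL,Number=0,Type=Flag,Description='
                 '"Variant disrupts a planted motif instance">\n')
        fh.write('##INFO=<ID=DELTA,Number=.,Type=String,Description='
                 '"Per-cell-type true effect on log intensity odds">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, v in enumerate(variants):
            delta = ",".join(f"{c}:{d:.4f}" for c, d in v.delta.items())
            info = f"DELTA={delta}"
            if v.causal:
                info = "CAUSAL;" + info
            fh.write(f"{v.chrom}\t{v.pos + 1}\tvar{i}\t{v.ref}\t{v.alt}\t.\t.\t{info}\n")


def read_vcf(path) -> list[Variant]:
    """Read variants (positions converted back to 0-based)."""
    import pysam
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            delta = {}
            raw = rec.info.get("DELTA")
            if raw:
                items = raw if isinstance(raw, tuple) else (raw,)
                for item in items:
                    ct, val = item.split(":")
                    delta[ct] = float(val)
            out.append(Variant(rec.chrom, rec.pos - 1, rec.ref, rec.alts[0],
                               delta, causal="CAUSAL" in rec.info))
    return out


def write_allelic_counts(variants: list[Variant], path) -> None:
    rows = []
    for i, v in enumerate(variants):
        for track, (ref_reads, alt_reads) in v.allelic_counts.items():
            rows.append({"track": track, "variant_id": f"var{i}",
                         "ref_reads": ref_reads, "alt_reads": alt_reads})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_allelic_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"track", "variant_id", "ref_reads", "alt_reads"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_presence_tsv(matrix, path) -> None:
    df = pd.DataFrame(matrix.presence.astype(int),
                      columns=[str(t) for t in matrix.track_ids])
    df.insert(0, "chrom", [r[0] for r in matrix.rows])
    df.insert(1, "start", [r[1] for r in matrix.rows])
    df.insert(2, "end", [r[2] for r in matrix.rows])
    df["N"] = matrix.N
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SECTION_KEYS = {
    "simulation": {f.name for f in fields(SimConfig)},
    "peakcall": {"alpha", "collapse"},
    "model": {"input_length", "capacity_grid", "single_task", "fc_units",
              "conv_channels"},
    "training": {"mode", "stride", "val_chroms", "test_chroms", "epochs",
                 "single_task_epochs", "patience", "batch_size",
                 "learning_rate", "replicate_seeds"},
    "evaluation": {"min_n", "log1p"},
    "variant": {"n_causal", "n_neutral", "het_depth", "min_total_reads", "seed"},
    "interpretability": {"n_backgrounds", "q_threshold", "seed"},
}


@dataclass
class RunConfig:
    """Validated nested run configuration; unknown keys are rejected and all
    stage seeds are materialized from the top-level seed."""

    seed: int
    simulation: dict = field(default_factory=dict)
    peakcall: dict = field(default_factory=lambda: {"alpha": 0.01,
                                                    "collapse": "per_bin"})
    model: dict = field(default_factory=lambda: {"input_length": 512,
                                                 "capacity_grid": [1],
                                                 "single_task": True})
    training: dict = field(default_factory=lambda: {
        "mode": "peaks_plus_equal_nonpeaks", "stride": 512,
        "val_chroms": ["chr7"], "test_chroms": ["chr4", "chr5"],
        "epochs": 10, "patience": 2, "batch_size": 64, "learning_rate": 3e-3})
    evaluation: dict = field(default_factory=lambda: {"min_n": 10, "log1p": False})
    variant: dict = field(default_factory=lambda: {"n_causal": 200, "n_neutral": 200,
                                                   "het_depth": 60,
                                                   "min_total_reads": 10})
    interpretability: dict = field(default_factory=lambda: {"n_backgrounds": 1000,
                                                            "q_threshold": 0.05})

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        if "seed" not in doc:
            raise ValueError("config must provide a top-level seed")
        unknown = set(doc) - ({"seed"} | set(_SECTION_KEYS))
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls(seed=int(doc.pop("seed")))
        for section, allowed in _SECTION_KEYS.items():
            if section not in doc:
                continue
            payload = doc[section]
            bad = set(payload) - allowed
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
            getattr(cfg, section).update(payload)
        cfg.materialize_seeds()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def materialize_seeds(self) -> None:
        ss = np.random.SeedSequence(self.seed)
        subs = ss.spawn(4)
        self.simulation.setdefault("seed", int(subs[0].generate_state(1)[0] % 2**31))
        self.training.setdefault("replicate_seeds",
                                 [int(s % 2**31) for s in subs[1].generate_state(3)])
        self.variant.setdefault("seed", int(subs[2].generate_state(1)[0] % 2**31))
        self.interpretability.setdefault(
            "seed", int(subs[3].generate_state(1)[0] % 2**31))

    def sim_config(self) -> SimConfig:
        return SimConfig(**self.simulation)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)
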