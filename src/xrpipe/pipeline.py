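"""End-to-end orchestration: configuration, logging, deterministic seeding,
and the staged run simulate -> QC -> repair quantification -> intergenic
discovery -> chromatin profiling -> repair dynamics."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin, discovery, dynamics, qc, simulate, tcr
from .genomics import (
    GenomeBuild,
    ReadSet,
    tile_genome,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_fasta,
)

log = logging.getLogger("xrpipe")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected at load time."""

    seed: int = 0
    outdir: str = "xrpipe_out"
    bin_width: int = 200
    upstream_bp: int = 2000
    n_perm: int = 50
    perm_quantile: float = 0.95
    xr_replicates: int = 2
    run_discovery: bool = True
    run_chromatin: bool = True
    run_dynamics: bool = True
    write_outputs: bool = True
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)

    def fingerprint(self) -> str:
        blob = json.dumps(_to_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _build_dataclass(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        default = f.default_factory() if f.default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(default) and isinstance(value, dict):
            kwargs[name] = _build_dataclass(type(default), value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def validate_config(path: str | Path | dict | None = None) -> PipelineConfig:
    """Load and semantically validate a YAML pipeline config (or a dict).

    Checks: unknown keys rejected; timepoints ordered as the assay schedule;
    discovery requires two repair replicates.
    """
    if path is None:
        data = {}
    elif isinstance(path, dict):
        data = path
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    try:
        cfg = _build_dataclass(PipelineConfig, data, "config")
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc

    sim = cfg.simulation
    known = [t for t in simulate.TIMEPOINTS if t in sim.timepoints]
    if known != sim.timepoints:
        raise ConfigError(f"timepoints must be ordered as {simulate.TIMEPOINTS}")
    if cfg.run_discovery and cfg.xr_replicates < 2:
        raise ConfigError(
            "discovery detection calls require non-zero repair in both replicates; "
            "configure xr_replicates >= 2 or disable run_discovery"
        )
    if cfg.run_dynamics and len(sim.timepoints) < 4:
        raise ConfigError("dynamics needs at least 4 ordered timepoints")
    return cfg


@dataclass
class RunReport:
    fingerprint: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, seconds: float, **counts) -> None:
        self.stages[stage] = {"seconds": round(seconds, 3), **_to_jsonable(counts)}

    def as_json(self) -> str:
        return json.dumps({"config_fingerprint": self.fingerprint, "stages": self.stages},
                          indent=2)


@dataclass
class PipelineResult:
    """In-memory products of a full run (also written to disk when enabled)."""

    report: RunReport
    genome: GenomeBuild
    genes: pd.DataFrame
    truth: simulate.SyntheticTruth
    qc_reports: dict[str, qc.QCReport]
    summaries: dict[str, pd.DataFrame]
    metagene: tcr.MetageneMatrix | None
    venn: dict[str, int] | None
    classification: discovery.BinClassification | None
    metrics: dict[str, discovery.DetectionMetrics] | None
    state_profiles: dict[str, chromatin.StateProfile] | None
    track_comparison: pd.DataFrame | None
    dynamic: dynamics.DynamicClassification | None
    truth_bins: np.ndarray | None = None
    intergenic: pd.DataFrame | None = None
    calls: pd.DataFrame | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every enabled stage in dependency order.

    All randomness descends from ``config.seed`` through named spawn keys, so
    a fixed config yields byte-identical outputs.
    """
    t_all = time.time()
    outdir = Path(config.outdir)
    if config.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(fingerprint=config.fingerprint())
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: np.random.default_rng(s) for name, s in zip(
        ["genome", "annotations", "xr", "rna", "capped", "tracks", "chromatin", "dynamics"],
        ss.spawn(8),
    )}

    # --- stage: simulate -------------------------------------------------
    t0 = time.time()
    sim = config.simulation
    genome = simulate.simulate_genome(sim, seeds["genome"])
    genes, annotations, blacklist, truth = simulate.simulate_annotations(
        sim, genome, seeds["annotations"])
    ttmap = qc.build_tt_map(genome)

    xr_sets: dict[tuple[str, str, int], ReadSet] = {}
    for tp in sim.timepoints:
        for rep in range(1, config.xr_replicates + 1):
            rs = simulate.simulate_xrseq(sim, genome, genes, truth, "xpc-1", tp, rep,
                                         seeds["xr"], ttmap)
            xr_sets[("xpc-1", tp, rep)] = rs
    for genotype in ("WT", "csb-1"):
        xr_sets[(genotype, "1h", 1)] = simulate.simulate_xrseq(
            sim, genome, genes, truth, genotype, "1h", 1, seeds["xr"], ttmap)
    rna_counts, rna_sets = simulate.simulate_rnaseq(sim, genome, genes, truth, seeds["rna"])
    shortcap, longcap = simulate.simulate_capped(sim, genome, genes, truth, seeds["capped"])
    tracks, states = simulate.simulate_tracks(sim, genome, genes, truth, seeds["tracks"])
    report.record("simulate", time.time() - t0, n_genes=len(genes),
                  n_xr_samples=len(xr_sets), n_annotations=len(annotations))
    log.info("simulate: %d genes, %d XR samples", len(genes), len(xr_sets))

    if config.write_outputs:
        write_fasta(genome, outdir / "genome.fa")
        write_chrom_sizes(genome, outdir / "genome.chrom.sizes")
        write_bed(genes, outdir / "genes.bed")
        write_bed(annotations, outdir / "annotations.bed")
        write_bed(blacklist, outdir / "blacklist.bed")
        rna_counts.to_csv(outdir / "rnaseq_counts.tsv", sep="\t", index=False)
        for name, track in tracks.items():
            write_bedgraph(track, outdir / f"track_{name}.bedGraph")
        write_bed(states, outdir / "chromatin_states.bed")

    # --- stage: qc --------------------------------------------------------
    t0 = time.time()
    nuclear = [c for c in genome.chroms if c != "chrM"]
    qc_reports: dict[str, qc.QCReport] = {}
    clean: dict[tuple[str, str, int], ReadSet] = {}
    for key, rs in xr_sets.items():
        filtered, rep_ = qc.qc_filter(rs, min_mapq=20, allowed_chroms=nuclear)
        clean[key] = filtered
        qc_reports[rs.sample_id] = rep_
    report.record("qc", time.time() - t0,
                  reads_in=sum(r.total_mapped for r in qc_reports.values()),
                  reads_out=sum(r.length for r in qc_reports.values()))

    # --- stage: tcr -------------------------------------------------------
    t0 = time.time()
    profiled = tcr.select_profile_genes(genes)
    kept = tcr.gene_qc(genes, ttmap, list(clean.values()))
    summaries = {}
    for genotype in ("WT", "csb-1", "xpc-1"):
        rs = clean[(genotype, "1h", 1)]
        summaries[genotype] = tcr.repair_strand_summary(kept, rs)
    metagene = tcr.metagene_profile(profiled, clean[("xpc-1", "1h", 1)], "TS", genome)
    heat = tcr.tss_heatmap(tcr.gene_tss_table(genes), clean[("xpc-1", "1h", 1)], genome)
    report.record("tcr", time.time() - t0, n_profiled=len(profiled), n_kept=len(kept),
                  n_tss=len(heat.tss))
    if config.write_outputs:
        for genotype, summ in summaries.items():
            summ.to_csv(outdir / f"repair_summary_{genotype}.tsv", sep="\t", index=False)
        pd.DataFrame({"bin": np.arange(len(metagene.mean_profile)),
                      "mean_rpkm": metagene.mean_profile}).to_csv(
            outdir / "metagene_ts.tsv", sep="\t", index=False)

    # --- stage: discovery -------------------------------------------------
    venn = classification = metrics = None
    truth_bins = None
    calls = None
    grid = tile_genome(genome, config.bin_width)
    inter = discovery.intergenic_bins(grid, genes, genome, config.upstream_bp, blacklist)
    if config.run_discovery:
        t0 = time.time()
        per_rep = {}
        for rep in (1, 2):
            cols = []
            for tp in sim.timepoints:
                rs = clean[("xpc-1", tp, rep)]
                counts = discovery.count_reads_in_bins(inter, rs, config.bin_width)
                cols.append(discovery.adjust_library_size(counts, rs.library_size))
            per_rep[rep] = discovery.combine_timepoints(np.column_stack(cols))
        rna_adj = {s: discovery.adjust_library_size(
            discovery.count_reads_in_bins(inter, rna_sets[s], config.bin_width),
            rna_sets[s].library_size) for s in rna_sets}
        sc_adj = discovery.adjust_library_size(
            discovery.count_reads_in_bins(inter, shortcap, config.bin_width),
            shortcap.library_size)
        lc_adj = discovery.adjust_library_size(
            discovery.count_reads_in_bins(inter, longcap, config.bin_width),
            longcap.library_size)
        calls = discovery.call_detected(per_rep[1], per_rep[2], rna_adj["WT"],
                                        rna_adj["xpc-1"], sc_adj, lc_adj)
        venn = discovery.venn_partition(calls)
        unique = inter[calls["xr"] & ~calls["rna"] & ~calls["capped"]]
        classification = discovery.classify_unique_bins(unique, annotations)
        truth_bins = _truth_transcribed_bins(inter, truth, ttmap)
        metrics = {
            "xr": discovery.detection_metrics(calls["xr"], calls["capped"]),
            "rna": discovery.detection_metrics(calls["rna"], calls["capped"]),
        }
        report.record("discovery", time.time() - t0, n_bins=len(grid),
                      n_intergenic=len(inter), **venn)
        if config.write_outputs:
            with open(outdir / "venn.json", "w") as fh:
                json.dump(venn, fh, indent=2)
            classification.per_bin.to_csv(outdir / "xr_unique_bins.tsv", sep="\t", index=False)

    # --- stage: chromatin -------------------------------------------------
    state_profiles = track_comparison = None
    if config.run_chromatin:
        t0 = time.time()
        state_profiles = {
            "xpc-1_XR": chromatin.state_read_proportions(clean[("xpc-1", "1h", 1)], states),
            "shortcap": chromatin.state_read_proportions(shortcap, states),
            "longcap": chromatin.state_read_proportions(longcap, states),
            "RNA_WT": chromatin.state_read_proportions(rna_sets["WT"], states),
        }
        if config.run_discovery:
            unique = inter[calls["xr"] & ~calls["rna"]]
        else:
            unique = inter.head(200)
        track_comparison = chromatin.compare_to_random(
            unique, tracks, genome, rng=seeds["chromatin"])
        report.record("chromatin", time.time() - t0,
                      n_query_regions=len(unique))
        if config.write_outputs:
            rows = []
            for name, prof in state_profiles.items():
                for state, p in prof.proportions.items():
                    rows.append({"sample": name, "state": state, "proportion": p,
                                 "sqrt_proportion": float(np.sqrt(p))})
            pd.DataFrame(rows).to_csv(outdir / "state_profiles.tsv", sep="\t", index=False)
            track_comparison.to_csv(outdir / "track_comparison.tsv", sep="\t", index=False)

    # --- stage: dynamics --------------------------------------------------
    dynamic = None
    if config.run_dynamics:
        t0 = time.time()
        sub = kept
        mats = {}
        for rep in (1, 2):
            cols = []
            for tp in sim.timepoints:
                rs = clean[("xpc-1", tp, min(rep, config.xr_replicates))]
                ts_counts, _ = tcr.ts_nts_counts(sub, rs)
                cols.append(tcr.rpkm(ts_counts, (sub["end"] - sub["start"]).to_numpy(),
                                     rs.library_size))
            mats[rep] = np.column_stack(cols)
        fits = {rep: dynamics.fit_matrix(mats[rep]) for rep in (1, 2)}
        thr, _ = dynamics.permutation_threshold(
            np.vstack([mats[1], mats[2]]), n_perm=config.n_perm,
            quantile=config.perm_quantile, rng=seeds["dynamics"])
        profiles = (mats[1] + mats[2]) / 2.0
        dynamic = dynamics.classify_dynamic_genes(
            sub["name"].to_numpy(), fits[1]["r2"].to_numpy(), fits[2]["r2"].to_numpy(),
            profiles, thr)
        report.record("dynamics", time.time() - t0, threshold=thr,
                      n_significant=int(dynamic.table["significant"].sum()))
        if config.write_outputs:
            dynamic.table.to_csv(outdir / "dynamic_genes.tsv", sep="\t", index=False)

    report.record("total", time.time() - t_all)
    result = PipelineResult(
        report=report, genome=genome, genes=genes, truth=truth, qc_reports=qc_reports,
        summaries=summaries, metagene=metagene, venn=venn, classification=classification,
        metrics=metrics, state_profiles=state_profiles, track_comparison=track_comparison,
        dynamic=dynamic, truth_bins=truth_bins, intergenic=inter, calls=calls,
    )
    if config.write_outputs:
        with open(outdir / "run_report.json", "w") as fh:
            fh.write(report.as_json())
    return result


def _truth_transcribed_bins(
    inter: pd.DataFrame, truth: simulate.SyntheticTruth, ttmap
) -> np.ndarray:
    """Boolean mask over the intergenic bin universe: bins overlapping a
    truth-transcribed intergenic locus whose template strand carries >= 1 TT
    dimer inside the bin-locus intersection."""
    flip = {"+": "-", "-": "+"}
    mask = np.zeros(len(inter), dtype=bool)
    b = inter.reset_index(drop=True)
    for row in truth.intergenic_loci.itertuples(index=False):
        sel = (b["chrom"] == row.chrom) & (b["start"] < row.end) & (b["end"] > row.start)
        if not sel.any():
            continue
        template = flip[row.strand]
        for i in np.flatnonzero(sel.to_numpy()):
            lo = max(b.at[i, "start"], row.start)
            hi = min(b.at[i, "end"], row.end)
            if ttmap.count(row.chrom, lo, hi, template) >= 1:
                mask[i] = True
    return mask
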