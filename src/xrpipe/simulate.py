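"""Synthetic genomes, annotations, and assay read sets for strand-resolved
repair analysis.

The generator emulates the statistical structure the downstream analysis
assumes rather than sequence-level realism:

* an AT-rich multi-chromosome genome (plus a small mitochondrial contig that
  exercises the chromosome filter),
* non-overlapping protein-coding genes with a minimum spacing, a piRNA
  cluster confined to one chromosome, bidirectional enhancer RNAs, lincRNAs,
  pseudogenes, and planted *novel* transcribed intergenic loci,
* UV damage restricted to TT dinucleotides, dual-incision excision geometry
  (~19 nt 5' and ~6 nt 3' of the 2-nt dimer, hence ~27-nt products) with
  3'-preserving 5'-only trimming to 19-24-nt reads,
* genotype presets for the two excision-repair pathways: WT repairs by both,
  a csb-1 mutant by global repair only (no strand preference), an xpc-1
  mutant by transcription-coupled repair only (template strand of
  transcribed loci, with a 5'->3' exponential gradient that flattens over
  the time course),
* poly(A)-restricted RNA-seq versus capped RNA-seq that also covers
  intergenic loci (piRNA precursors appear in long-cap but not short-cap),
* promoter/enhancer-enriched epigenomic tracks and a labelled chromatin-state
  segmentation.

Every sampled quantity flows from a single :class:`numpy.random.Generator`,
so a fixed seed fixes every output byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genomics import GenomeBuild, ReadSet, as_intervals, sort_intervals
from .qc import TTMap, build_tt_map

TIMEPOINTS = ["5min", "1h", "8h", "16h", "24h", "48h"]

_FLIP = {"+": "-", "-": "+"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    #: worm-like autosomes + X, sized so the full pipeline runs in minutes
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {
        "chrI": 300_000, "chrII": 300_000, "chrIII": 300_000,
        "chrIV": 300_000, "chrV": 300_000, "chrX": 300_000, "chrM": 13_794,
    })
    #: AT-rich composition (worm genomes are ~65% AT)
    base_probs: dict[str, float] = field(default_factory=lambda: {
        "A": 0.32, "C": 0.18, "G": 0.18, "T": 0.32,
    })


@dataclass
class GeneSpec:
    n_per_chrom: int = 35
    length_log_mean: float = 8.0     # lognormal length, median ~3 kb
    length_log_sigma: float = 0.4
    length_min: int = 1200
    length_max: int = 8000
    min_spacing: int = 600           # > the 500-bp profile-selection gap
    plus_strand_prob: float = 0.5
    expressed_fraction: float = 0.9
    expression_log_sigma: float = 1.0
    edge_margin: int = 1600          # keeps metagene windows on-chromosome


@dataclass
class NcRNASpec:
    pirna_chrom: str = "chrIV"
    pirna_cluster: tuple[int, int] = (60_000, 180_000)
    pirna_count: int = 150
    pirna_length: int = 28
    erna_count: int = 40
    erna_bidirectional_fraction: float = 0.9
    erna_length: int = 500
    lincrna_count: int = 20
    lincrna_length: tuple[int, int] = (600, 1500)
    lincrna_polya_fraction: float = 0.3
    novel_locus_count: int = 30
    novel_locus_length: int = 400
    pseudogene_count: int = 10
    misc_ncrna_count: int = 10
    other_count: int = 6


@dataclass
class BlacklistSpec:
    count: int = 8
    length_range: tuple[int, int] = (1000, 3000)


@dataclass
class ExcisionSpec:
    five_prime_nt: int = 19
    three_prime_nt: int = 6
    dimer_len: int = 2
    #: jitter on the 5' incision only; offsets -2..+2, mode 0
    jitter_offsets: tuple[int, ...] = (-2, -1, 0, 1, 2)
    jitter_probs: tuple[float, ...] = (0.1, 0.2, 0.4, 0.2, 0.1)
    #: sequenced read lengths after 3'-preserving trimming
    read_lengths: tuple[int, ...] = (19, 20, 21, 22, 23, 24)
    read_length_probs: tuple[float, ...] = (0.08, 0.15, 0.27, 0.25, 0.15, 0.10)


@dataclass
class XRSpec:
    reads_per_sample: int = 30_000
    #: fraction of repair events that are TCR / global, per genotype
    genotype_weights: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "WT": (0.6, 0.4), "csb-1": (0.0, 1.0), "xpc-1": (1.0, 0.0),
    })
    #: uniform TT background (mapping noise), both strands, all chromosomes
    background_weight: float = 0.01
    #: share of TCR events routed to transcribed intergenic loci; None matches
    #: the global component's intergenic TT share, which makes the planted
    #: tcr_weight recoverable from the pooled genic TS fraction
    intergenic_tcr_fraction: float | None = None
    #: 5'->3' positional gradient over gene bodies (bp)
    gradient_decay_bp: float = 500.0
    #: per-timepoint multiplier of the decay length: gradient flattens with time
    timepoint_skew: dict[str, float] = field(default_factory=lambda: {
        "5min": 1.0, "1h": 1.5, "8h": 2.5, "16h": 4.0, "24h": 6.0, "48h": 10.0,
    })
    low_mapq_fraction: float = 0.03
    duplicate_fraction: float = 0.02


@dataclass
class RNASpec:
    reads_per_sample: int = 50_000
    read_length: int = 50
    depth_per_gene: float = 60.0      # mean counts for a unit-expression gene
    dispersion: float = 0.08          # NB dispersion (1/size)
    intergenic_noise_fraction: float = 0.002


@dataclass
class CappedSpec:
    shortcap_reads: int = 20_000
    longcap_reads: int = 30_000
    shortcap_length: tuple[int, int] = (30, 80)
    longcap_length: int = 120
    tss_jitter: int = 20
    #: long-cap allocation between gene bodies and intergenic ncRNA loci
    longcap_gene_share: float = 0.55


@dataclass
class TrackSpec:
    resolution: int = 200
    promoter_flank: int = 250
    baseline: float = 0.5
    promoter_fold: dict[str, float] = field(default_factory=lambda: {
        "ATAC": 6.0, "DNase": 6.0, "H3K4me3": 8.0, "H3K4me1": 2.0, "H3K27me3": 0.3,
    })
    enhancer_fold: dict[str, float] = field(default_factory=lambda: {
        "ATAC": 3.0, "DNase": 3.0, "H3K4me3": 1.5, "H3K4me1": 6.0, "H3K27me3": 0.5,
    })
    repressed_fold: dict[str, float] = field(default_factory=lambda: {
        "ATAC": 0.5, "DNase": 0.5, "H3K4me3": 0.7, "H3K4me1": 0.7, "H3K27me3": 5.0,
    })
    repressed_domain_bp: tuple[int, int] = (10_000, 20_000)
    repressed_genome_fraction: float = 0.2
    n_states: int = 20


@dataclass
class TrendSpec:
    dynamic_fraction: float = 0.10
    early_fraction: float = 0.90      # of dynamic genes; the rest are late
    profiles: dict[str, tuple[float, ...]] = field(default_factory=lambda: {
        "flat": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
        "early": (2.5, 2.2, 1.6, 1.0, 0.6, 0.4),
        "late": (0.4, 0.5, 0.8, 1.3, 2.0, 2.5),
    })


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    genes: GeneSpec = field(default_factory=GeneSpec)
    ncrna: NcRNASpec = field(default_factory=NcRNASpec)
    blacklist: BlacklistSpec = field(default_factory=BlacklistSpec)
    excision: ExcisionSpec = field(default_factory=ExcisionSpec)
    xr: XRSpec = field(default_factory=XRSpec)
    rna: RNASpec = field(default_factory=RNASpec)
    capped: CappedSpec = field(default_factory=CappedSpec)
    tracks: TrackSpec = field(default_factory=TrackSpec)
    trend: TrendSpec = field(default_factory=TrendSpec)
    timepoints: list[str] = field(default_factory=lambda: list(TIMEPOINTS))

    def __post_init__(self) -> None:
        for g, (tcr, glob) in self.xr.genotype_weights.items():
            if not (0 <= tcr <= 1 and 0 <= glob <= 1):
                raise ValueError(f"genotype {g}: weights must lie in [0, 1]")
        if self.xr.genotype_weights.get("csb-1", (0, 1))[0] != 0:
            raise ValueError("csb-1 preset must have tcr_weight 0")
        if self.xr.genotype_weights.get("xpc-1", (1, 0))[1] != 0:
            raise ValueError("xpc-1 preset must have global_weight 0")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for parameter-recovery tests."""

    genes: pd.DataFrame                 # BED6 + biotype
    gene_expression: pd.Series          # per gene_id, 0 for silent genes
    trend_class: pd.Series              # per gene_id: flat / early / late
    intergenic_loci: pd.DataFrame       # BED6 + class, shortcap/longcap/polya flags
    genotype_weights: dict[str, tuple[float, float]]
    injected_duplicates: dict[str, int] = field(default_factory=dict)

    def transcribed_loci(self) -> pd.DataFrame:
        """All truth-transcribed loci (expressed genes + intergenic), one row
        per transcribed strand."""
        g = self.genes[self.gene_expression.reindex(self.genes["name"]).to_numpy() > 0]
        return pd.concat(
            [g[["chrom", "start", "end", "name", "score", "strand"]],
             self.intergenic_loci[["chrom", "start", "end", "name", "score", "strand"]]],
            ignore_index=True,
        )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig, rng: np.random.Generator) -> GenomeBuild:
    """I.i.d. bases with the configured composition; deterministic per seed."""
    bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    order = ["A", "C", "G", "T"]
    probs = np.array([config.genome.base_probs[b] for b in order], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("base probabilities must sum to 1")
    seqs: dict[str, str] = {}
    for chrom, length in config.genome.chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        draw = rng.choice(4, size=length, p=probs)
        seqs[chrom] = bases[draw].tobytes().decode("ascii")
    return GenomeBuild(name="synthetic", chrom_lengths=dict(config.genome.chrom_lengths),
                       sequences=seqs)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def _place_in_segments(
    segments: list[tuple[str, int, int]],
    lengths: np.ndarray,
    min_gap: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place intervals of the given lengths into free segments, non-overlapping
    with pairwise gaps >= ``min_gap``.  Raises with the achievable count when
    the request does not fit."""
    if not segments and len(lengths):
        raise ValueError(
            f"cannot place {len(lengths)} intervals at spacing {min_gap}; achievable count 0"
        )
    n = len(lengths)
    remaining = np.array([e - s for _, s, e in segments], dtype=np.int64)
    per_segment: list[list[int]] = [[] for _ in segments]
    placed = 0
    # largest-first placement into a feasible segment chosen with probability
    # proportional to remaining capacity, so layouts stay random but packing
    # failures occur only when the request genuinely does not fit
    for L in np.sort(lengths)[::-1]:
        cost = int(L) + np.where([len(p) for p in per_segment], min_gap, 0)
        feasible = remaining >= cost
        if not feasible.any():
            continue
        p = remaining * feasible
        si = int(rng.choice(len(segments), p=p / p.sum()))
        per_segment[si].append(int(L))
        remaining[si] -= cost[si]
        placed += 1
    if placed < n:
        raise ValueError(
            f"cannot place {n} intervals at spacing {min_gap}; achievable count {placed}"
        )
    chroms, starts, ends = [], [], []
    for (chrom, s0, e0), lens in zip(segments, per_segment):
        if not lens:
            continue
        lens = [lens[i] for i in rng.permutation(len(lens))]
        slack = (e0 - s0) - (sum(lens) + (len(lens) - 1) * min_gap)
        cuts = np.sort(rng.integers(0, slack + 1, size=len(lens)))
        pos = s0
        prev_cut = 0
        for L, cut in zip(lens, cuts):
            pos += int(cut - prev_cut)
            prev_cut = cut
            chroms.append(chrom); starts.append(pos); ends.append(pos + L)
            pos += L + min_gap
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def _free_segments(
    genome: GenomeBuild,
    occupied: pd.DataFrame,
    margin: int,
    edge: int,
    chroms: list[str],
    min_width: int,
) -> list[tuple[str, int, int]]:
    """Complement of ``occupied`` (each interval padded by ``margin``) within
    each chromosome, ``edge`` bp away from the ends."""
    segs: list[tuple[str, int, int]] = []
    for chrom in chroms:
        length = genome.chrom_lengths[chrom]
        occ = occupied[occupied["chrom"] == chrom].sort_values("start")
        pos = edge
        for s, e in zip(occ["start"] - margin, occ["end"] + margin):
            if s - pos >= min_width:
                segs.append((chrom, pos, int(s)))
            pos = max(pos, int(e))
        if length - edge - pos >= min_width:
            segs.append((chrom, pos, length - edge))
    return segs


def simulate_annotations(
    config: SimulationConfig, genome: GenomeBuild, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate genes, the annotation catalogue, blacklist regions, and truth.

    Returns ``(genes, annotations, blacklist, truth)``.  Genes are
    non-overlapping with the configured minimum spacing; piRNAs are confined
    to their cluster; the configured fraction of eRNAs is bidirectional.
    """
    gs, ns = config.genes, config.ncrna
    nuclear = [c for c in genome.chroms if c != "chrM"]

    # --- genes ---
    gene_frames = []
    for chrom in nuclear:
        length = genome.chrom_lengths[chrom]
        if chrom == ns.pirna_chrom:
            c0, c1 = ns.pirna_cluster
            segments = [(chrom, gs.edge_margin, max(gs.edge_margin, c0 - 2500)),
                        (chrom, min(length, c1 + 2500), length - gs.edge_margin)]
        else:
            segments = [(chrom, gs.edge_margin, length - gs.edge_margin)]
        lens = np.exp(rng.normal(gs.length_log_mean, gs.length_log_sigma, gs.n_per_chrom))
        lens = np.clip(lens, gs.length_min, gs.length_max).astype(np.int64)
        gene_frames.append(_place_in_segments(segments, lens, gs.min_spacing, rng))
    genes = pd.concat(gene_frames, ignore_index=True)
    genes["name"] = [f"gene{i:04d}" for i in range(len(genes))]
    genes["score"] = 0
    genes["strand"] = np.where(rng.random(len(genes)) < gs.plus_strand_prob, "+", "-")
    genes["biotype"] = "protein_coding"
    genes = sort_intervals(as_intervals(genes), genome)

    # --- expression and trend classes ---
    expressed = rng.random(len(genes)) < gs.expressed_fraction
    expr = np.exp(rng.normal(0.0, gs.expression_log_sigma, len(genes)))
    expr[~expressed] = 0.0
    gene_expression = pd.Series(expr, index=genes["name"].to_numpy(), name="expression")
    classes = np.array(["flat"] * len(genes), dtype=object)
    dyn = rng.random(len(genes)) < config.trend.dynamic_fraction
    early = rng.random(len(genes)) < config.trend.early_fraction
    classes[dyn & early] = "early"
    classes[dyn & ~early] = "late"
    classes[~expressed] = "flat"
    trend_class = pd.Series(classes, index=genes["name"].to_numpy(), name="trend_class")

    # --- blacklist (placed intergenic so planted signal bins survive exclusion) ---
    bl_lens = rng.integers(config.blacklist.length_range[0],
                           config.blacklist.length_range[1] + 1, config.blacklist.count)
    bl_segs = _free_segments(genome, genes, margin=2400, edge=500, chroms=nuclear, min_width=4000)
    blacklist = _place_in_segments(bl_segs, bl_lens, 500, rng)
    blacklist = as_intervals(blacklist.assign(name="blacklist", score=0, strand="."))

    # --- intergenic ncRNA loci ---
    # keep a bin-width margin from genes+2kb-upstream and blacklist so that
    # every bin a locus touches survives the intergenic exclusion
    occupied = pd.concat([
        genes.assign(start=np.where(genes["strand"] == "+", genes["start"] - 2000, genes["start"]),
                     end=np.where(genes["strand"] == "-", genes["end"] + 2000, genes["end"])),
        blacklist,
    ], ignore_index=True)[["chrom", "start", "end"]]
    occupied["start"] = occupied["start"].clip(lower=0)

    # the piRNA cluster is reserved for piRNAs: other ncRNA classes stay out
    # so cluster loci carry only the capped signal the model assigns them
    occupied_plus_cluster = pd.concat([
        occupied,
        pd.DataFrame({"chrom": [ns.pirna_chrom], "start": [ns.pirna_cluster[0]],
                      "end": [ns.pirna_cluster[1]]}),
    ], ignore_index=True)

    def place(count, lens, chroms, min_width=600):
        segs = _free_segments(genome, occupied_plus_cluster, margin=250, edge=500,
                              chroms=chroms, min_width=min_width)
        lens = np.asarray(lens, dtype=np.int64)
        return _place_in_segments(segs, lens, 100, rng)

    cluster_chrom = ns.pirna_chrom
    c0, c1 = ns.pirna_cluster
    pir_segs = [
        (ch, max(s, c0), min(e, c1))
        for ch, s, e in _free_segments(genome, occupied, margin=250, edge=500,
                                       chroms=[cluster_chrom], min_width=200)
        if min(e, c1) - max(s, c0) >= 200
    ]
    pirna = _place_in_segments(pir_segs, np.full(ns.pirna_count, ns.pirna_length, np.int64),
                               60, rng)
    pirna = pirna.assign(name=[f"pirna{i:04d}" for i in range(len(pirna))],
                         strand=np.where(rng.random(len(pirna)) < 0.5, "+", "-"),
                         annotation_class="piRNA")

    other_chroms = [c for c in nuclear]
    erna = place(ns.erna_count, np.full(ns.erna_count, ns.erna_length), other_chroms)
    erna = erna.assign(name=[f"erna{i:03d}" for i in range(len(erna))],
                       strand=np.where(rng.random(len(erna)) < 0.5, "+", "-"),
                       annotation_class="eRNA")
    linc_lens = rng.integers(ns.lincrna_length[0], ns.lincrna_length[1] + 1, ns.lincrna_count)
    linc = place(ns.lincrna_count, linc_lens, other_chroms, min_width=2000)
    linc = linc.assign(name=[f"linc{i:03d}" for i in range(len(linc))],
                       strand=np.where(rng.random(len(linc)) < 0.5, "+", "-"),
                       annotation_class="lincRNA")
    novel = place(ns.novel_locus_count, np.full(ns.novel_locus_count, ns.novel_locus_length),
                  other_chroms)
    novel = novel.assign(name=[f"novel{i:03d}" for i in range(len(novel))],
                         strand=np.where(rng.random(len(novel)) < 0.5, "+", "-"),
                         annotation_class="novel")
    pseudo = place(ns.pseudogene_count, rng.integers(500, 1500, ns.pseudogene_count),
                   other_chroms, min_width=2000)
    pseudo = pseudo.assign(name=[f"pseudo{i:03d}" for i in range(len(pseudo))],
                           strand="+", annotation_class="pseudogene")
    misc = place(ns.misc_ncrna_count, rng.integers(80, 300, ns.misc_ncrna_count), other_chroms)
    misc = misc.assign(name=[f"ncrna{i:03d}" for i in range(len(misc))],
                       strand="+", annotation_class="ncRNA")
    other = place(ns.other_count, rng.integers(70, 150, ns.other_count), other_chroms)
    other = other.assign(name=[f"other{i:03d}" for i in range(len(other))],
                         strand="+", annotation_class="other")

    # --- truth: transcribed intergenic loci, one row per transcribed strand ---
    bidir = rng.random(len(erna)) < ns.erna_bidirectional_fraction
    erna = erna.assign(bidirectional=bidir)
    erna_rev = erna[bidir].assign(strand=erna.loc[bidir, "strand"].map(_FLIP),
                                  name=erna.loc[bidir, "name"] + "_rev")
    polya = rng.random(len(linc)) < ns.lincrna_polya_fraction
    linc = linc.assign(polya=polya)

    loci = pd.concat([
        pirna.assign(shortcap=False, longcap=True, polya=False),
        erna.assign(shortcap=True, longcap=True, polya=False).drop(columns="bidirectional"),
        erna_rev.assign(shortcap=True, longcap=True, polya=False).drop(columns="bidirectional"),
        linc.assign(shortcap=True, longcap=True),
        novel.assign(shortcap=False, longcap=True, polya=False),
    ], ignore_index=True)
    loci = as_intervals(loci.assign(score=0))

    annotations = pd.concat([
        genes.rename(columns={"biotype": "annotation_class"}),
        pirna, pseudo, erna.drop(columns="bidirectional"), linc.drop(columns="polya"),
        misc, other,
    ], ignore_index=True)
    annotations = sort_intervals(as_intervals(annotations.assign(score=0)), genome)

    truth = SyntheticTruth(
        genes=genes, gene_expression=gene_expression, trend_class=trend_class,
        intergenic_loci=loci, genotype_weights=dict(config.xr.genotype_weights),
    )
    return genes, annotations, as_intervals(blacklist), truth


# ---------------------------------------------------------------------------
# Excision geometry
# ---------------------------------------------------------------------------

def simulate_excision_products(
    config: SimulationConfig,
    damage_sites: pd.DataFrame,
    genome: GenomeBuild,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, int]:
    """Dual-incision products around TT dimers.

    Each fragment spans ``five_prime_nt`` (plus jitter) 5' of the dimer and
    ``three_prime_nt`` 3' of it; with zero jitter every product is
    19 + 2 + 6 = 27 nt.  Events whose fragment would leave the chromosome are
    dropped and counted.  Returns ``(fragments, n_dropped)``.
    """
    ex = config.excision
    n = len(damage_sites)
    jitter = rng.choice(ex.jitter_offsets, size=n, p=ex.jitter_probs) if n else np.array([], int)
    d0 = damage_sites["start"].to_numpy()
    d1 = d0 + ex.dimer_len
    minus = damage_sites["strand"].to_numpy() == "-"
    five = ex.five_prime_nt + jitter
    starts = np.where(minus, d0 - ex.three_prime_nt, d0 - five)
    ends = np.where(minus, d1 + five, d1 + ex.three_prime_nt)
    lengths = damage_sites["chrom"].map(genome.chrom_lengths).to_numpy()
    ok = (starts >= 0) & (ends <= lengths)
    frags = pd.DataFrame({
        "chrom": damage_sites["chrom"].to_numpy()[ok],
        "start": starts[ok],
        "end": ends[ok],
        "strand": damage_sites["strand"].to_numpy()[ok],
    })
    return as_intervals(frags), int((~ok).sum())


def trim_fragments(
    config: SimulationConfig, fragments: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """3'-preserving trimming: nucleotides are removed from the 5' end only,
    to a target length drawn from the configured 19-24 distribution, so the
    dimer's offset from the 3' end survives in the sequenced read."""
    ex = config.excision
    n = len(fragments)
    target = rng.choice(ex.read_lengths, size=n, p=ex.read_length_probs) if n else np.array([], int)
    flen = (fragments["end"] - fragments["start"]).to_numpy()
    L = np.minimum(target, flen)
    minus = fragments["strand"].to_numpy() == "-"
    starts = np.where(minus, fragments["start"].to_numpy(),
                      fragments["end"].to_numpy() - L)
    ends = starts + L
    return as_intervals(pd.DataFrame({
        "chrom": fragments["chrom"].to_numpy(), "start": starts, "end": ends,
        "strand": fragments["strand"].to_numpy(),
    }))


# ---------------------------------------------------------------------------
# XR-seq
# ---------------------------------------------------------------------------

def _tcr_candidates(
    config: SimulationConfig,
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    ttmap: TTMap,
    timepoint: str,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray]:
    """Candidate template-strand TT positions and sampling weights for the
    TCR component: genic (with the 5'->3' gradient and per-gene trend
    multiplier) and intergenic (uniform within each transcribed locus)."""
    skew = config.xr.timepoint_skew.get(timepoint, 1.0)
    decay = config.xr.gradient_decay_bp * skew
    t_idx = config.timepoints.index(timepoint) if timepoint in config.timepoints else 0

    g_chrom, g_pos, g_strand, g_w = [], [], [], []
    for row in genes.itertuples(index=False):
        expr = truth.gene_expression.get(row.name, 0.0)
        if expr <= 0:
            continue
        template = _FLIP[row.strand]
        pos = ttmap.positions_in(row.chrom, row.start, row.end, template)
        if len(pos) == 0:
            continue
        dist = (pos - row.start) if row.strand == "+" else (row.end - 2 - pos)
        profile = config.trend.profiles[truth.trend_class.get(row.name, "flat")]
        w = expr * profile[t_idx] * np.exp(-dist / decay)
        g_chrom.append(np.repeat(row.chrom, len(pos)))
        g_pos.append(pos)
        g_strand.append(np.repeat(template, len(pos)))
        g_w.append(w)
    genic = pd.DataFrame({
        "chrom": np.concatenate(g_chrom) if g_chrom else np.array([], dtype=object),
        "start": np.concatenate(g_pos) if g_pos else np.array([], dtype=np.int64),
        "strand": np.concatenate(g_strand) if g_strand else np.array([], dtype=object),
    })
    genic_w = np.concatenate(g_w) if g_w else np.array([])

    i_chrom, i_pos, i_strand, i_w = [], [], [], []
    for row in truth.intergenic_loci.itertuples(index=False):
        template = _FLIP[row.strand]
        pos = ttmap.positions_in(row.chrom, row.start, row.end, template)
        if len(pos) == 0:
            continue
        i_chrom.append(np.repeat(row.chrom, len(pos)))
        i_pos.append(pos)
        i_strand.append(np.repeat(template, len(pos)))
        i_w.append(np.full(len(pos), 1.0 / len(pos)))  # equal weight per locus
    inter = pd.DataFrame({
        "chrom": np.concatenate(i_chrom) if i_chrom else np.array([], dtype=object),
        "start": np.concatenate(i_pos) if i_pos else np.array([], dtype=np.int64),
        "strand": np.concatenate(i_strand) if i_strand else np.array([], dtype=object),
    })
    inter_w = np.concatenate(i_w) if i_w else np.array([])
    return genic, genic_w, inter, inter_w


def simulate_xrseq(
    config: SimulationConfig,
    genome: GenomeBuild,
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    genotype: str = "xpc-1",
    timepoint: str = "1h",
    replicate: int = 1,
    rng: np.random.Generator | None = None,
    ttmap: TTMap | None = None,
    n_reads: int | None = None,
) -> ReadSet:
    """One XR-seq sample: damage only at TT; the TCR component targets the
    template strand of transcribed loci with a 5'->3' gradient; the global
    component is strand-symmetric over genome TT density; a small uniform
    background adds mapping noise.  Fragments follow the dual-incision
    geometry and are trimmed 3'-preservingly to 19-24 nt."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if ttmap is None:
        ttmap = build_tt_map(genome)
    if genotype not in config.xr.genotype_weights:
        raise ValueError(f"unknown genotype preset {genotype!r}")
    tcr_w, glob_w = config.xr.genotype_weights[genotype]
    bg = config.xr.background_weight
    total = tcr_w + glob_w
    if total <= 0 and bg <= 0:
        raise ValueError(f"genotype {genotype!r} has no repair activity")
    p = np.array([tcr_w / total * (1 - bg) if total else 0.0,
                  glob_w / total * (1 - bg) if total else 0.0,
                  bg if total else 1.0])
    n = int(n_reads if n_reads is not None else config.xr.reads_per_sample)
    n_tcr, n_glob, n_bg = rng.multinomial(n, p / p.sum())

    parts = []
    if n_tcr:
        genic, gw, inter, iw = _tcr_candidates(config, genes, truth, ttmap, timepoint)
        fi = config.xr.intergenic_tcr_fraction
        if fi is None:
            # match the global component's genic/intergenic split: with the
            # TCR and global components dividing their mass identically
            # between gene territory and the rest, the pooled genic TS
            # fraction estimates tcr_weight + (1 - tcr_weight)/2 exactly
            tt_total = sum(len(ttmap.positions(c, s)) for c in genome.chroms for s in "+-")
            tt_genic = sum(
                ttmap.count(r.chrom, r.start, r.end, s)
                for r in genes.itertuples(index=False) for s in "+-"
            )
            fi = 1.0 - (tt_genic / tt_total if tt_total else 0.0)
        if not len(inter):
            fi = 0.0
        if len(genic) == 0:
            fi = 1.0 if len(inter) else 0.0
        n_int = rng.binomial(n_tcr, fi)
        n_gen = n_tcr - n_int
        if n_gen and len(genic):
            idx = rng.choice(len(genic), size=n_gen, p=gw / gw.sum())
            parts.append(genic.iloc[idx])
        if n_int and len(inter):
            idx = rng.choice(len(inter), size=n_int, p=iw / iw.sum())
            parts.append(inter.iloc[idx])
    # global + background: strand-symmetric, proportional to TT density
    n_uniform = n_glob + n_bg
    if n_uniform:
        pools = []
        for chrom in genome.chroms:
            for strand in "+-":
                pos = ttmap.positions(chrom, strand)
                if len(pos):
                    pools.append(pd.DataFrame({"chrom": chrom, "start": pos, "strand": strand}))
        pool = pd.concat(pools, ignore_index=True)
        idx = rng.integers(0, len(pool), size=n_uniform)
        parts.append(pool.iloc[idx])

    sites = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["chrom", "start", "strand"])
    sites = sites.assign(end=sites["start"] + config.excision.dimer_len) if len(sites) else sites
    frags, _ = simulate_excision_products(config, as_intervals(sites) if len(sites) else
                                          as_intervals(pd.DataFrame(columns=["chrom", "start", "end"])),
                                          genome, rng)
    reads = trim_fragments(config, frags, rng)

    m = len(reads)
    mapq = rng.integers(21, 43, size=m)
    low = rng.random(m) < config.xr.low_mapq_fraction
    mapq[low] = rng.integers(0, 21, size=int(low.sum()))
    reads["score"] = mapq
    reads["name"] = [f"{genotype}_{timepoint}_r{replicate}_{i}" for i in range(m)]

    n_dup = int(round(config.xr.duplicate_fraction * m))
    if n_dup:
        dup = reads.iloc[rng.integers(0, m, size=n_dup)]
        reads = pd.concat([reads, dup], ignore_index=True)
    sample_id = f"{genotype}_{timepoint}_rep{replicate}"
    truth.injected_duplicates[sample_id] = n_dup
    return ReadSet(sample_id=sample_id, reads=as_intervals(reads), genotype=genotype,
                   assay="XR", timepoint=timepoint, replicate=replicate)


# ---------------------------------------------------------------------------
# RNA-seq and capped RNA-seq
# ---------------------------------------------------------------------------

def simulate_rnaseq(
    config: SimulationConfig,
    genome: GenomeBuild,
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, ReadSet]]:
    """Poly(A)-restricted RNA-seq for two strains sharing true expression.

    Returns a per-gene count table (negative binomial around a shared mean)
    and per-strain read sets.  Reads fall only in poly(A) features (gene
    bodies and the poly(A) fraction of lincRNAs) plus a small uniform
    intergenic noise component; intergenic ncRNAs without poly(A) receive no
    reads, which is what makes capped RNA-seq informative."""
    rs = config.rna
    expr = truth.gene_expression.reindex(genes["name"]).to_numpy()
    mu = expr * rs.depth_per_gene
    size = 1.0 / rs.dispersion
    counts = {}
    for strain in ("WT", "xpc-1"):
        lam = rng.gamma(shape=size, scale=np.maximum(mu, 1e-12) / size)
        counts[strain] = rng.poisson(lam)
    count_table = pd.DataFrame({"gene_id": genes["name"], **counts})

    polya_linc = truth.intergenic_loci.query("polya")
    feats = pd.concat([
        genes[["chrom", "start", "end", "strand"]].assign(
            weight=np.maximum(expr, 0) * (genes["end"] - genes["start"])),
        polya_linc[["chrom", "start", "end", "strand"]].assign(
            weight=1.0 * (polya_linc["end"] - polya_linc["start"])),
    ], ignore_index=True)
    feats = feats[feats["weight"] > 0].reset_index(drop=True)

    readsets = {}
    chroms = np.array(genome.chroms)
    clens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    for strain in ("WT", "xpc-1"):
        n = rs.reads_per_sample
        n_noise = rng.binomial(n, rs.intergenic_noise_fraction)
        n_sig = n - n_noise
        fi = rng.choice(len(feats), size=n_sig, p=feats["weight"] / feats["weight"].sum())
        fs = feats["start"].to_numpy()[fi]
        fe = feats["end"].to_numpy()[fi]
        span = np.maximum(fe - fs - rs.read_length, 1)
        starts = fs + (rng.random(n_sig) * span).astype(np.int64)
        rows = pd.DataFrame({
            "chrom": feats["chrom"].to_numpy()[fi],
            "start": starts,
            "end": starts + rs.read_length,
            "strand": feats["strand"].to_numpy()[fi],
        })
        ci = rng.choice(len(chroms), size=n_noise, p=clens / clens.sum())
        npos = (rng.random(n_noise) * (clens[ci] - rs.read_length)).astype(np.int64)
        noise = pd.DataFrame({
            "chrom": chroms[ci], "start": npos, "end": npos + rs.read_length,
            "strand": np.where(rng.random(n_noise) < 0.5, "+", "-"),
        })
        df = pd.concat([rows, noise], ignore_index=True)
        lengths = df["chrom"].map(genome.chrom_lengths)
        df["end"] = np.minimum(df["end"], lengths)
        df["score"] = 60
        readsets[strain] = ReadSet(sample_id=f"RNA_{strain}", reads=as_intervals(df),
                                   genotype=strain, assay="RNA")
    return count_table, readsets


def simulate_capped(
    config: SimulationConfig,
    genome: GenomeBuild,
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> tuple[ReadSet, ReadSet]:
    """Capped RNA-seq: short-cap reads mark initiation (gene TSSs and eRNA
    loci); long-cap reads cover elongating transcripts (gene bodies,
    lincRNAs, novel loci, and 28-nt piRNA precursors).  piRNA loci get
    long-cap but no short-cap signal."""
    cs = config.capped
    expr = truth.gene_expression.reindex(genes["name"]).to_numpy()
    loci = truth.intergenic_loci

    # --- short cap ---
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    gene_t = pd.DataFrame({"chrom": genes["chrom"], "anchor": tss,
                           "strand": genes["strand"], "weight": np.maximum(expr, 0)})
    sc_loci = loci[loci["shortcap"]]
    loc_t = pd.DataFrame({
        "chrom": sc_loci["chrom"],
        "anchor": np.where(sc_loci["strand"] == "+", sc_loci["start"], sc_loci["end"] - 1),
        "strand": sc_loci["strand"],
        "weight": 1.0,
    })
    targets = pd.concat([gene_t, loc_t], ignore_index=True)
    targets = targets[targets["weight"] > 0].reset_index(drop=True)
    ti = rng.choice(len(targets), size=cs.shortcap_reads,
                    p=targets["weight"] / targets["weight"].sum())
    jit = rng.integers(0, cs.tss_jitter + 1, size=cs.shortcap_reads)
    L = rng.integers(cs.shortcap_length[0], cs.shortcap_length[1] + 1, size=cs.shortcap_reads)
    anchor = targets["anchor"].to_numpy()[ti]
    strand = targets["strand"].to_numpy()[ti]
    starts = np.where(strand == "+", anchor + jit, anchor - jit - L + 1)
    df = pd.DataFrame({"chrom": targets["chrom"].to_numpy()[ti], "start": starts,
                       "end": starts + L, "strand": strand})
    lengths = df["chrom"].map(genome.chrom_lengths)
    df = df[(df["start"] >= 0) & (df["end"] <= lengths)]
    shortcap = ReadSet(sample_id="shortcap_WT", reads=as_intervals(df.assign(score=60)),
                       assay="shortcap")

    # --- long cap ---
    lc_loci = loci[loci["longcap"]].reset_index(drop=True)
    is_pirna = (lc_loci["annotation_class"] == "piRNA").to_numpy()
    n_gene = rng.binomial(cs.longcap_reads, cs.longcap_gene_share)
    n_loci = cs.longcap_reads - n_gene
    gw = np.maximum(expr, 0) * (genes["end"] - genes["start"])
    gi = rng.choice(len(genes), size=n_gene, p=gw / gw.sum())
    gs_, ge_ = genes["start"].to_numpy()[gi], genes["end"].to_numpy()[gi]
    span = np.maximum(ge_ - gs_ - cs.longcap_length, 1)
    gstart = gs_ + (rng.random(n_gene) * span).astype(np.int64)
    gene_reads = pd.DataFrame({
        "chrom": genes["chrom"].to_numpy()[gi], "start": gstart,
        "end": np.minimum(gstart + cs.longcap_length, ge_),
        "strand": genes["strand"].to_numpy()[gi],
    })
    li = rng.integers(0, len(lc_loci), size=n_loci)
    ls, le = lc_loci["start"].to_numpy()[li], lc_loci["end"].to_numpy()[li]
    pir = is_pirna[li]
    # piRNA precursors: 28-nt reads spanning the locus; others: fragments inside
    span = np.maximum(le - ls - cs.longcap_length, 1)
    lstart = np.where(pir, ls, ls + (rng.random(n_loci) * span).astype(np.int64))
    lend = np.where(pir, ls + config.ncrna.pirna_length,
                    np.minimum(lstart + cs.longcap_length, le))
    loci_reads = pd.DataFrame({
        "chrom": lc_loci["chrom"].to_numpy()[li], "start": lstart, "end": lend,
        "strand": lc_loci["strand"].to_numpy()[li],
    })
    df = pd.concat([gene_reads, loci_reads], ignore_index=True)
    longcap = ReadSet(sample_id="longcap_WT", reads=as_intervals(df.assign(score=60)),
                      assay="longcap")
    return shortcap, longcap


# ---------------------------------------------------------------------------
# Epigenomic tracks and chromatin states
# ---------------------------------------------------------------------------

def simulate_tracks(
    config: SimulationConfig,
    genome: GenomeBuild,
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Piecewise-constant epigenomic tracks (bedGraph frames) with promoter /
    enhancer enrichment, plus a labelled chromatin-state segmentation.

    States: 1 promoter, 2 enhancer, 3 gene body, 4 piRNA cluster,
    5 repressed domain, 6..n_states background."""
    ts = config.tracks
    res = ts.resolution
    nuclear = [c for c in genome.chroms if c != "chrM"]

    # paint functional categories at track resolution
    cat = {}  # 0 background, 1 promoter, 2 enhancer, 3 gene body, 4 piRNA, 5 repressed
    for chrom in nuclear:
        nbin = -(-genome.chrom_lengths[chrom] // res)
        cat[chrom] = np.zeros(nbin, dtype=np.int8)

    def paint(chrom, start, end, code):
        arr = cat[chrom]
        arr[max(0, start // res): min(len(arr), -(-end // res))] = code

    # repressed domains over a configured genome fraction
    for chrom in nuclear:
        length = genome.chrom_lengths[chrom]
        covered = 0
        target = ts.repressed_genome_fraction * length
        while covered < target:
            w = int(rng.integers(*ts.repressed_domain_bp))
            s = int(rng.integers(0, max(1, length - w)))
            paint(chrom, s, s + w, 5)
            covered += w
    if config.ncrna.pirna_chrom in cat:
        paint(config.ncrna.pirna_chrom, *config.ncrna.pirna_cluster, 4)
    for row in genes.itertuples(index=False):
        if row.chrom in cat:
            paint(row.chrom, row.start, row.end, 3)
    erna = truth.intergenic_loci[truth.intergenic_loci["annotation_class"] == "eRNA"]
    for row in erna.itertuples(index=False):
        if row.chrom in cat:
            paint(row.chrom, row.start - ts.promoter_flank, row.end + ts.promoter_flank, 2)
    for row in genes.itertuples(index=False):
        if row.chrom not in cat:
            continue
        tss = row.start if row.strand == "+" else row.end - 1
        paint(row.chrom, tss - ts.promoter_flank, tss + ts.promoter_flank, 1)

    fold_by_cat = {
        name: np.array([1.0, ts.promoter_fold[name], ts.enhancer_fold[name],
                        1.0, 1.0, ts.repressed_fold[name]])
        for name in ts.promoter_fold
    }
    tracks: dict[str, pd.DataFrame] = {}
    for name, folds in fold_by_cat.items():
        frames = []
        for chrom in nuclear:
            codes = cat[chrom]
            base = rng.gamma(2.0, ts.baseline / 2.0, size=len(codes))
            vals = base * folds[codes]
            starts = np.arange(len(codes), dtype=np.int64) * res
            ends = np.minimum(starts + res, genome.chrom_lengths[chrom])
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                        "value": np.round(vals, 4)}))
        tracks[name] = pd.concat(frames, ignore_index=True)

    # chromatin states: functional categories keep their ids; background is
    # chopped into random blocks over the remaining state labels
    state_frames = []
    for chrom in nuclear:
        codes = cat[chrom].copy().astype(np.int16)
        bg = codes == 0
        block = np.maximum((rng.integers(2_000, 10_000) // res), 1)
        labels = rng.integers(6, ts.n_states + 1, size=len(codes) // int(block) + 2)
        fill = labels[(np.arange(len(codes)) // int(block))]
        codes[bg] = fill[bg]
        change = np.flatnonzero(np.diff(codes)) + 1
        seg_starts = np.concatenate([[0], change])
        seg_ends = np.concatenate([change, [len(codes)]])
        state_frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": seg_starts * res,
            "end": np.minimum(seg_ends * res, genome.chrom_lengths[chrom]),
            "name": [f"state{codes[s]}" for s in seg_starts],
            "state": codes[seg_starts],
        }))
    states = pd.concat(state_frames, ignore_index=True)
    return tracks, as_intervals(states)


# ---------------------------------------------------------------------------
# Time-course helpers for trend analysis
# ---------------------------------------------------------------------------

def simulate_null_timecourse(
    n_genes: int, n_timepoints: int, rng: np.random.Generator, sigma: float = 1.0
) -> np.ndarray:
    """Pure-noise repair matrix (genes x timepoints), no trend planted."""
    return rng.normal(0.0, sigma, size=(n_genes, n_timepoints))


def simulate_trend_series(
    profile: np.ndarray, noise_sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` noisy replicates of a planted per-timepoint profile."""
    profile = np.asarray(profile, dtype=float)
    return profile[None, :] + rng.normal(0.0, noise_sd, size=(n, len(profile)))
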