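"""Generator contracts: genome composition, annotation placement, excision
geometry, genotype presets, assay structure, determinism."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xrpipe.genomics import GenomeBuild, as_intervals, intersect_count
from xrpipe.qc import build_tt_map
from xrpipe.simulate import (
    SimulationConfig,
    simulate_annotations,
    simulate_capped,
    simulate_excision_products,
    simulate_genome,
    simulate_rnaseq,
    simulate_tracks,
    simulate_xrseq,
    trim_fragments,
)


def small_config(**overrides):
    cfg = SimulationConfig(seed=3)
    cfg.genome.chrom_lengths = {"chrI": 120_000, "chrIV": 120_000}
    cfg.ncrna.pirna_cluster = (30_000, 70_000)
    cfg.ncrna.pirna_count = 40
    cfg.ncrna.erna_count = 10
    cfg.ncrna.lincrna_count = 5
    cfg.ncrna.novel_locus_count = 8
    cfg.ncrna.pseudogene_count = 3
    cfg.ncrna.misc_ncrna_count = 3
    cfg.ncrna.other_count = 2
    cfg.genes.n_per_chrom = 12
    cfg.blacklist.count = 2
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def test_genome_extreme_compositions():
    cfg = SimulationConfig()
    cfg.genome.chrom_lengths = {"c": 100}
    cfg.genome.base_probs = {"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0}
    g = simulate_genome(cfg, np.random.default_rng(0))
    assert g.sequences["c"] == "A" * 100
    assert len(build_tt_map(g).positions("c", "+")) == 0
    cfg.genome.base_probs = {"A": 0.0, "C": 0.0, "G": 0.0, "T": 1.0}
    g = simulate_genome(cfg, np.random.default_rng(0))
    assert len(build_tt_map(g).positions("c", "+")) == 99


def test_genome_tt_frequency_matches_binomial_expectation():
    cfg = SimulationConfig()
    cfg.genome.chrom_lengths = {"c": 100_000}
    g = simulate_genome(cfg, np.random.default_rng(1))
    pT = cfg.genome.base_probs["T"]
    n = len(build_tt_map(g).positions("c", "+"))
    expected = pT ** 2 * (100_000 - 1)
    sigma = np.sqrt(expected * (1 - pT ** 2))
    assert abs(n - expected) < 3 * sigma


def test_genome_rejects_zero_length():
    cfg = SimulationConfig()
    cfg.genome.chrom_lengths = {"c": 0}
    with pytest.raises(ValueError):
        simulate_genome(cfg, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def test_gene_spacing_and_pirna_cluster(sim):
    genes = sim.genes.sort_values(["chrom", "start"])
    for _, sub in genes.groupby("chrom"):
        gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
        assert (gaps >= sim.cfg.genes.min_spacing).all()
    pir = sim.annotations[sim.annotations["annotation_class"] == "piRNA"]
    assert len(pir) == sim.cfg.ncrna.pirna_count
    assert (pir["chrom"] == sim.cfg.ncrna.pirna_chrom).all()
    c0, c1 = sim.cfg.ncrna.pirna_cluster
    assert (pir["start"] >= c0).all() and (pir["end"] <= c1).all()


def test_erna_bidirectional_fraction_within_ci():
    cfg = small_config()
    cfg.genome.chrom_lengths = {"chrI": 500_000, "chrIV": 200_000}
    cfg.ncrna.erna_count = 1000
    cfg.ncrna.erna_length = 60
    cfg.genes.n_per_chrom = 8
    genome = simulate_genome(cfg, np.random.default_rng(12))
    _, _, _, truth = simulate_annotations(cfg, genome, np.random.default_rng(12))
    loci = truth.intergenic_loci
    n_fwd = (loci["annotation_class"] == "eRNA").sum() - loci["name"].str.endswith("_rev").sum()
    n_rev = loci["name"].str.endswith("_rev").sum()
    phat = n_rev / cfg.ncrna.erna_count
    se = np.sqrt(0.9 * 0.1 / cfg.ncrna.erna_count)
    assert abs(phat - 0.9) < 2.576 * se
    assert n_fwd == cfg.ncrna.erna_count


def test_annotation_overflow_reports_achievable_count():
    cfg = small_config()
    cfg.genes.n_per_chrom = 400  # cannot fit 400 genes of >= 1.2 kb in 120 kb
    genome = simulate_genome(cfg, np.random.default_rng(0))
    with pytest.raises(ValueError, match="achievable count"):
        simulate_annotations(cfg, genome, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Excision geometry
# ---------------------------------------------------------------------------

def _no_jitter(cfg):
    cfg.excision.jitter_offsets = (0,)
    cfg.excision.jitter_probs = (1.0,)
    return cfg


def test_excision_geometry_plus_strand():
    cfg = _no_jitter(SimulationConfig())
    genome = GenomeBuild("g", {"c": 1000})
    sites = as_intervals(pd.DataFrame({"chrom": ["c"], "start": [100], "end": [102],
                                       "strand": ["+"]}))
    frags, dropped = simulate_excision_products(cfg, sites, genome, np.random.default_rng(0))
    assert dropped == 0
    assert (frags.iloc[0]["start"], frags.iloc[0]["end"]) == (81, 108)
    assert frags.iloc[0]["end"] - frags.iloc[0]["start"] == 27


def test_excision_geometry_minus_strand():
    cfg = _no_jitter(SimulationConfig())
    genome = GenomeBuild("g", {"c": 1000})
    sites = as_intervals(pd.DataFrame({"chrom": ["c"], "start": [100], "end": [102],
                                       "strand": ["-"]}))
    frags, _ = simulate_excision_products(cfg, sites, genome, np.random.default_rng(0))
    assert (frags.iloc[0]["start"], frags.iloc[0]["end"]) == (94, 121)


def test_excision_modal_length_27_with_jitter():
    cfg = SimulationConfig()
    genome = GenomeBuild("g", {"c": 1_000_000})
    rng = np.random.default_rng(8)
    starts = rng.integers(100, 999_800, 10_000)
    sites = as_intervals(pd.DataFrame({
        "chrom": "c", "start": starts, "end": starts + 2,
        "strand": rng.choice(["+", "-"], 10_000),
    }))
    frags, _ = simulate_excision_products(cfg, sites, genome, rng)
    lengths = (frags["end"] - frags["start"]).value_counts()
    assert lengths.idxmax() == 27
    assert set(lengths.index) <= {25, 26, 27, 28, 29}


def test_excision_drops_edge_events():
    cfg = _no_jitter(SimulationConfig())
    genome = GenomeBuild("g", {"c": 50})
    sites = as_intervals(pd.DataFrame({"chrom": ["c", "c"], "start": [5, 30],
                                       "end": [7, 32], "strand": ["+", "+"]}))
    frags, dropped = simulate_excision_products(cfg, sites, genome, np.random.default_rng(0))
    assert dropped == 1 and len(frags) == 1


def test_trimming_preserves_3prime_tt_offset(sim):
    """Every simulated repair read covers a template TT whose 3' base sits
    exactly 6 nt from the read's 3' end, for all trim lengths."""
    rng = np.random.default_rng(21)
    rs = simulate_xrseq(sim.cfg, sim.genome, sim.genes, sim.truth, "xpc-1", "1h", 1,
                        rng, sim.ttmap, n_reads=4000)
    ex = sim.cfg.excision
    reads = rs.reads
    for row in reads.sample(n=500, random_state=1).itertuples(index=False):
        seq = sim.genome.sequences[row.chrom][row.start:row.end]
        if row.strand == "+":
            dimer = seq[-(ex.three_prime_nt + 2):-ex.three_prime_nt]
        else:
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            rc = "".join(comp[b] for b in reversed(seq))
            dimer = rc[-(ex.three_prime_nt + 2):-ex.three_prime_nt]
        assert dimer == "TT"


# ---------------------------------------------------------------------------
# Genotype presets
# ---------------------------------------------------------------------------

def test_xpc1_zero_background_reads_are_pure_ts(sim):
    cfg = SimulationConfig(seed=1)
    cfg.xr.background_weight = 0.0
    rng = np.random.default_rng(5)
    rs = simulate_xrseq(cfg, sim.genome, sim.genes, sim.truth, "xpc-1", "1h", 1,
                        rng, sim.ttmap, n_reads=20_000)
    ts = intersect_count(sim.genes, rs, 0.5, "opposite").sum()
    nts = intersect_count(sim.genes, rs, 0.5, "same").sum()
    assert nts == 0 and ts > 0


def test_csb1_preset_is_strand_symmetric(sim):
    rng = np.random.default_rng(6)
    rs = simulate_xrseq(sim.cfg, sim.genome, sim.genes, sim.truth, "csb-1", "1h", 1,
                        rng, sim.ttmap, n_reads=50_000)
    ts = intersect_count(sim.genes, rs, 0.5, "opposite").sum()
    nts = intersect_count(sim.genes, rs, 0.5, "same").sum()
    n = ts + nts
    phat = ts / n
    assert abs(phat - 0.5) < 2.576 * np.sqrt(0.25 / n)


def test_unknown_genotype_rejected(sim):
    with pytest.raises(ValueError, match="genotype"):
        simulate_xrseq(sim.cfg, sim.genome, sim.genes, sim.truth, "xpa-1", "1h", 1,
                       np.random.default_rng(0), sim.ttmap)


def test_preset_invariants_enforced():
    cfg = SimulationConfig()
    with pytest.raises(ValueError, match="csb-1"):
        SimulationConfig(xr=type(cfg.xr)(genotype_weights={
            "WT": (0.6, 0.4), "csb-1": (0.2, 0.8), "xpc-1": (1.0, 0.0)}))


# ---------------------------------------------------------------------------
# RNA-seq / capped structure
# ---------------------------------------------------------------------------

def test_rnaseq_polya_restriction_and_capped_coverage(sim):
    rng = np.random.default_rng(7)
    counts, rna_sets = simulate_rnaseq(sim.cfg, sim.genome, sim.genes, sim.truth, rng)
    shortcap, longcap = simulate_capped(sim.cfg, sim.genome, sim.genes, sim.truth,
                                        np.random.default_rng(8))
    loci = sim.truth.intergenic_loci
    pirna = loci[loci["annotation_class"] == "piRNA"]
    # piRNA loci: long-cap covered, short-cap silent
    lc = intersect_count(pirna, longcap, 0.5, "ignore")
    sc = intersect_count(pirna, shortcap, 0.5, "ignore")
    assert lc.sum() > 0
    assert sc.sum() == 0
    # non-poly(A) ncRNA loci receive no RNA-seq signal beyond uniform noise
    nonpolya = loci[~loci["polya"]]
    rna = intersect_count(nonpolya, rna_sets["WT"], 0.5, "ignore")
    assert rna.sum() <= max(3, 0.001 * rna_sets["WT"].library_size)


def test_rnaseq_strains_highly_correlated(sim):
    counts, _ = simulate_rnaseq(sim.cfg, sim.genome, sim.genes, sim.truth,
                                np.random.default_rng(9))
    rho = stats.spearmanr(counts["WT"], counts["xpc-1"]).statistic
    assert rho > 0.9


def test_truth_loci_receive_tcr_reads_at_default_depth(sim):
    rng = np.random.default_rng(10)
    rs = simulate_xrseq(sim.cfg, sim.genome, sim.genes, sim.truth, "xpc-1", "1h", 1,
                        rng, sim.ttmap)
    loci = sim.truth.intergenic_loci
    flip = {"+": "-", "-": "+"}
    has_tt = np.array([sim.ttmap.count(r.chrom, r.start, r.end, flip[r.strand]) > 0
                       for r in loci.itertuples(index=False)])
    counts = intersect_count(loci, rs, 0.25, "ignore")
    assert (counts[has_tt] > 0).mean() > 0.99


# ---------------------------------------------------------------------------
# Tracks and states
# ---------------------------------------------------------------------------

def test_tracks_promoter_enrichment_and_state_partition(sim):
    tracks, states = simulate_tracks(sim.cfg, sim.genome, sim.genes, sim.truth,
                                     np.random.default_rng(11))
    atac = tracks["ATAC"]
    tss = np.where(sim.genes["strand"] == "+", sim.genes["start"], sim.genes["end"] - 1)
    prom = set(zip(sim.genes["chrom"], tss // 200))
    in_prom = atac.apply(lambda r: (r["chrom"], r["start"] // 200) in prom, axis=1)
    assert atac.loc[in_prom, "value"].mean() > 3 * atac.loc[~in_prom, "value"].mean()
    # states tile each nuclear chromosome without overlap
    for chrom in [c for c in sim.genome.chroms if c != "chrM"]:
        sub = states[states["chrom"] == chrom].sort_values("start")
        assert sub.iloc[0]["start"] == 0
        assert sub.iloc[-1]["end"] == sim.genome.chrom_lengths[chrom]
        assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------

def test_fixed_seed_fixes_every_output(sim):
    cfg = SimulationConfig(seed=5)
    g1 = simulate_genome(cfg, np.random.default_rng(5))
    g2 = simulate_genome(cfg, np.random.default_rng(5))
    assert g1.sequences == g2.sequences
    rs1 = simulate_xrseq(sim.cfg, sim.genome, sim.genes, sim.truth, "WT", "8h", 1,
                         np.random.default_rng(5), sim.ttmap, n_reads=2000)
    rs2 = simulate_xrseq(sim.cfg, sim.genome, sim.genes, sim.truth, "WT", "8h", 1,
                         np.random.default_rng(5), sim.ttmap, n_reads=2000)
    pd.testing.assert_frame_equal(rs1.reads, rs2.reads)
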