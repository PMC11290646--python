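"""Interval model, tiling, intersection counting, algebra, and format I/O."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from xrpipe.genomics import (
    CE11_CHROM_LENGTHS,
    GenomeBuild,
    GenomicsError,
    StrandedInterval,
    as_intervals,
    extend_upstream,
    intersect_count,
    merge,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_gff_subset,
    subtract,
    tile_genome,
    write_bed,
)


def frame(rows):
    return as_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"]))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def test_interval_invariants():
    with pytest.raises(GenomicsError):
        StrandedInterval("chr1", 10, 10)
    with pytest.raises(GenomicsError):
        StrandedInterval("chr1", 20, 10)
    with pytest.raises(GenomicsError):
        StrandedInterval("chr1", 0, 10, "x")
    assert len(StrandedInterval("chr1", 0, 24, "+")) == 24


def test_genome_build_rejects_bad_lengths():
    with pytest.raises(GenomicsError):
        GenomeBuild("g", {"chr1": 0})
    with pytest.raises(GenomicsError):
        GenomeBuild("g", {})


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,width,n_bins", [
    (1000, 200, 5),
    (13_794, 200, 69),
    (999, 1000, 1),
])
def test_tile_counts(length, width, n_bins):
    grid = tile_genome(GenomeBuild("g", {"c": length}), width)
    assert len(grid) == n_bins
    assert grid.bins.iloc[-1]["end"] == length


def test_tile_terminal_partial_bin():
    grid = tile_genome(GenomeBuild("g", {"c": 13_794}), 200)
    last = grid.bins.iloc[-1]
    assert (last["start"], last["end"]) == (13_600, 13_794)


def test_tile_partitions_each_chromosome(toy_genome):
    grid = tile_genome(toy_genome, 333)
    for chrom, length in toy_genome.chrom_lengths.items():
        sub = grid.bins[grid.bins["chrom"] == chrom].sort_values("start")
        widths = (sub["end"] - sub["start"]).sum()
        assert widths == length
        assert len(sub) == math.ceil(length / 333)
        # consecutive and non-overlapping
        assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()


def test_tile_reference_scale_bin_total():
    grid = tile_genome(GenomeBuild("ce11", CE11_CHROM_LENGTHS), 200)
    assert len(grid) == sum(math.ceil(v / 200) for v in CE11_CHROM_LENGTHS.values())


def test_tile_rejects_empty_or_bad_width(toy_genome):
    with pytest.raises(GenomicsError):
        tile_genome(toy_genome, 0)


# ---------------------------------------------------------------------------
# Intersection counting
# ---------------------------------------------------------------------------

def test_intersect_basic_same_strand():
    features = frame([("chr1", 0, 1000, "f", 0, "+")])
    reads = frame([("chr1", 100, 124, "r", 0, "+")])
    assert intersect_count(features, reads, 0.5, "same").tolist() == [1]
    assert intersect_count(features, reads, 0.5, "opposite").tolist() == [0]


def test_intersect_fraction_boundary():
    # 22-nt read with 10 nt inside: 10/22 fails at 0.5, passes at 0.45
    features = frame([("chr1", 0, 100, "f", 0, "+")])
    reads = frame([("chr1", 90, 112, "r", 0, "+")])
    assert intersect_count(features, reads, 0.5, "same").tolist() == [0]
    assert intersect_count(features, reads, 0.45, "same").tolist() == [1]


def test_intersect_exact_half_tie_counts():
    features = frame([("chr1", 0, 12, "f", 0, "+")])
    reads = frame([("chr1", 0, 24, "r", 0, "+")])  # exactly half inside
    assert intersect_count(features, reads, 0.5, "same").tolist() == [1]


def brute_force_counts(features, reads, frac, rule):
    out = []
    for f in features.itertuples(index=False):
        c = 0
        for r in reads.itertuples(index=False):
            if r.chrom != f.chrom:
                continue
            ov = min(r.end, f.end) - max(r.start, f.start)
            if ov <= 0 or Fraction(ov, r.end - r.start) < Fraction(frac).limit_denominator(64):
                continue
            if rule == "same" and r.strand != f.strand:
                continue
            if rule == "opposite" and (r.strand == f.strand or r.strand == "."):
                continue
            c += 1
        out.append(c)
    return out


@pytest.mark.parametrize("rule", ["same", "opposite", "ignore"])
@pytest.mark.parametrize("frac", [0.25, 0.5, 1.0])
def test_intersect_matches_brute_force(rule, frac):
    rng = np.random.default_rng(17)
    n_feat, n_read = 50, 200
    fstart = rng.integers(0, 5000, n_feat)
    rstart = rng.integers(0, 5000, n_read)
    features = frame([
        ("chr1", s, s + rng.integers(50, 400), f"f{i}", 0, rng.choice(["+", "-"]))
        for i, s in enumerate(fstart)
    ])
    reads = frame([
        ("chr1", s, s + rng.integers(19, 30), f"r{i}", 0, rng.choice(["+", "-"]))
        for i, s in enumerate(rstart)
    ])
    got = intersect_count(features, reads, frac, rule).tolist()
    assert got == brute_force_counts(features, reads, frac, rule)


def test_intersect_read_counts_in_multiple_features():
    features = frame([("chr1", 0, 100, "a", 0, "+"), ("chr1", 50, 150, "b", 0, "+")])
    reads = frame([("chr1", 60, 80, "r", 0, "+")])
    assert intersect_count(features, reads, 0.5, "same").tolist() == [1, 1]


def test_intersect_warns_on_orphan_chromosomes():
    features = frame([("chr1", 0, 100, "f", 0, "+")])
    reads = frame([("chr9", 0, 24, "r", 0, "+")])
    with pytest.warns(UserWarning):
        assert intersect_count(features, reads, 0.5, "ignore").tolist() == [0]


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def test_merge_overlapping():
    out = merge(frame([("c", 0, 10, ".", 0, "."), ("c", 5, 20, ".", 0, ".")]))
    assert out[["start", "end"]].to_numpy().tolist() == [[0, 20]]


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 400)), min_size=1,
                    max_size=60))
    def test_merge_properties_hold_for_any_input(ivs):
        df = frame([("c", s, s + w, ".", 0, ".") for s, w in ivs])
        m = merge(df)
        # sorted, disjoint, within bounds, covering the same positions
        assert (m["start"].to_numpy()[1:] >= m["end"].to_numpy()[:-1]).all()
        assert m["start"].min() == df["start"].min()
        assert m["end"].max() == df["end"].max()
        covered = set()
        for s, w in ivs:
            covered.update(range(s, s + w))
        merged_cov = set()
        for r in m.itertuples(index=False):
            merged_cov.update(range(r.start, r.end))
        assert covered == merged_cov
except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


def test_merge_sorted_disjoint_idempotent():
    rng = np.random.default_rng(3)
    s = rng.integers(0, 10_000, 300)
    ivs = frame([("c", x, x + rng.integers(1, 500), ".", 0, ".") for x in s])
    m = merge(ivs)
    assert (m["start"].to_numpy()[1:] >= m["end"].to_numpy()[:-1]).all()
    pd.testing.assert_frame_equal(merge(m), m)


def test_subtract_removes_whole_overlapping_intervals():
    bins = frame([("c", i * 100, (i + 1) * 100, ".", 0, ".") for i in range(10)])
    feature = frame([("c", 250, 480, ".", 0, ".")])  # spans bins 3-5 (1-based)
    out = subtract(bins, feature)
    assert len(out) == 7
    assert 200 not in out["start"].tolist() and 400 not in out["start"].tolist()


def test_extend_upstream_minus_strand(toy_genome):
    gene = frame([("chr1", 5000, 6000, "g", 0, "-")])
    out = extend_upstream(gene, 2000, toy_genome)
    assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (5000, 8000)


def test_extend_upstream_clips_at_bounds(toy_genome):
    gene = frame([("chr1", 500, 1500, "g", 0, "+"), ("chr1", 99_000, 99_900, "h", 0, "-")])
    out = extend_upstream(gene, 2000, toy_genome)
    assert out.iloc[0]["start"] == 0
    assert out.iloc[1]["end"] == 100_000


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_bed_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    df = frame([
        ("chr1", int(s), int(s) + int(rng.integers(1, 100)), f"r{i}",
         int(rng.integers(0, 60)), rng.choice(["+", "-"]))
        for i, s in enumerate(rng.integers(0, 10_000, 1000))
    ])
    path = tmp_path / "t.bed"
    write_bed(df, path)
    back = read_bed(path)
    pd.testing.assert_frame_equal(back.astype({"score": int}), df.astype({"score": int}))


def test_bed_line_parsing_and_errors(tmp_path):
    p = tmp_path / "x.bed"
    p.write_text("chrI\t100\t124\tr1\t0\t+\n")
    df = read_bed(p)
    assert df.iloc[0][["chrom", "start", "end", "strand"]].tolist() == ["chrI", 100, 124, "+"]
    p.write_text("chrI\t100\t124\nchrI\tnope\t5\n")
    with pytest.raises(GenomicsError, match=":2"):
        read_bed(p)


def test_gff_coordinate_conversion(tmp_path):
    p = tmp_path / "x.gff3"
    p.write_text("chrI\tsrc\tgene\t101\t124\t.\t+\t.\tID=g1\n")
    df = read_gff_subset(p)
    assert (df.iloc[0]["start"], df.iloc[0]["end"]) == (100, 124)
    assert df.iloc[0]["name"] == "g1"
    assert df.iloc[0]["biotype"] == "gene"


def test_chrom_sizes_and_bedgraph(tmp_path):
    p = tmp_path / "g.chrom.sizes"
    p.write_text("chrI\t1500\nchrII\t900\n")
    g = read_chrom_sizes(p)
    assert g.chroms == ["chrI", "chrII"]
    assert g.chrom_lengths["chrII"] == 900
    bg = tmp_path / "t.bedGraph"
    bg.write_text("chrI\t0\t100\t2.5\nchrI\t100\t200\t4\n")
    track = read_bedgraph(bg)
    assert track["value"].tolist() == [2.5, 4.0]
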