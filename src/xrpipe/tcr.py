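"""Strand-resolved repair quantification over genes.

Transcription-coupled repair (TCR) removes lesions from the template strand
of transcribed genes, so its genome-wide signature is an excess of repair
reads mapping opposite to the annotated (coding) strand.  The per-gene proxy
statistic is the TS fraction, TS/(TS+NTS): 0.5 means no strand preference
(pure global repair), values near 1 mean pure TCR.

Counting follows bedtools `intersect -c -wa -F 0.5` semantics: a read counts
toward a feature when at least half the read overlaps it, on the template
strand (``-S``, opposite of the gene) for TS and the coding strand (``-s``)
for NTS.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics import GenomeBuild, ReadSet, intersect_count, metagene_windows


# ---------------------------------------------------------------------------
# Gene selection and QC
# ---------------------------------------------------------------------------

def select_profile_genes(
    genes: pd.DataFrame, min_length: int = 2000, min_gap: int = 500
) -> pd.DataFrame:
    """Genes strictly longer than ``min_length`` and at least ``min_gap`` bp
    from the nearest neighbouring gene on either side (any strand).

    Overlapping neighbours count as gap < 0 and disqualify both.
    """
    g = genes.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    keep = np.zeros(len(g), dtype=bool)
    for _, idx in g.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        starts = g.loc[idx, "start"].to_numpy()
        ends = g.loc[idx, "end"].to_numpy()
        prev_end = np.concatenate([[-np.inf], ends[:-1]])
        next_start = np.concatenate([starts[1:], [np.inf]])
        gap_ok = (starts - prev_end >= min_gap) & (next_start - ends >= min_gap)
        keep[idx] = gap_ok
    keep &= (g["end"] - g["start"]).to_numpy() > min_length
    return g[keep].reset_index(drop=True)


def gene_qc(
    genes: pd.DataFrame,
    ttmap,
    readsets: list[ReadSet],
    min_tt: int = 10,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Retain genes with >= ``min_tt`` TT dimers on the template OR coding
    strand, and >= ``min_reads`` reads in total across all samples (TS+NTS
    counts at the half-read overlap rule)."""
    flip = {"+": "-", "-": "+"}
    tt_ts = np.array([ttmap.count(r.chrom, r.start, r.end, flip[r.strand])
                      for r in genes.itertuples(index=False)])
    tt_nts = np.array([ttmap.count(r.chrom, r.start, r.end, r.strand)
                       for r in genes.itertuples(index=False)])
    total = np.zeros(len(genes), dtype=np.int64)
    for rs in readsets:
        total += intersect_count(genes, rs, 0.5, "opposite")
        total += intersect_count(genes, rs, 0.5, "same")
    keep = ((tt_ts >= min_tt) | (tt_nts >= min_tt)) & (total >= min_reads)
    return genes[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# TS / NTS counting and normalisation
# ---------------------------------------------------------------------------

def ts_nts_counts(
    genes: pd.DataFrame, readset: ReadSet | pd.DataFrame, frac: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (TS, NTS) read counts: TS counts reads on the strand opposite
    the gene (template strand), NTS on the gene's own strand."""
    rdf = readset.reads if isinstance(readset, ReadSet) else readset
    if (rdf["strand"] == ".").any():
        raise ValueError("repair reads must be stranded")
    if (genes["strand"] == ".").any():
        raise ValueError("genes must be stranded")
    ts = intersect_count(genes, rdf, frac, "opposite")
    nts = intersect_count(genes, rdf, frac, "same")
    return ts, nts


def ts_fraction(ts_count, nts_count):
    """TS/(TS+NTS); undefined (NaN) where both counts are zero."""
    ts = np.asarray(ts_count, dtype=float)
    nts = np.asarray(nts_count, dtype=float)
    tot = ts + nts
    return np.divide(ts, tot, out=np.full_like(ts, np.nan), where=tot > 0)


def rpkm(count, length_bp, library_size):
    """Reads per kilobase of feature per million mapped reads."""
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0) or library_size <= 0:
        raise ValueError("length and library size must be positive")
    return np.asarray(count, dtype=float) / (length_bp / 1e3) / (library_size / 1e6)


def repair_strand_summary(genes: pd.DataFrame, readset: ReadSet) -> pd.DataFrame:
    """Per-gene strand-resolved repair summary: counts, RPKM, TS fraction.

    The ``undefined`` flag marks 0/0 genes; their TS fraction is missing and
    must be excluded from cohort means.
    """
    ts, nts = ts_nts_counts(genes, readset)
    length = (genes["end"] - genes["start"]).to_numpy()
    lib = readset.library_size
    frac = ts_fraction(ts, nts)
    return pd.DataFrame({
        "gene_id": genes["name"].to_numpy(),
        "ts_count": ts,
        "nts_count": nts,
        "ts_rpkm": rpkm(ts, length, lib),
        "nts_rpkm": rpkm(nts, length, lib),
        "ts_fraction": frac,
        "undefined": np.isnan(frac),
    })


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneMatrix:
    """Per-gene x 100-bin RPKM matrix for one strand class, plus column means."""

    matrix: pd.DataFrame          # genes x bins, RPKM
    mean_profile: np.ndarray      # length 100
    strand_class: str
    n_dropped: int


def metagene_profile(
    genes: pd.DataFrame,
    readset: ReadSet,
    strand_class: str = "TS",
    genome: GenomeBuild | None = None,
    frac: float = 0.5,
    **window_kwargs,
) -> MetageneMatrix:
    """Mean strand-resolved repair across gene-anchored windows.

    The TSS window (500 bp upstream to 1 kb downstream) and the TES window
    (1 kb upstream to 500 bp downstream) are each split into 50 bins along
    transcription, 100 bins per gene; per-bin counts are normalised to RPKM
    by bin width and library size.  Genes whose windows leave the chromosome
    are dropped and counted.
    """
    if strand_class not in ("TS", "NTS"):
        raise ValueError("strand_class must be TS or NTS")
    if genome is None:
        raise ValueError("metagene_profile requires the genome for window clipping")
    windows, dropped = metagene_windows(genes, genome, **window_kwargs)
    rule = "opposite" if strand_class == "TS" else "same"
    counts = intersect_count(windows, readset, frac, rule)
    width = (windows["end"] - windows["start"]).to_numpy()
    vals = rpkm(counts, width, readset.library_size)
    mat = windows.assign(v=vals).pivot(index="gene_id", columns="bin", values="v")
    n_bins = mat.shape[1]
    if len(mat) and n_bins != 2 * window_kwargs.get("bins_per_window", 50):
        raise AssertionError(f"expected {2 * window_kwargs.get('bins_per_window', 50)} bins, got {n_bins}")
    return MetageneMatrix(matrix=mat, mean_profile=mat.to_numpy().mean(axis=0) if len(mat)
                          else np.zeros(n_bins), strand_class=strand_class, n_dropped=dropped)


# ---------------------------------------------------------------------------
# TSS heatmaps
# ---------------------------------------------------------------------------

@dataclass
class TSSHeatmap:
    ts: pd.DataFrame              # TSS x bins RPKM, rows in ranked order
    nts: pd.DataFrame
    row_order: np.ndarray         # indices into the filtered TSS table, by descending signal
    tss: pd.DataFrame             # the retained TSS records

    def best_half(self) -> np.ndarray:
        """Row indices of the best represented half (top 50% by row sum)."""
        return self.row_order[: max(1, len(self.row_order) // 2)]


def filter_tss(tss: pd.DataFrame, min_separation: int = 1000) -> pd.DataFrame:
    """Deduplicate TSSs and enforce a minimum pairwise separation by a
    coordinate-order scan: keep a TSS iff it lies >= ``min_separation`` from
    the last kept one (deterministic keep-first rule)."""
    t = tss.drop_duplicates(subset=["chrom", "pos"]).sort_values(["chrom", "pos"])
    keep_rows = []
    for _, sub in t.groupby("chrom", sort=False):
        last = -np.inf
        for row in sub.itertuples():
            if row.pos - last >= min_separation:
                keep_rows.append(row.Index)
                last = row.pos
    return t.loc[keep_rows].reset_index(drop=True)


def tss_heatmap(
    tss: pd.DataFrame,
    readset: ReadSet,
    genome: GenomeBuild,
    flank: int = 500,
    bin_width: int = 10,
    min_separation: int = 1000,
    frac: float = 0.5,
) -> TSSHeatmap:
    """Strand-resolved RPKM matrix over [TSS - flank, TSS + flank), binned at
    ``bin_width``, rows ranked by total signal (descending, stable).

    ``tss`` needs columns chrom, pos, strand.  Bins run 5'->3' along the
    annotated direction of transcription.
    """
    t = filter_tss(tss, min_separation)
    n_bins = 2 * flank // bin_width
    windows = []
    for i, row in enumerate(t.itertuples(index=False)):
        length = genome.chrom_lengths[row.chrom]
        lo, hi = row.pos - flank, row.pos + flank
        if lo < 0 or hi > length:
            continue
        starts = lo + np.arange(n_bins) * bin_width
        b = np.arange(n_bins) if row.strand == "+" else np.arange(n_bins)[::-1]
        windows.append(pd.DataFrame({
            "row": i, "bin": b, "chrom": row.chrom, "start": starts,
            "end": starts + bin_width, "strand": row.strand,
        }))
    if not windows:
        empty = pd.DataFrame()
        return TSSHeatmap(ts=empty, nts=empty, row_order=np.array([], int), tss=t)
    wdf = pd.concat(windows, ignore_index=True)
    lib = readset.library_size
    mats = {}
    for name, rule in (("ts", "opposite"), ("nts", "same")):
        counts = intersect_count(wdf, readset, frac, rule)
        vals = rpkm(counts, bin_width, lib) if lib > 0 else np.zeros(len(wdf))
        mats[name] = wdf.assign(v=vals).pivot(index="row", columns="bin", values="v")
    total = mats["ts"].sum(axis=1) + mats["nts"].sum(axis=1)
    order = np.argsort(-total.to_numpy(), kind="stable")
    return TSSHeatmap(ts=mats["ts"].iloc[order], nts=mats["nts"].iloc[order],
                      row_order=total.index.to_numpy()[order], tss=t)


def gene_tss_table(genes: pd.DataFrame) -> pd.DataFrame:
    """TSS records (chrom, pos, strand) from a gene table."""
    pos = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return pd.DataFrame({"chrom": genes["chrom"], "pos": pos, "strand": genes["strand"]})
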