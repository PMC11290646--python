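"""Discovery of intergenic transcription by genomic binning.

The genome is tiled into fixed-width bins; bins touching gene bodies, their
2-kb upstream promoter extensions, or blacklist regions are excluded.  Reads
from each assay are counted per surviving bin (>= 1 bp overlap, strand
collapsed), adjusted for library size, and time-course repair is combined as
the median across timepoints per replicate.  Detection calls follow fixed
combination rules — repair (XR) requires both replicates non-zero, RNA-seq
requires both strains, capped RNA-seq requires either cap fraction — and the
three call sets are partitioned into a Venn diagram; bins unique to the
repair assay are classified against the annotation catalogue.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics import BinGrid, GenomeBuild, ReadSet, extend_upstream, overlaps_any

ANNOTATION_PRIORITY = ["piRNA", "pseudogene", "protein_coding", "eRNA", "lincRNA", "ncRNA", "other"]


# ---------------------------------------------------------------------------
# Bin universe
# ---------------------------------------------------------------------------

def intergenic_bins(
    grid: BinGrid,
    genes: pd.DataFrame,
    genome: GenomeBuild,
    upstream: int = 2000,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bins not overlapping (>= 1 bp) any gene body, any strand-aware
    ``upstream``-bp promoter extension, or any blacklist interval."""
    extended = extend_upstream(genes, upstream, genome)
    drop = overlaps_any(grid.bins, extended)
    if blacklist is not None and len(blacklist):
        drop |= overlaps_any(grid.bins, blacklist)
    return grid.bins[~drop].reset_index(drop=True)


def count_reads_in_bins(
    bins: pd.DataFrame, reads: pd.DataFrame | ReadSet, bin_width: int
) -> np.ndarray:
    """Reads per bin at >= 1 bp overlap, strand-collapsed.

    Requires fixed-width tiling bins (the terminal chromosome bin may be
    short); a read overlapping several bins counts in each.
    """
    rdf = reads.reads if isinstance(reads, ReadSet) else reads
    out = np.zeros(len(bins), dtype=np.int64)
    b = bins.reset_index(drop=True)
    for chrom, bsub in b.groupby("chrom", sort=False):
        sel = rdf["chrom"] == chrom
        if not sel.any():
            continue
        rstart = rdf.loc[sel, "start"].to_numpy()
        rend = rdf.loc[sel, "end"].to_numpy()
        # map tiled bin start -> row, then count every tile index the read touches
        starts = bsub["start"].to_numpy()
        rows = bsub.index.to_numpy()
        n_tiles = int(starts.max() // bin_width) + 1 if len(starts) else 0
        tile_map = np.full(n_tiles, -1, dtype=np.int64)
        tile_map[starts // bin_width] = rows
        first = rstart // bin_width
        last = (rend - 1) // bin_width
        span = int((last - first).max()) + 1 if len(first) else 0
        for k in range(span):
            idx = first + k
            live = (idx <= last) & (idx < n_tiles)
            hit = tile_map[idx[live]]
            hit = hit[hit >= 0]
            np.add.at(out, hit, 1)
    return out


# ---------------------------------------------------------------------------
# Adjusted counts and combination rules
# ---------------------------------------------------------------------------

def adjust_library_size(count, library_size: int):
    """Counts per million mapped reads: count / (library_size / 1e6)."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return np.asarray(count, dtype=float) / (library_size / 1e6)


def combine_timepoints(per_timepoint: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median across timepoint columns, per bin (one replicate)."""
    arr = per_timepoint.to_numpy() if isinstance(per_timepoint, pd.DataFrame) else np.asarray(per_timepoint)
    return np.median(arr, axis=1)


@dataclass
class CallMatrix:
    """Per-bin adjusted counts for every assay and the three boolean call sets."""

    bins: pd.DataFrame
    counts: pd.DataFrame          # columns: xr_rep1, xr_rep2, rna_WT, rna_xpc, shortcap, longcap
    calls: pd.DataFrame           # columns: xr, rna, capped (bool)


def call_detected(
    xr_rep1, xr_rep2, rna_wt, rna_xpc, shortcap, longcap
) -> pd.DataFrame:
    """Detection calls per bin.

    XR: non-zero combined repair in both replicates; RNA: non-zero in both
    strains; capped: non-zero in either cap fraction.
    """
    arrays = {"xr_rep1": xr_rep1, "xr_rep2": xr_rep2, "rna_wt": rna_wt,
              "rna_xpc": rna_xpc, "shortcap": shortcap, "longcap": longcap}
    for name, arr in arrays.items():
        if arr is None:
            raise ValueError(f"missing required assay input: {name}")
        arrays[name] = np.asarray(arr, dtype=float)
    n = {len(a) for a in arrays.values()}
    if len(n) != 1:
        raise ValueError("all assay vectors must cover the same bin universe")
    return pd.DataFrame({
        "xr": (arrays["xr_rep1"] > 0) & (arrays["xr_rep2"] > 0),
        "rna": (arrays["rna_wt"] > 0) & (arrays["rna_xpc"] > 0),
        "capped": (arrays["shortcap"] > 0) | (arrays["longcap"] > 0),
    })


# ---------------------------------------------------------------------------
# Venn partition and classification
# ---------------------------------------------------------------------------

def venn_partition(calls: pd.DataFrame) -> dict[str, int]:
    """Counts of the seven exclusive regions of the XR/RNA/capped call sets.

    The regions partition the union: their counts sum to ``union``.
    """
    xr = calls["xr"].to_numpy()
    rna = calls["rna"].to_numpy()
    cap = calls["capped"].to_numpy()
    return {
        "xr_only": int((xr & ~rna & ~cap).sum()),
        "rna_only": int((~xr & rna & ~cap).sum()),
        "capped_only": int((~xr & ~rna & cap).sum()),
        "xr_rna": int((xr & rna & ~cap).sum()),
        "xr_capped": int((xr & ~rna & cap).sum()),
        "rna_capped": int((~xr & rna & cap).sum()),
        "xr_rna_capped": int((xr & rna & cap).sum()),
        "union": int((xr | rna | cap).sum()),
    }


@dataclass
class BinClassification:
    per_bin: pd.DataFrame         # bins + annotated flag + class
    class_fractions: pd.Series    # over annotated classes + unannotated, sums to 1
    chrom_distribution: pd.Series


def classify_unique_bins(
    unique_bins: pd.DataFrame, annotations: pd.DataFrame
) -> BinClassification:
    """Classify repair-unique bins against the annotation catalogue.

    A bin is annotated iff it overlaps (>= 1 bp) any annotation record;
    among several overlapping classes the fixed priority
    piRNA > pseudogene > protein_coding > eRNA > lincRNA > ncRNA > other
    wins.  Fractions over classes plus ``unannotated`` sum to 1.
    """
    b = unique_bins.reset_index(drop=True)
    cls = np.full(len(b), "unannotated", dtype=object)
    for klass in reversed(ANNOTATION_PRIORITY):   # low priority painted first
        sub = annotations[annotations["annotation_class"] == klass]
        if len(sub):
            cls[overlaps_any(b, sub)] = klass
    per_bin = b.assign(annotation_class=cls, annotated=cls != "unannotated")
    if len(b):
        fractions = per_bin["annotation_class"].value_counts(normalize=True)
    else:
        fractions = pd.Series(dtype=float)
    return BinClassification(
        per_bin=per_bin,
        class_fractions=fractions,
        chrom_distribution=per_bin["chrom"].value_counts(),
    )


# ---------------------------------------------------------------------------
# Detection metrics
# ---------------------------------------------------------------------------

@dataclass
class DetectionMetrics:
    sensitivity: float
    specificity: float
    f_measure: float              # geometric mean of sensitivity and specificity


def detection_metrics(predicted, truth) -> DetectionMetrics:
    """Sensitivity, specificity, and their geometric mean, against a boolean
    truth call set on the same bin universe.  With degenerate truth (all
    positive or all negative) the undefined metric is reported missing."""
    pred = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if pred.shape != t.shape:
        raise ValueError("predicted and truth must cover the same bin universe")
    tp = int((pred & t).sum())
    fn = int((~pred & t).sum())
    tn = int((~pred & ~t).sum())
    fp = int((pred & ~t).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    f = float(np.sqrt(sens * spec))
    return DetectionMetrics(sensitivity=sens, specificity=spec, f_measure=f)
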