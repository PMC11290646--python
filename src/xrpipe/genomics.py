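"""Coordinate-safe genomic intervals, interval algebra, genome tiling and text-format I/O.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  GFF input
(1-based, inclusive) is converted at the format boundary.  Interval collections
are plain :class:`pandas.DataFrame` objects with the canonical BED6 columns
``chrom, start, end, name, score, strand``; ``strand`` is one of ``+``, ``-``
or ``.`` (unstranded).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

#: ce11 chromosome lengths (UCSC), used for the reference-scale tiling check.
CE11_CHROM_LENGTHS = {
    "chrI": 15_072_434,
    "chrII": 15_279_421,
    "chrIII": 13_783_801,
    "chrIV": 17_493_829,
    "chrV": 20_924_180,
    "chrX": 17_718_942,
    "chrM": 13_794,
}


class GenomicsError(ValueError):
    """Raised on malformed coordinates or files."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeBuild:
    """Named reference frame: ordered chromosome names with lengths (bp).

    Optionally carries per-chromosome sequence (uppercase strings) when a
    FASTA is available; sequence is required only by the damage-landscape
    and read-composition operations.
    """

    name: str
    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise GenomicsError("genome must contain at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise GenomicsError(f"chromosome {chrom!r} has non-positive length {length}")
        if self.sequences is not None:
            for chrom, seq in self.sequences.items():
                if chrom in self.chrom_lengths and len(seq) != self.chrom_lengths[chrom]:
                    raise GenomicsError(
                        f"sequence length for {chrom!r} ({len(seq)}) disagrees with "
                        f"declared length ({self.chrom_lengths[chrom]})"
                    )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths


@dataclass(frozen=True)
class StrandedInterval:
    """Single 0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomicsError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise GenomicsError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReadSet:
    """A sample's mapped reads plus its assay metadata.

    ``reads`` holds BED6 columns; the BED score column carries the mapping
    quality when available.  ``library_size`` is the current read count.
    """

    sample_id: str
    reads: pd.DataFrame
    genotype: str = "WT"
    assay: str = "XR"
    timepoint: str | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        self.reads = as_intervals(self.reads)

    @property
    def library_size(self) -> int:
        return len(self.reads)


@dataclass
class BinGrid:
    """Consecutive non-overlapping fixed-width tiling of a genome.

    The terminal bin of each chromosome may be shorter than ``bin_width``.
    """

    bin_width: int
    bins: pd.DataFrame
    provenance: str = ""
    _chrom_offsets: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.bins)

    def bin_range(self, chrom: str) -> tuple[int, int]:
        """Row range [lo, hi) of this chromosome's bins in ``bins``."""
        return self._chrom_offsets[chrom]


# ---------------------------------------------------------------------------
# Interval frame helpers
# ---------------------------------------------------------------------------

def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise a frame to BED6 columns, filling name/score/strand defaults."""
    df = df.copy()
    if "chrom" not in df or "start" not in df or "end" not in df:
        raise GenomicsError("interval frame requires chrom/start/end columns")
    if "name" not in df:
        df["name"] = "."
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    extra = [c for c in df.columns if c not in BED_COLUMNS]
    return df[BED_COLUMNS + extra]


def validate_intervals(df: pd.DataFrame, genome: GenomeBuild) -> None:
    """Assert every interval lies within its chromosome of ``genome``."""
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise GenomicsError(f"chromosome {chrom!r} absent from genome {genome.name!r}")
        length = genome.chrom_lengths[chrom]
        if (sub["start"] < 0).any() or (sub["end"] > length).any():
            raise GenomicsError(f"interval outside [0, {length}) on {chrom}")
        if (sub["start"] >= sub["end"]).any():
            raise GenomicsError(f"empty or inverted interval on {chrom}")


def sort_intervals(df: pd.DataFrame, genome: GenomeBuild | None = None) -> pd.DataFrame:
    if genome is not None:
        order = {c: i for i, c in enumerate(genome.chroms)}
        key = df["chrom"].map(order)
        return df.assign(_k=key).sort_values(["_k", "start", "end"]).drop(columns="_k").reset_index(drop=True)
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_genome(genome: GenomeBuild, width: int) -> BinGrid:
    """Tile every chromosome into consecutive non-overlapping ``width``-bp bins.

    The terminal partial bin of each chromosome is kept, so each chromosome
    contributes ``ceil(length / width)`` bins.
    """
    if width < 1:
        raise GenomicsError(f"bin width must be >= 1, got {width}")
    chroms, starts, ends = [], [], []
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for chrom, length in genome.chrom_lengths.items():
        s = np.arange(0, length, width, dtype=np.int64)
        e = np.minimum(s + width, length)
        chroms.append(np.repeat(chrom, len(s)))
        starts.append(s)
        ends.append(e)
        offsets[chrom] = (pos, pos + len(s))
        pos += len(s)
    bins = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
        }
    )
    return BinGrid(bin_width=width, bins=as_intervals(bins), provenance=genome.name,
                   _chrom_offsets=offsets)


# ---------------------------------------------------------------------------
# Intersection counting (bedtools -c -wa -F <frac> [-s|-S] semantics)
# ---------------------------------------------------------------------------

def intersect_count(
    features: pd.DataFrame,
    reads: pd.DataFrame | ReadSet,
    min_read_overlap_frac: float = 0.5,
    strand_rule: str = "ignore",
) -> np.ndarray:
    """Count, per feature, reads overlapping it by ``>= frac`` of the read length.

    ``strand_rule``: ``same`` keeps reads on the feature's strand, ``opposite``
    keeps reads on the complementary strand (template-strand counting for
    repair reads against a gene's coding strand), ``ignore`` keeps all.
    A read may count toward several features.  Reads on chromosomes not
    carrying any feature contribute nothing (a warning is emitted once).
    """
    if not (0 < min_read_overlap_frac <= 1):
        raise GenomicsError("min_read_overlap_frac must be in (0, 1]")
    if strand_rule not in ("same", "opposite", "ignore"):
        raise GenomicsError(f"unknown strand_rule {strand_rule!r}")
    rdf = reads.reads if isinstance(reads, ReadSet) else reads

    counts = np.zeros(len(features), dtype=np.int64)
    feature_chroms = set(features["chrom"].unique())
    orphan = set(rdf["chrom"].unique()) - feature_chroms
    if orphan and len(features):
        warnings.warn(f"reads on chromosomes without features ignored: {sorted(orphan)}")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for chrom, sub in rdf.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        strands = sub["strand"].to_numpy()
        maxlen = int((ends - starts).max()) if len(sub) else 0
        by_chrom[chrom] = (starts, ends, strands, maxlen)

    frow = features.reset_index(drop=True)
    for chrom, fsub in frow.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        rs, re, rstr, maxlen = by_chrom[chrom]
        for idx, fs, fe, fstrand in zip(
            fsub.index, fsub["start"].to_numpy(), fsub["end"].to_numpy(), fsub["strand"].to_numpy()
        ):
            lo = np.searchsorted(rs, fs - maxlen, side="left")
            hi = np.searchsorted(rs, fe, side="left")
            if hi <= lo:
                continue
            s = rs[lo:hi]
            e = re[lo:hi]
            overlap = np.minimum(e, fe) - np.maximum(s, fs)
            rlen = e - s
            keep = overlap >= min_read_overlap_frac * rlen - 1e-9
            if strand_rule == "same":
                keep &= rstr[lo:hi] == fstrand
            elif strand_rule == "opposite":
                keep &= (rstr[lo:hi] != fstrand) & (rstr[lo:hi] != ".")
            counts[idx] = int(keep.sum())
    return counts


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: sorted, disjoint, strand-blind (bedtools merge)."""
    if len(intervals) == 0:
        return as_intervals(pd.DataFrame(columns=["chrom", "start", "end"]))
    out_chrom, out_start, out_end = [], [], []
    for chrom, sub in intervals.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out_chrom.append(chrom); out_start.append(cur_s); out_end.append(cur_e)
                cur_s, cur_e = s, e
        out_chrom.append(chrom); out_start.append(cur_s); out_end.append(cur_e)
    return as_intervals(pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end}))


def overlaps_any(query: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: overlaps (>= 1 bp) any interval of ``other``."""
    hit = np.zeros(len(query), dtype=bool)
    if len(other) == 0 or len(query) == 0:
        return hit
    merged = merge(other)
    q = query.reset_index(drop=True)
    for chrom, msub in merged.groupby("chrom", sort=False):
        sel = q["chrom"] == chrom
        if not sel.any():
            continue
        qs = q.loc[sel, "start"].to_numpy()
        qe = q.loc[sel, "end"].to_numpy()
        ms = msub["start"].to_numpy()
        me = msub["end"].to_numpy()
        # merged intervals are disjoint+sorted: candidate is the one whose
        # start is the last <= query end-1; overlap iff its end > query start
        j = np.searchsorted(ms, qe - 1, side="right") - 1
        ok = j >= 0
        jj = np.clip(j, 0, len(ms) - 1)
        hit[np.flatnonzero(sel.to_numpy())] = ok & (me[jj] > qs)
    return hit


def subtract(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Remove every interval of ``a`` that overlaps ``b`` by >= 1 bp.

    Whole-interval removal (bedtools intersect -v), the semantics used for
    bin exclusion; intervals are never clipped.
    """
    keep = ~overlaps_any(a, b)
    return a.reset_index(drop=True).loc[keep].reset_index(drop=True)


def extend_upstream(features: pd.DataFrame, d: int, genome: GenomeBuild) -> pd.DataFrame:
    """Extend each feature ``d`` bp 5' of its TSS (leftward on +, rightward on -).

    Coordinates are clipped at chromosome bounds.  Unstranded features extend
    leftward.
    """
    out = features.copy()
    plus = out["strand"] != "-"
    out.loc[plus, "start"] = np.maximum(out.loc[plus, "start"] - d, 0)
    lengths = out["chrom"].map(genome.chrom_lengths)
    out.loc[~plus, "end"] = np.minimum(out.loc[~plus, "end"] + d, lengths[~plus])
    return as_intervals(out)


# ---------------------------------------------------------------------------
# Sequence and gene-window helpers shared across modules
# ---------------------------------------------------------------------------

_BASE_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODES[ord(_b)] = _i
    _BASE_CODES[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes A=0, C=1, G=2, T=3, other=4."""
    return _BASE_CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def metagene_windows(
    genes: pd.DataFrame,
    genome: GenomeBuild,
    tss_upstream: int = 500,
    tss_downstream: int = 1000,
    tes_upstream: int = 1000,
    tes_downstream: int = 500,
    bins_per_window: int = 50,
) -> tuple[pd.DataFrame, int]:
    """Per-gene anchored windows split into equal bins in transcription orientation.

    Two windows per gene — around the TSS (``tss_upstream`` bp 5' to
    ``tss_downstream`` bp 3') and around the TES — each divided into
    ``bins_per_window`` equal bins, yielding ``2 * bins_per_window`` bins per
    gene.  Bin index runs 5'->3' along transcription (reversed genomic order
    for minus-strand genes).  Genes whose windows leave the chromosome are
    dropped; the count of dropped genes is returned.

    Returns a long frame (gene_id, bin, chrom, start, end, strand) and the
    dropped-gene count.
    """
    wa = tss_upstream + tss_downstream
    wb = tes_upstream + tes_downstream
    if wa % bins_per_window or wb % bins_per_window:
        raise GenomicsError("window widths must divide evenly into bins")
    ba, bb = wa // bins_per_window, wb // bins_per_window

    frames = []
    dropped = 0
    k = np.arange(bins_per_window)
    for row in genes.itertuples(index=False):
        length = genome.chrom_lengths[row.chrom]
        if row.strand == "-":
            tss_edge, tes_edge = row.end, row.start
            a_start = tss_edge + tss_upstream - ba * (k + 1)
            b_start = tes_edge + tes_upstream - bb * (k + 1)
            lo = min(b_start[-1], a_start[-1])
            hi = max(a_start[0] + ba, b_start[0] + bb)
        else:
            tss_edge, tes_edge = row.start, row.end
            a_start = tss_edge - tss_upstream + ba * k
            b_start = tes_edge - tes_upstream + bb * k
            lo = min(a_start[0], b_start[0])
            hi = max(a_start[-1] + ba, b_start[-1] + bb)
        if lo < 0 or hi > length:
            dropped += 1
            continue
        starts = np.concatenate([a_start, b_start])
        widths = np.concatenate([np.full(bins_per_window, ba), np.full(bins_per_window, bb)])
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": row.name,
                    "bin": np.arange(2 * bins_per_window),
                    "chrom": row.chrom,
                    "start": starts,
                    "end": starts + widths,
                    "strand": row.strand,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["gene_id", "bin", "chrom", "start", "end", "strand"]), dropped
    return pd.concat(frames, ignore_index=True), dropped


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path, name: str | None = None) -> GenomeBuild:
    """Two-column TSV (chrom, length) -> GenomeBuild, preserving file order."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GenomicsError(f"{path}:{i}: expected 'chrom<TAB>length'")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise GenomicsError(f"{path}:{i}: bad length {parts[1]!r}") from exc
    return GenomeBuild(name=name or Path(path).stem, chrom_lengths=lengths)


def write_chrom_sizes(genome: GenomeBuild, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | Path, genome: GenomeBuild | None = None) -> pd.DataFrame:
    """Read BED3–BED6 (0-based half-open) into an interval frame."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomicsError(f"{path}:{i}: BED needs >= 3 fields")
            try:
                rec = {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": parts[3] if len(parts) > 3 else ".",
                    "score": float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0,
                    "strand": parts[5] if len(parts) > 5 else ".",
                }
            except ValueError as exc:
                raise GenomicsError(f"{path}:{i}: malformed BED line") from exc
            rows.append(rec)
    df = as_intervals(pd.DataFrame(rows, columns=BED_COLUMNS)) if rows else as_intervals(
        pd.DataFrame(columns=BED_COLUMNS)
    )
    if genome is not None and len(df):
        validate_intervals(df, genome)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    as_intervals(df)[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph (chrom, start, end, value) -> frame with a ``value`` column."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GenomicsError(f"{path}:{i}: bedGraph needs 4 fields")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise GenomicsError(f"{path}:{i}: malformed bedGraph line") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_gff_subset(path: str | Path, feature_types: Iterable[str] | None = None) -> pd.DataFrame:
    """Read gene/ncRNA features from a GFF3 subset, converting to 0-based half-open.

    Only the columns needed downstream are kept; the ``ID`` attribute (or a
    positional fallback) becomes ``name`` and the feature type ``biotype``.
    """
    wanted = set(feature_types) if feature_types is not None else None
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenomicsError(f"{path}:{i}: GFF3 needs 9 fields")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = parts
            if wanted is not None and ftype not in wanted:
                continue
            try:
                start, end = int(start1) - 1, int(end1)  # 1-based inclusive -> 0-based half-open
            except ValueError as exc:
                raise GenomicsError(f"{path}:{i}: malformed coordinates") from exc
            name = f"feat{i}"
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    name = kv[3:]
                    break
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "name": name,
                 "score": 0, "strand": strand if strand in "+-" else ".", "biotype": ftype}
            )
    return as_intervals(pd.DataFrame(rows)) if rows else as_intervals(
        pd.DataFrame(columns=BED_COLUMNS + ["biotype"])
    )


def read_fasta(path: str | Path, name: str | None = None) -> GenomeBuild:
    """FASTA -> GenomeBuild carrying uppercase sequence."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise GenomicsError(f"no FASTA records in {path}")
    return GenomeBuild(
        name=name or Path(path).stem,
        chrom_lengths={c: len(s) for c, s in seqs.items()},
        sequences=seqs,
    )


def write_fasta(genome: GenomeBuild, path: str | Path) -> None:
    if genome.sequences is None:
        raise GenomicsError("genome carries no sequence")
    records = [SeqRecord(Seq(genome.sequences[c]), id=c, description="") for c in genome.chroms]
    SeqIO.write(records, str(path), "fasta")
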