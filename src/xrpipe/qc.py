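"""Post-alignment read QC, duplicate collapse, 3'-anchored read composition,
and strand-resolved TT-dinucleotide damage landscapes.

UV-induced cyclobutane pyrimidine dimers form almost exclusively at TT
dinucleotides, so the genome's strand-resolved TT map is the expected-damage
landscape against which repair reads are interpreted.  Excised repair
fragments carry the dimer at a fixed distance from their 3' end; the
positional dinucleotide profile makes that geometry visible.

3'-anchor convention used throughout (generator and profiler agree):
the *position* of a dinucleotide is the number of nucleotides strictly 3' of
it in the read.  A read ``5'-...N N [T T] x x x x x x-3'`` has its TT at
position 6 (six nucleotides follow the dimer); the dimer's 3' base is then 6
nt from the 3' end and its 5' base 7 nt.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomics import GenomeBuild, ReadSet, encode_bases, metagene_windows

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]
_TT = DINUCLEOTIDES.index("TT")


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Survivor counts after each sequential filter (non-increasing)."""

    total_mapped: int
    dedup: int
    mapq: int
    chrom: int
    length: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = [self.total_mapped, self.dedup, self.mapq, self.chrom, self.length]
        if any(b > a for a, b in zip(seq, seq[1:])):
            raise ValueError(f"QC counts must be non-increasing, got {seq}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": ["total_mapped", "dedup", "mapq", "chrom", "length"],
                "reads": [self.total_mapped, self.dedup, self.mapq, self.chrom, self.length],
            }
        )


def dedup(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse reads identical in (chrom, start, end, strand) to one record."""
    return reads.drop_duplicates(subset=["chrom", "start", "end", "strand"]).reset_index(drop=True)


def qc_filter(
    readset: ReadSet,
    min_mapq: int = 20,
    allowed_chroms: list[str] | None = None,
    len_range: tuple[int, int] = (19, 24),
) -> tuple[ReadSet, QCReport]:
    """Sequential post-alignment filters: dedup, mapq (strictly greater than
    ``min_mapq``), chromosome whitelist, read length within ``len_range``
    (inclusive).  Mapping quality is taken from the BED score column; reads
    without one fail the mapq filter (warned once).
    """
    df = readset.reads
    n_total = len(df)
    df = dedup(df)
    n_dedup = len(df)

    mapq = pd.to_numeric(df["score"], errors="coerce")
    if mapq.isna().any():
        warnings.warn("reads without mapping quality treated as failing the mapq filter")
    df = df[mapq > min_mapq]
    n_mapq = len(df)

    if allowed_chroms is not None:
        df = df[df["chrom"].isin(allowed_chroms)]
    n_chrom = len(df)

    rlen = df["end"] - df["start"]
    df = df[(rlen >= len_range[0]) & (rlen <= len_range[1])].reset_index(drop=True)
    n_len = len(df)

    report = QCReport(
        total_mapped=n_total, dedup=n_dedup, mapq=n_mapq, chrom=n_chrom, length=n_len,
        params={"min_mapq": min_mapq, "allowed_chroms": allowed_chroms, "len_range": list(len_range)},
    )
    out = ReadSet(
        sample_id=readset.sample_id, reads=df, genotype=readset.genotype,
        assay=readset.assay, timepoint=readset.timepoint, replicate=readset.replicate,
    )
    return out, report


# ---------------------------------------------------------------------------
# TT damage map
# ---------------------------------------------------------------------------

@dataclass
class TTMap:
    """Sorted TT dimer start positions per chromosome and strand.

    A TT on the minus strand reads AA on the plus-strand sequence; positions
    are always plus-strand coordinates of the dimer interval ``[p, p+2)``.
    """

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        table = self.plus if strand == "+" else self.minus
        return table.get(chrom, np.empty(0, dtype=np.int64))

    def count(self, chrom: str, start: int, end: int, strand: str) -> int:
        """Number of TT dimers fully inside [start, end) on ``strand``."""
        pos = self.positions(chrom, strand)
        return int(np.searchsorted(pos, end - 2, side="right") - np.searchsorted(pos, start))

    def positions_in(self, chrom: str, start: int, end: int, strand: str) -> np.ndarray:
        pos = self.positions(chrom, strand)
        lo = np.searchsorted(pos, start)
        hi = np.searchsorted(pos, end - 2, side="right")
        return pos[lo:hi]


def build_tt_map(genome: GenomeBuild) -> TTMap:
    """Scan genome sequence for TT dimers on both strands."""
    if genome.sequences is None:
        raise ValueError("genome carries no sequence; TT map needs a FASTA")
    plus: dict[str, np.ndarray] = {}
    minus: dict[str, np.ndarray] = {}
    T, A = 3, 0
    for chrom in genome.chroms:
        codes = encode_bases(genome.sequences[chrom])
        plus[chrom] = np.flatnonzero((codes[:-1] == T) & (codes[1:] == T)).astype(np.int64)
        minus[chrom] = np.flatnonzero((codes[:-1] == A) & (codes[1:] == A)).astype(np.int64)
    return TTMap(plus=plus, minus=minus)


# ---------------------------------------------------------------------------
# Positional dinucleotide composition (3'-anchored)
# ---------------------------------------------------------------------------

@dataclass
class DinucProfile:
    """Dinucleotide frequency by distance from the 3' read end.

    ``table`` is long-form: stratum (read length, or "pooled"), position
    (nt 3' of the dinucleotide), dinucleotide, frequency, n_obs.
    """

    table: pd.DataFrame
    n_excluded: int = 0

    def frequencies(self, stratum: str = "pooled") -> pd.DataFrame:
        sub = self.table[self.table["stratum"] == str(stratum)]
        return sub.pivot(index="position", columns="dinucleotide", values="frequency")

    def tt_argmax(self, stratum: str = "pooled") -> int:
        """Position (nt from 3' end) of maximal TT frequency."""
        freq = self.frequencies(stratum)["TT"]
        return int(freq.idxmax())


def positional_dinuc_freq(reads: pd.DataFrame | ReadSet, genome: GenomeBuild) -> DinucProfile:
    """Dinucleotide frequencies by position from the 3' end, per read-length
    stratum and pooled.  Minus-strand reads are reverse-complemented so every
    profile is in the read's own 5'->3' orientation.  Reads extending past a
    chromosome end (or containing non-ACGT bases at a position) are excluded
    from the affected counts.
    """
    if genome.sequences is None:
        raise ValueError("genome carries no sequence")
    df = reads.reads if isinstance(reads, ReadSet) else reads
    codes_by_chrom = {c: encode_bases(genome.sequences[c]) for c in df["chrom"].unique()
                      if c in (genome.sequences or {})}

    counts: dict[int, np.ndarray] = {}
    excluded = 0
    rlen = (df["end"] - df["start"]).to_numpy()
    for (chrom, strand, L), sub in df.groupby([df["chrom"], df["strand"], rlen]):
        L = int(L)
        if chrom not in codes_by_chrom or L < 2:
            excluded += len(sub)
            continue
        chrom_codes = codes_by_chrom[chrom]
        starts = sub["start"].to_numpy()
        ok = (starts >= 0) & (starts + L <= len(chrom_codes))
        excluded += int((~ok).sum())
        starts = starts[ok]
        if len(starts) == 0:
            continue
        idx = starts[:, None] + np.arange(L)[None, :]
        mat = chrom_codes[idx]
        if strand == "-":
            mat = 3 - mat[:, ::-1]  # reverse-complement; non-ACGT (4) -> -1, masked below
        dinuc = mat[:, :-1].astype(np.int16) * 4 + mat[:, 1:]
        valid = (mat[:, :-1] < 4) & (mat[:, :-1] >= 0) & (mat[:, 1:] < 4) & (mat[:, 1:] >= 0)
        stratum = counts.setdefault(L, np.zeros((L - 1, 16), dtype=np.int64))
        for j in range(L - 1):
            p = L - 2 - j  # nt strictly 3' of the dinucleotide
            col = dinuc[:, j][valid[:, j]]
            stratum[p] += np.bincount(col, minlength=16)

    rows = []
    max_p = max((arr.shape[0] for arr in counts.values()), default=0)
    pooled = np.zeros((max_p, 16), dtype=np.int64)
    for L, arr in sorted(counts.items()):
        pooled[: arr.shape[0]] += arr
        tot = arr.sum(axis=1, keepdims=True)
        freq = np.divide(arr, tot, out=np.zeros_like(arr, dtype=float), where=tot > 0)
        for p in range(arr.shape[0]):
            for d in range(16):
                rows.append((str(L), p, DINUCLEOTIDES[d], freq[p, d], int(arr[p].sum())))
    tot = pooled.sum(axis=1, keepdims=True)
    freq = np.divide(pooled, tot, out=np.zeros_like(pooled, dtype=float), where=tot > 0)
    for p in range(max_p):
        for d in range(16):
            rows.append(("pooled", p, DINUCLEOTIDES[d], freq[p, d], int(pooled[p].sum())))
    table = pd.DataFrame(rows, columns=["stratum", "position", "dinucleotide", "frequency", "n_obs"])
    return DinucProfile(table=table, n_excluded=excluded)


# ---------------------------------------------------------------------------
# TT landscape summaries
# ---------------------------------------------------------------------------

def tt_metagene(
    genes: pd.DataFrame,
    ttmap: TTMap,
    genome: GenomeBuild,
    strand_class: str = "TS",
    **window_kwargs,
) -> pd.DataFrame:
    """Mean TT dimer count per metagene bin (same 100-bin scheme as repair
    profiles).  ``strand_class``: TS counts dimers on the template strand
    (complement of the gene's coding strand), NTS on the coding strand.
    """
    if strand_class not in ("TS", "NTS"):
        raise ValueError("strand_class must be TS or NTS")
    windows, _ = metagene_windows(genes, genome, **window_kwargs)
    flip = {"+": "-", "-": "+"}
    vals = np.empty(len(windows))
    for i, row in enumerate(windows.itertuples(index=False)):
        strand = flip[row.strand] if strand_class == "TS" else row.strand
        vals[i] = ttmap.count(row.chrom, row.start, row.end, strand)
    windows = windows.assign(tt=vals)
    return windows.groupby("bin", as_index=False)["tt"].mean().rename(columns={"tt": "mean_tt"})


@dataclass
class TTLengthResult:
    per_gene: pd.DataFrame
    r_ts_nts: float
    r_ts_length: float
    r_nts_length: float
    n_excluded_zero: int


def tt_vs_length(genes: pd.DataFrame, ttmap: TTMap) -> TTLengthResult:
    """Per-gene TS/NTS TT counts and their log-log Pearson correlations with
    each other and with gene length (natural log; zero-count genes excluded
    from the correlations, with the exclusion count reported)."""
    flip = {"+": "-", "-": "+"}
    recs = []
    for row in genes.itertuples(index=False):
        ts = ttmap.count(row.chrom, row.start, row.end, flip[row.strand])
        nts = ttmap.count(row.chrom, row.start, row.end, row.strand)
        recs.append((row.name, row.end - row.start, ts, nts))
    per_gene = pd.DataFrame(recs, columns=["gene_id", "length", "tt_ts", "tt_nts"])
    ok = (per_gene["tt_ts"] > 0) & (per_gene["tt_nts"] > 0)
    sub = per_gene[ok]
    if len(sub) >= 3:
        lts, lnts, llen = np.log(sub["tt_ts"]), np.log(sub["tt_nts"]), np.log(sub["length"])
        r_ts_nts = float(np.corrcoef(lts, lnts)[0, 1])
        r_ts_len = float(np.corrcoef(lts, llen)[0, 1])
        r_nts_len = float(np.corrcoef(lnts, llen)[0, 1])
    else:
        r_ts_nts = r_ts_len = r_nts_len = float("nan")
    return TTLengthResult(
        per_gene=per_gene, r_ts_nts=r_ts_nts, r_ts_length=r_ts_len,
        r_nts_length=r_nts_len, n_excluded_zero=int((~ok).sum()),
    )
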