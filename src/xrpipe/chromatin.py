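"""Chromatin-state read profiling and epigenomic-track comparisons.

Reads are assigned to the chromatin state they overlap most (deterministic
tie-break toward the lower state id) and summarised as per-state proportions;
the square-root transform is applied for heatmap export.  Regions of interest
are scored against piecewise-constant tracks (bedGraph) by width-weighted
averaging, and compared to randomly placed width-matched regions with a
two-sided Wilcoxon rank-sum test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomics import GenomeBuild, ReadSet


# ---------------------------------------------------------------------------
# State read proportions
# ---------------------------------------------------------------------------

@dataclass
class StateProfile:
    proportions: pd.Series        # by state label, sums to 1 over assigned reads
    sqrt_proportions: pd.Series
    n_assigned: int
    n_excluded: int


def state_read_proportions(
    reads: pd.DataFrame | ReadSet, states: pd.DataFrame
) -> StateProfile:
    """Proportion of reads per chromatin state.

    ``states`` is a labelled segmentation (columns chrom, start, end, state;
    non-overlapping within a chromosome).  Each read goes to the state with
    the largest overlap; on ties the lowest state id wins.  Reads overlapping
    no state are excluded and counted.
    """
    rdf = reads.reads if isinstance(reads, ReadSet) else reads
    state_ids = np.sort(states["state"].unique())
    totals = pd.Series(0, index=state_ids, dtype=np.int64)
    excluded = 0
    for chrom, ssub in states.groupby("chrom", sort=False):
        ssub = ssub.sort_values("start")
        s_start = ssub["start"].to_numpy()
        s_end = ssub["end"].to_numpy()
        s_id = ssub["state"].to_numpy()
        sel = rdf["chrom"] == chrom
        if not sel.any():
            continue
        r_start = rdf.loc[sel, "start"].to_numpy()
        r_end = rdf.loc[sel, "end"].to_numpy()
        # candidate segments: the one containing the 5' base and the one
        # containing the last base (reads are short relative to segments)
        i0 = np.searchsorted(s_start, r_start, side="right") - 1
        i1 = np.searchsorted(s_start, r_end - 1, side="right") - 1
        best = np.full(len(r_start), -1, dtype=np.int64)
        best_ov = np.zeros(len(r_start), dtype=np.int64)
        for cand in (i0, i1):
            ok = cand >= 0
            c = np.clip(cand, 0, len(s_start) - 1)
            ov = np.minimum(r_end, s_end[c]) - np.maximum(r_start, s_start[c])
            ov = np.where(ok, np.maximum(ov, 0), 0)
            better = (ov > best_ov) | ((ov == best_ov) & (ov > 0) & (s_id[c] < np.where(best >= 0, s_id[np.clip(best, 0, None)], np.iinfo(np.int64).max)))
            best = np.where(better, c, best)
            best_ov = np.maximum(best_ov, ov)
        assigned = best[best_ov > 0]
        excluded += int((best_ov == 0).sum())
        counts = pd.Series(s_id[assigned]).value_counts()
        totals = totals.add(counts, fill_value=0).astype(np.int64)
    n_assigned = int(totals.sum())
    excluded += 0 if n_assigned else 0
    # reads on chromosomes without any state are excluded too
    excluded += int((~rdf["chrom"].isin(states["chrom"].unique())).sum())
    props = totals / n_assigned if n_assigned else totals.astype(float)
    return StateProfile(proportions=props, sqrt_proportions=np.sqrt(props),
                        n_assigned=n_assigned, n_excluded=excluded)


# ---------------------------------------------------------------------------
# Track scoring
# ---------------------------------------------------------------------------

def region_track_score(regions: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Width-weighted mean track value per region.

    score = sum(value * overlap_width) / sum(overlap_width) over track
    intervals overlapping the region; regions without any track coverage get
    NaN.  The track must be sorted and non-overlapping per chromosome (the
    bedGraph convention).
    """
    out = np.full(len(regions), np.nan)
    r = regions.reset_index(drop=True)
    for chrom, tsub in track.groupby("chrom", sort=False):
        tsub = tsub.sort_values("start")
        t_start = tsub["start"].to_numpy()
        t_end = tsub["end"].to_numpy()
        t_val = tsub["value"].to_numpy()
        sel = r["chrom"] == chrom
        if not sel.any():
            continue
        idx = np.flatnonzero(sel.to_numpy())
        for i in idx:
            qs, qe = r.at[i, "start"], r.at[i, "end"]
            lo = np.searchsorted(t_end, qs, side="right")
            hi = np.searchsorted(t_start, qe, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(t_end[lo:hi], qe) - np.maximum(t_start[lo:hi], qs)
            ov = np.maximum(ov, 0)
            w = ov.sum()
            if w > 0:
                out[i] = float((t_val[lo:hi] * ov).sum() / w)
    return out


# ---------------------------------------------------------------------------
# Random-region comparison
# ---------------------------------------------------------------------------

def sample_random_regions(
    n: int,
    widths: np.ndarray,
    genome: GenomeBuild,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """``n`` regions with widths resampled (with replacement) from ``widths``,
    placed uniformly over the genome (chromosome chosen proportional to its
    length among those that fit the width)."""
    widths = np.asarray(widths, dtype=np.int64)
    if len(widths) == 0:
        raise ValueError("need at least one query width")
    chroms = np.array(genome.chroms)
    clens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    if widths.max() > clens.max():
        raise ValueError("region wider than any chromosome")
    w = widths[rng.integers(0, len(widths), size=n)]
    chrom_idx = np.empty(n, dtype=np.int64)
    for i, wi in enumerate(w):                      # redraw among chroms that fit
        fit = clens >= wi
        p = clens * fit
        chrom_idx[i] = rng.choice(len(chroms), p=p / p.sum())
    starts = (rng.random(n) * (clens[chrom_idx] - w + 1)).astype(np.int64)
    return pd.DataFrame({"chrom": chroms[chrom_idx], "start": starts, "end": starts + w,
                         "name": ".", "score": 0, "strand": "."})


def compare_to_random(
    query: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    genome: GenomeBuild,
    n_random: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-track comparison of query regions against width-matched random
    regions: two-sided Wilcoxon rank-sum on per-region scores, direction from
    the sign of the median difference."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n_random = n_random if n_random is not None else max(len(query), 1000)
    if n_random < len(query):
        raise ValueError("n_random must be at least the query size")
    widths = (query["end"] - query["start"]).to_numpy()
    random_regions = sample_random_regions(n_random, widths, genome, rng)
    rows = []
    for name, track in tracks.items():
        q = region_track_score(query, track)
        r = region_track_score(random_regions, track)
        q = q[~np.isnan(q)]
        r = r[~np.isnan(r)]
        stat, p = stats.ranksums(q, r)
        diff = float(np.median(q) - np.median(r)) if len(q) and len(r) else float("nan")
        rows.append({
            "track": name,
            "query_median": float(np.median(q)) if len(q) else float("nan"),
            "random_median": float(np.median(r)) if len(r) else float("nan"),
            "statistic": float(stat),
            "p_value": float(p),
            "direction": int(np.sign(diff)) if not np.isnan(diff) else 0,
        })
    return pd.DataFrame(rows)
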