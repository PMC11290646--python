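"""Time-course analysis of per-gene repair: segmented-trend fitting with
breakpoints, a permutation-derived significance threshold on R-squared, and
two-clade classification into early and late repair.

The model is continuous piecewise-linear least squares over ordered
timepoints (encoded as indices 0..T-1 by default, since the sampling times
span three orders of magnitude), with at most two breakpoints, three
segments, and at least one sample per segment.  Candidate breakpoints lie
at the interior timepoints themselves (the slope may change where a sample
was taken) and the search is exhaustive; the breakpoint count is chosen by
BIC.  Significance is calibrated by refitting
under shuffled timepoint orders (one shared shuffle per permutation) and
pooling the resulting R-squared values; the threshold is a quantile of that
null distribution, so under the null the per-gene exceedance rate is
1 - quantile.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Exhaustive placement machinery
# ---------------------------------------------------------------------------

def _placements(n: int, max_breakpoints: int) -> list[tuple[float, ...]]:
    """All admissible breakpoint placements for ``n`` ordered samples:
    breakpoints at interior sample positions, >= 1 sample per segment."""
    interior = [float(j) for j in range(1, n - 1)]
    out: list[tuple[float, ...]] = [()]
    for k in range(1, max_breakpoints + 1):
        out.extend(combinations(interior, k))
    return out


def _design(n: int, bps: tuple[float, ...], time: np.ndarray | None = None) -> np.ndarray:
    x = np.arange(n, dtype=float) if time is None else np.asarray(time, dtype=float)
    cols = [np.ones(n), x] + [np.maximum(x - b, 0.0) for b in bps]
    return np.column_stack(cols)


_CACHE: dict[tuple[int, int], list[tuple[tuple[float, ...], np.ndarray, np.ndarray]]] = {}


def _machinery(n: int, max_breakpoints: int):
    """(placement, pinv, hat) triplets, cached per (n, max_breakpoints)."""
    key = (n, max_breakpoints)
    if key not in _CACHE:
        entries = []
        for bps in _placements(n, max_breakpoints):
            X = _design(n, bps)
            pinv = np.linalg.pinv(X)
            entries.append((bps, pinv, X @ pinv))
        _CACHE[key] = entries
    return _CACHE[key]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    gene_id: str
    n_breakpoints: int
    breakpoints: tuple[int, ...]   # index of the last sample before each break
    slopes: tuple[float, ...]      # one per segment
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-9:
            raise ValueError(f"R^2 out of range: {self.r2}")
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")


def fit_matrix(Y: np.ndarray, max_breakpoints: int = 2) -> pd.DataFrame:
    """Fit every row of ``Y`` (genes x timepoints): exhaustive breakpoint
    search, per-row best SSE for each breakpoint count, BIC model selection.

    Returns a frame with columns k, r2, breakpoints (tuple), sse.
    Constant rows get k = 0, r2 = 0.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_genes, n = Y.shape
    if n < 4:
        raise ValueError("need at least 4 timepoints to fit a segmented trend")
    entries = _machinery(n, max_breakpoints)
    Yt = Y.T
    best_sse = {}
    best_bps = {}
    for bps, _pinv, hat in entries:
        k = len(bps)
        resid = Yt - hat @ Yt
        sse = np.einsum("ij,ij->j", resid, resid)
        if k not in best_sse:
            best_sse[k] = sse.copy()
            best_bps[k] = [bps] * n_genes
        else:
            better = sse < best_sse[k]
            best_sse[k][better] = sse[better]
            for i in np.flatnonzero(better):
                best_bps[k][i] = bps
    ks = sorted(best_sse)
    sse_mat = np.stack([best_sse[k] for k in ks])                  # K x genes
    p = np.array([k + 2 for k in ks], dtype=float)
    bic = n * np.log(np.maximum(sse_mat, _EPS) / n) + p[:, None] * np.log(n)
    choice = np.argmin(bic, axis=0)                                 # ties -> smaller k
    sst = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    chosen_sse = sse_mat[choice, np.arange(n_genes)]
    r2 = np.where(sst > _EPS, 1.0 - chosen_sse / np.maximum(sst, _EPS), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    k_sel = np.array(ks)[choice]
    k_sel = np.where(sst > _EPS, k_sel, 0)
    bps_sel = [best_bps[k][i] if sst[i] > _EPS else () for i, k in enumerate(k_sel)]
    return pd.DataFrame({"k": k_sel, "r2": r2, "breakpoints": bps_sel,
                         "sse": np.where(sst > _EPS, chosen_sse, 0.0)})


def fit_segmented_trend(
    y: np.ndarray, max_breakpoints: int = 2, gene_id: str = ""
) -> TrendFit:
    """Fit one per-timepoint series; see :func:`fit_matrix` for the search.

    Segment slopes come from the selected placement's coefficients
    (cumulative sums of the hinge terms).
    """
    y = np.asarray(y, dtype=float)
    row = fit_matrix(y[None, :], max_breakpoints).iloc[0]
    bps = tuple(row["breakpoints"])
    X = _design(len(y), bps)
    beta = np.linalg.pinv(X) @ y
    slopes = tuple(np.cumsum(np.concatenate([[beta[1]], beta[2:]])).tolist())
    if row["k"] == 0 and row["r2"] == 0.0 and np.allclose(y, y[0]):
        slopes = (0.0,)
    return TrendFit(
        gene_id=gene_id,
        n_breakpoints=int(row["k"]),
        breakpoints=tuple(int(np.floor(b)) for b in bps),
        slopes=slopes,
        r2=float(row["r2"]),
    )


# ---------------------------------------------------------------------------
# Permutation threshold
# ---------------------------------------------------------------------------

def permutation_threshold(
    Y: np.ndarray,
    n_perm: int = 100,
    quantile: float = 0.95,
    rng: np.random.Generator | None = None,
    max_breakpoints: int = 2,
) -> tuple[float, np.ndarray]:
    """R-squared significance threshold from shuffled timepoint orders.

    Each permutation applies one shared shuffle of the timepoint labels to
    every gene, refits, and records the selected model's R-squared per gene;
    the threshold is the requested quantile of the pooled permuted values.
    Returns ``(threshold, pooled_r2)``.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    rng = rng if rng is not None else np.random.default_rng(0)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[1]
    pooled = []
    for _ in range(n_perm):
        order = rng.permutation(n)
        pooled.append(fit_matrix(Y[:, order], max_breakpoints)["r2"].to_numpy())
    pooled = np.concatenate(pooled)
    return float(np.quantile(pooled, quantile)), pooled


# ---------------------------------------------------------------------------
# Classification into early / late clades
# ---------------------------------------------------------------------------

@dataclass
class DynamicClassification:
    table: pd.DataFrame           # gene_id, r2_rep1, r2_rep2, significant, clade
    threshold: float
    flags: list[str]


def classify_dynamic_genes(
    gene_ids: np.ndarray,
    r2_rep1: np.ndarray,
    r2_rep2: np.ndarray,
    profiles: np.ndarray,
    threshold: float,
) -> DynamicClassification:
    """Significant genes (R-squared above threshold in both replicates) are
    clustered hierarchically on standardised time profiles (correlation
    distance, average linkage, tree cut at two clades); the clade whose mean
    profile peaks earlier is labelled ``early``, the other ``late``."""
    gene_ids = np.asarray(gene_ids)
    r1 = np.asarray(r2_rep1, dtype=float)
    r2_ = np.asarray(r2_rep2, dtype=float)
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    sig = (r1 > threshold) & (r2_ > threshold)
    clade = np.full(len(gene_ids), "", dtype=object)
    flags: list[str] = []
    n_sig = int(sig.sum())
    if n_sig < 2:
        flags.append("fewer than 2 significant genes; clustering skipped")
        if n_sig == 1:
            clade[sig] = "unclustered"
    else:
        P = profiles[sig]
        mu = P.mean(axis=1, keepdims=True)
        sd = P.std(axis=1, keepdims=True)
        Z = np.divide(P - mu, sd, out=np.zeros_like(P), where=sd > 0)
        D = pdist(Z, metric="correlation")
        if np.isnan(D).any():
            D = np.nan_to_num(D, nan=0.0)
            flags.append("zero-variance profiles; correlation distance set to 0 for them")
        labels = fcluster(linkage(D, method="average"), t=2, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            flags.append("degenerate clustering: single clade")
            clade[sig] = "early"
        else:
            peaks = {lab: float(np.argmax(P[labels == lab].mean(axis=0)))
                     for lab in np.unique(labels)}
            early_lab = min(peaks, key=lambda lab: (peaks[lab], lab))
            names = np.where(labels == early_lab, "early", "late")
            clade[np.flatnonzero(sig)] = names
    table = pd.DataFrame({"gene_id": gene_ids, "r2_rep1": r1, "r2_rep2": r2_,
                          "significant": sig, "clade": clade})
    return DynamicClassification(table=table, threshold=threshold, flags=flags)
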