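"""Downstream association statistics: rank correlation, fold-change binning,
box-plot summaries, direction classification, set-overlap tests and
fold-change density traces."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .density import gaussian_kde_1d
from .exact import fisher_two_tailed


def spearman(x, y, n_permutations: int = 10_000, seed: int | None = 0):
    """Spearman rank correlation with a permutation p-value.

    Ranks use average ranks for ties. The p-value is the two-sided
    permutation probability of an |rho| at least as large as observed,
    estimated from ``n_permutations`` seeded shuffles of ``y`` (with the
    +1 correction so p is never zero). Pass ``n_permutations=0`` to skip
    the permutation test (p is then NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rho = float((rx_c * ry_c).sum() / denom)
    if n_permutations <= 0:
        return rho, float("nan")
    rng = np.random.default_rng(seed)
    hits = 0
    perm = ry_c.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if abs((rx_c * perm).sum() / denom) >= abs(rho) - 1e-15:
            hits += 1
    return rho, (hits + 1) / (n_permutations + 1)


def bin_by_log2fc(
    table: pd.DataFrame, edges: Sequence[float], column: str = "log2fc"
) -> pd.DataFrame:
    """Assign genes to half-open fold-change bins [e_i, e_{i+1}).

    Values below the first or at/above the last edge land in the end bins.
    An ``all`` pseudo-bin containing every row is always appended, matching
    the "all genes" column of binned box-plot figures.
    """
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing, length >= 2")
    out = table.copy()
    if out.empty:
        out["bin"] = pd.Series(dtype=object)
        return out
    idx = np.searchsorted(edges, out[column].to_numpy(), side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    out["bin"] = [f"[{edges[i]:g},{edges[i+1]:g})" for i in idx]
    all_rows = table.copy()
    all_rows["bin"] = "all"
    return pd.concat([out, all_rows], ignore_index=True)


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n: int


def boxplot_summary(values) -> BoxplotSummary:
    """Five-number box-plot summary with Tukey 1.5-IQR whiskers.

    Quartiles use linear interpolation of the empirical CDF (the numpy
    default); whiskers are the most extreme observations within
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``, so they never exceed the observed
    range.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("need at least one finite value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()), n=int(v.size),
    )


def classify_direction(log2fc: float, threshold: float = 0.5) -> str:
    """Up/down/none by strict +-threshold on the log2 mutant/WT ratio."""
    if not np.isfinite(log2fc):
        raise ValueError("log2 fold change must be finite")
    if log2fc > threshold:
        return "up"
    if log2fc < -threshold:
        return "down"
    return "none"


def overlap_test(set_a, set_b, universe_size: int) -> tuple[int, float]:
    """Overlap of two gene sets with a two-tailed Fisher exact p.

    The 2x2 table is |A∩B|, |A\\B|, |B\\A| and the remainder of the
    universe; shares the package's single Fisher implementation.
    """
    a, b = set(set_a), set(set_b)
    union = a | b
    if universe_size < len(union):
        raise ValueError("universe smaller than the union of the sets")
    inter = len(a & b)
    only_a = len(a) - inter
    only_b = len(b) - inter
    rest = universe_size - len(union)
    return inter, fisher_two_tailed(inter, only_a, only_b, rest)


def fold_change_kde(
    log2fc_by_set: dict[str, Sequence[float]],
    bandwidth: float | None = None,
    lo: float = -10.0,
    hi: float = 10.0,
    n_grid: int = 512,
) -> pd.DataFrame:
    """Gaussian-kernel density traces of log2 fold changes per gene set."""
    rows = []
    for label, values in log2fc_by_set.items():
        grid, dens = gaussian_kde_1d(values, bandwidth=bandwidth, lo=lo, hi=hi, n_grid=n_grid)
        rows.append(pd.DataFrame({"set": label, "log2fc": grid, "density": dens}))
    return pd.concat(rows, ignore_index=True)


def median_ratio(values_a, values_b) -> float:
    """Ratio of group medians (e.g. expression of high- vs low-enrichment
    genes); a report field, not a test statistic."""
    ma = float(np.median(np.asarray(values_a, dtype=float)))
    mb = float(np.median(np.asarray(values_b, dtype=float)))
    if mb == 0:
        return float("inf") if ma > 0 else float("nan")
    return ma / mb
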