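"""Bisulfite methylome analysis: context calling, weighted methylation levels,
ends-aligned metaplots, 50-bp differential-methylation windows and
locus-level extraction.

Methylation calls live in a pandas DataFrame with columns
``chrom, pos, strand, context, c, t`` where ``pos`` is 0-based, ``c`` is the
methylated and ``t`` the unmethylated read count at that cytosine. Plant
methylation contexts are CG, CHG and CHH (H = A, T or C), read on the strand
of the cytosine. All aggregate levels are *weighted*: pooled
:math:`\\sum c / (\\sum c + \\sum t)`, never a mean of per-site fractions, so
low-coverage sites cannot dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .density import gaussian_kde_1d
from .exact import fisher_two_tailed
from .genome import Anchor, GeneModel, GenomeSequence

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "c", "t"]
CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ContextError(ValueError):
    """Context undeterminable (N in the trinucleotide or out of range)."""


def call_context(genome: GenomeSequence, chrom: str, pos: int, strand: str) -> str:
    """Methylation context of the cytosine at ``pos`` on ``strand``.

    Reads the strand-appropriate trinucleotide (reverse-complemented for the
    minus strand): CG if the next base is G, CHG if the base after next is G,
    CHH otherwise. Returns ``"not_cytosine"`` when the strand base is not C.
    """
    seq = genome[chrom]
    n = len(seq)
    if not 0 <= pos < n:
        raise ContextError(f"{chrom}:{pos} outside chromosome")
    if strand == "+":
        tri = seq[pos : pos + 3]
    elif strand == "-":
        tri = seq[max(0, pos - 2) : pos + 1].translate(_COMPLEMENT)[::-1]
    else:
        raise ValueError(f"bad strand {strand!r}")
    if tri[:1] != "C":
        if tri[:1] == "N":
            raise ContextError(f"{chrom}:{pos}{strand}: N at cytosine position")
        return "not_cytosine"
    if len(tri) < 3 or "N" in tri:
        raise ContextError(f"{chrom}:{pos}{strand}: context undeterminable")
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def cytosine_sites(genome: GenomeSequence, chrom: str) -> pd.DataFrame:
    """All genomic cytosines on both strands with their contexts.

    Sites whose context is undeterminable (chromosome edge, N) are omitted.
    """
    seq = np.frombuffer(genome[chrom].encode(), dtype="S1")
    rows = []
    for strand, base in (("+", b"C"), ("-", b"G")):
        pos = np.flatnonzero(seq == base)
        pos = pos[(pos >= 2) & (pos < len(seq) - 2)]
        if strand == "+":
            b1 = seq[pos + 1]
            b2 = seq[pos + 2]
            is_g1, is_g2 = b1 == b"G", b2 == b"G"
        else:
            b1 = seq[pos - 1]
            b2 = seq[pos - 2]
            is_g1, is_g2 = b1 == b"C", b2 == b"C"
        ctx = np.where(is_g1, "CG", np.where(is_g2, "CHG", "CHH"))
        ok = ~np.isin(b1, [b"N"]) & ~np.isin(b2, [b"N"])
        rows.append(
            pd.DataFrame({"chrom": chrom, "pos": pos[ok], "strand": strand, "context": ctx[ok]})
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def weighted_level(c, t) -> float:
    """Pooled methylation level sum(c)/(sum(c)+sum(t)); NaN when uncovered."""
    total_c = float(np.sum(c))
    total = total_c + float(np.sum(t))
    return total_c / total if total > 0 else float("nan")


@dataclass
class MetaplotProfile:
    """Ends-aligned average profile.

    ``offsets`` are the inward bin left edges (negative = outside the
    feature); ``values`` are pooled weighted levels (NaN where no coverage);
    ``coverage`` is the pooled ``c + t`` (or base count, for enrichment) per
    bin.
    """

    anchor: Anchor
    bin_size: int
    upstream: int
    into: int
    offsets: np.ndarray
    values: np.ndarray
    coverage: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "value": self.values, "coverage": self.coverage}
        )


def _feature_window(feature: GeneModel, anchor: Anchor, upstream: int, into: int):
    """Genomic [lo, hi) covering inward offsets [-upstream, into)."""
    if (feature.strand == "+") == (anchor == "five_prime"):
        return feature.start - upstream, feature.start + into
    return feature.end - into, feature.end + upstream


def _inward_offsets(feature: GeneModel, pos: np.ndarray, anchor: Anchor) -> np.ndarray:
    if feature.strand == "+":
        t = pos - feature.start
    else:
        t = (feature.end - 1) - pos
    if anchor == "three_prime":
        t = (feature.length - 1) - t
    return t


def ends_aligned_metaplot(
    calls: pd.DataFrame,
    features: Sequence[GeneModel],
    context: str,
    anchor: Anchor = "five_prime",
    upstream: int = 2000,
    into: int = 5000,
    bin_size: int = 100,
) -> MetaplotProfile:
    """Average methylation per fixed-width bin over features aligned at one end.

    Every cytosine of the requested context contributes its (c, t) counts to
    the bin of its signed inward offset, once per feature whose window covers
    it; the bin value is the pooled weighted level.
    """
    if not features:
        raise ValueError("no features supplied")
    if (upstream + into) % bin_size:
        raise ValueError("upstream+into must be a multiple of bin_size")
    n_bins = (upstream + into) // bin_size
    pooled_c = np.zeros(n_bins)
    pooled_t = np.zeros(n_bins)

    sub = calls[calls["context"] == context]
    by_chrom = {
        chrom: (g["pos"].to_numpy(), g["c"].to_numpy(float), g["t"].to_numpy(float))
        for chrom, g in sub.sort_values("pos", kind="stable").groupby("chrom")
    }
    for feat in features:
        entry = by_chrom.get(feat.chrom)
        if entry is None:
            continue
        pos, cc, tt = entry
        lo, hi = _feature_window(feat, anchor, upstream, into)
        i, j = np.searchsorted(pos, [lo, hi])
        if i == j:
            continue
        off = _inward_offsets(feat, pos[i:j], anchor)
        idx = (off + upstream) // bin_size
        np.add.at(pooled_c, idx, cc[i:j])
        np.add.at(pooled_t, idx, tt[i:j])

    coverage = pooled_c + pooled_t
    with np.errstate(invalid="ignore"):
        values = np.where(coverage > 0, pooled_c / np.where(coverage > 0, coverage, 1), np.nan)
    offsets = np.arange(n_bins) * bin_size - upstream
    return MetaplotProfile(anchor, bin_size, upstream, into, offsets, values, coverage)


def window_table(calls: pd.DataFrame, context: str, window: int = 50) -> pd.DataFrame:
    """Pool calls of one context into fixed, non-overlapping genomic windows.

    Windows tile each chromosome from coordinate 0; output is keyed by
    ``(chrom, start)`` and carries pooled ``c``, ``t`` and the weighted level.
    """
    sub = calls[calls["context"] == context]
    if sub.empty:
        return pd.DataFrame(columns=["chrom", "start", "c", "t", "level"])
    grp = (
        sub.assign(start=(sub["pos"] // window) * window)
        .groupby(["chrom", "start"], as_index=False)[["c", "t"]]
        .sum()
    )
    grp["level"] = grp["c"] / (grp["c"] + grp["t"]).where(grp["c"] + grp["t"] > 0)
    return grp


def pool_window_tables(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Pool replicate window tables by summing c and t counts."""
    cat = pd.concat(list(tables), ignore_index=True)
    out = cat.groupby(["chrom", "start"], as_index=False)[["c", "t"]].sum()
    out["level"] = out["c"] / (out["c"] + out["t"]).where(out["c"] + out["t"] > 0)
    return out


def _overlaps_any(
    chrom: np.ndarray, start: np.ndarray, end: np.ndarray, exclude: Sequence[GeneModel]
) -> np.ndarray:
    """Boolean mask of windows overlapping any excluded feature."""
    mask = np.zeros(len(start), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in exclude:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    for ch, ivals in by_chrom.items():
        ivals.sort()
        starts = np.array([s for s, _ in ivals])
        # merge to monotone ends so a single searchsorted pass suffices
        ends = np.maximum.accumulate(np.array([e for _, e in ivals]))
        sel = chrom == ch
        if not sel.any():
            continue
        k = np.searchsorted(starts, end[sel], side="left")  # features starting before window end
        hit = np.zeros(sel.sum(), dtype=bool)
        has = k > 0
        hit[has] = ends[k[has] - 1] > start[sel][has]
        mask[sel] |= hit
    return mask


def differential_methylation_windows(
    mut_windows: pd.DataFrame,
    wt_windows: pd.DataFrame,
    min_diff: float = 0.10,
    window: int = 50,
    exclude: Sequence[GeneModel] = (),
    histogram_edges: Sequence[float] = (0, 1e-5, 1e-4, 1e-3, 1e-2, 0.05, 1.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed differential methylation between pooled mutant and WT tables.

    Windows are matched by (chrom, start); each is tested with a two-tailed
    Fisher exact test on the pooled 2x2 count table
    ``[[c_mut, t_mut], [c_wt, t_wt]]``. Windows with an absolute level
    difference below ``min_diff`` (10% by default) or overlapping an excluded
    feature (typically transposon annotations) are dropped. Returns the
    retained windows (``diff`` > 0 marks methylation gain in the mutant) and
    a per-direction histogram of p-values.
    """
    merged = mut_windows.merge(
        wt_windows, on=["chrom", "start"], suffixes=("_mut", "_wt"), how="inner"
    )
    cov_mut = merged["c_mut"] + merged["t_mut"]
    cov_wt = merged["c_wt"] + merged["t_wt"]
    uncovered = (cov_mut == 0) | (cov_wt == 0)
    if uncovered.any():
        logger.info("skipping %d windows with zero coverage in one condition", uncovered.sum())
    merged = merged[~uncovered].copy()
    merged["level_mut"] = merged["c_mut"] / (merged["c_mut"] + merged["t_mut"])
    merged["level_wt"] = merged["c_wt"] / (merged["c_wt"] + merged["t_wt"])
    merged["diff"] = merged["level_mut"] - merged["level_wt"]

    merged = merged[merged["diff"].abs() >= min_diff]
    if len(merged) and len(exclude):
        drop = _overlaps_any(
            merged["chrom"].to_numpy(),
            merged["start"].to_numpy(),
            merged["start"].to_numpy() + window,
            exclude,
        )
        merged = merged[~drop]
    merged = merged.copy()
    merged["p_value"] = [
        fisher_two_tailed(int(a), int(b), int(c), int(d))
        for a, b, c, d in zip(merged["c_mut"], merged["t_mut"], merged["c_wt"], merged["t_wt"])
    ]

    edges = np.asarray(histogram_edges, dtype=float)
    hist_rows = []
    for direction, sub in (
        ("gain", merged[merged["diff"] > 0]),
        ("loss", merged[merged["diff"] < 0]),
    ):
        counts, _ = np.histogram(sub["p_value"], bins=edges)
        for lo, hi, n in zip(edges[:-1], edges[1:], counts):
            hist_rows.append({"direction": direction, "p_lo": lo, "p_hi": hi, "count": int(n)})
    return merged.reset_index(drop=True), pd.DataFrame(hist_rows)


def methylation_difference_kde(
    window_diffs, bandwidth: float | None = None, n_grid: int = 512
):
    """Gaussian KDE of per-window methylation differences over [-1, 1]."""
    diffs = np.asarray(window_diffs, dtype=float)
    if diffs.size < 2 and bandwidth is None:
        raise ValueError("need at least 2 window differences")
    return gaussian_kde_1d(diffs, bandwidth=bandwidth, lo=-1.0, hi=1.0, n_grid=n_grid)


def extract_locus_methylation(
    calls: pd.DataFrame, chrom: str, start: int, end: int, site_list: Sequence[int]
) -> tuple[pd.DataFrame, float]:
    """Per-site and pooled percent methylation at selected sites of one locus.

    Mirrors in-silico extraction of the reads covering a locus: per-site
    levels are c/(c+t) at exactly the requested positions (NaN when
    uncovered, excluded from the pooled denominator); the locus average is
    the pooled weighted level over the covered sites.
    """
    if len(site_list) == 0:
        raise ValueError("empty site list")
    for s in site_list:
        if not start <= s < end:
            raise ValueError(f"site {s} outside locus [{start},{end})")
    sub = calls[(calls["chrom"] == chrom) & calls["pos"].isin(site_list)]
    pooled = sub.groupby("pos")[["c", "t"]].sum()
    rows = []
    for s in site_list:
        if s in pooled.index and (pooled.loc[s, "c"] + pooled.loc[s, "t"]) > 0:
            c, t = int(pooled.loc[s, "c"]), int(pooled.loc[s, "t"])
            rows.append({"pos": s, "c": c, "t": t, "level": c / (c + t)})
        else:
            rows.append({"pos": s, "c": 0, "t": 0, "level": np.nan})
    per_site = pd.DataFrame(rows)
    covered = per_site.dropna(subset=["level"])
    avg = weighted_level(covered["c"], covered["t"])
    return per_site, avg
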