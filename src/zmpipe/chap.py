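"""H2A.Z ChAP-seq enrichment: nucleosome midpoints, IP - input tracks,
ends-aligned enrichment metaplots, TSS/body scores, heat-map matrices and the
nine-cluster partition.

Single-end 50-bp reads are converted to nucleosome midpoints by shifting the
read's 5' end 75 bp in read orientation (half of an average 150-bp
nucleosome). IP and input midpoint densities are normalized to counts per
million midpoints before base-wise subtraction, so libraries of unequal
depth are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Anchor, GeneModel

logger = logging.getLogger(__name__)

MIDPOINT_SHIFT = 75  # half of the average 150-bp nucleosome

READ_COLUMNS = ["chrom", "start", "end", "strand"]


def estimate_midpoints(
    reads: pd.DataFrame, chrom_lengths: Mapping[str, int], shift: int = MIDPOINT_SHIFT,
    literal_start: bool = False,
) -> dict[str, np.ndarray]:
    """Per-base nucleosome midpoint counts from single-end read intervals.

    The midpoint is the read's 5' end plus ``shift`` toward the read's 3'
    direction: ``start + shift`` for plus-strand reads, ``end - 1 - shift``
    for minus-strand reads. With ``literal_start`` the shift is applied to
    the leftmost coordinate regardless of strand (the strand-naive reading).
    Midpoints falling off the chromosome are dropped and logged.
    """
    counts = {ch: np.zeros(n, dtype=np.int64) for ch, n in chrom_lengths.items()}
    dropped = 0
    for chrom, grp in reads.groupby("chrom"):
        if chrom not in counts:
            dropped += len(grp)
            continue
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        if literal_start:
            mid = start + shift
        else:
            minus = (grp["strand"] == "-").to_numpy()
            mid = np.where(minus, end - 1 - shift, start + shift)
        ok = (mid >= 0) & (mid < len(counts[chrom]))
        dropped += int((~ok).sum())
        np.add.at(counts[chrom], mid[ok], 1)
    if dropped:
        logger.info("dropped %d reads with off-chromosome midpoints", dropped)
    return counts


@dataclass
class EnrichmentTrack:
    """Per-base H2A.Z enrichment: IP midpoint CPM minus input midpoint CPM."""

    data: dict[str, np.ndarray]
    ip_total: int
    input_total: int

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                arr = self.data[chrom]
                # run-length encode constant stretches
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(arr)]])
                for s, e in zip(starts, ends):
                    if arr[s] != 0.0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


def build_track(
    ip_midpoints: Mapping[str, np.ndarray], input_midpoints: Mapping[str, np.ndarray]
) -> EnrichmentTrack:
    """IP - input enrichment with both libraries scaled to midpoints per million."""
    ip_total = int(sum(int(a.sum()) for a in ip_midpoints.values()))
    input_total = int(sum(int(a.sum()) for a in input_midpoints.values()))
    if ip_total == 0 or input_total == 0:
        raise ValueError("empty IP or input midpoint library")
    data = {}
    for chrom in ip_midpoints:
        ip_cpm = ip_midpoints[chrom] * (1e6 / ip_total)
        in_cpm = input_midpoints[chrom] * (1e6 / input_total)
        data[chrom] = (ip_cpm - in_cpm).astype(np.float64)
    return EnrichmentTrack(data=data, ip_total=ip_total, input_total=input_total)


def _gene_bin_stats(
    track_arr: np.ndarray,
    feature: GeneModel,
    anchor: Anchor,
    upstream: int,
    into: int,
    bin_size: int,
    opposite_end_exclusion: int,
):
    """Per-bin (sum, count) of per-base enrichment for one gene.

    Inward offsets run over ``[-upstream, min(into, L - exclusion))``: for a
    short gene, data within ``opposite_end_exclusion`` of the opposite end
    (and beyond it) are omitted so the two end peaks do not bleed into the
    body average.
    """
    n_bins = (upstream + into) // bin_size
    hi_off = min(into, feature.length - opposite_end_exclusion)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    if hi_off <= -upstream:
        return sums, counts
    offs = np.arange(-upstream, hi_off)
    if anchor == "five_prime":
        pos = feature.start + offs if feature.strand == "+" else feature.end - 1 - offs
    else:
        pos = feature.end - 1 - offs if feature.strand == "+" else feature.start + offs
    ok = (pos >= 0) & (pos < len(track_arr))
    idx = (offs[ok] + upstream) // bin_size
    np.add.at(sums, idx, track_arr[pos[ok]])
    np.add.at(counts, idx, 1)
    return sums, counts


def enrichment_metaplot(
    track: EnrichmentTrack,
    features: Sequence[GeneModel],
    anchor: Anchor = "five_prime",
    upstream: int = 1000,
    into: int = 3000,
    bin_size: int = 50,
    opposite_end_exclusion: int = 1000,
) -> pd.DataFrame:
    """Average enrichment per fixed bin over ends-aligned features.

    Bin values are means of per-base enrichment pooled over every
    contributing base of every feature. Returns a frame with ``offset``
    (inward bin left edge), ``value`` (NaN where no base contributes) and
    ``coverage`` (contributing base count).
    """
    if (upstream + into) % bin_size:
        raise ValueError("upstream+into must be a multiple of bin_size")
    n_bins = (upstream + into) // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for feat in features:
        if feat.chrom not in track.data:
            continue
        s, c = _gene_bin_stats(
            track[feat.chrom], feat, anchor, upstream, into, bin_size, opposite_end_exclusion
        )
        sums += s
        counts += c
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    offsets = np.arange(n_bins) * bin_size - upstream
    return pd.DataFrame({"offset": offsets, "value": values, "coverage": counts})


@dataclass
class GeneEnrichmentScores:
    """Mean enrichment over the three canonical gene windows.

    ``tss_score``: [0, 500) bp from the TSS; ``body_score``: [1000, L-1000)
    (defined only for genes of at least 2100 bp, so the window cannot touch
    the end peaks); ``sort_body_score``: [500, L-500), the ordering key for
    heat maps.
    """

    gene_id: str
    tss_score: float
    body_score: float
    sort_body_score: float
    feature_class: str = "gene"
    length: int = 0


def _interval_mean(track_arr: np.ndarray, feature: GeneModel, lo_off: int, hi_off: int) -> float:
    """Mean track value over inward offsets [lo_off, hi_off) of a gene."""
    if hi_off <= lo_off:
        return float("nan")
    offs = np.arange(lo_off, hi_off)
    pos = feature.start + offs if feature.strand == "+" else feature.end - 1 - offs
    ok = (pos >= 0) & (pos < len(track_arr))
    if not ok.any():
        return float("nan")
    return float(track_arr[pos[ok]].mean())


def gene_scores(
    track: EnrichmentTrack, gene: GeneModel, min_body_length: int = 2100
) -> GeneEnrichmentScores:
    arr = track[gene.chrom]
    L = gene.length
    tss = _interval_mean(arr, gene, 0, min(500, L))
    body = _interval_mean(arr, gene, 1000, L - 1000) if L >= min_body_length else float("nan")
    sort_body = _interval_mean(arr, gene, 500, L - 500) if L >= 1100 else float("nan")
    return GeneEnrichmentScores(
        gene_id=gene.id, tss_score=tss, body_score=body, sort_body_score=sort_body,
        feature_class=gene.feature_class, length=L,
    )


def scores_table(track: EnrichmentTrack, features: Sequence[GeneModel]) -> pd.DataFrame:
    rows = [vars(gene_scores(track, g)) for g in features if g.chrom in track.data]
    return pd.DataFrame(rows)


TIER_NAMES = ("low", "mid", "high")


def _terciles(scores: pd.Series, ids: pd.Series) -> pd.Series:
    """Tier labels low/mid/high by rank, ties broken by gene id order."""
    order = pd.DataFrame({"score": scores.to_numpy(), "id": ids.to_numpy()})
    rank = order.sort_values(["score", "id"], kind="stable").index
    n = len(rank)
    tiers = np.empty(n, dtype=object)
    tiers[rank[: n // 3]] = "low"
    tiers[rank[n // 3 : (2 * n) // 3]] = "mid"
    tiers[rank[(2 * n) // 3 :]] = "high"
    return pd.Series(tiers, index=scores.index)


def nine_cluster_partition(scores: pd.DataFrame) -> pd.DataFrame:
    """Partition genes into nine groups by TSS-tier x body-tier.

    Pseudogenes are pulled out into their own group first; remaining genes
    with a defined body score are split into marginal terciles independently
    on the TSS score and on the body score, making nine approximately
    equal-sized clusters labelled 1-9 (body tier major, TSS tier minor).
    """
    df = scores.copy()
    df["cluster"] = pd.NA
    df["tss_tier"] = pd.NA
    df["body_tier"] = pd.NA
    is_pg = df["feature_class"] == "pseudogene"
    df.loc[is_pg, "cluster"] = "pG"
    eligible = (~is_pg) & df["body_score"].notna() & df["tss_score"].notna()
    sub = df[eligible]
    if len(sub) < 9:
        raise ValueError("need at least 9 eligible genes for a nine-way partition")
    tss_tier = _terciles(sub["tss_score"].reset_index(drop=True),
                         sub["gene_id"].reset_index(drop=True))
    body_tier = _terciles(sub["body_score"].reset_index(drop=True),
                          sub["gene_id"].reset_index(drop=True))
    df.loc[eligible, "tss_tier"] = tss_tier.to_numpy()
    df.loc[eligible, "body_tier"] = body_tier.to_numpy()
    cluster = (
        3 * pd.Categorical(body_tier, categories=TIER_NAMES).codes
        + pd.Categorical(tss_tier, categories=TIER_NAMES).codes
        + 1
    )
    df.loc[eligible, "cluster"] = [str(c) for c in cluster]
    return df


def heatmap_matrix(
    track: EnrichmentTrack,
    features: Sequence[GeneModel],
    anchor: Anchor = "five_prime",
    upstream: int = 1000,
    into: int = 3000,
    bin_size: int = 50,
    opposite_end_exclusion: int = 1000,
    difference_track: EnrichmentTrack | None = None,
) -> pd.DataFrame:
    """Per-gene enrichment matrix, rows sorted by ascending sort-body score.

    One row per gene, columns are the metaplot bins (per-gene means, no
    pooling across genes); cells where a gene's excluded or absent region
    falls are NaN. With ``difference_track`` the matrix holds
    track - difference_track (e.g. mutant minus WT).
    """
    rows, ids, sort_keys = [], [], []
    n_bins = (upstream + into) // bin_size
    for feat in features:
        if feat.chrom not in track.data:
            continue
        arr = track[feat.chrom]
        if difference_track is not None:
            arr = arr - difference_track[feat.chrom]
        s, c = _gene_bin_stats(arr, feat, anchor, upstream, into, bin_size,
                               opposite_end_exclusion)
        with np.errstate(invalid="ignore"):
            row = np.where(c > 0, s / np.where(c > 0, c, 1), np.nan)
        rows.append(row)
        ids.append(feat.id)
        sort_keys.append(gene_scores(track, feat).sort_body_score)
    offsets = np.arange(n_bins) * bin_size - upstream
    mat = pd.DataFrame(rows, index=ids, columns=offsets)
    order = np.argsort(np.asarray(sort_keys), kind="stable")
    return mat.iloc[order]
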