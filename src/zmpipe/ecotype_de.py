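"""Ecotype-aware differential expression for a WS/Col mosaic genome.

The mutant line under study is a mosaic of two Arabidopsis accessions (WS
and Col), so a naive mutant-vs-WT comparison confounds trans effects with
cis expression differences between the accessions. The procedure here
resolves that: RNA-seq reads are assigned to parental alleles by exact
matching against 75-bp SNP scaffolds, each SNP region is genotyped
(homozygous WS, homozygous Col, or heterozygous), read-count contributions
at heterozygous SNPs are smoothed along the chromosome, per-gene counts are
partitioned into WS- and Col-derived parts, and each ecotype's partition is
tested separately with a two-tailed Fisher exact test on counts normalized
to the smallest library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exact import fisher_two_tailed
from .genome import GeneModel, GenomeSequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------- scaffolds


def build_scaffolds(
    genome: GenomeSequence, snps: pd.DataFrame, length: int = 75
) -> pd.DataFrame:
    """Per-SNP WS and Col scaffolds: the genomic context with the SNP centered.

    Each scaffold is ``length`` bp with ``length//2`` bp of flank on each
    side and the ecotype's allele substituted at the center; the two
    scaffolds of a SNP differ only there. SNPs without a full flank are
    dropped and logged.
    """
    flank = length // 2
    rows = []
    dropped = 0
    for rec in snps.itertuples(index=False):
        chrom_len = genome.length(rec.chrom)
        if rec.pos < flank or rec.pos + flank >= chrom_len:
            dropped += 1
            continue
        ctx = genome.slice(rec.chrom, rec.pos - flank, rec.pos + flank + 1)
        row = rec._asdict()
        row["ws_scaffold"] = ctx[:flank] + rec.allele_ws + ctx[flank + 1 :]
        row["col_scaffold"] = ctx[:flank] + rec.allele_col + ctx[flank + 1 :]
        rows.append(row)
    if dropped:
        logger.info("dropped %d SNPs without a full %d bp flank", dropped, flank)
    return pd.DataFrame(rows)


class ScaffoldIndex:
    """K-mer index over SNP scaffolds for exact, mismatch-free read assignment.

    For a fixed read length, records every substring of every scaffold,
    split into substrings that cover the central SNP base and those that do
    not. A read is assigned to an ecotype at a SNP only if it (in either
    orientation) matches that ecotype's scaffold over the SNP base and does
    not occur anywhere in the other ecotype's scaffold.
    """

    def __init__(self, scaffolds: pd.DataFrame, read_length: int):
        self.read_length = read_length
        self.cover: dict[str, set[tuple[int, str]]] = {}
        self.anywhere: dict[str, set[tuple[int, str]]] = {}
        self.n_snps = len(scaffolds)
        for i, rec in enumerate(scaffolds.itertuples(index=False)):
            for eco, scaffold in (("ws", rec.ws_scaffold), ("col", rec.col_scaffold)):
                center = len(scaffold) // 2
                for off in range(len(scaffold) - read_length + 1):
                    kmer = scaffold[off : off + read_length]
                    key = (i, eco)
                    self.anywhere.setdefault(kmer, set()).add(key)
                    if off <= center <= off + read_length - 1:
                        self.cover.setdefault(kmer, set()).add(key)

    def assign(self, read: str) -> list[tuple[int, str]]:
        seqs = (read, _revcomp(read))
        covering: set[tuple[int, str]] = set()
        matching: set[tuple[int, str]] = set()
        for s in seqs:
            covering |= self.cover.get(s, set())
            matching |= self.anywhere.get(s, set())
        out = []
        for i, eco in covering:
            other = (i, "col" if eco == "ws" else "ws")
            if other not in matching:
                out.append((i, eco))
        return out


def assign_reads(reads: Sequence[str], scaffolds: pd.DataFrame) -> pd.DataFrame:
    """Count SNP-informative reads per scaffold pair.

    Exact substring matching in both orientations with no mismatch
    tolerance; reads matching both scaffolds of a SNP (i.e. not spanning the
    SNP base) are uninformative and ignored for that SNP. Returns the
    scaffold table with ``ws_count``/``col_count`` columns added.
    """
    ws = np.zeros(len(scaffolds), dtype=np.int64)
    col = np.zeros(len(scaffolds), dtype=np.int64)
    by_len: dict[int, ScaffoldIndex] = {}
    for read in reads:
        k = len(read)
        if k not in by_len:
            by_len[k] = ScaffoldIndex(scaffolds, k)
        for i, eco in by_len[k].assign(read):
            if eco == "ws":
                ws[i] += 1
            else:
                col[i] += 1
    out = scaffolds.copy()
    out["ws_count"] = ws
    out["col_count"] = col
    return out


def sum_sample_counts(per_sample: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Total WS/Col counts per SNP summed over samples."""
    samples = list(per_sample.values())
    out = samples[0].copy()
    for df in samples[1:]:
        out["ws_count"] = out["ws_count"] + df["ws_count"].to_numpy()
        out["col_count"] = out["col_count"] + df["col_count"].to_numpy()
    return out


# ----------------------------------------------------------- SNP filtering


def filter_snps(
    snps: pd.DataFrame,
    genes: Mapping[str, GeneModel],
    min_gene_len: int = 200,
    min_reads: int = 10,
    min_dist_from_exon_end: int = 36,
) -> pd.DataFrame:
    """Keep SNPs inside an exon of a sufficiently long gene, far enough from
    the exon edge, with enough assigned reads.

    A SNP is retained when its gene is strictly longer than ``min_gene_len``
    bp, the SNP lies at least one read length (``min_dist_from_exon_end``)
    from both ends of its exon, and ``ws_count + col_count`` (summed over all
    samples beforehand) is at least ``min_reads``.
    """
    keep = []
    for idx, rec in snps.iterrows():
        gene = genes.get(rec["gene_id"])
        if gene is None or gene.length <= min_gene_len:
            continue
        exon = next(((s, e) for s, e in gene.exons if s <= rec["pos"] < e), None)
        if exon is None:
            continue
        dist = min(rec["pos"] - exon[0], (exon[1] - 1) - rec["pos"])
        if dist < min_dist_from_exon_end:
            continue
        if rec["ws_count"] + rec["col_count"] < min_reads:
            continue
        keep.append(idx)
    return snps.loc[keep].copy()


# ----------------------------------------------------- genotype & smoothing


def call_genotype(
    ws_count: int,
    col_count: int,
    min_reads: int = 10,
    het_minor_frac: float = 0.1,
    het_minor_count: int = 2,
) -> str:
    """Genotype of a SNP region from allele-assigned read counts.

    Heterozygous when the minor allele carries at least ``het_minor_frac`` of
    the reads and at least ``het_minor_count`` reads (robust to ~1%
    sequencing error at depth 10-100); otherwise homozygous for the majority
    allele; ``untyped`` below ``min_reads`` total.
    """
    total = ws_count + col_count
    if total < min_reads:
        return "untyped"
    minor = min(ws_count, col_count)
    if minor / total >= het_minor_frac and minor >= het_minor_count:
        return "Het"
    return "WS" if ws_count >= col_count else "Col"


def genotype_snps(snps: pd.DataFrame, **kwargs) -> pd.DataFrame:
    out = snps.copy()
    out["genotype"] = [
        call_genotype(int(w), int(c), **kwargs)
        for w, c in zip(out["ws_count"], out["col_count"])
    ]
    total = out["ws_count"] + out["col_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = out["ws_count"] / total
    out["contribution_ws"] = contrib.where(out["genotype"] == "Het")
    return out


def smooth_contributions(snps: pd.DataFrame, window: int = 20) -> pd.DataFrame:
    """Centered rolling mean of WS read-count contributions along each
    contiguous heterozygous block.

    SNPs are ordered by (chrom, pos); a block is a maximal run of Het SNPs
    uninterrupted by homozygous calls on the same chromosome. Windows are
    truncated at block edges, so a block shorter than ``window`` is smoothed
    to its mean.
    """
    out = snps.sort_values(["chrom", "pos"], kind="stable").copy()
    smoothed = np.full(len(out), np.nan)
    is_het = (out["genotype"] == "Het").to_numpy()
    chroms = out["chrom"].to_numpy()
    values = out["contribution_ws"].to_numpy(float)
    # block id increments at every chromosome change or Het-run break
    new_block = np.ones(len(out), dtype=bool)
    if len(out) > 1:
        new_block[1:] = (chroms[1:] != chroms[:-1]) | ~is_het[:-1] | ~is_het[1:]
    block_id = np.cumsum(new_block)
    for _, idx in pd.Series(np.arange(len(out))[is_het]).groupby(block_id[is_het]):
        pos = idx.to_numpy()
        v = values[pos]
        n = len(v)
        csum = np.concatenate([[0.0], np.cumsum(v)])
        lo = np.maximum(0, np.arange(n) - window // 2)
        hi = np.minimum(n, np.arange(n) + (window - window // 2))
        smoothed[pos] = (csum[hi] - csum[lo]) / (hi - lo)
    out["smoothed_contribution_ws"] = smoothed
    return out


# --------------------------------------------------------------- DE proper


def rpkm(count: float, exon_model_length_bp: int, library_reads: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_model_length_bp <= 0:
        raise ValueError("exon model length must be positive")
    if library_reads <= 0:
        raise ValueError("library size must be positive")
    return count / (exon_model_length_bp / 1000) / (library_reads / 1e6)


@dataclass
class GenePartition:
    gene_id: str
    genotype: str
    contribution_ws: float  # fraction of counts attributed to WS (0, 1, or f)


def assign_gene_partitions(
    genes: Sequence[GeneModel],
    snps: pd.DataFrame,
    search_radius: int = 50_000,
) -> dict[str, GenePartition]:
    """Link each gene to a genotype region and a WS contribution fraction.

    A gene's genotype is the majority genotype of its own retained exonic
    SNPs (ties resolve to Het); a gene without retained SNPs takes the
    genotype of the nearest retained SNP by gene-midpoint distance (ties to
    the lower coordinate) within ``search_radius``. Heterozygous genes take
    the smoothed WS contribution of the nearest retained Het SNP. Genes
    that cannot be linked are flagged unpartitionable and excluded from DE.
    """
    parts: dict[str, GenePartition] = {}
    by_chrom = {ch: grp.sort_values("pos") for ch, grp in snps.groupby("chrom")}
    for gene in genes:
        grp = by_chrom.get(gene.chrom)
        if grp is None:
            parts[gene.id] = GenePartition(gene.id, "unpartitionable", np.nan)
            continue
        own = grp[grp["gene_id"] == gene.id] if "gene_id" in grp else grp.iloc[0:0]
        if len(own):
            counts = own["genotype"].value_counts()
            top = counts[counts == counts.max()]
            genotype = "Het" if len(top) > 1 else str(top.index[0])
        else:
            dist = (grp["pos"] - gene.midpoint).abs()
            order = np.lexsort((grp["pos"].to_numpy(), dist.to_numpy()))
            if dist.iloc[order[0]] > search_radius:
                parts[gene.id] = GenePartition(gene.id, "unpartitionable", np.nan)
                continue
            genotype = str(grp["genotype"].iloc[order[0]])
        if genotype == "WS":
            f = 1.0
        elif genotype == "Col":
            f = 0.0
        elif genotype == "Het":
            het = grp[grp["genotype"] == "Het"]
            if het.empty:
                parts[gene.id] = GenePartition(gene.id, "unpartitionable", np.nan)
                continue
            dist = (het["pos"] - gene.midpoint).abs()
            order = np.lexsort((het["pos"].to_numpy(), dist.to_numpy()))
            if dist.iloc[order[0]] > search_radius:
                parts[gene.id] = GenePartition(gene.id, "unpartitionable", np.nan)
                continue
            f = float(het["smoothed_contribution_ws"].iloc[order[0]])
        else:  # untyped
            parts[gene.id] = GenePartition(gene.id, "unpartitionable", np.nan)
            continue
        parts[gene.id] = GenePartition(gene.id, genotype, f)
    return parts


def partition_counts(count: float, partition: GenePartition) -> tuple[float, float]:
    """Split a gene's count into WS- and Col-derived parts.

    Homozygous regions send everything to one ecotype; heterozygous regions
    split by the smoothed WS contribution ``f``. The parts conserve the
    total exactly (the Col part is computed as the remainder).
    """
    if partition.genotype == "unpartitionable" or np.isnan(partition.contribution_ws):
        raise ValueError(f"{partition.gene_id}: gene is not partitionable")
    ws = count * partition.contribution_ws
    col = count - ws
    # pick float representations whose sum reproduces the total bitwise
    # (plain a*f and a - a*f can land one ulp off)
    for _ in range(5):
        if ws + col == count:
            break
        ws = count - col
        if ws + col == count:
            break
        col = count - ws
    return ws, col


def fisher_de_test(mut_part: int, wt_part: int, mut_lib: int, wt_lib: int) -> float:
    """Two-tailed Fisher exact p for a gene's mutant-vs-WT partitioned counts.

    The 2x2 table is gene reads vs rest-of-library reads in each condition;
    inputs must already be normalized to the smallest library and rounded to
    integers. Degenerate (zero-margin) tables return p = 1.
    """
    if mut_part > mut_lib or wt_part > wt_lib:
        raise ValueError("gene counts exceed library size")
    if (mut_part + wt_part) == 0:
        logger.debug("zero gene counts in both conditions; p = 1")
        return 1.0
    return fisher_two_tailed(mut_part, mut_lib - mut_part, wt_part, wt_lib - wt_part)


def call_de(
    log2fc_ws: float,
    log2fc_col: float,
    p_ws: float,
    p_col: float,
    fold: float = 2.0,
    p_single: float = 0.001,
    p_both: float = 0.005,
) -> str:
    """Differential-expression call from per-ecotype fold changes and p-values.

    A gene is DE if either ecotype shows at least a ``fold`` change with
    p < ``p_single``, or both ecotypes show at least a ``fold`` change in the
    same direction with p < ``p_both`` each. Contradictory qualifying
    directions yield ``none``.
    """
    lfc_thresh = np.log2(fold)
    directions = set()
    ecotypes = [(log2fc_ws, p_ws), (log2fc_col, p_col)]
    defined = [(l, p) for l, p in ecotypes if np.isfinite(l) and np.isfinite(p)]
    if not defined:
        raise ValueError("no ecotype with defined fold change and p-value")
    for lfc, p in defined:
        if abs(lfc) >= lfc_thresh and p < p_single:
            directions.add("up" if lfc > 0 else "down")
    if len(defined) == 2:
        (l1, p1), (l2, p2) = defined
        if (
            abs(l1) >= lfc_thresh and abs(l2) >= lfc_thresh
            and p1 < p_both and p2 < p_both and np.sign(l1) == np.sign(l2)
        ):
            directions.add("up" if l1 > 0 else "down")
    if len(directions) == 1:
        return directions.pop()
    if len(directions) > 1:
        logger.warning("contradictory DE directions; calling none")
    return "none"


def run_de(
    genes: Sequence[GeneModel],
    gene_counts: pd.DataFrame,
    sample_conditions: Mapping[str, str],
    partitions: Mapping[str, GenePartition],
    pseudocount_rpkm: float = 0.5,
    fold: float = 2.0,
    p_single: float = 0.001,
    p_both: float = 0.005,
) -> pd.DataFrame:
    """Per-gene ecotype-partitioned differential expression.

    ``gene_counts`` is a genes x samples frame of raw read counts;
    ``sample_conditions`` maps each sample to ``"mutant"`` or ``"wt"``.
    Fold changes are computed on replicate-mean RPKM per ecotype with an
    RPKM pseudocount; significance uses counts rescaled to the smallest
    library, summed over replicates, partitioned, rounded half-to-even and
    Fisher-tested gene-vs-rest-of-library per ecotype.
    """
    samples = list(gene_counts.columns)
    lib_sizes = gene_counts.sum(axis=0)
    min_lib = float(lib_sizes.min())
    exon_len = {g.id: g.exon_model_length for g in genes}
    mut_samples = [s for s in samples if sample_conditions[s] == "mutant"]
    wt_samples = [s for s in samples if sample_conditions[s] == "wt"]
    if not mut_samples or not wt_samples:
        raise ValueError("need at least one mutant and one wt sample")

    # smallest-library normalization, summed over replicates per condition
    scale = min_lib / lib_sizes
    norm = gene_counts * scale
    norm_mut = norm[mut_samples].sum(axis=1)
    norm_wt = norm[wt_samples].sum(axis=1)
    lib_mut = int(round(min_lib * len(mut_samples)))
    lib_wt = int(round(min_lib * len(wt_samples)))

    rows = []
    for gene in genes:
        part = partitions.get(gene.id)
        if part is None or part.genotype == "unpartitionable":
            continue
        if gene.id not in gene_counts.index:
            continue
        raw = gene_counts.loc[gene.id]
        L = exon_len[gene.id]
        rpkm_mut = float(np.mean([rpkm(raw[s], L, lib_sizes[s]) for s in mut_samples]))
        rpkm_wt = float(np.mean([rpkm(raw[s], L, lib_sizes[s]) for s in wt_samples]))

        row: dict = {
            "gene_id": gene.id,
            "genotype": part.genotype,
            "contribution_ws": part.contribution_ws,
            "rpkm_mut": rpkm_mut,
            "rpkm_wt": rpkm_wt,
        }
        l2 = {"ws": np.nan, "col": np.nan}
        pv = {"ws": np.nan, "col": np.nan}
        nm_ws, nm_col = partition_counts(float(norm_mut[gene.id]), part)
        nw_ws, nw_col = partition_counts(float(norm_wt[gene.id]), part)
        rm_ws, rm_col = partition_counts(rpkm_mut, part)
        rw_ws, rw_col = partition_counts(rpkm_wt, part)
        for eco, nm, nw, rm, rw in (
            ("ws", nm_ws, nw_ws, rm_ws, rw_ws),
            ("col", nm_col, nw_col, rm_col, rw_col),
        ):
            f = part.contribution_ws if eco == "ws" else 1 - part.contribution_ws
            if f == 0:
                continue  # ecotype absent from this region
            l2[eco] = float(
                np.log2((rm + pseudocount_rpkm) / (rw + pseudocount_rpkm))
            )
            pv[eco] = fisher_de_test(
                int(np.rint(nm)), int(np.rint(nw)), lib_mut, lib_wt
            )
        row.update(
            norm_mut=float(norm_mut[gene.id]), norm_wt=float(norm_wt[gene.id]),
            norm_mut_ws=nm_ws, norm_mut_col=nm_col, norm_wt_ws=nw_ws, norm_wt_col=nw_col,
            log2fc_ws=l2["ws"], log2fc_col=l2["col"], p_ws=pv["ws"], p_col=pv["col"],
        )
        row["call"] = call_de(
            l2["ws"], l2["col"], pv["ws"], pv["col"],
            fold=fold, p_single=p_single, p_both=p_both,
        )
        rows.append(row)
    return pd.DataFrame(rows)
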