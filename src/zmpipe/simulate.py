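"""Synthetic data generators with planted structure for every pipeline stage.

The generators emulate the shape of the study's inputs — genic CG-enriched
methylomes with all-context transposon methylation, ChAP read sets with
designed TSS-peak and gene-body enrichment tiers, allele-mosaic RNA-seq over
WS/Col/heterozygous blocks, and responsiveness scores rank-correlated with
body enrichment — while recording ground truth so recovery can be measured.
Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GeneModel, GenomeSequence
from .methylome import cytosine_sites

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ------------------------------------------------------------------ genome


@dataclass
class GenomeDesign:
    chrom_names: tuple[str, ...] = ("chr1",)
    n_genes: int = 200
    n_tes: int = 40
    n_pseudogenes: int = 10
    gene_length: tuple[int, int] = (7000, 7000)  # uniform range, inclusive
    te_length: tuple[int, int] = (2000, 4000)
    pseudogene_length: tuple[int, int] = (1000, 2000)
    gap: tuple[int, int] = (2200, 3000)  # intergenic gap range
    gc: float = 0.36  # Arabidopsis-like base composition


def generate_genome(
    design: GenomeDesign, rng: np.random.Generator
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome plus non-overlapping gene/TE/pseudogene annotations.

    Features are laid down left to right with random intergenic gaps,
    round-robin across chromosomes; strands are random. Raises if the
    requested features cannot be packed (they always fit because the
    chromosome length is derived from the layout).
    """
    specs: list[tuple[str, tuple[int, int]]] = (
        [("gene", design.gene_length)] * design.n_genes
        + [("transposon", design.te_length)] * design.n_tes
        + [("pseudogene", design.pseudogene_length)] * design.n_pseudogenes
    )
    order = rng.permutation(len(specs))
    per_chrom: dict[str, list] = {ch: [] for ch in design.chrom_names}
    for k, i in enumerate(order):
        per_chrom[design.chrom_names[k % len(design.chrom_names)]].append(specs[i])

    p = np.array(
        [(1 - design.gc) / 2, design.gc / 2, design.gc / 2, (1 - design.gc) / 2]
    )
    chroms: dict[str, str] = {}
    models: list[GeneModel] = []
    counter = {"gene": 0, "transposon": 0, "pseudogene": 0}
    prefix = {"gene": "G", "transposon": "TE", "pseudogene": "PG"}
    for chrom, feats in per_chrom.items():
        cursor = int(rng.integers(*design.gap))
        for fclass, (lo, hi) in feats:
            length = int(rng.integers(lo, hi + 1))
            counter[fclass] += 1
            models.append(
                GeneModel(
                    id=f"{prefix[fclass]}{counter[fclass]:05d}",
                    chrom=chrom,
                    start=cursor,
                    end=cursor + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    feature_class=fclass,
                )
            )
            cursor += length + int(rng.integers(*design.gap))
        chroms[chrom] = "".join(rng.choice(BASES, size=cursor, p=p))
    return GenomeSequence(chroms), models


# --------------------------------------------------------------- methylome


@dataclass
class PlantedWindow:
    """A fixed window whose true methylation differs between conditions."""

    chrom: str
    start: int
    end: int
    context: str
    level_wt: float
    level_mut: float


@dataclass
class MethylomeDesign:
    """True per-site methylation levels by feature class and context.

    Genic CG methylation ramps linearly from ``genic_cg_base`` at the 5' end
    to ``genic_cg_peak`` over ``genic_cg_ramp`` bp and stays at the peak
    through the body, emulating the canonical gene-body CG profile; CHG/CHH
    stay at background inside genes. Transposons are methylated in all three
    contexts; the mutant condition alters only the transposon levels
    (``te_levels_mut``), leaving genic patterns untouched.
    """

    background: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.05, "CHG": 0.02, "CHH": 0.02}
    )
    genic_cg_base: float = 0.05
    genic_cg_peak: float = 0.40
    genic_cg_ramp: int = 1500
    te_levels: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.80, "CHG": 0.40, "CHH": 0.10}
    )
    te_levels_mut: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.82, "CHG": 0.33, "CHH": 0.05}
    )
    planted_windows: list[PlantedWindow] = field(default_factory=list)

    def genic_cg_level(self, inward_distance) -> np.ndarray:
        d = np.asarray(inward_distance, dtype=float)
        ramp = self.genic_cg_base + (self.genic_cg_peak - self.genic_cg_base) * np.clip(
            d / self.genic_cg_ramp, 0, 1
        )
        return np.where(d < 0, self.background["CG"], ramp)

    def expected_genic_cg_profile(
        self, upstream: int = 2000, into: int = 5000, bin_size: int = 100
    ) -> np.ndarray:
        """Expected pooled CG level per metaplot bin (integral average of the
        piecewise-linear design over each bin)."""
        edges = np.arange(-upstream, into + 1, bin_size, dtype=float)
        lo, hi = self.genic_cg_level(edges[:-1]), self.genic_cg_level(edges[1:] - 1)
        return (lo + hi) / 2


def generate_methylome(
    genome: GenomeSequence,
    annotations: Sequence[GeneModel],
    design: MethylomeDesign,
    depth: float,
    condition: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-cytosine call table with binomially sampled counts.

    Each true cytosine receives ``n ~ Poisson(depth)`` reads and
    ``c ~ Binomial(n, p)`` methylated ones, where ``p`` follows the design
    for the feature the site falls in (``condition`` in {"wt", "mutant"}).
    Planted windows override ``p`` for their context regardless of feature.
    """
    if condition not in ("wt", "mutant"):
        raise ValueError("condition must be 'wt' or 'mutant'")
    te_levels = design.te_levels_mut if condition == "mutant" else design.te_levels
    frames = []
    for chrom in genome.chroms:
        sites = cytosine_sites(genome, chrom)
        pos = sites["pos"].to_numpy()
        ctx = sites["context"].to_numpy()
        p = np.empty(len(sites))
        for c in ("CG", "CHG", "CHH"):
            p[ctx == c] = design.background[c]
        for feat in annotations:
            if feat.chrom != chrom:
                continue
            inside = (pos >= feat.start) & (pos < feat.end)
            if feat.feature_class == "transposon":
                for c in ("CG", "CHG", "CHH"):
                    p[inside & (ctx == c)] = te_levels[c]
            elif feat.feature_class == "gene":
                sel = inside & (ctx == "CG")
                d = pos[sel] - feat.start if feat.strand == "+" else feat.end - 1 - pos[sel]
                p[sel] = design.genic_cg_level(d)
        for w in design.planted_windows:
            if w.chrom != chrom:
                continue
            sel = (pos >= w.start) & (pos < w.end) & (ctx == w.context)
            p[sel] = w.level_mut if condition == "mutant" else w.level_wt
        n = rng.poisson(depth, size=len(sites))
        c_counts = rng.binomial(n, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": sites["strand"].to_numpy(),
                    "context": ctx,
                    "c": c_counts,
                    "t": n - c_counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# -------------------------------------------------------------------- ChAP


@dataclass
class ChapDesign:
    """Designed H2A.Z occupancy: a TSS Gaussian peak whose amplitude and a
    gene-body plateau whose height each take one of three tier values."""

    baseline_rate: float = 0.03  # input midpoints per bp (30 per kb)
    tss_amplitudes: tuple[float, float, float] = (0.0, 8.0, 20.0)  # low/mid/high
    body_levels: tuple[float, float, float] = (0.0, 1.5, 4.0)
    tss_peak_center: int = 200
    tss_peak_sigma: int = 90
    body_from: int = 500  # plateau spans [body_from, L - body_from)
    read_length: int = 50


def _midpoints_to_reads(
    counts: np.ndarray, chrom: str, read_length: int, shift: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Emit read intervals whose midpoint rule inverts the +75 estimator."""
    mid = np.repeat(np.arange(len(counts)), counts)
    strand = rng.random(len(mid)) < 0.5
    start = np.where(strand, mid - shift, mid + shift + 1 - read_length)
    end = start + read_length
    ok = (start >= 0) & (end <= len(counts))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start[ok],
            "end": end[ok],
            "strand": np.where(strand, "+", "-")[ok],
        }
    )


def generate_chap(
    genome_lengths: Mapping[str, int],
    genes: Sequence[GeneModel],
    design: ChapDesign,
    rng: np.random.Generator,
    shift: int = 75,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """IP and input 50-bp read sets plus a per-gene tier truth table.

    Input midpoints are uniform at ``baseline_rate``; IP midpoints follow
    per-base intensity ``baseline * (1 + tss_amp * gauss + body_level)``
    with tiers assigned to genes in rotation through the nine
    (TSS tier x body tier) classes. Pseudogenes keep baseline intensity
    (no enrichment).
    """
    rates = {ch: np.full(n, design.baseline_rate) for ch, n in genome_lengths.items()}
    truth_rows = []
    gene_like = [g for g in genes if g.feature_class == "gene"]
    for k, gene in enumerate(gene_like):
        tss_tier, body_tier = k % 3, (k // 3) % 3
        truth_rows.append(
            {
                "gene_id": gene.id,
                "tss_tier": ("low", "mid", "high")[tss_tier],
                "body_tier": ("low", "mid", "high")[body_tier],
                "cluster": str(3 * body_tier + tss_tier + 1),
            }
        )
        L = gene.length
        d = np.arange(L, dtype=float)
        intensity = design.tss_amplitudes[tss_tier] * np.exp(
            -0.5 * ((d - design.tss_peak_center) / design.tss_peak_sigma) ** 2
        )
        body = (d >= design.body_from) & (d < L - design.body_from)
        intensity += np.where(body, design.body_levels[body_tier], 0.0)
        pos = gene.start + d.astype(int) if gene.strand == "+" else gene.end - 1 - d.astype(int)
        rates[gene.chrom][pos] *= 1 + intensity
    ip_frames, input_frames = [], []
    for ch, n in genome_lengths.items():
        ip_counts = rng.poisson(rates[ch])
        input_counts = rng.poisson(np.full(n, design.baseline_rate))
        ip_frames.append(_midpoints_to_reads(ip_counts, ch, design.read_length, shift, rng))
        input_frames.append(
            _midpoints_to_reads(input_counts, ch, design.read_length, shift, rng)
        )
    return (
        pd.concat(ip_frames, ignore_index=True),
        pd.concat(input_frames, ignore_index=True),
        pd.DataFrame(truth_rows),
    )


# ----------------------------------------------------------------- RNA-seq


@dataclass
class RnaDesign:
    """Allele-mosaic RNA-seq design.

    The genome is segmented into blocks cycling through homozygous-WS,
    heterozygous and homozygous-Col genotypes (``block_cycle`` holds the WS
    contribution of each block type: 1.0 = WS, 0.0 = Col, in between =
    heterozygous). Per-gene counts are negative-binomial around
    ``mean_reads`` with the planted log2 fold change applied to the mutant.
    """

    n_replicates: int = 3
    read_length: int = 36
    mean_reads: float = 50.0
    nb_size: float = 100.0  # NB dispersion: var = mu + mu^2 / size
    snps_per_gene: int = 2
    block_size: int = 60_000
    block_cycle: tuple[float, ...] = (0.5, 1.0, 0.25, 0.0)
    planted_log2fc: Mapping[str, float] = field(default_factory=dict)


def _place_snps(
    genome: GenomeSequence, genes: Sequence[GeneModel], design: RnaDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    margin = design.read_length + 6  # keep SNPs clear of the exon-end filter
    for gene in genes:
        L = gene.length
        if L <= 2 * margin:
            continue
        offsets = np.linspace(margin, L - 1 - margin, design.snps_per_gene).astype(int)
        for off in np.unique(offsets):
            pos = gene.start + int(off)
            ref = genome[gene.chrom][pos]
            if ref == "N":
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append(
                {
                    "chrom": gene.chrom,
                    "pos": pos,
                    "allele_ws": ref,
                    "allele_col": str(alt),
                    "gene_id": gene.id,
                }
            )
    return pd.DataFrame(rows)


def generate_rnaseq(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    design: RnaDesign,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame, pd.DataFrame]:
    """SNP table, per-sample read sequences, per-gene counts, and truth ledger.

    Reads are 36-mers sampled uniformly across each gene; every read draws a
    parental haplotype (WS with the block's contribution probability) and
    carries that haplotype's alleles at any SNP it covers, reverse-
    complemented on the minus strand. The truth ledger records each gene's
    block genotype, WS contribution and planted log2 fold change.
    """
    gene_like = [g for g in genes if g.feature_class == "gene"]
    snps = _place_snps(genome, gene_like, design, rng)
    snps_by_gene = {gid: grp for gid, grp in snps.groupby("gene_id")}

    samples = [f"mut_{i+1}" for i in range(design.n_replicates)] + [
        f"wt_{i+1}" for i in range(design.n_replicates)
    ]
    conditions = {s: ("mutant" if s.startswith("mut") else "wt") for s in samples}
    reads: dict[str, list[str]] = {s: [] for s in samples}
    counts = pd.DataFrame(0, index=[g.id for g in gene_like], columns=samples)
    truth_rows = []
    for gene in gene_like:
        block = (gene.midpoint // design.block_size) % len(design.block_cycle)
        f_ws = design.block_cycle[block]
        lfc = float(design.planted_log2fc.get(gene.id, 0.0))
        truth_rows.append(
            {"gene_id": gene.id, "contribution_ws": f_ws, "planted_log2fc": lfc,
             "genotype": "WS" if f_ws == 1.0 else "Col" if f_ws == 0.0 else "Het"}
        )
        seq = genome[gene.chrom]
        gene_snps = snps_by_gene.get(gene.id)
        for sample in samples:
            mu = design.mean_reads * (2.0**lfc if conditions[sample] == "mutant" else 1.0)
            # NB as Gamma-Poisson mixture
            lam = rng.gamma(design.nb_size, mu / design.nb_size)
            n_reads = rng.poisson(lam)
            counts.loc[gene.id, sample] = n_reads
            if n_reads == 0:
                continue
            starts = rng.integers(gene.start, gene.end - design.read_length + 1, n_reads)
            from_ws = rng.random(n_reads) < f_ws
            minus = rng.random(n_reads) < 0.5
            for s, ws, mi in zip(starts, from_ws, minus):
                r = seq[s : s + design.read_length]
                if gene_snps is not None and not ws:
                    for snp in gene_snps.itertuples(index=False):
                        if s <= snp.pos < s + design.read_length:
                            i = snp.pos - s
                            r = r[:i] + snp.allele_col + r[i + 1 :]
                if mi:
                    r = r.translate(_COMPLEMENT)[::-1]
                reads[sample].append(r)
    return snps, reads, counts, pd.DataFrame(truth_rows)


# --------------------------------------------------------- responsiveness


@dataclass
class ResponsivenessDesign:
    target_rho: float = 0.33  # Spearman rank correlation with body enrichment
    housekeeping_quantile: float = 0.05
    hypervariable_quantile: float = 0.95


def generate_responsiveness(
    body_scores: pd.Series,
    design: ResponsivenessDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Responsiveness scores with a target rank correlation to body enrichment.

    A Gaussian copula draw: body scores are rank-normalized, a correlated
    normal is drawn (Pearson parameter ``2 sin(pi rho_s / 6)`` so the
    *Spearman* correlation hits the target), and a monotone transform maps
    it to a 0-100 score. Tissue/abiotic/biotic subscores are Dirichlet
    shares of the total; housekeeping and hypervariable labels mark the
    score-quantile extremes.
    """
    rho_s = design.target_rho
    if not -1 <= rho_s <= 1:
        raise ValueError("target rho must be in [-1, 1]")
    x = body_scores.to_numpy(dtype=float)
    n = len(x)
    ranks = sps.rankdata(x, method="average")
    z1 = sps.norm.ppf((ranks - 0.5) / n)
    if abs(rho_s) == 1.0:
        z2 = np.sign(rho_s) * z1
    else:
        rho_p = 2 * np.sin(np.pi * rho_s / 6)
        z2 = rho_p * z1 + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
    score = 100 * sps.norm.cdf(z2)
    shares = rng.dirichlet([2.0, 2.0, 1.0], size=n)
    lo, hi = np.quantile(score, [design.housekeeping_quantile, design.hypervariable_quantile])
    return pd.DataFrame(
        {
            "gene_id": body_scores.index,
            "responsiveness_score": score,
            "response_tissue": score * shares[:, 0],
            "response_abiotic": score * shares[:, 1],
            "response_biotic": score * shares[:, 2],
            "housekeeping": score <= lo,
            "hypervariable": score >= hi,
        }
    )


# ------------------------------------------------------------- top level


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeDesign = field(default_factory=GenomeDesign)
    methylome: MethylomeDesign = field(default_factory=MethylomeDesign)
    chap: ChapDesign = field(default_factory=ChapDesign)
    rna: RnaDesign = field(default_factory=RnaDesign)
    responsiveness: ResponsivenessDesign = field(default_factory=ResponsivenessDesign)
    methylome_depth: float = 20.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
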