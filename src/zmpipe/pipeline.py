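"""Pipeline orchestration: validated run configuration, staged execution in
dependency order, a provenance manifest, and checksum-based stage caching."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chap, ecotype_de, simulate, stats
from .genome import GenomeSequence, load_annotation, write_bed
from .io import (
    read_fastq_sequences,
    read_methylation_calls,
    read_reads_bed,
    sha256_file,
    sha256_obj,
    write_fastq,
    write_methylation_calls,
    write_reads_bed,
    write_table,
)
from .methylome import (
    differential_methylation_windows,
    ends_aligned_metaplot,
    window_table,
)

logger = logging.getLogger(__name__)

STAGES = ("sim", "meth", "chap", "de", "stats")


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    outdir: str = "zm_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # simulation scale
    n_genes: int = 60
    n_tes: int = 12
    n_pseudogenes: int = 6
    gene_length: tuple[int, int] = (2600, 4000)
    methylome_depth: float = 10.0
    chap_rate: float = 0.03
    rna_mean_reads: float = 200.0
    n_planted_de: int = 6
    planted_fold: float = 4.0
    # analysis parameters (defaults follow the study conventions)
    context: str = "CG"
    meth_bin: int = 100
    meth_upstream: int = 2000
    meth_into: int = 5000
    dmw_window: int = 50
    dmw_min_diff: float = 0.10
    chap_bin: int = 50
    chap_upstream: int = 1000
    chap_into: int = 3000
    opposite_end_exclusion: int = 1000
    de_fold: float = 2.0
    de_p_single: float = 0.001
    de_p_both: float = 0.005
    smoothing_window: int = 20
    target_rho: float = 0.33

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "gene_length"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _params_of(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir")
    d.pop("stages")
    return d


class PipelineRunner:
    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.previous = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )
        self.manifest: dict = {
            "tool": "zmpipe",
            "version": __version__,
            "seed": config.seed,
            "parameters": _params_of(config),
            "stages": {},
        }

    # ---------------------------------------------------------------- util

    def _path(self, name: str) -> Path:
        return self.out / name

    def _signature(self, stage: str, inputs: list[str]) -> dict:
        for p in inputs:
            if not self._path(p).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' needs missing input {p}; run its producing stage first"
                )
        return {
            "params": sha256_obj(_params_of(self.config)),
            "inputs": {p: sha256_file(self._path(p)) for p in inputs},
        }

    def _cached(self, stage: str, signature: dict, outputs: list[str]) -> bool:
        prev = self.previous.get("stages", {}).get(stage)
        if not prev or prev.get("signature") != signature:
            return False
        return all(self._path(p).exists() for p in outputs)

    def _record(self, stage: str, signature: dict, outputs: list[str], cached: bool) -> None:
        self.manifest["stages"][stage] = {
            "signature": signature,
            "outputs": {p: sha256_file(self._path(p)) for p in outputs},
            "cached": cached,
        }

    def _run_stage(self, stage: str, inputs: list[str], outputs: list[str], fn) -> None:
        signature = self._signature(stage, inputs)
        if self._cached(stage, signature, outputs):
            logger.info("stage %s: inputs and parameters unchanged, skipping", stage)
            self._record(stage, signature, outputs, cached=True)
            return
        logger.info("stage %s: running", stage)
        fn()
        self._record(stage, signature, outputs, cached=False)

    # -------------------------------------------------------------- stages

    def stage_sim(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        gdesign = simulate.GenomeDesign(
            n_genes=cfg.n_genes, n_tes=cfg.n_tes, n_pseudogenes=cfg.n_pseudogenes,
            gene_length=cfg.gene_length,
        )
        genome, models = simulate.generate_genome(gdesign, rng)
        genome.to_fasta(self._path("genome.fa"))
        write_bed(models, self._path("annotations.bed"))

        mdesign = simulate.MethylomeDesign()
        for condition in ("wt", "mutant"):
            calls = simulate.generate_methylome(
                genome, models, mdesign, cfg.methylome_depth, condition, rng
            )
            write_methylation_calls(calls, self._path(f"methylome_{condition}.tsv"))

        genes = [m for m in models if m.feature_class == "gene"]
        cdesign = simulate.ChapDesign(baseline_rate=cfg.chap_rate)
        lengths = {ch: genome.length(ch) for ch in genome.chroms}
        ip, inp, chap_truth = simulate.generate_chap(lengths, genes, cdesign, rng)
        write_reads_bed(ip, self._path("chap_ip.bed"))
        write_reads_bed(inp, self._path("chap_input.bed"))
        write_table(chap_truth, self._path("chap_truth.tsv"))

        planted = {g.id: np.log2(cfg.planted_fold) for g in genes[: cfg.n_planted_de]}
        rdesign = simulate.RnaDesign(
            mean_reads=cfg.rna_mean_reads, planted_log2fc=planted
        )
        snps, reads, counts, rna_truth = simulate.generate_rnaseq(genome, genes, rdesign, rng)
        write_table(snps, self._path("snps.tsv"))
        for sample, seqs in reads.items():
            write_fastq(seqs, self._path(f"rna_{sample}.fastq"), prefix=sample)
        write_table(counts.rename_axis("gene_id").reset_index(), self._path("gene_counts.tsv"))
        write_table(rna_truth, self._path("rna_truth.tsv"))

    def stage_meth(self) -> None:
        cfg = self.config
        models = load_annotation(self._path("annotations.bed"))
        genes = [m for m in models if m.feature_class == "gene"]
        tes = [m for m in models if m.feature_class == "transposon"]
        wt = read_methylation_calls(self._path("methylome_wt.tsv"))
        mut = read_methylation_calls(self._path("methylome_mutant.tsv"))
        for anchor in ("five_prime", "three_prime"):
            prof = ends_aligned_metaplot(
                wt, genes, cfg.context, anchor, cfg.meth_upstream, cfg.meth_into, cfg.meth_bin
            )
            write_table(prof.to_frame(), self._path(f"metaplot_wt_{anchor}.tsv"))
        dmw, hist = differential_methylation_windows(
            window_table(mut, cfg.context, cfg.dmw_window),
            window_table(wt, cfg.context, cfg.dmw_window),
            min_diff=cfg.dmw_min_diff, window=cfg.dmw_window, exclude=tes,
        )
        write_table(dmw, self._path("dmw.tsv"))
        write_table(hist, self._path("dmw_histogram.tsv"))

    def stage_chap(self) -> None:
        cfg = self.config
        genome = GenomeSequence.from_fasta(self._path("genome.fa"))
        models = load_annotation(self._path("annotations.bed"))
        genes = [m for m in models if m.feature_class in ("gene", "pseudogene")]
        lengths = {ch: genome.length(ch) for ch in genome.chroms}
        ip_mid = chap.estimate_midpoints(read_reads_bed(self._path("chap_ip.bed")), lengths)
        in_mid = chap.estimate_midpoints(read_reads_bed(self._path("chap_input.bed")), lengths)
        track = chap.build_track(ip_mid, in_mid)
        track.to_bedgraph(self._path("enrichment.bedgraph"))
        prof = chap.enrichment_metaplot(
            track, [g for g in genes if g.feature_class == "gene"],
            upstream=cfg.chap_upstream, into=cfg.chap_into, bin_size=cfg.chap_bin,
            opposite_end_exclusion=cfg.opposite_end_exclusion,
        )
        write_table(prof, self._path("chap_metaplot.tsv"))
        scores = chap.scores_table(track, genes)
        clusters = chap.nine_cluster_partition(scores)
        write_table(clusters, self._path("chap_clusters.tsv"))

    def stage_de(self) -> None:
        cfg = self.config
        genome = GenomeSequence.from_fasta(self._path("genome.fa"))
        models = load_annotation(self._path("annotations.bed"))
        genes = [m for m in models if m.feature_class == "gene"]
        snps = pd.read_csv(self._path("snps.tsv"), sep="\t").rename(
            columns=lambda c: c.lstrip("#")
        )
        scaffolds = ecotype_de.build_scaffolds(genome, snps)
        counts = pd.read_csv(self._path("gene_counts.tsv"), sep="\t").rename(
            columns=lambda c: c.lstrip("#")
        ).set_index("gene_id")
        samples = list(counts.columns)
        per_sample = {}
        for sample in samples:
            seqs = read_fastq_sequences(self._path(f"rna_{sample}.fastq"))
            per_sample[sample] = ecotype_de.assign_reads(seqs, scaffolds)
        totals = ecotype_de.sum_sample_counts(per_sample)
        retained = ecotype_de.filter_snps(totals, {g.id: g for g in genes})
        typed = ecotype_de.genotype_snps(retained)
        smoothed = ecotype_de.smooth_contributions(typed, window=cfg.smoothing_window)
        write_table(
            smoothed.drop(columns=["ws_scaffold", "col_scaffold"]),
            self._path("snp_genotypes.tsv"),
        )
        partitions = ecotype_de.assign_gene_partitions(genes, smoothed)
        conditions = {s: ("mutant" if s.startswith("mut") else "wt") for s in samples}
        results = ecotype_de.run_de(
            genes, counts, conditions, partitions,
            fold=cfg.de_fold, p_single=cfg.de_p_single, p_both=cfg.de_p_both,
        )
        write_table(results, self._path("de_results.tsv"))

    def stage_stats(self) -> None:
        cfg = self.config
        clusters = pd.read_csv(self._path("chap_clusters.tsv"), sep="\t").rename(
            columns=lambda c: c.lstrip("#")
        )
        eligible = clusters.dropna(subset=["body_score"]).set_index("gene_id")
        rng = np.random.default_rng(cfg.seed + 1)
        resp = simulate.generate_responsiveness(
            eligible["body_score"],
            simulate.ResponsivenessDesign(target_rho=cfg.target_rho),
            rng,
        )
        write_table(resp, self._path("responsiveness.tsv"))
        rho, p = stats.spearman(
            eligible["body_score"].to_numpy(),
            resp["responsiveness_score"].to_numpy(),
            n_permutations=2000,
            seed=cfg.seed + 2,
        )
        de = pd.read_csv(self._path("de_results.tsv"), sep="\t").rename(
            columns=lambda c: c.lstrip("#")
        )
        n_up = int((de["call"] == "up").sum())
        n_down = int((de["call"] == "down").sum())
        summary = pd.DataFrame(
            [
                {"statistic": "spearman_rho_body_vs_responsiveness", "value": rho},
                {"statistic": "spearman_permutation_p", "value": p},
                {"statistic": "n_genes_up", "value": n_up},
                {"statistic": "n_genes_down", "value": n_down},
            ]
        )
        write_table(summary, self._path("stats_summary.tsv"))

    # ----------------------------------------------------------------- run

    def run(self) -> dict:
        spec = {
            "sim": ([], ["genome.fa", "annotations.bed", "methylome_wt.tsv",
                         "methylome_mutant.tsv", "chap_ip.bed", "chap_input.bed",
                         "chap_truth.tsv", "snps.tsv", "gene_counts.tsv", "rna_truth.tsv"],
                    self.stage_sim),
            "meth": (["annotations.bed", "methylome_wt.tsv", "methylome_mutant.tsv"],
                     ["dmw.tsv", "dmw_histogram.tsv"], self.stage_meth),
            "chap": (["genome.fa", "annotations.bed", "chap_ip.bed", "chap_input.bed"],
                     ["enrichment.bedgraph", "chap_metaplot.tsv", "chap_clusters.tsv"],
                     self.stage_chap),
            "de": (["genome.fa", "annotations.bed", "snps.tsv", "gene_counts.tsv"],
                   ["snp_genotypes.tsv", "de_results.tsv"], self.stage_de),
            "stats": (["chap_clusters.tsv", "de_results.tsv"],
                      ["responsiveness.tsv", "stats_summary.tsv"], self.stage_stats),
        }
        for stage in STAGES:
            if stage not in self.config.stages:
                continue
            inputs, outputs, fn = spec[stage]
            self._run_stage(stage, inputs, outputs, fn)
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return self.manifest


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    return PipelineRunner(config).run()
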