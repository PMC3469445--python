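import numpy as np
import pandas as pd
import pytest

from zmpipe import simulate
from zmpipe.genome import GeneModel
from zmpipe.methylome import ends_aligned_metaplot
from zmpipe.stats import spearman


def _small_genome(seed=5, **kwargs):
    design = simulate.GenomeDesign(
        n_genes=kwargs.pop("n_genes", 10),
        n_tes=kwargs.pop("n_tes", 3),
        n_pseudogenes=kwargs.pop("n_pseudogenes", 2),
        gene_length=kwargs.pop("gene_length", (1500, 2500)),
        **kwargs,
    )
    rng = np.random.default_rng(seed)
    return simulate.generate_genome(design, rng)


class TestGenerateGenome:
    def test_same_seed_is_byte_identical(self):
        g1, m1 = _small_genome()
        g2, m2 = _small_genome()
        assert g1.chroms == g2.chroms
        assert [(m.id, m.start, m.end, m.strand) for m in m1] == [
            (m.id, m.start, m.end, m.strand) for m in m2
        ]

    def test_feature_counts_match_config(self):
        _, models = _small_genome()
        by_class = pd.Series([m.feature_class for m in models]).value_counts()
        assert by_class["gene"] == 10 and by_class["transposon"] == 3
        assert by_class["pseudogene"] == 2

    def test_no_genes_requested(self):
        design = simulate.GenomeDesign(n_genes=0, n_tes=2, n_pseudogenes=0)
        _, models = simulate.generate_genome(design, np.random.default_rng(0))
        assert all(m.feature_class == "transposon" for m in models)

    def test_features_do_not_overlap(self):
        _, models = _small_genome(n_genes=30)
        by_chrom: dict = {}
        for m in models:
            by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
        for ivals in by_chrom.values():
            ivals.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivals, ivals[1:]))


class TestGenerateMethylome:
    def test_zero_design_gives_no_methylation(self):
        genome, models = _small_genome()
        design = simulate.MethylomeDesign(
            background={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            genic_cg_base=0.0, genic_cg_peak=0.0,
            te_levels={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
            te_levels_mut={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
        )
        calls = simulate.generate_methylome(
            genome, models, design, 5.0, "wt", np.random.default_rng(0)
        )
        assert (calls["c"] == 0).all()

    def test_saturated_design_has_no_unmethylated_reads(self):
        genome, models = _small_genome()
        design = simulate.MethylomeDesign(
            background={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
            genic_cg_base=1.0, genic_cg_peak=1.0,
            te_levels={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
        )
        calls = simulate.generate_methylome(
            genome, models, design, 5.0, "wt", np.random.default_rng(0)
        )
        assert (calls["t"] == 0).all()

    def test_mutant_condition_changes_only_transposons(self):
        genome, models = _small_genome()
        design = simulate.MethylomeDesign()
        rng = np.random.default_rng(3)
        wt = simulate.generate_methylome(genome, models, design, 50.0, "wt", rng)
        mut = simulate.generate_methylome(genome, models, design, 50.0, "mutant", rng)
        tes = [m for m in models if m.feature_class == "transposon"]
        in_te = np.zeros(len(wt), dtype=bool)
        for te in tes:
            in_te |= (wt["pos"] >= te.start) & (wt["pos"] < te.end)
        chh = (wt["context"] == "CHH").to_numpy()
        lvl = lambda df, m: df.loc[m, "c"].sum() / (df.loc[m, "c"].sum() + df.loc[m, "t"].sum())
        assert lvl(mut, in_te & chh) < lvl(wt, in_te & chh) - 0.03
        assert abs(lvl(mut, ~in_te & chh) - lvl(wt, ~in_te & chh)) < 0.01

    def test_planted_window_overrides_design(self):
        genome, models = _small_genome()
        gene = next(m for m in models if m.feature_class == "gene")
        w = simulate.PlantedWindow(gene.chrom, gene.start + 500, gene.start + 550,
                                   "CG", 0.2, 0.8)
        design = simulate.MethylomeDesign(planted_windows=[w])
        mut = simulate.generate_methylome(genome, models, design, 100.0, "mutant",
                                          np.random.default_rng(1))
        sel = (mut["pos"] >= w.start) & (mut["pos"] < w.end) & (mut["context"] == "CG")
        level = mut.loc[sel, "c"].sum() / (mut.loc[sel, ["c", "t"]].sum().sum())
        assert level == pytest.approx(0.8, abs=0.1)


class TestGenerateChap:
    def test_zero_design_gives_flat_track(self):
        from zmpipe.chap import build_track, estimate_midpoints

        genome, models = _small_genome(n_genes=5)
        genes = [m for m in models if m.feature_class == "gene"]
        design = simulate.ChapDesign(tss_amplitudes=(0, 0, 0), body_levels=(0, 0, 0))
        lengths = {ch: genome.length(ch) for ch in genome.chroms}
        ip, inp, _ = simulate.generate_chap(lengths, genes, design, np.random.default_rng(2))
        track = build_track(
            estimate_midpoints(ip, lengths), estimate_midpoints(inp, lengths)
        )
        assert abs(track["chr1"].mean()) < 0.01

    def test_truth_table_covers_nine_classes(self):
        genome, models = _small_genome(n_genes=18, gene_length=(2600, 3000))
        genes = [m for m in models if m.feature_class == "gene"]
        lengths = {ch: genome.length(ch) for ch in genome.chroms}
        _, _, truth = simulate.generate_chap(
            lengths, genes, simulate.ChapDesign(), np.random.default_rng(0)
        )
        assert sorted(truth["cluster"].unique()) == [str(i) for i in range(1, 10)]

    def test_reads_invert_the_midpoint_estimator(self):
        from zmpipe.chap import estimate_midpoints

        genome, models = _small_genome(n_genes=4)
        genes = [m for m in models if m.feature_class == "gene"]
        lengths = {ch: genome.length(ch) for ch in genome.chroms}
        ip, _, _ = simulate.generate_chap(
            lengths, genes, simulate.ChapDesign(), np.random.default_rng(0)
        )
        mids = estimate_midpoints(ip, lengths)
        assert sum(a.sum() for a in mids.values()) == len(ip)


@pytest.fixture(scope="module")
def sim():
    genome, models = _small_genome(seed=11, n_genes=12, n_tes=0, n_pseudogenes=0,
                                   gene_length=(1000, 1000))
    design = simulate.RnaDesign(mean_reads=300.0, block_cycle=(0.25,))
    rng = np.random.default_rng(7)
    return genome, models, simulate.generate_rnaseq(genome, models, design, rng)


class TestGenerateRnaseq:

    def test_het_block_allele_ratio(self, sim):
        """Contribution 0.25 -> WS:Col read ratio near 1:3 at covered SNPs."""
        from zmpipe.ecotype_de import assign_reads, build_scaffolds

        genome, models, (snps, reads, counts, truth) = sim
        scaffolds = build_scaffolds(genome, snps)
        all_reads = [r for seqs in reads.values() for r in seqs]
        out = assign_reads(all_reads, scaffolds)
        frac = out["ws_count"].sum() / (out["ws_count"].sum() + out["col_count"].sum())
        assert frac == pytest.approx(0.25, abs=0.05)

    def test_same_seed_identical_reads(self):
        genome, models = _small_genome(seed=11, n_genes=4, n_tes=0, n_pseudogenes=0)
        design = simulate.RnaDesign(mean_reads=30.0)
        r1 = simulate.generate_rnaseq(genome, models, design, np.random.default_rng(9))
        r2 = simulate.generate_rnaseq(genome, models, design, np.random.default_rng(9))
        assert r1[1] == r2[1]
        pd.testing.assert_frame_equal(r1[0], r2[0])

    def test_counts_table_matches_emitted_reads(self, sim):
        _, _, (snps, reads, counts, truth) = sim
        for sample, seqs in reads.items():
            assert counts[sample].sum() == len(seqs)

    def test_planted_fold_change_raises_mutant_counts(self):
        genome, models = _small_genome(seed=11, n_genes=6, n_tes=0, n_pseudogenes=0)
        planted = {models[0].id: 2.0}
        design = simulate.RnaDesign(mean_reads=100.0, planted_log2fc=planted)
        snps, reads, counts, truth = simulate.generate_rnaseq(
            genome, models, design, np.random.default_rng(4)
        )
        mut = counts.loc[models[0].id, ["mut_1", "mut_2", "mut_3"]].mean()
        wt = counts.loc[models[0].id, ["wt_1", "wt_2", "wt_3"]].mean()
        assert 2.5 < mut / wt < 6.5


class TestResponsiveness:
    def test_perfect_target_rho_is_exact(self, rng):
        body = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        out = simulate.generate_responsiveness(
            body, simulate.ResponsivenessDesign(target_rho=1.0), rng
        )
        rho, _ = spearman(body.to_numpy(), out["responsiveness_score"].to_numpy(),
                          n_permutations=0)
        assert rho == pytest.approx(1.0)

    def test_zero_target_rho_near_zero(self, rng):
        body = pd.Series(rng.normal(size=5000))
        out = simulate.generate_responsiveness(
            body, simulate.ResponsivenessDesign(target_rho=0.0), rng
        )
        rho, _ = spearman(body.to_numpy(), out["responsiveness_score"].to_numpy(),
                          n_permutations=0)
        assert abs(rho) < 0.05

    def test_labels_partition_by_score_quantiles(self, rng):
        body = pd.Series(rng.normal(size=1000))
        out = simulate.generate_responsiveness(
            body, simulate.ResponsivenessDesign(target_rho=0.3), rng
        )
        hk = out[out["housekeeping"]]["responsiveness_score"]
        hv = out[out["hypervariable"]]["responsiveness_score"]
        mid = out[~out["housekeeping"] & ~out["hypervariable"]]["responsiveness_score"]
        assert hk.max() <= mid.min()
        assert hv.min() >= mid.max()

    def test_subscores_sum_to_total(self, rng):
        body = pd.Series(rng.normal(size=50))
        out = simulate.generate_responsiveness(
            body, simulate.ResponsivenessDesign(), rng
        )
        total = out[["response_tissue", "response_abiotic", "response_biotic"]].sum(axis=1)
        np.testing.assert_allclose(total, out["responsiveness_score"], rtol=1e-9)


def test_metaplot_recovery_is_within_binomial_error():
    """The designed genic CG profile is recovered bin-by-bin at 20x depth."""
    design = simulate.GenomeDesign(n_genes=60, n_tes=0, n_pseudogenes=0)
    rng = np.random.default_rng(21)
    genome, models = simulate.generate_genome(design, rng)
    mdesign = simulate.MethylomeDesign()
    calls = simulate.generate_methylome(genome, models, mdesign, 20.0, "wt", rng)
    prof = ends_aligned_metaplot(calls, models, "CG")
    expected = mdesign.expected_genic_cg_profile()
    assert np.nanmax(np.abs(prof.values - expected)) < 0.03
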