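import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_oracle, rolling_mean_oracle
from zmpipe.ecotype_de import (
    GenePartition,
    assign_reads,
    build_scaffolds,
    call_de,
    call_genotype,
    fisher_de_test,
    filter_snps,
    genotype_snps,
    partition_counts,
    rpkm,
    smooth_contributions,
)
from zmpipe.genome import GeneModel, GenomeSequence

_RC = str.maketrans("ACGT", "TGCA")


def _genome(rng, n=5000):
    return GenomeSequence({"chr1": "".join(rng.choice(list("ACGT"), size=n))})


def _snp_frame(genome, positions):
    rows = []
    for pos in positions:
        ref = genome["chr1"][pos]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        rows.append(
            {"chrom": "chr1", "pos": pos, "allele_ws": ref, "allele_col": alt,
             "gene_id": "g1"}
        )
    return pd.DataFrame(rows)


class TestScaffolds:
    def test_scaffolds_differ_only_at_center(self, rng):
        genome = _genome(rng)
        sc = build_scaffolds(genome, _snp_frame(genome, [100]))
        ws, col = sc.loc[0, "ws_scaffold"], sc.loc[0, "col_scaffold"]
        assert len(ws) == len(col) == 75
        diffs = [i for i in range(75) if ws[i] != col[i]]
        assert diffs == [37]

    def test_edge_snp_dropped(self, rng):
        genome = _genome(rng)
        sc = build_scaffolds(genome, _snp_frame(genome, [10]))
        assert sc.empty

    def test_scaffold_equals_genome_slice_with_substituted_center(self, rng):
        genome = _genome(rng)
        sc = build_scaffolds(genome, _snp_frame(genome, [200]))
        raw = genome.slice("chr1", 200 - 37, 200 + 38)
        assert sc.loc[0, "ws_scaffold"] == raw[:37] + sc.loc[0, "allele_ws"] + raw[38:]
        assert sc.loc[0, "col_scaffold"] == raw[:37] + sc.loc[0, "allele_col"] + raw[38:]


class TestAssignReads:
    @pytest.fixture
    def scaffolds(self, rng):
        genome = _genome(rng)
        return build_scaffolds(genome, _snp_frame(genome, [300]))

    def test_center_covering_read_counts_once(self, scaffolds):
        read = scaffolds.loc[0, "ws_scaffold"][20:56]  # covers position 37
        out = assign_reads([read], scaffolds)
        assert out.loc[0, "ws_count"] == 1 and out.loc[0, "col_count"] == 0

    def test_reverse_complement_read_counts(self, scaffolds):
        read = scaffolds.loc[0, "col_scaffold"][10:46].translate(_RC)[::-1]
        out = assign_reads([read], scaffolds)
        assert out.loc[0, "col_count"] == 1 and out.loc[0, "ws_count"] == 0

    def test_non_covering_read_matches_both_and_is_discarded(self, scaffolds):
        read = scaffolds.loc[0, "ws_scaffold"][0:36]  # stops before the SNP
        out = assign_reads([read], scaffolds)
        assert out.loc[0, "ws_count"] == 0 and out.loc[0, "col_count"] == 0

    def test_single_mismatch_unassigned(self, scaffolds):
        read = list(scaffolds.loc[0, "ws_scaffold"][20:56])
        read[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[5]]
        out = assign_reads(["".join(read)], scaffolds)
        assert out.loc[0, "ws_count"] == 0 and out.loc[0, "col_count"] == 0

    def test_matches_exhaustive_offset_scan(self, rng):
        """Oracle: for each read, scan every offset of every scaffold."""
        genome = _genome(rng)
        scaffolds = build_scaffolds(genome, _snp_frame(genome, [300, 900, 1500]))
        reads = []
        for _ in range(200):
            i = int(rng.integers(0, 3))
            eco = "ws_scaffold" if rng.random() < 0.5 else "col_scaffold"
            off = int(rng.integers(0, 40))
            r = scaffolds.loc[i, eco][off : off + 36]
            if rng.random() < 0.5:
                r = r.translate(_RC)[::-1]
            if rng.random() < 0.1:  # corrupt some reads
                r = "A" + r[1:]
            reads.append(r)
        out = assign_reads(reads, scaffolds)

        exp_ws = np.zeros(3, dtype=int)
        exp_col = np.zeros(3, dtype=int)
        for r in reads:
            for i in range(3):
                hits = {}
                for eco in ("ws", "col"):
                    scaffold = scaffolds.loc[i, f"{eco}_scaffold"]
                    cover = anywhere = False
                    for seq in (r, r.translate(_RC)[::-1]):
                        for off in range(len(scaffold) - len(seq) + 1):
                            if scaffold[off : off + len(seq)] == seq:
                                anywhere = True
                                if off <= 37 <= off + len(seq) - 1:
                                    cover = True
                    hits[eco] = (cover, anywhere)
                if hits["ws"][0] and not hits["col"][1]:
                    exp_ws[i] += 1
                if hits["col"][0] and not hits["ws"][1]:
                    exp_col[i] += 1
        assert out["ws_count"].tolist() == exp_ws.tolist()
        assert out["col_count"].tolist() == exp_col.tolist()


class TestFilterSnps:
    def _gene(self, length=1000):
        return GeneModel(id="g1", chrom="chr1", start=0, end=length, strand="+")

    def _snp(self, pos, ws=20, col=20):
        return pd.DataFrame(
            [{"chrom": "chr1", "pos": pos, "gene_id": "g1", "ws_count": ws, "col_count": col}]
        )

    def test_snp_near_exon_end_removed(self):
        out = filter_snps(self._snp(970), {"g1": self._gene()})  # 30 bp from end
        assert out.empty

    def test_short_gene_removed(self):
        out = filter_snps(self._snp(75), {"g1": self._gene(150)})
        assert out.empty

    def test_read_count_threshold(self):
        assert filter_snps(self._snp(500, 4, 5), {"g1": self._gene()}).empty
        assert len(filter_snps(self._snp(500, 5, 5), {"g1": self._gene()})) == 1


class TestGenotype:
    @pytest.mark.parametrize(
        "ws, col, expected",
        [
            (20, 0, "WS"),
            (10, 12, "Het"),
            (48, 2, "WS"),  # minor fraction 0.04 < 0.1
            (0, 20, "Col"),
            (4, 3, "untyped"),
            (45, 5, "Het"),  # fraction 0.1, count 5
        ],
    )
    def test_calls(self, ws, col, expected):
        assert call_genotype(ws, col) == expected


def _het_snps(contributions, chrom="chr1", genotypes=None):
    n = len(contributions)
    genotypes = genotypes or ["Het"] * n
    ws = [int(round(100 * c)) if g == "Het" else (100 if g == "WS" else 0)
          for c, g in zip(contributions, genotypes)]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n) * 100,
            "ws_count": ws,
            "col_count": [100 - w for w in ws],
        }
    )
    out = genotype_snps(df, min_reads=10)
    out["genotype"] = genotypes  # force the intended genotype labels
    out.loc[out["genotype"] != "Het", "contribution_ws"] = np.nan
    return out


class TestSmoothing:
    def test_constant_vector_is_fixed_point(self):
        snps = _het_snps([0.25] * 50)
        out = smooth_contributions(snps)
        assert (out["smoothed_contribution_ws"] == 0.25).all()

    def test_short_block_smooths_to_block_mean(self):
        snps = _het_snps([0.1, 0.2, 0.3, 0.4, 0.5])
        out = smooth_contributions(snps, window=20)
        np.testing.assert_allclose(out["smoothed_contribution_ws"], 0.3)

    def test_matches_brute_force_loop(self, rng):
        vals = rng.uniform(0.1, 0.9, 100)
        snps = _het_snps(np.round(vals, 2))
        out = smooth_contributions(snps, window=20)
        expected = rolling_mean_oracle(list(snps["contribution_ws"]), 20)
        np.testing.assert_allclose(out["smoothed_contribution_ws"], expected, atol=1e-12)

    def test_homozygous_snp_breaks_the_block(self):
        genotypes = ["Het", "Het", "WS", "Het", "Het"]
        snps = _het_snps([0.2, 0.4, np.nan, 0.6, 0.8], genotypes=genotypes)
        out = smooth_contributions(snps, window=20)
        s = out["smoothed_contribution_ws"].to_numpy()
        np.testing.assert_allclose(s[[0, 1]], 0.3)
        np.testing.assert_allclose(s[[3, 4]], 0.7)
        assert np.isnan(s[2])


class TestRpkm:
    def test_formula(self):
        assert rpkm(100, 2000, 1e7) == pytest.approx(5.0)

    def test_zero_reads(self):
        assert rpkm(0, 2000, 1e7) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 1e6)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_matches_formula_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(0, 1000))
            L = int(rng.integers(100, 10_000))
            lib = float(rng.integers(int(1e5), int(1e8)))
            assert rpkm(n, L, lib) == pytest.approx(n * 1e9 / (L * lib))


class TestPartition:
    def test_het_split(self):
        ws, col = partition_counts(100, GenePartition("g", "Het", 0.25))
        assert (ws, col) == (25.0, 75.0)

    def test_homozygous_all_one_side(self):
        assert partition_counts(40, GenePartition("g", "WS", 1.0)) == (40.0, 0.0)
        assert partition_counts(40, GenePartition("g", "Col", 0.0)) == (0.0, 40.0)

    def test_conservation_exact_pre_rounding(self, rng):
        for _ in range(1000):
            count = float(rng.integers(0, 10_000))
            f = float(rng.uniform(0, 1))
            ws, col = partition_counts(count, GenePartition("g", "Het", f))
            assert ws + col == count  # exact, not approx

    def test_unpartitionable_gene_rejected(self):
        with pytest.raises(ValueError):
            partition_counts(10, GenePartition("g", "unpartitionable", np.nan))


class TestFisherDeTest:
    def test_equal_counts_equal_libraries(self):
        assert fisher_de_test(50, 50, 10_000, 10_000) == 1.0

    def test_matches_enumeration(self):
        p = fisher_de_test(0, 20, 10_000, 10_000)
        assert p == pytest.approx(fisher_oracle(0, 10_000, 20, 9_980), abs=1e-12)

    def test_doubling_scale_decreases_p(self):
        p1 = fisher_de_test(10, 30, 10_000, 10_000)
        p2 = fisher_de_test(20, 60, 20_000, 20_000)
        assert p2 < p1
        assert p2 == pytest.approx(fisher_oracle(20, 19_980, 60, 19_940), abs=1e-12)


class TestCallDe:
    def test_single_ecotype_strong(self):
        assert call_de(np.nan, np.log2(2.3), np.nan, 5e-4) == "up"

    def test_fold_threshold_blocks_significant_gene(self):
        assert call_de(np.log2(1.9), np.nan, 1e-6, np.nan) == "none"

    def test_both_ecotypes_relaxed_p(self):
        lfc = np.log2(2.5)
        assert call_de(lfc, lfc, 0.003, 0.003) == "up"
        assert call_de(-lfc, -lfc, 0.003, 0.003) == "down"

    def test_both_rule_requires_same_direction(self):
        lfc = np.log2(2.5)
        assert call_de(lfc, -lfc, 0.003, 0.003) == "none"

    def test_contradictory_strong_directions_flagged_none(self):
        lfc = np.log2(4.0)
        assert call_de(lfc, -lfc, 1e-5, 1e-5) == "none"

    def test_no_defined_ecotype_errors(self):
        with pytest.raises(ValueError):
            call_de(np.nan, np.nan, np.nan, np.nan)
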