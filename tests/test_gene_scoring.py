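"""Gene scoring: window-minimum SNP-to-gene mapping and the finding list."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igea.gene_scoring import GeneQtMatrix, map_snps_to_genes, significant_pairs
from igea.io import GeneAnnotation, SnpAssociation


def snp(snp_id, pos, qt, p, chrom="1"):
    return SnpAssociation(snp_id=snp_id, chrom=chrom, pos=pos, qt_id=qt, p_value=p)


GENE = GeneAnnotation(gene_id="G", chrom="1", start=10_000, end=11_000)


class TestWindowMinimumMapping:
    def test_snp_outside_window_is_ignored(self):
        m = map_snps_to_genes(
            [snp("rs1", 15_000, "q", 0.01), snp("rs2", 40_000, "q", 1e-8)],
            [GENE],
            window_bp=20_000,
        )
        assert m.p_values[0, 0] == 0.01  # rs2 sits outside [1, 31000]

    def test_minimum_over_in_window_snps(self):
        m = map_snps_to_genes(
            [snp("rs1", 10_500, "q", 0.5), snp("rs2", 10_600, "q", 1e-6)], [GENE]
        )
        assert m.p_values[0, 0] == 1e-6

    def test_window_boundaries_are_inclusive(self):
        gene = GeneAnnotation(gene_id="G", chrom="1", start=50_000, end=51_000)
        inside_lo, inside_hi = gene.start - 20_000, gene.end + 20_000
        m = map_snps_to_genes(
            [
                snp("rs_lo", inside_lo, "q", 0.01),
                snp("rs_hi", inside_hi, "q", 0.02),
                snp("rs_out_lo", inside_lo - 1, "q", 1e-9),
                snp("rs_out_hi", inside_hi + 1, "q", 1e-9),
            ],
            [gene],
        )
        assert m.p_values[0, 0] == 0.01

    def test_uncovered_gene_is_dropped(self):
        far = GeneAnnotation(gene_id="FAR", chrom="1", start=900_000, end=901_000)
        m = map_snps_to_genes([snp("rs1", 10_500, "q", 0.1)], [GENE, far])
        assert m.gene_ids == ["G"]

    def test_gene_covered_for_one_qt_gets_filler_for_the_other(self):
        m = map_snps_to_genes(
            [snp("rs1", 10_500, "qa", 0.1), snp("rs2", 500_000, "qb", 0.2)],
            [GENE, GeneAnnotation("G2", "1", 495_000, 505_000)],
        )
        df = m.to_frame()
        assert df.loc["G", "qa"] == 0.1
        assert df.loc["G", "qb"] == 1.0  # rectangular universe filler
        assert df.loc["G2", "qa"] == 1.0

    def test_chromosome_dialects_match(self):
        gene = GeneAnnotation(gene_id="G", chrom="chr1", start=10_000, end=11_000)
        m = map_snps_to_genes([snp("rs1", 10_500, "q", 0.05, chrom="1")], [gene])
        assert m.p_values[0, 0] == 0.05

    def test_no_covered_gene_raises(self):
        far = GeneAnnotation(gene_id="FAR", chrom="2", start=1, end=10)
        with pytest.raises(ValueError, match="no gene"):
            map_snps_to_genes([snp("rs1", 10_500, "q", 0.1)], [far])

    def test_matches_exhaustive_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        genes = [
            GeneAnnotation(f"G{i}", "1", int(s), int(s) + 5_000)
            for i, s in enumerate(rng.integers(1, 200_000, size=5))
        ]
        qts = ["qa", "qb", "qc"]
        snps = [
            snp(f"rs{i}", int(rng.integers(1, 250_000)), qts[i % 3], float(rng.uniform(1e-8, 1)))
            for i in range(50)
        ]
        w = 20_000
        expected = {}
        for g in genes:
            for q in qts:
                ps = [
                    s.p_value
                    for s in snps
                    if s.qt_id == q and max(1, g.start - w) <= s.pos <= g.end + w
                ]
                covered_any = any(
                    max(1, g.start - w) <= s.pos <= g.end + w for s in snps
                )
                if covered_any:
                    expected[(g.gene_id, q)] = min(ps) if ps else 1.0
        m = map_snps_to_genes(snps, genes, window_bp=w)
        got = {
            (g, q): m.p_values[i, j]
            for i, g in enumerate(m.gene_ids)
            for j, q in enumerate(m.qt_ids)
        }
        assert got == pytest.approx(expected)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=30_000), st.integers(min_value=0, max_value=30_000))
    def test_enlarging_window_never_increases_gene_pvalues(self, w1, w2):
        w_small, w_big = sorted((w1, w2))
        rng = np.random.default_rng(5)
        snps = [
            snp(f"rs{i}", int(p), "q", float(v))
            for i, (p, v) in enumerate(
                zip(rng.integers(1, 80_000, size=30), rng.uniform(1e-6, 1, size=30))
            )
        ]
        try:
            small = map_snps_to_genes(snps, [GENE], window_bp=w_small)
        except ValueError:
            return  # gene uncovered at the small window: nothing to compare
        big = map_snps_to_genes(snps, [GENE], window_bp=w_big)
        assert big.p_values[0, 0] <= small.p_values[0, 0]


class TestSignificantPairs:
    def test_strict_threshold_comparison(self, tiny_gene_qt):
        got = significant_pairs(tiny_gene_qt, threshold=1e-5)
        assert got.pairs == {("g1", "b1"), ("g2", "b2")}
        assert got.count == 2

    def test_threshold_one_takes_strictly_smaller_only(self, tiny_gene_qt):
        # all entries are < 1.0 here, so the whole universe passes
        assert significant_pairs(tiny_gene_qt, threshold=1.0).count == 4

    def test_all_ones_matrix_yields_empty_set(self):
        m = GeneQtMatrix(["g"], ["b"], np.array([[1.0]]))
        assert significant_pairs(m, 1e-5).pairs == set()

    def test_count_monotone_in_threshold(self, tiny_gene_qt):
        thresholds = [1e-8, 1e-6, 1e-4, 1e-2, 1.0]
        counts = [significant_pairs(tiny_gene_qt, t).count for t in thresholds]
        assert counts == sorted(counts)


def test_universe_size_is_product_of_axes():
    m = GeneQtMatrix(
        gene_ids=[f"g{i}" for i in range(7)],
        qt_ids=[f"b{j}" for j in range(3)],
        p_values=np.full((7, 3), 0.5),
    )
    assert m.universe_size == 21
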