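"""Module construction: preprocessing, clustering, scoring, selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from igea.io import RawExpressionTable
from igea.modules import (
    BrainCircuit,
    GeneSet,
    GsBcModule,
    combine_modules,
    cut_half_height,
    dissimilarity_matrix,
    filter_gene_clusters,
    fisher_z,
    gene_dissimilarity,
    make_brain_circuits,
    module_z_gene,
    module_z_roi,
    preprocess_expression,
    roi_dissimilarity,
    select_top_fraction,
    upgma_cluster,
)
from igea.simulate import simulate_expression, single_block_spec

ARCTANH_HALF = 0.5493061443340548


class TestPreprocess:
    def test_samples_merge_to_roi_by_mean(self):
        raw = RawExpressionTable(
            pd.DataFrame([[1.0, 3.0], [2.0, 6.0]], index=["g1", "g2"], columns=["s1", "s2"]),
            col_kind="sample",
        )
        merged = preprocess_expression(raw, sample_to_roi={"s1": "r", "s2": "r"})
        assert merged.roi_ids == ["r"]
        # one column only: z-scoring maps the means (2, 4) to (-1, +1)
        np.testing.assert_allclose(merged.values[:, 0], [-1.0, 1.0])

    def test_probes_merge_to_gene_by_mean(self):
        raw = RawExpressionTable(
            pd.DataFrame(
                [[2.0, 1.0], [4.0, 5.0], [0.0, 9.0]],
                index=["p1", "p2", "p3"],
                columns=["r1", "r2"],
            ),
            row_kind="probe",
        )
        merged = preprocess_expression(raw, probe_to_gene={"p1": "g", "p2": "g", "p3": "h"})
        assert merged.gene_ids == ["g", "h"]
        # before normalization: gene g = mean(p1, p2) = (3, 3); h = (0, 9)
        # column r1: values (3, 0) -> z-scores (+1, -1)
        np.testing.assert_allclose(merged.values[:, 0], [1.0, -1.0])

    def test_every_column_is_standardized(self):
        rng = np.random.default_rng(3)
        raw = RawExpressionTable(
            pd.DataFrame(
                rng.uniform(1, 100, size=(20, 6)),
                index=[f"g{i}" for i in range(20)],
                columns=[f"r{j}" for j in range(6)],
            )
        )
        expr = preprocess_expression(raw)
        np.testing.assert_allclose(expr.values.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(expr.values.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_zeroed_and_flagged(self):
        raw = RawExpressionTable(
            pd.DataFrame([[1.0, 5.0], [2.0, 5.0]], index=["g1", "g2"], columns=["r1", "r2"])
        )
        expr = preprocess_expression(raw)
        assert expr.constant_rois == ["r2"]
        np.testing.assert_array_equal(expr.values[:, 1], 0.0)


class TestDissimilarity:
    def test_identical_vectors_have_zero_dissimilarity(self):
        a = np.array([1.0, 2.0, 3.0])
        assert gene_dissimilarity(a, a) == pytest.approx(0.0)

    def test_anticorrelated_vectors_have_dissimilarity_one(self):
        assert gene_dissimilarity(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])) == pytest.approx(1.0)

    def test_hand_computed_pearson_case(self):
        # corr((1,2,3),(1,3,2)) = 0.5, so d = (1 - 0.5)/2 = 0.25
        a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0, 2.0])
        assert gene_dissimilarity(a, b) == pytest.approx(0.25)
        assert roi_dissimilarity(a, b) == pytest.approx(0.25)

    def test_zero_variance_vector_maps_to_half(self):
        assert gene_dissimilarity(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])) == 0.5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(np.float64, (2, 5), elements=st.floats(-100, 100, allow_nan=False)),
    )
    def test_bounds_and_symmetry(self, rows):
        d_ab = gene_dissimilarity(rows[0], rows[1])
        d_ba = gene_dissimilarity(rows[1], rows[0])
        assert 0.0 <= d_ab <= 1.0
        assert d_ab == pytest.approx(d_ba)

    def test_matrix_form_matches_scalar_form(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal((6, 8))
        d = dissimilarity_matrix(values, axis="gene")
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(gene_dissimilarity(values[i], values[j]), abs=1e-12)
        d_roi = dissimilarity_matrix(values, axis="roi")
        assert d_roi.shape == (8, 8)
        np.testing.assert_allclose(d_roi, dissimilarity_matrix(values.T, axis="gene"))


class TestUpgmaAndCut:
    def test_two_leaves_merge_at_their_distance(self):
        dend = upgma_cluster(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
        (merge,) = dend.merges
        assert merge[2] == pytest.approx(0.4)

    def test_three_leaf_hand_fixture(self):
        # d(A,B)=2, d(A,C)=d(B,C)=4: merge (A,B)@2 then ({A,B},C)@mean(4,4)=4
        dist = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dend = upgma_cluster(dist, ["A", "B", "C"])
        heights = [m[2] for m in dend.merges]
        assert heights == pytest.approx([2.0, 4.0])
        assert cut_half_height(dend) == [["A", "B"], ["C"]]

    def test_identical_points_all_merge_at_zero(self):
        dend = upgma_cluster(np.zeros((4, 4)), list("ABCD"))
        assert all(m[2] == 0.0 for m in dend.merges)
        assert cut_half_height(dend) == [["A", "B", "C", "D"]]

    def test_equidistant_points_cut_to_singletons(self):
        # every merge sits at height 1.0 > cutoff 0.5
        dist = np.ones((4, 4)) - np.eye(4)
        clusters = cut_half_height(upgma_cluster(dist, list("ABCD")))
        assert sorted(map(tuple, clusters)) == [("A",), ("B",), ("C",), ("D",)]

    def test_nan_distance_rejected(self):
        dist = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            upgma_cluster(dist, ["A", "B"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=2, max_value=12), st.integers(min_value=0, max_value=10_000))
    def test_heights_monotone_and_cut_is_a_partition(self, n, seed):
        rng = np.random.default_rng(seed)
        d = dissimilarity_matrix(rng.standard_normal((n, 6)), axis="gene")
        labels = [f"L{i}" for i in range(n)]
        dend = upgma_cluster(d, labels)
        heights = [m[2] for m in dend.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))
        clusters = cut_half_height(dend)
        flat = [leaf for c in clusters for leaf in c]
        assert sorted(flat) == sorted(labels)  # disjoint and covering


class TestClusterFiltering:
    def test_size_bounds_are_inclusive(self):
        clusters = [
            [f"g{i}" for i in range(n)] for n in (5, 10, 200, 201)
        ]
        kept = filter_gene_clusters(clusters)
        assert [gs.size for gs in kept] == [10, 200]

    def test_empty_input_gives_empty_output(self):
        assert filter_gene_clusters([]) == []

    def test_all_in_range_all_kept_with_stable_ids(self):
        clusters = [[f"g{i}_{j}" for j in range(12)] for i in range(3)]
        kept = filter_gene_clusters(clusters)
        assert [gs.gs_id for gs in kept] == ["GS01", "GS02", "GS03"]

    def test_circuits_require_at_least_a_pair(self):
        circuits = make_brain_circuits([["r1"], ["r2", "r3"]])
        assert [bc.roi_ids for bc in circuits] == [("r2", "r3")]


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_matches_arctanh(self):
        assert fisher_z(0.5) == pytest.approx(ARCTANH_HALF, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    def test_odd_function(self, c):
        assert fisher_z(-c) == pytest.approx(-fisher_z(c), abs=0.0)

    def test_perfect_correlation_is_clamped_finite(self):
        assert math.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-12))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0001)


def _module(values):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return GsBcModule(
        module_id="GS-BC",
        gene_set=GeneSet("GS", tuple(f"g{i}" for i in range(n))),
        circuit=BrainCircuit("BC", tuple(f"r{j}" for j in range(m))),
        submatrix=values,
    )


class TestModuleScores:
    def test_uncorrelated_gene_pair_scores_zero(self):
        mod = _module([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        assert module_z_gene(mod) == pytest.approx(0.0, abs=1e-12)

    def test_equicorrelated_triple_scores_arctanh_half(self):
        # rows u+v, u+w, v+w for orthonormal u, v, w: all pairwise corr = 0.5
        u = np.array([1.0, 1.0, -1.0, -1.0])
        v = np.array([1.0, -1.0, 1.0, -1.0])
        w = np.array([1.0, -1.0, -1.0, 1.0])
        mod = _module([u + v, u + w, v + w])
        assert module_z_gene(mod) == pytest.approx(ARCTANH_HALF, abs=1e-12)
        mod_cols = _module(np.array([u + v, u + w, v + w]).T)
        assert module_z_roi(mod_cols) == pytest.approx(ARCTANH_HALF, abs=1e-12)

    def test_identical_gene_rows_score_clamped_but_finite(self):
        mod = _module([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        z = module_z_gene(mod)
        assert math.isfinite(z)
        assert z == pytest.approx(np.arctanh(1 - 1e-12))

    def test_transposition_swaps_gene_and_roi_scores_exactly(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal((5, 7))
        assert module_z_gene(_module(x)) == module_z_roi(_module(x.T))
        assert module_z_roi(_module(x)) == module_z_gene(_module(x.T))

    def test_symmetric_square_module_has_equal_scores(self):
        rng = np.random.default_rng(22)
        a = rng.standard_normal((4, 4))
        x = a + a.T
        mod = _module(x)
        assert module_z_gene(mod) == pytest.approx(module_z_roi(mod))

    def test_single_gene_module_rejected(self):
        with pytest.raises(ValueError):
            module_z_gene(_module([[1.0, 2.0, 3.0]]))


class TestCombineAndSelect:
    def test_cartesian_product_counts(self, paper_scale_modules):
        assert len(paper_scale_modules) == 171 * 9 == 1539

    def test_small_products(self):
        rng = np.random.default_rng(1)
        gene_ids = [f"g{i}" for i in range(6)]
        roi_ids = [f"r{j}" for j in range(6)]
        from igea.modules import ExpressionMatrix

        expr = ExpressionMatrix(gene_ids, roi_ids, rng.standard_normal((6, 6)))
        gss = [GeneSet(f"GS{i}", tuple(gene_ids[i * 3 : i * 3 + 3])) for i in range(2)]
        bcs = [BrainCircuit(f"BC{j}", tuple(roi_ids[j * 2 : j * 2 + 2])) for j in range(3)]
        assert len(combine_modules(gss, bcs, expr)) == 6
        assert len(combine_modules(gss[:1], bcs[:1], expr)) == 1
        with pytest.raises(ValueError):
            combine_modules([], bcs, expr)

    def test_ceiling_selection_counts(self, paper_scale_modules):
        assert len(select_top_fraction(paper_scale_modules, 0.2, "gene_based")) == 308
        ten = paper_scale_modules[:10]
        assert len(select_top_fraction(ten, 0.2, "gene_based")) == 2
        nine = paper_scale_modules[:9]
        assert len(select_top_fraction(nine, 0.2, "gene_based")) == 2  # ceil(1.8)

    def test_selection_ranks_by_score(self, paper_scale_modules):
        selected = select_top_fraction(paper_scale_modules, 0.2, "gene_based")
        worst_selected = min(m.z_gene for m in selected)
        best_rejected = max(
            m.z_gene
            for m in paper_scale_modules
            if m.module_id not in {s.module_id for s in selected}
        )
        assert worst_selected >= best_rejected

    def test_boundary_ties_break_by_module_id(self):
        mods = [
            _module(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
            for _ in range(4)
        ]
        for i, m in enumerate(mods):
            m.module_id = f"M{i}"
            m.z_gene = 1.0  # all tied
        assert [m.module_id for m in select_top_fraction(mods, 0.5, "gene_based")] == ["M0", "M1"]

    def test_intersection_strategy_is_subset_of_both(self, paper_scale_modules):
        by_gene = {m.module_id for m in select_top_fraction(paper_scale_modules, 0.2, "gene_based")}
        by_roi = {m.module_id for m in select_top_fraction(paper_scale_modules, 0.2, "roi_based")}
        both = {m.module_id for m in select_top_fraction(paper_scale_modules, 0.2, "gene_and_roi")}
        assert both == by_gene & by_roi


def test_planted_block_attains_top_ranks():
    """A planted high-co-expression block out-scores all background modules."""
    from igea.modules import build_modules

    spec = single_block_spec(seed=0)
    expr, truth = simulate_expression(spec)
    built = build_modules(expr, min_bc=4)
    planted_genes = set(truth.coexpression_modules[0]["gene_ids"])
    planted_rois = set(truth.coexpression_modules[0]["roi_ids"])

    def is_planted(m):
        return (
            planted_genes <= set(m.gene_set.gene_ids)
            and planted_rois <= set(m.circuit.roi_ids)
        )

    best_gene = max(built["modules"], key=lambda m: m.z_gene)
    best_roi = max(built["modules"], key=lambda m: m.z_roi)
    assert is_planted(best_gene)
    assert is_planted(best_roi)
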