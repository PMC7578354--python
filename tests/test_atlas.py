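"""Tests for the atlas identity-mapping stage."""
import numpy as np
import pandas as pd
import pytest

from hsrpipe import (ExpressionMatrix, category_enrichment, correlate_all_pairs,
                     generate_queries, intersect_genes, score_map_matrix,
                     write_score_map)
from hsrpipe.errors import (InputError, InsufficientOverlapError,
                            UndefinedCorrelationError)


def _em(values, genes, samples, meta=None):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            meta)


class TestIntersectGenes:
    def test_identical_sets_pass_through(self, tiny_matrix):
        q, a = intersect_genes(tiny_matrix, tiny_matrix, min_genes=5)
        assert q.gene_ids == a.gene_ids == sorted(tiny_matrix.gene_ids)

    def test_partial_overlap(self):
        q = _em([[1, 2]] * 3, ["A", "B", "C"], ["s1", "s2"])
        a = _em([[3, 4]] * 3, ["B", "C", "D"], ["t1", "t2"])
        qi, ai = intersect_genes(q, a, min_genes=2)
        assert qi.gene_ids == ai.gene_ids == ["B", "C"]

    def test_disjoint_sets_error(self):
        q = _em([[1, 2]], ["A"], ["s1", "s2"])
        a = _em([[3, 4]], ["B"], ["t1", "t2"])
        with pytest.raises(InsufficientOverlapError):
            intersect_genes(q, a, min_genes=1)


class TestCorrelateAllPairs:
    def test_self_correlation_is_one(self, small_atlas):
        atlas, _ = small_atlas
        first = ExpressionMatrix(atlas.values.iloc[:, [0]])
        corr = correlate_all_pairs(first, atlas)
        self_row = corr.loc[corr["atlas_sample_id"] == first.sample_ids[0]]
        assert self_row["rho"].iloc[0] == pytest.approx(1.0)
        assert (corr["rho"] <= 1).all() and (corr["rho"] >= -1).all()

    def test_row_count_and_columns(self, small_atlas):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("neocortex", "pcw16"), 3, seed=1)
        corr = correlate_all_pairs(*intersect_genes(q, atlas, min_genes=10))
        assert len(corr) == 3 * atlas.n_samples
        assert set(corr["n_genes_used"]) == {atlas.n_genes}

    def test_monotone_transform_invariance(self, small_atlas):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("subcortex", "pcw12"), 2, seed=2)
        base = correlate_all_pairs(q, atlas)
        cubed = ExpressionMatrix(q.values ** 3)
        np.testing.assert_allclose(
            base["rho"], correlate_all_pairs(cubed, atlas)["rho"],
            atol=1e-12)

    def test_flat_profile_rejected(self, small_atlas):
        atlas, _ = small_atlas
        flat = ExpressionMatrix(pd.DataFrame(
            1.0, index=atlas.gene_ids, columns=["flat"]))
        with pytest.raises(UndefinedCorrelationError, match="flat"):
            correlate_all_pairs(flat, atlas)


class TestCategoryEnrichment:
    def test_recovers_true_category(self, small_atlas):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("neocortex", "pcw16"), 2, seed=3)
        corr = correlate_all_pairs(q, atlas)
        scores = category_enrichment(corr, atlas.sample_meta)
        for _, per_query in scores.groupby("query_id"):
            best = per_query.loc[per_query["neglog10_p"].idxmax()]
            assert best["category"] == "neocortex:pcw16"
            assert bool(best["direction_confirmed"])

    def test_map_is_complete_per_query(self, small_atlas):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("neocortex", "pcw12"), 2, seed=4)
        scores = category_enrichment(correlate_all_pairs(q, atlas),
                                     atlas.sample_meta)
        n_categories = atlas.sample_meta[["region", "stage"]].drop_duplicates()
        for _, per_query in scores.groupby("query_id"):
            assert len(per_query) == len(n_categories)
            assert per_query["category"].is_unique

    def test_identical_rho_degenerates_to_p_one(self, small_atlas):
        atlas, _ = small_atlas
        corr = pd.DataFrame({
            "query_id": "q", "atlas_sample_id": atlas.sample_ids,
            "rho": 0.5, "n_genes_used": atlas.n_genes})
        scores = category_enrichment(corr, atlas.sample_meta)
        assert (scores["p_value"] == 1.0).all()
        assert (scores["neglog10_p"] == 0.0).all()

    def test_neglog_transform_convention(self, small_atlas):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("neocortex", "pcw16"), 1, seed=5)
        scores = category_enrichment(correlate_all_pairs(q, atlas),
                                     atlas.sample_meta)
        np.testing.assert_allclose(scores["neglog10_p"],
                                   -np.log10(scores["p_value"]))
        # the significance threshold p=0.05 prints as 1.30 on this scale
        assert round(-np.log10(0.05), 2) == 1.30

    def test_region_granularity(self, small_atlas):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("subcortex", "pcw16"), 1, seed=6)
        scores = category_enrichment(correlate_all_pairs(q, atlas),
                                     atlas.sample_meta, granularity="region")
        assert sorted(scores["category"]) == ["neocortex", "subcortex"]
        assert scores.loc[scores["neglog10_p"].idxmax(),
                          "category"] == "subcortex"

    def test_background_modes_agree_for_small_categories(self, small_atlas):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("neocortex", "pcw16"), 1, seed=7)
        corr = correlate_all_pairs(q, atlas)
        inc = category_enrichment(corr, atlas.sample_meta)
        exc = category_enrichment(corr, atlas.sample_meta,
                                  background="exclusive")
        # same ordering of cells and nearly identical evidence
        assert (inc.loc[inc["neglog10_p"].idxmax(), "category"]
                == exc.loc[exc["neglog10_p"].idxmax(), "category"])
        r = np.corrcoef(inc["neglog10_p"], exc["neglog10_p"])[0, 1]
        assert r > 0.99


class TestScoreMap:
    def test_matrix_shape_and_order(self, small_atlas, tmp_path):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("neocortex", "pcw16"), 4, seed=8)
        scores = category_enrichment(correlate_all_pairs(q, atlas),
                                     atlas.sample_meta)
        mat = write_score_map(scores, tmp_path / "map.tsv")
        assert mat.shape == (4, 4)  # 2 regions x 2 stages, 4 queries
        assert list(mat.index) == ["neocortex:pcw12", "neocortex:pcw16",
                                   "subcortex:pcw12", "subcortex:pcw16"]

    def test_round_trip_preserves_values(self, small_atlas, tmp_path):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("subcortex", "pcw12"), 2, seed=9)
        scores = category_enrichment(correlate_all_pairs(q, atlas),
                                     atlas.sample_meta)
        path = tmp_path / "map.tsv"
        mat = write_score_map(scores, path)
        back = pd.read_csv(path, sep="\t", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), mat.to_numpy(),
                                   rtol=1e-11)  # 12 significant digits

    def test_masking_blanks_non_significant_cells(self, small_atlas, tmp_path):
        atlas, truth = small_atlas
        q = generate_queries(truth, ("neocortex", "pcw16"), 1, seed=10)
        scores = category_enrichment(correlate_all_pairs(q, atlas),
                                     atlas.sample_meta)
        mat = write_score_map(scores, tmp_path / "m.tsv", mask_alpha=0.05)
        masked = score_map_matrix(scores, mask_alpha=0.05)
        by_cat = scores.set_index("category")
        for cat in masked.index:
            cell = masked.loc[cat].iloc[0]
            if by_cat.loc[cat, "p_value"] >= 0.05:
                assert np.isnan(cell)
            else:
                assert not np.isnan(cell)
        assert mat.isna().to_numpy().sum() == masked.isna().to_numpy().sum()

    def test_missing_meta_raises(self, small_atlas):
        atlas, truth = small_atlas
        corr = pd.DataFrame({"query_id": "q", "atlas_sample_id": ["nope"],
                             "rho": [0.5], "n_genes_used": 10})
        with pytest.raises(InputError):
            category_enrichment(corr, atlas.sample_meta)
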