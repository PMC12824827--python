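import numpy as np
import pandas as pd
import pytest

from betashift.diversity import gower_block_dissimilarity
from betashift.panels import TraitBlock, TraitDatabase
from betashift.traits import (
    community_weighted_means,
    compute_block_weights,
    impute_traits,
    normalize_trait_blocks,
    trait_coverage_report,
)


class TestNormalization:
    def test_row_sum_division(self, tiny_trait_db):
        norm = normalize_trait_blocks(tiny_trait_db)
        np.testing.assert_allclose(
            norm.values.loc["sp_a", ["sapro::m0", "sapro::m1", "sapro::m2"]],
            [0.3, 0.3, 0.4],
        )

    def test_single_assignment_already_proportion(self, tiny_trait_db):
        norm = normalize_trait_blocks(tiny_trait_db)
        np.testing.assert_allclose(
            norm.values.loc["sp_a", ["feed::m0", "feed::m1"]], [1.0, 0.0]
        )

    def test_all_zero_row_flagged_missing(self):
        blocks = [TraitBlock("b", ["m0", "m1"], "fuzzy", "biological")]
        values = pd.DataFrame(
            {"b::m0": [0.0, 1.0], "b::m1": [0.0, 1.0]}, index=["t1", "t2"]
        )
        hier = pd.DataFrame(
            {"genus": ["", ""], "family": ["", ""], "order": ["", ""]},
            index=["t1", "t2"],
        )
        norm = normalize_trait_blocks(TraitDatabase(blocks, values, hier))
        assert norm.values.loc["t1"].isna().all()
        assert norm.provenance.at["t1", "b"] == "missing"

    def test_negative_value_is_hard_error(self, tiny_trait_db):
        tiny_trait_db.values.at["sp_a", "feed::m0"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            normalize_trait_blocks(tiny_trait_db)

    def test_resolved_rows_sum_to_one(self, small_dataset):
        norm = normalize_trait_blocks(small_dataset["traits"])
        for b in norm.blocks:
            cols = norm.block_columns(b.name)
            sums = norm.values[cols].dropna().sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestImputation:
    def test_parent_rank_copy(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        # sp_miss has no data; genus gA has its own feed entry (2, 8)
        np.testing.assert_allclose(
            norm.values.loc["sp_miss", ["feed::m0", "feed::m1"]], [0.2, 0.8]
        )
        assert norm.provenance.at["sp_miss", "feed"] == "parent_rank"

    def test_group_mean_of_congeners(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        # gA has no sapro entry, so sp_miss averages congeners sp_a, sp_b
        expected = np.mean([[0.3, 0.3, 0.4], [0.2, 0.2, 0.6]], axis=0)
        np.testing.assert_allclose(
            norm.values.loc["sp_miss", ["sapro::m0", "sapro::m1", "sapro::m2"]],
            expected,
        )
        assert norm.provenance.at["sp_miss", "sapro"] == "group_mean"

    def test_unresolvable_taxon_dropped(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        assert norm.provenance.at["sp_lost", "feed"] == "dropped"
        assert norm.values.loc["sp_lost"].isna().all()
        report = trait_coverage_report(norm)
        assert (report["dropped"] > 0).any()

    def test_idempotent(self, small_dataset):
        norm1 = impute_traits(normalize_trait_blocks(small_dataset["traits"]))
        norm2 = impute_traits(norm1)
        pd.testing.assert_frame_equal(norm1.values, norm2.values)
        pd.testing.assert_frame_equal(norm1.provenance, norm2.provenance)

    def test_cyclic_hierarchy_rejected(self):
        blocks = [TraitBlock("b", ["m0", "m1"], "fuzzy", "biological")]
        values = pd.DataFrame(
            {"b::m0": [1.0, np.nan], "b::m1": [1.0, np.nan]}, index=["gA", "gB"]
        )
        hier = pd.DataFrame(
            {"genus": ["gB", "gA"], "family": ["", ""], "order": ["", ""]},
            index=["gA", "gB"],
        )
        with pytest.raises(ValueError, match="cyclic"):
            impute_traits(normalize_trait_blocks(TraitDatabase(blocks, values, hier)))


class TestBlockWeights:
    def _db(self, values: dict, blocks):
        idx = list(next(iter(values.values())).keys()) if values else []
        frame = pd.DataFrame(values)
        hier = pd.DataFrame(
            {"genus": "", "family": "", "order": ""}, index=frame.index
        )
        return TraitDatabase(blocks, frame, hier)

    def test_identical_blocks_get_equal_weights(self):
        blocks = [
            TraitBlock("b1", ["m0", "m1"], "fuzzy", "biological"),
            TraitBlock("b2", ["m0", "m1"], "fuzzy", "biological"),
        ]
        values = pd.DataFrame(
            {
                "b1::m0": [1.0, 0.0, 0.5],
                "b1::m1": [0.0, 1.0, 0.5],
                "b2::m0": [1.0, 0.0, 0.5],
                "b2::m1": [0.0, 1.0, 0.5],
            },
            index=["t1", "t2", "t3"],
        )
        db = self._db(values.to_dict(), blocks)
        norm = normalize_trait_blocks(db)
        w = compute_block_weights(norm)
        assert w["b1"] == pytest.approx(0.5) and w["b2"] == pytest.approx(0.5)

    def test_constant_block_gets_mean_weight_with_warning(self):
        blocks = [
            TraitBlock("var", ["m0", "m1"], "fuzzy", "biological"),
            TraitBlock("flat", ["m0", "m1"], "fuzzy", "biological"),
        ]
        values = pd.DataFrame(
            {
                "var::m0": [1.0, 0.0],
                "var::m1": [0.0, 1.0],
                "flat::m0": [0.5, 0.5],
                "flat::m1": [0.5, 0.5],
            },
            index=["t1", "t2"],
        )
        db = self._db(values.to_dict(), blocks)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            w = compute_block_weights(normalize_trait_blocks(db))
        assert w["flat"] == pytest.approx(w["var"])

    def test_balancing_equalizes_mean_contributions(self, small_dataset):
        norm = impute_traits(normalize_trait_blocks(small_dataset["traits"]))
        w = compute_block_weights(norm)
        contribs = []
        for b in norm.blocks:
            D = gower_block_dissimilarity(
                norm.values[norm.block_columns(b.name)].to_numpy()
            )
            iu = np.triu_indices(D.shape[0], 1)
            c = np.nanmean(D[iu])
            contribs.append(w[b.name] * c)
        contribs = np.array(contribs)
        assert contribs.max() / contribs.min() - 1 < 0.01


class TestCWM:
    def test_single_taxon_identity(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        A = pd.DataFrame({"sp_a": [4.0]}, index=["s1"])
        cwm = community_weighted_means(A, norm, block_names=["feed"], apply_weights=False)
        np.testing.assert_allclose(cwm.loc["s1"], norm.values.loc["sp_a", ["feed::m0", "feed::m1"]])

    def test_weighted_mean_hand_computed(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        A = pd.DataFrame({"sp_a": [3.0], "sp_b": [1.0]}, index=["s1"])
        cwm = community_weighted_means(A, norm, block_names=["feed"], apply_weights=False)
        np.testing.assert_allclose(cwm.loc["s1"], [0.75, 0.25])

    def test_equal_abundance_midpoint(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        A = pd.DataFrame({"sp_a": [2.0], "sp_b": [2.0]}, index=["s1"])
        cwm = community_weighted_means(A, norm, block_names=["feed"], apply_weights=False)
        np.testing.assert_allclose(cwm.loc["s1"], [0.5, 0.5])

    def test_invariant_to_abundance_rescaling(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        A = pd.DataFrame({"sp_a": [3.0, 1.0], "sp_b": [1.0, 2.0]}, index=["s1", "s2"])
        c1 = community_weighted_means(A, norm, apply_weights=False)
        c2 = community_weighted_means(A * 7.5, norm, apply_weights=False)
        pd.testing.assert_frame_equal(c1, c2)

    def test_zero_abundance_taxon_is_irrelevant(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        A1 = pd.DataFrame({"sp_a": [3.0], "sp_b": [1.0]}, index=["s1"])
        A2 = pd.DataFrame({"sp_a": [3.0], "sp_b": [1.0], "sp_c": [0.0]}, index=["s1"])
        c1 = community_weighted_means(A1, norm, apply_weights=False)
        c2 = community_weighted_means(A2, norm, apply_weights=False)
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy())

    def test_block_rows_sum_to_one_before_weighting(self, small_dataset):
        from betashift.traits import compute_block_weights

        norm = impute_traits(normalize_trait_blocks(small_dataset["traits"]))
        norm.weights = compute_block_weights(norm)
        panel = next(iter(small_dataset["panels"].values()))
        A = panel.year_matrix(panel.years[0])
        known = [t for t in A.columns if t in norm.values.index]
        cwm = community_weighted_means(A[known], norm, apply_weights=False)
        for b in norm.blocks:
            cols = norm.block_columns(b.name)
            np.testing.assert_allclose(cwm[cols].sum(axis=1), 1.0, atol=1e-9)

    def test_zero_total_abundance_errors(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        A = pd.DataFrame({"sp_a": [0.0]}, index=["s1"])
        with pytest.raises(ValueError, match="zero total"):
            community_weighted_means(A, norm)

    def test_strict_mode_rejects_unresolved_taxa(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        A = pd.DataFrame({"sp_a": [1.0], "sp_lost": [1.0]}, index=["s1"])
        with pytest.raises(ValueError, match="unresolved"):
            community_weighted_means(A, norm, strict=True)
        # default renormalizes over resolved taxa instead
        cwm = community_weighted_means(A, norm, block_names=["feed"], apply_weights=False)
        np.testing.assert_allclose(cwm.loc["s1"], [1.0, 0.0])


class TestCoverageReport:
    def test_complete_db_fully_provided(self, small_dataset):
        from betashift.simulate import _taxon_pool, default_trait_blocks, generate_trait_database

        db = generate_trait_database(
            _taxon_pool(30), default_trait_blocks()[:3], {}, seed=0
        )
        norm = impute_traits(normalize_trait_blocks(db))
        report = trait_coverage_report(norm)
        np.testing.assert_allclose(report["provided"], 1.0)

    def test_counts_match_known_fill_pattern(self, tiny_trait_db):
        norm = impute_traits(normalize_trait_blocks(tiny_trait_db))
        report = trait_coverage_report(norm).set_index("block")
        n = len(norm.values.index)  # 6 taxa
        # feed: sp_a, sp_b, sp_c, gA provided; sp_miss parent_rank; sp_lost dropped
        assert report.at["feed", "provided"] == pytest.approx(4 / n)
        assert report.at["feed", "parent_rank"] == pytest.approx(1 / n)
        assert report.at["feed", "dropped"] == pytest.approx(1 / n)
        # sapro: gA missing too -> sp_miss group_mean, gA group_mean of sp_a+sp_b
        assert report.at["sapro", "provided"] == pytest.approx(3 / n)
        assert report.at["sapro", "group_mean"] == pytest.approx(2 / n)
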