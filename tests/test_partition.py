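import numpy as np
import pandas as pd
import pytest

from betashift.diversity import multisite_bray
from betashift.partition import (
    partition_delta_beta,
    partition_series,
    per_column_contributions,
    split_changes,
    summarize_contributions,
)

BETA = lambda X: multisite_bray(X)[0]


def random_pair(rng, n_sites=4, n_feat=6):
    X1 = rng.integers(0, 8, size=(n_sites, n_feat)).astype(float)
    X2 = rng.integers(0, 8, size=(n_sites, n_feat)).astype(float)
    X1[:, 0] += 1.0  # keep all rows (and intermediates) non-empty
    X2[:, 0] = X1[:, 0]
    return X1, X2


class TestSplitChanges:
    def test_equal_matrices_give_zero_deltas(self):
        X = np.arange(6.0).reshape(2, 3)
        loss, gain = split_changes(X, X)
        assert not loss.any() and not gain.any()

    def test_pure_gain(self):
        X1 = np.ones((2, 2))
        E = np.array([[0.5, 0.0], [1.0, 2.0]])
        loss, gain = split_changes(X1, X1 + E)
        assert not loss.any()
        np.testing.assert_array_equal(gain, E)

    def test_mixed_change_elementwise(self):
        X1 = np.array([[2.0, 0.0], [1.0, 3.0]])
        X2 = np.array([[0.0, 1.0], [2.0, 3.0]])
        loss, gain = split_changes(X1, X2)
        np.testing.assert_array_equal(loss, [[2.0, 0.0], [0.0, 0.0]])
        np.testing.assert_array_equal(gain, [[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(X1 - loss + gain, X2)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            split_changes(np.ones((2, 2)), np.ones((2, 3)))

    def test_label_mismatch_errors(self):
        a = pd.DataFrame(np.ones((2, 2)), columns=["x", "y"])
        b = pd.DataFrame(np.ones((2, 2)), columns=["x", "z"])
        with pytest.raises(ValueError, match="labels"):
            split_changes(a, b)


class TestPartitionDeltaBeta:
    def test_no_change_gives_zero_components(self):
        X = np.array([[2.0, 1.0], [1.0, 3.0]])
        assert partition_delta_beta(X, X) == (0.0, 0.0, 0.0)

    def test_gains_only_have_no_subtractive_part(self):
        rng = np.random.default_rng(0)
        X1 = rng.integers(1, 6, size=(3, 5)).astype(float)
        X2 = X1 + rng.integers(0, 4, size=(3, 5))
        for scheme in ("loss_first", "gain_first", "symmetrized"):
            total, add, sub = partition_delta_beta(X1, X2, scheme=scheme)
            assert sub == 0.0
            assert add == pytest.approx(total, abs=1e-12)

    def test_symmetrized_is_mean_of_the_two_orders(self):
        X1 = np.array([[4.0, 0.0, 2.0, 1.0], [1.0, 3.0, 0.0, 2.0], [2.0, 2.0, 2.0, 0.0]])
        X2 = np.array([[2.0, 1.0, 3.0, 1.0], [2.0, 1.0, 1.0, 2.0], [1.0, 4.0, 2.0, 1.0]])
        _, add_l, sub_l = partition_delta_beta(X1, X2, scheme="loss_first")
        _, add_g, sub_g = partition_delta_beta(X1, X2, scheme="gain_first")
        total, add_s, sub_s = partition_delta_beta(X1, X2, scheme="symmetrized")
        assert add_s == pytest.approx(0.5 * (add_l + add_g), abs=1e-15)
        assert sub_s == pytest.approx(0.5 * (sub_l + sub_g), abs=1e-15)
        assert add_s + sub_s == pytest.approx(total, abs=1e-12)

    def test_exact_additivity_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            X1, X2 = random_pair(rng)
            expected = BETA(X2) - BETA(X1)
            for scheme in ("loss_first", "gain_first", "symmetrized"):
                total, add, sub = partition_delta_beta(X1, X2, scheme=scheme)
                assert add + sub == pytest.approx(expected, abs=1e-9)

    def test_antisymmetry_of_symmetrized_scheme(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            X1, X2 = random_pair(rng)
            _, add, sub = partition_delta_beta(X1, X2, scheme="symmetrized")
            _, add_r, sub_r = partition_delta_beta(X2, X1, scheme="symmetrized")
            assert add_r == pytest.approx(-sub, abs=1e-12)
            assert sub_r == pytest.approx(-add, abs=1e-12)

    def test_site_extirpation_raises_unless_floored(self):
        X1 = np.array([[2.0, 0.0], [1.0, 3.0]])
        X2 = np.array([[0.0, 1.0], [1.0, 3.0]])  # site 0 loses everything first
        with pytest.raises(ValueError, match="site_extirpated"):
            partition_delta_beta(X1, X2, scheme="loss_first")
        total, add, sub = partition_delta_beta(X1, X2, scheme="loss_first", floor=1e-6)
        assert add + sub == pytest.approx(total, abs=1e-9)


class TestPerColumnContributions:
    def test_single_changed_column_carries_everything(self):
        X1 = np.array([[3.0, 1.0, 2.0], [1.0, 1.0, 4.0]])
        X2 = X1.copy()
        X2[:, 1] = [4.0, 0.5]
        res = per_column_contributions(X1, X2)
        total, add, sub = partition_delta_beta(X1, X2)
        assert res.per_column[1]["additive"] == pytest.approx(add, abs=1e-12)
        assert res.per_column[1]["subtractive"] == pytest.approx(sub, abs=1e-12)
        for j in (0, 2):
            assert res.per_column[j] == {"additive": 0.0, "subtractive": 0.0}

    def test_identical_twin_columns_share_equally(self):
        X1 = np.array([[3.0, 2.0, 2.0], [1.0, 1.0, 1.0]])
        X2 = np.array([[3.0, 4.0, 4.0], [1.0, 0.5, 0.5]])
        res = per_column_contributions(X1, X2)
        assert res.per_column[1]["additive"] == pytest.approx(
            res.per_column[2]["additive"], abs=1e-12
        )
        assert res.per_column[1]["subtractive"] == pytest.approx(
            res.per_column[2]["subtractive"], abs=1e-12
        )

    def test_sums_match_components_exactly_under_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X1, X2 = random_pair(rng, 3, 5)
            res = per_column_contributions(X1, X2)
            assert res.method_meta["attribution"].startswith("exact") or res.method_meta[
                "n_players"
            ] == 0
            add_sum = sum(v["additive"] for v in res.per_column.values())
            sub_sum = sum(v["subtractive"] for v in res.per_column.values())
            assert add_sum == pytest.approx(res.delta_additive, abs=1e-12)
            assert sub_sum == pytest.approx(res.delta_subtractive, abs=1e-12)

    def test_monte_carlo_close_to_enumeration(self):
        rng = np.random.default_rng(4)
        X1 = rng.integers(1, 8, size=(4, 5)).astype(float)
        X2 = X1.copy()
        # exactly 5 changed players: 3 gains, 2 losses on distinct columns
        X2[:, 0] += 3.0
        X2[:, 1] += 2.0
        X2[:, 2] += 4.0
        X2[0, 3] -= 1.0
        X2[1, 4] -= 2.0
        exact = per_column_contributions(X1, X2)
        mc = per_column_contributions(X1, X2, max_exact_players=0, n_perm=2000, seed=9)
        scale = max(abs(exact.delta_total), 1e-3)
        for j in range(5):
            for d in ("additive", "subtractive"):
                assert abs(mc.per_column[j][d] - exact.per_column[j][d]) <= 0.02 * max(
                    scale, abs(exact.per_column[j][d])
                )

    def test_monte_carlo_is_seed_reproducible(self):
        rng = np.random.default_rng(5)
        X1, X2 = random_pair(rng, 4, 14)
        a = per_column_contributions(X1, X2, max_exact_players=0, n_perm=100, seed=3)
        b = per_column_contributions(X1, X2, max_exact_players=0, n_perm=100, seed=3)
        assert a.per_column == b.per_column


class TestSummaries:
    def _results(self, values_by_basin):
        from betashift.partition import PartitionResult

        out = []
        for basin, vals in values_by_basin.items():
            for v in vals:
                out.append(
                    PartitionResult(
                        basin,
                        (2000, 2001),
                        "taxonomic",
                        v,
                        v,
                        0.0,
                        {"colA": {"additive": v, "subtractive": 0.0}},
                        {},
                    )
                )
        return out

    def test_zero_contributions_not_significant(self):
        res = summarize_contributions(
            self._results({"b1": [0.0] * 4, "b2": [0.0] * 4, "b3": [0.0] * 4})
        )
        row = res[(res["column"] == "colA") & (res["direction"] == "additive")].iloc[0]
        assert row["estimate"] == pytest.approx(0.0)
        assert not row["significant"]

    def test_constant_contribution_recovers_intercept(self):
        res = summarize_contributions(
            self._results({"b1": [0.25] * 4, "b2": [0.25] * 4, "b3": [0.25] * 4})
        )
        row = res[(res["column"] == "colA") & (res["direction"] == "additive")].iloc[0]
        assert row["estimate"] == pytest.approx(0.25, abs=1e-9)

    def test_intercept_recovered_from_noisy_basin_effects(self):
        rng = np.random.default_rng(6)
        truth = 0.05
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            data = {}
            for b in range(8):
                eff = rng.normal(0, 0.02)
                data[f"b{b}"] = list(truth + eff + rng.normal(0, 0.02, size=5))
            res = summarize_contributions(self._results(data))
            row = res[
                (res["column"] == "colA") & (res["direction"] == "additive")
            ].iloc[0]
            hits += row["ci_low"] <= truth <= row["ci_high"]
        assert hits / n_rep >= 0.9

    def test_partition_series_on_panels(self, small_dataset):
        results = partition_series(small_dataset["panels"], pairs="endpoints")
        assert len(results) == len(small_dataset["panels"])
        for r in results:
            assert r.delta_additive + r.delta_subtractive == pytest.approx(
                r.delta_total, abs=1e-9
            )
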