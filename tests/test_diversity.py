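import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from betashift.diversity import (
    FRicResult,
    beta_series,
    functional_richness,
    multisite_bray,
    pairwise_bray,
    pcoa_coordinates,
    taxon_richness,
    weighted_gower,
)
from betashift.panels import TraitBlock


def oracle_multisite_bray(X):
    """Independent transcription of the multiple-site Bray-Curtis component
    formulas: plain loops over site pairs, no shared code with the
    implementation."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    A = 0.0
    min_b = 0.0
    max_b = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            shared = 0.0
            b_ij = 0.0
            b_ji = 0.0
            for k in range(X.shape[1]):
                shared += min(X[i, k], X[j, k])
                if X[i, k] > X[j, k]:
                    b_ij += X[i, k] - X[j, k]
                else:
                    b_ji += X[j, k] - X[i, k]
            A += shared
            min_b += min(b_ij, b_ji)
            max_b += max(b_ij, b_ji)
    total = (min_b + max_b) / (2 * A + min_b + max_b)
    bal = min_b / (min_b + A)
    gra = (A / (min_b + A)) * ((max_b - min_b) / (2 * A + min_b + max_b))
    return total, bal, gra


def random_matrix(rng, n_sites=5, n_feat=8):
    X = rng.integers(0, 10, size=(n_sites, n_feat)).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1.0
    return X


class TestMultisiteBray:
    def test_identical_rows_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        assert multisite_bray(X) == (0.0, 0.0, 0.0)

    def test_disjoint_two_sites_is_pure_balanced(self):
        total, bal, grad = multisite_bray([[1.0, 2.0, 0.0, 0.0], [0.0, 0.0, 3.0, 1.0]])
        assert total == pytest.approx(1.0)
        assert bal == pytest.approx(1.0)
        assert grad == pytest.approx(0.0)

    def test_worked_pairwise_case(self):
        total, bal, grad = multisite_bray([[3.0, 0.0], [1.0, 2.0]])
        assert total == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            X = random_matrix(rng, int(rng.integers(2, 8)), int(rng.integers(2, 12)))
            got = multisite_bray(X)
            want = oracle_multisite_bray(X)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_two_site_reduction_equals_pairwise(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            X = random_matrix(rng, 2, int(rng.integers(2, 15)))
            total = multisite_bray(X)[0]
            assert total == pytest.approx(pairwise_bray(X[0], X[1]), abs=1e-12)

    @given(
        X=hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=7),
            elements=hst.floats(0, 50, allow_subnormal=False),
        ),
        c=hst.floats(0.01, 100),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_scale_and_permutation_invariance_and_additivity(self, X, c):
        X = X + 0.5  # keep every site row clearly occupied
        total, bal, grad = multisite_bray(X)
        assert 0.0 <= total <= 1.0
        assert bal + grad == pytest.approx(total, abs=1e-9)
        np.testing.assert_allclose(multisite_bray(c * X), (total, bal, grad), atol=1e-9)
        rng = np.random.default_rng(0)
        P = X[rng.permutation(X.shape[0])][:, rng.permutation(X.shape[1])]
        np.testing.assert_allclose(multisite_bray(P), (total, bal, grad), atol=1e-9)

    def test_duplicated_sites_change_beta_only_via_pair_counts(self):
        # duplicating every row creates four cross pairs repeating the
        # original pair structure plus two identical pairs that contribute
        # only shared abundance (their exclusive sums vanish); the value
        # follows exactly from the component formula on those six pairs
        X = np.array([[3.0, 0.0, 1.0], [1.0, 2.0, 0.0]])
        X4 = np.vstack([X, X])
        a = np.minimum(X[0], X[1]).sum()
        b = np.maximum(X[0] - X[1], 0).sum()
        c = np.maximum(X[1] - X[0], 0).sum()
        A = 4 * a + X[0].sum() + X[1].sum()
        mn, mx = 4 * min(b, c), 4 * max(b, c)
        expect = (mn + mx) / (2 * A + mn + mx)
        assert multisite_bray(X4)[0] == pytest.approx(expect, abs=1e-12)

    def test_zero_row_is_error(self):
        with pytest.raises(ValueError, match="empty_community"):
            multisite_bray([[1.0, 2.0], [0.0, 0.0]])


class TestBetaSeries:
    def test_constant_panels_give_constant_series(self, toy_panel):
        panels = {"b1": toy_panel}
        toy_panel.abundance[1] = toy_panel.abundance[0]
        toy_panel.abundance[2] = toy_panel.abundance[0]
        out = beta_series(panels)
        assert out["beta_total"].nunique() == 1

    def test_one_record_per_basin_year(self, small_dataset):
        out = beta_series(small_dataset["panels"])
        panel = next(iter(small_dataset["panels"].values()))
        assert len(out) == len(small_dataset["panels"]) * panel.n_years
        assert ((out["beta_total"] >= 0) & (out["beta_total"] <= 1)).all()
        np.testing.assert_allclose(
            out["beta_balanced"] + out["beta_gradient"], out["beta_total"], atol=1e-9
        )

    def test_relative_mode_rescales_rows(self, toy_panel):
        out_raw = beta_series({"b1": toy_panel}, relative=False)
        out_rel = beta_series({"b1": toy_panel}, relative=True)
        assert not np.allclose(out_raw["beta_total"], out_rel["beta_total"])


class TestRichness:
    def test_counts_positive_taxa(self, toy_panel):
        out = taxon_richness({"b1": toy_panel})
        first = out[(out["site"] == "s1") & (out["year"] == 2000)]
        assert first["taxon_richness"].item() == 2

    def test_invariant_to_rescaling(self, toy_panel):
        before = taxon_richness({"b1": toy_panel})["taxon_richness"]
        toy_panel.abundance *= 13.7
        after = taxon_richness({"b1": toy_panel})["taxon_richness"]
        assert (before == after).all()


def _one_block(n_mod=4):
    return [TraitBlock("b", [f"m{j}" for j in range(n_mod)], "fuzzy", "biological")]


class TestFunctionalRichness:
    def test_identical_traits_zero_volume(self):
        blocks = _one_block(3)
        vals = pd.DataFrame(
            np.tile([0.2, 0.3, 0.5], (5, 1)),
            columns=["b::m0", "b::m1", "b::m2"],
            index=[f"t{i}" for i in range(5)],
        )
        res = functional_richness(np.ones(5), vals, blocks, {"b": 1.0}, n_axes=2)
        assert res.value == 0.0 or res.degenerate

    def test_square_corners_have_unit_area(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        from scipy.spatial import ConvexHull

        assert ConvexHull(coords).volume == pytest.approx(1.0)
        # and the same square recovered through the PCoA pathway scales to
        # the alternative hull computation below
        rng = np.random.default_rng(3)
        vals = rng.dirichlet(np.ones(4), size=10)
        df = pd.DataFrame(vals, columns=[f"b::m{j}" for j in range(4)],
                          index=[f"t{i}" for i in range(10)])
        blocks = _one_block(4)
        D = weighted_gower(df, blocks, {"b": 1.0})
        pts = pcoa_coordinates(D, 2)[:, :2]
        res = functional_richness(np.ones(10), df, blocks, {"b": 1.0}, n_axes=2)
        # oracle: monotone-chain hull + shoelace area, no scipy involved
        def cross(o, a, b):
            return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

        P = sorted(map(tuple, pts))
        lower, upper = [], []
        for p in P:
            while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
                lower.pop()
            lower.append(p)
        for p in reversed(P):
            while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
                upper.pop()
            upper.append(p)
        hull = lower[:-1] + upper[:-1]
        area = 0.0
        for i in range(len(hull)):
            x1, y1 = hull[i]
            x2, y2 = hull[(i + 1) % len(hull)]
            area += x1 * y2 - x2 * y1
        assert res.value == pytest.approx(abs(area) / 2.0, rel=1e-6)

    def test_too_few_taxa_flagged_degenerate(self):
        blocks = _one_block(3)
        vals = pd.DataFrame(
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
            columns=["b::m0", "b::m1", "b::m2"],
            index=["t0", "t1"],
        )
        res = functional_richness(np.ones(2), vals, blocks, {"b": 1.0}, n_axes=2)
        assert res.degenerate and np.isnan(res.value)

    def test_adding_exterior_taxon_never_shrinks_hull(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        from scipy.spatial import ConvexHull

        base = ConvexHull(pts).volume
        outside = pts.mean(axis=0) + 10 * (pts[0] - pts.mean(axis=0))
        grown = ConvexHull(np.vstack([pts, outside])).volume
        assert grown >= base
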