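"""Local richness and multiple-site abundance-based beta-diversity.

The central statistic is the multiple-site Bray-Curtis dissimilarity family
(Baselga's abundance-based framework): a single value in [0, 1] summarising
compositional variation across all sites of a basin at once, decomposed into
a balanced-variation component (abundance turnover) and an abundance-gradient
component (nested abundance differences).  For two sites the total reduces to
the classic pairwise Bray-Curtis (B + C) / (2A + B + C).

Trait ("functional") richness is the convex-hull volume of a community's
taxa in a PCoA ordination of weighted Gower-type trait dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "multisite_bray",
    "pairwise_bray",
    "beta_series",
    "taxon_richness",
    "functional_richness",
    "gower_block_dissimilarity",
    "weighted_gower",
    "pcoa_coordinates",
]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 site rows")
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    if np.any(X.sum(axis=1) <= 0):
        raise ValueError("empty_community: a site row has zero total abundance")
    return X


def multisite_bray(X) -> tuple[float, float, float]:
    """Multiple-site Bray-Curtis dissimilarity and its two components.

    Parameters
    ----------
    X : array-like, shape (n_sites, n_features)
        Non-negative site x feature matrix (taxon abundances or
        weight-scaled community-weighted trait means); every row must have
        a positive sum.

    Returns
    -------
    (beta_total, beta_balanced, beta_gradient)
        With ``A`` the summed pairwise shared abundance, and ``min_b`` /
        ``max_b`` the sums over site pairs of the smaller / larger
        one-directional exclusive abundance sums::

            beta_balanced = min_b / (min_b + A)
            beta_gradient = A / (min_b + A) * (max_b - min_b)
                            / (2 A + min_b + max_b)
            beta_total    = (min_b + max_b) / (2 A + min_b + max_b)

        The components add exactly to the total.  For two sites the total
        equals pairwise Bray-Curtis.
    """
    X = _as_matrix(X)
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    # pairwise shared and one-directional exclusive abundance sums
    mins = np.minimum(X[iu], X[ju]).sum(axis=1)
    b_ij = np.maximum(X[iu] - X[ju], 0.0).sum(axis=1)
    b_ji = np.maximum(X[ju] - X[iu], 0.0).sum(axis=1)
    A = float(mins.sum())
    min_b = float(np.minimum(b_ij, b_ji).sum())
    max_b = float(np.maximum(b_ij, b_ji).sum())
    denom = 2.0 * A + min_b + max_b
    if denom == 0.0:  # unreachable for valid input (rows have positive sums)
        return 0.0, 0.0, 0.0
    total = (min_b + max_b) / denom
    if min_b + A == 0.0:
        balanced = 0.0
    else:
        balanced = min_b / (min_b + A)
    gradient = total - balanced
    return total, balanced, gradient


def pairwise_bray(x, y) -> float:
    """Classic pairwise Bray-Curtis dissimilarity (B+C)/(2A+B+C)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.minimum(x, y).sum()
    b = np.maximum(x - y, 0.0).sum()
    c = np.maximum(y - x, 0.0).sum()
    denom = 2.0 * a + b + c
    return float((b + c) / denom) if denom else 0.0


# ---------------------------------------------------------------------------
# series over panels


def beta_series(
    panels,
    cwm_provider=None,
    relative: bool = False,
) -> pd.DataFrame:
    """Multiple-site beta-diversity per basin, year and index type.

    ``cwm_provider`` is an optional callable ``(panel, year, block_class)``
    returning a site x modality matrix of weight-scaled community-weighted
    means (or None when traits cannot be resolved); when given, biological
    and ecological index types are computed alongside the taxonomic one.
    ``relative=True`` converts the taxonomic matrices to within-site
    relative abundances first (the default keeps raw abundances).
    """
    records = []
    for basin_id in sorted(panels):
        panel = panels[basin_id]
        for year in panel.years:
            mats = {"taxonomic": panel.year_matrix(year).to_numpy()}
            if relative:
                M = mats["taxonomic"]
                mats["taxonomic"] = M / M.sum(axis=1, keepdims=True)
            if cwm_provider is not None:
                for block_class in ("biological", "ecological"):
                    M = cwm_provider(panel, year, block_class)
                    if M is not None:
                        mats[block_class] = np.asarray(M, dtype=float)
            for index_type, M in mats.items():
                total, bal, grad = multisite_bray(M)
                records.append(
                    {
                        "basin": basin_id,
                        "year": year,
                        "index_type": index_type,
                        "beta_total": total,
                        "beta_balanced": bal,
                        "beta_gradient": grad,
                        "n_sites": M.shape[0],
                    }
                )
    return pd.DataFrame.from_records(records)


def taxon_richness(panels) -> pd.DataFrame:
    """Count of taxa with positive abundance per basin, site and year."""
    records = []
    for basin_id in sorted(panels):
        panel = panels[basin_id]
        counts = (panel.abundance > 0).sum(axis=2)  # year x site
        for yi, year in enumerate(panel.years):
            for si, site in enumerate(panel.sites):
                records.append(
                    {
                        "basin": basin_id,
                        "site": site,
                        "year": year,
                        "taxon_richness": int(counts[yi, si]),
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# trait-space dissimilarity and functional richness


def gower_block_dissimilarity(T: np.ndarray) -> np.ndarray:
    """Pairwise dissimilarity within one trait block.

    Rows of ``T`` are per-taxon modality proportions summing to 1; the
    block dissimilarity is half the L1 distance, so it lies in [0, 1].
    Rows containing NaN yield NaN against every partner.
    """
    T = np.asarray(T, dtype=float)
    D = 0.5 * np.abs(T[:, None, :] - T[None, :, :]).sum(axis=2)
    bad = np.isnan(T).any(axis=1)
    D[bad, :] = np.nan
    D[:, bad] = np.nan
    np.fill_diagonal(D, np.where(bad, np.nan, 0.0))
    return D


def weighted_gower(norm_values: pd.DataFrame, blocks, weights: dict) -> np.ndarray:
    """Weighted Gower-type dissimilarity across trait blocks.

    For each taxon pair the dissimilarity is the weight-averaged block
    dissimilarity over the blocks resolved for both taxa; pairs sharing no
    resolved block get NaN.
    """
    n = len(norm_values)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for b in blocks:
        cols = [f"{b.name}::{m}" for m in b.modalities]
        D = gower_block_dissimilarity(norm_values[cols].to_numpy())
        ok = ~np.isnan(D)
        w = weights[b.name]
        num[ok] += w * D[ok]
        den[ok] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def pcoa_coordinates(D: np.ndarray, n_axes: int) -> np.ndarray:
    """Classical PCoA coordinates from a square-root-transformed
    dissimilarity matrix, keeping the leading positive-eigenvalue axes."""
    from skbio.stats.ordination import pcoa

    res = pcoa(np.sqrt(D), number_of_dimensions=min(n_axes, D.shape[0] - 1))
    coords = res.samples.to_numpy()
    eig = res.eigvals.to_numpy()[: coords.shape[1]]
    return coords[:, eig > 1e-12]


@dataclass
class FRicResult:
    value: float
    degenerate: bool
    n_taxa: int
    reason: str = ""


def functional_richness(
    abundances,
    norm_values: pd.DataFrame,
    blocks,
    weights: dict,
    n_axes: int = 3,
    standardize: bool = False,
    pooled_coords: np.ndarray | None = None,
) -> FRicResult:
    """Convex-hull volume of a community in weighted trait space.

    The taxa present (abundance > 0) with fully resolved traits are placed
    by PCoA of the square-root-transformed weighted Gower dissimilarity and
    the hull volume over the first ``n_axes`` axes is returned.  When
    ``pooled_coords`` is given (shared ordination of the full taxon pool,
    rows aligned with ``norm_values``), the community hull is computed in
    that common space instead, which makes values comparable across
    communities; ``standardize=True`` then divides by the pooled hull
    volume so values lie in [0, 1].

    Communities with fewer than ``n_axes + 1`` distinct trait points are
    degenerate: flagged, value NaN, never an error.
    """
    abundances = np.asarray(abundances, dtype=float)
    present = abundances > 0
    resolved = ~norm_values.isna().any(axis=1).to_numpy()
    use = present & resolved
    n = int(use.sum())
    if n < n_axes + 1:
        return FRicResult(np.nan, True, n, "too_few_taxa")
    if pooled_coords is not None:
        coords = pooled_coords[use, :n_axes]
    else:
        D = weighted_gower(norm_values.loc[use], blocks, weights)
        if np.isnan(D).any():
            return FRicResult(np.nan, True, n, "unresolved_dissimilarity")
        coords = pcoa_coordinates(D, n_axes)
    if coords.shape[1] == 0 or np.unique(coords, axis=0).shape[0] < coords.shape[1] + 1:
        return FRicResult(0.0, True, n, "collapsed_trait_space")
    try:
        vol = float(ConvexHull(coords, qhull_options="QJ").volume)
    except QhullError:
        return FRicResult(0.0, True, n, "degenerate_hull")
    if standardize and pooled_coords is not None:
        pool = pooled_coords[resolved, :n_axes]
        try:
            pool_vol = float(ConvexHull(pool, qhull_options="QJ").volume)
            if pool_vol > 0:
                vol = vol / pool_vol
        except QhullError:
            pass
    return FRicResult(vol, False, n)
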