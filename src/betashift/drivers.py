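"""Basin-level anthropogenic stress covariates.

Three spatial stress gradients are built per basin: mean ecological quality
ratio (EQR, a standardized observed-vs-reference community index; higher =
less impacted), the OLS slope of sampling-season air temperature on year
(degC per year; higher = stronger warming) and two principal components of
the mean forest/urban/agriculture land-cover proportions.  PC1 is oriented
so the forest loading is positive (increasing forest, decreasing
agriculture/urban) and PC2 so the urban loading is positive.  Drivers are
z-scaled across basins before entering the trend models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panels import SiteMetadata

__all__ = [
    "DriverSet",
    "mean_eqr",
    "temperature_slope",
    "landcover_pca",
    "assemble_drivers",
]

DRIVER_COLUMNS = ["eqr_mean", "temp_slope", "pc1", "pc2"]


@dataclass
class DriverSet:
    raw: pd.DataFrame  # basin x driver, unscaled
    scaled: pd.DataFrame  # z-scaled across basins
    scaling: pd.DataFrame  # mean/sd per driver
    pca_loadings: pd.DataFrame  # land-cover variable x component
    pca_var_explained: np.ndarray

    def unscale(self, driver: str, values) -> np.ndarray:
        m = self.scaling.at[driver, "mean"]
        s = self.scaling.at[driver, "sd"]
        return np.asarray(values) * s + m


def mean_eqr(metadata: SiteMetadata, basin: str) -> float:
    """Arithmetic mean EQR over all site-year records of the basin."""
    recs = metadata.eqr.loc[metadata.eqr["basin"].astype(str) == str(basin), "eqr"]
    if len(recs) == 0:
        raise ValueError(f"no EQR records for basin {basin!r}")
    return float(recs.mean())


def temperature_slope(series: pd.Series | dict) -> float:
    """OLS slope of sampling-season mean temperature on calendar year."""
    if isinstance(series, dict):
        series = pd.Series(series)
    years = np.asarray(series.index, dtype=float)
    temps = np.asarray(series.to_numpy(), dtype=float)
    if len(years) < 3:
        raise ValueError("temperature slope needs >= 3 years")
    return float(stats.linregress(years, temps).slope)


def landcover_pca(proportions: pd.DataFrame, standardize: bool = True):
    """PCA of per-basin mean land-cover proportions.

    ``proportions``: basin-indexed frame with columns forest, urban,
    agriculture.  Columns are centered (and standardized by default, since
    the three proportions have unequal variances).  A constant column is
    dropped with a warning.  Returns ``(scores, loadings, var_explained)``
    with the sign convention: PC1 forest-positive, PC2 urban-positive.
    """
    cols = ["forest", "urban", "agriculture"]
    X = proportions[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("landcover PCA needs >= 3 basins")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 1e-12
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"constant land-cover columns dropped: {dropped}", RuntimeWarning,
                      stacklevel=2)
    use_cols = [c for c, k in zip(cols, keep) if k]
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    if standardize:
        Xc = Xc / Xc.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    var_explained = var / var.sum()
    n_comp = min(2, Vt.shape[0])
    loadings = Vt[:n_comp].T  # variable x component
    scores = Xc @ loadings
    # orientation: PC1 forest-positive, PC2 urban-positive
    for j, anchor in enumerate(["forest", "urban"][:n_comp]):
        if anchor in use_cols:
            i = use_cols.index(anchor)
            if loadings[i, j] < 0:
                loadings[:, j] *= -1
                scores[:, j] *= -1
    load_df = pd.DataFrame(
        loadings, index=use_cols, columns=[f"pc{j + 1}" for j in range(n_comp)]
    )
    score_df = pd.DataFrame(
        scores, index=proportions.index, columns=[f"pc{j + 1}" for j in range(n_comp)]
    )
    return score_df, load_df, var_explained[:n_comp]


def assemble_drivers(metadata: SiteMetadata, basins, standardize_pca: bool = True) -> DriverSet:
    """Join the three stress covariates and z-scale them across basins."""
    basins = [str(b) for b in basins]
    if len(basins) < 2:
        raise ValueError("driver scaling needs >= 2 basins (SD undefined otherwise)")
    rows = {}
    for b in basins:
        temp_b = metadata.temperature[metadata.temperature["basin"].astype(str) == b]
        series = temp_b.groupby("year")["temp_c"].mean()
        rows[b] = {
            "eqr_mean": mean_eqr(metadata, b),
            "temp_slope": temperature_slope(series),
        }
    lc = (
        metadata.land_cover[metadata.land_cover["basin"].astype(str).isin(basins)]
        .groupby(metadata.land_cover["basin"].astype(str))[["forest", "urban", "agriculture"]]
        .mean()
        .reindex(basins)
    )
    scores, loadings, var_explained = landcover_pca(lc, standardize=standardize_pca)
    raw = pd.DataFrame(rows).T.reindex(basins)
    for c in scores.columns:
        raw[c] = scores[c]
    raw = raw.reindex(columns=[c for c in DRIVER_COLUMNS if c in raw.columns])
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    if (sds <= 0).any():
        bad = list(sds.index[sds <= 0])
        raise ValueError(f"drivers with zero across-basin SD cannot be scaled: {bad}")
    scaled = (raw - means) / sds
    scaling = pd.DataFrame({"mean": means, "sd": sds})
    return DriverSet(raw, scaled, scaling, loadings, var_explained)
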