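"""Mixed-model trends in beta-diversity and local richness.

Three beta-likelihood model forms are supported, all on the logit scale
with year centred at its mid-span (coefficients are per year):

* ``overall``      beta ~ year + (1 | basin)
* ``per_basin``    beta ~ basin + basin:year          (all fixed effects)
* ``interaction``  beta ~ driver * year + (1 | basin)

Local richness trends use a Gaussian linear mixed model, richness ~ year
with a random intercept per site and a random slope (with intercept) per
basin; each basin's trend is the fixed slope plus its BLUP deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .betareg import BetaMixedModel, BetaRegression, BetaResults, compress_unit_interval

__all__ = [
    "BetaTrendFit",
    "RichnessTrendFit",
    "fit_beta_mixed",
    "fit_richness_mixed",
    "marginal_year_effect",
    "recovering_subset",
    "residual_diagnostics",
    "morans_i",
]


@dataclass
class BetaTrendFit:
    """A fitted beta-diversity trend model plus its context."""

    results: BetaResults
    kind: str
    year_center: float
    records: pd.DataFrame
    driver: str | None = None
    boundary_compressed: bool = False

    @property
    def converged(self) -> bool:
        return self.results.converged

    def coef(self, name: str) -> float:
        return float(self.results.params[self.results.exog_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.results.bse[self.results.exog_names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.results.pvalues[self.results.exog_names.index(name)])

    def basin_slopes(self) -> pd.DataFrame:
        """Per-basin year slopes; only defined for the per-basin model."""
        if self.kind != "per_basin":
            raise ValueError("basin slopes require the per-basin model")
        rows = []
        for name, est, se, p in zip(
            self.results.exog_names,
            self.results.params,
            self.results.bse,
            self.results.pvalues,
        ):
            if name.startswith("year_c:"):
                rows.append(
                    {"basin": name.split(":", 1)[1], "slope": est, "se": se, "p_value": p}
                )
        return pd.DataFrame(rows).set_index("basin")

    def summary(self) -> str:
        head = f"beta-diversity trend model [{self.kind}]"
        if self.driver:
            head += f" driver={self.driver}"
        return head + "\n" + self.results.summary()


def _prepare_beta(records: pd.DataFrame, value_col: str):
    y = records[value_col].to_numpy(dtype=float)
    compressed = False
    if np.any((y <= 0) | (y >= 1)):
        y = compress_unit_interval(y)
        compressed = True
    center = 0.5 * (records["year"].min() + records["year"].max())
    year_c = records["year"].to_numpy(dtype=float) - center
    return y, year_c, center, compressed


def fit_beta_mixed(
    records: pd.DataFrame,
    formula_spec: str = "overall",
    value_col: str = "beta_total",
    driver_values: pd.Series | None = None,
    driver_name: str = "driver",
    n_nodes: int = 15,
    fix_sigma: float | None = None,
) -> BetaTrendFit:
    """Fit one of the three beta-likelihood trend model forms.

    ``records`` needs columns basin, year and ``value_col``.  For the
    interaction form, ``driver_values`` maps basin -> scaled driver value.
    Responses at the unit-interval boundary are compressed (flagged).
    Non-convergence is flagged on the returned fit, never silent.
    """
    records = records.reset_index(drop=True)
    y, year_c, center, compressed = _prepare_beta(records, value_col)
    basins = records["basin"].astype(str).to_numpy()

    if formula_spec == "overall":
        X = np.column_stack([np.ones_like(year_c), year_c])
        names = ["const", "year_c"]
        model = BetaMixedModel(y, X, basins, names, n_nodes=n_nodes, fix_sigma=fix_sigma)
    elif formula_spec == "per_basin":
        labels = sorted(set(basins))
        dummies = np.column_stack([(basins == b).astype(float) for b in labels])
        slopes = dummies * year_c[:, None]
        X = np.column_stack([dummies, slopes])
        names = [f"basin:{b}" for b in labels] + [f"year_c:{b}" for b in labels]
        model = BetaRegression(y, X, names)
    elif formula_spec == "interaction":
        if driver_values is None:
            raise ValueError("interaction model requires driver_values")
        d = records["basin"].astype(str).map(
            {str(k): float(v) for k, v in driver_values.items()}
        )
        if d.isna().any():
            missing = sorted(set(records.loc[d.isna(), "basin"].astype(str)))
            raise ValueError(f"driver values missing for basins {missing}")
        d = d.to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(year_c), d, year_c, d * year_c])
        names = ["const", driver_name, "year_c", f"{driver_name}:year_c"]
        model = BetaMixedModel(y, X, basins, names, n_nodes=n_nodes, fix_sigma=fix_sigma)
    else:
        raise ValueError(f"unknown formula_spec {formula_spec!r}")

    results = model.fit()
    if not results.converged:
        warnings.warn(
            f"beta trend model ({formula_spec}) did not converge: {results.message}",
            RuntimeWarning,
            stacklevel=2,
        )
    rec = records.copy()
    rec["year_c"] = year_c
    if formula_spec == "interaction":
        rec["driver_value"] = d
    return BetaTrendFit(
        results=results,
        kind=formula_spec,
        year_center=center,
        records=rec,
        driver=driver_name if formula_spec == "interaction" else None,
        boundary_compressed=compressed,
    )


# ---------------------------------------------------------------------------
# richness trends (Gaussian LMM)


@dataclass
class RichnessTrendFit:
    fixed_slope: float
    fixed_slope_se: float
    fixed_slope_p: float
    basin_slopes: pd.Series  # BLUP total slope per basin
    resid_var: float
    converged: bool
    flagged: str = ""
    _fit: object = None

    def summary(self) -> str:
        return (
            f"richness trend LMM: slope={self.fixed_slope:.4f} "
            f"(se={self.fixed_slope_se:.4f}, p={self.fixed_slope_p:.3g}), "
            f"resid var={self.resid_var:.4f}, converged={self.converged}"
            + (f", note: {self.flagged}" if self.flagged else "")
        )


def fit_richness_mixed(
    records: pd.DataFrame, value_col: str = "taxon_richness", reml: bool = True
) -> RichnessTrendFit:
    """richness ~ year with site random intercepts and basin random slopes.

    Requires columns basin, site, year and ``value_col``.  A singular
    basin-level covariance triggers a refit with independent basin
    intercept/slope components (flagged).
    """
    import statsmodels.api as sm

    df = records.dropna(subset=[value_col]).copy()
    if df["basin"].nunique() < 2 or df["site"].nunique() < 2:
        raise ValueError("need >= 2 basins and >= 2 sites")
    center = 0.5 * (df["year"].min() + df["year"].max())
    df["year_c"] = df["year"].astype(float) - center
    if np.allclose(df[value_col].std(), 0.0):
        basins = sorted(df["basin"].astype(str).unique())
        return RichnessTrendFit(
            0.0, 0.0, 1.0, pd.Series(0.0, index=basins), 0.0, True, "constant_response"
        )

    def _extract(fit, correlated: bool):
        fe = fit.fe_params
        slope = float(fe["year_c"])
        se = float(fit.bse_fe["year_c"])
        p = float(2 * st.norm.sf(abs(slope / se))) if se > 0 else np.nan
        blups = {}
        for basin, re in fit.random_effects.items():
            dev = re.get("year_c", 0.0)
            blups[str(basin)] = slope + float(dev)
        return RichnessTrendFit(
            slope,
            se,
            p,
            pd.Series(blups).sort_index(),
            float(fit.scale),
            bool(fit.converged),
            "" if correlated else "independent_basin_components(flagged)",
            fit,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = sm.MixedLM.from_formula(
                f"{value_col} ~ year_c",
                groups="basin",
                re_formula="~year_c",
                vc_formula={"site": "0 + C(site)"},
                data=df,
            )
            fit = md.fit(reml=reml, method="lbfgs")
            cov = fit.cov_re.to_numpy()
            if not fit.converged or np.linalg.cond(cov) > 1e8:
                raise ValueError("singular basin covariance")
            return _extract(fit, correlated=True)
        except Exception:
            md = sm.MixedLM.from_formula(
                f"{value_col} ~ year_c",
                groups="basin",
                re_formula="1",
                vc_formula={"site": "0 + C(site)", "bslope": "0 + year_c"},
                data=df,
            )
            fit = md.fit(reml=reml, method="lbfgs")
            # slope BLUPs live in the vc part
            fe = fit.fe_params
            slope = float(fe["year_c"])
            se = float(fit.bse_fe["year_c"])
            p = float(2 * st.norm.sf(abs(slope / se))) if se > 0 else np.nan
            blups = {}
            for basin, re in fit.random_effects.items():
                dev = re.get("bslope[year_c]", re.get("year_c", 0.0))
                blups[str(basin)] = slope + float(dev)
            return RichnessTrendFit(
                slope,
                se,
                p,
                pd.Series(blups).sort_index(),
                float(fit.scale),
                bool(fit.converged),
                "independent_basin_components(flagged)",
                fit,
            )


# ---------------------------------------------------------------------------
# marginal effects, recovery subset, diagnostics


def marginal_year_effect(
    fit: BetaTrendFit, driver_grid=None, n_points: int = 5, alpha: float = 0.05
) -> pd.DataFrame:
    """Year slope (logit scale) along the driver gradient, delta-method SE.

    slope(year | driver = d) = b_year + b_interaction * d.  The default
    grid is ``n_points`` equally spaced values over the observed driver
    range in the fitted records.
    """
    if fit.kind != "interaction":
        raise ValueError("marginal effects require the interaction model")
    names = fit.results.exog_names
    i_year = names.index("year_c")
    i_int = names.index(f"{fit.driver}:year_c")
    b = fit.results.params
    V = fit.results.cov_params
    if driver_grid is None:
        dvals = fit.records["driver_value"].to_numpy(dtype=float)
        driver_grid = np.linspace(dvals.min(), dvals.max(), n_points)
    driver_grid = np.asarray(driver_grid, dtype=float)
    z = st.norm.ppf(1 - alpha / 2)
    rows = []
    for d in driver_grid:
        slope = b[i_year] + b[i_int] * d
        var = V[i_year, i_year] + d**2 * V[i_int, i_int] + 2 * d * V[i_year, i_int]
        se = float(np.sqrt(max(var, 0.0)))
        rows.append(
            {
                "driver_value": d,
                "year_slope": float(slope),
                "se": se,
                "ci_low": float(slope - z * se),
                "ci_high": float(slope + z * se),
                "significant": bool(abs(slope) > z * se),
            }
        )
    return pd.DataFrame(rows)


RICHNESS_MATCH = {
    "taxonomic": "taxon_richness",
    "biological": "fric_biological",
    "ecological": "fric_ecological",
}


def recovering_subset(
    beta_records: pd.DataFrame, richness_fits: dict[str, RichnessTrendFit]
) -> pd.DataFrame:
    """Keep basins whose matching local-richness BLUP slope is positive.

    ``richness_fits`` maps richness column names (see RICHNESS_MATCH) to
    fitted richness trends.  Taxonomic beta records are filtered on taxon
    richness, biological/ecological trait beta on the matching functional
    richness.  An empty result triggers a warning.
    """
    keep_masks = []
    for index_type, g in beta_records.groupby("index_type"):
        fit = richness_fits.get(RICHNESS_MATCH.get(index_type, index_type))
        if fit is None:
            keep_masks.append(g)
            continue
        increasing = set(fit.basin_slopes.index[fit.basin_slopes > 0])
        keep_masks.append(g[g["basin"].astype(str).isin(increasing)])
    out = pd.concat(keep_masks) if keep_masks else beta_records.iloc[:0]
    if out.empty:
        warnings.warn("no basins with increasing local richness remain", RuntimeWarning,
                      stacklevel=2)
    return out.sort_index()


def morans_i(values: np.ndarray, coords: np.ndarray) -> dict:
    """Moran's I with inverse-distance weights and normal-approximation p.

    ``values`` are one residual per spatial unit; ``coords`` the unit
    midpoints, shape (n, 2).
    """
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    n = len(z)
    if n < 3 or np.allclose(z, 0.0):
        return {"I": np.nan, "expected": np.nan, "p_value": np.nan, "degenerate": True}
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    with np.errstate(divide="ignore"):
        W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    s0 = W.sum()
    I = n / s0 * (z @ W @ z) / (z @ z)
    EI = -1.0 / (n - 1)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    varI = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - EI**2
    zscore = (I - EI) / np.sqrt(varI)
    p = 2 * st.norm.sf(abs(zscore))
    return {"I": float(I), "expected": float(EI), "p_value": float(p), "degenerate": False}


def residual_diagnostics(
    fit: BetaTrendFit, coords: pd.DataFrame | None = None
) -> dict:
    """Spatial and temporal autocorrelation checks on model residuals.

    Durbin-Watson per within-basin residual sequence (ordered by year) and
    Moran's I on basin-mean residuals when basin midpoint ``coords``
    (frame with basin index and columns x, y) are supplied.  Residuals are
    response-scale, fixed effects only.  Constant residuals are reported
    as degenerate rather than raising.
    """
    from statsmodels.stats.stattools import durbin_watson

    rec = fit.records.copy()
    rec["resid"] = rec[
        "beta_total" if "beta_total" in rec.columns else rec.columns[-1]
    ].to_numpy(dtype=float) - fit.results.fittedvalues
    dw = {}
    for basin, g in rec.sort_values("year").groupby("basin"):
        r = g["resid"].to_numpy()
        if len(r) >= 3 and not np.allclose(r.std(), 0.0):
            dw[str(basin)] = float(durbin_watson(r))
        else:
            dw[str(basin)] = np.nan
    out = {"durbin_watson": dw, "durbin_watson_mean": float(np.nanmean(list(dw.values())))}
    if coords is not None:
        means = rec.groupby("basin")["resid"].mean()
        common = [b for b in means.index if b in coords.index]
        out["morans_i"] = morans_i(
            means.loc[common].to_numpy(), coords.loc[common, ["x", "y"]].to_numpy()
        )
    by_basin = rec.groupby("basin").agg(
        n_sites=("n_sites", "max") if "n_sites" in rec.columns else ("resid", "size"),
        series_length=("year", "nunique"),
        mean_abs_resid=("resid", lambda r: float(np.abs(r).mean())),
    )
    out["residual_vs_descriptors"] = by_basin
    return out
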