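"""End-to-end pipeline: data -> traits -> diversity -> drivers -> trends ->
partition -> summaries, with a reproducibility manifest.

A run is driven by a single validated :class:`RunConfig` (YAML-loadable;
unknown keys rejected).  Outputs are tidy CSVs plus a JSON manifest
recording the config hash, seeds, package versions and per-stage row
counts; identical manifests imply identical numeric artifacts.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .diversity import beta_series, functional_richness, taxon_richness, weighted_gower, pcoa_coordinates
from .drivers import assemble_drivers
from .panels import (
    read_community_table,
    read_metadata,
    read_trait_table,
    select_panel,
    validate_dataset,
    write_community_table,
    write_metadata,
    write_trait_table,
)
from .partition import partition_series, summarize_contributions
from .simulate import SimConfig, generate_metacommunity
from .traits import (
    compute_block_weights,
    impute_traits,
    make_cwm_provider,
    normalize_trait_blocks,
    trait_coverage_report,
)
from .trends import fit_beta_mixed, fit_richness_mixed, marginal_year_effect

__all__ = ["RunConfig", "run_pipeline", "make_reports", "figure7_experiment", "compute_richness_series"]

STAGES = ["data", "traits", "diversity", "drivers", "trends", "partition", "summaries"]


class SimSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_basins: int = 8
    sites_per_basin: int = 8
    years_per_basin: int = 10
    n_taxa_pool: int = 150
    gain_rate: float = 1.0
    loss_rate: float = 0.25


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    community_csv: Optional[str] = None
    trait_csv: Optional[str] = None
    metadata_dir: Optional[str] = None
    simulate: Optional[SimSection] = None
    min_sites: int = 5
    min_years: int = 5
    drop_sites: bool = False
    relative_abundance: bool = False
    strict_traits: bool = False
    scheme: Literal["symmetrized", "loss_first", "gain_first"] = "symmetrized"
    pairs: Literal["consecutive", "endpoints"] = "consecutive"
    attribute_columns: bool = False
    n_perm: int = 2000
    quadrature_nodes: int = 15
    pca_standardize: bool = True
    fric_axes: int = 3
    seed: int = 0
    out_dir: str = "run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def compute_richness_series(panels, norm, n_axes: int = 3) -> pd.DataFrame:
    """Taxonomic and functional (trait-hull) richness per basin-site-year.

    Functional richness uses, per basin, a pooled PCoA of the weighted
    Gower trait dissimilarity over the basin's resolved taxa, so community
    hull volumes share one ordination and are comparable within a basin.
    """
    rich = taxon_richness(panels)
    out = rich.set_index(["basin", "site", "year"])
    for block_class, col in (("biological", "fric_biological"), ("ecological", "fric_ecological")):
        blocks = norm.blocks_of_class(block_class)
        if not blocks:
            out[col] = np.nan
            continue
        vals = {}
        cols = [c for b in blocks for c in norm.block_columns(b.name)]
        for basin_id in sorted(panels):
            panel = panels[basin_id]
            aligned = norm.values.reindex(panel.taxon_ids)[cols]
            resolved = ~aligned.isna().any(axis=1).to_numpy()
            if resolved.sum() < n_axes + 1:
                for year in panel.years:
                    for site in panel.sites:
                        vals[(basin_id, site, year)] = np.nan
                continue
            D = weighted_gower(aligned.loc[resolved], blocks, norm.weights)
            coords = pcoa_coordinates(D, n_axes)
            k = coords.shape[1]
            pooled = np.zeros((len(panel.taxon_ids), k))
            pooled[resolved] = coords
            for yi, year in enumerate(panel.years):
                for si, site in enumerate(panel.sites):
                    res = functional_richness(
                        panel.abundance[yi, si],
                        aligned,
                        blocks,
                        norm.weights,
                        n_axes=k,
                        pooled_coords=pooled,
                    )
                    vals[(basin_id, site, year)] = res.value
        out[col] = pd.Series(vals)
    return out.reset_index()


def run_pipeline(config: RunConfig) -> str:
    """Execute all stages and write tidy outputs plus the manifest.

    Returns the run directory.  Any stage failure aborts with the stage
    name in the exception message.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    stage = "data"
    try:
        if config.simulate is not None:
            sim = SimConfig(seed=config.seed, **config.simulate.model_dump())
            raw_panels, metadata, traits_db, truth = generate_metacommunity(sim)
            write_community_table(raw_panels, os.path.join(config.out_dir, "community.csv"))
            write_trait_table(traits_db, os.path.join(config.out_dir, "traits.csv"))
            write_metadata(metadata, config.out_dir)
            with open(os.path.join(config.out_dir, "ground_truth.json"), "w") as fh:
                json.dump(
                    {
                        b: {k: v for k, v in t.items() if k not in ("events", "baseline")}
                        for b, t in truth.items()
                    },
                    fh,
                    indent=1,
                )
        else:
            if not (config.community_csv and config.trait_csv and config.metadata_dir):
                raise ValueError("provide either simulate: or all input paths")
            raw_panels = read_community_table(config.community_csv)
            traits_db = read_trait_table(config.trait_csv)
            metadata = read_metadata(config.metadata_dir)
        panels = {}
        rejections = []
        for basin_id, p in raw_panels.items():
            res = select_panel(p, config.min_sites, config.min_years, config.drop_sites)
            if hasattr(res, "reason"):
                rejections.append({"basin": basin_id, "reason": res.reason})
            else:
                panels[basin_id] = res
        if not panels:
            raise ValueError("no basin passed panel selection")
        report = validate_dataset(panels, traits_db, metadata)
        manifest["stages"]["data"] = {
            "n_basins": len(panels),
            "n_rejected": len(rejections),
            "n_issues": len(report["issues"]),
        }

        stage = "traits"
        norm = impute_traits(normalize_trait_blocks(traits_db))
        norm.weights = compute_block_weights(norm)
        coverage = trait_coverage_report(norm)
        coverage.to_csv(os.path.join(config.out_dir, "trait_coverage.csv"), index=False)
        manifest["stages"]["traits"] = {
            "n_blocks": len(norm.blocks),
            "mean_coverage": float(coverage["coverage"].mean()),
        }

        stage = "diversity"
        provider = make_cwm_provider(norm, strict=config.strict_traits)
        beta = beta_series(panels, provider, relative=config.relative_abundance)
        beta.to_csv(os.path.join(config.out_dir, "beta.csv"), index=False)
        richness = compute_richness_series(panels, norm, n_axes=config.fric_axes)
        richness.to_csv(os.path.join(config.out_dir, "richness.csv"), index=False)
        manifest["stages"]["diversity"] = {"beta_rows": len(beta), "richness_rows": len(richness)}

        stage = "drivers"
        driver_set = assemble_drivers(metadata, sorted(panels), config.pca_standardize)
        driver_set.scaled.to_csv(os.path.join(config.out_dir, "drivers_scaled.csv"))
        driver_set.raw.to_csv(os.path.join(config.out_dir, "drivers_raw.csv"))
        driver_set.pca_loadings.to_csv(os.path.join(config.out_dir, "pca_loadings.csv"))
        manifest["stages"]["drivers"] = {
            "n_basins": len(driver_set.raw),
            "pca_var_explained": [float(v) for v in driver_set.pca_var_explained],
        }

        stage = "trends"
        coef_rows = []
        marginal_frames = []
        for index_type, g in beta.groupby("index_type"):
            fit = fit_beta_mixed(g, "overall", n_nodes=config.quadrature_nodes)
            coef_rows.append(
                {
                    "index_type": index_type,
                    "model": "overall",
                    "driver": "",
                    "term": "year_c",
                    "estimate": fit.coef("year_c"),
                    "se": fit.se("year_c"),
                    "p_value": fit.pvalue("year_c"),
                    "converged": fit.converged,
                }
            )
            for driver in driver_set.scaled.columns:
                dfit = fit_beta_mixed(
                    g,
                    "interaction",
                    driver_values=driver_set.scaled[driver],
                    driver_name=driver,
                    n_nodes=config.quadrature_nodes,
                )
                term = f"{driver}:year_c"
                coef_rows.append(
                    {
                        "index_type": index_type,
                        "model": "interaction",
                        "driver": driver,
                        "term": term,
                        "estimate": dfit.coef(term),
                        "se": dfit.se(term),
                        "p_value": dfit.pvalue(term),
                        "converged": dfit.converged,
                    }
                )
                me = marginal_year_effect(dfit)
                me.insert(0, "index_type", index_type)
                me.insert(1, "driver", driver)
                marginal_frames.append(me)
        coefs = pd.DataFrame(coef_rows)
        coefs.to_csv(os.path.join(config.out_dir, "trend_coefficients.csv"), index=False)
        pd.concat(marginal_frames, ignore_index=True).to_csv(
            os.path.join(config.out_dir, "marginal_effects.csv"), index=False
        )
        richness_fits = {}
        for col in ("taxon_richness", "fric_biological", "fric_ecological"):
            if richness[col].notna().sum() > 10:
                richness_fits[col] = fit_richness_mixed(richness, value_col=col)
        pd.DataFrame(
            {
                col: {"slope": f.fixed_slope, "se": f.fixed_slope_se, "p": f.fixed_slope_p}
                for col, f in richness_fits.items()
            }
        ).T.to_csv(os.path.join(config.out_dir, "richness_trends.csv"))
        manifest["stages"]["trends"] = {"n_models": len(coefs)}

        stage = "partition"
        results = partition_series(
            panels,
            provider,
            pairs=config.pairs,
            scheme=config.scheme,
            attribute_columns=config.attribute_columns,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        part_rows = [
            {
                "basin": r.basin,
                "year_from": r.year_pair[0],
                "year_to": r.year_pair[1],
                "index_type": r.index_type,
                "delta_total": r.delta_total,
                "delta_additive": r.delta_additive,
                "delta_subtractive": r.delta_subtractive,
            }
            for r in results
        ]
        partition_df = pd.DataFrame(part_rows)
        partition_df.to_csv(os.path.join(config.out_dir, "partition.csv"), index=False)
        manifest["stages"]["partition"] = {"rows": len(partition_df)}

        stage = "summaries"
        summary = summarize_contributions(
            results, grouping="per_column" if config.attribute_columns else "components"
        )
        summary.to_csv(os.path.join(config.out_dir, "contribution_tests.csv"), index=False)
        manifest["stages"]["summaries"] = {"rows": len(summary)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return config.out_dir


# ---------------------------------------------------------------------------
# figure-analog reports


def make_reports(run_dir: str) -> list[str]:
    """Render figure-analog plots from a completed run directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    beta = pd.read_csv(os.path.join(run_dir, "beta.csv"))
    fig, axes = plt.subplots(1, beta["index_type"].nunique(), figsize=(12, 4), squeeze=False)
    for ax, (index_type, g) in zip(axes[0], beta.groupby("index_type")):
        for basin, gb in g.groupby("basin"):
            ax.plot(gb["year"], gb["beta_total"], color="grey", alpha=0.5, lw=0.8)
        mean = g.groupby("year")["beta_total"].mean()
        ax.plot(mean.index, mean.values, color="C0", lw=2)
        ax.set_title(index_type)
        ax.set_xlabel("year")
        ax.set_ylabel("multi-site Bray-Curtis")
    path = os.path.join(run_dir, "fig_beta_trends.png")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    me_path = os.path.join(run_dir, "marginal_effects.csv")
    if os.path.exists(me_path):
        me = pd.read_csv(me_path)
        if not me.empty:
            drivers = me["driver"].unique()
            fig, axes = plt.subplots(1, len(drivers), figsize=(4 * len(drivers), 4), squeeze=False)
            for ax, driver in zip(axes[0], drivers):
                for index_type, g in me[me["driver"] == driver].groupby("index_type"):
                    ax.plot(g["driver_value"], g["year_slope"], marker="o", label=index_type)
                    ax.fill_between(g["driver_value"], g["ci_low"], g["ci_high"], alpha=0.15)
                ax.axhline(0, color="k", lw=0.5)
                ax.set_title(driver)
                ax.set_xlabel(f"{driver} (scaled)")
                ax.set_ylabel("year slope (logit)")
                ax.legend(fontsize=7)
            path = os.path.join(run_dir, "fig_marginal_effects.png")
            fig.tight_layout()
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)

    ct_path = os.path.join(run_dir, "contribution_tests.csv")
    if os.path.exists(ct_path):
        ct = pd.read_csv(ct_path)
        if ct.empty:
            print("contribution plot skipped: empty partition summary")
        else:
            colors = {"additive": "seagreen", "subtractive": "purple"}
            fig, ax = plt.subplots(figsize=(6, max(3, 0.25 * len(ct))))
            for i, row in ct.reset_index(drop=True).iterrows():
                c = colors.get(row["direction"], "grey") if row["significant"] else "grey"
                ax.errorbar(
                    row["estimate"],
                    i,
                    xerr=[[row["estimate"] - row["ci_low"]], [row["ci_high"] - row["estimate"]]],
                    fmt="o",
                    color=c,
                    ms=4,
                )
            ax.axvline(0, color="k", lw=0.5)
            ax.set_yticks(range(len(ct)))
            ax.set_yticklabels(
                [f"{r['column']} ({r['direction'][:3]})" for _, r in ct.iterrows()], fontsize=6
            )
            ax.set_xlabel("contribution to delta beta")
            path = os.path.join(run_dir, "fig_contributions.png")
            fig.tight_layout()
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    return written


# ---------------------------------------------------------------------------
# stress-release (recovery-trajectory) experiment


def figure7_experiment(
    n_reps: int = 20,
    n_years: int = 14,
    n_sites: int = 8,
    s_start: float = 0.95,
    s_end: float = 0.05,
    gain_rate: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """In-silico stress-release trajectory test.

    Each replicate simulates one basin whose stress declines from
    ``s_start`` to ``s_end`` over the first six tenths of the series and
    then stays low (conservation-driven stress release followed by a
    low-stress plateau); the shared fraction of gain events therefore
    falls through time, so the hypothesis predicts beta first declines
    (shared gains homogenize while stress is high) and then rises
    (distinct gains differentiate once stress is low).  Reported per
    replicate: OLS slopes of the taxonomic multi-site Bray-Curtis on year
    over the early and late halves, and whether the trajectory is
    non-monotone in the hypothesized direction (early slope < 0 < late
    slope).
    """
    from scipy import stats as st

    def release(s: float, frac: float) -> float:
        ramp = min(frac / 0.6, 1.0)
        return s_start + (s_end - s_start) * ramp

    rows = []
    for rep in range(n_reps):
        cfg = SimConfig(
            n_basins=1,
            sites_per_basin=n_sites,
            years_per_basin=n_years,
            gain_rate=gain_rate,
            loss_rate=0.0,
            stress=[1.0],
            stress_schedule=release,
            seed=seed + 101 * rep,
        )
        panels, *_ = generate_metacommunity(cfg)
        beta = beta_series(panels)
        g = beta[beta["index_type"] == "taxonomic"].sort_values("year")
        years = g["year"].to_numpy(dtype=float)
        vals = g["beta_total"].to_numpy()
        half = len(years) // 2
        early = st.linregress(years[: half + 1], vals[: half + 1]).slope
        late = st.linregress(years[half:], vals[half:]).slope
        rows.append(
            {
                "rep": rep,
                "early_slope": float(early),
                "late_slope": float(late),
                "u_shaped": bool(early < 0 < late),
            }
        )
    return pd.DataFrame(rows)
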