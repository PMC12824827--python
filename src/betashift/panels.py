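"""Community panels, trait databases and site metadata.

The spatial unit of analysis is the river basin: a metacommunity of
hydrologically connected sampling sites monitored once a year.  A
:class:`CommunityPanel` stores the complete year x site x taxon abundance
array for one basin, with every (year, site) combination present; panel
construction enforces that all sites within a basin share the same sampling
years, rejecting basins that end up with too few sites or years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityPanel",
    "TraitBlock",
    "TraitDatabase",
    "SiteMetadata",
    "PanelRejection",
    "read_community_table",
    "write_community_table",
    "select_panel",
    "validate_dataset",
    "read_trait_table",
    "write_trait_table",
    "read_metadata",
    "write_metadata",
]

COMMUNITY_COLUMNS = ["basin", "site", "year", "taxon", "abundance"]
TRAIT_COLUMNS = [
    "taxon",
    "parent_genus",
    "parent_family",
    "parent_order",
    "block",
    "modality",
    "value",
    "coding",
    "block_class",
]

CODING_SYSTEMS = ("ten_point", "fuzzy", "single")
BLOCK_CLASSES = ("biological", "ecological")


@dataclass
class CommunityPanel:
    """Complete abundance panel for one basin.

    Parameters
    ----------
    basin_id : str
        Opaque basin identifier.
    sites : list of str
        Site identifiers (rows of each yearly matrix).
    years : list of int
        Ordered shared sampling years.
    taxon_ids : list of str
        Taxon identifiers (columns).
    abundance : ndarray, shape (n_years, n_sites, n_taxa)
        Non-negative abundances or densities; zeros mean absence.
    """

    basin_id: str
    sites: list[str]
    years: list[int]
    taxon_ids: list[str]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        expected = (len(self.years), len(self.sites), len(self.taxon_ids))
        if self.abundance.shape != expected:
            raise ValueError(
                f"abundance shape {self.abundance.shape} != {expected} "
                f"for basin {self.basin_id!r}"
            )
        if np.any(self.abundance < 0):
            raise ValueError(f"negative abundance in basin {self.basin_id!r}")
        if list(self.years) != sorted(self.years):
            raise ValueError("years must be sorted ascending")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def year_matrix(self, year: int) -> pd.DataFrame:
        """Site x taxon abundance matrix for one sampling year."""
        i = self.years.index(year)
        return pd.DataFrame(
            self.abundance[i], index=self.sites, columns=self.taxon_ids
        )

    def is_analysis_ready(self, min_sites: int = 5, min_years: int = 5) -> bool:
        """True when the panel meets the size thresholds and every
        site-year community is non-empty."""
        if self.n_sites < min_sites or self.n_years < min_years:
            return False
        return bool(np.all(self.abundance.sum(axis=2) > 0))

    def to_long(self) -> pd.DataFrame:
        """Long-format records, zeros included."""
        ny, ns, nt = self.abundance.shape
        idx = pd.MultiIndex.from_product(
            [self.years, self.sites, self.taxon_ids],
            names=["year", "site", "taxon"],
        )
        df = pd.DataFrame(
            {"abundance": self.abundance.reshape(-1)}, index=idx
        ).reset_index()
        df.insert(0, "basin", self.basin_id)
        return df[COMMUNITY_COLUMNS]


@dataclass
class TraitBlock:
    """One named trait (e.g. voltinism) with its modality columns."""

    name: str
    modalities: list[str]
    coding: str
    block_class: str

    def __post_init__(self) -> None:
        if self.coding not in CODING_SYSTEMS:
            raise ValueError(f"unknown coding system {self.coding!r}")
        if self.block_class not in BLOCK_CLASSES:
            raise ValueError(f"unknown block class {self.block_class!r}")


@dataclass
class TraitDatabase:
    """Taxon x modality trait values grouped into blocks.

    ``values`` is a taxon-indexed frame whose columns are
    ``"<block>::<modality>"`` keys; NaN marks missing.  ``hierarchy`` maps
    each taxon to its parent chain (genus, family, order), with empty
    strings where a rank does not apply (e.g. a genus-level taxon has no
    parent genus of its own).
    """

    blocks: list[TraitBlock]
    values: pd.DataFrame
    hierarchy: pd.DataFrame  # index: taxon; columns genus, family, order

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for b in self.blocks:
            for m in b.modalities:
                key = f"{b.name}::{m}"
                if key in seen:
                    raise ValueError(f"modality {key!r} appears twice")
                seen[key] = b.name
        expected = list(seen)
        if list(self.values.columns) != expected:
            missing = set(expected) - set(self.values.columns)
            extra = set(self.values.columns) - set(expected)
            raise ValueError(
                f"trait value columns do not partition into blocks "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    def block(self, name: str) -> TraitBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def block_columns(self, name: str) -> list[str]:
        b = self.block(name)
        return [f"{b.name}::{m}" for m in b.modalities]

    def blocks_of_class(self, block_class: str) -> list[TraitBlock]:
        return [b for b in self.blocks if b.block_class == block_class]


@dataclass
class SiteMetadata:
    """Per-site stress descriptors consumed by the driver module.

    eqr : frame with columns basin, site, year, eqr (ratio >= 0)
    temperature : frame with columns basin, year, temp_c
        (sampling-season mean, already averaged across sites)
    land_cover : frame with columns basin, site, year, forest, urban,
        agriculture (proportions in [0, 1])
    """

    eqr: pd.DataFrame
    temperature: pd.DataFrame
    land_cover: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.eqr["eqr"] < 0).any():
            raise ValueError("EQR values must be >= 0")
        lc = self.land_cover[["forest", "urban", "agriculture"]]
        if ((lc < 0) | (lc > 1)).any().any():
            raise ValueError("land-cover proportions must lie in [0, 1]")


@dataclass
class PanelRejection:
    """Returned (not raised) when a basin fails panel construction."""

    basin_id: str
    reason: str
    n_sites: int
    n_years: int


# ---------------------------------------------------------------------------
# community table I/O


def _panel_from_long(basin_id: str, df: pd.DataFrame) -> CommunityPanel:
    sites = sorted(df["site"].astype(str).unique())
    years = sorted(int(y) for y in df["year"].unique())
    taxa = sorted(df["taxon"].astype(str).unique())
    site_ix = {s: i for i, s in enumerate(sites)}
    year_ix = {y: i for i, y in enumerate(years)}
    taxon_ix = {t: i for i, t in enumerate(taxa)}
    arr = np.zeros((len(years), len(sites), len(taxa)))
    yi = df["year"].astype(int).map(year_ix).to_numpy()
    si = df["site"].astype(str).map(site_ix).to_numpy()
    ti = df["taxon"].astype(str).map(taxon_ix).to_numpy()
    arr[yi, si, ti] = df["abundance"].to_numpy(dtype=float)
    return CommunityPanel(basin_id, sites, years, taxa, arr)


def read_community_table(path, sep: str | None = None) -> dict[str, CommunityPanel]:
    """Read a long-format community table into one panel per basin.

    The file must have columns ``basin,site,year,taxon,abundance``.  Within
    each basin the taxon list is the union over all records and absent
    taxon-site-year combinations are filled with zeros.  Duplicate
    (site, year, taxon) rows within a basin and negative abundances are
    hard errors.  No panel-construction rule is applied here; pass the
    result through :func:`select_panel` to enforce shared sampling years.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in COMMUNITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"community table missing columns {missing}")
    if (df["abundance"] < 0).any():
        bad = df.index[df["abundance"] < 0][0]
        raise ValueError(f"negative abundance at row {bad}: {df.loc[bad].to_dict()}")
    dup = df.duplicated(subset=["basin", "site", "year", "taxon"], keep=False)
    if dup.any():
        bad = df.index[dup][0]
        raise ValueError(
            f"duplicate (site, year, taxon) record at row {bad}: "
            f"{df.loc[bad, ['basin', 'site', 'year', 'taxon']].to_dict()}"
        )
    return {
        str(basin): _panel_from_long(str(basin), g)
        for basin, g in df.groupby("basin", sort=True)
    }


def write_community_table(panels: Mapping[str, CommunityPanel], path) -> None:
    """Write panels to a long-format CSV, dropping zero-abundance rows."""
    frames = []
    for basin in sorted(panels):
        long = panels[basin].to_long()
        frames.append(long[long["abundance"] > 0])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# panel-construction rule


def select_panel(
    records: pd.DataFrame | CommunityPanel,
    min_sites: int = 5,
    min_years: int = 5,
    drop_sites: bool = False,
) -> CommunityPanel | PanelRejection:
    """Enforce shared sampling years across all sites of one basin.

    With ``drop_sites=False`` (default) every site is kept and the years are
    intersected across sites.  With ``drop_sites=True`` a greedy search
    drops the site whose removal most improves sites x shared-years until
    no removal helps, maximising panel area.  The basin is rejected (a
    :class:`PanelRejection`, not an exception) when the result has fewer
    than ``min_sites`` sites or ``min_years`` years.
    """
    if isinstance(records, CommunityPanel):
        df = records.to_long()
        df = df[df["abundance"] > 0]
    else:
        df = records
    basin_ids = df["basin"].unique()
    if len(basin_ids) != 1:
        raise ValueError("select_panel operates on a single basin")
    basin_id = str(basin_ids[0])

    site_years = {
        str(s): frozenset(int(y) for y in g["year"].unique())
        for s, g in df.groupby("site")
    }

    def shared(sites: Sequence[str]) -> frozenset[int]:
        out = None
        for s in sites:
            out = site_years[s] if out is None else out & site_years[s]
        return out if out is not None else frozenset()

    sites = sorted(site_years)
    years = shared(sites)
    if drop_sites:
        improved = True
        while improved and len(sites) > min_sites:
            improved = False
            area = len(sites) * len(years)
            best = None
            for s in sites:
                rest = [t for t in sites if t != s]
                yr = shared(rest)
                if len(rest) * len(yr) > area:
                    area = len(rest) * len(yr)
                    best = (rest, yr)
            if best is not None:
                sites, years = best
                improved = True

    if len(sites) < min_sites:
        return PanelRejection(basin_id, "too_few_sites", len(sites), len(years))
    if len(years) < min_years:
        return PanelRejection(basin_id, "too_few_years", len(sites), len(years))

    keep = df[df["site"].astype(str).isin(sites) & df["year"].astype(int).isin(years)]
    return _panel_from_long(basin_id, keep)


# ---------------------------------------------------------------------------
# dataset validation


def validate_dataset(
    panels: Mapping[str, CommunityPanel],
    traits: TraitDatabase | None = None,
    metadata: SiteMetadata | None = None,
) -> dict:
    """Cross-check panels, traits and metadata; never mutates inputs.

    Returns a report dict with per-basin panel summaries and an ``issues``
    list of (code, detail) pairs, e.g. taxa with no trait information or
    site-years lacking EQR records.
    """
    issues: list[tuple[str, str]] = []
    summaries = {}
    all_taxa: set[str] = set()
    for basin, panel in panels.items():
        summaries[basin] = {
            "n_sites": panel.n_sites,
            "n_years": panel.n_years,
            "n_taxa": panel.n_taxa,
        }
        all_taxa.update(panel.taxon_ids)
        empty = np.argwhere(panel.abundance.sum(axis=2) == 0)
        for yi, si in empty:
            issues.append(
                (
                    "empty_community",
                    f"basin={basin} site={panel.sites[si]} year={panel.years[yi]}",
                )
            )
    if traits is not None:
        known = set(traits.taxa)
        for t in sorted(all_taxa - known):
            issues.append(("no_trait_information", t))
    if metadata is not None:
        eqr_keys = set(
            zip(metadata.eqr["basin"].astype(str), metadata.eqr["site"].astype(str))
        )
        for basin, panel in panels.items():
            for s in panel.sites:
                if (basin, s) not in eqr_keys:
                    issues.append(("missing_eqr", f"basin={basin} site={s}"))
            temp_b = metadata.temperature[
                metadata.temperature["basin"].astype(str) == basin
            ]
            if len(temp_b) < 3:
                issues.append(("short_temperature_series", f"basin={basin}"))
    return {"summaries": summaries, "issues": issues}


# ---------------------------------------------------------------------------
# trait table and metadata I/O


def read_trait_table(path) -> TraitDatabase:
    """Read the long-format trait CSV into a :class:`TraitDatabase`.

    Expected columns: ``taxon, parent_genus, parent_family, parent_order,
    block, modality, value, coding, block_class``.  Missing values may be
    encoded as empty cells.
    """
    df = pd.read_csv(path, dtype={"taxon": str}, keep_default_na=True)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns {missing}")
    blocks = []
    for name, g in df.groupby("block", sort=True):
        coding = g["coding"].dropna().unique()
        bclass = g["block_class"].dropna().unique()
        if len(coding) != 1 or len(bclass) != 1:
            raise ValueError(f"block {name!r} has inconsistent coding/class tags")
        mods = list(dict.fromkeys(g["modality"]))
        blocks.append(TraitBlock(str(name), [str(m) for m in mods], coding[0], bclass[0]))
    df["key"] = df["block"].astype(str) + "::" + df["modality"].astype(str)
    values = df.pivot_table(
        index="taxon", columns="key", values="value", aggfunc="first", dropna=False
    )
    order = [f"{b.name}::{m}" for b in blocks for m in b.modalities]
    values = values.reindex(columns=order)
    hier = (
        df.groupby("taxon")[["parent_genus", "parent_family", "parent_order"]]
        .first()
        .rename(
            columns={
                "parent_genus": "genus",
                "parent_family": "family",
                "parent_order": "order",
            }
        )
        .fillna("")
    )
    values = values.loc[hier.index]
    return TraitDatabase(blocks, values, hier)


def write_trait_table(db: TraitDatabase, path) -> None:
    rows = []
    for b in db.blocks:
        for m in b.modalities:
            key = f"{b.name}::{m}"
            for taxon in db.taxa:
                h = db.hierarchy.loc[taxon]
                rows.append(
                    {
                        "taxon": taxon,
                        "parent_genus": h["genus"],
                        "parent_family": h["family"],
                        "parent_order": h["order"],
                        "block": b.name,
                        "modality": m,
                        "value": db.values.at[taxon, key],
                        "coding": b.coding,
                        "block_class": b.block_class,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(directory) -> SiteMetadata:
    """Read ``eqr.csv``, ``temperature.csv`` and ``landcover.csv``."""
    import os

    eqr = pd.read_csv(os.path.join(directory, "eqr.csv"))
    temp = pd.read_csv(os.path.join(directory, "temperature.csv"))
    lc = pd.read_csv(os.path.join(directory, "landcover.csv"))
    return SiteMetadata(eqr=eqr, temperature=temp, land_cover=lc)


def write_metadata(meta: SiteMetadata, directory) -> None:
    import os

    os.makedirs(directory, exist_ok=True)
    meta.eqr.to_csv(os.path.join(directory, "eqr.csv"), index=False)
    meta.temperature.to_csv(os.path.join(directory, "temperature.csv"), index=False)
    meta.land_cover.to_csv(os.path.join(directory, "landcover.csv"), index=False)
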