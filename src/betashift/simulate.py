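"""Synthetic metacommunity generator with known beta-diversity regime.

Emulates annual invertebrate monitoring panels: each basin holds 5-32 sites
sampled over 5-20 shared years, with a year-0 community drawn from a
log-normal abundance law over a taxon pool and subsequent years perturbed
by gain and loss events.  An event is *shared* (same taxon, same change at
every site) with probability ``shared_fraction(s)`` of the basin's
anthropogenic stress level s, else *distinct* (each site changes its own
taxon).  Shared gains push sites toward each other (homogenization),
distinct gains apart (differentiation); losses behave inversely, which is
the directional contrast the downstream partitioning is designed to see.

Stress also drives the emitted covariates: ecological quality decreases
with s, the temperature slope and urban land-cover share increase with s,
each with Gaussian noise of one fifth of the covariate's range.  Every
event is logged in a ground-truth record that replays exactly to the
emitted abundance arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .panels import CommunityPanel, SiteMetadata, TraitBlock, TraitDatabase

__all__ = [
    "SimConfig",
    "TraitBlockSpec",
    "default_trait_blocks",
    "generate_metacommunity",
    "generate_trait_database",
    "replay_events",
]


@dataclass(frozen=True)
class TraitBlockSpec:
    name: str
    n_modalities: int
    coding: str  # ten_point | fuzzy | single
    block_class: str  # biological | ecological


def default_trait_blocks() -> list[TraitBlockSpec]:
    """Trait set mirroring standard invertebrate databases: six biological
    traits (life history / morphology) and three ecological preferences."""
    return [
        TraitBlockSpec("aquatic_stages", 4, "fuzzy", "biological"),
        TraitBlockSpec("dispersal", 4, "fuzzy", "biological"),
        TraitBlockSpec("voltinism", 3, "ten_point", "biological"),
        TraitBlockSpec("feeding_habits", 6, "ten_point", "biological"),
        TraitBlockSpec("resistance_forms", 5, "single", "biological"),
        TraitBlockSpec("body_size", 7, "fuzzy", "biological"),
        TraitBlockSpec("temperature_preference", 6, "ten_point", "ecological"),
        TraitBlockSpec("microhabitat", 7, "ten_point", "ecological"),
        TraitBlockSpec("saprobity", 5, "ten_point", "ecological"),
    ]


def _identity(s: float) -> float:
    return s


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults reflect the monitored system: mid-range basin sizes (8 sites,
    10 years, the medians of the 5-32 / 5-20 ranges), a log-normal
    abundance law, one expected gain event per year and a smaller loss
    rate (the system is recovering, so gains dominate), and the identity
    link between stress and the probability that an event is spatially
    shared.
    """

    n_basins: int = 8
    sites_per_basin: int = 8  # monitoring basins span 5-32 sites, median 8
    years_per_basin: int = 10  # series span 5-20 years, median 10
    start_year: int = 2000
    n_taxa_pool: int = 150  # regional pool, far larger than local richness
    baseline_log_mean: float = 2.5  # log-normal abundance law
    baseline_log_sd: float = 1.0
    baseline_occupancy: float = 0.2  # P(taxon present at a site in year 0)
    site_log_sd: float = 0.5  # site-level abundance heterogeneity
    gain_rate: float = 1.0  # expected gain events / year
    loss_rate: float = 0.25  # expected loss events / year
    loss_severity: tuple[float, float] = (0.5, 1.0)  # uniform range
    stress: Sequence[float] | None = None  # basin -> s in [0,1]; default even grid
    shared_fraction: Callable[[float], float] = _identity
    stress_schedule: Callable[[float, float], float] | None = None
    # (basin stress s, time fraction in [0,1]) -> effective stress that year
    trait_blocks: list[TraitBlockSpec] = field(default_factory=default_trait_blocks)
    missingness: dict = field(
        default_factory=lambda: {"species": 0.25, "genus": 0.10, "family": 0.0}
    )
    trait_icc: float = 0.7  # within-genus trait similarity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa_pool <= 0 or self.years_per_basin <= 0:
            raise ValueError("degenerate config: need > 0 taxa and > 0 years")
        if self.n_basins <= 0 or self.sites_per_basin <= 0:
            raise ValueError("degenerate config: need > 0 basins and sites")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("event rates must be >= 0")

    def basin_stress(self) -> np.ndarray:
        if self.stress is not None:
            s = np.asarray(self.stress, dtype=float)
            if len(s) != self.n_basins:
                raise ValueError("stress vector length != n_basins")
            return s
        if self.n_basins == 1:
            return np.array([0.5])
        return np.linspace(0.0, 1.0, self.n_basins)


def _basin_rng(seed: int, basin_index: int) -> np.random.Generator:
    # counter-derived substream: adding a basin never perturbs the others
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(basin_index,))
    )


def _taxon_pool(n: int) -> pd.DataFrame:
    """Species pool with nested genus/family/order structure (3 species per
    genus, 3 genera per family, 3 families per order)."""
    rows = []
    for i in range(n):
        g, f, o = i // 3, i // 9, i // 27
        rows.append(
            {
                "taxon": f"sp{i:03d}",
                "genus": f"g{g:02d}",
                "family": f"f{f:02d}",
                "order": f"o{o:02d}",
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def _simulate_basin(config: SimConfig, basin_index: int, s: float, rng):
    ns, ny, nt = config.sites_per_basin, config.years_per_basin, config.n_taxa_pool
    taxa = [f"sp{i:03d}" for i in range(nt)]
    # year-0 baseline: basin-level taxon means, thinned per site
    m = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=nt)
    present = rng.random((ns, nt)) < config.baseline_occupancy
    # guarantee non-empty starting communities
    for i in range(ns):
        if not present[i].any():
            present[i, rng.integers(nt)] = True
    X0 = np.where(
        present, m[None, :] * rng.lognormal(0.0, config.site_log_sd, size=(ns, nt)), 0.0
    )
    abundance = np.zeros((ny, ns, nt))
    abundance[0] = X0
    events = []
    for t in range(1, ny):
        X = abundance[t - 1].copy()
        frac = t / max(ny - 1, 1)
        s_t = s if config.stress_schedule is None else config.stress_schedule(s, frac)
        p_shared = float(np.clip(config.shared_fraction(s_t), 0.0, 1.0))
        n_gain = rng.poisson(config.gain_rate)
        n_loss = rng.poisson(config.loss_rate)
        for kind, count in (("gain", n_gain), ("loss", n_loss)):
            for _ in range(count):
                shared = bool(rng.random() < p_shared)
                deltas = []  # (site index, taxon index, signed delta)
                if kind == "gain":
                    if shared:
                        # basin-wide event: the same taxon gains the same
                        # amount everywhere, pulling sites together
                        k = int(rng.integers(nt))
                        a = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)
                        for i in range(ns):
                            deltas.append((i, k, float(a)))
                    else:
                        # site-specific event: each site either establishes a
                        # taxon absent from the whole basin or boosts one of
                        # its own exclusive taxa, so different sites gain
                        # different taxa (the differentiation mechanism)
                        used: set[int] = set()
                        occupied_elsewhere = X.sum(axis=0)
                        for i in rng.permutation(ns):
                            basin_absent = [
                                k
                                for k in np.flatnonzero(occupied_elsewhere <= 0)
                                if k not in used
                            ]
                            exclusive = [
                                k
                                for k in np.flatnonzero(
                                    (X[i] > 0) & (X.sum(axis=0) - X[i] <= 0)
                                )
                                if k not in used
                            ]
                            site_absent = [
                                k for k in np.flatnonzero(X[i] <= 0) if k not in used
                            ]
                            for candidates in (basin_absent, exclusive, site_absent):
                                if candidates:
                                    k = int(rng.choice(candidates))
                                    break
                            else:
                                k = int(rng.integers(nt))
                            used.add(k)
                            a = rng.lognormal(
                                config.baseline_log_mean, config.baseline_log_sd
                            )
                            deltas.append((int(i), k, float(a)))
                else:
                    sev = rng.uniform(*config.loss_severity)
                    if shared:
                        occupied = np.flatnonzero(X.sum(axis=0) > 0)
                        if len(occupied) == 0:
                            continue
                        k = int(rng.choice(occupied))
                        for i in range(ns):
                            deltas.append((i, k, float(-sev * X[i, k])))
                    else:
                        for i in range(ns):
                            occ = np.flatnonzero(X[i] > 0)
                            if len(occ) == 0:
                                continue
                            k = int(rng.choice(occ))
                            deltas.append((i, k, float(-sev * X[i, k])))
                for i, k, d in deltas:
                    X[i, k] = max(X[i, k] + d, 0.0)
                events.append(
                    {"year_index": t, "kind": kind, "shared": shared, "deltas": deltas}
                )
        # floor: keep every site-year community non-empty
        for i in range(ns):
            if X[i].sum() <= 0:
                k = int(rng.integers(nt))
                X[i, k] = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd)
                events.append(
                    {
                        "year_index": t,
                        "kind": "rescue_gain",
                        "shared": False,
                        "deltas": [(i, k, float(X[i, k]))],
                    }
                )
        abundance[t] = X
    basin_id = f"basin{basin_index:02d}"
    sites = [f"{basin_id}_s{i:02d}" for i in range(ns)]
    years = list(range(config.start_year, config.start_year + ny))
    panel = CommunityPanel(basin_id, sites, years, taxa, abundance)
    truth = {
        "stress": float(s),
        "mean_shared_fraction": float(
            np.mean([e["shared"] for e in events if e["kind"] != "rescue_gain"])
        )
        if any(e["kind"] != "rescue_gain" for e in events)
        else None,
        "events": events,
        "baseline": X0.tolist(),
    }
    return panel, truth


def _basin_metadata(config: SimConfig, panel: CommunityPanel, s: float, rng):
    """Stress-linked covariates; noise sd = 20% of each driver's range."""
    ns, ny = panel.n_sites, panel.n_years
    eqr_rows = []
    eqr_mean = 0.9 - 0.6 * s  # range 0.6 over s in [0,1]
    for site in panel.sites:
        for year in panel.years:
            eqr_rows.append(
                {
                    "basin": panel.basin_id,
                    "site": site,
                    "year": year,
                    "eqr": max(eqr_mean + rng.normal(0.0, 0.12), 0.0),
                }
            )
    slope = 0.01 + 0.06 * s + rng.normal(0.0, 0.012)  # degC / yr, range 0.06
    base = rng.normal(10.0, 1.5)
    temp_rows = [
        {
            "basin": panel.basin_id,
            "year": year,
            "temp_c": base + slope * (year - panel.years[0]) + rng.normal(0.0, 0.2),
        }
        for year in panel.years
    ]
    lc_rows = []
    urban0 = 0.05 + 0.40 * s
    forest0 = 0.75 - 0.55 * s
    for site in panel.sites:
        for year in panel.years:
            urban = float(np.clip(urban0 + rng.normal(0.0, 0.08), 0.0, 1.0))
            forest = float(np.clip(forest0 + rng.normal(0.0, 0.11), 0.0, 1.0))
            agri = float(np.clip(1.0 - urban - forest + rng.normal(0.0, 0.05), 0.0, 1.0))
            lc_rows.append(
                {
                    "basin": panel.basin_id,
                    "site": site,
                    "year": year,
                    "forest": forest,
                    "urban": urban,
                    "agriculture": agri,
                }
            )
    return eqr_rows, temp_rows, lc_rows, slope


def generate_metacommunity(config: SimConfig, seed: int | None = None):
    """Generate panels, covariates, a trait database and the ground truth.

    Returns ``(panels, metadata, traits, ground_truth)``.  ``ground_truth``
    maps basin ids to the stress level, the realized shared-event fraction,
    the generating temperature slope and the full event log; the log
    replays exactly to the emitted abundance arrays
    (:func:`replay_events`).  Same seed and config give bit-identical
    output; basin substreams are counter-derived so adding a basin leaves
    earlier basins untouched.
    """
    if seed is not None:
        config = replace(config, seed=seed)
    stress = config.basin_stress()
    panels: dict[str, CommunityPanel] = {}
    truth: dict[str, dict] = {}
    eqr_rows, temp_rows, lc_rows = [], [], []
    for b in range(config.n_basins):
        rng = _basin_rng(config.seed, b)
        panel, basin_truth = _simulate_basin(config, b, float(stress[b]), rng)
        e, t, l, slope = _basin_metadata(config, panel, float(stress[b]), rng)
        basin_truth["temp_slope_true"] = float(slope)
        panels[panel.basin_id] = panel
        truth[panel.basin_id] = basin_truth
        eqr_rows += e
        temp_rows += t
        lc_rows += l
    metadata = SiteMetadata(
        eqr=pd.DataFrame(eqr_rows),
        temperature=pd.DataFrame(temp_rows),
        land_cover=pd.DataFrame(lc_rows),
    )
    pool = _taxon_pool(config.n_taxa_pool)
    traits = generate_trait_database(
        pool,
        config.trait_blocks,
        config.missingness,
        seed=np.random.SeedSequence(entropy=config.seed, spawn_key=(10_000,)),
        icc=config.trait_icc,
    )
    return panels, metadata, traits, truth


def replay_events(truth: dict, panel: CommunityPanel) -> np.ndarray:
    """Rebuild the abundance array from the baseline and the event log."""
    X = np.array(truth["baseline"], dtype=float)
    out = np.zeros_like(panel.abundance)
    out[0] = X
    by_year: dict[int, list] = {}
    for e in truth["events"]:
        by_year.setdefault(e["year_index"], []).append(e)
    for t in range(1, panel.n_years):
        X = X.copy()
        for e in by_year.get(t, []):
            for i, k, d in e["deltas"]:
                X[i, k] = max(X[i, k] + d, 0.0)
        out[t] = X
    return out


# ---------------------------------------------------------------------------
# trait database generation


def _encode(prop: np.ndarray, coding: str, rng) -> np.ndarray:
    if coding == "single":
        out = np.zeros_like(prop)
        out[np.argmax(prop)] = 1.0
        return out
    scale = 10 if coding == "ten_point" else 5
    raw = prop * scale
    ints = np.floor(raw)
    rem = raw - ints
    short = int(round(scale - ints.sum()))
    if short > 0:
        for j in np.argsort(-rem)[:short]:
            ints[j] += 1
    if ints.sum() == 0:
        ints[np.argmax(prop)] = 1
    return ints


def generate_trait_database(
    taxon_pool: pd.DataFrame,
    trait_blocks: Sequence[TraitBlockSpec],
    missingness: dict,
    seed,
    icc: float = 0.7,
) -> TraitDatabase:
    """Trait table over the species pool plus genus- and family-level rows.

    Species profiles are convex mixtures of a genus archetype and an
    individual Dirichlet draw, so trait values are correlated within genus
    (mixture weight ``icc``) and hierarchical imputation is meaningful.
    Each (taxon, block) cell is set missing with the rate configured for
    the taxon's rank (species / genus / family).
    """
    rng = np.random.default_rng(seed)
    blocks = [
        TraitBlock(s.name, [f"m{j}" for j in range(s.n_modalities)], s.coding, s.block_class)
        for s in trait_blocks
    ]
    genera = sorted(taxon_pool["genus"].unique())
    families = sorted(taxon_pool["family"].unique())
    gen_family = taxon_pool.groupby("genus")["family"].first()
    gen_order = taxon_pool.groupby("genus")["order"].first()
    fam_order = taxon_pool.groupby("family")["order"].first()

    archetype = {
        (g, s.name): rng.dirichlet(np.full(s.n_modalities, 0.8))
        for g in genera
        for s in trait_blocks
    }
    fam_arch = {}
    for f in families:
        gs = [g for g in genera if gen_family[g] == f]
        for s in trait_blocks:
            fam_arch[(f, s.name)] = np.mean([archetype[(g, s.name)] for g in gs], axis=0)

    rows: dict[str, dict] = {}
    hier_rows = []

    def add_taxon(taxon, genus, family, order, level, profiles):
        rate = missingness.get(level, 0.0)
        rec = {}
        for s, prop in zip(trait_blocks, profiles):
            cols = [f"{s.name}::m{j}" for j in range(s.n_modalities)]
            if rng.random() < rate:
                vals = [np.nan] * s.n_modalities
            else:
                vals = _encode(np.asarray(prop, dtype=float), s.coding, rng)
            rec.update(dict(zip(cols, vals)))
        rows[taxon] = rec
        hier_rows.append(
            {"taxon": taxon, "genus": genus, "family": family, "order": order}
        )

    for taxon, h in taxon_pool.iterrows():
        profiles = []
        for s in trait_blocks:
            own = rng.dirichlet(np.full(s.n_modalities, 0.8))
            profiles.append(icc * archetype[(h["genus"], s.name)] + (1 - icc) * own)
        add_taxon(taxon, h["genus"], h["family"], h["order"], "species", profiles)
    for g in genera:
        profiles = [archetype[(g, s.name)] for s in trait_blocks]
        add_taxon(g, "", gen_family[g], gen_order[g], "genus", profiles)
    for f in families:
        profiles = [fam_arch[(f, s.name)] for s in trait_blocks]
        add_taxon(f, "", "", fam_order[f], "family", profiles)

    order_cols = [f"{b.name}::{m}" for b in blocks for m in b.modalities]
    values = pd.DataFrame.from_dict(rows, orient="index")[order_cols]
    hierarchy = pd.DataFrame(hier_rows).set_index("taxon")
    values = values.loc[hierarchy.index]
    return TraitDatabase(blocks, values, hierarchy)
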