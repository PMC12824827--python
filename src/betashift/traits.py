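"""Trait normalization, hierarchical imputation, block weighting and CWMs.

Invertebrate trait databases mix coding systems: 10-point assignments,
fuzzy scores and single (one-hot) assignments.  All are made comparable by
dividing each taxon's values within a trait block by the block row sum, so
every resolved row is a proportion vector summing to 1.  Missing rows are
filled from the taxonomic hierarchy (a parent rank's own entry first, then
the mean over relatives sharing the nearest resolvable ancestor); taxa that
stay unresolved are dropped from trait analyses but kept for taxonomic ones.

Block weights equalize the mean contribution of each trait to the overall
Gower-type dissimilarity, so traits with many modalities do not dominate
the community-weighted means used for trait beta-diversity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import gower_block_dissimilarity
from .panels import TraitBlock, TraitDatabase

__all__ = [
    "NormalizedTraits",
    "normalize_trait_blocks",
    "impute_traits",
    "compute_block_weights",
    "community_weighted_means",
    "trait_coverage_report",
    "make_cwm_provider",
]

log = logging.getLogger(__name__)

PROVENANCE_LEVELS = ("provided", "parent_rank", "group_mean", "dropped")


@dataclass
class NormalizedTraits:
    """Normalized (and possibly imputed) trait proportions.

    ``values``: taxon x "block::modality" proportions; NaN where a taxon's
    block is unresolved.  ``provenance``: taxon x block labels from
    :data:`PROVENANCE_LEVELS` ('dropped' only after imputation).
    ``weights``: block name -> scalar weight (None until computed).
    """

    blocks: list[TraitBlock]
    values: pd.DataFrame
    provenance: pd.DataFrame
    hierarchy: pd.DataFrame
    weights: dict | None = None

    def block_columns(self, name: str) -> list[str]:
        for b in self.blocks:
            if b.name == name:
                return [f"{name}::{m}" for m in b.modalities]
        raise KeyError(name)

    def blocks_of_class(self, block_class: str) -> list[TraitBlock]:
        return [b for b in self.blocks if b.block_class == block_class]

    def resolved_taxa(self, block_names=None) -> pd.Index:
        """Taxa resolved (not NaN) for every listed block (default: all)."""
        names = [b.name for b in self.blocks] if block_names is None else list(block_names)
        cols = [c for n in names for c in self.block_columns(n)]
        return self.values.index[~self.values[cols].isna().any(axis=1)]


def normalize_trait_blocks(db: TraitDatabase) -> NormalizedTraits:
    """Divide each taxon's block values by the block row sum.

    All-zero or all-missing rows are flagged missing (NaN), not
    zero-filled; a partially missing row is treated as missing as well,
    since affinity scores are only interpretable as a complete profile.
    Negative values are a hard error.
    """
    if (db.values < 0).any().any():
        raise ValueError("negative trait value")
    values = pd.DataFrame(index=db.values.index, columns=db.values.columns, dtype=float)
    prov = pd.DataFrame(
        "dropped", index=db.values.index, columns=[b.name for b in db.blocks]
    )
    for b in db.blocks:
        cols = db.block_columns(b.name)
        block = db.values[cols].astype(float)
        sums = block.sum(axis=1, skipna=False)
        ok = (~block.isna().any(axis=1)) & (sums > 0)
        values.loc[ok, cols] = block.loc[ok].div(sums[ok], axis=0)
        values.loc[~ok, cols] = np.nan
        prov.loc[ok, b.name] = "provided"
        prov.loc[~ok, b.name] = "missing"
    return NormalizedTraits(list(db.blocks), values, prov, db.hierarchy.copy())


def _check_acyclic(hier: pd.DataFrame) -> None:
    # parent chain is rank-structured; a cycle exists iff some taxon is its
    # own ancestor through the genus/family/order columns
    parent = {}
    for taxon, row in hier.iterrows():
        chain = [v for v in (row.get("genus", ""), row.get("family", ""), row.get("order", "")) if v]
        parent[taxon] = chain[0] if chain else None
    for taxon in parent:
        seen = {taxon}
        cur = parent.get(taxon)
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cyclic taxonomic hierarchy at {taxon!r}")
            seen.add(cur)
            cur = parent.get(cur)


def impute_traits(norm: NormalizedTraits) -> NormalizedTraits:
    """Fill missing taxon-block rows from the taxonomic hierarchy.

    For each missing (taxon, block): first copy the nearest ancestor's own
    database entry (genus entry for a species, then family, then order);
    failing that, use the mean of normalized rows across taxa sharing the
    nearest ancestor that yields at least one resolved taxon; failing both,
    mark the block 'dropped' for that taxon.  Idempotent: a second pass
    changes nothing.
    """
    hier = norm.hierarchy
    _check_acyclic(hier)
    values = norm.values.copy()
    prov = norm.provenance.copy()
    ancestors = {
        taxon: [
            a
            for a in (
                hier.at[taxon, "genus"] if "genus" in hier.columns else "",
                hier.at[taxon, "family"] if "family" in hier.columns else "",
                hier.at[taxon, "order"] if "order" in hier.columns else "",
            )
            if a
        ]
        for taxon in values.index
    }
    for b in norm.blocks:
        cols = norm.block_columns(b.name)
        base = norm.values[cols]  # pre-imputation state: fills never cascade
        resolved = ~base.isna().any(axis=1)
        for taxon in values.index[~resolved]:
            filled = False
            for anc in ancestors[taxon]:
                if anc in base.index and resolved.loc[anc]:
                    values.loc[taxon, cols] = base.loc[anc].to_numpy()
                    prov.at[taxon, b.name] = "parent_rank"
                    filled = True
                    break
            if filled:
                continue
            for rank in ("genus", "family", "order"):
                if rank not in hier.columns:
                    continue
                anc = hier.at[taxon, rank]
                if not anc:
                    continue
                group = hier.index[(hier[rank] == anc) & resolved.reindex(hier.index, fill_value=False)]
                group = group.difference([taxon])
                if len(group):
                    values.loc[taxon, cols] = base.loc[group].mean(axis=0).to_numpy()
                    prov.at[taxon, b.name] = "group_mean"
                    filled = True
                    break
            if not filled:
                prov.at[taxon, b.name] = "dropped"
    return NormalizedTraits(norm.blocks, values, prov, hier.copy(), norm.weights)


def compute_block_weights(norm: NormalizedTraits, tol: float = 1e-8, max_iter: int = 100) -> dict:
    """Per-block weights equalizing mean contributions to trait dissimilarity.

    The contribution of block b under weights w is ``w_b * c_b`` with
    ``c_b`` the mean over resolved taxon pairs of the block's normalized
    dissimilarity (half-L1 on proportion rows, in [0, 1]).  The analytic
    balance point is ``w_b ∝ 1 / c_b``; the fixed-point loop re-evaluates
    until weights are stable (the c_b do not depend on w, so convergence is
    immediate, but the loop guards future weighted-c variants).  Weights
    are normalized to sum to 1.  A block constant across all taxa (c_b = 0)
    cannot be balanced: it gets the mean weight of the remaining blocks and
    a warning is logged.
    """
    if len(norm.values.index) < 2:
        raise ValueError("need at least 2 taxa to balance block weights")
    c = {}
    for b in norm.blocks:
        D = gower_block_dissimilarity(norm.values[norm.block_columns(b.name)].to_numpy())
        iu = np.triu_indices(D.shape[0], k=1)
        vals = D[iu]
        vals = vals[~np.isnan(vals)]
        c[b.name] = float(vals.mean()) if len(vals) else 0.0
    live = [n for n, v in c.items() if v > 0]
    degenerate = [n for n, v in c.items() if v <= 0]
    if not live:
        raise ValueError("all trait blocks are constant; weights undefined")
    w = {n: 1.0 / len(live) for n in live}
    for _ in range(max_iter):
        new = {n: 1.0 / c[n] for n in live}
        total = sum(new.values())
        new = {n: v / total for n, v in new.items()}
        if max(abs(new[n] - w[n]) for n in live) < tol:
            w = new
            break
        w = new
    if degenerate:
        warnings.warn(
            f"trait blocks with zero variance assigned mean weight: {degenerate}",
            RuntimeWarning,
            stacklevel=2,
        )
        mean_w = float(np.mean([w[n] for n in live]))
        for n in degenerate:
            w[n] = mean_w
        total = sum(w.values())
        w = {n: v / total for n, v in w.items()}
    return w


def community_weighted_means(
    abundances,
    norm: NormalizedTraits,
    weights: dict | None = None,
    block_names=None,
    strict: bool = False,
    apply_weights: bool = True,
) -> pd.DataFrame:
    """Site x modality community-weighted means for one basin-year.

    ``abundances`` is a site x taxon frame (columns = taxon ids).  Per
    block, relative abundances are renormalized over the taxa resolved for
    that block (``strict=True`` errors instead when any community member is
    unresolved), then CWM(site, modality) = sum_t p(t|site) * trait(t, m).
    With ``apply_weights`` the modality columns are scaled by their block's
    weight, which is the form consumed by trait beta-diversity.
    """
    A = abundances if isinstance(abundances, pd.DataFrame) else pd.DataFrame(abundances)
    if (A.sum(axis=1) <= 0).any():
        raise ValueError("site with zero total abundance")
    blocks = norm.blocks if block_names is None else [b for b in norm.blocks if b.name in set(block_names)]
    if weights is None:
        weights = {b.name: 1.0 for b in blocks}
    out = {}
    for b in blocks:
        cols = norm.block_columns(b.name)
        T = norm.values[cols]
        resolved = T.index[~T.isna().any(axis=1)]
        taxa = [t for t in A.columns if t in set(resolved)]
        if strict:
            active = A.columns[(A > 0).any(axis=0)]
            unresolved = [t for t in active if t not in set(resolved)]
            if unresolved:
                raise ValueError(
                    f"block {b.name!r}: unresolved taxa in community: {unresolved[:5]}"
                )
        sub = A[taxa].to_numpy(dtype=float)
        totals = sub.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError(
                f"block {b.name!r}: a site has no resolved taxa with positive abundance"
            )
        P = sub / totals[:, None]
        cwm = P @ T.loc[taxa].to_numpy()
        if apply_weights:
            cwm = cwm * weights[b.name]
        for j, col in enumerate(cols):
            out[col] = cwm[:, j]
    return pd.DataFrame(out, index=A.index)


def trait_coverage_report(norm: NormalizedTraits) -> pd.DataFrame:
    """Fraction of taxa at each provenance level, per block and overall."""
    rows = []
    n = len(norm.provenance.index)
    for b in norm.blocks:
        counts = norm.provenance[b.name].value_counts()
        row = {"block": b.name, "block_class": b.block_class, "n_taxa": n}
        for level in PROVENANCE_LEVELS:
            row[level] = counts.get(level, 0) / n if n else 0.0
        row["missing"] = counts.get("missing", 0) / n if n else 0.0
        row["coverage"] = row["provided"] + row["parent_rank"] + row["group_mean"]
        rows.append(row)
    return pd.DataFrame(rows)


def prepare_traits(db: TraitDatabase) -> NormalizedTraits:
    """normalize -> impute -> weight, the canonical preparation order."""
    norm = impute_traits(normalize_trait_blocks(db))
    norm.weights = compute_block_weights(norm)
    return norm


def make_cwm_provider(norm: NormalizedTraits, strict: bool = False):
    """Provider callable for :func:`betashift.diversity.beta_series`.

    Returns ``(panel, year, block_class) -> site x modality matrix`` of
    weight-scaled CWMs, or None when no taxa resolve for that class.
    """
    if norm.weights is None:
        raise ValueError("block weights not computed; call compute_block_weights")

    def provider(panel, year, block_class):
        blocks = norm.blocks_of_class(block_class)
        if not blocks:
            return None
        A = panel.year_matrix(year)
        known = [t for t in A.columns if t in norm.values.index]
        try:
            cwm = community_weighted_means(
                A[known],
                norm,
                norm.weights,
                block_names=[b.name for b in blocks],
                strict=strict,
            )
        except ValueError:
            return None
        return cwm.to_numpy()

    return provider
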