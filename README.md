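# betashift

Temporal β-diversity analysis for river invertebrate metacommunities:
do recovering communities **differentiate** (β-diversity rises) or
**homogenize** (β-diversity falls), and how does the answer depend on
anthropogenic stress?

The package is aimed at freshwater community ecologists working with
long-term biomonitoring panels — annual site × taxon abundance samples
grouped into river basins — together with a taxon trait database and
basin-level stress descriptors (ecological quality ratio, warming rate,
land-cover composition).

## What it computes

For each basin *b* and year *t* the package builds a site × feature
matrix — raw taxon abundances, or community-weighted mean (CWM) trait
profiles — and summarises among-site compositional variation with the
**multiple-site abundance-based Bray–Curtis dissimilarity**. With
*A* the summed pairwise shared abundance and, for each site pair, the two
one-directional exclusive abundance sums *b\_ij*, *b\_ji*:

```
min_b = Σ_pairs min(b_ij, b_ji)        max_b = Σ_pairs max(b_ij, b_ji)

β_bal = min_b / (min_b + A)                              (balanced variation)
β_gra = A/(min_b + A) · (max_b − min_b)/(2A + min_b + max_b)   (abundance gradient)
β_tot = (min_b + max_b) / (2A + min_b + max_b)
```

with β_bal + β_gra = β_tot exactly, and β_tot reducing to the classic
pairwise Bray–Curtis (B + C)/(2A + B + C) for two sites.

Around this statistic the package provides:

* **Trait engine** — mixed-coding trait blocks (10-point, fuzzy, single
  assignment) normalized to within-block proportions, hierarchically
  imputed (genus → family → order entries, then group means), balanced
  with per-block weights `w_b ∝ 1/c̄_b` so every trait contributes
  equally to Gower-type dissimilarity, and aggregated into
  abundance-weighted CWM matrices.
* **Trend inference** — beta-likelihood mixed models on the logit scale:
  `β ~ year + (1|basin)`, `β ~ basin + basin:year`, and
  `β ~ driver × year + (1|basin)`, with Gaussian random intercepts
  integrated by adaptive Gauss–Hermite quadrature; Gaussian LMMs for
  local taxonomic and functional richness trends (via statsmodels).
* **Gain/loss partitioning** — the change in any β statistic between two
  years split exactly into an **additive** (abundance gains) and a
  **subtractive** (abundance losses) component via intermediate-matrix
  evaluation, with Shapley attribution to individual taxa or trait
  modalities.
* **Stress drivers** — basin mean EQR, the OLS temperature slope, and
  oriented principal components of forest/urban/agriculture cover.
* **Synthetic metacommunities** — a seeded event-based generator whose
  gain/loss events are spatially *shared* (→ homogenization) or
  *site-specific* (→ differentiation) with a probability tied to a basin
  stress level, giving every downstream stage a known ground truth.

## Worked example

```python
from betashift import SimConfig, generate_metacommunity, fit_beta_mixed
from betashift.diversity import beta_series
from betashift.traits import prepare_traits, make_cwm_provider

cfg = SimConfig(n_basins=8, seed=7)          # stress gradient over 8 basins
panels, metadata, traits, truth = generate_metacommunity(cfg)
norm = prepare_traits(traits)                # normalize -> impute -> weight
beta = beta_series(panels, make_cwm_provider(norm))
print(beta.head(4))

fit = fit_beta_mixed(beta[beta.index_type == "ecological"], "overall")
print(fit.summary())
```

prints

```
  basin  year index_type  beta_total  beta_balanced  beta_gradient  n_sites
basin00  2000  taxonomic    0.868552       0.853409   1.514291e-02        8
basin00  2000 biological    0.137470       0.137470   2.775558e-17        8
basin00  2000 ecological    0.105807       0.105807   2.775558e-17        8
basin00  2001  taxonomic    0.878958       0.868130   1.082716e-02        8

beta-diversity trend model [overall]
BetaMixedModel results (logit link, ML)
  n obs: 80   log-likelihood: 293.2016   converged: True
  precision phi: 3481.3097   random-intercept var: 0.007047

           coef  std err         z    P>|z|   [0.025   0.975]
const  -2.10091  0.03030 -69.34228  0.00000 -2.16030 -2.04153
year_c -0.01475  0.00212  -6.96204  0.00000 -0.01890 -0.01060
```

Trait β-diversity (CWM-based) is much lower than taxonomic β because
community trait profiles are far more similar among sites than taxon
lists. The fitted year coefficient (−0.0148 on the logit scale per year,
p < 10⁻¹¹) says ecological-trait composition homogenized across this
simulated basin set, whose stress gradient makes shared (homogenizing)
events dominate in most basins.

A full pipeline run — panels → traits → β series → drivers → mixed-model
trends → gain/loss partition → figure-analog plots — is driven by one
YAML config:

```sh
betashift run --config run.yaml
betashift report --run-dir run/
```

See `betashift --help` for the individual `simulate / traits / beta /
partition / drivers / trends` subcommands.

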