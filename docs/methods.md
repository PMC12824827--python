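# Methods

This note documents the models and procedures implemented in `betashift`,
the assumptions behind them, the defaults that matter, and what the
simulation-based tests do and do not demonstrate.

## Data model and panel construction

The unit of analysis is the river basin, treated as a metacommunity of
hydrologically connected sites sampled once a year. A `CommunityPanel`
is a complete year × site × taxon array: every retained site contributes
every retained year. Raw monitoring tables are rarely complete, so
`select_panel` enforces the shared-year rule. Two strategies are
exposed because the upstream rule is genuinely open:

* default — keep all sites, intersect their year sets;
* `drop_sites=True` — greedily drop the site whose removal most
  increases sites × shared-years (a panel-area criterion).

Basins falling below 5 sites or 5 years after selection are *rejected
values*, not errors, carrying a reason code. Abundances are non-negative
floats throughout; no integer assumption is made anywhere downstream, so
densities are as valid as counts.

## Trait engine

Invertebrate trait databases mix 10-point assignments, fuzzy scores and
single assignments. All are made comparable by dividing each taxon's
values within a trait block by the block row sum, producing per-block
proportion vectors that sum to 1 (tolerance 1e-9). Rows that are all
zero or contain missing cells are flagged missing rather than
zero-filled: a partial affinity profile is not interpretable as a
proportion.

Missing taxon-blocks are imputed from the taxonomic hierarchy in two
steps: (1) copy the nearest ancestor's *own* database entry (genus entry
for a species, then family, then order); (2) failing that, average the
normalized rows of taxa sharing the nearest ancestor that yields at
least one resolved taxon. Taxa resolving nothing are dropped from trait
analyses but kept for taxonomic ones. Imputation operates on
*normalized* proportions so every fill is itself a valid proportion, and
fills are computed from the pre-imputation state so they never cascade;
this makes the operation idempotent (a tested invariant). Provenance
(`provided / parent_rank / group_mean / dropped`) is recorded per
taxon-block and summarized by `trait_coverage_report`.

Blocks with different modality counts contribute unequally to raw
Gower-type dissimilarity. `compute_block_weights` equalizes them
analytically: with `c_b` the mean over resolved taxon pairs of the
block's dissimilarity (half-L1 between proportion rows, in [0, 1]), the
balance point is `w_b ∝ 1/c_b`, normalized to sum to 1. The fixed-point
loop (tolerance 1e-8, max 100 iterations) converges in one pass because
`c_b` does not depend on the weights; it is kept for forward
compatibility with weighted-`c` variants. A zero-variance block cannot
be balanced and receives the mean weight of the remaining blocks with a
warning.

CWMs use relative abundances renormalized over the taxa resolved for the
block (matching the removal of no-trait taxa); a strict mode errors
instead. CWM modality columns are scaled by their block weight before
entering β-diversity, so each trait contributes evenly there too.

## Diversity metrics

`multisite_bray` implements the multiple-site abundance-based
Bray–Curtis family (balanced-variation and abundance-gradient
components; formulas in the README). The components add exactly to the
total, the two-site case reduces to pairwise Bray–Curtis, and the value
is invariant to scaling the whole matrix and to row/column permutations
— all tested at scale against an independently coded transcription of
the component formulas. Taxonomic matrices enter with raw abundances by
default (`relative=True` switches to within-site relative abundances);
trait matrices enter as weight-scaled CWMs.

Functional richness is the convex-hull volume of a community's taxa in a
PCoA ordination of the square-root-transformed weighted Gower
dissimilarity (the square-root transform pre-corrects negative
eigenvalues; Cailliez correction would be an alternative). The axis
count is fixed (default 3) rather than data-driven so values are
comparable across communities; communities with fewer than `n_axes + 1`
distinct taxa are flagged degenerate, never silently dropped. Within the
pipeline all communities of a basin are placed in one pooled ordination
of the basin's resolved taxa, so hull volumes share a common space.

## Gain/loss partitioning

The change in any β statistic between years t1 and t2 is split by
intermediate-matrix evaluation: with `L = max(X1 − X2, 0)` and
`G = max(X2 − X1, 0)`, the loss-first scheme evaluates β at `X1 − L`,
giving `Δβ_sub = β(X1 − L) − β(X1)` and `Δβ_add = β(X2) − β(X1 − L)`;
the gain-first scheme mirrors it through `X1 + G`. Because the steps
telescope, `Δβ_add + Δβ_sub = β(X2) − β(X1)` holds exactly for *any*
β function, which is why β is a pluggable argument. The default
`symmetrized` scheme averages the two orders — exactly the two-player
Shapley attribution of the aggregate loss and gain matrices — and is
antisymmetric under swapping the year pair.

Per-column attribution treats each changed column's loss matrix and gain
matrix as players and computes Shapley values over orderings of player
application starting from X1: exact subset enumeration up to 10 players
(2^n evaluations with caching), seeded Monte-Carlo over permutations
beyond (default 2,000). Shapley values over 2m column players do not
aggregate exactly to the two-player scheme components, so per-direction
sums are aligned to the reported components by an equal additive shift
across that direction's players; the shift preserves the symmetry axiom,
leaves excluded (unchanged) columns at exactly zero, and is small in
practice. Under enumeration the aligned sums match the components to
machine precision.

An intermediate matrix can extirpate a site (all-zero row). The default
is a hard error naming the condition, because silently flooring
abundances changes β; an explicit `floor=ε` option replaces dead rows
with ε. Additivity is unaffected by the floor since both component
evaluations use the same intermediate matrix.

Trait-level contribution tests use a Gaussian random-intercept model
(`contribution ~ 1 + (1|basin)`, statsmodels MixedLM, REML) per modality
and direction, with a one-sample t-test on basin means as a flagged
fallback for singular fits, and a three-way significance classification
(additive / subtractive / neither) per column.

## Stress drivers

Three basin-level spatial stress descriptors: the arithmetic mean EQR
over all site-year records (EQR is consumed as a given number; national
index internals are out of scope); the OLS slope of sampling-season mean
air temperature on calendar year (≥ 3 years required); and the first two
principal components of mean forest/urban/agriculture proportions. PCA
uses the correlation matrix by default (`pca_standardize` switches to
covariance) because the three proportions have unequal variances. Signs
are fixed by convention — PC1 forest-positive, PC2 urban-positive — so
"higher PC1" always reads "more forest, less agriculture/urban".
Drivers are z-scaled across basins before entering models; scaling
metadata is kept for back-transformation.

## Trend models

β-diversity lies in (0, 1), so trends are fitted by maximum likelihood
with a beta-distributed response, logit link and precision φ:
`y ~ Beta(µφ, (1−µ)φ)`. Three fixed-effect structures are supported:
overall (`year`), per-basin (`basin + basin:year`, all fixed, one shared
φ), and driver interaction (`driver × year`). The Gaussian basin random
intercept is integrated by adaptive Gauss–Hermite quadrature: a
per-group Newton search locates the mode of the joint integrand and the
node grid is centred and scaled there, keeping 15 nodes (default)
accurate — the log-likelihood moves by far less than 1e-4 between 15 and
31 nodes on the standard fixture. Fixing the random-intercept SD to 0
reduces exactly to the fixed-effects beta regression (tested to 1e-6).
One test cross-checks coefficients, SEs and the random-intercept SD
against glmmTMB's beta-family fit on the same data.

Numerical choices: the year covariate is centred at its mid-span and
kept in year units; internally, non-intercept columns are mean-centred
and estimates mapped back exactly, so uncentred calendar years do not
stall the optimizer. Responses at the unit-interval boundary (possible
on degenerate synthetic data) are compressed with `(y(n−1)+0.5)/n` and
flagged. Inference is Wald (observed information via numerical Hessian);
the reported pseudo-R² is the Cox–Snell likelihood-ratio form, which
will not numerically match other R² flavours. Non-convergence is flagged
on the results object and warned about, never silent.

A calibration caveat found during validation and reproduced identically
by glmmTMB (coefficients and p-values agree to ~1e-4): the Wald test for
the year term under the random-intercept model is mildly
anti-conservative at panel sizes of tens of basins — the observed-
information SE slightly understates the sampling SD of the slope. The
acceptance-scale simulation quantifies the realized rejection rate.

Local richness trends use a Gaussian LMM (`richness ~ year`, random
intercept per site, correlated random intercept + slope per basin; ML or
REML). A singular basin covariance triggers a flagged refit with
independent components. Basin trends are fixed slope + BLUP deviation;
the recovering-basin subset keeps basins whose BLUP slope is positive
for the richness type matching the β index (taxon richness ↔ taxonomic
β, biological/ecological functional richness ↔ the trait βs).

Residual diagnostics: Durbin–Watson per within-basin residual sequence
and Moran's I with inverse-distance weights on basin-mean residuals
(normal-approximation p-value), plus residual summaries against basin
descriptors. Constant residual vectors are reported degenerate.

## Synthetic metacommunity generator

The generator emulates the monitoring data's structure, not its
mechanics: no dispersal kernels or population dynamics, just an event
model, because the partitioning distinguishes only increases versus
decreases.

* Year 0: each taxon of a regional pool (default 150, far larger than
  local richness) gets a basin-level log-normal mean abundance
  (log-mean 2.5, log-SD 1.0); each site holds each taxon with
  probability 0.2, with extra site-level log-normal scatter (log-SD
  0.5). Median site richness lands near 30 taxa, realistic for kick
  samples, and the large pool keeps site compositions from saturating.
* Each later year draws Poisson numbers of gain and loss events
  (defaults 1.0 and 0.25 per year — gains dominate, as in a recovering
  system). An event is *shared* with probability `shared_fraction(s)`
  of the basin stress s (identity link by default).
  - shared gain: one taxon gains the same log-normal amount at every
    site (pulls sites together);
  - distinct gain: each site establishes a taxon absent from the whole
    basin, or failing that boosts one of its own exclusive taxa
    (pushes sites apart) — site-specific choices are drawn without
    replacement within an event;
  - shared loss: one basin-wide taxon loses the same fraction
    everywhere; distinct loss: each site loses a fraction of its own
    taxon (severity uniform on [0.5, 1], floored at zero).
  The event polarity reproduces the full directional contrast: shared
  gains homogenize and distinct gains differentiate, while losses behave
  inversely (losing site-exclusive abundance homogenizes; losing a
  shared taxon differentiates).
* Communities emptied by losses are rescued with a logged colonization
  so every site-year stays non-empty, as the panel invariant requires.
* Covariates are tied to stress with Gaussian noise of one fifth of each
  driver's range: EQR mean 0.9 − 0.6s, temperature slope
  0.01 + 0.06 s °C/yr, urban share 0.05 + 0.4 s (forest decreasing
  accordingly).
* Randomness: one global seed; per-basin substreams are derived by
  counter (`SeedSequence(seed, spawn_key=(basin,))`), so adding a basin
  never perturbs the others. Every event is logged and the log replays
  exactly to the emitted arrays (tested).

Trait tables are generated over the species pool plus genus- and
family-level rows: species profiles mix a genus Dirichlet archetype with
an individual draw (mixture weight 0.7), encoded per block as 10-point,
fuzzy or single assignments, with configurable missingness per
taxonomic rank (defaults: species 0.25, genus 0.10) so hierarchical
imputation is exercised meaningfully.

What passing simulation tests do **not** show about real data: the
generator has no detection error, no taxonomic drift over time, no
spatial autocorrelation among sites, no abundance trends unrelated to
events, and stress-covariate links are linear by construction. Tests
against it demonstrate internal correctness and statistical calibration
under the stated model, not field validity.

## Experiment problem sizes

The simulation experiments run at sizes chosen to keep a full check on a
single CPU comfortable while retaining power: regime recovery uses 20
replicate single-basin runs per regime (8 sites × 10 years); model
calibration uses 200 replicates of 48 basins × 10 years (φ = 50,
random-intercept SD 0.3, matching the recovery fixture); driver
recovery uses 50 replicate 12-basin datasets; the stress-release
experiment uses 20 replicates of a 14-year basin whose stress ramps from
0.95 to 0.05 over the first six tenths of the series and then plateaus —
a release-then-hold trajectory, under which β declines while shared
events dominate and rises once site-specific gains take over.

## Known limitations

* The per-basin model assumes a single precision φ across basins.
* Shapley Monte-Carlo error is controlled empirically (2,000
  permutations ≈ well under 2% of the total change on small fixtures),
  not by a bound.
* Moran's I uses a normal approximation, adequate for tens of basins.
* The beta mixed model fits a single random intercept; no random slopes,
  zero/one inflation, or spatial random fields.
* FRic hull volumes depend on the retained axis count; comparisons are
  only meaningful at fixed `n_axes` within one pooled ordination.
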