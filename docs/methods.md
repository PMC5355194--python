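# Methods

`reefshift` implements an analysis chain that asks how much of the
present-day distribution of tropical reef fishes is explained by the
Quaternary history of their habitat, over and above contemporary
environmental conditions — and whether that historical signal is
concentrated in species with particular life-history traits. Because the
compiled occurrence, trait, and paleoclimate datasets such analyses are
built on are not redistributable, the package pairs the analysis chain
with a synthetic-world generator that reproduces the statistical structure
the chain assumes, with known ground truth, so every stage can be tested
end to end.

## Habitat reconstruction

Sediment-core series (SST in °C, sea level in m relative to present) on a
regular 1,000-year age grid are linearly interpolated to a common grid
spanning the union of their age ranges and cross-checked with pairwise
Pearson correlations over pairwise-complete slices. Each SST core is
anchored to the pre-warming baseline map at its (nearest sea) cell; the
unweighted cross-core mean anomaly per slice is applied to the baseline as
a single basin-wide additive shift. With a handful of cores spanning an
ocean basin, a spatially interpolated anomaly field would be mostly
extrapolation; a uniform shift preserves the spatial SST ranking and makes
the reconstruction's assumptions explicit.

A cell is reef-suitable at slice *t* when it is immerged under the
contemporaneous sea stand (elevation h < s(t)), its water depth
d = s(t) − h falls in the reef depth window (default 0–100 m below the
contemporaneous stand, reflecting the depth limit of reef growth), and the
hindcast SST meets a thermal threshold. Thresholds are swept from 23 to
28 °C in 1 °C steps as a sensitivity analysis; the biology expects reef
formation near 25 °C with an optimum around 26–27 °C.

Coarse analysis cells that are ≥90 % land are excluded.

## Isolation from stable areas (IREF)

Per slice, the least-cost distance from every sea cell to the nearest
suitable cell is computed on the 8-connected grid graph with great-circle
step costs (diagonals cost their true geodesic length); land under the
contemporaneous stand is a barrier, so glacial low stands both remove
habitat and close dispersal corridors. The statistic is

    IREF(cell) = C / K,

with C the distance summed over slices and K the number of slices the cell
itself was suitable. Stable refugia score 0; cells whose habitat collapsed
often and whose nearest refuge was far score high.

Two policies keep the statistic finite for analyzable cells. Slices with
no suitable cell anywhere (possible at the warmest thresholds) are skipped
and counted rather than contributing unbounded distances. Sea cells
disconnected from all habitat at a slice contribute the grid-diagonal
great-circle length as a capped penalty; the cap is recorded on the
result. Exact shortest-path behavior is verified against an independent
exhaustive search (networkx Dijkstra) on random grids.

IREF is computed at the fine grid resolution and block-averaged to the
analysis grid. The block average runs over *established present-day reef*
cells only — suitable at present and suitable for at least a third of the
window — and analysis cells must contain at least one such cell.
Occurrence data can only come from extant reefs, reef frameworks require
sustained accretion to exist at all, and a cell suitable for one or two
slices would otherwise enter the mean with a value orders of magnitude
above the median (the 1/K leverage, amplified by the unreachable cap),
which destabilizes every downstream regression.

## Species distribution models and deviance partitioning

Each species' presence/absence over the analysis cells is fit with a
binomial GLM (logit link) in linear and quadratic terms of the predictors
(SST, CHL, O2, NI, SSS contemporary; IREF historical), z-scored before
expansion for conditioning and coefficient comparability. Explained
deviance is D² = 1 − residual/null deviance. Fitting the full,
contemporary-only, and historical-only predictor sets partitions total
deviance into pure-contemporary, shared, pure-historical, and unexplained
fractions via the standard identities; the fractions close to 1 by
construction, tiny negative values (> −1e−6) are clamped with the
knowledge that genuine suppression can produce larger negative shared
fractions, which are reported as-is.

Species with fewer than 10 presence cells are dropped, as are species with
fewer than 10 absence cells (a presence floor alone leaves
ubiquitous species unidentifiable). Fits are flagged non-converged on
optimizer failure, non-finite coefficients, or any standardized
|coefficient| > 15 (quasi-separation); such species are excluded from
downstream analyses.

Validation: AUC by the rank (Mann–Whitney) formulation with midrank ties,
averaged over repeated stratified 70/30 split-sample refits (default 100
repeats, configurable); and Moran's I of response residuals under
row-standardized queen adjacency on the analysis grid, reported with its
null expectation −1/(n−1). No multiple-testing correction is applied
anywhere.

## Trait analyses

The response is the pure-historical fraction per species. All 2³ subsets
of {size, mobility, specialization} are fit by OLS; Akaike weights
w ∝ exp(−ΔAIC/2) give per-trait importances (summed weights of models
containing the trait) and conditionally averaged slopes, with
unconditional standard errors that include between-model variance
(full-set averaging is available as an option). Size enters in cm by
default (a log10 option exists); mobility is dummy-coded against
mobile-within-reef so the reported contrasts are "sedentary" and "very
mobile"; specialization against coral-specialized.

Phylogenetic GLS uses the Brownian-motion covariance implied by the
(ultrametric) tree, with Pagel's λ scaling the off-diagonal entries,
estimated by bounded profile maximum likelihood on [0, 1] (grid restarts,
tolerance 1e−6). At λ = 0 the fit reduces exactly to OLS, which is tested
to 1e−8. Species missing from the tree are grafted at the midpoint of a
randomly chosen (seeded) congeneric tip's terminal branch, preserving
ultrametricity; species with no congeneric tip are reported unplaceable.

The triangular size–history pattern — small species can carry high *or*
low historical signal, large species only low — is summarized by linear
quantile regressions of the fraction on size at q = 0.75 and 0.9, fit by
the standard check-loss linear program.

## Assemblage mapping

Per analysis cell, the unweighted means over occupant species of the
pure-historical fraction and of body size, plus richness; cells with no
retained occupants are undefined. A cross-cell OLS of mean historical
fraction on mean body size (direction follows the wording of the source
analysis; R² is direction-symmetric) tests whether small-bodied
assemblages sit where the historical signal concentrates.

## The synthetic world

The generator emulates, from a single seed, every input the chain
consumes. Design choices, with what they do and do not capture:

* **Paleo series** are a shared glacial–interglacial sinusoid (period 20
  slices, two full cycles over the default 40-slice window — a scaled-down
  stand-in for the ~50 Quaternary cycles) plus independent AR(1) noise per
  core (SD 0.3 °C, φ = 0.5). SST amplitude defaults to 3 °C (tropical
  glacial cooling); sea level to 60 m, the lower end of reconstructed low
  stands, chosen so that the deepest shelf band (60–100 m) remains inside
  the habitat window through a full cycle and true refugia exist. Real
  curves are asymmetric sawtooths; the sinusoid keeps the cyclicity the
  analysis needs without that structure.
* **Geography**: a smooth Gaussian random field thresholded at 30 % land,
  post-processed to a single connected ocean (an enclosed random sea would
  sit permanently at the distance cap, which no real basin does). About
  20 % of the sea is shelf with cell-mean depths spread over 20–100 m
  (a one-degree cell averages reef flats with deeper water, so cell means
  below ~20 m do not occur); deep shelf clusters into regional provinces
  via an independent smooth field, so refugium density varies within as
  well as across thermal bands. The rest ramps to abyssal depth. Baseline
  SST has a meridional gradient (29.5 °C equator, −8 °C to the grid edge)
  plus a 1.5 °C western warm pool — the Indo-Australian-archipelago
  analog that keeps western equatorial habitat above coral thresholds
  through glacial cooling, concentrating refugia there so isolation grows
  smoothly eastward. Real coastline geometry and circulation are
  non-goals.
* **Species** are sampled cell-wise Bernoulli from the same
  linear-quadratic logit family the SDM fits (making parameter recovery
  well-posed; there is no extra spatial autocorrelation beyond what the
  smooth predictor fields induce). Contemporary niches are Gaussian with
  random optima and widths; intercepts are solved by bisection so target
  prevalences (uniform 0.35–0.7) are hit. The isolation coefficient is
  −b·z(IREF) with b = envelope × U(0.3, 1), where the envelope grows with
  small size and low mobility and scales with `lag_strength` — the
  uniform multiplier produces the triangular pattern rather than a line.
  With `lag_strength = 0` every b is exactly 0. Effect magnitudes were
  chosen so the pure-historical fraction distribution matches what such
  analyses report on real reef-fish data (mean ≈ 0.09, 5th–95th
  percentiles ≈ 0.02–0.21); full-model D² lands near 0.4, somewhat below
  real compilations, a deliberate trade-off — pushing it higher requires
  near-deterministic ranges that break coefficient identifiability at a
  few hundred cells.
* **Traits and phylogeny**: size is log-uniform on 4–200 cm; mobility is
  ordered and positively associated with size; specialization is mostly
  independent with a mild small-fish bias toward coral specialization. A
  birth–death tree is simulated, log-size is evolved on it under Brownian
  motion and rank-matched to the generated sizes, so size (and hence the
  historical effect) carries phylogenetic signal for the PGLS to correct;
  genera are the clades crossing 60 % of tree depth.

What passing tests on this world do **not** show about real data: the
generator has no observation error in occurrences, no spatial aggregation
bias from range polygons, no missing trait data, and its predictor fields
are smoother and better behaved than satellite climatologies; recovery
performance on real compilations would be lower.

## Experiment sizes and numerical choices

The default scenario (the headline recovery experiment) uses a 72×320
one-degree fine grid aggregated 4× (analysis cells ≈ 4°, n ≈ 300–550
depending on the seed's geography), 40 slices, 200 species. Replicated
experiments use scaled-down worlds: the threshold sweep runs ten 60×240 /
120-species replicates with 12 AUC repeats; trait-lag and assemblage
experiments ten 48×160 / 250-species replicates per condition. The full
AUC protocol (100 repeats) is the library default; experiments pass
smaller repeat counts through the exposed parameter.

Ties in AUC use midranks; stratified splits keep at least one cell of
each class on both sides. The λ search restarts from a 10-point grid.
Degenerate inputs (constant predictors, single-class responses, zero
residual variance, all-collapsed windows) raise informative errors rather
than returning numbers.

## Known limitations

* The anomaly is basin-uniform; regional SST divergence between sub-basins
  is not represented (a stated limitation of the approach itself).
* IREF magnitudes depend on the window length and the collapse/cap
  policies; comparisons are meaningful within a configuration only.
* The deviance partition can report negative shared fractions under
  suppression; they are passed through, not clamped (beyond 1e−6 noise).
* PGLS treats the fraction as unbounded; a logit transform option exists
  but is off by default, and fractions near 0 make its residuals skewed.
* With a single depth per cell, habitat persistence through a cycle
  requires the sea-level amplitude to stay below the depth-window width;
  worlds configured otherwise have no refugia and the isolation statistic
  degenerates (this is a property of the metric, not a bug).
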