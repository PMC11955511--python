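# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `syntopy`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A dataset is four tables tied by `spider_id`: individuals (species, sex,
maturity, focal/attendee role), movement tracks (waypoints in meters in a
local planar frame, seconds from follow start), sun/shade bout series
(contiguous, non-overlapping, timed to the second), and pairwise behavioral
interactions (looking / courtship / aggression / other, optional initiator).
Coordinates are planar because the animals are mapped by hand against local
landmarks; no geodetic CRS is supported. Species vocabularies are declared
in `metadata.json`, not hard-coded, so the pipeline generalizes beyond the
four species it was built around. The raw-field column layout of the
original campaign was never published; the CSV schema here is self-defined
and documented in `io.py`.

## Kernel home ranges and overlap

The KUD of a group is a fixed-bandwidth isotropic bivariate-normal kernel
density over its observed positions, evaluated on a regular square grid and
renormalized so Σ density × cell_area = 1 (tolerance 1e−6 asserted in
tests). The default bandwidth is the home-range literature's ad-hoc
reference rule h = ½(σ_x + σ_y) n^(−1/6); a numeric override is accepted.
The source analyses name no bandwidth, so the community default is the
honest choice.

Isopleths accumulate cells by descending density until the cumulative mass
first reaches p/100; ties are broken by row-major cell order, so results are
deterministic. The p = 100 level is defined as every positive-mass cell.
Area is cell count × cell area; polygons are the union of the cell squares
(shapely), so polygon area equals mask area exactly.

All groups in an overlap analysis share one grid (pooled bounding box,
padded by half the span per side, 200×200 cells by default, and never less
than 4h so a tight cluster's kernel stays on-grid). Sharing the grid makes
intersection areas cell-exact, which the asymmetric overlap proportion
HR_ij = A_ij / A_i requires. On synthetic data with one wide-ranging group
the matrix shows the expected asymmetry: the wide group's rows (its own
large area as denominator) are small while its columns are large.

By default every waypoint of every follow enters the group's KUD; a
per-spider-centroid option exists because one-point-per-individual is the
other defensible reading of sparse focal-follow data. Species-level KUDs
pool sexes; a `species_sex` grouping is available.

## Phenology smoothing

Daily observation counts (zeros included) over the pooled season are
smoothed by loess: for each day the nearest ⌈span·n⌉ days are fit by
weighted least squares of degree 2 with tricube weights, span 0.75 by
default — the plotting-tool convention the field uses. The installed
statsmodels lowess is locally *linear* only, so the locally quadratic
smoother is implemented here directly; its constant- and linear-trend limits
and its recovery of generating seasonal peaks (±10 days at the default
noise) are asserted in tests. Groups with fewer than five observations are
skipped with a warning rather than smoothed.

## Rank-test battery

All tests use midranks. Kruskal–Wallis is delegated to
`scipy.stats.kruskal` (tie-corrected H, χ² p with k−1 df); the degenerate
all-values-identical case returns H = 0, p = 1 instead of raising. Dunn's
pairwise statistic is

Z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − T/(12(N−1)))(1/n_i + 1/n_j)],
T = Σ(t³−t),

with two-sided normal p and Bonferroni family m = k(k−1)/2 (all pairwise
comparisons).

The Scheirer–Ray–Hare statistic divides each effect's rank sum of squares by
MS_total, the *sample variance of the midranks*. Algebraically MS_total =
N(N+1)/12 · D with D = 1 − Σ(t³−t)/(N³−N), so this single division already
applies the classical tie correction, and a single-factor SRH equals
tie-corrected Kruskal–Wallis exactly (asserted to 1e−8). Sums of squares are
sequential (type-I) in the fixed order species, sex, species×sex — the
campaign's design is unbalanced and some convention must be fixed; type-I in
that order treats species as the primary stratifier. Empty cells produce a
warning, not an error.

## Interaction networks and the reference model

The mixing statistic is 100 × (#heterospecific edges)/(#edges) on the simple
undirected graph of interacting individuals. The reference model retains the
vertices and their species labels and redraws |E| simple edges uniformly
without replacement from all C(N,2) pairs, once per replicate; replicate k
uses its own generator seeded seed_base + k − 1 (default base 1), making
the null distribution reproducible bit for bit. Degree is deliberately
*not* preserved by the default scheme: its closed-form mean
1 − Σ_s C(n_s,2)/C(N,2) is the natural "random with respect to species"
benchmark, and a degree-preserving rewiring variant is provided for
sensitivity analysis. Same-sex edges are allowed in the null because the
observed data contain them; a male–female-only constraint would be a
different (stricter) null and is intentionally not the default.

The empirical P is the add-one estimator (1 + #{null ≤ obs})/(1 + n_perm)
for direction "less" (mirrored for "greater", doubled and capped for
two-sided), so P is never zero and remains valid under the discreteness of
the statistic; calibration under uniform pairing is checked by a
Kolmogorov–Smirnov test across 200 replicate synthetic assemblages.
"Less" is the default direction because the scientific claim under test is a
*deficit* of heterospecific interaction.

## The frozen observed network

The published network is reported only through marginals; the exact edge
list is not public. `fixture.py` freezes one hand-constructed assignment
satisfying every printed marginal simultaneously (vertex composition, edge
count, heterospecific and same-sex counts, behavior counts, courtship
sub-network composition, and exactly three degree-2 males) together with the
reported qualitative aggression/"other" cases. Per-class percentages beyond
those marginals are over-constrained by rounding; the fixture's docstring
records which are matched (species-level incidence percentages, courtship
sex-level percentages) and which cannot be (the full-network coecatus
sex-level figures, which are mutually inconsistent with the species-level
value). Tests assert only the marginals.

The analogous all-interactions null mean printed for the full 63-vertex
network is not recoverable from its printed composition under this (or any
examined) randomization scheme — the closed form gives ≈68.6% — so the
courtship network, where the closed form ≈71.7% matches the printed ≈72%,
is the quantitative anchor; the full-network analysis is still computed and
reported, with its P value, by the same code path.

## Synthetic assemblage generator

The generator is the package's stand-in for field data and encodes the
study conditions as defaults: the 108-individual roster by species and sex;
per-follow path lengths log-normal with sex medians 2.763 m (M) and 0.34 m
(F) (log-sd 0.9, a field-realistic dispersion giving 95% ranges of roughly
0.3–16 m for males); sun preferences anchored at the reported extremes
(0.94 and 0.33) with intermediate species at 0.60/0.50; seasonal peaks at
day-of-year 128 and 176 (sd 15 d) for the two shifted species and flat
(sd 45 d) for the others; home centers a few meters apart with sd 2.5–3 m,
and one wide-ranging species at sd 8 m (≈3× the others) to reproduce the
reported overlap asymmetry; 33 interactions with behavior mix 13/14/4/2 and
conspecific odds multiplier β = 4, which under the roster's pair composition
yields heterospecific fractions near the observed ~36%.

Mechanics: one numpy generator seeded from `config.seed` drives all draws in
a documented order, so a seed fixes the dataset bit for bit. Light bouts are
an alternating renewal process with exponential sojourn means proportional
to (p, 1−p) over a 900-s follow — the simplest process whose long-run sun
fraction equals p. Tracks place a bivariate-normal origin per individual and
split a log-normal total path length over Dirichlet-weighted segments in
uniformly random directions. Interactions are weighted sampling without
replacement over all unordered distinct pairs (weight β for conspecific
pairs, 1 otherwise) via exponential sort keys; β = 1 recovers the uniform
null exactly, which is what makes the generator usable for type-I
calibration.

What the generator does *not* emulate: movement autocorrelation (no
correlated random walk), detection bias, weather-dependent sampling gaps,
repeated follows of one individual, maturity effects, and any coupling
between spatial proximity and interaction probability. Passing tests
therefore demonstrate correctness of the estimators under the assumed
structure, not robustness of the field inferences to these real-data
features.

## Problem sizes and determinism

Default analysis sizes are the study's own: 10,000 permutation replicates
(seeds 1…10,000), 200×200 KUD grids, and 200-seed batteries for the
power/calibration properties. The whole suite runs in about a minute on one
CPU; the acceptance script in a few seconds. Every stochastic component
takes an explicit seed, and rerunning any stage from its persisted CSV
inputs reproduces its outputs byte for byte.

## Known limitations

Reproducing the published home-range areas, light/movement medians, and
test statistics requires the deposited raw coordinates, which are not
packaged; those analyses run only on user-supplied or synthetic data. KUD
areas are grid-quantized (cell-count × cell-area), so very coarse grids
bias areas upward. The loess smoother is O(n²) per group, fine for seasonal
day counts, not meant for long time series. The permutation engine
enumerates all C(N,2) pairs, which is the right regime for observational
interaction networks (tens to hundreds of vertices), not for massive graphs.
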