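# Methods

This note documents the models and procedures the package implements, the
defaults that matter, the numerical choices at the edges, and what the
synthetic-data tests do and do not demonstrate.

## Data model

A study is a taxa-by-samples matrix of integer diatom valve counts bound to
per-sample metadata (mat P in µg P g⁻¹ dry periphyton mass, region code,
latitude/longitude, year). Mat P must be positive where present; samples
without it are retained but excluded from gradient-dependent analyses.
Trait tables are long-form, one row per (taxon, source), with
trait ∈ {lowP, highP, unassigned}, source ∈ {literature, regression, titan},
and optional WA optimum/tolerance columns.

## Counting-effort standardisation

Counts are standardised to a fixed effort (default 600 valves) by uniform
random subsampling without replacement — operationally, ranking every
counted valve by a random number and keeping the lowest 600, which is a
multivariate hypergeometric draw per sample. Samples already at or below
the target are kept unchanged and flagged rather than dropped: an
under-effort count is a data problem the analyst should see. The expected
standardised count of taxon *i* is `target · A_ij / V_j` (hypergeometric
mean), which the tests verify by Monte Carlo.

## Trait assignment

**Regression.** For each taxon present in ≥ 5 samples (inclusive bound,
configurable), relative abundance is regressed on log₂(mat P). The log₂
transform evens the left-heavy distribution of samples along the gradient.
The linear slope is tested first at α = 0.05; if not significant, a
quadratic model's overall F-test is consulted and the trait is the sign of
the fitted change between the gradient extremes. The sequential rule means
linear evidence takes precedence and a conflict between the two models
cannot occur. Because the quadratic model nests the linear term, the two
tests are strongly dependent and the procedure's null assignment rate is
close to α itself (measured ≈ 0.06 on gradient-free simulations), not the
independence bound 1 − (1 − α)².

**TITAN.** Candidate changepoints are the midpoints between distinct sorted
gradient values with at least `min_split = 5` samples per side; tied mat P
values stay on one side, since a threshold on a measured value cannot
separate equal measurements. At each candidate the taxon's
Dufrêne–Legendre indicator value (specificity × occurrence fidelity,
scaled 0–100) is computed for both groups and the larger side taken. The
observed IndVal curve is standardised into z scores using the
per-candidate mean/SD over `n_perm = 250` label permutations; the selected
changepoint maximises z (`select_by="indval"` reproduces the raw-IndVal
argmax instead). The permutation p-value is **selection-adjusted**: each
permutation's IndVal curve is z-scored with the same ensemble statistics
and its maximum over candidates is compared with the observed maximum.
Without this adjustment the p-value at the selected candidate is
anti-conservative because the candidate was chosen to maximise z; with it,
the null rejection rate matches the nominal level (verified at 0.05 ± 0.03
over 200 null taxa). `n_boot = 500` bootstrap resamples yield purity (the
fraction of replicates reproducing the observed direction), reliability
(fraction with p ≤ 0.05) and changepoint quantiles; taxa passing
purity ≥ 0.95 and reliability ≥ 0.95 receive traits (z− → lowP,
z+ → highP). Purity for a signal-free taxon is *not* 0.5: the bootstrap
resamples the same data that produced the observed direction, so agreement
is positively correlated (measured ≈ 0.7–0.8 for noise taxa); what is
symmetric under the null is the direction itself, which splits evenly
across independent noise taxa.

**Weighted averages.** Optima and tolerances are the abundance-weighted
mean and SD of mat P, computed for **all** taxa (no occurrence filter — WA
inference is most precise with the full assemblage) from relative
abundances so that unequal totals do not weight samples. Optima are
reported on raw mat P, in µg g⁻¹; a log₂-space option exists but recovers
simulated optimum rankings slightly worse, because the raw-space weighted
mean uses the informative high-P tail more efficiently under a left-heavy
gradient.

**Merging.** The three sources are merged into one long table over the
union of taxa, absent combinations becoming `unassigned`, and a
disagreement report lists any taxon called lowP by one source and highP by
another — a situation that occurs in real data when literature traits come
from regions with a different nutrient range.

## The metric suite

For each source and trait: PropValves (trait share of valves), PropTaxa
(trait share of taxa), noTaxa (count of trait taxa present) and RlogA. All
denominators (V_j valves, T_j taxa) cover trait-assigned taxa only;
unassigned taxa are invisible to the trait metrics, so
lowP + highP = 1 for the three proportion-type metrics wherever defined.
RlogA divides each taxon's ln(valve count) by the summed ln counts of
assigned taxa; the per-taxon double ratio reduces algebraically to
`Σ_{i∈t} ln A_ij / Σ_{i∈assigned} ln A_ij` (tested to 1e−12). A taxon
counted once contributes ln 1 = 0 — the formula is applied literally, with
no +1 shift; a sample whose assigned taxa are all singletons has an
undefined RlogA (flagged). This sharp edge is deliberate: the +1 variant
is a different metric and silently substituting it would change values.

Diversity: richness on the standardised counts, Shannon H (natural log),
Pielou J = H / ln S (undefined at S = 1). WA inference: the simple variant
is the abundance-weighted mean of taxon optima; the `tol` variant
additionally downweights by t_i² (zero tolerances replaced by the smallest
positive tolerance observed). No deshrinking is applied. The two variants
are this package's reading of "two WA metrics" — the simple/tolerance pair
is the conventional one in the transfer-function literature.

Full suite: 24 trait metrics + 3 diversity + 2 WAM = 29 columns, with a
metadata table (type, source, trait) alongside.

## Performance evaluation

Each metric is scored by OLS against log₂(mat P): slope, adjusted R²
(negative values preserved — rankings depend on them) and slope p-value;
and by the adjusted R² of `metric ~ lat + long + lat·long`, the geographic
surrogate for distance to the disturbance source. Family comparisons use
one-way ANOVA with Tukey HSD on the 24 trait-metric adjusted R² values,
and Kruskal–Wallis tests on within-group ranks: the 4 types ranked inside
each source × trait group, 3 sources inside each type × trait group, 2
traits inside each type × source group, ties mid-ranked. Ranking within
groups controls the other two factors when testing one.

## Benchmarks

* **Tree changepoints** — recursive SSE-minimising binary splits of mat P
  (min 5 observations per side, breakpoints at midpoints of straddling
  values), each accepted only if its SSE reduction beats a within-node
  permutation test (999 permutations, α = 0.01). The permutation test is
  this package's significance construction: it is distribution-free and
  compares like with like (best split vs best split under permutation),
  and its null rejection rate is verified to match α.
* **Cluster percentiles** — Bray–Curtis dissimilarity on relative
  abundances, average-linkage agglomeration (complete and Ward available),
  tree cut at 0.75 dissimilarity; groups are numbered by increasing median
  mat P and reported with 50th/75th/90th mat P percentiles (linear
  interpolation between order statistics — percentile benchmarks depend on
  this convention) and mean within-group dissimilarity.
* **TITAN community profiles** — z curves of pure, reliable taxa are
  clipped at zero and summed by direction; the argmax over candidates is
  the community changepoint, and bootstrap replicates of the whole profile
  give cumulative frequency curves of its location. Clipping keeps the
  profiles non-negative accumulations of indicator signal; without it a
  few strongly negative z values from unrelated taxa could mask a real
  peak.
* **Reference percentiles** — median/75th/90th mat P and fractions below
  fixed cutoffs within user-designated minimally disturbed regions.

The benchmark metric subset is the 3 diversity + 2 WAM + 8 TITAN-trait
metrics (13); literature- and regression-trait metrics are excluded as
redundant with the better-performing TITAN-trait versions.

## Synthetic assemblages

The simulator draws mat P log-uniformly over 52–1200 µg g⁻¹ (mimicking the
left-heavy sampling of real gradients), gives each taxon a Gaussian
response on the log₂ gradient — optimum u_i (low-P taxa 80–250 µg g⁻¹,
high-P taxa 350–1400 µg g⁻¹, log-uniform), breadth σ_i ∈ (0.8, 1.8) log₂
units, peak relative abundance h_i ∈ (0.05, 0.30) — and rescales the 10
low-P taxa so they jointly account for 65% of the expected assemblage at
the gradient floor, with 40 high-P taxa sharing the remainder. Counts are
multinomial draws of exactly 600 valves per sample: the observation
process is a fixed-effort count, not independent Poisson noise. Latitude
and longitude are generated so log₂(mat P) is a noisy linear function of
position. Presets: `marsh_gradient` (the defaults above),
`step_threshold` (sharp community transition at 400 µg g⁻¹ for
changepoint-recovery tests), `null` (50 gradient-independent taxa for
type-I calibration).

Recorded truth distinguishes the *drawn block* of a taxon from its
*realized* trait: because expected proportions are compositional, a
high-P-block taxon with an optimum below the community turnover can
genuinely decline in relative terms across the gradient, making it a
low-P indicator in any observable sense (real assemblages show the same
phenomenon — high-P taxa that are abundant in low-P conditions). The
`trait` field is therefore the sign of the expected-proportion trend on
the log₂ gradient, computed from the configuration on a dense grid;
`block` keeps the drawn membership, and `optimum` is the response-curve
parameter u_i.

What the simulator does **not** emulate: spatial autocorrelation beyond
the linear lat/long surface, repeat visits to sites, taxonomist effects,
overdispersion beyond multinomial sampling, and secondary gradients (pH,
conductivity). Passing recovery tests therefore demonstrates correctness
of the estimators under the assumed response model, not robustness to
those field realities.

## Problem sizes, tolerances, determinism

All stochastic stages accept one master seed and derive independent named
substreams (`SeedSequence` spawn keys), so outputs are bit-reproducible
and changing one stage's draw count does not perturb another's. The test
and acceptance harnesses use 10 recovery replicates at n = 80 samples with
TITAN at 100 permutations / 50 bootstraps, 200 null replicates for
calibration, and 50 replicates for the metric-family ordering — sizes
chosen to estimate each quantity to a few percent. Under these conditions
regression recovers ≈ 97% and TITAN ≈ 89% of realized trait labels, WA
inferred mat P correlates with truth at r ≈ 0.9, and the rank correlation
of estimated vs true optima averages ≈ 0.90 with a seed-to-seed SD of
≈ 0.01 — this last quantity sits exactly at its nominal recovery bound,
and individual seeds land on either side of it; the high-P optima
extending to 1400 µg g⁻¹, beyond the sampled gradient, are intrinsically
hard to rank-resolve from range-bounded WA estimates. RlogA's adjusted R²
against the gradient beats PropValves in roughly three quarters of seeded
replicates, the qualitative ordering that motivates the metric.

## Known limitations

* IndVal uses abundance weighting only; a presence/absence IndVal variant
  is not implemented.
* The tree changepoint scanner splits on a single predictor (mat P); it is
  not a general CART.
* Bray–Curtis can violate the triangle inequality; only symmetry and
  [0, 1] bounds are guaranteed (and tested).
* WA inference is range-bound by construction (min u_i ≤ x̂ ≤ max u_i) and
  inherits WA's compression bias at the gradient extremes; no deshrinking
  is offered.
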