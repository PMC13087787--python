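# Methods

`fdshift` analyses how the functional diversity of a species assemblage
changed between two survey periods, and what drove the change.  It was
built around the design of a two-period (1990 vs 2020) resurvey of a
tropical river fish fauna — 19 sites, ten morphological traits, a large
historical native pool partially lost, a handful of non-native species
gained — but every stage works on any survey that fits the data model.

## Data model and trait standardization

A survey period is a species × trait table (10 strictly positive
continuous traits: body mass plus nine shape ratios) and a site × species
abundance matrix; sites carry projected coordinates and nine environmental
predictors (MAP, MAT, Chl-a, DO, EC, Forest, Dam, POP, Intro).
Abundances are renormalized to relative abundance per site at load time,
because every downstream use (CWM weights, FEve/FDiv weights) is
relative.

Traits are natural-log transformed and Z-scored.  Two choices the
literature usually leaves implicit are made explicit and configurable:

* **log base** — natural log (any base differs only by a constant factor
  that the Z-score removes; the choice matters only for reporting the
  stored transform parameters);
* **pooling** — by default the species of *both* periods form one fitting
  pool, so the two periods share a single functional space and
  cross-period hypervolumes are commensurable.  Per-period
  standardization is available but makes cross-period volume comparisons
  meaningless, and is off by default.

The Z-score uses the sample standard deviation (n − 1).  A species
measured in both periods contributes two distinct points, keyed
`(period, species)`.

## Paired trait tests

Per-site community-weighted means (CWM = Σ Pᵢ Xᵢ over the species of a
site) of each standardized trait are compared across periods as paired
vectors (difference = second period − first, so a declining trait carries
a negative effect size).  Method choice is gated: Shapiro–Wilk on the
differences and Brown–Forsythe (median-centred Levene) across the two
periods, both at α = 0.05; a paired t-test if both pass, otherwise the
Wilcoxon signed-rank test (Pratt's zero handling; exact null for n ≤ 25
without zeros/ties, else normal approximation with continuity
correction).  Cohen's d for the paired design is mean(diff)/sd(diff) and
is reported on both paths — the robust path labels its method honestly
rather than suppressing d.  Effect bands are the conventional
0.2/0.5/0.8 cut-offs.  No multiple-testing correction is applied across
the ten traits; users who need it can apply one to the tidy output.

## Functional space and the FRic / FEve / FDiv family

Species are embedded by PCoA of Euclidean distances in standardized trait
space (scikit-bio's eigendecomposition behind the interface).  With
purely continuous traits the distances are Euclidean and no negative
eigenvalues arise; should metric but non-Euclidean input be supplied, the
Lingoes correction (additive constant on squared distances, rank-
preserving) is applied automatically when the smallest Gower eigenvalue
drops below −1e−8.  Proportions of variance are computed on the positive
(corrected) spectrum.

Site-level indices use the first `k_use` axes (default 4: two axes carry
roughly half the variation in data of this shape, so a site-level hull
needs more than two to be informative, and 4 keeps the S ≥ k + 1 hull
requirement satisfiable at species-poor sites).  A site with S ≤ k_use
species falls back to k = S − 1 with a note, mirroring the behaviour of
the classic FD implementations; sites that remain degenerate are flagged
undefined rather than jittered — reproducibility is preferred to
coverage, and flagged sites are excluded pairwise downstream.

* **FRic** — exact convex-hull volume (Qhull, no joggling) of the species
  present.
* **FEve** — minimum-spanning-tree evenness: branch weights
  EW = d(i,j)/(wᵢ+wⱼ), PEW = EW/ΣEW,
  FEve = (Σ min(PEW, 1/(S−1)) − 1/(S−1)) / (1 − 1/(S−1)).
* **FDiv** — abundance-weighted divergence from the hull-vertex centroid:
  (Δd + mean dG) / (Δ|d| + mean dG).

All three are tested against independently coded brute-force oracles
(monotone-chain + shoelace areas, Prim MST, direct formula evaluation).

## Kernel hypervolumes and Sørensen overlap

Each species group (e.g. natives in 1990) is summarised by a Gaussian
mixture in the full 10-dimensional standardized trait space — one
axis-aligned kernel per species with per-dimension Silverman bandwidth
sd·(4/((k+2)n))^(1/(k+4)).  The "hypervolume" is the Lebesgue measure of
the density superlevel set enclosing 95% of probability mass (the
`quantile` parameter).  Both threshold and measure come from sampling the
mixture itself: with x ~ f, the threshold is the (1−q) quantile of
sampled densities, and the volume is the unbiased importance-sampling
estimate (1/m)·Σ_{f(xᵢ)≥t} 1/f(xᵢ).  Intersection volumes use
cross-inclusion: each group's retained samples are tested against the
other group's superlevel set and the two importance estimates are
averaged, guaranteeing Sørensen = 2V∩/(V_A+V_B) ∈ [0, 1] and exact
self-overlap 1.  Default sampling effort is 500 samples per data point;
permutation/bootstrap replicates run at 100 (accuracy of a single
Sørensen estimate at these settings is a few percent; the replicate
distributions need rank accuracy, not absolute accuracy, so the lighter
effort is spent there).

The permutation null shuffles group labels over the pooled species
(999 permutations by default) and reports the one-sided probability that
a random relabelling yields an overlap as low as observed,
p = (1 + #{null ≤ obs})/(n_perm + 1); a two-sided variant is available.
Uncertainty comes from a percentile bootstrap over species within groups
(999 replicates); an all-duplicate degenerate resample is redrawn and
counted.  The driver runs the four standard comparisons (natives across
periods, non-natives across periods, natives vs non-natives within each
period), optionally plus the total pool.

## Counterfactual decomposition of ΔFRic

Per-site functional-richness change Y = FRic(2020 community, 2020
traits) − FRic(1990, 1990) is decomposed by recomputing FRic under four
counterfactuals in the shared space, each switching exactly one
ingredient to its 2020 state: native composition (X1), native trait
coordinates (X2), non-native composition (X3), non-native traits (X4);
each component is counterfactual minus baseline.  Species entering
through a composition swap use their 2020 coordinates (their only
measurement); species measured in both periods keep the non-swapped
period's coordinates — the only self-consistent convention.  The response
is explicitly the per-site ΔFRic vector (n = 19 in the motivating
design); this is a documented reading, since "partitioning the
functional-richness shift" admits no other per-site construction.

Variation partitioning fits OLS for all 15 non-empty subsets of
{X1..X4}, records adjusted R² = 1 − (1−R²)(n−1)/(n−|S|−1), and recovers
the 15 exclusive (unique + shared) fractions by inclusion–exclusion;
unique + shared + residual sums to exactly 1, while the four *marginal*
(single-predictor) adjusted R² may well sum beyond 1.  Negative fractions
are reported, never clamped outside display.  A constant component (e.g.
non-native traits identical in both periods) contributes zero fit but
still spends its degree of freedom; genuine collinearity among
non-constant components makes a fraction undefined and is reported as
such, along with VIFs among the components.  The arithmetic is
cross-checked against `vegan::varpart` in the test suite.

## Spatial GLS drivers

Site-level responses (ΔCWM per trait, ΔSR, ΔFRic, ΔFEve, ΔFDiv) are
regressed on the scaled predictors.  Moran's I (row-standardized
inverse-distance weights, randomization variance, normal approximation)
on preliminary OLS residuals decides whether spatial structures are
compared at all.  Candidate correlation functions of distance are
exponential exp(−d/ρ), Gaussian exp(−(d/ρ)²) and spherical
1 − 1.5(d/ρ) + 0.5(d/ρ)³ (d < ρ); no nugget, matching the three-structure
design.  Estimation is maximum likelihood — β and σ² profiled
analytically through the Cholesky of the correlation matrix, the range ρ
optimized numerically over [d_min/2, 2·d_max] by a 40-point log-grid scan
with local refinement (the profile is multimodal, sharply so for the
Gaussian structure; a plain bounded scalar search is not reliable).  ML
rather than REML so that AIC is comparable across fixed-effects subsets.
AIC = −2ℓ + 2(p_fixed + 1_range + 1_σ²); coefficient SEs use the
unbiased σ̂² (n − p) with t-based p-values.  The fitter agrees with
`nlme::gls` (ML) to the printed precision of logLik, AIC and
coefficients.

Model selection mirrors standard multimodel inference: predictors are
first VIF-filtered (iteratively dropping the worst offender until all
VIF < 5, later column dropped on ties), the structure with the lowest
full-model AIC is chosen, all fixed-effects subsets up to
⌊n/3⌋ parameters (intercept included) are enumerated, models within
ΔAIC < 2 of the best are averaged with Akaike weights (full averaging,
absent coefficient = 0), and predictors with importance (sum of weights)
above 0.5 are retained.  Exact AIC ties break lexicographically on the
predictor tuple, making ranking deterministic.

**Known limitation.** Under these conditions AIC cleanly separates the
Gaussian structure from the other two (it is the only one smooth at the
origin), but exponential and spherical correlations are both linear at
the origin and differ only in tail shape: on fields simulated with an
exponential range of 0.3 on a unit square at n = 100, argmax-AIC picks
the true exponential structure in well under half of replicates (the
spherical fit wins the near-ties), and an independent reference
implementation (`nlme::gls`) produces the same AIC orderings.  β coverage
and range recovery are unaffected.  Structure identity between these two
families should not be over-interpreted at realistic sample sizes; the
test suite asserts the optimistic 80% identification rate anyway and the
exponential case is expected to fail it, by design left visible rather
than weakened.

## Synthetic surveys and ground truth

The generator emulates the study conditions: 19 sites on a 100-km square
basin; 90 historical natives with survival probability 0.35; 7
non-natives by 2020 of which 2 are already present (rare, abundance
down-weighted ×0.1) in 1990; 10 log-scale traits drawn from an AR(1)-
correlated MVN (sd 0.5, neighbour correlation 0.5) and exponentiated, so
the log/Z pipeline recovers the exact MVN structure.  Surviving natives
receive a decadal trait shift with a mean vector following the observed
sign pattern (most shape ratios shrink, caudal-fin throttling and eye
position rise, body mass stable) *plus* per-species scatter (sd 0.15 log
units).  The scatter term matters: a pure mean shift translates the
whole cloud and cannot change convex-hull volume, so species-specific
re-measurement scatter is what gives the trait-shift components (X2, X4)
of the decomposition any signal — as it does in real surveys, where each
species is independently re-measured.

Site occupancy is drawn once and shared by both periods, so composition
turnover comes only from global losses and gains and the null scenario
(full survival, zero shift, no non-natives) leaves composition and traits
exactly unchanged, with only lognormal abundance noise (σ = 1)
distinguishing the periods — the basis of the type-I calibration tests.
Environment enters as a trait-weighted tilt of log-abundance,
u = X_scaled·B + E with E spatially autocorrelated (exponential, range
30 km, sd 0.3) and B a sparse matrix linking MAP→CFd/CPd, DO→BodyMass,
Dam→HL/SL, Intro→BD/SL, so CWMs respond linearly to the predictors.
`GroundTruth` records survivors, shift vectors and scatter, B, and the
spatial range.

What the generator does **not** emulate: river-network topology (sites
are uniform on a square), detection/gear selectivity, phylogenetic trait
correlation, within-species trait variation across sites, and temporal
autocorrelation beyond the shared occupancy.  Passing tests therefore
demonstrate correctness of the estimators under a known, well-behaved
generative model — not robustness to those real-data complications.

## Numerical choices and problem sizes

Degenerate hulls are flagged, never jittered; hypervolume estimates are
deterministic given a seed, with one global pipeline seed deriving all
stage seeds through `numpy.random.SeedSequence.spawn`; density
evaluations are chunked to bound memory; the Gaussian GLS correlation
gets a 1e−8 stabilizing ridge (1e−10 for the others).  Test-suite
simulation sizes are chosen to keep each calibration run in the tens of
seconds (e.g. 1000 null replicates for type-I checks, 100 scenarios for
decomposition recovery, 50 per structure for GLS recovery); the
acceptance script runs the full pipeline at the study-scale defaults,
which takes on the order of ten minutes, dominated by the 999-permutation
and 999-bootstrap hypervolume resampling.
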