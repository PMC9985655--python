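# Methods

This note documents the models, the parameters that matter, the synthetic
data generator, and the numerical and design decisions behind `phylocomm`.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and filtering

The pipeline consumes an ASV count table (samples × taxa, nonnegative
integers), a rooted phylogeny over the same taxa, a seven-rank taxonomy,
and sample metadata for a reciprocal-transplant design (origin site,
destination site, timepoint, tissue, transplant status, plot). Upstream
steps — denoising, taxonomy assignment, alignment, tree inference — are out
of scope; the tree is treated as given and is expected to be ultrametric,
though nothing requires it.

`align_and_filter` intersects the taxon sets, keeps taxa present in at
least `min_prevalence` samples (default 2, the standard low-prevalence
guard), and drops samples below `min_sample_depth` reads (default 1980,
matching the rarefaction depth used for richness; configurable because
deeper tissues warrant a higher floor). Because dropping taxa lowers
depths and dropping samples lowers prevalence, filtering iterates to a
fixed point — this is what makes the operation idempotent, a property the
tests assert. Every dropped identifier is logged.

Trees are read from Newick; a root of degree ≥ 3 is treated as unrooted
and rejected. Polytomies below the root are resolved deterministically —
children grouped left-to-right in file order under zero-length branches —
and internal nodes are labeled `n1 … n(T−1)` in preorder so balance
identities are stable across runs.

## Phylogenetic ILR transform

Counts receive a pseudocount (default 1) before closure; zero replacement
is a modelling choice, so it is an explicit, logged parameter rather than
a hidden constant. Each internal node contributes one balance,
y_i = k_i ln(g(x_R)/g(x_S)) with k_i = sqrt(rs/(r+s)); the numerator is
always the node's first child in preorder, fixing the sign convention.
With uniform taxon weights the contrast matrix is orthonormal and balance
space is an isometric embedding of the Aitchison simplex — the property
the acceptance suite checks to 1e−8 against a brute-force clr oracle.
A branch-length weighting (each balance scaled by the square root of the
mean of its two child branch lengths) is available behind a flag; it
breaks orthonormality and is excluded from the isometry guarantees, so
uniform is the default.

## PERMANOVA, ordination, dispersion

PERMANOVA uses the trace formulation: with G the Gower-centered squared
distance matrix, the sequential SS of term *m* is tr((H_m − H_{m−1})G),
where H_m is the hat matrix of the cumulative design. Degrees of freedom
are rank increments of the orthonormalized design, so aliased terms are
detected and rejected by name. Pseudo-F is the usual ratio of mean
squares; p-values come from free permutation of sample labels with the
(count+1)/(n_perm+1) convention (default 999 permutations), switching to
exhaustive enumeration of all n! permutations when that is cheaper than
the requested budget — on tiny designs the p-value is exact. Sums of
squares agree with coordinate-wise sequential ANOVA on Euclidean data to
1e−8 (asserted against an independent least-squares oracle).

Term order is the analyst's: destination before origin before their
interaction by default, mirroring how transplant results are reported.
Restricted permutation within plots is deliberately not implemented; free
permutation matches the cited default of the method.

PCoA is an eigendecomposition of the Gower-centered matrix that reports
negative eigenvalues instead of clipping them, keeping the
negative-axis coordinates. The dispersion test needs them: the squared
distance of a sample to its group centroid subtracts the imaginary-axis
contribution and clips at zero before the square root — the standard
correction for non-Euclidean distance matrices. Distances then go through
one-way ANOVA plus Tukey HSD. With the spatial-median center option the
geometric median is computed on the real axes (Weiszfeld iteration) and
the imaginary correction uses the centroid; on Euclidean inputs (the
balance-space case, where no negative eigenvalues exist) this is exact.

Pairwise PERMANOVA runs one two-level test per unordered level pair,
optionally within a stratifying level, and adjusts p-values by
Benjamini–Hochberg by default (raw p always reported; Holm available).

## Richness

Rarefied richness subsamples exactly `depth` reads (default 1980) without
replacement — a multivariate hypergeometric draw — `reps` times (default
200) and averages the observed-taxon count; the Monte-Carlo mean matches
the closed-form hypergeometric expectation in the tests. Group
differences are modelled with a negative-binomial GLM (log link) on the
rounded mean richness; the NB2 dispersion α is profiled out by maximum
likelihood over GLM fits (bounded search on log α, so the Poisson limit
α→0 is handled smoothly — an intercept-only fit on constant data returns
exactly ln of the constant). Per-term Wald tests and all pairwise level
contrasts are reported; the contrast family is adjusted single-step from
the max-|z| distribution of the jointly normal contrast estimates
(Tukey-style), by seeded Monte Carlo on the contrast correlation matrix.
A zero-variance response is accepted only for the intercept-only model.

## Community phylogenetics

MPD uses the identity p'Dp/(1 − Σp²), which equals the unordered-pair
mean for presence weights and the abundance-weighted pair average for
relative-abundance weights; a sample with fewer than two taxa is flagged
missing. The null model performs a fixed number of *accepted*
checkerboard swaps (default 1000) on the full community matrix, starting
from the observed matrix for each of the `n_null` draws (default 999;
99 in the scaled validation experiments). Swaps preserve row and column
occurrence counts exactly and the multiset of abundance values within
each row — asserted exactly in the tests. SES and NRI = −SES follow, with
a two-sided empirical rank p per sample.

Group inference: a one-sample t-test of NRI against zero per group (a
Wilcoxon alternative is reported alongside, since the choice of test at
this step is a convention, not a derivation), and an among-group ANOVA on
SES gated by Shapiro–Wilk normality of the group-centered residuals at
α = 0.05, falling back to Kruskal–Wallis; post-hoc contrasts on the
chosen scale (Tukey HSD or pairwise Mann–Whitney with BH).

**A caveat the synthetic experiments exposed.** Abundance-weighted NRI
against the independent-swap null measures a sample's clustering relative
to the pooled occurrence frequencies. Two consequences matter for real
data. First, a matrix containing only samples from one strongly filtered
habitat carries no signal — the pool *is* the filtered clade — so
clustering tests should run on matrices that span habitats. Second, when
all samples share one abundance ranking (a common baseline community),
the dominant taxa sit at fixed, arbitrary positions on the tree, and
every sample inherits the same SES offset; group means can then sit
1–2 SE from zero under fully neutral assembly. This pseudo-replication is
a property of the statistic, not an implementation artifact; the neutral
calibration experiment therefore uses exchangeable samples (flat shared
baseline), and real-data group tests should be read with the shared
baseline in mind.

## Discriminating balances

Site labels are regressed on the balance table with lasso-penalized
multinomial logistic regression (saga solver; the objective matches the
glmnet-style (1/n)Σloss + λ|w|₁ via C = 1/(nλ)). Predictors are
standardized before penalization and coefficients reported on the
original scale. The penalty grid is log-spaced over 25 values from the
smallest all-zero λ down three decades. Each of the `reps` repetitions
(default 100; 20 in the scaled recovery experiment) draws fresh
class-stratified folds (default 10, reduced with a warning when a class
is smaller), picks λ at minimum cross-validated deviance — per
repetition, which is the natural reading of repeating the CV procedure —
refits on all samples, and records the nonzero balances per class. The
reported quantity is each balance's selection frequency, overall and per
class, with the mean coefficient sign. The "distinguishing" set uses a
0.5 frequency threshold; the full frequency table is always written.

Node placement is tested with a Welch t-test on log descendant-tip count,
selected versus unselected nodes ("less basal" = smaller clades); the
unselected complement serves as the null rather than a resampling
scheme — simpler, and a permutation alternative would test the same
contrast. The family universe for the leaf-versus-root Fisher test is
all families annotated among retained ASVs.

With site-graded occupancy filtering active, *every* balance carries some
genuine site signal through presence patterns, and cross-validated
deviance keeps improving toward dense models — dense selection is then
correct, not overfitting. The planted-clade recovery experiment therefore
runs under neutral occupancy, where the three planted clades are the only
signal; there, 20 repetitions select the planted balances in every
repetition and the median frequency elsewhere is 0.

## Synthetic data generator

The generator emulates the transplant design: 4 sites (CC, MM, WP, DB)
crossed as origins and destinations, 3 monthly timepoints, leaf and root
tissues, back-transplant controls, and uneven log-normal read depths
(median 10 000, log-sd 0.7, bounded to [2 000, 80 000]).

* **Tree and trait.** Ultrametric Yule topology with unit depth;
  Brownian "environmental tolerance" trait (σ = 1) so trait similarity is
  phylogenetically structured.
* **Filtering.** Each site has a trait optimum (CC −1, WP −1/3, DB +1/3,
  MM +1, echoing an environmental gradient) and a filter width σ_f
  (defaults CC 2.0, WP 1.0, DB 0.7, MM 0.5 — weakest at the most oceanic
  site); a taxon's ecological presence probability is the Gaussian kernel
  of its trait distance to the optimum, scaled to mean occupancy 0.8.
  σ_f = ∞ recovers neutral assembly.
* **Abundances.** Dirichlet (concentration 300) around a shared log-normal
  baseline (log-sd 1) with a tissue-specific multiplicative shift
  (log-sd 0.3). Under the default design this yields a destination R² on
  balances of ≈ 0.35 at month one — the scale a strong site effect
  produces in real transplant data — which is why 300 is the standing
  concentration.
* **Planted differential clades.** Three internal nodes with 3–10
  descendant tips and ≥ 2 tips on each side (a side carried by a single
  taxon would be dominated by its detection noise); the *numerator* clade's
  tips are multiplied by the fold-change (default 4) at the node's
  assigned site, so the node's own balance shifts by k·ln(fold) — scaling
  the whole clade would cancel inside its own log-ratio. Fold-changes also
  multiply the odds of ecological presence: differential taxa shift in
  prevalence as well as abundance, as real differentially abundant taxa
  do.
* **Origin memory.** A transplant keeps its origin's fold-change pattern
  attenuated as fold^(decay^t) (decay 0.3): multiplier ≈ 1.5 at month 1,
  ≈ 1.1 at month 2 — a real but weak and fading origin effect. decay = 0
  silences it; decay = 1 makes it persistent (both asserted in tests).
* **Transplant handling.** Roots (only) get a multiplicative disturbance
  pattern (log-sd 0.3) on transplanted samples, so the
  transplant-vs-control comparison has a root-specific signal.

What the generator does **not** emulate: tens of thousands of ASVs with
~1% occupancy (it runs at 32–128 taxa with dense occupancy), sequencing
error and chimeras, compositional overdispersion beyond Dirichlet,
spatial/plot autocorrelation, and temporal autocorrelation within plants.
Passing the recovery experiments shows the estimators trace planted
signal through realistic compositional noise at desk scale; it does not
certify power or calibration at real-study dimensions.

## Problem sizes and determinism

The validation experiments are scaled to a single CPU: 99 null draws
instead of 999 for NRI, 20 selection repetitions instead of 100, 64–128
taxa, 20–40 samples per group, 500 simulations for type-I calibration.
All randomness flows from explicit seeds; per-stage seeds are derived as
a SHA-256 hash of (master seed, stage name) so toggling one stage never
shifts another's draws, and the saga solver's internal shuffling is
pinned. Two runs of the full pipeline from the same config and master
seed produce byte-identical tables (asserted in the acceptance suite);
output headers carry parameters and seeds but no timestamps for exactly
this reason.

## Known limitations

* Sequential (Type-I) SS means term order matters in unbalanced designs;
  the order is configurable but there is no Type-II/III option.
* The dispersion test's spatial-median center is approximate under
  negative eigenvalues (centroid correction on imaginary axes).
* The NB richness model fits the *mean* over rarefaction repetitions,
  rounded — repetition-level uncertainty is not propagated.
* Stability selection frequencies are descriptive evidence, not
  error-controlled inference; no per-family selection error bound is
  claimed.
* The independent swap fixes the number of accepted swaps (default 1000)
  rather than monitoring mixing; very dense or very sparse matrices may
  need more swaps, and a matrix with no checkerboard is returned
  unchanged with a warning.
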