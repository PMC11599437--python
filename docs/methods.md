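# Methods

This note records the statistical and numerical methods implemented in
`esoxtrace`, and the places where problem sizes are deliberately scaled down
so that the full validation suite runs in minutes on a laptop.

## Transect preprocessing (`transect_io`)

Laser-ablation transects carry a quasi-continuous Sr:Ca channel and sparse
δ¹⁸O spots. `pair_channels` assigns each δ¹⁸O spot the mean Sr:Ca inside a
symmetric window of half-width equal to half the median spacing between
δ¹⁸O spots, producing one paired record per spot.

δ¹⁸O reflects both temperature and salinity. Because Sr:Ca is a salinity
proxy, `correct_temperature_proxy` fits a single pooled ordinary
least-squares line of δ¹⁸O on Sr:Ca across all fish and takes the residual
as a thermal proxy (`d18o_res`). By construction the residuals have mean
zero and zero sample covariance with Sr:Ca; this algebraic identity is
verified to 1e-10 in the acceptance tests.

Annual means are computed per life year between consecutive annuli; life
stages are summarised as natal (annulus 1), early (annulus 2) and later
(mean of annuli ≥ 3).

## Trajectory clustering (`dtw_core`)

Annual multivariate series (Sr:Ca, thermal proxy) are compared with dynamic
time warping under a Sakoe–Chiba band: cell (i, j) is admissible iff
|i·(m−1) − j·(n−1)| ≤ band·max(n−1, m−1) with
band = ceil(window_frac·max(n, m)). The accumulated cost is normalised by
path length. The implementation is validated against an exhaustive
enumeration of all monotone warping paths for short series.

Hierarchical clustering uses Ward linkage via the Lance–Williams update and
is validated against a from-scratch greedy Ward merger that recomputes
within-cluster sums of squares exactly for n ≤ 7. The number of clusters is
chosen by majority vote over six cluster-validity indices (silhouette,
Calinski–Harabasz-style, Dunn, Davies–Bouldin, C-index, COP-style), each
computed directly from the DTW distance matrix.

## Phenotype rules and validation (`phenotyper`)

Natal origin is classified from the annulus-1 Sr:Ca mean with inclusive
freshwater/brackish thresholds. Habitat excursions are counted as runs of
at least `min_run` consecutive annual means on the opposite side of the
threshold. Five ordered rules assign FW_RESIDENT, BRACKISH_RESIDENT,
ANADROMOUS or CROSS_HABITAT; unmatched fish are UNCLASSIFIED. Every call
carries a rule trace for auditability.

Label quality is estimated by leave-one-out linear discriminant analysis on
the stage features (jackknife reclassification rate); the implementation is
cross-checked against scikit-learn's LDA with leave-one-out splitting.
Phenotype-frequency differences between groups use chi-square tests with
zero-margin categories dropped.

## Growth models (`growthmod`)

Annual increment widths are modelled on the log10 scale with fixed effects
age, age², thermal proxy, Sr:Ca z-score, sex and phenotype, and a fish-level
random intercept (REML). Terms are tested with likelihood-ratio tests on ML
refits that respect marginality (dropping `age` also drops `age²` and
interactions). Variance explained is reported as Nakagawa marginal and
conditional R². At zero random-effect variance the fixed effects provably
reduce to ordinary least squares; this limit is verified to 1e-6.

Back-calculated radii follow a hierarchical von Bertalanffy model
R(t) = L∞(1 − exp(−K(t + s0))) with fish-level parameters drawn from
gamma group-level distributions parameterised by mean and precision
(shape = μ²τ, rate = μτ). The posterior is sampled with an adaptive
random-walk Metropolis sampler; convergence is monitored with split-R̂ via
ArviZ, and group differences are declared when 95% credible intervals of
group means do not overlap.

## Genetics (`genetics`)

Genotype assignment probabilities (Q-matrices, read from CSV or STRUCTURE
outfiles) are compared across phenotypes with Euclidean PERMANOVA. For a
univariate response the pseudo-F statistic is algebraically identical to
the one-way ANOVA F; the acceptance tests verify this to 1e-10 and that the
permutation test holds its nominal size. Pairwise PERMANOVAs are corrected
with Benjamini–Hochberg; phenotypes whose pairwise tests are
non-significant are merged into ecotypes by transitive closure.

## Synthetic studies (`synthgen`)

The generator plants four life-history archetypes with distinct Sr:Ca
trajectory shapes, couples genotype Q-vectors to the planted phenotype via
Dirichlet concentrations, and simulates increments and radii from the same
linear-mixed-model and von Bertalanffy forms the package fits. Generator
defaults define the study conditions used throughout the tests; planted
phenotypes are separable by design so that recovery checks are meaningful.

## Deterministic pipeline (`pipeline`, `cli`)

Each pipeline stage derives its own seed as
SHA-256(f"{seed}:{stage}") truncated to 31 bits, so stages are independent
and reproducible in isolation. Every artifact is hashed; the manifest hash
covers all artifact hashes but not output paths, so identical configuration
and seed yield an identical manifest hash regardless of output directory.

## Scaled-down problem sizes

To keep the validation suite fast, the package's tests and demos use
reduced sizes relative to a full field study. These are choices made for
this package's test budget, and are flagged where they occur:

- MCMC chains in tests and the demo pipeline are short (2 chains, a few
  hundred retained draws after thinning); R̂ thresholds are relaxed
  accordingly. Production analyses should use 4 chains and ≥ 2000 draws.
- Hierarchical von Bertalanffy recovery is checked at 30 fish per group
  with short chains rather than full-length runs.
- Mixed-model confidence-interval coverage uses 200 simulations of 200
  fish; likelihood-ratio type-I error uses 500 simulations of 60 fish.
- PERMANOVA null calibration uses 500 replicates at 999 permutations;
  headline analyses use 9999 permutations.
- The demo pipeline simulates 8 fish per archetype instead of 20.
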