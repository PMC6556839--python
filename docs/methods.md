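# Methods

## Graph metrics

The unit of analysis is a symmetric, nonnegative, zero-diagonal matrix of
FA-like weights over 85 regions (34 cortical per hemisphere in a
Desikan-Killiany-style parcellation plus 17 subcortical structures by
default; any n ≥ 3 is accepted). `build_network` accepts a possibly
asymmetric streamline-count matrix (seeding direction) together with a
mean-FA matrix: counts are symmetrized by averaging, an edge exists where
the symmetrized count is positive, and the FA value is the weight.

Shortest weighted paths need a weight-to-length map. The default is
`f(w) = 1/w`, the standard choice for FA-like weights where larger values
mean better-organized tracts; `f(w) = −log(w)` is available for users who
prefer multiplicative path costs. Distances are computed by Dijkstra's
algorithm (nonnegative lengths) from every source; unreachable pairs get
`+∞` and contribute zero inverse distance to efficiency, so no infinities
propagate. The nodal quantity `E_j` implemented here is the per-node mean
inverse distance exactly as the efficiency formula above states — not the
neighborhood-subgraph "local efficiency" some graph-theory texts define
under a similar name; the formula is implemented as printed and this
documentation is the record of that choice.

Proportional thresholding keeps the `k = round(d·n(n−1)/2)` largest-weight
edges. Ties at the boundary are broken by a stable sort on (weight
descending, node-pair lexicographic), so repeated runs keep the identical
edge set. The density grid defaults to 0.30–0.90 in steps of 0.05 (13
levels); the step size is a free choice and is configurable. Metrics are
aggregated across the grid by the trapezoidal rule; a single density is
rejected because no area exists.

Numerical invariants enforced by tests: `E_G` equals the mean of `E_j` at
every density; with `f(w) = 1/w`, scaling all weights by `c` scales `E_G`
by exactly `c`; `E_G` is non-decreasing in density; node relabeling leaves
`E_G` and the multiset of `E_j` unchanged; distances agree with an
independent Floyd–Warshall implementation to 1e−12 on random graphs.

## Factor analysis

Scores are z-scored columnwise (denominator n−1). Outlier screening flags
|z| > 3 univariate and squared Mahalanobis distances above the chi-square
quantile with df = number of measures at p = 0.001 (the conventional
multivariate cutoff; configurable); flags are reported, never applied
silently.

The ML EFA maximizes the normal-theory likelihood for `Σ = ΛΛᵀ + Ψ` using
the profile-likelihood reduction: loadings are eliminated analytically and
L-BFGS-B optimizes over the uniquenesses alone, started at `1 − SMC`
(squared multiple correlations, `1/diag(R⁻¹)`) and bounded below at
Ψ ≥ 0.005. Estimates on the bound are flagged as Heywood cases. Each
factor is oriented so its largest-magnitude loading is positive. The
likelihood-ratio statistic uses the Bartlett correction
`(n − 1 − (2p+5)/6 − 2k/3)`; from it, RMSEA = √(max(χ²−df,0)/(df(n−1))) and
the Tucker-Lewis index against the independence model; RMSR is the RMS
off-diagonal residual correlation. For a just-identified model (df = 0,
e.g. three indicators and one factor), RMSR is still reported while RMSEA
and TLI are NaN ("not applicable"). Variance explained is the mean
communality, which for standardized measures equals the mean of squared
loadings — an identity the tests check on every fit.

Parallel analysis shuffles every column independently per permutation
(destroying cross-column structure, preserving margins) and compares the
observed correlation-matrix eigenvalues — the principal-component scree —
with a summary of the permutation distribution. The summary defaults to
the mean, with the 95th percentile as an option, because the retention
rule in the source methodology is stated only as "above the eigenvalue for
scrambled data". Retention counts leading eigenvalues that beat their null
counterpart, stopping at the first failure. The default permutation count
is 10,000; the calibration tests use 100 permutations per replicate, which
at n = 500 changes the null summary by far less than the gap between
signal and null eigenvalues.

Factor scores use the Thurstone regression method `Z R⁻¹ Λ` and are
standardized. Loading confidence bounds (5–95%) come from a
subject-resampling bootstrap (default 10,000 resamples, reduced in tests);
resampling subjects rather than permuting columns is an assumption, made
because it is the only resampling scheme that yields sampling variability
of loadings. Residualization regresses scores on (1, age, age², sex) by
OLS and re-standardizes the residuals; a constant covariate (e.g. a
single-sex subsample) is dropped with a warning.

## Inference

All regressions standardize both sides, so β is the Pearson correlation,
R² = β², and F = R²·df₂/(1−R²) with df = (1, n−2) — identities tested to
1e−8. Confidence bands for fitted lines use 500 subject resamples.
Mediation is estimated by two OLS path regressions (a from m ~ x; b and c′
from y ~ x + m), equivalent to the saturated three-variable path model, so
c = c′ + a·b holds exactly per sample; no latent-variable SEM is fit. The
indirect-effect CI is a percentile bootstrap over subject resamples
(default 5,000; the published band count of 500 applies to regression
lines, so the indirect effect gets the larger conventional count).
"Partial mediation" is flagged when the CI excludes zero while c′ stays
significant. Exactly collinear predictor and mediator (|r| > 0.999) are
rejected. Regional association maps regress the factor score on each
node's `E_j` AUC, with and without that region's grey-matter volume as a
covariate; no multiple-testing correction is applied by default, matching
descriptive per-region reporting (Benjamini–Hochberg can be applied
downstream on the returned p-values).

## Synthetic cohorts

The generator emulates the study conditions, not the imaging physics. A
template connectome is a random geometric graph: random 3-d coordinates,
edges sampled with probability decreasing in distance (short-range
connections dominate) to the target density, minimum-spanning-tree edges
added if needed for connectivity, and beta-distributed weights in
(0.2, 0.7) to mimic tract-average FA. Template density defaults to 0.7 so
most of the 0.30–0.90 threshold sweep is non-degenerate.

Each subject i has an integrity latent `s_i ~ N(0,1)`; subject edge
weights are `template_uv · logistic(γ·s_i + ε_uv)` with edge noise
`ε_uv ~ N(0, noise_sd²)`. The logistic squash keeps weights in (0,1) and
makes `E_G` increase smoothly in `s_i` — the simplest mechanism with a
continuous efficiency gradient. γ defaults to 1, an explicitly arbitrary
magnitude: no empirical between-subject connectome variance component is
available to calibrate it. The z-scored `E_G` AUC then drives
`g = a·z(E_G) + √(1−a²)·e`, and attainment
`y = b·g + c′·z(E_G) + residual` with the residual scaled so var(y) = 1;
observed scores load on their latent with the one-factor loadings
(defaults: cognitive (0.75, 0.62, 0.66, 0.82, 0.59), attainment
(0.93, 0.91, 0.74)), defaults n = 139 subjects. Path defaults
(a, b, c′) = (0.34, 0.55, 0.10) imply a total efficiency → attainment
effect of ≈ 0.29, in the range of the standardized brain–behavior effects
the pipeline targets. Nuisance variables are independent draws (age
uniform 7–12 y, sex Bernoulli(0.5), motion lognormal with median
≈ 0.37 mm, brain volume N(1.2·10⁶, 10⁵) mm³, regional grey-matter volumes
N(5000, 1000²) mm³ truncated at 0); `age_coupling` optionally routes age
into g so residualization is exercised non-trivially. The `truth` record
(latents, generating spec) exists solely for recovery tests; the pipeline
is tested to give bit-identical output with truth deleted.

What the generator does not emulate: anatomy (no real parcellation
geometry or hemispheric structure), measurement floor/ceiling effects,
non-normal score distributions, missing data, age-dependent connectome
growth, or motion-related weight bias. Passing recovery tests therefore
certify the estimators under the model's own assumptions, not robustness
to real-data violations of them.

## Problem sizes in tests and the acceptance script

Cohort-level tests use 6–20 nodes and 2–5 densities; the estimators are
size-agnostic, so small networks exercise the same code paths. The
mediation parameter-recovery check uses 20 cohorts of n = 2000 at 20
nodes and five densities; CI-coverage uses 200 trivariate replicates at
n = 139 with 1000 bootstrap resamples. The acceptance script runs the full
pipeline at study scale (139 subjects, 85 nodes, 13 densities) with 1,000
parallel-analysis permutations and 2,000 mediation resamples, sizes at
which the reported quantities are stable to well inside their rounding.

## Known limitations

- The profile-likelihood EFA assumes an admissible correlation matrix;
  near-singular inputs should be screened first (the outlier screen
  rejects singular covariance explicitly).
- Bootstrap CIs are percentile-based; no bias-corrected (BCa) variant.
- Parallel analysis returns 0 for structure-free data; the pipeline floors
  the fitted factor count at 1 because a factor score must exist for the
  downstream stages.
- No factor rotation, confirmatory or bifactor models; single-factor
  domains are the design target.
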