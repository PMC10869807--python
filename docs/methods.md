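# Methods

## The question and the data model

Whether non-native species succeed where close relatives live (shared
habitat suitability — "pre-adaptation") or where relatives are absent
(escape from competition — Darwin's naturalization hypothesis) is decided
here with presence/absence records at the river-basin grain.  The data
model is a species-by-basin occurrence table with a two-valued status
(`native`/`nonnative`), a basin metadata table (one country per basin, one
realm per country, surface area, centroid), and a phylogeny with branch
lengths covering the species pool.  Basins shared between countries carry
a single primary country; no splitting is attempted.  Species names are
canonicalised with underscore/space equivalence so occurrence tables and
Newick tip labels interoperate.

## Classification and record construction

A non-native record (s, b) in administrative unit U (country by default,
realm optionally) is **translocated** iff s has at least one native basin
in U, else **exotic**.  The rule is per-unit: one species may be exotic in
one country and translocated in another, and every record translocated at
country scope is translocated at realm scope because countries nest in
realms.

The modeling table pairs each species carrying the group label in a unit
with every *candidate* basin of that unit: all basins for exotics; all
basins minus the species' native ("origin") basins for translocated
species.  Presence is 1 where the species is established.  Before
construction, units with zero non-native records are removed (relatedness
of invaders to natives cannot be scored there) and species absent from the
phylogeny are dropped; both removals are reported.  Rows whose
relatedness is undefined (no natives in the basin) are dropped; undefined
native MPD/MNTD (fewer than two natives) is carried as NaN — never zero —
and only excluded by models that use those covariates.

## Metrics

All metrics use patristic (cophenetic) distances, computed in a single
postorder sweep as depth(i) + depth(j) − 2·depth(mrca).  Nonnative–native
MPD/MNTD are the mean and minimum distance from the focal species to the
basin's natives; native MPD is the mean over unordered native pairs and
native MNTD the mean nearest-neighbour distance.  The phylogenetic
covariance matrix C(i,j) = depth(mrca(i,j)) is exposed for
phylogenetically-correlated extensions and satisfies
d(i,j) = C(i,i) + C(j,j) − 2C(i,j) exactly; fitting a phylogenetic mixed
model is deliberately out of scope.  Polytomies and zero-length branches
are accepted.

Continuous covariates are z-scored with the sample (n−1) SD over the
emitted table of the fit at hand, so coefficients are comparable within a
fit; basin area is log-transformed first because areas span orders of
magnitude.

## Estimation

The occurrence model is a Bernoulli mixed model with independent Gaussian
random intercepts for species, country, and basin-within-country (species
and basin only in single-country fits).  Nesting is encoded by globally
unique basin labels.  The marginal likelihood is maximised under the
Laplace approximation: the conditional mode of the random effects is found
by damped Newton iteration (indicator-structure reductions, never
materialising Z), and L-BFGS-B with finite-difference gradients optimises
(β, log σ_g), with σ parameterised on the log scale and bounded in
[e⁻⁸, e⁵].  Fixed-effect covariance uses the Schur-complement information
X′WX − X′WZ(Z′WZ+G⁻¹)⁻¹Z′WX at the optimum, matching lme4's Wald
machinery; on a reference dataset the fit agrees with `glmer` to ~1e−3 on
estimates, SEs, variance components, and log-likelihood (cross-checked in
the test suite via Rscript when R is available).  The cloglog link uses
analytically derived first/second derivatives with expm1/log1p stability
and is selected automatically when the success fraction falls below a
configurable threshold (default 0.10); the distribution-specific variances
in the Nakagawa–Schielzeth R² are π²/3 (logit) and π²/6 (cloglog).  A
Gaussian family (identity link, residual SD estimated on the log scale)
shares the same engine — the Laplace approximation is exact there — and
serves as the mediator model of the path analysis.

The mediation analysis re-expresses the Bayesian multivariate path model
as two piecewise component models with identical random-effect structure:
relatedness_z ~ richness_z + native-diversity_z (Gaussian) and presence ~
relatedness_z + richness_z + native-diversity_z (Bernoulli).  Direct
effects are the outcome-model paths; indirect effects are products of the
path into relatedness and the relatedness→presence path (an arithmetic
identity, asserted exactly), with delta-method 95% intervals.  Maximum
likelihood with Wald intervals replaces MCMC: the path structure and
effect definitions are identical, and point estimation is treated as
machinery, not substance.

## The synthetic generator

The generator reproduces the statistical structure the models assume, not
any real geography.  A seeded pure-birth tree (birth rate 1.0) gives the
species pool; a Brownian trait (rate 1.0) encodes environmental
tolerance; countries draw environmental optima N(0,1) with basin jitter
N(0,0.5); species are native in a basin with probability
0.35·exp(−Δ²/(2·2²)) where Δ is the trait–environment mismatch, which
makes related species co-occur and couples richness to relatedness the way
environmental filtering does in real basins.  Introductions are proposed
for 30% of species–country pairs (exotic where the species has no native
basin in the country, translocated otherwise, never into native basins),
and each candidate (species, basin) establishes with probability
logit⁻¹(−1.0 − 0.5·MPD_z + 0.3·richness_z + u_s + u_c + u_b), with random
intercept SDs 0.5/0.3/0.3.  MPD_z is standardized over the proposal set —
the same convention as the record builder — so the programmed coefficient
is recoverable on the fitted scale.  Default sizes are 100 species and
3 realms × 2 countries × 8 basins, chosen so replicate batteries run in
seconds while leaving hundreds of Bernoulli records per fit.  Random
streams are split per stage (tree / traits / assembly / introductions), so
changing one stage's parameters leaves the other stages' draws intact.

What the generator does not emulate: sampling effort and detection bias,
propagule pressure, introduction history, spatial autocorrelation beyond
the country/basin hierarchy, and the real database's skewed richness
distributions.  Passing tests therefore demonstrate correctness of the
pipeline and calibration of the estimators under the assumed model, not
robustness of the ecological conclusion to those unmodelled features.

Two additional simulators draw records directly from the fitted models
themselves (the Bernoulli mixed model; the path model with standardized
paths).  They exist because the full generator conditions the modeling
table on at least one establishment per species-unit — a selection that
attenuates slope estimates by roughly a third at the default effect size —
so estimator properties (interval coverage, type-I error at the record
level) are assessed where the data-generating process and the fitted model
coincide, while sign recovery of the programmed effect is assessed
end-to-end through the full pipeline including that selection.

## Validation studies and sizes

The acceptance-level checks use: 100 end-to-end replicates at the default
conditions for sign recovery of β_MPD = −0.5; 200 end-to-end replicates at
β_MPD = 0 for Wald type-I error; 100 direct-model replicates
(100 species × 5 countries × 10 basins) for interval coverage; 100
path-model replicates (40 species × 6 countries × 5 basins) each for
indirect-effect recovery of (−0.4)·(−0.6) = +0.24 and for the null
(richness path 0).  Metric oracles (path enumeration for distances,
brute-force loops for MPD/MNTD/diversity, a triple loop for record
counts) agree to 1e−9.

## Numerical choices and edge cases

η is clipped at ±30 (logit) and capped at 3 (cloglog, where exp(η) ~ 20
already gives μ within 2e−9 of 1); Newton working weights are floored at
1e−10; inner-mode gradient tolerance 1e−9, outer gradient tolerance 1e−6.
Percentages in descriptive tables are half-up rounded to two decimals.
Zero-SD columns cannot be z-scored and are an explicit error from
`standardize_records`; the `build_model_table` convenience wrapper skips
degenerate columns (possible on toy inputs) rather than failing the whole
run.  A response that is all-0 or all-1, a rank-deficient design, or a
grouping factor with one level are rejected up front; non-convergence of
the outer optimiser is flagged on the fit, not raised.

## Known limitations

Wald inference is asymptotic; at the default battery sizes measured
coverage is ~0.92–0.94 rather than 0.95.  Variance components on the
boundary (SD → 0) are reported as ~0 without boundary-corrected tests.
The delta-method interval for products of paths is first-order.  Dense
distance matrices are used throughout (adequate to ~20k tips in memory);
no out-of-core path is provided.  No global occurrence database is
bundled; all shipped analyses run on generated data.
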