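# Methods

`bgpathways` implements a Bayesian evidence pipeline for region-of-interest
(ROI) fMRI data from action-control experiments: stop-signal-style paradigms
in which participants execute, proactively withhold, or reactively cancel
manual responses. The pipeline quantifies how consistent the observed
pattern of subcortical activation is with the three putative
cortico-basal-ganglia routes for action control — the *direct* (execution),
*indirect* (tonic suppression) and *hyperdirect* (fast cancellation)
pathways.

## Data model

Input is a long-format table of percent BOLD signal change, one value per
(participant, contrast, ROI). Sixteen lateralized ROIs are recognized:
pre-SMA and IFG cortically, and STR, GPe, GPi, SN, STN, THAL subcortically,
each left (L) and right (R). Contrasts are assigned by a user-supplied
table to one of three behavioural conditions: `execution`,
`inhibition_pro` (proactive/preparatory inhibition) and `inhibition_reac`
(reactive stopping). Values are stored as percent (0.15 means 0.15 %BOLD)
and never rescaled. Rectangular completeness is not required on ingest;
each downstream operation checks the cells it needs and raises a named
error identifying the missing (participant, ROI, condition).

## Compound contrasts

Different published contrasts can index the same behavioural state under
different baselines. Averaging a participant's %BOLD over all contrasts in
a condition set cancels contrast-specific baselines and retains the shared
signal, producing one "compound" value per participant × ROI × condition.
The pooled `inhibition_all` cell is the mean over the **union** of
proactive and reactive observations, weighting each contrast equally. The
alternative (mean of the two sub-means) differs whenever the sub-set sizes
differ and is exposed as `all_mode="submeans"`; union weighting is the
default because the compound construction treats every contrast as an
exchangeable probe of the condition.

## JZS Bayes factors

Per-ROI activation is tested with the Jeffreys–Zellner–Siow default Bayes
factor for the one-sample t-test. With standardized effect size
δ = μ/σ, H0: δ = 0 is compared against H1: δ ~ Cauchy(0, r):

    BF10 = ∫ f(t; ν, δ√N) Cauchy(δ; 0, r) dδ / f(t; ν, 0)

where f(·; ν, λ) is the noncentral-t density, ν the degrees of freedom and
N the effective sample size. The integral is evaluated by adaptive
quadrature under the substitution δ = r·tan(θ), which maps the real line
onto (−π/2, π/2) and absorbs the Cauchy weight into 1/π. The integrand is
the likelihood *ratio* exp(log f₁ − log f₀), additionally shifted by its
value at the peak θ* = arctan(t/(r√N)), so evaluation is numerically exact
in log space for |t| at least up to 20 (validated against an independent
implementation to ~1e-9 relative). The quadrature relative tolerance is
1e-4, an order below the 0.1% accuracy the package promises; a 10⁷-draw
Monte-Carlo average of the likelihood over Cauchy draws serves as the
independent oracle in the test suite (agreement within 0.5% on a
(t, ν) grid).

**Prior scale.** The default is r = √(1/2) ≈ 0.7071, the conventional
"medium" default. It was fixed by calibration: published (t, df = 29,
N = 30) pairs with their Bayes factors — (3.01, 7.68), (3.46, 20.87),
(3.22, 12.10), (7.96, 1454887.67) — are reproduced to within 0.3% at this
scale and at no other candidate scale (1, √2, √12 are off by 15–70%).

Evidence categories follow the conventional thresholds: BF10 > 3
substantial for H1, BF10 < 1/3 substantial for H0, BF10 in [0.9, 1.1]
insensitive, otherwise intermediate. Two-sided p-values from the central
t-distribution accompany every test. When a Bayes factor is derived from a
(t, df) pair alone, N defaults to df + 1 (one-sample convention); the
regression intercept test passes N explicitly.

## Activation tables and the active criterion

Per condition, each ROI's compound values are tested against zero. An ROI
is *active* when p < 0.05 **or** BF10 > 3. At N = 30 the BF10 > 3 region
(|t| ≳ 2.5) lies strictly inside the p < 0.05 region (|t| > 2.045), so the
OR-rule's joint false-positive level equals 0.05 — the test suite verifies
this empirically. Exploratory tables are uncorrected by default;
Holm-Bonferroni step-down adjustment (via statsmodels) is available as an
opt-in. Condition differences use the paired test with the sign convention
that positive t means the first condition exceeds the second.

## Moderator/mediator analysis

For every ordered pair of active ROIs, the target's compound values are
regressed on the covariate's (simple OLS, one covariate — deliberately not
a multi-covariate or causal path model). The intercept t-statistic
(ν = N − 2) tests whether the target remains non-zero given the covariate;
a JZS Bayes factor is derived from it with n_eff = N. Classification
compares adjusted against original evidence:

- **mediated** — adjusted BF10 < 1/3 and adjusted p > 0.05;
- **moderated** — 1/3 ≤ adjusted BF10 < 3, below the original BF10;
- **unchanged** — adjusted BF10 ≥ 3 or not reduced;
- **inconsistent** — the remaining cells (BF10 < 1/3 with p ≤ 0.05),
  flagged explicitly because the two elimination indicators do not
  partition the outcome space.

A consequence worth knowing: under *exact* mediation the adjusted
intercept t is a pivotal central t(N−2) variable, and BF10 < 1/3 at N = 30
requires |t| ≲ 1.07, so even a perfectly mediated pair is classified
"mediated" in only ~71% of replicates at this sample size; the rest fall
into "moderated". This is a property of the conjunction rule itself, not
of the estimator, and disappears only as N grows. The perfect-collinearity
limit (target ≡ covariate) is handled explicitly: zero residual variance
with a zero intercept yields t = 0 by convention.

## Pathway evidence products

Each pathway model names its member structures in one hemisphere; for
right-hand responses the direct route is left-lateralized (STR, GPi, SN,
THAL), and the indirect (all six subcortical structures) and hyperdirect
(GPi, STN, SN, THAL) routes are right-lateralized; mirror-imaged for
left-hand responses. The evidence score under a condition multiplies BF10
for every member and 1/BF10 for every non-member of the 12 lateralized
subcortical ROIs — the reciprocal quantifying evidence of *absence* where
the model predicts silence. Cortical ROIs never enter the product.
Products are accumulated in log10 space with a per-ROI contribution ledger.
Activation sign is ignored (the per-ROI tests are two-sided), so predicted
down-regulation is not encoded. The full grid crosses all four conditions
(execution, pooled, proactive, reactive inhibition) with all three
pathways, so behaviourally mismatched cells are always computed as
over-fitting controls; matched cells are flagged (direct ↔ execution;
indirect and hyperdirect ↔ the inhibition conditions).

The direct and indirect membership defaults were fixed by requiring that
the published per-ROI BF columns, pushed through the product rule,
reproduce the published evidence grid; the package ships those printed
inputs (`bgpathways.published`) and the reproduction is an acceptance
test (5% relative tolerance, the inputs being 2-decimal rounded).

A structural property of the product rule: a model with few members gains
+|log10 BF| from every silent non-member. Under a *true null*, a typical
per-ROI BF at N = 30 is ≈ 0.25, so a 4-member model's expected log10
product is ≈ −4·0.6 + 8·0.6 = +2.4 — null data systematically favour
sparse models. Users comparing pathway scores should therefore read them
*relative to each other* and to the matched/mismatched contrast, not as
absolute evidence against a global null.

## Synthetic data

The generator emulates the target study's structure: 30 participants, 16
ROIs, 131 contrasts split 44/44/43 across the three conditions (the true
split is not public; equal thirds is the configurable stand-in). It is a
two-level Gaussian hierarchy: participant-level latent means
m = μ[ROI, condition] + N(0, τ²), drawn independently per participant,
ROI and condition, and per-contrast observations m + N(0, σ²). Defaults
τ = 0.2, σ = 0.3 %BOLD, active-ROI effect 0.3 %BOLD give per-ROI
t-statistics in the single digits at n = 30, comparable to published ROI
tables. Coupling directives rewrite a target ROI's latent mean as
α + β·m_covariate + N(0, resid²) on the *latent* level, so an α = 0
directive creates exact full mediation recoverable by the intercept test
in expectation. All draws come from `numpy.random.default_rng` (PCG64) in
a documented fixed order, so (params, seed) reproduces a table
bit-for-bit.

What the generator does **not** emulate: hemodynamic time courses, voxel
noise and spatial smoothing, inter-ROI correlation beyond the explicit
coupling directives, condition-correlated participant effects,
heavy-tailed or heteroscedastic noise, and behavioural (RT/stop-signal)
structure. Passing recovery tests therefore demonstrates correctness of
the *statistical machinery* under the assumed Gaussian hierarchy, not
robustness to real fMRI artefacts.

Scenario presets: `null`; one preset per pathway placing the default
effect on that pathway's member ROIs under its matched condition(s);
`full_mediation_pair` (left THAL active, left GPe fully driven by it,
β = 0.8, residual sd 0.05); `independent_pair` (left THAL and GPe
independently active, μ = 0.5, τ = 0.1). Under each pathway preset the
matched pathway × condition cell wins the evidence grid in 50/50 seeded
replicates at the default conditions.

## Problem sizes and numerical choices

The test suite runs the full study-scale recovery simulations (50
replicates × 4 scenarios for the evidence grid, 50 × 2 for mediation) and
a 10⁷-draw Monte-Carlo oracle on an 18-point (t, ν) grid; the whole suite
completes in a few minutes on one core. The Monte-Carlo oracle tabulates
the noncentral-t density on a 2¹⁶+1-point noncentrality grid (span ±50
around t, where the density has decayed below ~1e-250 relative) and
linearly interpolates onto the Cauchy draws; the interpolation error
(~1e-7 relative) is negligible against Monte-Carlo noise. Property tests
are seeded/derandomized throughout. Degenerate inputs (zero-variance
samples, constant covariates, exact fits, unassigned contrasts, missing
cells) raise distinct named errors rather than propagating NaNs.

## Known limitations

- The pathway products inherit the sparse-model bias under null data
  described above.
- The mediated/moderated classification is threshold-based and sample-size
  dependent; at n = 30 its "mediated" sensitivity under exact mediation is
  capped near 71%.
- Membership maps encode presence/absence only; predicted directions of
  activation within a pathway are not scored.
- Simple regression only: one covariate at a time, no indirect-effect
  bootstrap, no causal identification.
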