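# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `surveycog`. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Response-error scores (module `irt`)

**Model.** One unidimensional graded response model (GRM) per scale, logistic
link without the 1.7 scaling constant, latent trait identified as N(0, 1).
Cumulative category curves `P*_ijk = logistic(a_j(θ − b_j,k−1))`; category
probabilities are adjacent differences.

**Estimation.** Marginal maximum likelihood via EM over fixed quadrature:
61 equally spaced nodes on [−6, 6] with standard-normal weights (the dense
oracle used in tests has 2001 nodes on [−8, 8]). The M-step maximizes each
item's expected complete-data log-likelihood under an order-preserving
parameterization (log discrimination; first threshold plus log-spacings)
with box bounds; discriminations are capped at `a_max = 6` because short
contaminated scales can otherwise drive an item's discrimination to infinity
along a likelihood ridge (items at the cap are flagged on the results). EM
stops when the largest absolute parameter change falls below 1e−4, with a
500-iteration cap; if the cap is hit, a direct quasi-Newton step on the
marginal likelihood under the same bounds finishes the fit, and
non-convergence is reported, never silently accepted. Refits on identical
data are bit-reproducible (fixed quadrature, no randomness).

**Scoring.** EAP trait estimates and posterior SDs come from the same
quadrature. The error score is `|y − E(Y|θ̂)|/(m_j − 1)`. Scores are computed
only for person × scale blocks with complete responses; persons contribute
to estimation with all available responses. Items keying against the scale
direction (negative item-rest correlation in a pre-pass) are reverse-coded
with an audit record; unused response categories are collapsed onto observed
ones with the mapping recorded, and the error-score denominator uses the
post-collapse category count.

**Fit summary.** An SRMR-style statistic: the root-mean-square difference
between observed and model-implied pairwise Pearson item-score correlations
(model-implied moments obtained by quadrature). A polychoric version was
considered and rejected — no pre-installed estimator exists, the Pearson
version answers the same question (how much pairwise association the
unidimensional model leaves unexplained), and published limited-information
indices are not reproduction targets here.

**Standard errors.** Outer product of per-person score vectors (numerical
derivatives of the marginal log-likelihood), the BHHH approximation.

## Complexity coding (module `complexity`)

Ten binary indicators per item: WC (≥ 10 words), DC (≥ 2 words off a
familiar-word list), UTT/VRT/VNP (precomputed clarity flags, e.g. from
QUAID, ingested and validated, never recomputed), and five contained-any
lexicon categories (CON, NEG, DIS, TEN, EXC). Composite = sum (0–10); bins
1–5 partition composites 0–1 / 2–3 / 4–5 / 6–7 / 8–9 (values above 9 fall
into bin 5). Tokenization: lowercase maximal runs of letters/digits with
intra-word apostrophes and hyphens kept (a hyphenated form is one token);
possessive `'s` of a familiar word counts as familiar. The thresholds 10 and
2 are parameters; an optional mode recomputes them as medians of the item
set at hand. The shipped word lists are open approximations written for this
package (filenames carry a `_synthetic` suffix); exact reproduction of
proprietary dictionaries is not promised, and users can point the loader at
replacement lists.

## Worst-performance-rule analysis (module `wpr`)

Cube-root transform first (error scores are strongly right-skewed; the cube
root is strictly monotone, so decile membership is identical to raw-score
binning — asserted in tests). Per person, scores are stable-sorted ascending
and split into ten bins whose sizes differ by at most one, remainder
allocated to the lowest bins (with 102 items: 11, 11, 10 × 8). Persons with
fewer than 10 scored items cannot fill ten bins and are excluded (threshold
configurable).

The ten decile–ability Pearson correlations are dependent. Their joint
asymptotic covariance is estimated from empirical influence functions
(delta method over the joint moments of the eleven variables — robust to
non-normality), mapped to Fisher-z scale with the `n/(n−3)` small-sample
scaling. The omnibus test is a Wald statistic on a rank-9 contrast of the z
vector against χ²(9); it is invariant to the contrast basis (successive
differences vs deviation-from-mean, asserted to 1e−8), returns (0, p = 1)
when the correlations are exactly equal, and a person-level bootstrap
covariance is available both as a fallback and as the cross-check oracle in
tests (delta and bootstrap SEs agree within 15% at n = 1500 in the suite).
Pairwise decile contrasts use the same covariance. Under an exchangeable
null the omnibus rejection rate at α = .05 is calibrated: the acceptance
suite measures it over 1000 replicates at n = 500 and requires [0.03, 0.07].

Across waves, retest correlations of person-level mean error and per-decile
means are Pearson correlations over overlapping persons, with overlap counts
reported.

## Task-complexity models (module `tch`)

**Cross-level interaction model.** Item-level (transformed) errors regressed
on complexity with person random intercepts and slopes, both regressed on
ability at level 2. Estimation is direct ML on the per-person marginal
Gaussian likelihood: the random-effect covariance is parameterized by its
log-Cholesky factor (positive semidefiniteness by construction), the
residual variance and all fixed effects are profiled out, and Woodbury
identities reduce every likelihood evaluation to small per-person sufficient
statistics (`Z'Z`, `Z'F`, `F'F`, `Z'y`, `F'y`, `y'y`), so persons may have
arbitrary item subsets. Optimization: L-BFGS-B then a Nelder–Mead polish at
tight tolerances (so that reparameterized fits of the same likelihood agree
to ~1e−4 in log-likelihood), with three perturbed restarts on failure.
Fixed-effect SEs are person-clustered sandwich estimates; model-based SEs
are available from the bread matrix. A random-slope variance at the boundary
is flagged. The engine's log-likelihood is verified against a brute-force
dense multivariate-normal evaluation, and fixed effects against statsmodels
`MixedLM` (whose optimizer, not likelihood, occasionally stops early — the
suite asserts our optimum is no worse). Ability and complexity enter
uncentered; simple slopes are reported at zero.

**Binned sensitivity model.** Complexity entered as five bins with per-bin
intercepts and per-bin ability slopes; the random structure stays person
intercept + linear complexity slope (an audited reduction — correlated
per-bin random slopes are what makes such models fragile). Reported:
percent change of the within-bin ability slope relative to the lowest bin,
and bin-midpoint predictions for cross-model agreement with the linear
parameterization (r > 0.99 under linear truth in the suite).

**Latent-error reparameterization.** Basis weights `(9−c)/9` and `c/9`
replace intercept and slope, so the person effects are latent error levels
at complexity 0 and 9; ability joins as a third person-level variable with a
free mean, giving a full 3 × 3 person-level covariance and the derived
correlations corr(ability, u₀) and corr(ability, u₁). This model is fitted
by its own direct optimization (log-Cholesky of the 3 × 3 covariance plus
residual variance, means profiled). Because the joint likelihood of (errors,
ability) factorizes into the conditional model — which spans exactly the
intercept/slope family — times a saturated Gaussian ability margin, the
results expose `llf_conditional` (joint log-likelihood minus the maximized
ability-margin log-likelihood); the suite verifies it matches the
intercept/slope fit to better than 1e−4 even though the two routes are
optimized independently. The mean-structure identities (e.g. low-complexity
mean = conditional intercept) hold when ability is centered, and are tested
that way. This model requires a complete scored item vector per person
(incomplete persons are dropped and counted); the conditional
parameterization remains the tool for unbalanced data.

**Ability factor model.** One factor over the four subtests, factor variance
fixed at 1, free residual covariance between the two recall subtests, ML on
the sample covariance; χ²(1) goodness of fit, delta-method SEs (the recall
residual covariance is weakly identified with four indicators — its SE is
reported and used in tests), regression-method factor scores. Near-zero
residual variances are flagged as Heywood-type boundaries.

**Latent joint model.** Errors and subtests share one per-person Gaussian
likelihood. The person effects are written u = αg + e with g ~ N(0,1) and
e ~ N(0, Ψ), which enforces a valid joint covariance and gives
corr(g, u_k) = α_k/√τ_kk directly. Starting values come from the factor
model and per-person least squares; a clearly labeled two-step fallback
(factor scores, then the composite-mode model) exists and is reported as an
approximation — it mildly attenuates the latent correlations, which the
suite checks. The expected disattenuation (latent correlations exceeding
manifest-composite ones in magnitude under subtest measurement error) is an
acceptance property.

**Scale-level analysis.** Per scale: mean item complexity and the
correlation between person mean error and ability; across scales, the
Pearson meta-correlation with a Fisher-z CI. Zero-variance scales are
excluded with warnings; constant complexity across scales yields an
explicitly undefined meta-correlation.

Error scores are modeled on the cube-root scale; any ×100 rescaling is for
reporting only.

## Synthetic-data generator (module `simulate`)

**What it emulates.** A panel study: 21 multi-item scales (item counts
5,5,6,4,3,4,4,5,5,4,5,3,4,5,5,5,7,7,5,4,7 — 102 items), 3–7 ordinal
categories per scale, persons with a standard-normal general ability g
correlated 0.2 by default with each scale's latent trait, four discretized
cognitive subtests (0–10, 0–10, 0–5, 0–2; standardized loadings ≈
.75/.75/.60/.45 with a recall-pair residual correlation of 0.4, composite
0–27), and optional multi-wave administration with exchangeable person
latents at a configurable retest correlation.

**Contamination.** Each response is replaced, with probability
`logistic(λ0 + λ1 g + λ2 c + λ3 g·c + ω_i)`, by a uniform draw over the
categories (an extreme-response variant sits behind a config flag); ω is a
stable person lapse propensity (SD 0.5). Defaults λ0 = −3.2, λ1 = −0.5,
λ2 = 0.1, λ3 = −0.05 give a mean lapse rate around 5% — *occasional* lapses,
more frequent for less able persons and on more complex items, with the
deficit amplified by complexity. Item discriminations are lognormal around
3.0 (SD of log 0.25): established rating scales are strongly discriminating,
and this is what produces the tight, right-skewed error distribution
(median ≈ .1) in which the largest errors are lapse-dominated. Both choices
are deliberate study conditions: with weak discriminations (around 1.5) or
frequent lapses (λ0 ≈ −2.2), ordinary category noise or lapse saturation
dominates every person's top error decile and the worst-performance
structure the generator exists to emulate disappears.

**Complexity.** Item composites are drawn from a beta-binomial(9, 0.85,
1.51) over 0–9 (mean ≈ 3.25, SD ≈ 2.65 — a realistically overdispersed
profile), realized as a random subset of the ten indicators; item texts are
synthesized from a controlled vocabulary so that the lexical indicators code
back to exactly the drawn profile (round-trip asserted in tests), and the
three clarity flags are emitted as a precomputed-flag table.

**What it does not emulate.** Survey sampling design, attrition, proxy
respondents, demographic covariates, response-style heterogeneity beyond the
lapse mechanism, item-position/fatigue effects, and practice effects across
waves. Passing tests therefore demonstrate that the machinery recovers known
structure under the stated mechanism, not that real questionnaire data obey
that mechanism.

## Problem sizes and numerical conventions

Default pipeline runs use 2000 persons; the test suite uses 300–5000
persons depending on what the check estimates, with 200 replicates for the
interaction-coverage study and 1000 replicates for the null calibration of
the omnibus test — sizes chosen so each Monte-Carlo check has enough
resolution for its stated tolerance. Convergence tolerances: GRM EM 1e−4
(parameter change); mixed-model optimizers run to ~1e−9 in the objective so
likelihood-equivalence checks at 1e−4 are meaningful. Degenerate inputs
(constant columns, empty bins, all-missing persons, single-category items,
no overlapping persons) raise informative errors or documented fallbacks
rather than propagating NaNs. All randomness flows from explicit
`numpy.random.Generator` objects; a pipeline run is a pure function of
(config, seed), and reruns are byte-identical.

## Known limitations

- The GRM assumes unidimensionality per scale and identical measurement
  across persons; no differential-item-functioning checks are built in.
- The delta-method correlation covariance is asymptotic; below a few hundred
  persons the bootstrap covariance is preferable.
- The latent-error models require complete scored item vectors; with
  item-level missingness beyond the listwise-by-scale rule they fall back to
  fewer persons (the pipeline skips them below 100 and says so).
- The complexity lexicons are approximations; absolute indicator prevalences
  depend on the lists supplied.
- Latent correlations from the generator's default conditions are stronger
  than one should expect of real questionnaire data, where lapse behavior is
  less tightly coupled to measured ability.
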