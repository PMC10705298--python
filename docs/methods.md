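# Methods

This note documents the models behind `phylopower`, the choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate about real data.

## Data model

A species table carries one row per species: a categorical power label
(MD male dominant / CD co-dominant / FD female dominant; MD is "male-biased
power", MP) and four continuous predictors — body mass ratio (BMR,
male/female), upper-canine crown-height ratio (CR), expected estrous
overlap (EO) and adult sex ratio (SR, males per female). All ratios must be
strictly positive; EO is stored on the **percent** scale (0–100). The
percent convention matters because predictors enter every model as log₁₀
values: with percent-scale EO the fitted estrous-overlap model crosses a
50% probability of MP near EO ≈ 4–5, which is the behavior the package's
acceptance checks pin down; a proportion-scale EO would shift the intercept
by b₁·2. Missing cells stay missing and species are dropped per-analysis,
never imputed — e.g. a dataset lacking canine measurements for tarsiers
simply has no tarsiers, and therefore no separate haplorhine node, in its
CR analyses.

Trees are rooted, dated (branch lengths in millions of years, never
auto-detected), possibly polytomous; every algorithm below handles
polytomies. Zero-length branches are accepted with a warning (they are
degenerate for the kappa and OU transforms: κ of a zero branch stays zero).

## Fossil grafting

A fossil record names an attachment tip or node, a geological age, and a
divergence date from its sister. The new common node is placed at the
divergence date on the edge above the attachment point (an error if that
date does not fall on the edge). The fossil's branch length is
(divergence − fossil age) + 1 My when the fossil is younger than the
divergence, and a flat 1 My when its known age precedes the divergence.
"Younger" is operationalized as a strict comparison of the two dates; no
quantitative threshold for "substantially younger" exists in the
literature the rule derives from, so the strict inequality is the
package's choice. Grafting never changes path lengths among original tips,
and pruning the fossil back recovers the original tree exactly.

## Phylogenetic logistic regression

The binary label (MP = 1, so a positive slope favors male-biased power) is
modelled with a logistic mean P(yᵢ=1) = logistic(b₀ + b₁xᵢ) on a predictor
standardized after log₁₀ transform (mean 0, sample SD 1). Residual
dependence follows a quasi-likelihood / GEE scheme: working covariance
A^{1/2} R(λ) A^{1/2} with A the Bernoulli variances and
R(λ) = (1−λ)I + λ·corr(V), λ ∈ [0,1] the phylogenetic-signal parameter.
This working family is chosen for two properties: it is positive
semi-definite for any λ, and on a star phylogeny corr(V) = I so the
estimating equations collapse *exactly* to ordinary logistic IRLS — the
package's oracle test.

Estimation alternates Fisher scoring for (b₀, b₁) with a method-of-moments
update of λ (ρ-weighted regression of standardized-residual cross-products
on corr(V), weights emphasizing closely related pairs, clipped to [0,1],
damped by ½ between iterations). Numerical safeguards, each needed on
strongly clustered binary data:

* a ridge of 1e-4 on the estimating equations (shifts well-conditioned
  solutions by ~1e-5, far below reporting precision) keeps them coercive
  when R is nearly singular;
* Newton steps are capped at length 2;
* when the equations have no root at a proposed λ (a real phenomenon for
  binary GEE under near-singular working correlation), λ is halved and
  capped there — the fit settles at the largest solvable signal level;
* with identity working correlation the iteration is classical IRLS with
  step-halving, and the recorded binomial deviance is non-increasing.

Complete separation is diagnosed (linear predictor beyond ±30) and raised,
never silently returned. Optimizer tolerance is 1e-8 on the score norm,
300 iterations maximum.

**Parametric bootstrap.** Each replicate re-simulates the binary trait up
the tree under the fitted model — a two-state switching process whose
stationary probability at each tip is the fitted logistic mean — refits,
and records the estimates (default 2000 replicates, α = 0.05; replicates
that fail to converge are counted, and the bootstrap aborts if more than
20% fail). The simulator's retention parameter is chosen so that the label
correlation it *actually induces* (computable in closed form, including
the caps that keep conditional probabilities valid) matches the fitted
working correlation; matching the nominal retention instead systematically
under-replicates the dependence. The summary reports replicate means,
percentile intervals, two-sided percentile p-values (the implemented
reading of "bootstrapped p-values"), and — because the point estimator is
biased away from zero when phylogenetic signal is strong, which is the
standard motivation for bootstrapping this estimator — bias-corrected
estimates 2·b̂ − mean(b*) and "basic" intervals (2·b̂ − q₁₋α/₂, 2·b̂ − qα/₂).
The basic interval is the package's inferential interval: in the
calibration study below it covers at 0.99, while the raw percentile
interval covers at ~0.79.

## Discrete ancestral states (Mk)

A continuous-time Markov chain on {MD, CD, FD} with equal-rates structure
by default (symmetric and all-rates-different selectable); the likelihood
is computed by Felsenstein pruning with per-node rescaling, maximized over
log-rates (bounded scalar search for ER, Nelder–Mead otherwise). The root
prior is flat over the three states (stationary-prior optional); with the
ER structure the two coincide. Marginal ("scaled") likelihoods at each
internal node combine the pruning partials below the node with an
"outside" message computed in a preorder pass — equivalent to re-rooting —
and are normalized to sum to one. A single observed state yields a
degenerate rate-0 fit with a warning. Fitted rates and scaled likelihoods
were cross-checked during development against `ape::ace` (type `discrete`,
model `ER`), matching to printed precision; `ape` reports log-likelihoods
up to an additive log k from a different root-prior bookkeeping.

## Continuous ancestral states and model selection

Log₁₀ traits are modelled as multivariate normal, x ~ N(μ1, σ²V(θ)). The
mean and rate are profiled analytically (ML, divisor n); the shape
parameter of each non-BM model is optimized by bounded scalar search:
λ ∈ [0,1] scales off-diagonal covariances, κ ∈ [1e-6, 3] powers branch
lengths, δ ∈ (0, 3] powers node depths, OU strength α ∈ [0, 10] /My
applies the Ornstein–Uhlenbeck covariance decay, EB rate r ∈ [−5, 0] /My
the early-burst deceleration (`expm1` is used so the α, r → 0 limits
recover BM to machine precision). Parameter counts: BM 2, others 3;
AIC = 2k − 2lnL. Models failing to converge are excluded and reported.
Selection: among non-BM models with a likelihood-ratio test against BM
significant at 0.05, the lowest-AIC model's parameters rescale the tree;
otherwise the tree is untransformed. (The conventional lowest-AIC reading
is used for "best".)

Reconstruction exploits the Gaussian-Markov structure: node values given
tips have precision equal to the branch-length-weighted graph Laplacian
(edge weight 1/length), so the conditional means solve one sparse
harmonic system and the conditional variances are the inverse
internal-block diagonal times σ̂². This is algebraically identical to dense
GLS with an estimated root — the test suite asserts equality to 1e-8
against an independent dense implementation — and matches
`phytools::fastAnc` point estimates exactly (CIs differ by the ML-vs-REML
variance divisor, n vs n−1; ML is used here). 95% CIs use the normal
quantile 1.959964. σ̂² is floored at 1e-12 so degenerate constant traits
still yield defined (hairline) intervals. Reconstruction is done on the
log₁₀ scale and back-transformed by 10^x for ratio-scale reporting; the
back-transform is monotone, so node orderings are preserved.

## Ancestral power prediction

odds = exp(b₀ + log₁₀(m)·b₁) at the ratio-scale node MLE m, probability =
odds/(1+odds). The predictor enters unstandardized on the log₁₀ scale:
this convention exactly reproduces the published per-clade probability
table from its printed coefficients and MLEs (verified across all ~28
cells to ±0.01, the precision permitted by 2-dp rounded MLEs); a flag
applies full standardization (mean/SD of the fitted sample) for users
fitting their own data. Probability CIs are the mapped trait-CI endpoints,
kept in trait order — visibly reversed when b₁ < 0, as for sex ratio.
Named clades resolve to MRCA nodes of configured tip lists; when a larger
clade's node collapses onto a nested clade's MRCA because its
distinguishing members are missing from a predictor's dataset (the
haplorhine/anthropoid case without tarsiers), the more exclusive clade
keeps the node and the larger clade's cells are blank.

## Synthetic data

The fixture emulates the anatomy of the study sample: 79 species in six
clades (20 lemuriform, 5 lorisiform, 2 tarsier, 20 platyrrhine,
22 cercopithecoid, 10 hominoid) on a backbone with realistic divergence
dates (crown Primates 74 My) and Yule subtrees within clades
(birth rate 0.15/My). A latent dimorphism axis evolves by BM
(σ² = 5e-5 per My on the log₁₀ scale) with a +0.06 mean shift on the
catarrhine stem; BMR, CR and SR load on it (+1, +1.8, −1.2) plus
independent BM noise (σ² = 1e-4), around roots of 1.10, 1.10 and 0.70.
These values were calibrated once so the generated data reproduce the
documented features of the real sample — BMR spanning ~0.85–2.45 with
catarrhines most dimorphic, the >1.36 exclusion removing roughly the upper
quarter of species, and ~55–60% of species male-dominant — and are not
revisited per test. EO is right-skewed (10^N(0.6, 0.45²) percent, capped
at 100) and phylogenetically independent. The tarsier-like clade lacks CR
and SR, exercising the missing-haplorhine machinery.

Labels come from the Markov switching generator: every node gets a target
marginal P(MP) = logistic(0.2134 + 1.6228·z) (z the standardized log₁₀
BMR; internal nodes use descendant means), and the state is retained along
a branch of length t with probability signal^(t/T) (default signal 0.5,
T the tree height), capped so conditional probabilities stay valid. The
construction makes tip marginals *exactly* logistic for any signal, which
is what lets slope recovery be tested cleanly. A latent-liability
threshold generator is available behind a flag for robustness checks.
Non-MP labels split CD/FD by a fair Bernoulli. All generators are pure
functions of (config, seed).

**What passing tests show — and don't.** The fixtures share the real
data's dependence structure by construction, so recovery/coverage results
demonstrate internal consistency of estimator and generator, not
robustness to model misspecification: real power labels are scored from
heterogeneous literature, the true label process need not have logistic
marginals or this correlation family, and real predictors carry
measurement error the generator omits. The calibration study (100
fixtures, bootstrap reps 200 — sizes chosen to keep the default test run
proportionate) finds the bias-corrected slope estimator unbiased within
Monte-Carlo error, basic-interval coverage 0.99, and type-I error of the
bootstrap p within three Monte-Carlo SEs of the nominal 0.05; the raw
point estimator is biased upward under strong signal, which is precisely
why the bootstrap corrections are the reported quantities.

## Known limitations

* The logistic estimator is quasi-likelihood, not full likelihood; its λ
  is a working-correlation parameter, comparable across fits but not a
  calibrated evolutionary rate.
* Percentile p-values test whether the replicate distribution straddles
  zero; they are anti-conservative by ~2× at the 0.05 level in the
  calibration study (0.10 observed), within the accepted Monte-Carlo band
  but worth remembering for borderline effects.
* One predictor at a time, as in the analysis this package reproduces; no
  multi-predictor models.
* OU tree rescaling requires an ultrametric tree (the covariance-level
  transform has no tree representation otherwise); κ has no
  covariance-level form and is applied to trees only.
* Fossil placement takes divergence dates as user inputs; no dating or
  calibration is performed.
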