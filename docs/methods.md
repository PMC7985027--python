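# Methods

This note records the models, numerical choices, and design decisions behind
`vtstain`, and what the synthetic-data experiments do and do not demonstrate.

## Tiling and whitespace

Slides are processed as square tiles on half-open, 0-based boxes in row-major
order.  Two grids exist on purpose: the **training** grid is non-overlapping
(stride = tile size) and drops ragged edges, because training tolerates losing
a sliver of tissue; the **inference** grid appends an extra edge-flush origin
per axis whenever the last regular box stops short of the image edge, so the
union of boxes is provably the full pixel set (the coverage property is
brute-force checked in the tests).

The whitespace detector is deliberately simple: a pixel is whitespace when the
rounded mean of its R, G, B values exceeds a brightness threshold
(default 230 of 255), and a training tile is kept when its whitespace fraction
is at most 8%.  Both numbers are module defaults, not facts about any
particular scanner; the threshold matches the common slide-background
heuristic of near-saturated brightness, and 8% is the filtering operating
point the pipeline is designed around.  Tiles stay 8-bit RGB through all file
I/O (bit-exact round trips) and are converted to floats in [−1, 1] only
inside the translator.

## The stain translator

The training objective is the standard unpaired-translation triple for two
domains A (H&E) and B (trichrome):

* least-squares adversarial terms, `mean[(D(real)−1)²] + mean[D(fake)²]` for
  each discriminator and `mean[(D(fake)−1)²]` for each generator;
* cycle consistency, `L1(G_BA(G_AB(a)), a) + L1(G_AB(G_BA(b)), b)`, weight 10;
* identity terms, `L1(G_AB(b), b) + L1(G_BA(a), a)`, weight 5.

Training alternates discriminator and generator Adam steps on seeded batches
of random 32–256 px crops, checkpoints at iteration 0 (the baseline every
convergence comparison uses), every `checkpoint_every` iterations, and at
termination, and aborts cleanly—returning the checkpoints accumulated so
far—if any loss goes non-finite.

The networks are sized for a single CPU core, which is the scale at which
this package validates the *objective* rather than generator capacity: the
generators are per-pixel residual colour maps (`x + MLP(x)`, one hidden layer
of 16 units, i.e. a 1×1-convolution residual block) and the discriminators
are per-pixel colour critics of the same width.  Gradients are derived by
hand (the architectures are three matrix products deep), verified against
central finite differences in the tests.  For the synthetic stain pairs the
true inter-domain map is an affine palette map, which this family contains,
so translation error has an exact oracle.  Two optimizer profiles are used:
the conventional Adam(2e-4) default, and 3e-3 for the 500-iteration toy runs
in the examples and acceptance checks — per-pixel colour nets are far better
conditioned than deep convolutional generators and tolerate (and at this
iteration budget need) the larger step.  Generators initialize with a random
output layer by default so the initial cycle loss is positive and
convergence is measurable; an exact pass-through initialization
(`identity=True`) exists for the blending and baseline contracts.

## Whole-slide inference and blending

A slide is translated tile by tile on the edge-flush grid and re-assembled as
a weighted average: each output pixel is `Σ w·translated / Σ w` over every
covering tile, accumulated in float64 and quantized to 8 bits exactly once.
Because the normalization divides by the accumulated weights, the scheme is
exact by construction: an identity translator reproduces the input
bit-for-bit at any stride, and any per-pixel colour map commutes with the
tiling to within one quantization level — both are enforced as tests at
full-, 3/4- and half-tile strides on non-divisible slide dimensions.  The
weight map is a separable raised-cosine window
`h(i) = 0.5 − 0.5·cos(2π(i+0.5)/T)`, strictly positive (so the division is
always defined) and symmetric; it down-weights tile borders so the seams an
imperfect translator produces are feathered away.  Default overlap is half a
tile.  Slides smaller than one tile are reflection-padded, translated once,
and cropped.  Viewer export writes a tiled pyramidal TIFF whose levels are
2×2 block means halving until the largest dimension is ≤ 512, with level 0
bit-exact on read-back.

## Turing tests

Realism is assessed per rater and patch size (256/512/1024) on blinded,
shuffled sets of 100 real + 100 virtual patches sampled uniformly over
low-whitespace positions (whether to exclude whitespace is a module decision;
sampled patches obey the same ≤ 8% rule as training tiles).  The presentation
table carries no truth labels; unblinding requires the keyed manifest.  Each
(rater, size) cell is scored with a two-sided Fisher exact test on the
truth×guess table — probability-mass ordering over the hypergeometric support
with a 1e-7 relative tolerance on the mass comparison, validated against a
log-factorial enumeration oracle — and the test *passes* when p ≥ α = 0.05.
Under a simulated guessing rater the suite's rejection rate is calibrated to
at most α within Monte-Carlo error.

## The concordance model

The response is the virtual stage a rater assigned; the design pairs it with
the same rater's real stage from each staging round (round k pairs with
virtual round k when the generator produced one, otherwise with the single
virtual staging).  The likelihood is cumulative-logit with four ordered
cutpoints; real stage enters as a monotonic effect `b·Σ_{i≤x} ζ_i` with ζ on
the simplex; each rater has intercept and slope offsets (reference rater
zero); each case has a correlated random intercept and test-index slope.
Priors are weakly informative: Normal(0, 5) on cutpoints, `b`, and rater
effects; Dirichlet(1,1,1,1) on ζ (implemented as independent Exp(1) gammas,
which adds a harmless auxiliary scale); half-Normal(0, 2) on the random-effect
SDs; LKJ(2) on their correlation.  Interval reports use the upper-/lower-bound
simplification — two separate fits — rather than an interval-censored
likelihood, which is out of scope here.

**Sampler.**  The joint log-density is written explicitly and sampled with
adaptive Metropolis-within-Gibbs: component-wise random-walk updates on the
~18 global parameters (Robbins–Monro adaptation to 0.44 acceptance), joint
proposals along the empirically adapted covariance (classic adaptive
Metropolis with diminishing adaptation, target 0.25 — the cutpoints, rater
intercepts and monotonic coefficient are strongly correlated and coordinate
updates alone mix poorly), and vectorized per-case proposals for the
non-centred random effects (target 0.35).  Defaults are 2 chains × 1500
warmup + 2000 draws.  Convergence is gated on split-R̂ ≤ 1.05 over cutpoints,
coefficient, rater effects and SDs (arviz); if the gate fails the chains are
extended by further draw segments up to twice before the fit raises.  On the
default 120-case synthetic study a fit takes ~20 s on one CPU core, and
planted rater intercepts, the monotonic coefficient, and both group SDs are
recovered with ≥ 80% empirical coverage of 90% credible intervals across 20
replicates.

**Bias adjustment.**  "Bias adjusted" is operationalized as the
posterior-predictive expected stage `E[Y] = Σ_k k·P(Y=k)` with the rater
intercept and slope offsets replaced by their across-rater means (case random
effects retained), averaged over draws.  This is one defensible reading of
integrating the rater out of the predictive posterior; it is exactly a no-op
when all raters share identical effects, and in simulation it pulls a rater
planted one level high back toward the unbiased consensus.  Rows naming cases
absent from the fit are an error unless new-case prediction with zero random
effects is explicitly requested.

**Statistics.**  Spearman correlations use average ranks; bootstrap CIs are
percentile intervals over 10,000 case-level resamples (resampling cases, not
rows, respects the repeated-measures structure; row-level resampling is
available when no grouping exists).  The IQR ≤ 0.3 agreement filter and all
medians use linear-interpolation (type-7) quantiles — the convention must be
pinned for the 0.3 cutoff and the F ≥ 3.5 dichotomy to be reproducible.
Advanced-fibrosis agreement reports per-rater sensitivity on unanimous-F4
cases and Cohen's κ on the strict median-F=4 dichotomy with a 2000-resample
case-level bootstrap.

## Clinical endpoints

Stages enter as case-level across-rater medians (half steps allowed with an
even rater count).  Serology correlations are Spearman with pairwise-complete
deletion; sodium is capped at 137 mEq/L (the MELD convention) before
correlating; an AST/ALT ratio column is derived, undefined when ALT is
missing or zero.  Survival uses Kaplan–Meier curves with the log-rank test,
grouping either by the median stage rounded to the nearest integer — halves
round *up* (3.5 → 4), consistent with the separate F ≥ 3.5 advanced-fibrosis
dichotomy — or by that dichotomy itself.  Cox proportional-hazards fits (via
lifelines, Efron ties) adjust for age+BMI or age+sex; both covariate sets are
exposed because both are legitimate adjustment choices and neither is
privileged.  The composite ESLD event is the earliest of ascites,
liver-related hospitalization, encephalopathy, variceal bleed, varices on
imaging, hepatocellular carcinoma, dialysis, or prophylactic propranolol;
component onsets before the index date are a validation error.

## Synthetic data: what it emulates and what it does not

`make_stain_pair` renders a shared band-limited tissue texture with blob
nuclei in an H&E palette and produces the trichrome by a stored affine
palette map, plus a blue recolouring on a fibrosis mask whose area fraction
grows 0.10 per stage (0 at F0, 0.40 at F4) — monotone "fibrous tissue extent"
is the one histological property the generator preserves.  Because the map is
stored, translation error is measured against exact ground truth rather than
by eye.  Whitespace layouts (border, corner blocks) exercise the filters.

`simulate_rater_stages` draws real stages from a latent case severity read
through sharp cutpoints with per-rater logistic noise and a retest jitter,
then draws virtual stages *conditionally on the observed real stage* from the
concordance model itself, with planted rater biases (default intercept
offsets up to 0.5, slope offsets up to 0.6 on a monotonic coefficient of 6)
and correlated case effects (SDs 0.7/0.4, correlation 0.3).  Defaults are 280
cases and 4 raters with two real staging rounds; 15% of reports are widened
to the interval [stage−1, stage] (degenerate at F0, so the *observable*
interval fraction among F1+ reports is what matches 15%).  The upper bound of
a widened report equals the originally drawn stage, which is why upper-bound
fits recover the planted parameters cleanly.

`simulate_clinical` draws exponential event times with hazard
`baseline·exp(0.693·stage)` (doubling per stage), independent exponential
censoring calibrated by root-finding to a target censor fraction (default
60%), and serology linear in stage plus Gaussian noise with signs matching
clinical direction (AST/ALT/INR/MELD/Fib4 up; albumin/sodium/platelets down;
sodium straddles the 137 cap so the capping rule is exercised).  Cohort
covariates centre on age 53 and BMI 34.

What passing tests therefore show: the estimators are correct against their
own generative assumptions, the exact invariants hold, and the full pipeline
is deterministic under seeding.  What they do not show: performance on real
histology.  The image generator has no scanner artifacts, JPEG compression,
stain variation, edge staining or tissue deformation; the rater model has no
case-difficulty interactions or drift; serology noise is Gaussian and
independent across markers.  Cohort-scale agreement numbers measured here
describe the synthetic conditions only.

## Problem sizes and runtime

Defaults were chosen so the full validation runs on one CPU core in minutes:
256²-pixel slides with 64-px tiles for translator studies, 500-iteration toy
training, 120-case concordance studies (960 model rows), 10,000-sample
bootstraps, and 2-chain MCMC as above.  All generators and analyses are pure
functions of their seeds; the CLI writes byte-identical outputs on rerun.

## Known limitations

* The translator family is per-pixel in colour; it cannot express spatial
  texture synthesis, which is the point at desk scale (the objective and the
  surrounding pipeline are what is validated) but means toy translation
  quality saturates at the palette-map component of the synthetic transform.
* Interval reports are handled by bound selection, not an interval-censored
  likelihood; the two bound fits bracket, but do not integrate over, staging
  uncertainty.
* The random-walk sampler is adequate for the default model size (~260
  parameters); much larger cohorts or more raters would warrant a
  gradient-based sampler.
* `advanced_fibrosis_agreement` is sensitive to how many unanimous-F4 cases
  the cohort contains; with few such cases the sensitivity estimate is
  reported but carries little information.
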