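# Methods

`treegs` implements the analysis pipeline of a cross-generational genomic
selection (GS) study in a two-generation forest-tree breeding population:
pedigree-based evaluation (ABLUP), deregression of breeding values,
marker-effect prediction models, and the validation experiments that compare
them — together with a synthetic-data generator that reproduces the study
design so every stage is testable without external data.

## The evaluation model (ABLUP)

Phenotypes from a multi-site progeny trial are analysed with the
individual-tree linear mixed model

    y = Xb + Z1 a + Z2 sa + Z3 s(rep) + Z4 sf + Z5 f + e

with fixed mean, site and age effects; additive genetic effects
`a ~ N(0, A s2_a)` structured by the numerator relationship matrix `A`;
site x additive interaction `sa`; block-within-site `s(rep)`; site x family
interaction `sf`; family `f`; and a residual `e ~ N(0, I s2_e)` with a
common variance across sites (the parsimonious choice when many
environments are modelled jointly).

**Covariance of the site x additive term.** Every tree grows on exactly one
site, so a site x additive term with identity covariance would contribute to
each observation's variance only through the sum `s2_sa + s2_e` — it would
be exactly aliased with the residual, and no restricted likelihood could
separate the two (we observed the flat ridge directly: EM-REML wanders to
`s2_e -> 0` with `s2_sa` absorbing the difference). The term is therefore
given the additive covariance restricted to each site's trees
(block-diagonal over sites, independent across sites). Relatives planted on
the same site then share the interaction, relatives on different sites do
not, and the component is identified by the within-site vs cross-site
difference in relative covariance. The synthetic generator draws the
interaction with the same pedigree structure per site.

**Heritability.** The narrow-sense heritability is reported as

    h2 = s2_a / (s2_a + s2_sa + s2_sf + s2_f + s2_e)

The block-within-site variance is deliberately excluded from the
denominator. This is the convention of the study the package models; it
treats the block effect as a feature of the experimental layout rather than
of the phenotype a deployment population would express. `heritability()`
implements exactly this ratio.

**REML algorithm.** Variance components are estimated on the mixed-model
equations (MME). Two updates are available:

* `method="em"` — classical EM-REML. Monotone in the restricted likelihood
  (property-tested) but needs hundreds of iterations near boundaries.
* `method="ai"` (default) — a hybrid: 3 EM warm-up rounds, then
  Average-Information (Newton-type) steps. Each AI step is accepted only if
  it keeps all components inside a trust region and does not decrease the
  restricted likelihood (checked by a cheap extra factorisation); otherwise
  the iteration falls back to the EM update. Components near zero are
  excluded from the AI system (they make it numerically singular) and
  updated by EM.

Variances are constrained non-negative by projection on a small floor
(1e-8 x the fixed-effects-adjusted phenotypic variance); a component whose
*EM update* stays at the floor for 5 consecutive iterations is dropped from
the model. AI-only boundary visits do not count — Newton steps can
overshoot through zero even when the optimum is interior. Convergence
requires |d logL| < 1e-6 together with a relative parameter change below
1e-5 (components that are effectively zero are ignored in that test).
Defaults: 200 iterations maximum; non-convergence raises an error carrying
the likelihood trace.

Initialisation matters: all scalings use the *fixed-effects-adjusted*
variance (the OLS residual variance of y on X), not raw var(y), which in a
multi-site trial is dominated by site-mean gaps; a start scaled by raw
var(y) reproducibly fell into a degenerate zero-residual basin. The default
start assigns 70% of the adjusted variance to the residual and 20% to the
additive component.

At very small scale (a few hundred trees) the restricted likelihood of this
model family is genuinely multimodal and boundary solutions
(`s2_a = 0`) can be the global optimum of a particular realisation; this is
sampling behaviour, not an optimiser defect (verified by multi-start
comparisons), and it disappears at the study's actual scale.

All REML internals — the trace identities through the MME inverse, the
determinant identity `log|V| + log|X'V^-1X| = log|R| + log|G| + log|M|`,
the AI matrix, and prediction-error variances — are verified in the test
suite against direct dense-`V` computations on small problems.

**Derived statistics.** `SE_i = sqrt(PEV_i)` from the MME inverse;
reliability `r2_i = 1 - PEV_i / ((1+f_i) s2_a)`; theoretical accuracy
`r = sqrt(1 - SE_i^2 / ((1+f_i) s2_a))`, clamped at 0 when the radicand is
negative (flagged). EBVs are produced for every pedigree member, including
unphenotyped ones (property: an unrecorded tip individual's EBV equals its
parents' average EBV).

## Pedigree machinery

`build_A` uses the recursive tabular method; unknown parents are treated as
unrelated, non-inbred founders (sentinel `0` in files). Its output is
checked against a Monte-Carlo gene-dropping oracle (IBD probabilities from
2x10^5 allele drops) and closed forms. Effective population size uses
Lindgren's status number `Ns = 0.5 / theta`, with the group coancestry
`theta` computed from `A` as the mean of `A_ij / 2` over all ordered pairs
including self-pairs.

## Deregression

Garrick-style parent-average removal back-solves, per individual, the 2x2
system

    [ Z'PA Z_PA + 4L   -2L          ] [ PA  ]   [ y_PA   ]
    [ -2L              Z'i Z_i + 2L ] [ EBV ] = [ y_i-PA ]

with `L = (1-h2)/h2`, information contents from
`alpha = 1/(0.5 - r2_PA)` and `delta = (0.5 - r2_PA)/(1 - r2_i)`, and
`DEBV = y_i-PA / Z'i Z_i`. Parent-average reliability is
`(r2_sire + r2_dam)/4`, an unknown parent contributing 0. Records whose
reliability does not exceed their parent-average reliability (margin 1e-6)
carry no own information and are excluded from downstream GS training with
a logged count. No weighting of DEBVs is applied downstream. Parental
reliabilities for validation individuals come from the single full-data
fit (the alternative — training-only reliabilities — is not used; the
choice only perturbs `r2_PA` slightly and is documented here).

The coefficient-matrix reconstruction (multiplying the assembled 2x2 matrix
by `(PA, EBV)` reproduces the right-hand side) is asserted to 1e-10 for
every record, and the implementation is tested against an independent
matrix-multiplication solve.

## Marker-effect models

All models fit `y = 1 mu + Z g + e` on EBVs or DEBVs with the intercept
absorbed as the response mean and `Z` centred by training-set column means
(stored in the fitted model and re-used at prediction time).

* **RR-BLUP**: `g = (Zc'Zc + lambda I)^-1 Zc' yc`. When `p > n` the
  algebraically identical dual form
  `g = Zc'(Zc Zc' + lambda I)^-1 yc` is used — this is what makes
  panels of tens of thousands of markers tractable, and the two routes are
  asserted equal on toys. `lambda = s2_e/s2_g` can be estimated by REML on
  the equivalent kernel model (one eigendecomposition of `Zc Zc'` on the
  intercept's orthogonal complement, then a 1-D profiled optimisation). A
  genomic variance pinned at the zero boundary raises an error advising a
  fixed lambda.
* **GRR**: step 1 is RR-BLUP; step 2 sets per-marker
  `lambda_k = s2_e / (g_k^2 / (1 - h_kk))` where `h_kk` is the (n+k)-th
  diagonal element of the influence matrix of the ridge-augmented design
  `T = [[1, Z], [0, lambda I]]`. Block elimination reduces it to
  `h_kk = 1 - zc_k'(lambda^2 I + Zc Zc')^-1 zc_k`, an n x n solve checked
  against the brute-force `diag(T(T'T)^-1 T')`. Markers with vanishing
  step-1 effects or leverage ~1 get shrinkage capped at 1e12 (logged).
* **Bayes-B**: mixture prior — `var(g_k) = 0` with probability `pi`,
  otherwise scaled-inverse-chi-square(`nu`, S); fitted by a single-site
  Gibbs sampler (numba-compiled) sampling, per marker, an inclusion
  indicator (by integrated-likelihood Bayes factor at the current
  per-marker variance), the effect, and the variance. `pi` is fixed, not
  estimated; the analysis default is 0.5. Hyper-parameters are not dictated
  by the method: we use `nu = 5` and set S so the *prior mean* effect
  variance equals `R2 var(y) / ((1-pi) sum_k var(z_k))` with `R2 = 0.5`,
  i.e. the mixture explains half the response variance a priori; the
  residual prior scale matches the other half. Chains are reproducible
  from a seed; a degenerate residual draw triggers one jittered-seed
  restart. Test-scale defaults are 10,000 iterations / 2,000 burn-in /
  thinning 10; production-scale settings (100,000 / 20,000 / 100) are
  plain arguments.

A consequence of the S rule worth recording: with `pi = 0.5` the slab
variance is of the same order as the single-marker estimation noise, so for
null markers the spike and slab are nearly indistinguishable and their
posterior inclusion probability stays near the prior (~0.5) regardless of
signal strength elsewhere. Posterior inclusion probabilities are therefore
only informative about *which* markers carry effects when the prior is
sparse; the signal-recovery experiment in the acceptance suite accordingly
runs with `pi = 0.9` (still much denser than the simulated truth of 2%
causal markers), where enrichment of causal over null markers is strong
(~7x). Whole-genome *predictions* are insensitive to this choice.

Missing genotypes are imputed to the marker mean; markers with call rate
below 0.9 or zero minor-allele frequency are dropped; individuals with no
called genotypes are dropped with a warning.

## Validation experiments

Four scenarios pair training responses (F1 juvenile-height EBVs or DEBVs,
F1 mature-height EBVs or DEBVs) with matched validation responses for the
genotyped F2 set. Training uses tenfold partitions of the F1 individuals,
repeated ten times; the full F2 validation set is predicted in every fold,
fold predictions are averaged within a repetition, and the Pearson
correlation with the validation response ("accuracy") or the raw F2
phenotype ("predictive ability") is computed once per repetition. Reported
SEs are the standard deviation over the 10 repetitions divided by sqrt(10)
— which is why published SEs of this design are tiny (the validation set is
fixed; only the training resampling varies).

The ABLUP baseline runs on the same folds, re-solving the pedigree model on
each fold's phenotypes. Variance components are estimated once on the full
data and re-used across folds; re-estimating per fold is available
(`reestimate_varcomps=True`) but costs ~100 REML fits for a quantity that
changes negligibly between 90% resamples. The ridge lambda for
RR-BLUP/GRR is likewise estimated once per training response
(`lambda_policy="once"`, the default) with a per-fold option; the same
90%-resample argument applies. A training response with no detectable
genomic variance (typical for deregressed mature-height responses) falls
back to a hard shrinkage `lambda = 1e6` with a warning instead of failing.

**Cluster sub-analysis.** Validation individuals are split at an EBV
threshold (default: the sample median — any fixed split value is a
dataset-specific choice, so it is a parameter, not a constant) and each
cluster is re-scored under three training compositions: (1) all genotyped
F1; (2) all F1 minus the parents of the opposing cluster; (3) only the
cluster's own F1 parents. High overall accuracy combined with near-zero
within-cluster accuracy is the signature of a correlation driven by family
means rather than within-family information. The generator provides a
deliberately pathological two-lineage fixture (`build_two_cluster_bundle`:
two founder-disjoint families, F2 bred within lineage, a heritable mean
offset between lineages) on which this signature is reproduced; with only
two families the family variance components are inestimable, so that
fixture is evaluated with the family terms disabled and the lineage gap
flowing through the additive effect.

**Marker density.** Random marker subsets of increasing size are scored by
k-fold cross-validation with RR-BLUP, several draws per size (one fold
partition is shared across all sizes and draws, so the full-panel size
reproduces the plain CV exactly and the per-size spread reflects marker
sampling only).

## The synthetic generator

The generator is the package's study stand-in, not a test fixture: a
30-founder pool crossed into 37 full-sib F1 families planted on three sites
(449/441/431 trees), 17 F1 individuals reused as parents of 42 F2 families
on a fourth site (247 trees, 136 genotyped), juvenile height phenotyped in
both generations and mature height in F1 only. These counts, the per-site
heritability targets (0.19/0.22/0.13 for the F1 sites, 0.39 for the F2
site), and the low effective population size they produce
(status number ~21 for the 1321 F1 trees, emerging from the founder-pool
reuse rather than being set directly) are the emulated study's conditions.

Choices the emulated study does not pin down, fixed once here:

* **Marker panel, p = 2000 unlinked biallelic SNPs** (founder MAF ~
  U(0.05, 0.5)), with the ~100 causal loci (QTL) *excluded* from the panel.
  With unlinked loci, marker-QTL LD is exactly zero by construction, making
  "prediction accuracy reflects relatedness, not LD" the ground truth of
  the simulation rather than a hope. Marker-derived relationships converge
  at O(p^-1/2), so 2,000 markers reproduce the relatedness-driven regime
  that a 69k panel exhibits at full scale; the panel size is a fidelity
  parameter only for realized-kinship noise. An optional block-LD mode
  (founder haplotypes copied from a small per-block pool, crossovers at
  2% between adjacent loci) provides genuine LD for the density experiment.
* **Genetic architecture**: 100 QTL with bivariate normal effects for the
  juvenile and mature traits, correlation 0.7 (a loose calibration to the
  within-generation juvenile-mature correlation reported in the literature
  this design draws on), each trait's effects scaled so the expected
  additive variance `sum 2 p q a^2` hits `s2_a = 400 cm^2` (sd 20 cm).
* **Nuisance variances** relative to `s2_a`: site x additive 0.3,
  block 0.2, site x family 0.2, family 0.1 — moderate values typical of
  conifer progeny trials. Per-site residuals are solved from the target
  per-site h2 under the package's h2 convention (so an infeasible target
  raises immediately).
* **Fixed effects**: site means around 650 cm (juvenile, F1 sites), 350 cm
  for the younger F2 site, 2500 cm for mature height, plus a 30 cm/year age
  slope. Age is constant within a site, hence aliased with site effects —
  deliberately retained because the evaluation model must absorb such
  aliasing (the fixed design is reduced to full rank by QR pivoting).
* 1% missing genotypes; genotyped subsets mirror the design (all F1, a
  random 136 of 247 F2).

A single master seed fans out to named sub-streams (founders, gene drop,
effects, design, noise), so stages are independently reproducible. The
truth channel (per-individual true breeding values and Mendelian-sampling
deviations) feeds the parameter-recovery and deregression tests.

What the generator deliberately does not emulate: genome maps and realistic
LD decay, genotyping error and allele-dropout patterns, selection history
in the founders, non-additive (dominance/epistatic) variance, and
environment-specific residual variances (the evaluation model assumes a
common one; the generator's per-site residuals create a mild, realistic
misspecification). Passing tests therefore demonstrate correctness of the
machinery and the relatedness-driven phenomenology — not that real exome
panels behave quantitatively like the simulation.

## Problem sizes used in the shipped experiments

The acceptance experiments run the generator at the design's census scale
(1321 + 247 trees) with the 2,000-marker default; parameter-recovery
checks use single-site populations of n = 2000; the Bayes-B recovery
experiment uses n = 500 with 20 causal among 1000 observed markers; the
density experiment uses a 600-tree single-site block-LD population with a
~2,500-marker panel. These sizes were chosen so each experiment's Monte
Carlo error is small relative to the effect it demonstrates.

## Known limitations

* The evaluation solves dense MME (all pedigree members); fine to a few
  thousand individuals, not for national-scale evaluations (no sparse
  A-inverse assembly).
* Single-trait only; the juvenile/mature pair is handled as two separate
  fits, not a bivariate model.
* Bayes-B's `pi` is fixed, not estimated, and no Bayes-A/Bayesian-LASSO
  variants are provided.
* Realized-relationship (G-matrix) evaluation is out of scope.
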