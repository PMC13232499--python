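# Methods

This note documents the models, the synthetic data generator, the numerical
choices and the known limitations of `ensgp`.

## The prediction problem

Each unit of analysis is a *prediction scenario*: one RIL population, one
train/test ratio (0.8/0.2, 0.65/0.35 or 0.5/0.5), one resampling replicate.
RILs are split at the line level — with multi-environment data every record
of a RIL stays on one side, so no line leaks information across the split.
All six member models are fitted on the training side and scored on the
test side with Pearson correlation and MSE; models are then discarded, and
group-level summaries use medians (robust to occasional degenerate
scenarios). Scenario seeds derive from a single global seed by SHA-256
hashing of the (population, ratio index, replicate, stage) tuple, so any
scenario is reproducible in isolation.

## Member models

* **rrBLUP** — Bayesian ridge regression: all marker effects share a normal
  prior with common variance; scaled inverse-χ² hyperpriors (df ν = 5,
  scales splitting the phenotypic variance 50/50 between markers and
  residual a priori). Single-site Gibbs updates; posterior means of the
  intercept and effects are retained. With the variance components frozen,
  the posterior mean is exactly the closed-form ridge solution
  `(X′X + λI)⁻¹X′y`, which the tests exploit as an oracle.
* **BayesB** — per-marker point mass at zero (prior exclusion probability
  π = 0.5 under a flat Beta hyperprior, sampled each iteration) and a
  scaled-t slab implemented as a normal effect with its own scaled-inv-χ²
  variance (ν = 5). Inclusion is sampled from the marginal likelihood with
  the effect integrated out. As π → 0 the model reduces to rrBLUP, which is
  verified as a limiting-case test.
* **RKHS** — Gaussian kernel `K_ij = exp(−d²_ij / (h · mean d²))` on squared
  Euclidean genotype distances, bandwidth h = 1 (single kernel); the mean
  over training pairs sets the length scale. The Bayesian fit runs the
  ridge sampler on the kernel eigenbasis (eigenvalues below 1e-10 of the
  maximum dropped); test points enter through the cross-kernel.
* **RF** — scikit-learn regression forest, 1,000 trees, ⌊p/3⌋ features per
  split, unlimited depth, per-scenario seed.
* **SVR** — ε-insensitive RBF regression at library defaults (C = 1,
  ε = 0.1, γ = 'scale').
* **MLP** — one ReLU hidden layer, trained full-batch on inputs
  standardized with training-split statistics only. Presets:
  `teonam` = 50 units, dropout 0, 200 epochs, AdamW (decoupled weight decay
  0.01 on weight matrices); `maizenam` = 10 units, dropout 0.1,
  2,500 epochs, RMSprop (α = 0.99). Learning rate 0.005 in both. Written in
  numpy with seeded initialization and dropout, so training is
  deterministic given the seed.

MCMC models default to 12,000 iterations / 2,000 burn-in. The test suite
and the acceptance script run 2,000 / 500: at the panel sizes used there
the posterior means are stable well within the tolerances tested, and the
full-length chains remain the package default.

## Ensemble and the Diversity Prediction Theorem

The ensemble prediction is the unweighted mean of the six member
predictions per test record. For each scenario the three theorem terms —
ensemble (Many-Model) error, mean member error, prediction diversity — are
computed per test sample and averaged over the test set. Averaging makes
term 1 equal the ensemble's MSE exactly, which is asserted (to 1e-10
relative) every time a decomposition is built. Term summaries report the
mean, the standard error of the mean *across scenarios*, and
CV = sample sd / mean pooled over all ratios, populations and replicates
within a trait × dataset group; CV is flagged unavailable for single
scenarios or zero means. The ensemble's gain over the member mean is
reported as the median of (prediction diversity / mean error) — the
fraction of the mean member MSE removed by averaging — because that
quantity is scale-free and comparable across datasets with different trait
variances.

## Variance components

`GA = WW′/n` with W the column-mean-centered dosage matrix and n the number
of individuals — the /n normalization is used exactly as written rather
than VanRaden's 2Σpq scaling, so GA's diagonal mean depends on the marker
panel; proportions of total variance are unaffected.
`GAA = (GA⊙GA)/(tr(GA⊙GA)/n)` has trace n exactly. The extended-GBLUP REML
fit maximizes the restricted log-likelihood over log-variances with
L-BFGS-B from three spread starting points (log-parameterization keeps all
components positive; effective floor 1e-8, components bounded above by 50×
the phenotypic variance). The fixed effects are the GLS solution at the
optimum. Non-convergence raises with the last iterate and gradient norm.
Components are reported as proportions of their sum. For multi-environment
designs the fits run per environment and proportions are averaged within
population; dataset-level summaries use the median across populations,
which is robust to the extreme component values individual populations can
produce. Note that under weakly structured kinship (near-identity GA) the
additive and residual components are poorly identified — the null
simulations in the tests therefore use RIL panels with real family
structure.

## Marker effects

* Linear models: posterior-mean allele substitution effects.
* RF: impurity-based importance (mean weighted impurity decrease per
  feature over trees; sums to 1 after library normalization).
* RKHS/SVR/MLP: Shapley values by seeded permutation sampling. Each
  permutation draws one background row; walking the ordering from the
  background point to the explained sample makes the sampled values satisfy
  the efficiency property exactly with respect to the drawn baselines,
  and `|Σφ − (f(x) − baseline)| ≤ 1e-3 · spread(y)` is asserted per sample.
  The marker effect is the mean |Shapley value| over the explanation set
  (the scenario's training records, capped at 30), with a 100-draw
  background. Absolute values are used for track intensity.
* RF pairwise interactions: the Shapley interaction index estimated by
  subset sampling — a subset size drawn uniformly, then a uniform subset,
  which reproduces the Shapley interaction kernel exactly in expectation —
  with Δ_ij contrasts completed from background draws. Scores are
  symmetric by construction; the reported set keeps the top 0.01% of pairs
  by |score| (at least one pair), flagged within/between chromosome.
  Exact subset enumeration at small p serves as the test oracle. For dense
  panels a candidate-pair pre-screen (e.g. top markers by importance)
  bounds the cost.

Normalization is |raw| / max|raw| per model (scale- and sign-free, so
heterogeneous methods are comparable; all-zero profiles map to zeros); the
ensemble profile is the per-marker mean of the six normalized profiles.
Genome tracks bin the normalized effect into 10 decile levels; ties share
the lower level, so a constant profile is all level 1 and level 10 is
strongest.

## Synthetic NAM generator

Meiosis is a Poisson crossover process at 1 event / 100 cM with no
interference (Haldane map function) — the simplest defensible model.
Line development either backcrosses the F1 once to the recurrent parent and
then selfs 4 generations by single-seed descent (BC1-derived RILs: expected
donor allele frequency 0.25, F5-equivalent heterozygosity), or selfs only
(F5 lines: heterozygosity (1/2)⁴ = 0.0625). Genotypes are donor-allele
dosages in {0, 1, 2}; the generator never models selection, mutation or
segregation distortion.

Phenotypes: genetic value = Σ additive effect × dosage + Σ interaction
effect × dosage product. The epistatic component is orthogonalized against
the additive component before scaling (the standard variance-partition
convention; linked QTL otherwise induce covariance between the two), then
both components are rescaled so their population variances equal the target
fractions of the phenotypic variance and residual noise supplies the rest —
so realized heritabilities hit their targets in expectation for both
components. Environment shifts are additive.

Presets (chosen once, then frozen):

* **High-diversity preset** (`teonam_like_preset`): 5 BC1-derived selfed
  populations sharing one recurrent parent, 2 environments, 438–616 RILs
  per population, DTA-like targets (0.45 additive, 0.15 epistatic) and
  noisier ASI-like targets (0.30, 0.12); between-population heterogeneity
  as a deterministic linear ramp of trait scale (×0.6–1.8) and additive-h²
  multiplier (×0.6–1.4). The ramp emulates NAM designs whose populations
  differ strongly in phenotypic variance and variance-component
  composition because raw multi-environment phenotypes from divergent
  donors are analyzed directly.
* **Low-diversity preset** (`maizenam_like_preset`): 25 F5 selfed
  populations, one BLUE-like record per RIL, 126–196 RILs, targets (0.55,
  0.10) / (0.35, 0.10), near-flat ramps (×0.95–1.05) — per-population
  centering of BLUEs removes most between-population scale heterogeneity.

Trait scales are 3.0 (DTA-like, days) and 1.5 (ASI-like, days) before the
population ramp. What the generator does *not* emulate: linkage
disequilibrium inherited from ancestral haplotypes (founder genomes are
idealized homozygous lines), genotype-by-environment interaction beyond
additive environment shifts, genotyping error, and real marker ascertainment.
Passing tests therefore demonstrate the pipeline's statistical machinery
and the theorem's mechanics under controlled conditions, not performance
on any real dataset.

## Preprocessing

Missing genotypes are imputed from the nearest non-missing marker on the
same chromosome of the same RIL (cM distance; left flank on exact ties;
single flank copied at chromosome ends); observed calls are never altered.
RILs with a fully missing chromosome or no phenotype are removed with a
logged reason. LD pruning removes one marker of every pair with squared
dosage correlation ≥ 0.8 within a 30 kb window (PLINK indep-pairwise
style, 5-SNP steps), iterated to a fixpoint so an all-pairs within-window
audit of the output always passes; the removed member is the one with
lower minor-allele frequency (later map position on ties); monomorphic
pairs have undefined r² and are skipped with a flag. The window is in bp as
stated, not cM. Environments are concatenated as stacked records sharing
the RIL's genotype row with one-hot-minus-reference factor columns, and the
factor enters the models as an ordinary feature rather than a
pre-adjustment. Line BLUPs come from a one-way random-effects model with
environment fixed (per-environment centering), shrinkage by the line-mean
repeatability H² = (MS_line − MS_err)/MS_line, and BLUEs unshrink them as
BLUP/H² on the centered scale — the direct one-parameter inverse of the
shrinkage.

## Problem sizes

The test suite and the acceptance script run the scenario grids at 2
populations × 3 ratios × 10 replicates with 200 markers and 150 RILs per
population and 2,000/500 MCMC chains; variance-component recovery uses
n = 400 lines over 10–25 replicates; Mendelian checks use 1,000 lines;
Shapley exactness uses 4-marker models where exact enumeration is
feasible. Larger grids (e.g. the full 7,500-scenario design) are a
configuration choice, not a code path difference.

## Known limitations

* REML enforces nonnegative components; software that permits negative
  estimates can differ near boundaries.
* The sampled Shapley interaction index is a Monte-Carlo estimate; its
  per-pair noise floor is set by `n_samples`, and genome-wide all-pairs
  scans at dense p are expensive without candidate pre-screening.
* Ensemble weights are fixed and equal; weight optimization is out of
  scope.
* Single-trait analyses only; no dominance component; no G×E modeling
  beyond environment main effects.
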