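# Methods

chronosom analyses age-structured case/control expression cohorts — the
setting is post-mortem prefrontal-cortex transcriptomes with a control arm
spanning the whole lifespan and disease arms (schizophrenia, bipolar
disorder, major depressive disorder) restricted to post-onset ages — and
asks *when* each co-expressed gene module's disease trajectory first
diverges from the healthy aging trajectory.  This note documents the models,
their assumptions, the tunable parameters, and the design choices made where
the design was genuinely open.

## Preprocessing

The input is a genes × samples matrix of log2 expression and a metadata
table (diagnosis, age in years, sex, pH, post-mortem interval in hours,
batch).  Nuisance covariates are removed per gene by ordinary-least-squares
residualization: expression is regressed on an intercept plus the nuisance
design (categorical covariates effect-coded, continuous covariates
mean-centered) and the fitted nuisance component is subtracted.  The
component is mean-centered before subtraction so the per-gene grand mean is
preserved exactly even for unbalanced designs, where effect-coded columns
are not orthogonal to the intercept.  A rank-deficient design fails loudly,
naming the collinear columns.

Genes are then centered at their cohort mean (value − mean), so all
downstream values are signed log2 fold changes relative to the gene's
average expression.  Samples are assigned to nine age bins tiling (0, 100]
years — (0–1], (1–5], (5–10], (10–18], (18–35], (35–50], (50–65], (65–85],
(85–100] — with left-exclusive/right-inclusive membership (age 18 falls in
(10–18]).  Bins are used for portraits and DEG tabulation only; all
trajectory modelling uses continuous age.

## SOM portraits

A batch-mode self-organizing map compresses the N × M matrix into a k × k
grid of metagenes (default k = 50 for full-scale data; desk-scale runs and
the test suite use k ≤ 20).  Weights are initialized linearly on the plane
spanned by the first two principal axes of the gene profiles (grid
coordinates mapped affinely onto ±2 standard deviations), and trained for
40 epochs with a Gaussian neighborhood whose radius decays linearly from
k/2 to 0.5.  Batch updates make training deterministic given the data and
turn the zero-radius limit into Lloyd's k-means iteration, which the test
suite exploits as an independent oracle (converged zero-radius weights must
equal member-gene centroids).  Best-matching units are chosen by Euclidean
distance with ties broken toward the lowest metagene index.  The training
loss recorded per completed epoch (mean gene-to-BMU distance) is
non-increasing; the pre-training value is stored separately because the
first coarse smoothing step can sit above the linear initialization.

Each sample's portrait is the k × k reshape of its weight column; group
portraits are element-wise means.  Gene placement is identical across
samples, so portraits are directly comparable, and portrait similarity is
summarized by Pearson correlation over the K cells.

## Spot segmentation

The variance summary map holds each metagene's expression variance (ddof 1)
across all samples; the overexpression map holds the maximum of group-mean
metagene expression over groups.  Spots — connected clusters of metagenes
treated as gene modules — are segmented by thresholding a summary map at a
quantile of its values and taking connected components (8-neighborhood by
default, 4 as an option), discarding components below a minimum size
(default 3) and labelling survivors A, B, C, … by decreasing size.

Two refinements apply when a trained model is available, both validated on
planted-module cohorts (gene-list Jaccard ≥ 0.99 between every planted
module and its recovered spot across 20 generator seeds):

* metagenes with no assigned genes are treated as background.  The SOM
  interpolates weights smoothly, so empty cells between two module basins
  inherit high variance without carrying any genes and would otherwise
  glue distinct modules into one component;
* adjacency is gated by the Pearson correlation of neighboring metagene
  weight profiles (default r > 0.9).  Within a module, neighboring cells
  correlate above ~0.95; cells at the border of two distinct modules
  correlate only at the module–module level, so the gate severs exactly
  the spurious bridges.

At a 20 × 20 grid the default foreground quantile is 0.80: the budget of
cells above the 0.90 quantile (40 of 400) is smaller than the combined SOM
basins of even five modules, whereas at 50 × 50 the same quantile leaves
250 cells and the choice is uncritical.

Spot expression in a sample is the arithmetic mean of its member metagene
weights; spots that end up with no member genes are excluded from all
downstream modelling with a warning.

## Annotation

Gene Set Z-scores standardize a set's mean centered expression per sample:
Z = (mean over set genes − mean over all genes) / (sd over all genes /
√n_set), with the gene-wise standard deviation taken with ddof 1 and n_set
counting set genes present in the matrix.  Overrepresentation of a set in a
spot's gene list uses the one-tailed Fisher exact test — the hypergeometric
upper tail of the 2 × 2 spot-by-set table over the universe of all matrix
genes (the most conservative self-contained universe) — with
Benjamini–Hochberg adjustment across sets within each spot.  Cell-type
structure is read out by correlating spot expression with per-sample
signature Z-scores; edges are kept where Pearson r strictly exceeds the
threshold (default 0.5).

## Differential expression

Gene-level disease-vs-control comparisons run within one age bin as a plain
two-sample linear model (pooled-variance t-test), Benjamini–Hochberg
adjusted across genes; a gene is differentially expressed iff its logFC is
non-zero and adjusted p < 0.05, counted separately by direction.  No
empirical-Bayes variance moderation is applied.  When both arms of a gene
have exactly zero variance the test is degenerate; the record is flagged
and reports p = 1 for a zero difference or the smallest positive double for
a non-zero one, so pathological synthetic inputs cannot crash a run.

Spot-level comparisons regress spot expression on diagnosis plus continuous
age over the union of the disease's samples and all controls, reporting the
diagnosis coefficient and its two-sided p; a design in which diagnosis and
age are collinear fails explicitly.  Under a planted null the p-values are
uniform (Kolmogorov–Smirnov calibration over 200 simulations is part of the
test suite).

## Perturbation-time inference

For one spot and one disease, control observations follow a zero-mean GP f
with squared-exponential kernel k(t,t′) = σ_f² exp(−(t−t′)²/2ℓ²), and
disease observations follow g = f + d, where the deviation d is an
independent GP pinned to zero at the branch age τ: d(t) = 0 for t ≤ τ and
Cov(d(s), d(t)) = k_d(s,t) − k_d(s,τ)k_d(τ,t)/σ_d² for s, t > τ.  The
pinned form is the Schur complement of the deviation kernel conditioned on
d(τ) = 0, hence positive semidefinite by construction, and the deviation
variance vanishes continuously as t → τ⁺.  Independent Gaussian noise σ_n²
sits on every observation.  The τ-posterior is evaluated on a grid of 50
evenly spaced ages spanning the *control* age range — the published cohorts
contain no pre-onset cases, and a module may have diverged long before the
youngest patient was sampled, so the grid must reach below the disease
ages — under a uniform prior, normalized in log space; MAP ties break
toward the smaller τ.  The likelihood ratio compares the best grid τ
against the no-perturbation model in which both arms share one GP.

Two estimation choices matter and were settled by simulation under the
generator's own study conditions (60 controls on 0–85 y, 40 cases on
18–85 y, divergence amplitude 3× the noise sd):

* **Base hyperparameters** (σ_f², ℓ, σ_n²) are fitted by maximum marginal
  likelihood treating the two arms as *independent* GPs with shared
  hyperparameters (L-BFGS-B on the log-parameters, analytic gradients, one
  data-driven start plus seeded random restarts), with ℓ bounded below at
  20 years.  Fitting a single shared function to both arms would absorb a
  genuine divergence into the noise variance and flatten the τ profile
  beyond use; without the lower bound, a secondary "wiggly" optimum
  (ℓ ≈ 12–18 y, small σ_f²) occasionally wins and lets the base process
  itself absorb post-onset divergence.  Healthy lifespan programmes change
  on decadal scales, so the bound encodes the model's scale assumption.
* **Deviation hyperparameters** (σ_d², ℓ_d) are fitted separately, with
  ℓ_d confined to 1–10 years, by maximizing the branch likelihood over a
  coarse τ profile (every 5th grid point, Nelder–Mead warm-started along
  the profile) and then held fixed across the fine grid so per-τ
  likelihoods remain comparable.  Lifespan baselines are smooth — fitted ℓ
  is typically 30–50 y — while disease divergence develops within about a
  decade of onset; if the deviation inherited the base lengthscale, a long
  slow deviation branching at the edge of the sampled ages could mimic any
  later branch and the MAP would drift 6–15 years early.  The two bounds
  together impose a slow/fast scale separation between the shared
  trajectory and the post-onset deviation.

Because two deviation hyperparameters are fitted to the same data that the
τ scan evaluates, the reported likelihood ratio passes through a BIC guard:
the deviation counts as supported only if the best-τ log likelihood beats
the shared model by at least ln n (its BIC cost); otherwise LR is reported
as 1 and the raw ratio is retained alongside.  This keeps the LR > 1
cut-off honest under the null (all 16/16 null replicates at LR ≤ 1.05 in
validation) without touching genuinely perturbed modules, whose
log-likelihood gains are orders of magnitude larger.

Numerical hygiene: all likelihoods are evaluated in log space via Cholesky
factorization with an escalating jitter ladder (0 → 10⁻⁶ σ_f²); failure
beyond the ladder raises, since the construction is PSD and a failure
signals a bug.  The branch likelihood at τ beyond all observed ages equals
the shared model's to 10⁻⁹, and the dense multivariate-normal log-density
is reproduced to better than 10⁻⁶ at every grid point (both are acceptance
checks).

Known limitations: τ below the youngest disease sample is only weakly
identified — the posterior flattens there, and a MAP near zero should be
read as "diverged before the sampled range", not as a day-level estimate;
divergences that vanish again before the first disease sample are
undetectable in principle; the model assumes a single branch point per
spot × disease and homoscedastic noise.

## eQTL enrichment and the timeline report

Each spot × tissue pair gets a one-tailed Fisher exact test of spot
membership against a binary gene × tissue cis-eQTL flag table over the
matrix-gene universe.  Bonferroni correction multiplies by the number of
tissues tested per spot (family size is a config knob; per-spot families
are the default reading of "for each spot-tissue comparison"); enrichment
requires adjusted p < 0.05.  The final report joins spots with LR above the
cut-off (default 1) to their MAP ages, the sign of the age-adjusted disease
effect, and their enriched tissues, ordered by perturbation age.

## The synthetic cohort generator

The generator is first-class, tested code: it emulates the statistical
structure the analysis assumes so every stage is verifiable against planted
truth offline.  Control ages are drawn from the nine-bin mixture weighted
by the reference cohort design (253 controls; bins up to (85–100]); disease
ages are uniform on [18, 85] — the "no pre-onset cases" structure that
makes early-τ inference rest on the shared-before-τ assumption.  Planted
modules share a closed-form baseline trajectory (logistic rise/decline or
Gaussian peak in age; closed forms were chosen over GP draws precisely so
tests can evaluate expected values independently), the default five
emulating canonical aging-brain programmes: early neurodevelopmental
decline (midpoint 12 y), adolescent metabolic rise (20 y), myelination
peaking at maturity (30 y), midlife synaptic decline (45 y), late
glial/immune rise (55 y), each with amplitude 2 log2 units.  Disease
divergence switches on at the planted τ as a half-sigmoid ramp with a
5-year rise scale — zero for ages ≤ τ, smooth afterwards, matching the
branch model's continuity assumption — with default amplitude 3× the noise
sd and alternating sign.  Sample-level nuisance offsets (batch levels 0.4
log2 apart, sex ±0.1, 0.3 per pH unit, 0.01 per PMI hour) and i.i.d.
Gaussian noise (sd 0.5 log2) complete the model.  Background genes sit at a
constant baseline.  The noise magnitude and nuisance scales are free
parameters of the config, chosen as plausible for harmonized microarray
data, not estimates of any real cohort.

What the generator does **not** emulate: per-gene baseline offsets and
gene-specific trajectory variation within a module (module genes share one
trajectory exactly, so within-module correlation is higher than in real
data), probe-level effects, count noise, heteroscedasticity across age,
correlated nuisance structure, and overlapping module membership.  Passing
tests therefore certify the machinery — recovery of planted structure under
the model's own assumptions — not performance on real cohorts.

## Problem sizes

The default synthetic cohort is 2,000 genes (5 modules of 100 genes), 150
samples (60 controls, 3 × 30 cases) at k = 20 — sizes at which a full
pipeline run takes seconds on one CPU while exercising every stage; the
test suite uses 300–400-gene cohorts at k ≤ 8 for unit-level checks.  The
GP validation battery uses 60 + 40 observations per time course, 50-point
τ grids, and 12–16 replicates per condition.
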