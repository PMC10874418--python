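# chronosom

SOM transcriptome portraits and Gaussian-process perturbation-time
inference for age-structured case/control expression cohorts.

## The problem

Psychiatric disorders such as schizophrenia, bipolar disorder, and major
depressive disorder manifest in adolescence or adulthood, so post-mortem
brain cohorts contain no pre-onset patients — yet the molecular events that
set the diseases in motion may begin decades earlier.  Given a control arm
spanning the whole lifespan and disease arms restricted to post-onset ages,
chronosom asks, for each co-expressed gene module, *at what age the
disease's expression trajectory first diverges from the healthy aging
trajectory*, extrapolating before the youngest case through the assumption
that both arms share one trajectory until the branch point.

The pipeline (for bioinformaticians analysing harmonized bulk expression
cohorts, and for methodologists who need a fully synthetic testbed):

1. **preprocess** — per-gene OLS removal of batch/sex/pH/PMI effects, gene
   centering to log2 fold changes, nine-bin age grouping;
2. **som_portrait** — a k × k batch self-organizing map turns the N × M
   gene matrix into a metagene matrix; each sample's weight column, drawn
   as a k × k image, is its expression "portrait";
3. **spots** — variance/overexpression summary maps are segmented into
   connected metagene clusters ("spots"), the gene modules of the analysis;
4. **annotate** — Gene Set Z-scores, one-tailed Fisher overrepresentation
   (hypergeometric upper tail), and cell-type signature correlation;
5. **diffexp** — per-age-bin DEG counts and age-adjusted spot regression;
6. **perturbation_time** — the core: for each spot × disease, a GP
   branch-point model.  Control expression follows a GP f with RBF kernel
   k(t,t′) = σ_f² exp(−(t−t′)²/2ℓ²); disease expression follows g = f + d
   where the deviation d is pinned to zero at the branch age τ
   (Cov(d(s),d(t)) = k_d(s,t) − k_d(s,τ)k_d(τ,t)/σ_d² for s,t > τ, zero
   otherwise).  A uniform-prior posterior over a τ grid gives the MAP
   perturbation age; a likelihood ratio against the shared-trajectory model
   (LR > 1, BIC-guarded) flags time-perturbed modules;
7. **enrichment** — one-tailed Fisher eQTL enrichment per spot × tissue
   with Bonferroni correction, joined with the perturbation results into a
   timeline report.

A synthetic-cohort generator (`chronosom.synthetic_data`) plants modules
with closed-form age trajectories, per-disease divergence times, nuisance
effects and noise, so every stage is testable against known truth without
any external data.  See `docs/methods.md` for models, defaults, and
limitations.

## Worked example

Infer the perturbation age of one module time course with a divergence
planted at age 30 (amplitude 3× the noise sd):

```python
import numpy as np
from chronosom.perturbation_time import TimeCoursePair, analyze_spot
from chronosom.synthetic_data import divergence_ramp

rng = np.random.default_rng(4)
t_c = np.sort(rng.uniform(0, 85, 60))    # control ages, whole lifespan
t_d = np.sort(rng.uniform(18, 85, 40))   # disease ages, post-onset only
base = lambda a: 0.5 - 1 / (1 + np.exp(-(a - 40) / 12))
y_c = base(t_c) + rng.normal(0, 0.3, 60)
y_d = base(t_d) + divergence_ramp(t_d, 30.0, 0.9) + rng.normal(0, 0.3, 40)

res = analyze_spot(TimeCoursePair(t_c, y_c, t_d, y_d), seed=4)
print(f"MAP tau = {res.map_tau:.1f} y")
print(f"likelihood ratio = {res.likelihood_ratio:.3g}")
```

prints

```
MAP tau = 26.4 y
likelihood ratio = 2.74e+23
```

— the divergence planted at age 30 is located at 26.4 years (the posterior
in `res.posterior` quantifies the uncertainty; MAP estimates below the
youngest disease sample mean "diverged before the sampled range"), and the
enormous likelihood ratio says a shared trajectory is untenable.  On a
matched null course the ratio stays at ≈ 1.

Run the whole pipeline on a synthetic cohort (2,000 genes, 5 planted
modules, 150 samples, 20 × 20 SOM):

```bash
chronosom run-all --out-dir myrun --seed 1
```

which writes portraits, `spots.tsv` (five spots of 100 genes each on the
default cohort), `perturbation_results.tsv` (MAP τ and LR per spot ×
disease), `eqtl_enrichment.tsv`, and `timeline.tsv`, the final report of
time-perturbed, eQTL-enriched modules ordered by perturbation age.  Stage
verbs (`simulate`, `preprocess`, `som`, `spots`, `annotate`, `diffexp`,
`perturb`, `enrich`) re-run individual steps on a run directory;
`--config cfg.yaml` drives real input files instead of the simulator.

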