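# anaerodyn

Quantitative dynamics of commensal obligate anaerobes in the gut
microbiome of hematopoietic cell transplantation (HCT) patients.

Patients undergoing HCT receive cytotoxic conditioning and intensive
antibiotic treatment; their intestinal microbiota — normally dominated
by obligate anaerobes (Clostridia, Negativicutes, Bacteroidetes,
Fusobacteria) tied to colonization resistance and good transplant
outcomes — collapses over days. Because 16S sequencing alone is
compositional, quantifying that collapse requires absolute densities:
relative abundances multiplied by total 16S copies per gram of stool
from qPCR. `anaerodyn` is a pipeline for cohorts of near-daily stool
samples with medication records:

* **absolute abundance reconstruction** — per-taxon copies/g, pooled
  obligate-anaerobe density N, inverse Simpson diversity;
* **compositional volatility** — V(t+Δt/2) = (1/2Δt) Σᵢ|xᵢ(t+Δt)−xᵢ(t)|,
  half the Manhattan distance per day between consecutive genus-level
  compositions (0 = unchanged, 1 = complete daily turnover);
* **Bayesian hierarchical growth model** — per-day log changes of N
  regressed on transplant phase, seven unpooled empirical antibiotics,
  four partially pooled prophylactic antibiotics, a per-patient random
  intercept and a logistic capacity term:
  `y ~ N(r + β_p1·I + β_p2·II + Σβ_a·A + Σ(β_o+o_dev)·O + (1|P) + β_c·Ñ, σ_m)`,
  sampled by ensemble MCMC with R̂/ESS diagnostics;
* **posterior prediction** — per-patient forward simulation of density
  trajectories, and course-resampling estimates of the fraction of
  anaerobes lost over realistic antibiotic courses;
* **synthetic cohorts** — an 18-patient generator with known ground
  truth (phase structure, prophylactic/empirical exposure patterns,
  ~23% missing sampling days, multinomial 16S reads, qPCR noise) so
  the whole loop simulate → fit → predict is testable offline.

## Worked example

```python
import numpy as np
from anaerodyn import (GeneratorConfig, HierarchicalGrowthModel,
                       build_deltas, compile_courses, density_series,
                       generate_cohort, predict_course_loss)

samples, exposures, metas, truth = generate_cohort(GeneratorConfig(seed=1))
deltas = build_deltas(density_series(samples), exposures, metas)

model = HierarchicalGrowthModel(chains=3, draws=1500, warmup=500,
                                steps=600, seed=101).fit(deltas)
print(model.summarize())

courses = compile_courses(exposures, metas)
loss = predict_course_loss(model.posterior_, courses,
                           "piperacillin-tazobactam",
                           n_resamples=10_000,
                           rng=np.random.default_rng(3))
print(loss.percent_loss)
```

prints (328 deltas from 382 samples; posterior mean and central 95%
interval against the generative truth):

```
r                           +0.03  [ -0.13,  +0.20]   truth +0.05
phase1                      +0.09  [ -0.12,  +0.27]   truth -0.05
phase2                      -0.22  [ -0.41,  -0.00]   truth -0.30
piperacillin-tazobactam     -1.41  [ -1.61,  -1.21]   truth -1.50
meropenem                   -1.08  [ -1.30,  -0.88]   truth -1.20
cefepime                    -0.51  [ -0.82,  -0.20]   truth -0.80
capacity                    -0.03  [ -0.09,  +0.02]   truth +0.00
sigma_m                     +0.45  [ +0.41,  +0.50]   truth +0.50
pip-tazo: residual fraction 8.60e-05 -> percent loss 99.991
```

Effects are per-day natural-log growth-rate changes: −1.41/day for
piperacillin-tazobactam means the anaerobe community shrinks ~4-fold
per treated day beyond the baseline. Integrated over the cohort's
actual courses (durations, phases, coadministered drugs), a typical
piperacillin-tazobactam course leaves < 0.01% of the community —
the >99% loss regime expected for broad-spectrum agents.

## Command line

```bash
anaerodyn simulate --seed 1 --out cohort/        # four tables + truth
anaerodyn run --config run.yaml --out results/   # all stages
anaerodyn report --config run.yaml --out results/  # + figure analogs
```

`run.yaml` (defaults shown for the optional blocks):

```yaml
seed: 1
cohort:
  source: synthetic        # or: taxa/qpcr/meds/meta file paths
n_ref: 1.0e11              # capacity reference density, copies/g
sampler: {chains: 3, draws: 10000, warmup: 1000, steps: 1000}
predict:
  n_resamples: 10000
  drugs: [piperacillin-tazobactam, meropenem]
figures: false
```

Stages write `density.csv`, `volatility.csv`, `deltas.csv`,
`posterior.csv` (long-format chain/draw/parameter/value),
`summary.csv`, `loss.csv`, `forward_sim.csv` and `manifest.json`
(config hash, seed, input checksums, output inventory) into the run
directory. See `docs/methods.md` for the model, priors, generator
defaults and their rationale.

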