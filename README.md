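# treeresp

Intra-population climate response functions from pedigree-based genetic
evaluation.

`treeresp` combines individual-tree genetic evaluation (a bivariate animal
model fitted by REML, with BLUP breeding values predicted through Henderson's
mixed-model equations) with climate response functions, so that tree-to-tree
adaptive variation within a single population can be mapped along a climatic
gradient. A synthetic seed-orchard progeny simulator makes the whole pipeline
testable end to end by parameter recovery, without any external data.

## Pipeline

1. **orchard_sim** — simulate an open-pollinated clonal seed orchard:
   53 parents, pollen contamination (external sires flagged and treated as
   unknown), offspring planted across 21 sites on a winter-temperature
   gradient, two genetically correlated traits (growth as mean annual
   increment, recorded as height x stand age; wood density) with known
   heritabilities, plus a per-site climate table containing a collinear
   winter-temperature block and pure-noise decoy variables.
2. **pedigree** — validated pedigree (3-column CSV `id,sire,dam`, `0` =
   unknown), the average numerator relationship matrix **A** by the tabular
   method, half-sib/full-sib family structure, half-diallel coverage.
3. **animal_model** — bivariate REML (log-Cholesky parameterization; a fast
   eigendecomposition path for complete-case data and a general dense path
   for partial missingness), mixed-model equations for fixed site effects
   and breeding values with prediction-error variances, heritability and
   genetic correlation with delta-method SEs, all-pairwise site contrasts.
4. **performance** — mean annual increment (height/age), predicted
   phenotypic performance `PMAI = overall mean + site effect + breeding
   value`, and the rule trimming half-sib families represented in fewer
   than six sites.
5. **climate_select** — repeated random-forest importance ranking (mean
   decrease in accuracy via permutation, mean decrease in node impurity),
   top-k recurrence counts, collinearity blocks at |r| > 0.85, and
   nomination of the single gradient variable.
6. **response_function** — population- and family-level quadratic response
   functions of PMAI on the gradient variable (with linear and Gaussian
   alternatives compared by AIC), reporting the optimum (vertex), adjusted
   R² and overall F-test p-value per curve.

## Command line

```bash
# synthetic dataset (three CSV tables + truth sidecar)
respfun-pipeline simulate --seed 1 --out data/

# REML fit -> fit.json (variance components, h2, r_a, breeding values)
respfun-pipeline fit --pedigree data/ped.csv --phenotypes data/phen.csv --out fit.json

# climatic variable nomination and response functions
respfun-pipeline select-climate --climate data/climate.csv --performance perf.csv --runs 20 --seed 1
respfun-pipeline respfun --performance perf.csv --climate data/climate.csv --variable mtcm --out curves.csv

# everything at once, from a YAML config
respfun-pipeline run --config cfg.yaml
```

A minimal `cfg.yaml` for a synthetic run:

```yaml
out_dir: runs/demo
seed: 1
synthetic: true
min_sites: 6
collinearity_threshold: 0.85
rf_runs: 20
```

The manifest written by `run` contains the config hash, the seed and a
sha256 per artifact; reruns with the same config and seed are
byte-identical.

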