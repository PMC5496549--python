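# coralsieve

Analysis pipeline for a coral reciprocal-transplant experiment between a
highly variable (HV) and a moderately variable (MV) backreef pool:
colony-level fitness scoring, mixed-model and permutation inference,
weighted coexpression module detection from pre-transplant RNA-seq
counts, module–fitness association, and cross-experiment stability —
plus a synthetic-data generator that reproduces the statistical
structure of the study design with known ground truth.

## What it does

- **`coralsieve.synthetic_data`** — simulates the 21-colony × 12-crate
  design (13 MV-origin, 8 HV-origin colonies; 6 crates per pool):
  fragment loss, origin-dependent survival mean and variance,
  location-dependent growth, a negative colony-level survival–growth
  correlation, and negative-binomial count matrices with planted
  coexpressed modules (trait-linked or driven by a single outlier
  sample), follow-up panels, and symbiont proportions.
- **`coralsieve.io`** — validated readers/writers for the fragment
  table (`fragments.csv`), count matrices (`counts.tsv`), temperature
  logs, and a threshold-exceedance summarizer.
- **`coralsieve.fitness`** — per-colony proportional survival,
  crate-normalized survival/growth scores (OLS residuals on crate
  indicators), binomial/Gaussian mixed models with crossed random
  intercepts for colony and crate (ML; Laplace approximation for the
  binomial family — cross-checked against lme4 and a Gauss–Hermite
  oracle), backward-AIC model selection, reaction norms, the one-sided
  permutation test for heterogeneity in colony survival (shuffling
  outcomes within destination pools), sensitivity perturbations, and
  the survival–growth trade-off regression with leave-one-out influence
  analysis.
- **`coralsieve.coexpression`** — mean-count ≥ 1 coverage filter,
  median-of-ratios size factors, unsigned adjacency `|cor|^power`
  (default power 4), topological overlap, average-linkage clustering
  with a static cut, eigengene merging (merge cutoff 0.3), per-module
  eigengenes (first PC), and a leave-one-out filter for modules whose
  variance is carried by a single sample.
- **`coralsieve.association`** — eigengene vs fitness-score
  regressions with BH-adjusted q-values, origin t-tests, AIC comparison
  against symbiont composition, and projection of a module onto
  follow-up count panels.
- **`coralsieve.cli`** — `coralsieve` command with `simulate`,
  `fitness`, `coexpress`, `associate`, and `run` subcommands.

## CLI

```sh
# generate a synthetic dataset with ground truth
coralsieve simulate --seed 1 --out data_dir

# individual stages
coralsieve fitness --fragments data_dir/fragments.csv --out out/fitness \
    --n-perm 10000 --seed 1
coralsieve coexpress --counts data_dir/counts.tsv --power 4 \
    --merge-cut 0.3 --min-size 30 --out out/coexpress
coralsieve associate --eigengenes out/coexpress/eigengenes.csv \
    --scores out/fitness/scores.csv --symbionts data_dir/symbionts.csv \
    --modules out/coexpress/modules.csv --panels data_dir/panels \
    --out out/associate

# or everything from one YAML config
coralsieve run --config config.yaml
```

A minimal `config.yaml`:

```yaml
out_dir: my_run
seed: 1
params:
  n_perm: 10000
  power: 4
  merge_cut: 0.3
  min_size: 30
```

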