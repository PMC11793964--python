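# morphoconverge

Landmark-based geometric morphometrics for testing phenotypic convergence
between lineages over time. The package implements the full analysis chain:

1. **landmark_io** — readers/writers for 3D landmark files (CSV wide/long,
   TPS, pts), metadata and bilateral-pairing tables; dataset assembly and
   validation.
2. **superimposition** — centroid size, generalized Procrustes analysis
   (full Procrustes fit, proper rotations only), and object symmetry via
   reflected-relabelled copies (the symmetric shape component).
3. **ordination** — covariance PCA of Procrustes coordinates, group mean
   shapes, projection of new shapes into an existing morphospace.
4. **perm_stats** — Type II permutation ANOVA with residual randomization
   (RRPP), pairwise least-squares-mean distance tests, Procrustes variance
   (disparity) and pairwise variance-difference tests.
5. **convergence** — the multidimensional convergence index (MCI: ratio of
   pooled historic to pooled modern Procrustes variance of two lineages;
   values > 1 indicate convergence) with a label-randomization test.
6. **synthetic** — a generator of landmark datasets with a lineage x
   time-period design (lineage offsets, period shift, convergence factor,
   size structure) plus an analytic expectation for the MCI, used for
   calibration and testing without any external data.
7. **pipeline** — one-config orchestration of the whole workflow
   (full dataset "A" with the wild control, domestic-only dataset "B"),
   emitting per-stage CSV/JSON and a machine-readable run report.

## CLI

```bash
# generate a synthetic dataset (CSV long + metadata + pairs tables)
morphoconverge simulate --params params.yaml --out data/

# bundle coordinate + metadata + pairing files into one artifact
morphoconverge load --coords data/coords.csv --meta data/metadata.csv \
    --pairs data/pairs.csv --out dataset.h5

# symmetric GPA, shape PCA, permutation ANOVA, convergence test
morphoconverge gpa   --in dataset.h5 --out gpa/
morphoconverge pca   --in dataset.h5 --out pca/
morphoconverge anova --in dataset.h5 --response shape --perms 999 --seed 1 --out tables/
morphoconverge mci   --in dataset.h5 --rand 999 --seed 1 --out mci.json

# or run everything from one YAML config
morphoconverge run --config run.yaml
```

A minimal `run.yaml`:

```yaml
seed: 1
outdir: out/
simulate:            # or coords_path/meta_path/pairs_path for real data
  k_pairs: 6
  k_midline: 4
  convergence: 0.5
n_perm: 999
n_rand: 999
```

## Statistical conventions

* Permutation p-values count the observed statistic in its own null:
  `p = (1 + #{perm >= obs}) / (1 + n_perm)`, so 999 permutations floor at
  p = 0.001. Effect sizes `Z` standardize the observed statistic within
  the permutation distribution (on ln F for ANOVA terms; on the raw
  statistic for pairwise distances/variances — negative values mean the
  observation sits below the null mean).
* Type II sums of squares; residual randomization permutes reduced-model
  residuals, with each term's reduced model containing all terms that do
  not include it.
* Disparity (Procrustes variance) divides by group size `n_g`, not
  `n_g - 1`.
* The MCI randomization shuffles historic/modern attributions stratified
  within lineage by default (an unstratified variant is available for
  sensitivity analysis).
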