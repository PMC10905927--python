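# triclust

Model-based clustering of three-way (gene × time × experiment) time-course
RNA-seq data.

Genes measured over several time points in several experimental conditions
are usually clustered after flattening everything into one long vector per
gene, which discards the array structure and burns parameters on an
unrestricted covariance. `triclust` instead:

1. turns counts into **normalised expression profiles** — per-gene,
   per-experiment proportions over time (median-of-ratios size factors,
   pseudo-count, replicate averaging);
2. maps these compositions to Euclidean coordinates with the **additive
   log-ratio (ALR) transform** relative to the first time point (CLR and
   ILR pivot coordinates are also provided);
3. fits a mixture of **matrix-variate Gaussians** by EM, with a diagonal
   experiment covariance and a time correlation that is either a general
   correlation matrix or AR1 ($\rho^{|t-s|}$), selecting the number of
   clusters by ICL (or BIC). The Kronecker structure is the point: at
   $J=2$ experiments and 5 time coordinates the separable covariance has
   18 free parameters versus 55 for an unrestricted one;
4. diagnoses the partition with the **density-based silhouette (dbsi)**,
   a back-transformed **cluster map** (separation vs compactness with
   convex hulls), classic silhouettes, adjusted Rand index and
   contingency tables.

A simulation harness (`triclust.simulate`) reproduces the qualitative
comparison of this three-way route against a flattened Gaussian mixture
and k-means. See `docs/methods.md` for the model, defaults and numerical
choices.

## Worked example

Generate a synthetic 300-gene count table (6 time points × 2 experiments
× 3 replicates, drawn from a known 3-component model) and run the whole
pipeline:

```python
from triclust.simulate import synthetic_count_table, default_study_model

counts, meta, labels = synthetic_count_table(
    model=default_study_model(K=3), n_genes=300, n_replicates=3, seed=11)
counts.to_csv("counts.tsv", sep="\t")
meta.to_csv("meta.tsv", sep="\t", index=False)
```

```bash
triclust preprocess --counts counts.tsv --metadata meta.tsv -o step1
triclust cluster    --profiles step1/profiles.tsv --k-min 1 --k-max 6 \
                    --n-starts 4 --seed 0 -o step2
triclust evaluate   --profiles step1/profiles.tsv --model step2/model.json -o step3
```

Output of this exact run:

```
INFO triclust: read 300 genes, 6 time points, 2 experiments, 3 replicates
INFO triclust: selected K = 3 by ICL (loglik -908.92)
INFO triclust: overall average dbsi 0.809; per-cluster averages: 0: 0.529, 1: 0.835, 2: 0.964
```

with the criterion table in `step2/criterion_table.tsv` (per-observation
ICL minimised at K = 3):

```
K   loglik     nu   BIC      ICL
1   -2303.51   13   7.8019   7.8019
2   -1101.13   27   3.9271   3.9280
3    -908.92   41   3.4195   3.4432
4    -896.11   55   3.5099   3.6010
```

The recovered partition in `step2/assignments.tsv` matches the generating
labels with ARI 0.987. `step3/` contains per-gene diagnostics and the
dbsi, cluster-map and profile figures. Every subcommand also writes a
YAML snapshot of its configuration.

To use your own data, supply a TSV count matrix (first column gene ids)
plus a metadata table with `sample`, `experiment`, `time`, `replicate`
columns; an optional `--gene-list` file restricts the analysis to (e.g.)
differentially expressed genes.

## The simulation study

```bash
triclust simulate --n-datasets 10 --seed 1 -o study
```

runs the four-method comparison on 10 datasets of 769 genes drawn from a
moderately overlapping 10-component AR1 generator (average dbsi ≈ 0.58
under the true model's own posteriors). Result of this exact run
(~7 min on one CPU):

| method        | ARI (median, IQR)       | modal selected K |
|---------------|-------------------------|------------------|
| threeway-ar1  | **0.896** (0.853–0.901) | **8**            |
| threeway-full | 0.683 (0.647–0.765)     | 5                |
| twoway-gmm    | 0.570 (0.530–0.587)     | 4                |
| kmeans        | 0.217 (0.183–0.629)     | 2                |

Respecting the three-way structure with the parsimonious AR1 correlation
both recovers the partition far better and gets much closer to the true
number of clusters than flattening does.

## Layout

```
src/triclust/
  preprocess.py       counts -> size factors -> profiles (Step 1)
  compositional.py    ALR / CLR / ILR transforms (Step 2)
  matnorm_mixture.py  matrix-variate mixture EM, ICL/BIC, K selection (Step 3)
  postprocess.py      dbsi, cluster map, silhouette, ARI (Step 4)
  simulate.py         seeded generators and the comparison study
  cli.py              `triclust` command-line interface
docs/methods.md       model, defaults, numerical choices, limitations
scripts/acceptance.py seeded recomputation of the headline numbers
```
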