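# ascakit

ANOVA-based multivariate analysis of designed omics (LC-MS metabolomics)
experiments. The package decomposes a samples × variables matrix by the
experimental design and assesses factor significance with three related
multivariate methods, then compares the variables each method selects:

* **ASCA** — simultaneous component analysis of the ANOVA effect matrices,
  with an SSQ permutation test (the shared permutation engine).
* **rMANOVA** — regularized MANOVA: the within-group covariance is shrunk
  toward a scaled identity by a Ledoit–Wolf factor δ ∈ [0, 1]; δ = 0 is
  classical MANOVA (Lawley–Hotelling trace), δ = 1 reproduces ASCA
  p-values seed-for-seed.
* **GASCA** — group-wise ASCA: components whose loadings are confined to
  one group of correlated variables (groups = connected components of the
  thresholded |r| graph).

Reference baselines: PCA exploration, PLS-DA with VIP scores and
selectivity ratio (plus replicate-model stability frequencies), and
univariate t-test/ANOVA p-values with Benjamini–Hochberg adjustment.
Concordance tooling: top-k selection, Venn region counts, profile
correlations and coincidence counts against PLS-DA VIP.

A synthetic-data module generates p ≫ n feature matrices with planted
markers, correlated blocks, zero inflation, internal-standard channels and
per-sample drift (plus Gaussian-peak TIC chromatograms and centroided scan
tables for the simplified ROI feature extractor), so every stage is
testable with known ground truth.

## Library quick start

```python
import ascakit as ak

cfg = ak.SyntheticConfig(n_per_group=8, n_variables=500, n_markers=50,
                         effect_size=3.0, drift_sd=0.3, seed=42)
ds = ak.generate_feature_dataset(cfg)
table = ak.normalize(ds.features, ds.design).drop_internal_standards()
X = ak.autoscale(table.values)

res = ak.permutation_test(X, ds.design, "group", n_permutations=10_000, seed=1)
print(res.p_value)

model = ak.fit_rmanova(X, ds.design, "group", delta="auto")
groups = ak.find_groups(X, threshold=0.7)
```

## CLI

```sh
ascakit simulate --prefix demo --n-per-group 8 --n-variables 300 --seed 1
ascakit asca    --features demo_features.csv --design demo_design.csv \
                --factor group --nperm 10000 --seed 1
ascakit rmanova --features demo_features.csv --design demo_design.csv \
                --factor group --delta auto
ascakit gasca   --features demo_features.csv --design demo_design.csv \
                --factor group --threshold 0.7
ascakit plsda   --features demo_features.csv --design demo_design.csv \
                --factor group --selector vip --out ranking.csv
ascakit run -c config.yaml -o results/
```

`run` executes the full workflow (normalize → scale → decompose → all
methods → concordance report) from a YAML/JSON config with keys
`factor`, `synthetic` or `inputs` (features/design CSV paths), `scaling`,
`methods`, `k`, `n_permutations`, `seed`, `output_dir`; it writes a
deterministic `report.json`, per-method ranking CSVs and a parameter log.

## Notes

* The ROI feature extractor is a deliberately simplified greedy trace
  builder for centroided scan tables, not a full MSROI implementation.
* Unbalanced designs are supported for one-factor models; multi-factor
  models require balancing first (`balance_by_removal`).
* Permutation p-values use the (larger + 1)/(N + 1) convention: permuted
  statistics tied with the observed one (e.g. permutations reproducing
  the observed grouping) are not counted as exceedances.
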