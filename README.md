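# methyltraj

Pseudotime analysis of DNA-methylation aging as a tested, reusable pipeline:

- **`methyltraj.simulate`** — synthetic methylation cohorts with a latent aging
  state following a saturating sum-of-two-exponentials trend, per-site linear
  responses on the beta scale, two probe design types, and age-stratified
  train/validation/test splits. Generating parameters are retained for
  parameter-recovery tests.
- **`methyltraj.preprocess`** — site selection by |Pearson correlation with
  age| above a strict threshold, and probe-type-aware quantile normalization
  against a per-rank-median training reference.
- **`methyltraj.reduce_cluster`** — centered PCA embedding (components
  sign-fixed to correlate non-negatively with age) and a Gaussian-mixture EM
  under six covariance families (spherical/diagonal/full × shared/free) with
  BIC model selection.
- **`methyltraj.trajectory`** — single-lineage trajectory: Euclidean MST over
  cluster centers, start at the youngest cluster, local-linear
  principal-curve smoothing, and arc-length pseudotime with out-of-sample
  projection. Branching topologies raise an explicit error.
- **`methyltraj.pacemaker`** — alternating least-squares estimation of
  per-site intercepts/rates and per-sample epigenetic states
  (`m = m0 + r·s + eps`), initialized at chronological ages, with
  age-stratified cross-validation.
- **`methyltraj.trends`** — competitive fitting of five functional forms of
  age (quadratic, logarithmic, square-root, saturating exponential, sum of
  two exponentials; plus plain linear), Gaussian ML AIC / RMSE / R²,
  Pearson correlation with p-value, and exponential doubling times
  (`ln 2 / rate`).
- **`methyltraj.pipeline` / `methyltraj.cli`** — end-to-end orchestration
  with a TOML config, per-stage text serialization carrying the config hash
  and seed, bit-identical reruns, and stage-level resume.

## CLI

```bash
methyltraj simulate --n-samples 300 --n-sites 400 --seed 7 --outdir data/
methyltraj preprocess --betas data/betas_train.tsv --metadata data/metadata.tsv \
    --probes data/probes.tsv --outdir prep/
methyltraj fit-trajectory --betas prep/normalized_train.tsv \
    --metadata data/metadata.tsv --probes data/probes.tsv \
    --selection prep/selection.tsv --model-dir model/
methyltraj predict-pseudotime --model-dir model/ --betas prep/normalized_train.tsv \
    --metadata data/metadata.tsv --probes data/probes.tsv --out pt.tsv
methyltraj fit-epm --betas prep/normalized_train.tsv --metadata data/metadata.tsv \
    --probes data/probes.tsv --selection prep/selection.tsv \
    --model-out epm.tsv --states-out states.tsv
methyltraj fit-trends --data age_value.tsv --out trend_table.tsv
methyltraj run-all --config pipeline.toml
methyltraj report --outdir pipeline_out/
```

A minimal `pipeline.toml`:

```toml
seed = 7
outdir = "pipeline_out"
pcc_threshold = 0.4

[simulation]
n_samples = 1500
n_sites = 2000
seed = 7
```

All I/O is tab-separated text; every pipeline output carries the config hash
and seed in its header. Re-running `run-all` with the same config is
byte-identical, and stages whose outputs already exist are loaded rather
than refitted.

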