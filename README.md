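# codelcnn

Detection of chromosome 1p/19q co-deletion from per-bin copy-number
profiles with a two-branch ensemble 1D convolutional neural network, plus a
deterministic rule-based arm-deletion caller, FISH count interpretation,
SMOTE class balancing, cross-platform signal reformatting, ROC/Youden
evaluation and a synthetic-profile simulator.

## What it does

* **profile_io** — reads/writes per-bin log2 copy-ratio tables (CNR
  dialect: `chromosome start end gene log2 depth weight`) and a minimal
  array-probe dialect (`chromosome position log2`), plus label sheets.
* **vectorize** — orders each chromosome's bins and summarizes chr1 and
  chr19 as fixed-length vectors (1869 and 649 values). Denser platforms
  (e.g. SNP arrays) are harmonized by contiguous group averaging.
* **arm_caller** — rule-based "complete segmental loss" calls for
  1p (chr1:1-125,000,000) and 19q (chr19:26,500,001-59,128,983, hg19);
  co-deletion is the conjunction of both arm calls. Also implements the
  FISH scoring rules (combined target/control ratio < 0.75 or > 50% of
  nuclei with ≤ 1 target signal).
* **balance** — from-scratch SMOTE oversampling of the minority class on
  the concatenated chr1‖chr19 feature vector.
* **ensemble** — the two-branch 1D CNN: per-branch pretraining convolution
  /max-pool blocks, three bottleneck residual blocks each repeated 10
  times, global average pooling bridged to 1024 features per branch,
  concatenation to 2048, and a 2-class softmax head. Implemented directly
  on NumPy (explicit forward/backward passes, Adam optimizer) so it runs
  anywhere NumPy does — no deep-learning framework required.
* **evaluate** — ROC curve over all distinct thresholds, AUC, the
  Youden-optimal cutoff, and sensitivity/specificity at a cutoff.
* **synthetic** — simulator for labeled panel- or array-density profiles
  with full/partial arm deletions, per-bin Gaussian noise and tumor-purity
  attenuation; the package's self-contained test and demo data source.

## Tests

```sh
python -m pytest tests/
```

The suite includes a full end-to-end training run of the default
architecture (several minutes on one CPU); everything else is fast.

## CLI

One entry point with subcommands; all defaults live in a single YAML
config schema (see `PipelineConfig` in `codelcnn/cli.py`):

```sh
# simulate a labeled cohort (19 co-deleted / 42 controls by default)
codelcnn simulate --out-dir demo

# rule-based arm calls
codelcnn call --out-dir demo demo/*.cnr

# features -> SMOTE-balanced training -> model artifact
codelcnn featurize --out-dir demo --labels demo/labels.tsv demo/*.cnr
codelcnn train --out-dir demo --features demo/features.tsv

# ROC / AUC / Youden cutoff report
codelcnn evaluate --out-dir demo --model demo/model.npz \
    --features demo/features.tsv

# harmonize dense array profiles onto the panel vector lengths
codelcnn reformat --out-dir demo demo/*.probes.tsv
```

Every run writes a manifest (config hash, version) next to its outputs.

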