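# maskmol

Masked graph modeling for small-molecule generation. The package learns
conditional distributions of masked atoms and bonds given the rest of a
molecular graph, and generates molecules by iteratively masking and
resampling graph components — a Gibbs-style sampler over discrete molecular
graphs. It supports unconditional and property-conditional generation and
ships the standard distribution-learning metrics (validity, uniqueness,
novelty, KL-divergence score, pluggable Fréchet embedding hook).

## Layout

| module | role |
|---|---|
| `maskmol.molgraph` | complete-graph molecule representation, vocabulary, SMILES ⇄ graph |
| `maskmol.corruption` | per-slot independent masking (Bernoulli for training, fixed-fraction for generation) |
| `maskmol.mgm_net` | property embeddings, tied message-passing layers (GRU + LayerNorm node update, feed-forward edge update), simplex projection heads, scalar-property conditioner |
| `maskmol.train` | masked cross-entropy training, Adam with gradient clipping/accumulation, checkpoint selection by validation loss |
| `maskmol.sample` | training/marginal initialization and the K-step masked-resampling loop (single chain and batched ensembles) |
| `maskmol.evalmetrics` | validity / uniqueness / novelty / KLD score, Fréchet hook, Spearman metric-correlation matrix |
| `maskmol.fixtures` + `maskmol.cli` | exhaustive desk-scale molecule enumeration, dataset IO, command line |

The network runs on a small reverse-mode autodiff engine
(`maskmol._autodiff`, NumPy float64) so no deep-learning framework is
required; its gradients are tested against finite differences.

## CLI

```bash
# exhaustive fixture set: every valid molecule with <= 4 heavy atoms over C/N/O
maskmol fixtures --max-heavy-atoms 4 --elements C,N,O -o fixture.smi

# train (80/20 split by default), save checkpoint + JSON sidecar
maskmol train --train-file fixture.smi --d0 128 --layers 3 --epochs 100 \
    --seed 0 -o model

# generate by iterative masked resampling
maskmol generate --checkpoint model --train-file fixture.smi \
    --n-samples 500 --alpha 0.1 --steps 200 --init marginal --seed 0 \
    -o generated.smi --manifest run.json

# score a generated set
maskmol evaluate --generated generated.smi --dataset fixture.smi -o report.json

# Spearman correlation between metrics across runs (CSV: one row per run)
maskmol correlate --runs runs.csv -o matrix.csv
```

Conditional generation: train with `--conditional-property molwt` (or
`logp`), then pass `--target <value>` to `maskmol generate`.

Every verb accepts `--config file.yaml` supplying flag defaults, and
`--seed` fixes all randomness. Exit codes: 0 success, 2 config/validation
error, 3 data error.

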