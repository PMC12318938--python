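# moeyield

County-level crop-yield estimation with a dynamic-gated mixture-of-experts
sequence regressor, plus the full pipeline around it: a synthetic
multi-source data generator, vegetation-index feature engineering,
training/evaluation protocols, ablations with FLOP accounting, and
gradient-based feature attribution.

The model embeds a season of 10 monthly feature vectors (NDVI, EVI, NIRv,
Red, LAI, Fpar, RHum, Rad, DEM, SoC), runs parallel Transformer-encoder
(4 layers, 8 heads) and bidirectional two-layer LSTM branches, concatenates
them into a `t x 2d` representation, routes its temporal mean through a
sparse Top-2 softmax gate over five architecturally heterogeneous experts
(each with a linear adapter back to width `d`), and fuses the mixture output
with both branch final states through a 512 -> 256 -> 1 head. Training uses
Huber loss, Adam (lr 1e-4), batch size 32 and gradient clipping at 1.0.

Everything runs on NumPy: the package ships a small reverse-mode autodiff
engine (`moeyield.autodiff`) and layer library (`moeyield.nn`), so no deep
learning framework is required. Feature attribution uses a deterministic
expected-gradients estimator (integrated gradients averaged over a
background set).

## Layout

| module | contents |
| --- | --- |
| `moeyield.synthetic` | seeded county-year dataset generator (correlated greenness cluster, static DEM/SoC, dominant negative humidity effect, optional late-loaded effects) |
| `moeyield.features` | NDVI/EVI/NIRv/GNDVI, Magnus relative humidity, season assembly with gap interpolation, train-fitted min-max scaling, month truncation |
| `moeyield.model` | gate network, Top-k selection, five-expert pool with adapters, sparse/dense/single mixtures, the seven model variants |
| `moeyield.flops` | analytic per-sample FLOP counts (2·m·n per dense layer) |
| `moeyield.training` | Huber/Adam/clipping loop, fixed-year and leave-one-year-out rolling splits, progressive monthly evaluation, leakage-instrumented pipeline |
| `moeyield.evaluation` | R²/RMSE/MAE, min/max sample accuracy, yield-tercile error stratification, correlation screening |
| `moeyield.interpretability` | expected-gradients attributions aggregated per feature |
| `moeyield.io`, `moeyield.cli` | long-format CSV schema, checkpoints, manifests, `moeyield` command |

## CLI

```bash
moeyield simulate --seed 0 --counties 100 --year-start 2012 --year-end 2021 --out runs/sim
moeyield train   --data runs/sim/data.csv --variant stf_moe --epochs 100 --d 32 --out runs/train
moeyield rolling --data runs/sim/data.csv --epochs 30 --d 32 --out runs/rolling
moeyield early   --data runs/sim/data.csv --months 1,2,3,4,5,6,7,8,9,10 --out runs/early
moeyield ablate  --data runs/sim/data.csv --epochs 30 --d 32 --out runs/ablate
moeyield explain --data runs/sim/data.csv --model runs/train/model.npz \
                 --scaler runs/train/scaler.json --out runs/explain
moeyield screen  --data runs/sim/data.csv --out runs/screen
moeyield evaluate --predictions runs/train/predictions.csv --out runs/eval
```

Each run directory receives a `manifest.json` with the effective config,
seeds and library versions. A YAML config file (`--config`) can supply
`model:`, `train:` and `synthetic:` sections; flags override it.

Model variants: `stf_moe` (full sparse mixture), `stf_moe_dense` (all five
experts, no Top-2), `stf_single_expert`, `stf_no_moe`, and the baselines
`lstm`, `transformer`, `lstm_transformer`.

## Conventions

- Season: month index 1 = September through 10 = June; the harvest year
  labels the season.
- Scaling: min-max parameters are fitted on the training split only
  (targets included); metrics are reported in kg/ha after inverse transform.
- Top-2 gate weights are the raw softmax entries (no renormalization;
  `ModelConfig(renormalize_top_k=True)` switches it on).
- Determinism: every stochastic step (init, dropout, shuffling, splits,
  generation) is driven by explicit seeds; repeated runs are bit-identical.
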