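# pupilstate

Brain-state clustering and PCA-based decoding of pupil dynamics from
resting-state fMRI, with a synthetic-cohort generator that plants a known
ground truth so every stage of the analysis is verifiable at desk scale.

The pipeline covers:

1. **Synthetic cohorts** (`pupilstate.synthetic`) — masked voxel grids,
   latent spatial components whose band-limited time courses drive both the
   voxel signals and the pupil trace, multiple brain states with distinct
   coupling weights and ultra-slow pupil oscillations, and landmark tracks
   that invert the pupil-diameter formula.
2. **Pupil signal conditioning** (`pupilstate.pupil`) — landmark-to-diameter
   conversion, eye-size normalization, TR binning, variance normalization,
   a double-gamma HRF kernel family with causal convolution, and Welch PSD
   (512-point DFT, Hann window, 50 % overlap).
3. **Correlation maps** (`pupilstate.corrmaps`) — voxel-wise pupil–fMRI
   Pearson maps, concatenated all-trial maps, map similarity, and
   variogram-matched surrogate maps (same value multiset and spatial
   autocorrelation, randomized pattern).
4. **State clustering** (`pupilstate.clustering`) — UMAP (or a deterministic
   PCA fallback) embedding, full-covariance GMM with silhouette model
   selection over k = 3…7, consensus labels over repeated runs, label-match
   metrics, half-split and temporal-split reproducibility batteries.
5. **Decoding** (`pupilstate.decoding`, `pupilstate.gru`) — PCA feature
   extraction fitted on training trials only, a correlation-template
   baseline, closed-form OLS/ridge (default α = 19861) plus lasso and
   elastic-net, and a single-layer GRU decoder implemented in numpy with
   exact BPTT gradients, correlation loss (1 − r), and gradient-clipped Adam
   (published hyperparameters as defaults); fourfold cross-validation,
   shift and component-count sweeps, paired t-test comparison.
6. **Prediction maps** (`pupilstate.maps`) — back-projection of linear
   weights or mean GRU input gradients through the PCA basis, randomization
   significance (whole-trace pairing shuffles, two-sided empirical p with
   the (b+1)/(n+1) rule) with Benjamini–Hochberg FDR, per-component
   explained-variance attribution, and per-cluster retrained maps.
7. **Workflow** (`pupilstate.workflow`, `pupilstate.cli`) — YAML config,
   zero-phase 0.002–0.15 Hz Butterworth band-pass, NIfTI/CSV/JSON/NPZ I/O,
   and the end-to-end reproduction run with a JSON report.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: oracle
equivalences (ridge vs normal equations, template vs hand-computed
correlations, GRU forward/gradients vs scalar and finite-difference
oracles, BH vs manual step-up), formula fidelity (diameter, HRF family,
Welch peak recovery), and the stochastic recovery batteries (clustering,
decoding, map recovery, type-I error control, reproducibility) on planted
synthetic cohorts.

## CLI

```bash
pupilstate simulate  --config cfg.yaml --seed 1 --out run/   # write trial bundles
pupilstate preprocess --config cfg.yaml --out run/           # band-pass fMRI
pupilstate corrmap   --config cfg.yaml --out run/            # correlation maps
pupilstate cluster   --config cfg.yaml --out run/            # sweep + consensus
pupilstate decode    --config cfg.yaml --out run/ --method ridge
pupilstate maps      --config cfg.yaml --out run/            # map + significance
pupilstate report    --config cfg.yaml --seed 1 --out run/   # full pipeline
```

All generator, clustering, decoding and significance knobs live in one YAML
file; see `pupilstate.workflow.PipelineConfig` for the schema and defaults.

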