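# osteotex

Texture analysis of trabecular-bone radiographs for osteoporosis screening:
pixel-wise multiscale fractal-dimension maps (constant-physical-disk blanket
method), offset-averaged differential box-counting lacunarity, local
gray-range Shannon-entropy maps, Davies-Bouldin scale selection, a
ballot-based neighborhood-component feature selector, and an RBF-SVM
classifier evaluated with percentile-bootstrap confidence intervals.

Because clinical radiographs are not redistributable, the package ships a
synthetic-texture generator (`osteotex.synth`): fractional-Brownian surfaces
with known Hurst exponent `H` (surface fractal dimension `3 - H`) plus
sparse darkening blobs that emulate lesion patchiness. Every pipeline stage
is testable end to end against these ground-truth textures.

## Pipeline

| stage | module | CLI subcommand |
| --- | --- | --- |
| enhancement (flat-field, dehaze, contrast window) | `osteotex.preprocess` | `osteotex enhance` |
| ROI construction / projection-scale normalization | `osteotex.preprocess` | - |
| fractal / lacunarity / entropy features (11 total) | `osteotex.fractal`, `.lacunarity`, `.local_entropy` | `osteotex features` |
| Davies-Bouldin scale scan | `osteotex.scale_opt` | `osteotex scales` |
| ballot feature selection (60 rounds, keep best 30, top 6) | `osteotex.nca_select` | `osteotex select` |
| RBF-SVM training (CV log-grid over C and kernel scale) | `osteotex.classify` | `osteotex train` |
| metrics, ROC/AUC, bootstrap CIs | `osteotex.evaluate` | `osteotex eval` |
| synthetic cohorts | `osteotex.synth` | `osteotex simulate` |

Example run on synthetic data:

```bash
osteotex simulate --out-dir sim --n-per-class 30 --h0 0.7 --h1 0.5 --seed 1
osteotex select sim/features.csv --out-ballot ballot.csv \
    --out-selected selected.json --rounds 60 --seed 1
osteotex train sim/features.csv --features selected.json \
    --out-model model.json --seed 1
osteotex eval sim/features.csv --model model.json --out report.json
```

Feature CSVs have the 11 canonical columns `fd_mode, fd_sigma, fd_skewness,
fd_kurtosis, fd_entropy, lac_A, lac_B, ent_mode, ent_sigma, ent_skewness,
ent_kurtosis` plus `label`. ROI corners are read from JSON
(`{"corners": [[x, y], ...]}`, 0-based pixel coordinates, diagonals
`(c1, c3)` and `(c2, c4)`).

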