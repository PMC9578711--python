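# macroflim

Non-invasive classification of human macrophage polarisation from
two-photon fluorescence lifetime imaging (2P-FLIM) of NAD(P)H and FAD⁺
autofluorescence.

IFNγ-activated (M1) macrophages lean on glycolysis; IL-4-activated (M2)
macrophages lean on oxidative phosphorylation. That metabolic split is
visible label-free: enzyme-bound NAD(P)H has a long fluorescence
lifetime, free NAD(P)H a short one, and the FAD⁺/NAD(P)H intensity
ratio tracks the cellular redox state. `macroflim` implements the full
computational workflow around that idea, for imaging groups who want to
phenotype macrophages (or validate a FLIM rig and analysis chain)
without staining:

- **Synthetic data** — seeded generators for per-pixel TCSPC
  photon-arrival histograms, matched FAD⁺ images, donor cohorts with
  the sequential-inhibitor design (oligomycin → FCCP → rotenone +
  antimycin A → 2-DG), and ECAR/OCR flux series, so the whole pipeline
  is testable without any instrument data.
- **Decay fitting** — tail fit (no IRF) of the bi-exponential model
  `I(t) = I₀[α₁e^(−t/τ₁) + α₂e^(−t/τ₂)] + C`, gated by reduced
  chi-square (χ²ν < 1.3), with `τ_avg = (τ₁α₁ + τ₂α₂)/(α₁ + α₂)` and
  the optical redox ratio `ORR = FAD⁺ / NAD(P)H`.
- **Phasor analysis** — model-free `(g, s)` coordinates at the laser
  repetition frequency and projection onto the fixed 0.4–3.4 ns
  reference chord.
- **Single-cell analysis** — segmentation from the NAD(P)H intensity
  image, per-cell aggregate-decay fits, and greedy centroid tracking
  across the inhibitor sequence (the field of view is held fixed).
- **Flux metrics** — phase means, basal/max glycolysis and respiration,
  and per-phase trapezoidal AUCs from ECAR/OCR series.
- **Classification** — random forests with trees capped at 8 terminal
  nodes, `(ntree, mtry)` tuned by out-of-bag (OOB) error grid search,
  ROC-AUC and confusion counts, OOB-permutation (mean decrease
  accuracy) and Gini importances, stratified 75/25 splits for per-donor
  single-cell models, and cosine-metric UMAP embeddings.

## Worked example

Fit one simulated megaphoton decay (`examples/01_simulate_and_fit.py`):

```
truth: tau1=2.500 ns  tau2=0.400 ns  alpha1=0.300  tau_avg=1.030 ns
fit:   tau1=2.495 ns  tau2=0.398 ns  alpha1=0.302  tau_avg=1.031 ns
chi2_nu=0.827  good=True  photons=1000000
```

Both lifetimes come back within a fraction of a percent and the fit
passes the χ²ν < 1.3 gate. Classify the default synthetic cohort —
6 donors × 2 phenotypes × 3 FCCP fields, i.e. 36 full field-of-view
rows (`examples/05_classification.py`):

```
rows: 36  selected ntree=50 mtry=1
OOB error: 2.78%  OOB ROC-AUC: 0.991
confusion (TP, FP, FN, TN): (18, 1, 0, 17)
               mda  mda_se     mdg
tau_avg_ns  0.1619  0.0274  0.3466
tau1_ns     0.1223  0.0239  0.2787
tau2_ns     0.0540  0.0140  0.1912
alpha2      0.0197  0.0093  0.0897
orr         0.0140  0.0058  0.0937
```

The lifetime family (τ_avg, τ₁, τ₂) dominates both importance
rankings, matching the biology the generator encodes: the M1/M2
lifetime contrast is strongest under FCCP. The other examples cover
phasors, single-cell features with tracking, flux rates and the
config-driven full pipeline.

## Command line

```bash
macroflim run --config config.yaml --seed 7 --out results_dir
```

Subcommands `simulate`, `features` (aliases `fit`, `phasor`,
`segment`), `classify` and `flux` run individual stages; every stage
materialises its outputs (TIFF/CSV/JSON), so later stages can rerun
from an earlier run's directory. Exit codes: 0 success, 2 invalid
configuration, 1 stage failure.

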