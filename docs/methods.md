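# Methods

## Decay model and fitting

Each pixel (or aggregated region) carries a TCSPC histogram of photon
arrival times over one laser period: 80 MHz repetition rate → 12.5 ns
window, 256 bins of ~48.8 ps. The model is the bi-exponential decay

    I(t) = I0 [ α1 exp(−t/τ1) + α2 exp(−t/τ2) ] + C

with τ1 the long (protein-bound NAD(P)H) and τ2 the short (free
NAD(P)H) lifetime, αi the fractional amplitude paired with τi
(α1 + α2 = 1), and C a constant background in photons/bin. The pairing
of αi with τi and the convention that index 1 is the long component
are enforced by a post-fit swap; amplitude-weighted mean lifetime
τ_avg = (τ1 α1 + τ2 α2)/(α1 + α2) always lies in [τ2, τ1].

Fitting is a tail fit: no instrument response function is modelled, so
only bins from the histogram peak onward are fitted, with five free
parameters (I0, α1, τ1, τ2, C), bounds τ ∈ [0.05, 10] ns, α1 ∈ [0, 1],
C ≥ 0, and starting values τ1 = 2.5 ns, τ2 = 0.4 ns, α1 = 0.5,
I0 = peak count, C = min bin count (the physiological NAD(P)H range).
Times are taken at bin centres relative to the peak-bin edge; the
midpoint rule keeps the binned-model bias second order — with bin-edge
times the α estimate picks up a multiplicative e^(w/2τ) bias per
component, visible as ~+0.01 on α1 at default settings.

Two objectives are available:

- `poisson` (default): Poisson maximum likelihood, implemented as
  least squares on signed deviance residuals so it runs through the
  same bounded trust-region optimiser as the WLS branch. It is
  calibrated (χ²ν ≈ 1.00) from per-cell photon budgets (~2×10⁴
  photons) up to megaphoton aggregates.
- `wls`: classic Neyman weighting 1/max(counts, 1). At ≥10⁵ photons it
  is indistinguishable from the Poisson fit; below that the
  low-count bias inflates χ²ν (mean ≈ 1.15 at 2×10⁴ photons, ~30% of
  fits then fail the goodness gate). It is kept because Neyman
  weighting is the common TCSPC convention, but it is deliberately not
  the default for exactly that reason.

Goodness of fit is the reduced chi-square with model-based Poisson
variance floored at 1, Σ(obs − model)²/max(model, 1) over the fitted
bins, divided by (fitted bins − 5). Fits with χ²ν < 1.3 are flagged
`good`; everything downstream admits only good fits. Units below the
photon minimum (500 by default) raise or, in batch mode, are emitted
as failed rows rather than aborting the batch.

The optical redox ratio is FAD⁺ intensity divided by NAD(P)H
intensity; per cell it is the ratio of mask means, per field the ratio
of mask sums. Full-field fits aggregate all pixels passing an
automatic photon mask (Otsu threshold on log1p counts) into one decay;
per-pixel fitting is supported in principle but per-cell and per-field
aggregates are the working units (cost, and single-pixel budgets are
too small for stable five-parameter fits).

## Phasor representation

g = Σc·cos(ωt)/Σc, s = Σc·sin(ωt)/Σc with t at bin centres and
ω = 2π × 80 MHz (fundamental harmonic; the harmonic is configurable
but defaults to 1). Mono-exponential decays land on the universal
semicircle (g − ½)² + s² = ¼ to ≤10⁻⁴ at 256 bins; the transform is
exactly linear in photon-wise mixtures. Decays are summarised by
orthogonal projection onto the chord joining the mono-exponential
phasors of 0.4 ns (free) and 3.4 ns (bound) — the standard NAD(P)H
reference pair — clipped to [0, 1] toward the long end. No instrument
phase/modulation calibration is applied (the synthetic data need
none); a calibration factor can be folded in upstream for real data.

## Synthetic data: what it emulates, what it does not

The generator is the package's ground-truth instrument. Per decay,
component i is chosen with probability ∝ αiτi (its share of the
integrated intensity) and the arrival time is drawn from a
window-truncated exponential by inverse CDF; background is Poisson
with mean C per bin. Truncation rather than periodic wrap-around keeps
the forward model exactly the one the fitter inverts; the only
systematic it introduces is a 1/(1 − e^(−T/τ)) amplitude inflation,
< 1% for τ ≤ 2.5 ns at T = 12.5 ns. Expected component-i photon
fractions equal αiτi/Σαjτj exactly.

Fields are non-overlapping disks (default radius 6 px at the 128 px
test scale, 24 cells per field as the minimum-cells-per-FOV convention)
placed by rejection sampling with ≥ 2r + 6 px centre separation so
cells remain separate connected components after the segmenter's
smoothing; positions depend only on (seed, donor, phenotype, field),
so a field keeps its layout across the treatment sequence, as in a
maintained field of view. Each cell draws (τ1, τ2, α2, ORR) from the
condition means plus an additive per-donor Gaussian random effect
(shared across that donor's conditions), a per-field wobble, and
cell-level noise. The FAD⁺ image realises each cell's ORR target as
Poisson counts with mean ORR × (realised NAD(P)H total)/area per
pixel, making the ratio exactly invertible in expectation.

Condition means sit in the physiological NAD(P)H range and encode the
established polarisation contrast — M2 above M1 in τ1, τ2, τ_avg and
below M1 in ORR, at full strength under FCCP (Δτ1 = 0.5 ns,
Δτ2 = 0.10 ns, Δα2 = −0.04, ΔORR = −0.15) and scaled to 0.3–0.5 for
the other treatments. Default cohort: 6 donors × 2 phenotypes ×
3 fields per condition (36 full-FoV rows under FCCP) with ~2×10⁴
photons per cell.

Deliberately not modelled: optics (PSF, IRF, detector afterpulsing),
photobleaching, cell morphology beyond disks, touching/overlapping
cells, cell motion between treatments, and donor-specific class
overlap. Passing tests therefore demonstrate that the analysis chain
is correct and well calibrated on data obeying its own model
assumptions — not that real images of real donors will classify this
cleanly. The default cohort separates more strongly than typical
donor data (per-donor single-cell ROC-AUC ≈ 1.0 here), so published
donor-level numbers should be expected to be lower and more variable.

## Segmentation and tracking

Gaussian smoothing (σ = 1), Otsu threshold on log1p intensity (or an
absolute threshold), connected-component labelling, removal of
components under `min_area` (20 px) and of border-touching components
(partial cells bias lifetime aggregates); labels are relabelled
consecutively. Watershed splitting exists behind a flag for real data
with touching cells but is off by default. Tracking across treatments
is greedy nearest-centroid matching by ascending distance within a
10 px radius; unmatched cells are flagged appeared/lost rather than
dropped silently.

## Flux metrics

Five phases are delimited by the four injections; a measurement
exactly at an injection time belongs to the preceding phase. Summary
rates follow the manufacturer-convention arithmetic, with
non-glycolytic ECAR operationalised as the post-2-DG phase mean and
non-mitochondrial OCR as the post-Rot+AA phase mean (the terms are
referenced but not defined upstream; the post-inhibitor plateaus are
the conventional estimates). AUCs are trapezoidal over each phase's
measured span, hence exactly additive over interior splits. Paired
blank-series subtraction shifts phase means by exactly the blank.

## Classification

Predictors are τ_avg, τ1, τ2, α2, ORR; α1 is removed because it is
deterministically 1 − α2. Rows failing the χ²ν gate are excluded.
Random forests use trees capped at 8 terminal nodes; (ntree, mtry) are
selected by grid search on the OOB error over
ntree ∈ {50, 100, 150, 200, 250, 300, 400, 500} and mtry ∈ {1..p}
(ties break toward the smaller ntree, then smaller mtry — the cheaper
model). The full field-of-view model is evaluated on its OOB
class-probability votes (36 rows leave no honest holdout; OOB is the
only unbiased score available at that size); donor-level single-cell
models use a stratified 75/25 train/test split and are scored on the
held-out quarter. The positive class for TP/FP accounting is M1 and
probabilities ≥ 0.5 are called positive, so vote ties go to the
positive class. Mean decrease accuracy is per-tree OOB permutation
importance (averaged over trees, with its standard error reported);
mean decrease Gini is the forest's accumulated impurity reduction.
ROC-AUC is the pairwise-ranking probability with ties counted ½.
z-score matrices use the population SD (ddof = 0); zero-variance
columns map to zero with a warning. UMAP embeds with cosine distance
and a fixed random state; n_neighbors is clamped below the row count.

## Pipeline and reproducibility

Every stochastic operation takes an explicit seed; cohort generation
derives all per-field streams from (seed, donor, phenotype, treatment,
field) seed sequences, so runs are bitwise reproducible and
individual fields can be regenerated in isolation. The pipeline
materialises every stage (TIFF stacks + JSON sidecars, CSV tables,
JSON reports) and a rerun into a clean directory reproduces the CSV
outputs byte-identically. Configuration documents are strictly
validated: unknown keys are rejected by name, exactly one input mode
may be active, and a missing seed is an error.

## Problem sizes

Tests run the generator at 64–128 px with 5–24 cells per field and
2×10³–10⁶ photons per decay; the acceptance script uses the default
cohort (36 fields, 864 cells, 128 px) and 100 megaphoton decays.
Production-scale 512 × 512 imaging is a configuration change
(`image_size`), not a code path change.
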