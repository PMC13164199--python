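# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the pipeline. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pipeline overview

1. **Simulation** — GC–IMS peak table and NIR spectra with the study's
   sampling structure (7 samples, 3 GC–IMS replicates, 50 spectra/sample on
   two instrument grids).
2. **GC–IMS side** — internal-standard normalization, monomer/dimer
   deduplication, OPLS–DA VIP marker screening (S vs P2; P2 vs P56),
   composite flavor and deterioration indices as PLS1 latent scores.
3. **NIRS side** — stratified 80/20 spectrum-level split, seven
   preprocessing methods, PLS1 calibration with 5-fold-CV latent-variable
   selection (grid 1–10), test-set R²/RMSE/RPD, regression-coefficient
   region analysis, and 200-iteration permutation validation.

## The synthetic-data generator

### NIR spectra

Each sample's noise-free spectrum is a Beer–Lambert mixture of Gaussian
bands, `a(λ) = Σ_k c_k(m)·Σ_b A_kb exp(−(λ−μ_kb)²/2σ_kb²)`, over five
latent components: water and a carbohydrate/protein background (constant in
storage months `m`), the lipid substrate (exponentially consumed,
`1 − 0.30(1 − e^{−m/25})`), oxidation products (logistic rise centered at
20 months, monotone nondecreasing — the invariant every region-recovery
check relies on) and a roasting component present only in processed
material (`e^{−m/80}`). On the long-wave grid the oxidation bands sit at
1450 and 1920 nm — inside the 1300–1500 / 1800–2000 nm combination-band
regions of O–H and C=O groups formed by lipid oxidation — with roughly
twice the amplitude of their short-wave counterparts, so the long-wave
instrument carries the stronger deterioration signal by construction.

Per spectrum the mixture is distorted by a multiplicative slope `(1+s)` and
an additive offset (s, o ~ Normal with SD 0.05 and 0.02 respectively, each
split 50/50 in variance between the subsample and scan levels; no
within-sample variance decomposition is reported for such acquisitions, so
the equal split is a config-exposed default) plus white noise of SD 0.002 AU — scatter
dispersions and noise typical of handheld diffuse-reflectance instruments.
The generator emits absorbance; an optional reflectance mode emits
`R = 10^{−a}` to exercise the `log10(1/R)` conversion operator.

### GC–IMS volatiles

74 compounds in the reported class census (19 aldehydes, 18 alcohols, 13
ketones, 9 esters, 6 acids, 3 pyrazines, 2 furans, 4 other). Each class
follows a smooth trend family in storage months, drawn per compound with
randomized parameters: logistic **rise** (aldehydes, acids, furans — lipid
oxidation products), exponential **fall** (alcohols), Gaussian
**dip-then-rebound** (ketones), late-centered logistic (esters),
**processing pulse** (pyrazines: created by roasting, absent in raw
material, slowly fading) and flat (other). Processing multipliers per class
encode the roasting chemistry (pyrazines ×3–8, furans ×2–5, alcohols
×0.35–0.8, …).

A volume is `base × processing^(processed) × trend(m) × injection ×
replicate-noise`. The injection factor (log-normal, SD 0.15) is shared by
every compound of one replicate including the 2-octanol-D internal
standard, so internal-standard division cancels it exactly; replicate noise
(log-normal, SD 0.05) is compound-independent. Injection variability
dominating replicate noise is deliberate — it is the premise of
internal-standard normalization, which must strictly reduce
between-replicate CV to be worth performing. 30% of each class's compounds
are emitted as monomer+dimer pairs sharing one CAS number and one trend up
to a fixed per-compound ratio (0.25–0.6).

`true_index` provides generator-side ground truth for recovery tests:
linear in months, scaled to exactly 6 dimensionless units across the
2–56-month span.

### What the generator does not emulate

No drift-tube physics, retention indices or 2-D IMS topology; no
Maillard-reaction kinetics (trends are phenomenological curves); no
instrument drift over an acquisition session, wavelength-correlated noise,
temperature/moisture effects, or between-batch biological variability; and
within-sample spectral heterogeneity is a two-level Gaussian, not real
particle-packing structure. Passing tests therefore demonstrate that the
*procedures* behave correctly under the assumed statistical structure —
monotone class trends, multiplicative injection effects, band-localized
oxidation signal — not that the numerical performance transfers to real
seeds.

## Numerical and design choices

* **Absorbance convention**: reflectance → absorbance is `log10(1/R)`
  (the universal NIRS convention); `R ≤ 0` is a hard error naming the cell.
* **Preprocessing order**: scatter correction (MSC or SNV) first, then the
  Savitzky–Golay first derivative for the *FD methods, then Min–Max — the
  derivative of a scatter-corrected spectrum is the standard composition;
  Min–Max is applied last and per wavelength using training statistics
  (per-spectrum scaling would duplicate SNV). SGFD computes smoothing and
  derivative in a single SG filter (window 11, polyorder 2 by default —
  common choices at 3.5–4.7 nm grid spacing; both exposed). Derivatives are
  per nm (`delta` = grid spacing); filter edges use the boundary polynomial
  fits, preserving length.
* **MSC reference** is the mean training spectrum, stored in the fitted
  state together with the Min–Max bounds; held-out spectra are always
  transformed with training statistics (checksummed, and asserted not to
  move when test rows change).
* **PLS1 scaling**: spectra are centered only (derivative spectra have
  meaningful relative magnitudes); GC–IMS marker matrices are centered and
  autoscaled (peak volumes span decades). Both are switches.
* **Cross-validated R²** (R²cv, and Q² in the permutation test) is computed
  from pooled out-of-fold residuals, not averaged per fold — stable for
  small folds. LV ties break toward fewer components. Fold assignment is
  deterministic given the seed and stratification labels; it depends on row
  order (the splitter enumerates rows within each stratum), which is fixed
  by the pipeline.
* **OPLS–DA**: class coded {0,1} and centered; accuracy cutoff at the 0.5
  midpoint; the orthogonal-component count starts at 0 and grows while CV
  Q² improves by more than 0.01, capped at 3 (standard practice at these
  sample sizes). CV folds keep all replicates of one physical sample
  together whenever each class contains more than one sample; in the
  study's own contrasts each class *is* one sample, so folds stratify at
  replicate level there — the only feasible choice.
* **Deduplication rule**: for a monomer/dimer pair the form with the higher
  stability ratio (mean volume / mean within-sample replicate CV) is
  retained; ties go to the monomer. The Spearman correlation of the two
  forms' sample-mean profiles is logged as a consistency check.
* **Composite index**: markers from the OPLS–DA screens (VIP > 1),
  replicates averaged to sample level before fitting, index = first
  latent-variable score (a single continuous metric; summing further LV
  contributions is a config option), sign-oriented to correlate positively
  with the response. The flavor response is the 0/1 processing stage over
  all 7 samples; the deterioration response is storage months on the
  natural scale over the 6 processed samples (raw excluded). The per-sample
  index value is attached to all 50 spectra of that sample for NIRS
  calibration.
* **Split protocol**: stratified by storage class at spectrum level,
  reproducing the study's protocol even though spectra of one physical
  sample then appear on both sides of the split; a sample-grouped mode
  would give the honest generalization estimate but is infeasible when
  every class is a single sample, and raises with an explanatory error.
* **Classification screen** uses stratified 10-fold CV (the screen's own
  reporting convention) while all PLSR model selection uses 5-fold CV.
* **Permutation test**: the preprocessing and LV count are frozen before
  permuting; each of the 200 iterations shuffles the response at spectrum
  level, refits, and records training R², pooled 5-fold CV Q² and the
  absolute correlation with the original response. Intercepts come from
  ordinary least squares over the (correlation, metric) pairs including the
  unpermuted model at correlation 1. Fewer than 20 iterations triggers an
  instability warning.

## Problem sizes in the test suite

The default acquisition (7×50 spectra, 74 compounds × 3 replicates) is used
for the shared end-to-end fixture, including all four 200-iteration
permutation tests, and for the 20-replicate coefficient-region recovery
study; classifier unit tests use a reduced 7×6-spectrum acquisition. The
whole suite runs in well under a minute on one core.

## Known limitations

* **VIP screening at two samples × three replicates is liberal.** With six
  observations a truly uninformative compound's sample correlation with the
  class contrast follows the fat-tailed t₄-induced distribution
  (SD ≈ 0.45), and VIP > 1 corresponds to roughly |r| > 0.66, so each null
  compound clears the threshold with probability ≈ 0.15. Planted-contrast
  simulations in the test suite show the consequence: discriminating
  compounds are recovered essentially always (and occupy the top VIP ranks
  with perfect purity), but a handful of false positives above VIP 1 is the
  expected behavior, not a defect — at this design size the VIP > 1 cut
  controls ranking, not the false-discovery count. Downstream stages are
  insensitive to this: the composite index re-weights markers by a PLS fit,
  so weakly informative extras receive near-zero weight.
* Spectrum-level splitting means test spectra share physical samples with
  training spectra; reported R²p/RPDp measure within-cohort prediction, not
  new-sample generalization (mirrors the protocol being reproduced).
* OPLS–DA diagnostics on 6–21 observations (R²Y, Q² near 1) reflect the
  tiny-n regime and are treated as qualitative separation evidence only.
* The generator's trend smoothness makes six storage durations nearly
  noise-free after replicate averaging; real biological replication would
  lower index precision and every downstream metric.
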